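# circkit

Post-discovery analysis of circular RNAs (circRNAs) from RNA-seq data:
annotation-based classification of back-splice (BS) events, reconstruction
of BS junction sequences from a genome, and alignment-free quantification
of junction-supporting reads, together with the null-sequence control
constructions used to interrogate such sets.

circRNAs arise when a downstream splice donor is joined back to an
upstream splice acceptor, producing a covalently closed transcript whose
junction sequence does not exist in any linear isoform. Reads spanning
that junction are the only direct RNA-seq evidence of a circRNA. circkit
takes BS coordinates produced by a discovery tool (CIRI-style TSV or
BED), a reference transcriptome (Ensembl-style GTF) and a genome FASTA,
and is aimed at anyone who needs to characterize and quantify a circRNA
set across many sequencing libraries without re-running discovery.

## What it computes

**Classification.** Each circRNA/transcript overlap falls in exactly one
of five classes — *multiexonic* (both BS sites on the boundaries of two
different exons), *monoexonic* (one full exon), *putative exonic* (BS
sites inside exons but off boundary), *intronic* (a BS site inside an
intron) and *intergenic* (a BS site beyond the gene span) — applied with
the precedence intergenic > intronic > boundary-exact > putative. The
univocal per-circRNA class comes from the host gene's main isoform
(Ensembl "-001" name suffix), falling back to annotation order. Names
follow `Circ_<GENE>_<r5>-<r3>` (exon ranks, strand-aware), `Circ_<GENE>_<r>`
for monoexonic, `I`/`PE` suffixes for intronic/putative, and genomic
coordinates for intergenic circRNAs.

**Junction reconstruction.** The reference sequence for a circRNA is the
±L genomic window around the BS point read in transcript orientation
(default L = 35, 70-bp junctions): the last L bases of the circularized
region followed by its first L bases. Circles shorter than 2L are split
in two halves and rotated so the BS point is centered.

**Quantification (two-stage).** Stage 1 decomposes the junction set s₁
into k-mers (sliding window) and hashes them into a membership function
`isPresent: {A,C,G,T}^k → {0,1}`. Stage 2 selects a read as putative when
at least N of its k-mers are present. Stage 3 aligns each putative read
against every junction with local Smith-Waterman (match 2, mismatch −2,
affine gaps 3/1) and increments the single best-scoring junction iff the
alignment reaches M matched bases. Defaults are k = 26, N = 21, M = 40;
scale them with read length. The exhaustive no-filter pipeline is
available as an oracle (`exhaustive_counts`) to audit what filtering
loses.

**Controls and scores.** Chimeric control sets by derangement re-pairing
of junction halves; per-sequence nucleotide shuffles; intron-length-
matched control-gene pairing (1,000 iterations by default); divergent
(inverted) repeat-pair detection in 500-bp intronic BS flanks;
coverage-style interval read counting; and the per-base signal ratio
between a 5′ circularizing exon and its upstream exon.

A synthetic-data module generates a toy genome, gene models, planted
circRNAs of all five categories and reads with known truth counts, so the
entire pipeline is testable offline.

## Worked example

```python
from circkit import (SimulationSpec, make_reference, plant_circrnas, simulate_reads,
                     classify_all, JunctionParams, HashCircParams, hashcirc_run)
from circkit.junction import build_all

spec = SimulationSpec(seed=1, circs_per_category={"multiexonic": 3, "intronic": 1})
ref = make_reference(spec)
circs, truth = plant_circrnas(ref, spec)

for cls in classify_all(circs, ref.transcripts):
    print(f"{cls.circ_id}  {cls.category.value:<12} {cls.name}")

junctions = build_all(circs, ref.genome, JunctionParams(L=35))
refs = {j.circ_id: j.sequence for j in junctions}
reads, truth_counts = simulate_reads(ref, circs, spec)
params = HashCircParams(k=15, n_min=6, m_min=40)   # scaled to 50-nt reads
table = hashcirc_run({"sample1": reads["sample1"]}, refs, params)
print(table.counts)
print(table.stats["sample1"])
```

prints

```
sim_multiexonic_001  multiexonic  Circ_GENE4_2-4
sim_multiexonic_002  multiexonic  Circ_GENE4_4-6
sim_multiexonic_003  multiexonic  Circ_GENE4_1-6
sim_intronic_004  intronic     Circ_GENE5_I
                     sample1
sim_intronic_004          99
sim_multiexonic_001      100
sim_multiexonic_002       98
sim_multiexonic_003      100
{'selected': 407, 'counted': 397, 'scanned': 1100}
```

Each planted circRNA is classified back to its category and named from
its host gene and exon ranks. The count table recovers 98–100 of the 100
planted junction reads per circRNA at a 1% substitution error rate; of
1,100 reads scanned, 407 pass the k-mer pre-filter and 397 survive the
alignment threshold — the 400 linear and 300 background reads contribute
no junction counts.

The same pipeline is available from the shell:

```sh
circkit simulate --out run/
circkit classify --gtf run/ann.gtf --circ run/circs.bed --dialect bed --out classified.tsv
circkit junction --genome run/genome.fa --circ classified.tsv --out junctions.fa
circkit quantify --junctions junctions.fa --reads run/reads_sample1.fq.gz \
        -k 15 -N 6 -M 40 --out counts.tsv --report run.json
```

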