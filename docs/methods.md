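# Methods

## Coordinate model

All coordinates are 0-based half-open internally; readers convert from
the CIRI convention (1-based inclusive) and writers convert back, so
off-by-one ambiguity is confined to I/O. Exon rank is strand-aware: rank
1 is the 5′-most exon in transcript orientation, i.e. on the minus strand
the exon with the largest genomic end. A back-splice (BS) event is stored
as the genomic span of the circularized region; the two BS sites are
derived, in transcript orientation, as the 5′-most base of the 5′
circularizing exon (5′CE) and the 3′-most base of the 3′CE. Ambiguous
bases are normalized to N and preserved in length.

## Classification

Each circRNA/transcript overlap is classified by a fixed-precedence
decision tree: (1) a BS site beyond the gene span ⇒ intergenic; (2) else
a BS site in an intron ⇒ intronic; (3) else both sites exactly on exon
boundaries ⇒ monoexonic (same exon) or multiexonic (two exons), with exon
ranks recorded; (4) else putative exonic. The precedence makes the five
classes mutually exclusive under the "at least one site" wording of the
intronic/intergenic definitions. Monoexonic requires an exact boundary
match of both sites on one exon; an exon that merely contains both sites
is putative exonic, keeping "no precise boundary match" and "spans the
entire region" disjoint. Boundary matching is exact by default; a
`wobble` tolerance (bp) is available for annotation-mismatch studies.

Univocal resolution: candidate transcripts are those sharing chromosome
and strand whose gene span overlaps the circRNA span. Each overlapping
gene is represented by its main isoform — transcript name ending in
"001" after a `-`/`.` separator — or, absent one, by its first-seen
isoform in annotation order. When several genes overlap, the
representative classification with the highest precedence
(boundary-exact > putative > intronic > intergenic) wins, ties broken by
annotation order; for a single gene this reduces to the main-isoform /
file-order rule. No overlapping gene ⇒ intergenic with a null transcript.

Names: `Circ_<GENE>_<r>` (monoexonic), `Circ_<GENE>_<r5>-<r3>`
(multiexonic), `Circ_<GENE>_I` (intronic), `Circ_<GENE>_PE` (putative —
no published convention exists for this class, the `PE` suffix is ours),
and `Circ_<chrom>:<start>-<end>(<strand>)` with 1-based inclusive display
coordinates for intergenic circRNAs.

## Junction reconstruction

The junction reference of a circle of oriented sequence S is
`S[-L:] + S[:L]` (default L = 35 nt, 70-bp junctions). Flanks are
*genomic* windows: introns retained inside the circle are not spliced
out, and for exons shorter than L the window simply continues across the
neighboring intron — both flanks abut the BS sites, which sit on exon
boundaries, so this is the sequence a junction-spanning read actually
carries. A spliced-flank variant was considered and rejected: it would
require transcript-aware stitching and does not correspond to the genomic
window definition used throughout.

Circles shorter than 2L are rotated by h = ⌈|S|/2⌉: the junction is
`S[h:] + S[:h]`, so odd lengths place the extra base upstream of the BS
point. In both cases `junction_offset` indexes the first base after the
BS point and `(sequence[offset-1], sequence[offset])` equals the circle's
(last, first) base pair.

## Two-stage quantification

Stage 1 indexes every k-mer of the junction set (sliding window; k-mers
containing N are never indexed). Unstranded mode (default) also indexes
reverse-complement k-mers, since library strandedness is usually unknown.
Stage 2 selects a read when **at least** N of its k-mers are present in
the union index. "At least" (rather than "strictly more than") is the
reading consistent with the published parameter arithmetic — a 50-nt
error-free junction-spanning read shares at most 25 26-mers, so N = 21
only admits it under ≥ — and a `strict_gt` flag restores the other
reading. A per-reference selection mode (maximum shared count against any
single junction) is available behind `per_reference`; the union index is
the default because it is what the hash membership function computes.

Stage 3 scores each putative read against every junction with local
Smith-Waterman under the SIMD-SW library convention: match +2, mismatch
−2, gap open 3, gap extend 1, a length-l gap costing 3 + (l−1). The
implementation is Biopython's `PairwiseAligner` (verified against a
hand-written Gotoh dynamic program in the tests). Each read increments
exactly one junction — the best-scoring one, ties broken by
lexicographically smallest id — iff the alignment reaches the counting
threshold M.

**M is a matched-base threshold.** A read is counted when its best local
score is at least `sw_match · M`, i.e. M net matched bases (M = 40 ⇒
score ≥ 80). Reading M as a raw score (M = 40 ⇒ 20 bases) makes the
stage-3 threshold weaker than the stage-1 filter: measured on random
50-nt/70-nt pairs under this scoring, local scores ≥ 30 occur at ~4×10⁻³
per pair, so an unfiltered aligner would count reads that share no k-mer
with the index and the two stages could never agree. Under the
matched-base reading the random tail at the default thresholds is
negligible and the filter is score-consistent. The raw-score reading
remains available via `m_units="score"`.

Parameter scaling: thresholds must track read length. For a read of
length R fully inside a 2L junction window, the filter tolerates e
substitutions when `R − k + 1 − e·k ≥ N`. The package defaults
(k=26, N=21, M=40) suit ~100-nt reads; the tests and the acceptance
script quantify 50-nt simulated reads at (k=15, N=6, M=40), chosen by
this arithmetic so that any read with ≤2 substitutions stays selectable
while a full one-flank linear match (35 matched bases) stays below
M = L + 5 = 40 and can never be counted.

Guaranteed properties (all tested): raising N or M never increases any
count; counted ≤ selected ≤ scanned per sample; reverse-complementing
every read leaves the unstranded count table unchanged; output is
deterministic for fixed inputs.

Scope of the filter-equivalence guarantee: the two-stage pipeline equals
the exhaustive no-filter pipeline only for libraries whose non-junction
reads stay below M against every junction. Reads from a host transcript
that overlap a circularizing-exon flank by ≥ M but < N + k − 1 bases sit
in an inherently unsound band — alignable above threshold yet sharing
fewer than N k-mers. The equivalence fixture therefore draws its linear
reads from non-circularized genes; host-derived flank reads are a
documented limitation of any such two-stage scheme, not of this
implementation.

## Control constructions

*Half permutation*: each control set re-pairs junction left halves (the
sequence upstream of the BS point) with right halves of different
junctions via a uniform random derangement, conserving both half
multisets while guaranteeing that no control equals an original junction
(resampled in the vanishingly rare colliding case). A within-sequence
half swap was rejected as it preserves too much local sequence to serve
as a null. *Shuffle*: a uniform permutation of each sequence's
nucleotides, conserving per-sequence length and composition exactly.
Both are bit-reproducible from `(seed, inputs, n_sets)`.

*Intron-length pairing*: per iteration (default 1,000) each host gene is
paired with a uniformly drawn control whose first-intron length is within
±10% relative difference; with no qualifying candidate the nearest-length
control is used and flagged. Controls may be reused across hosts.

*Divergent repeats*: the upstream flank covers `flank` bases (default
500) 5′ of the 5′ BS site and the downstream flank the same span from the
3′ site, both in transcript orientation; a qualifying pair is one repeat
overlapping each flank with opposite strands (the inverted configuration
that permits intron pairing). Orientation is not refined further.

*Interval counting* is coverageBed-style: a fragment counts for an
interval iff they overlap by ≥1 bp, once per interval. The *exon signal
ratio* is `(d₅ + ε) / (d_up + ε)` on per-base densities, ε = 0.1 per
base; per-base normalization is applied because exon lengths differ, and
the score is undefined (records skipped with a warning) when the 5′CE is
exon 1.

## Synthetic fixtures

The generator emits uniform-random chromosomes, non-overlapping genes
with 4–8 exons of 120–300 bp separated by 200–600 bp introns, randomized
strand, and one "-001"-named isoform per gene. circRNAs are planted so
the classifier must recover each category: exact exon-boundary pairs
(multiexonic), one full exon (monoexonic), +3 bp inside exon boundaries
(putative), a 5′ site mid-intron (intronic), and inter-gene spans
(intergenic). Reads are single-end 50 nt with i.i.d. substitutions at 1%
per base and constant qualities; BS reads are windows of the rotated
circle crossing the BS point, with the crossing offset uniform over the
positions that keep the read inside the 2L junction window — i.e. every
emitted junction read is in principle recoverable, which is what makes
truth counts exact rather than upper bounds. Linear reads are windows of
spliced transcript sequence (optionally restricted to non-host genes) and
background reads are uniform random. Depth defaults: 100 BS reads per
junction, matching the depth at which recovery is evaluated.

Problem sizes in the test suite and acceptance script — 10–50 junctions,
1,100–2,600 reads per library — were chosen as the smallest fixtures at
which every contract (exact truth recovery, filter/oracle equality,
specificity) is exercised with comfortable statistical margin; the
algorithms scale linearly in reads × junctions.

What passing these fixtures does *not* show: behaviour on repetitive or
biased genomes (k-mer collisions between unrelated loci), indel-dominated
error profiles, degraded or very short reads, and annotation errors.
Uniform-random sequence makes cross-junction k-mer collisions vanishingly
rare; on a real genome, paralogy and repeats can inflate both selection
and counting, which is why M should be kept near the read length and why
divergent-repeat flanks are analyzed separately.

## Numerical and degenerate-input choices

Ties in best-hit counting go to the lexicographically smallest junction
id (deterministic and input-order independent). Reads shorter than k are
never selected. An all-N junction is emitted with a warning; k-mers
containing N never match. Coordinate records with start ≥ end are
rejected and logged rather than fatal. Derangement sampling is by
rejection (expected ~e draws); for two junctions the swap is forced. All
stochastic operations take explicit seeds and use independent
deterministic substreams per stage and sample.

## Known limitations

Only the junction window is reconstructed, not the full circle sequence;
single-end quantification (mate-pair evidence such as intron retention is
out of scope); counts are raw — normalization and differential expression
belong to dedicated count-based tools; no quality trimming; discovery of
circRNAs and read alignment to the genome are upstream of this package.
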