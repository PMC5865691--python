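"""Synthetic fixture generator with known ground truth.

Emulates the kind of data the tool targets — a genome, multi-exon gene
models, circRNAs of all five classification categories planted at exact
known positions, and single-end FASTQ reads containing back-splice-
spanning, linear-splice and background sequences at known counts — so the
whole pipeline is testable without any external download.

What it deliberately does not emulate: realistic base composition and
repeat structure (chromosomes are uniform random ACGT, which makes k-mer
collisions between unrelated regions vanishingly rare), quality-score or
indel error models (substitutions only, constant qualities), and
paired-end mates.  Conclusions drawn from these fixtures are about the
algorithmic contracts, not about performance on real libraries.

Read names carry provenance (``class|origin|offset|serial``) so truth
reconciliation needs no auxiliary files.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as ckio
from .classify import Category
from .junction import JunctionParams, build_bs_sequence
from .model import CircRecord, ExonAnnotation, GenomicInterval, TranscriptModel

BASES = np.array(list("ACGT"))

DEFAULT_CATEGORY_COUNTS = {
    "multiexonic": 2,
    "monoexonic": 2,
    "putative_exonic": 2,
    "intronic": 2,
    "intergenic": 2,
}


@dataclass
class SimulationSpec:
    """Study conditions for the synthetic fixtures.

    Gene geometry (exon/intron length ranges) is scaled so flanking
    windows of the default 35 bp always fit inside single exons; reads
    are 50 nt with a 1% per-base substitution rate and a back-splice
    depth of 100 reads per junction, matching the depth at which
    recovery is evaluated.
    """

    seed: int = 0
    n_chroms: int = 1
    chrom_length: int = 60_000
    n_genes: int = 6
    exons_per_gene: tuple[int, int] = (4, 8)
    exon_length: tuple[int, int] = (120, 300)
    intron_length: tuple[int, int] = (200, 600)
    circs_per_category: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_COUNTS)
    )
    bs_depth: int = 100
    linear_reads: int = 500
    background_reads: int = 200
    read_length: int = 50
    error_rate: float = 0.01
    flank: int = 35
    linear_source: str = "all"  # "all" or "nonhost"

    def __post_init__(self) -> None:
        if not (0 <= self.error_rate < 1):
            raise ValueError("error rate must be in [0, 1)")
        if self.read_length < 2:
            raise ValueError("read_length must be >= 2 to cross a junction")
        for name in ("bs_depth", "linear_reads", "background_reads"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.linear_source not in ("all", "nonhost"):
            raise ValueError("linear_source must be 'all' or 'nonhost'")

    @classmethod
    def from_yaml(cls, path) -> "SimulationSpec":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        for key in ("exons_per_gene", "exon_length", "intron_length"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


@dataclass
class Reference:
    genome: dict[str, str]
    transcripts: list[TranscriptModel]

    def transcript(self, tid: str) -> TranscriptModel:
        return next(t for t in self.transcripts if t.transcript_id == tid)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(BASES, size=n))


def make_reference(spec: SimulationSpec) -> Reference:
    """Generate a random genome and non-overlapping multi-exon gene models."""
    rng = np.random.default_rng([spec.seed, 0])
    genome = {
        f"chr{i + 1}": _random_seq(rng, spec.chrom_length)
        for i in range(spec.n_chroms)
    }
    transcripts: list[TranscriptModel] = []
    chrom_names = list(genome)
    per_chrom = math.ceil(spec.n_genes / spec.n_chroms)
    gi = 0
    for chrom in chrom_names:
        cursor = 600  # leave intergenic margin at chromosome edges
        for _ in range(per_chrom):
            if gi >= spec.n_genes:
                break
            n_exons = int(rng.integers(spec.exons_per_gene[0], spec.exons_per_gene[1] + 1))
            exon_lens = rng.integers(spec.exon_length[0], spec.exon_length[1] + 1, n_exons)
            intron_lens = rng.integers(
                spec.intron_length[0], spec.intron_length[1] + 1, max(n_exons - 1, 0)
            )
            gene_len = int(exon_lens.sum() + intron_lens.sum())
            gap = int(rng.integers(800, 1500))
            if cursor + gene_len + gap + 600 > spec.chrom_length:
                raise ValueError(
                    f"chromosome {chrom} too short for {spec.n_genes} genes of "
                    "the requested geometry"
                )
            strand = "+" if rng.random() < 0.5 else "-"
            ivs = []
            pos = cursor
            for j in range(n_exons):
                ivs.append(GenomicInterval(chrom, pos, pos + int(exon_lens[j]), strand))
                pos += int(exon_lens[j])
                if j < n_exons - 1:
                    pos += int(intron_lens[j])
            if strand == "-":
                ivs = ivs[::-1]  # rank 1 = genomically last exon
            gene = f"GENE{gi + 1}"
            tid = f"t{gi + 1}"
            span = GenomicInterval(chrom, cursor, pos, strand)
            exons = [ExonAnnotation(iv, tid, r) for r, iv in enumerate(ivs, start=1)]
            transcripts.append(
                TranscriptModel(
                    transcript_id=tid,
                    transcript_name=f"{gene}-001",
                    gene_id=f"g{gi + 1}",
                    gene_symbol=gene,
                    gene_span=span,
                    exons=exons,
                    source_order=gi,
                )
            )
            cursor = pos + gap
            gi += 1
    if gi < spec.n_genes:
        raise ValueError("not enough chromosome space for requested genes")
    return Reference(genome, transcripts)


def _span_from_sites(chrom: str, strand: str, bs5: int, bs3: int) -> GenomicInterval:
    if strand == "+":
        return GenomicInterval(chrom, bs5, bs3 + 1, strand)
    return GenomicInterval(chrom, bs3, bs5 + 1, strand)


def plant_circrnas(
    reference: Reference, spec: SimulationSpec
) -> tuple[list[CircRecord], pd.DataFrame]:
    """Plant circRNAs so the classifier must recover each requested category.

    Multiexonic circles sit exactly on the boundaries of two distinct
    exons, monoexonic on one full exon, putative-exonic 3 bp inside exon
    boundaries, intronic with the 5' site mid-intron, and intergenic
    between genes.  Returns the records plus a truth table with category,
    host transcript, exon ranks and the expected name.
    """
    rng = np.random.default_rng([spec.seed, 1])
    transcripts = reference.transcripts
    circs: list[CircRecord] = []
    truth_rows: list[dict] = []
    used_multi: set[tuple[str, int, int]] = set()
    host_genes: set[str] = set()
    serial = 0

    def add(circ: CircRecord, category: str, t: TranscriptModel | None,
            r5: int | None, r3: int | None, name: str) -> None:
        circs.append(circ)
        truth_rows.append(
            {
                "circ_id": circ.circ_id,
                "category": category,
                "transcript_id": t.transcript_id if t else "",
                "gene_symbol": t.gene_symbol if t else "",
                "rank5": r5,
                "rank3": r3,
                "chrom": circ.chrom,
                "start": circ.span.start,
                "end": circ.span.end,
                "strand": circ.strand,
                "name": name,
            }
        )

    for category, n_wanted in spec.circs_per_category.items():
        Category(category)  # validates the key
        for _ in range(n_wanted):
            serial += 1
            cid = f"sim_{category}_{serial:03d}"
            if category == "intergenic":
                circ = _plant_intergenic(reference, rng, cid)
                add(circ, category, None, None, None,
                    f"Circ_{circ.chrom}:{circ.span.start + 1}-{circ.span.end}"
                    f"({circ.strand})")
                continue
            t = _pick_host(transcripts, rng, category, used_multi)
            if t is None:
                raise ValueError(
                    f"no gene structure can host a {category} circRNA"
                )
            host_genes.add(t.gene_id)
            chrom, strand = t.chrom, t.strand
            if category == "multiexonic":
                for _try in range(200):
                    r5 = int(rng.integers(1, len(t.exons)))
                    r3 = int(rng.integers(r5 + 1, len(t.exons) + 1))
                    if (t.transcript_id, r5, r3) not in used_multi:
                        break
                else:
                    raise ValueError("cannot find unused exon pair for multiexonic")
                used_multi.add((t.transcript_id, r5, r3))
                bs5 = t.exon_by_rank(r5).five_prime
                bs3 = t.exon_by_rank(r3).three_prime
                circ = CircRecord(cid, _span_from_sites(chrom, strand, bs5, bs3))
                add(circ, category, t, r5, r3, f"Circ_{t.gene_symbol}_{r5}-{r3}")
            elif category == "monoexonic":
                r = int(rng.integers(1, len(t.exons) + 1))
                e = t.exon_by_rank(r)
                circ = CircRecord(cid, _span_from_sites(chrom, strand, e.five_prime, e.three_prime))
                add(circ, category, t, r, r, f"Circ_{t.gene_symbol}_{r}")
            elif category == "putative_exonic":
                r5 = 1
                r3 = len(t.exons)
                e5, e3 = t.exon_by_rank(r5), t.exon_by_rank(r3)
                shift = 1 if strand == "+" else -1
                bs5 = e5.five_prime + 3 * shift
                bs3 = e3.three_prime - 3 * shift
                circ = CircRecord(cid, _span_from_sites(chrom, strand, bs5, bs3))
                add(circ, category, t, None, None, f"Circ_{t.gene_symbol}_PE")
            elif category == "intronic":
                # 5' site mid first intron (transcript orientation)
                e1, e2 = t.exon_by_rank(1).interval, t.exon_by_rank(2).interval
                lo, hi = (e1.end, e2.start) if strand == "+" else (e2.end, e1.start)
                bs5 = (lo + hi) // 2
                bs3 = t.exon_by_rank(len(t.exons)).three_prime
                circ = CircRecord(cid, _span_from_sites(chrom, strand, bs5, bs3))
                add(circ, category, t, None, None, f"Circ_{t.gene_symbol}_I")
            else:  # pragma: no cover - guarded by Category() above
                raise ValueError(category)

    truth = pd.DataFrame(truth_rows)
    if not truth.empty:
        truth.attrs["host_gene_ids"] = sorted(host_genes)
    return circs, truth


def _pick_host(transcripts, rng, category: str, used_multi) -> TranscriptModel | None:
    if category == "multiexonic":
        ok = [
            t for t in transcripts
            if len(t.exons) >= 2
            and any(
                (t.transcript_id, a, b) not in used_multi
                for a in range(1, len(t.exons))
                for b in range(a + 1, len(t.exons) + 1)
            )
        ]
    elif category == "intronic":
        ok = [t for t in transcripts if len(t.exons) >= 2]
    else:
        ok = list(transcripts)
    if not ok:
        return None
    return ok[int(rng.integers(len(ok)))]


def _plant_intergenic(reference: Reference, rng, cid: str) -> CircRecord:
    spans_by_chrom: dict[str, list[GenomicInterval]] = {}
    for t in reference.transcripts:
        spans_by_chrom.setdefault(t.chrom, []).append(t.gene_span)
    for chrom, seq in reference.genome.items():
        spans = sorted(spans_by_chrom.get(chrom, []), key=lambda s: s.start)
        edges = [0] + [s.end for s in spans]
        next_starts = [s.start for s in spans] + [len(seq)]
        gaps = [
            (lo + 100, hi - 100)
            for lo, hi in zip(edges, next_starts)
            if hi - lo > 500
        ]
        if gaps:
            lo, hi = gaps[int(rng.integers(len(gaps)))]
            length = int(rng.integers(150, min(300, hi - lo)))
            start = int(rng.integers(lo, hi - length))
            strand = "+" if rng.random() < 0.5 else "-"
            return CircRecord(cid, GenomicInterval(chrom, start, start + length, strand))
    raise ValueError("no intergenic space available to plant a circRNA")


# ---------------------------------------------------------------------------
# read simulation

def spliced_sequence(reference: Reference, t: TranscriptModel) -> str:
    """Exonic (spliced) transcript sequence, 5'->3' in transcript orientation."""
    return "".join(
        ckio.fetch_sequence(reference.genome, e.interval, orient=True)
        for e in t.exons
    )


def _apply_errors(seq: str, rng: np.random.Generator, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.flatnonzero(rng.random(len(arr)) < rate)
    for i in hits:
        current = arr[i].decode()
        choices = [b for b in "ACGT" if b != current]
        arr[i] = choices[int(rng.integers(3))].encode()
    return arr.tobytes().decode()


def simulate_reads(
    reference: Reference,
    circs: Sequence[CircRecord],
    spec: SimulationSpec,
    samples: Sequence[str] = ("sample1",),
    host_gene_ids: Iterable[str] = (),
) -> tuple[dict[str, list[tuple[str, str]]], pd.DataFrame]:
    """Emit per-sample reads with exact per-junction truth counts.

    Back-splice reads are windows of the circle sequence crossing the
    back-splice point, with the crossing offset drawn uniformly among the
    positions at which the read lies within the 2*flank junction window
    (so every emitted junction read is in principle recoverable by the
    quantifier).  Linear reads are windows of spliced transcript sequence
    and never cross a back-splice; background reads are uniform random.
    Substitution errors are applied i.i.d. per base.
    """
    rl = spec.read_length
    L = spec.flank
    if rl > 2 * L:
        raise ValueError("read_length must be <= 2*flank")
    host = set(host_gene_ids)
    lin_pool = [
        t for t in reference.transcripts
        if spec.linear_source == "all" or t.gene_id not in host
    ]
    out: dict[str, list[tuple[str, str]]] = {}
    truth = pd.DataFrame(
        0, index=[c.circ_id for c in circs], columns=list(samples), dtype=int
    )
    for si, sample in enumerate(samples):
        rng = np.random.default_rng([spec.seed, 2, si])
        reads: list[tuple[str, str]] = []
        x_lo, x_hi = max(1, rl - L), min(rl - 1, L)
        for circ in circs:
            circle = ckio.fetch_sequence(reference.genome, circ.span, orient=True)
            if len(circle) < rl:
                raise ValueError(
                    f"circRNA {circ.circ_id} shorter than read length"
                )
            for i in range(spec.bs_depth):
                x = int(rng.integers(x_lo, x_hi + 1))
                read = circle[-x:] + circle[: rl - x]
                read = _apply_errors(read, rng, spec.error_rate)
                reads.append((f"bs|{circ.circ_id}|{x}|{i}", read))
            truth.loc[circ.circ_id, sample] = spec.bs_depth
        if spec.linear_reads and lin_pool:
            spliced = [(t, spliced_sequence(reference, t)) for t in lin_pool]
            spliced = [(t, s) for t, s in spliced if len(s) >= rl]
            for i in range(spec.linear_reads):
                t, s = spliced[int(rng.integers(len(spliced)))]
                pos = int(rng.integers(0, len(s) - rl + 1))
                read = _apply_errors(s[pos : pos + rl], rng, spec.error_rate)
                reads.append((f"lin|{t.transcript_id}|{pos}|{i}", read))
        for i in range(spec.background_reads):
            reads.append((f"bg|||{i}", _random_seq(rng, rl)))
        out[sample] = reads
    return out, truth


# ---------------------------------------------------------------------------
# file output

def write_fastq(reads: Iterable[tuple[str, str]], path) -> None:
    path = str(path)
    opener = gzip.open if path.endswith(".gz") else open
    with opener(path, "wt") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_run(
    outdir,
    reference: Reference,
    circs: Sequence[CircRecord],
    truth_circs: pd.DataFrame,
    reads: Mapping[str, list[tuple[str, str]]],
    truth_counts: pd.DataFrame,
) -> dict[str, str]:
    """Write the complete fixture set (FASTA, GTF, BED, FASTQ, truth TSVs)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"genome": str(outdir / "genome.fa"), "gtf": str(outdir / "ann.gtf"),
             "circs": str(outdir / "circs.bed")}
    ckio.write_fasta(reference.genome.items(), paths["genome"])
    ckio.write_gtf(reference.transcripts, paths["gtf"])
    ckio.write_circ_table(circs, paths["circs"], dialect="bed")
    truth_circs.to_csv(outdir / "truth_circs.tsv", sep="\t", index=False)
    for sample, rs in reads.items():
        p = outdir / f"reads_{sample}.fq.gz"
        write_fastq(rs, p)
        paths[sample] = str(p)
    tc = truth_counts.copy()
    tc.index.name = "circ_id"
    tc.to_csv(outdir / "truth_counts.tsv", sep="\t")
    return paths
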