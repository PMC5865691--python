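"""Two-stage alignment-free quantification of junction-supporting reads.

Stage 1 decomposes the junction reference set into k-mers and builds a
hash membership function ``isPresent`` over them.  Stage 2 selects a read
as putative when at least N of its k-mers are present in the index (the
sliding-window decomposition of a length-l read yields l-k+1 k-mers).
Stage 3 aligns every putative read against every reference with a local
Smith-Waterman (affine gaps) and increments the single best-scoring
reference, provided the alignment reaches at least M matched bases.

Thresholds follow the tool's published settings (k=26, N=21, M=40 for
~100-nt RNA-seq reads); they should be scaled with read length.  M is a
matched-base threshold: a read is counted when its best local score is at
least ``sw_match * M`` (with the default unit match reward of 2, M=40
corresponds to score 80).  A raw-score reading of M is available via
``m_units="score"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd
import pysam
from Bio import Align

from .model import revcomp

log = logging.getLogger("circkit")


@dataclass(frozen=True)
class HashCircParams:
    """Quantifier thresholds and Smith-Waterman scoring.

    k: k-mer length; n_min: minimum shared k-mers for read selection (N);
    m_min: minimum matched bases for a read to be counted (M).  The
    alignment scoring (match 2, mismatch 2, gap open 3, gap extend 1,
    a length-l gap costing open + (l-1)*extend) matches the SIMD
    Smith-Waterman library convention.  With ``stranded=False`` the index
    holds both strands and counting takes the better of read/reverse
    complement.  ``strict_gt`` demands strictly more than N shared k-mers;
    ``per_reference`` counts shared k-mers against each reference
    separately (selection on the maximum) instead of the union index.
    """

    k: int = 26
    n_min: int = 21
    m_min: int = 40
    sw_match: int = 2
    sw_mismatch: int = 2
    sw_gap_open: int = 3
    sw_gap_extend: int = 1
    stranded: bool = False
    strict_gt: bool = False
    per_reference: bool = False
    m_units: str = "matches"  # or "score"

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.n_min < 0 or self.m_min < 0:
            raise ValueError("N and M must be >= 0")
        if self.m_units not in ("matches", "score"):
            raise ValueError("m_units must be 'matches' or 'score'")

    @property
    def score_threshold(self) -> float:
        if self.m_units == "matches":
            return self.sw_match * self.m_min
        return float(self.m_min)

    def make_aligner(self) -> Align.PairwiseAligner:
        al = Align.PairwiseAligner()
        al.mode = "local"
        al.match_score = self.sw_match
        al.mismatch_score = -self.sw_mismatch
        al.open_gap_score = -self.sw_gap_open
        al.extend_gap_score = -self.sw_gap_extend
        return al


def generate_kmers(seq: str, k: int) -> list[str]:
    """Sliding-window k-mer decomposition: seq[i:i+k] for i = 0..len-k.

    Empty for sequences shorter than k.  k-mers containing N are emitted
    (positions are preserved) but are never indexed or matched.
    """
    return [seq[i : i + k] for i in range(len(seq) - k + 1)]


class KmerIndex:
    """Hash membership structure over the k-mers of a reference set."""

    def __init__(self, k: int, stranded: bool = False):
        self.k = k
        self.stranded = stranded
        self._union: set[str] = set()
        self._per_ref: dict[str, set[str]] = {}

    @classmethod
    def build(cls, refs: Mapping[str, str], params: HashCircParams) -> "KmerIndex":
        if not refs:
            raise ValueError("reference set is empty")
        idx = cls(params.k, params.stranded)
        any_long_enough = False
        for name, seq in refs.items():
            seq = seq.upper()
            kmers = {m for m in generate_kmers(seq, params.k) if "N" not in m}
            if len(seq) >= params.k:
                any_long_enough = True
            if not params.stranded:
                kmers |= {revcomp(m) for m in kmers}
            idx._per_ref[name] = kmers
            idx._union |= kmers
        if not any_long_enough:
            raise ValueError(
                f"all reference sequences are shorter than k={params.k}"
            )
        return idx

    def is_present(self, kmer: str) -> bool:
        return kmer in self._union

    def count_shared(self, read: str) -> int:
        """Number of the read's k-mers present in the union index."""
        return sum(1 for m in generate_kmers(read.upper(), self.k) if m in self._union)

    def count_shared_per_reference(self, read: str) -> int:
        """Maximum shared k-mer count against any single reference."""
        kmers = generate_kmers(read.upper(), self.k)
        return max(
            (sum(1 for m in kmers if m in refset) for refset in self._per_ref.values()),
            default=0,
        )


Read = tuple[str, str]  # (name, sequence)


def select_reads(
    reads: Iterable[Read], index: KmerIndex, params: HashCircParams
) -> Iterator[Read]:
    """Yield putative reads: those sharing >= N k-mers with the index.

    Order-preserving and single-pass.  Reads shorter than k have no
    k-mers and are never selected unless N == 0 admits them vacuously —
    by contract a read must be at least k long to be selected, so short
    reads are always dropped.
    """
    counter = (
        index.count_shared_per_reference if params.per_reference else index.count_shared
    )
    for name, seq in reads:
        if len(seq) < params.k:
            continue
        n = counter(seq)
        if (n > params.n_min) if params.strict_gt else (n >= params.n_min):
            yield name, seq


def smith_waterman(a: str, b: str, params: HashCircParams = HashCircParams()) -> float:
    """Best local alignment score of a vs b under the affine-gap scoring."""
    if not a or not b:
        return 0.0
    return params.make_aligner().score(a, b)


@dataclass
class CountTable:
    """Junction x sample read counts plus per-sample run statistics."""

    counts: pd.DataFrame
    stats: dict[str, dict[str, int]] = field(default_factory=dict)

    def write_tsv(self, path) -> None:
        df = self.counts.copy()
        df.index.name = "junction_id"
        df.to_csv(path, sep="\t")


def _best_hit(
    seq: str,
    refs: Sequence[tuple[str, str]],
    aligner: Align.PairwiseAligner,
    stranded: bool,
) -> tuple[str | None, float]:
    """Best-scoring reference for a read; ties go to the smallest ref id.

    ``refs`` must be sorted by id so the first maximal score wins the tie.
    """
    best_id, best_score = None, 0.0
    rc = None if stranded else revcomp(seq)
    for ref_id, ref_seq in refs:
        s = aligner.score(ref_seq, seq)
        if rc is not None:
            s = max(s, aligner.score(ref_seq, rc))
        if s > best_score:
            best_id, best_score = ref_id, s
    return best_id, best_score


def count_reads(
    putative: Iterable[Read],
    refs: Mapping[str, str],
    params: HashCircParams,
    aligner: Align.PairwiseAligner | None = None,
) -> tuple[dict[str, int], dict[str, int]]:
    """Align putative reads and assign each to its single best reference.

    Returns (counts per reference id, stats).  A read increments exactly
    one reference — the one with the maximal Smith-Waterman score, ties
    broken by lexicographically smallest id — iff that score reaches the
    counting threshold derived from M.
    """
    if aligner is None:
        aligner = params.make_aligner()
    ref_items = sorted(refs.items())
    counts = {name: 0 for name, _ in ref_items}
    threshold = params.score_threshold
    n_put = n_counted = 0
    for _, seq in putative:
        n_put += 1
        best_id, best_score = _best_hit(seq, ref_items, aligner, params.stranded)
        if best_id is not None and best_score >= threshold and best_score > 0:
            counts[best_id] += 1
            n_counted += 1
    return counts, {"selected": n_put, "counted": n_counted}


def _read_fastq(path) -> Iterator[Read]:
    import os

    if not os.path.isfile(str(path)):
        raise OSError(f"not a readable FASTQ file: {path}")
    with pysam.FastxFile(str(path)) as fh:
        for i, rec in enumerate(fh):
            if rec.sequence is None:
                raise ValueError(f"{path}: malformed FASTQ record {i}")
            yield rec.name, rec.sequence.upper()


def quantify_sample(
    reads: Iterable[Read], refs: Mapping[str, str], params: HashCircParams
) -> tuple[dict[str, int], dict[str, int]]:
    """Run selection + counting on one read stream."""
    index = KmerIndex.build(refs, params)
    scanned = 0

    def counting(stream):
        nonlocal scanned
        for r in stream:
            scanned += 1
            yield r

    putative = select_reads(counting(reads), index, params)
    counts, stats = count_reads(putative, refs, params)
    stats["scanned"] = scanned
    return counts, stats


def hashcirc_run(
    samples: Mapping[str, object] | Sequence[object],
    junctions: Mapping[str, str] | str,
    params: HashCircParams = HashCircParams(),
    on_error: str = "raise",
) -> CountTable:
    """Quantify junction-supporting reads in one or more FASTQ samples.

    ``samples`` maps sample name to FASTQ path (a plain sequence of paths
    uses file basenames); ``junctions`` is a mapping of junction id to
    sequence or a FASTA path.  With ``on_error="continue"`` a failing
    sample is logged, its column omitted, and the failure recorded in
    ``stats`` so callers can exit non-zero.
    """
    from . import io as ckio

    if isinstance(junctions, (str, bytes)) or hasattr(junctions, "__fspath__"):
        refs = dict(ckio.read_fasta(junctions))
    else:
        refs = dict(junctions)
    if not refs:
        raise ValueError("junction reference set is empty")
    if isinstance(samples, Mapping):
        sample_items = list(samples.items())
    else:
        import os

        sample_items = [(os.path.basename(str(p)).split(".")[0], p) for p in samples]

    columns: dict[str, dict[str, int]] = {}
    stats: dict[str, dict] = {}
    failures: list[str] = []
    for name, path in sample_items:
        try:
            if isinstance(path, (list, tuple)) or (
                hasattr(path, "__iter__") and not isinstance(path, (str, bytes))
                and not hasattr(path, "__fspath__")
            ):
                stream: Iterable[Read] = path
            else:
                stream = _read_fastq(path)
            counts, st = quantify_sample(stream, refs, params)
        except (OSError, ValueError) as exc:
            if on_error == "raise":
                raise
            log.error("sample %s failed: %s", name, exc)
            failures.append(name)
            continue
        columns[name] = counts
        stats[name] = st
        log.info(
            "sample %s: scanned=%d selected=%d counted=%d",
            name, st["scanned"], st["selected"], st["counted"],
        )
    df = pd.DataFrame(
        {name: pd.Series(col) for name, col in columns.items()},
        index=sorted(refs),
    ).fillna(0).astype(int)
    df = df[[n for n, _ in sample_items if n in df.columns]]
    table = CountTable(df, stats)
    if failures:
        table.stats["_failures"] = {name: 1 for name in failures}
    return table


def exhaustive_counts(
    reads: Iterable[Read], refs: Mapping[str, str], params: HashCircParams
) -> dict[str, int]:
    """Reference pipeline with no k-mer pre-filter: Smith-Waterman of every
    read against every reference, same M threshold and tie rule.  Used to
    audit what the two-stage pipeline may lose to filtering."""
    aligner = params.make_aligner()
    ref_items = sorted(refs.items())
    counts = {name: 0 for name, _ in ref_items}
    threshold = params.score_threshold
    for _, seq in reads:
        best_id, best_score = _best_hit(seq, ref_items, aligner, params.stranded)
        if best_id is not None and best_score >= threshold and best_score > 0:
            counts[best_id] += 1
    return counts
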