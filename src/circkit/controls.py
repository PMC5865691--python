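"""Null-sequence constructions and exon-level scoring.

These are the control procedures used around the circRNA analyses:
chimeric junction sets built by re-pairing junction halves, per-sequence
nucleotide shuffles, intron-length-matched control-gene pairing, detection
of divergent (inverted) repeat pairs in the intronic flanks of a
back-splice, coverage-style interval read counting, and the ratio score
comparing chromatin signal at the 5' circularizing exon with its upstream
exon.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree

from .junction import BSJunction
from .model import CircRecord, ExonAnnotation, GenomicInterval

log = logging.getLogger("circkit")


@dataclass(frozen=True)
class ControlSetSpec:
    """How many control sets to draw, an optional subset size, and the seed."""

    n_sets: int = 100
    subset_size: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sets < 1:
            raise ValueError("n_sets must be >= 1")


@dataclass(frozen=True)
class ExonSignal:
    """Read count over an exon and its per-base density."""

    exon: ExonAnnotation | GenomicInterval
    read_count: int

    @property
    def interval(self) -> GenomicInterval:
        return self.exon.interval if isinstance(self.exon, ExonAnnotation) else self.exon

    @property
    def per_base(self) -> float:
        return self.read_count / len(self.interval)


def _derangement(n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform random permutation of 0..n-1 with no fixed point (rejection)."""
    if n < 2:
        raise ValueError("need at least 2 elements for a derangement")
    while True:
        perm = rng.permutation(n)
        if not np.any(perm == np.arange(n)):
            return perm


def permute_halves(
    junctions: Sequence[BSJunction], spec: ControlSetSpec
) -> list[list[tuple[str, str]]]:
    """Build control sets of chimeric junctions by re-pairing halves.

    Each control sequence joins the left half (upstream of the back-splice
    point) of one junction to the right half of a different junction,
    drawn as a random derangement, so each set conserves the multiset of
    left and of right halves and no chimera reproduces an original
    junction.  With ``subset_size`` a fresh random subset is drawn per
    set before permutation.  Bit-reproducible from the seed.
    """
    if len(junctions) < 2:
        raise ValueError("need at least 2 junctions to permute halves")
    rng = np.random.default_rng(spec.seed)
    originals = {j.sequence for j in junctions}
    sets: list[list[tuple[str, str]]] = []
    for _ in range(spec.n_sets):
        pool = list(junctions)
        if spec.subset_size is not None:
            if spec.subset_size > len(pool):
                raise ValueError("subset_size exceeds number of junctions")
            take = rng.choice(len(pool), size=spec.subset_size, replace=False)
            pool = [pool[i] for i in take]
        for _attempt in range(100):
            perm = _derangement(len(pool), rng)
            chimeras = [
                (
                    f"{pool[i].circ_id}|{pool[j].circ_id}",
                    pool[i].left_half + pool[j].right_half,
                )
                for i, j in enumerate(perm)
            ]
            if all(seq not in originals for _, seq in chimeras):
                break
        else:
            raise RuntimeError(
                "could not avoid identity chimeras; junction halves too redundant"
            )
        sets.append(chimeras)
    return sets


def shuffle_sequences(
    seqs: Sequence[tuple[str, str]] | Mapping[str, str], spec: ControlSetSpec
) -> list[list[tuple[str, str]]]:
    """Per-sequence nucleotide shuffles, preserving length and composition."""
    items = list(seqs.items()) if isinstance(seqs, Mapping) else list(seqs)
    rng = np.random.default_rng(spec.seed)
    out: list[list[tuple[str, str]]] = []
    for _ in range(spec.n_sets):
        pool = items
        if spec.subset_size is not None:
            take = rng.choice(len(items), size=spec.subset_size, replace=False)
            pool = [items[i] for i in take]
        out.append(
            [(name, "".join(rng.permutation(list(seq)))) for name, seq in pool]
        )
    return out


def pair_by_first_intron(
    hosts: Sequence[tuple[str, int]],
    controls: Sequence[tuple[str, int]],
    n_iter: int = 1000,
    tolerance: float = 0.1,
    seed: int = 0,
) -> list[list[tuple[str, str, bool]]]:
    """Pair each host gene with a control of similar first-intron length.

    Per iteration, every host is paired with a uniformly sampled control
    whose first-intron length is within ``tolerance`` relative difference
    (default +-10%); when no candidate qualifies the nearest-length control
    is used and flagged.  Controls may be reused.  Returns ``n_iter``
    pairings of (host, control, fallback_flag), reproducible from seed.
    """
    if not hosts or not controls:
        raise ValueError("hosts and controls must be non-empty")
    rng = np.random.default_rng(seed)
    ctrl_lengths = np.array([length for _, length in controls], dtype=float)
    candidates: list[np.ndarray] = []
    nearest: list[int] = []
    for _, hlen in hosts:
        rel = np.abs(ctrl_lengths - hlen) / max(hlen, 1)
        candidates.append(np.flatnonzero(rel <= tolerance))
        nearest.append(int(np.argmin(np.abs(ctrl_lengths - hlen))))
    pairings: list[list[tuple[str, str, bool]]] = []
    for _ in range(n_iter):
        batch = []
        for (hname, _), cand, near in zip(hosts, candidates, nearest):
            if cand.size:
                pick = int(cand[rng.integers(cand.size)])
                batch.append((hname, controls[pick][0], False))
            else:
                batch.append((hname, controls[near][0], True))
        pairings.append(batch)
    return pairings


def find_divergent_repeat_pairs(
    circ: CircRecord, repeats: Iterable[GenomicInterval], flank: int = 500
) -> tuple[bool, list[tuple[GenomicInterval, GenomicInterval]]]:
    """Detect divergent (inverted) repeat pairs flanking a back-splice.

    The upstream flank covers ``flank`` bases 5' of the 5' back-splice
    site and the downstream flank ``flank`` bases from the 3' site, both
    in transcript orientation.  A qualifying pair is one repeat in each
    flank with opposite strands (the inverted configuration that allows
    intron pairing).  Returns (any pair found, all qualifying pairs).
    """
    if flank < 1:
        raise ValueError("flank must be >= 1")
    if circ.strand == "+":
        up = GenomicInterval(circ.chrom, max(0, circ.bs5_site - flank), max(1, circ.bs5_site))
        down = GenomicInterval(circ.chrom, circ.bs3_site, circ.bs3_site + flank)
    else:
        up = GenomicInterval(circ.chrom, circ.bs5_site + 1, circ.bs5_site + 1 + flank)
        down = GenomicInterval(circ.chrom, max(0, circ.bs3_site + 1 - flank), circ.bs3_site + 1)
    up_hits = [r for r in repeats if r.overlaps(up)]
    down_hits = [r for r in repeats if r.overlaps(down)]
    pairs = [
        (a, b) for a in up_hits for b in down_hits if a.strand != b.strand
    ]
    return bool(pairs), pairs


def count_reads_in_intervals(
    intervals: Sequence[ExonAnnotation | GenomicInterval],
    fragments: Iterable[GenomicInterval],
) -> list[ExonSignal]:
    """coverageBed-style counting: a fragment counts for an interval iff
    they overlap by at least one base (a fragment spanning two intervals
    counts once in each)."""
    trees: dict[str, IntervalTree] = {}
    for frag in fragments:
        trees.setdefault(frag.chrom, IntervalTree()).addi(frag.start, frag.end)
    out = []
    for item in intervals:
        iv = item.interval if isinstance(item, ExonAnnotation) else item
        tree = trees.get(iv.chrom)
        n = len(tree.overlap(iv.start, iv.end)) if tree is not None else 0
        out.append(ExonSignal(item, n))
    return out


def exon_signal_ratio(
    ce5: ExonSignal, upstream: ExonSignal, pseudocount: float = 0.1
) -> float:
    """Ratio of per-base signal at the 5' circularizing exon vs its
    upstream exon, with a per-base pseudocount guarding against empty
    exons.  Undefined (and meaningless) when the 5'CE is exon 1 — callers
    skip those records."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    return (ce5.per_base + pseudocount) / (upstream.per_base + pseudocount)
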