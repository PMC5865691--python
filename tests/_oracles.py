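"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library code paths they are checking: the
Smith-Waterman oracle is a textbook Gotoh dynamic program, the k-mer and
overlap oracles are naive enumerations.
"""

from __future__ import annotations

NEG = float("-inf")


def gotoh_local_score(a: str, b: str, match: int = 2, mismatch: int = 2,
                      gap_open: int = 3, gap_extend: int = 1) -> float:
    """Best local alignment score with affine gaps.

    Convention: a gap of length l costs gap_open + (l-1)*gap_extend, i.e.
    the opening penalty covers the first gapped base.
    """
    n, m = len(a), len(b)
    best = 0.0
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (consume b)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consume a)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - gap_open, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - gap_open, F[i - 1][j] - gap_extend)
            s = match if a[i - 1] == b[j - 1] else -mismatch
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            if H[i][j] > best:
                best = H[i][j]
    return best


def naive_kmers(seq: str, k: int) -> list[str]:
    return [] if len(seq) < k else [seq[i:i + k] for i in range(len(seq) - k + 1)]


def naive_shared_count(read: str, ref_kmer_set: set[str], k: int) -> int:
    return sum(1 for m in naive_kmers(read, k) if m in ref_kmer_set)


def naive_overlap_count(interval, fragments) -> int:
    """O(n) overlap counting: >=1 bp shared on the same chromosome."""
    return sum(
        1
        for f in fragments
        if f.chrom == interval.chrom and f.start < interval.end and interval.start < f.end
    )
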