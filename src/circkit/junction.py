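"""Back-splice junction sequence reconstruction.

The junction reference for a circRNA is the genomic window of L bases on
each side of the back-splice point, read in transcript orientation: the
last L bases of the circularized region followed by its first L bases
(default L = 35, i.e. 70-bp junctions).  The flanks are genomic windows —
introns retained inside the circle are not spliced out, and for exons
shorter than L the flank simply extends across the neighboring intron,
which is where the back-splice point physically sits on the genome.

circRNAs shorter than 2L cannot provide two full flanks; they are split
in two halves and the junction is the circle sequence rotated so that the
back-splice point is centered (odd lengths put the extra base upstream of
the junction point).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable

from . import io as ckio
from .model import CircRecord, GenomicInterval

log = logging.getLogger("circkit")


@dataclass(frozen=True)
class JunctionParams:
    """Flank length L in nucleotides (junction sequences are 2L long)."""

    L: int = 35

    def __post_init__(self) -> None:
        if self.L < 1:
            raise ValueError("flank length L must be >= 1")


@dataclass(frozen=True)
class BSJunction:
    """A reconstructed junction sequence in transcript orientation.

    ``junction_offset`` is the 0-based index of the first base after the
    back-splice point, so the junction base pair is
    (sequence[offset-1], sequence[offset]) = (last base, first base) of
    the circle.
    """

    circ_id: str
    sequence: str
    junction_offset: int

    @property
    def left_half(self) -> str:
        return self.sequence[: self.junction_offset]

    @property
    def right_half(self) -> str:
        return self.sequence[self.junction_offset:]


def build_bs_sequence(
    circ: CircRecord, genome, params: JunctionParams = JunctionParams()
) -> BSJunction:
    """Reconstruct the junction sequence of one circRNA from the genome."""
    L = params.L
    span = circ.span
    circle = ckio.fetch_sequence(genome, span, orient=True)
    n = len(circle)
    if n >= 2 * L:
        seq = circle[-L:] + circle[:L]
        offset = L
    else:
        h = math.ceil(n / 2)
        seq = circle[h:] + circle[:h]
        offset = n - h
    if set(seq) == {"N"}:
        log.warning("junction %s consists only of N bases", circ.circ_id)
    return BSJunction(circ.circ_id, seq, offset)


def build_all(
    circs: Iterable[CircRecord], genome, params: JunctionParams = JunctionParams()
) -> list[BSJunction]:
    return [build_bs_sequence(c, genome, params) for c in circs]


def write_junction_fasta(junctions: Iterable[BSJunction], path) -> None:
    """Write junctions as FASTA, header = circ_id, input order preserved."""
    ckio.write_fasta(((j.circ_id, j.sequence) for j in junctions), path)


def read_junction_fasta(path) -> list[BSJunction]:
    """Read a junction FASTA back; the offset is len - ceil(len/2) for
    sequences shorter than is representable otherwise (i.e. the midpoint),
    which matches the constructor for both the 2L and the split-halves
    case."""
    out = []
    for name, seq in ckio.read_fasta(path).items():
        n = len(seq)
        out.append(BSJunction(name, seq, n - math.ceil(n / 2)))
    return out
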