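"""Core genomic data model shared by every circkit module.

All coordinates are 0-based half-open internally; only file readers and
writers convert (CIRI tables are 1-based inclusive, BED is already
half-open).  Exon rank is strand-aware: rank 1 is the 5'-most exon in
transcript orientation, which on the minus strand is the exon with the
largest genomic end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

STRANDS = ("+", "-")

_RC = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (A/C/G/T/N)."""
    return seq.translate(_RC)[::-1]


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains_point(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass(frozen=True)
class ExonAnnotation:
    """One exon of a transcript with its 1-based strand-aware rank."""

    interval: GenomicInterval
    transcript_id: str
    rank: int

    def __post_init__(self) -> None:
        if self.rank < 1:
            raise ValueError(f"exon rank must be >= 1, got {self.rank}")

    # 5' boundary position in transcript orientation
    @property
    def five_prime(self) -> int:
        return self.interval.start if self.interval.strand == "+" else self.interval.end - 1

    # 3' boundary position in transcript orientation
    @property
    def three_prime(self) -> int:
        return self.interval.end - 1 if self.interval.strand == "+" else self.interval.start


@dataclass
class TranscriptModel:
    """A transcript: ordered exons plus gene-level identifiers.

    ``source_order`` is the 0-based order of first appearance in the
    annotation file; it implements the "order provided by Ensembl" used
    when no main ("-001") isoform overlaps a circRNA.
    """

    transcript_id: str
    transcript_name: str
    gene_id: str
    gene_symbol: str
    gene_span: GenomicInterval
    exons: list[ExonAnnotation] = field(default_factory=list)
    source_order: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has no exons")
        ranks = [e.rank for e in self.exons]
        if ranks != list(range(1, len(ranks) + 1)):
            raise ValueError(
                f"transcript {self.transcript_id}: exon ranks {ranks} are not "
                "consecutive from 1"
            )
        span = self.gene_span
        by_start = sorted(self.exons, key=lambda e: e.interval.start)
        for a, b in zip(by_start, by_start[1:]):
            if a.interval.end > b.interval.start:
                raise ValueError(
                    f"transcript {self.transcript_id}: overlapping exons"
                )
        for e in self.exons:
            iv = e.interval
            if iv.chrom != span.chrom or iv.strand != span.strand:
                raise ValueError(
                    f"transcript {self.transcript_id}: exon off gene chrom/strand"
                )
            if iv.start < span.start or iv.end > span.end:
                raise ValueError(
                    f"transcript {self.transcript_id}: exon outside gene span"
                )
        # strand-aware rank ordering: rank 1 is 5'-most in transcript orientation
        genomic = [e.interval.start for e in self.exons]
        if span.strand == "+":
            if genomic != sorted(genomic):
                raise ValueError(
                    f"transcript {self.transcript_id}: ranks not 5'->3' on + strand"
                )
        else:
            if genomic != sorted(genomic, reverse=True):
                raise ValueError(
                    f"transcript {self.transcript_id}: ranks not 5'->3' on - strand"
                )

    @property
    def strand(self) -> str:
        return self.gene_span.strand

    @property
    def chrom(self) -> str:
        return self.gene_span.chrom

    @property
    def is_main_isoform(self) -> bool:
        """True for the Ensembl main isoform, named with the "001" suffix."""
        name = self.transcript_name
        if name.endswith("001"):
            stem = name[: -len("001")]
            # accept GENE-001, GENE.001 or a bare ...001 suffix
            return stem == "" or stem[-1] in "-." or not stem[-1].isdigit()
        return False

    def exon_by_rank(self, rank: int) -> ExonAnnotation:
        return self.exons[rank - 1]

    @property
    def first_intron_length(self) -> int | None:
        """Length of the intron between exon 1 and exon 2, None for 1-exon genes."""
        if len(self.exons) < 2:
            return None
        e1, e2 = self.exons[0].interval, self.exons[1].interval
        if self.strand == "+":
            return e2.start - e1.end
        return e1.start - e2.end

    def spliced_intervals(self) -> list[GenomicInterval]:
        """Exon intervals in transcript order (rank order)."""
        return [e.interval for e in self.exons]


@dataclass
class CircRecord:
    """A back-splice event: the genomic span of the circularized region.

    The two back-splice sites are derived from the span and strand: in
    transcript orientation, ``bs5_site`` is the 5'-most base of the 5'
    circularizing exon and ``bs3_site`` the 3'-most base of the 3'
    circularizing exon.
    """

    circ_id: str
    span: GenomicInterval
    support_reads: dict[str, int] | None = None

    def __post_init__(self) -> None:
        if len(self.span) < 2:
            raise ValueError(
                f"circRNA {self.circ_id}: span must cover at least 2 bases"
            )
        if self.support_reads is not None:
            for sample, n in self.support_reads.items():
                if n < 0:
                    raise ValueError(
                        f"circRNA {self.circ_id}: negative support in {sample}"
                    )

    @property
    def strand(self) -> str:
        return self.span.strand

    @property
    def chrom(self) -> str:
        return self.span.chrom

    @property
    def bs5_site(self) -> int:
        return self.span.start if self.strand == "+" else self.span.end - 1

    @property
    def bs3_site(self) -> int:
        return self.span.end - 1 if self.strand == "+" else self.span.start
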