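"""Classification of back-splice events against a reference transcriptome.

Each circRNA/transcript overlap falls into exactly one of five classes:

* ``multiexonic`` — both back-splice sites sit exactly on exon boundaries
  of two different exons;
* ``monoexonic`` — both sites are the boundaries of one and the same exon;
* ``putative_exonic`` — both sites are inside exons but at least one does
  not match an exon boundary;
* ``intronic`` — at least one site falls in an intron;
* ``intergenic`` — at least one site lies outside the gene span (or no
  gene overlaps the circRNA at all).

The precedence intergenic > intronic > boundary-exact > putative_exonic
makes the classes mutually exclusive.  The univocal (per-circRNA) class is
taken from the host gene's main isoform, recognized by the Ensembl "001"
name suffix; without a main isoform, isoforms are evaluated in annotation
file order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import pandas as pd

from .model import CircRecord, TranscriptModel

log = logging.getLogger("circkit")


class Category(str, Enum):
    MULTIEXONIC = "multiexonic"
    MONOEXONIC = "monoexonic"
    PUTATIVE_EXONIC = "putative_exonic"
    INTRONIC = "intronic"
    INTERGENIC = "intergenic"


# lower value = higher precedence when several genes overlap one circRNA
_PRECEDENCE = {
    Category.MULTIEXONIC: 0,
    Category.MONOEXONIC: 0,
    Category.PUTATIVE_EXONIC: 1,
    Category.INTRONIC: 2,
    Category.INTERGENIC: 3,
}


@dataclass
class Classification:
    circ_id: str
    category: Category
    transcript_id: str | None
    rank5: int | None
    rank3: int | None
    name: str = ""
    gene_symbol: str | None = None

    def __post_init__(self) -> None:
        exonic = self.category in (Category.MULTIEXONIC, Category.MONOEXONIC)
        if exonic and (self.rank5 is None or self.rank3 is None):
            raise ValueError("exon-boundary categories require rank5/rank3")
        if not exonic and not (self.rank5 is None and self.rank3 is None):
            raise ValueError("ranks only defined for multi-/monoexonic circRNAs")
        if self.category is Category.MONOEXONIC and self.rank5 != self.rank3:
            raise ValueError("monoexonic circRNA must have rank5 == rank3")


def classify_against_transcript(
    circ: CircRecord, transcript: TranscriptModel, wobble: int = 0
) -> tuple[Category, int | None, int | None]:
    """Classify one circRNA against one transcript.

    ``wobble`` is the boundary-matching tolerance in bp (0 by default, so
    back-splice sites must hit exon boundaries exactly).  Returns the
    category and, for boundary-exact classes, the 5'/3' circularizing exon
    ranks.  Raises ``ValueError`` on chrom/strand mismatch — callers treat
    such transcripts as non-overlapping.
    """
    if transcript.chrom != circ.chrom or transcript.strand != circ.strand:
        raise ValueError("circRNA and transcript on different chrom/strand")
    span = transcript.gene_span
    sites = (circ.bs5_site, circ.bs3_site)
    # 1) any site beyond the gene boundaries
    if any(not span.contains_point(p) for p in sites):
        return Category.INTERGENIC, None, None
    # 2) any site in an intron
    def host_exon(pos: int):
        for e in transcript.exons:
            if e.interval.contains_point(pos):
                return e
        return None

    e5, e3 = host_exon(sites[0]), host_exon(sites[1])
    if e5 is None or e3 is None:
        return Category.INTRONIC, None, None
    # 3) exact boundary match in transcript orientation
    if abs(circ.bs5_site - e5.five_prime) <= wobble and (
        abs(circ.bs3_site - e3.three_prime) <= wobble
    ):
        if e5.rank == e3.rank:
            return Category.MONOEXONIC, e5.rank, e3.rank
        return Category.MULTIEXONIC, e5.rank, e3.rank
    # 4) inside exons but no precise boundary match
    return Category.PUTATIVE_EXONIC, None, None


def resolve_univocal(
    circ: CircRecord,
    transcripts: Sequence[TranscriptModel],
    wobble: int = 0,
) -> Classification:
    """Produce the single (univocal) classification of a circRNA.

    ``transcripts`` is the candidate set; transcripts whose gene span does
    not overlap the circRNA span (or sit on another chrom/strand) are
    ignored.  Each overlapping gene is represented by its main ("-001")
    isoform when present, otherwise by its first-seen isoform; among genes
    the representative giving the highest-precedence category wins, ties
    broken by annotation order.  With no overlapping gene the circRNA is
    intergenic.
    """
    candidates = [
        t
        for t in transcripts
        if t.chrom == circ.chrom
        and t.strand == circ.strand
        and t.gene_span.overlaps(circ.span)
    ]
    if not candidates:
        c = Classification(circ.circ_id, Category.INTERGENIC, None, None, None)
        c.name = name_circrna(c, circ)
        return c

    by_gene: dict[str, list[TranscriptModel]] = {}
    for t in candidates:
        by_gene.setdefault(t.gene_id, []).append(t)

    best: tuple[tuple[int, int], Classification] | None = None
    for isoforms in by_gene.values():
        isoforms.sort(key=lambda t: (t.source_order, t.transcript_id))
        mains = [t for t in isoforms if t.is_main_isoform]
        rep = mains[0] if mains else isoforms[0]
        category, r5, r3 = classify_against_transcript(circ, rep, wobble)
        cls = Classification(
            circ.circ_id, category, rep.transcript_id, r5, r3,
            gene_symbol=rep.gene_symbol,
        )
        key = (_PRECEDENCE[category], rep.source_order)
        if best is None or key < best[0]:
            best = (key, cls)
    assert best is not None
    cls = best[1]
    cls.name = name_circrna(cls, circ)
    return cls


def name_circrna(c: Classification, circ: CircRecord) -> str:
    """Compose the circRNA name from host gene symbol and exon ranks.

    ``Circ_<GENE>_<r>`` for monoexonic, ``Circ_<GENE>_<r5>-<r3>`` for
    multiexonic, ``I`` suffix for intronic, ``PE`` for putative exonic;
    intergenic circRNAs are named by their 1-based inclusive coordinates.
    """
    if c.category is Category.INTERGENIC:
        return (
            f"Circ_{circ.chrom}:{circ.span.start + 1}-{circ.span.end}"
            f"({circ.strand})"
        )
    if not c.gene_symbol:
        raise ValueError(
            f"circRNA {c.circ_id}: {c.category.value} classification lacks a gene symbol"
        )
    if c.category is Category.MONOEXONIC:
        return f"Circ_{c.gene_symbol}_{c.rank5}"
    if c.category is Category.MULTIEXONIC:
        return f"Circ_{c.gene_symbol}_{c.rank5}-{c.rank3}"
    if c.category is Category.INTRONIC:
        return f"Circ_{c.gene_symbol}_I"
    return f"Circ_{c.gene_symbol}_PE"


def classify_all(
    circs: Iterable[CircRecord],
    transcripts: Sequence[TranscriptModel],
    wobble: int = 0,
) -> list[Classification]:
    return [resolve_univocal(c, transcripts, wobble) for c in circs]


def classification_summary(
    classifications: Iterable[Classification],
) -> dict[str, pd.DataFrame]:
    """Tabulate counts and fractions per category, exons spanned and exon rank.

    ``exons_spanned`` (rank3 - rank5 + 1) and the rank tables cover only
    the boundary-exact (multi-/monoexonic) circRNAs.  Category fractions
    sum to 1.
    """
    cls = list(classifications)
    if not cls:
        empty = pd.DataFrame(columns=["count", "fraction"])
        return {"categories": empty, "exons_spanned": empty.copy(),
                "rank5": empty.copy(), "rank3": empty.copy()}

    def table(values) -> pd.DataFrame:
        s = pd.Series(values).value_counts().sort_index()
        return pd.DataFrame({"count": s, "fraction": s / s.sum()})

    exonic = [c for c in cls if c.category in (Category.MULTIEXONIC, Category.MONOEXONIC)]
    out = {"categories": table([c.category.value for c in cls])}
    if exonic:
        out["exons_spanned"] = table([abs(c.rank3 - c.rank5) + 1 for c in exonic])
        out["rank5"] = table([c.rank5 for c in exonic])
        out["rank3"] = table([c.rank3 for c in exonic])
    else:
        empty = pd.DataFrame(columns=["count", "fraction"])
        out.update({"exons_spanned": empty, "rank5": empty.copy(), "rank3": empty.copy()})
    return out


def write_classification_tsv(
    classifications: Sequence[Classification],
    circs: Sequence[CircRecord],
    path,
) -> None:
    by_id = {c.circ_id: c for c in circs}
    rows = []
    for cl in classifications:
        circ = by_id[cl.circ_id]
        rows.append(
            {
                "circ_id": cl.circ_id,
                "chrom": circ.chrom,
                "start": circ.span.start,
                "end": circ.span.end,
                "strand": circ.strand,
                "category": cl.category.value,
                "transcript_id": cl.transcript_id or "",
                "rank5": "" if cl.rank5 is None else cl.rank5,
                "rank3": "" if cl.rank3 is None else cl.rank3,
                "name": cl.name,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
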