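"""Readers and writers for the standard formats circkit consumes.

GTF parsing of individual lines is delegated to :mod:`gffutils`; the
grouping of exon features into transcript models, strand-aware rank
assignment and source-order bookkeeping happen here.  FASTA access goes
through :mod:`pyfaidx` (or any mapping of chromosome name to sequence,
which lets in-memory fixtures stand in for an indexed genome file).
"""

from __future__ import annotations

import logging
import os
from collections import OrderedDict
from pathlib import Path
from typing import Iterable, Mapping

import pyfaidx
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from gffutils.feature import feature_from_line

from .model import CircRecord, ExonAnnotation, GenomicInterval, TranscriptModel, revcomp

log = logging.getLogger("circkit")

__all__ = [
    "read_gtf",
    "write_gtf",
    "read_circ_table",
    "write_circ_table",
    "open_genome",
    "fetch_sequence",
    "read_fasta",
    "write_fasta",
    "read_bed",
]


class GtfParseError(ValueError):
    pass


def _first(attrs, key: str, default: str | None = None) -> str | None:
    vals = attrs.get(key)
    if vals:
        return vals[0]
    return default


def read_gtf(path: str | os.PathLike) -> list[TranscriptModel]:
    """Read an Ensembl-attribute-style GTF into transcript models.

    Exon features must carry ``transcript_id`` and ``gene_id`` attributes;
    ``gene_name``/``transcript_name`` fall back to the ids.  The gene span
    is taken from a ``transcript`` (or ``gene``) feature when present,
    otherwise from the exon hull.  Transcripts without exon features are
    excluded with a warning.  Malformed lines raise :class:`GtfParseError`
    naming the line number.
    """
    exon_groups: "OrderedDict[str, dict]" = OrderedDict()
    spans: dict[str, tuple[str, int, int, str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                feat = feature_from_line(line)
            except Exception as exc:  # malformed line
                raise GtfParseError(f"{path}: malformed GTF line {lineno}: {exc}") from exc
            tid = _first(feat.attributes, "transcript_id")
            if feat.featuretype in ("transcript", "mRNA") and tid:
                spans[tid] = (feat.seqid, feat.start - 1, feat.end, feat.strand)
                if tid not in exon_groups:
                    exon_groups[tid] = _new_group(feat, tid)
                continue
            if feat.featuretype != "exon":
                continue
            if tid is None:
                raise GtfParseError(
                    f"{path}: exon without transcript_id at line {lineno}"
                )
            grp = exon_groups.setdefault(tid, _new_group(feat, tid))
            grp["exons"].append(
                (feat.seqid, feat.start - 1, feat.end, feat.strand)
            )

    models: list[TranscriptModel] = []
    order = 0
    for tid, grp in exon_groups.items():
        raw = grp["exons"]
        if not raw:
            log.warning("transcript %s has no exon features; excluded", tid)
            continue
        chrom, strand = raw[0][0], raw[0][3]
        raw.sort(key=lambda e: e[1], reverse=(strand == "-"))
        if tid in spans:
            schrom, s0, s1, sstrand = spans[tid]
            span = GenomicInterval(schrom, s0, s1, sstrand)
        else:
            span = GenomicInterval(
                chrom, min(e[1] for e in raw), max(e[2] for e in raw), strand
            )
        exons = [
            ExonAnnotation(GenomicInterval(c, s, e, st), tid, rank)
            for rank, (c, s, e, st) in enumerate(raw, start=1)
        ]
        models.append(
            TranscriptModel(
                transcript_id=tid,
                transcript_name=grp["transcript_name"],
                gene_id=grp["gene_id"],
                gene_symbol=grp["gene_symbol"],
                gene_span=span,
                exons=exons,
                source_order=order,
            )
        )
        order += 1
    return models


def _new_group(feat, tid: str) -> dict:
    attrs = feat.attributes
    gene_id = _first(attrs, "gene_id", tid)
    return {
        "gene_id": gene_id,
        "gene_symbol": _first(attrs, "gene_name", gene_id),
        "transcript_name": _first(attrs, "transcript_name", tid),
        "exons": [],
    }


def write_gtf(transcripts: Iterable[TranscriptModel], path: str | os.PathLike) -> None:
    """Write transcript models as Ensembl-attribute-style GTF (round-trippable)."""
    with open(path, "w") as fh:
        for t in transcripts:
            attrs = (
                f'gene_id "{t.gene_id}"; gene_name "{t.gene_symbol}"; '
                f'transcript_id "{t.transcript_id}"; '
                f'transcript_name "{t.transcript_name}";'
            )
            s = t.gene_span
            fh.write(
                f"{s.chrom}\tcirckit\ttranscript\t{s.start + 1}\t{s.end}\t.\t"
                f"{s.strand}\t.\t{attrs}\n"
            )
            for e in t.exons:
                iv = e.interval
                fh.write(
                    f"{iv.chrom}\tcirckit\texon\t{iv.start + 1}\t{iv.end}\t.\t"
                    f'{iv.strand}\t.\t{attrs} exon_number "{e.rank}";\n'
                )


# ---------------------------------------------------------------------------
# circRNA coordinate tables

CIRI_COLUMNS = ("circRNA_ID", "chr", "circRNA_start", "circRNA_end")


def read_circ_table(
    path: str | os.PathLike, dialect: str = "ciri"
) -> list[CircRecord]:
    """Read circRNA back-splice coordinates from a CIRI-style TSV or BED6.

    CIRI coordinates are 1-based inclusive and are converted to the
    internal 0-based half-open convention; BED is used as-is.  Records
    with start >= end are rejected and logged.
    """
    if dialect not in ("ciri", "bed"):
        raise ValueError(f"unknown circ-table dialect {dialect!r}")
    records: list[CircRecord] = []
    if dialect == "ciri":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            idx = {name: i for i, name in enumerate(header)}
            for want in CIRI_COLUMNS:
                if want not in idx:
                    raise ValueError(f"{path}: CIRI table missing column {want!r}")
            reads_col = idx.get("#junction_reads", idx.get("junction_reads"))
            strand_col = idx.get("strand")
            for lineno, line in enumerate(fh, start=2):
                if not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                cid = parts[idx["circRNA_ID"]]
                chrom = parts[idx["chr"]]
                start1 = int(parts[idx["circRNA_start"]])
                end1 = int(parts[idx["circRNA_end"]])
                strand = parts[strand_col] if strand_col is not None else "+"
                start, end = start1 - 1, end1
                if start >= end or start < 0:
                    log.warning(
                        "%s line %d: rejected record %s with start >= end",
                        path, lineno, cid,
                    )
                    continue
                support = None
                if reads_col is not None and len(parts) > reads_col:
                    try:
                        support = {"junction_reads": int(parts[reads_col])}
                    except ValueError:
                        support = None
                records.append(
                    CircRecord(cid, GenomicInterval(chrom, start, end, strand), support)
                )
    else:  # bed
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
                cid = parts[3] if len(parts) > 3 and parts[3] != "." else (
                    f"{chrom}:{start}-{end}"
                )
                strand = parts[5] if len(parts) > 5 else "+"
                if start >= end or start < 0:
                    log.warning("%s line %d: rejected record with start >= end", path, lineno)
                    continue
                records.append(
                    CircRecord(cid, GenomicInterval(chrom, start, end, strand))
                )
    return records


def write_circ_table(circs: Iterable[CircRecord], path: str | os.PathLike,
                     dialect: str = "bed") -> None:
    """Write circRNA records (BED6, or CIRI TSV with 1-based coordinates)."""
    with open(path, "w") as fh:
        if dialect == "ciri":
            fh.write("circRNA_ID\tchr\tcircRNA_start\tcircRNA_end\t#junction_reads\tstrand\n")
            for c in circs:
                n = (c.support_reads or {}).get("junction_reads", 0)
                fh.write(
                    f"{c.circ_id}\t{c.chrom}\t{c.span.start + 1}\t{c.span.end}\t{n}\t{c.strand}\n"
                )
        elif dialect == "bed":
            for c in circs:
                fh.write(
                    f"{c.chrom}\t{c.span.start}\t{c.span.end}\t{c.circ_id}\t.\t{c.strand}\n"
                )
        else:
            raise ValueError(f"unknown circ-table dialect {dialect!r}")


# ---------------------------------------------------------------------------
# genome sequence access

def open_genome(genome: str | os.PathLike | Mapping[str, str]):
    """Return a chromosome-name -> sliceable-sequence mapping.

    Accepts a FASTA path (opened with pyfaidx, .fai index created on
    demand) or any mapping of chromosome name to sequence string.
    """
    if isinstance(genome, (str, Path)):
        return pyfaidx.Fasta(str(genome))
    return genome


def fetch_sequence(genome, interval: GenomicInterval, orient: bool = False) -> str:
    """Extract the uppercase sequence of ``interval`` from ``genome``.

    With ``orient=True`` the reverse complement is returned for minus-strand
    intervals, i.e. the sequence reads 5'->3' in transcript orientation.
    Bases other than ACGT are normalized to N.
    """
    chrom = interval.chrom
    if chrom not in genome:
        raise KeyError(f"chromosome {chrom!r} not in genome")
    chrom_len = len(genome[chrom])
    if interval.end > chrom_len:
        raise ValueError(
            f"interval {chrom}:{interval.start}-{interval.end} exceeds "
            f"chromosome length {chrom_len}"
        )
    seq = str(genome[chrom][interval.start:interval.end]).upper()
    seq = "".join(b if b in "ACGT" else "N" for b in seq)
    if orient and interval.strand == "-":
        seq = revcomp(seq)
    return seq


# ---------------------------------------------------------------------------
# FASTA / BED helpers

def read_fasta(path: str | os.PathLike) -> "OrderedDict[str, str]":
    out: "OrderedDict[str, str]" = OrderedDict()
    for rec in SeqIO.parse(str(path), "fasta"):
        out[rec.id] = str(rec.seq).upper()
    return out


def write_fasta(records: Iterable[tuple[str, str]], path: str | os.PathLike) -> None:
    seen: set[str] = set()
    seqrecs = []
    for name, seq in records:
        if name in seen:
            raise ValueError(f"duplicate FASTA id {name!r}")
        seen.add(name)
        seqrecs.append(SeqRecord(Seq(seq), id=name, description=""))
    SeqIO.write(seqrecs, str(path), "fasta")


def read_bed(path: str | os.PathLike) -> list[GenomicInterval]:
    """Read BED (3-6 columns) intervals; strand defaults to '+'."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            strand = parts[5] if len(parts) > 5 and parts[5] in "+-" else "+"
            out.append(GenomicInterval(parts[0], int(parts[1]), int(parts[2]), strand))
    return out
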