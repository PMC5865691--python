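import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for tests._oracles imports

from circkit.model import ExonAnnotation, GenomicInterval, TranscriptModel
from circkit.simulate import SimulationSpec, make_reference, plant_circrnas


@pytest.fixture(scope="session")
def toy_spec():
    return SimulationSpec(seed=1)


@pytest.fixture(scope="session")
def toy_reference(toy_spec):
    return make_reference(toy_spec)


@pytest.fixture(scope="session")
def planted(toy_reference, toy_spec):
    """CircRecords of all five categories plus the generator truth table."""
    return plant_circrnas(toy_reference, toy_spec)


def make_transcript(
    tid="t1",
    name="GENEA-001",
    gene="ga",
    symbol="GENEA",
    chrom="chr1",
    strand="+",
    exon_coords=((100, 200), (400, 500), (700, 800), (1000, 1100), (1300, 1400)),
    source_order=0,
):
    """Hand-built transcript: exon_coords are genomic, 5'->3' rank order is
    derived from strand."""
    coords = sorted(exon_coords)
    if strand == "-":
        coords = coords[::-1]
    exons = [
        ExonAnnotation(GenomicInterval(chrom, s, e, strand), tid, rank)
        for rank, (s, e) in enumerate(coords, start=1)
    ]
    span = GenomicInterval(
        chrom, min(s for s, _ in exon_coords), max(e for _, e in exon_coords), strand
    )
    return TranscriptModel(tid, name, gene, symbol, span, exons, source_order)


@pytest.fixture
def plus_transcript():
    return make_transcript()


@pytest.fixture
def minus_transcript():
    return make_transcript(
        tid="t2", name="GENEB-001", gene="gb", symbol="GENEB", strand="-",
        exon_coords=((2000, 2150), (2400, 2500), (2700, 2850)),
    )
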