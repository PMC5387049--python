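import pytest

from splicecode.consensus import PairedConsensus, PairedConsensusTable
from splicecode.fixtures import load_fixture
from splicecode.genome_model import TranscriptModel


@pytest.fixture(scope="session")
def table1():
    return load_fixture("table1")


@pytest.fixture(scope="session")
def table2():
    return load_fixture("table2")


@pytest.fixture(scope="session")
def atp7a():
    return load_fixture("atp7a")


@pytest.fixture(scope="session")
def lkb1():
    return load_fixture("lkb1")


def make_table(*pairs: tuple[str, str]) -> PairedConsensusTable:
    """Ad-hoc consensus table from (donor, acceptor) pairs, ranked in order."""
    motifs = [
        PairedConsensus(d, a, count=1000 - i, rank=i + 1)
        for i, (d, a) in enumerate(pairs)
    ]
    return PairedConsensusTable(motifs=motifs, total_introns=sum(m.count for m in motifs))


def tx(gene, tid, exons, strand="+", contig="chr1"):
    return TranscriptModel(
        gene_id=gene,
        transcript_id=tid,
        contig_id=contig,
        strand=strand,
        exons=tuple(sorted(exons)),
    )
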