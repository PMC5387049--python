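"""Packaged reference fixtures.

``table1`` is the published human ranked paired-consensus table (42
motifs plus the rank-0 ALL total), ``table2`` the human alternative
splicing code (enriched/depleted motif ranks per intron class), and
``atp7a`` / ``lkb1`` are the splice-junction sequences of the two
disease worked examples (motif cores as published, interior filler
synthetic; see data/junctions.json).

Files are checksummed on load to guard against silent edits.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from importlib import resources

from .consensus import PairedConsensusTable
from .enrichment import SplicingCodeTable

_CHECKSUMS = {
    "table1.tsv": "6639487afd23c28214533afaba3e69e6d72ab80e4e53312e6ba74d3f50f2bda5",
    "table2.tsv": "afe9df403f3866350159812e151f70262592faa215e0d8f3c185a72fea469c06",
    "junctions.json": "6fa4a40b7ea176170dcd51ffed4f1462d83c68bb1ce174f773f9036dbd574fdf",
}


@dataclass(frozen=True)
class JunctionFixture:
    """One worked-example intron with its junction sequences."""

    gene: str
    intron_ordinal: int
    donor_seq: str
    acceptor_seq: str
    sequence: str
    wild_motif: str


def _read_data(filename: str) -> bytes:
    data = (resources.files("splicecode") / "data" / filename).read_bytes()
    digest = hashlib.sha256(data).hexdigest()
    expected = _CHECKSUMS[filename]
    if expected and digest != expected:
        raise ValueError(
            f"fixture {filename} checksum mismatch ({digest}); file was modified"
        )
    return data


def load_fixture(name: str):
    """Load a packaged fixture: ``table1``, ``table2``, ``atp7a`` or ``lkb1``."""
    import tempfile, os

    if name == "table1":
        data = _read_data("table1.tsv")
        with tempfile.NamedTemporaryFile("wb", suffix=".tsv", delete=False) as fh:
            fh.write(data)
            path = fh.name
        try:
            return PairedConsensusTable.from_tsv(path)
        finally:
            os.unlink(path)
    if name == "table2":
        data = _read_data("table2.tsv")
        with tempfile.NamedTemporaryFile("wb", suffix=".tsv", delete=False) as fh:
            fh.write(data)
            path = fh.name
        try:
            return SplicingCodeTable.from_tsv(path)
        finally:
            os.unlink(path)
    if name in ("atp7a", "lkb1"):
        payload = json.loads(_read_data("junctions.json"))
        key = "atp7a_intron6" if name == "atp7a" else "lkb1_intron2"
        fx = payload[key]
        return JunctionFixture(
            gene=fx["gene"],
            intron_ordinal=fx["intron_ordinal"],
            donor_seq=fx["donor_seq"],
            acceptor_seq=fx["acceptor_seq"],
            sequence=fx["sequence"],
            wild_motif=fx["wild_motif"],
        )
    raise KeyError(f"unknown fixture {name!r}")
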