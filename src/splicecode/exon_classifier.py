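"""Splicing-type classification of exons and intron class labels.

Each unique exon of a gene gets one of seven splicing types, decided on
the gene's full transcript set:

* ``R``   retained / invariant
* ``S``   skipped
* ``A5``  alternative 5' splice site (donor-side boundary varies)
* ``A3``  alternative 3' splice site (acceptor-side boundary varies)
* ``ME``  mutually exclusive
* ``APr`` alternative promoter (first exon, gene has >1 start)
* ``APA`` alternative poly-A (last exon, gene has >1 end)

An intron is labelled by its flanking exon types in transcription order,
``Xa-Xb``.  APr can only flank upstream and APA only downstream, so 36
ordered pairs are constructible from the 7 types.

The taxonomy gives no inherent tie-break when an exon satisfies several
definitions; the precedence used here (terminal types first, then the
rarest internal pattern, with R as the default) is

    APr > APA > ME > S > A5 > A3 > R

and is configurable via the ``precedence`` argument.
"""

from __future__ import annotations

from collections import defaultdict
from enum import Enum
from typing import Iterable, Mapping

from .genome_model import IntronRecord, TranscriptModel

import logging

logger = logging.getLogger(__name__)


class ExonType(str, Enum):
    R = "R"
    S = "S"
    A3 = "A3"
    A5 = "A5"
    ME = "ME"
    APR = "APr"
    APA = "APA"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


DEFAULT_PRECEDENCE = (
    ExonType.APR,
    ExonType.APA,
    ExonType.ME,
    ExonType.S,
    ExonType.A5,
    ExonType.A3,
)

#: Fixed enumeration order of intron classes (matrix layout: upstream rows,
#: downstream columns).
UPSTREAM_ORDER = (ExonType.APR, ExonType.A3, ExonType.A5, ExonType.ME, ExonType.R, ExonType.S)
DOWNSTREAM_ORDER = (ExonType.A3, ExonType.A5, ExonType.ME, ExonType.R, ExonType.S, ExonType.APA)

Exon = tuple[int, int]


class IntronClass(str, Enum):
    """One of the 36 valid ordered pairs of flanking exon types."""

    # Members are generated below; the Enum subclass keeps labels hashable,
    # comparable and serializable as plain strings.

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value

    @property
    def upstream(self) -> ExonType:
        return ExonType(self.value.split("-")[0])

    @property
    def downstream(self) -> ExonType:
        return ExonType(self.value.split("-")[1])


IntronClass = IntronClass(  # type: ignore[misc]
    "IntronClass",
    {
        f"{up.value}_{down.value}".upper(): f"{up.value}-{down.value}"
        for up in UPSTREAM_ORDER
        for down in DOWNSTREAM_ORDER
    },
)
IntronClass.__doc__ = "One of the 36 valid ordered pairs of flanking exon types."


def enumerate_intron_classes() -> list[IntronClass]:
    """All 36 valid classes, upstream-major in the documented fixed order."""
    return list(IntronClass)


def label_intron(upstream_type: ExonType, downstream_type: ExonType) -> IntronClass:
    """Class label ``Xa-Xb`` for an intron given its flanking exon types."""
    if upstream_type is ExonType.APA:
        raise ValueError("APA can never be the upstream flanking exon")
    if downstream_type is ExonType.APR:
        raise ValueError("APr can never be the downstream flanking exon")
    return IntronClass(f"{upstream_type.value}-{downstream_type.value}")


def _tx_key(exon: Exon, strand: str) -> tuple[int, int]:
    """(5'-boundary, 3'-boundary) of an exon in transcription order."""
    return exon if strand == "+" else (exon[1], exon[0])


def classify_exons(
    transcripts_of_gene: Iterable[TranscriptModel],
    precedence: tuple[ExonType, ...] = DEFAULT_PRECEDENCE,
) -> dict[Exon, ExonType]:
    """Assign every unique exon of one gene exactly one splicing type.

    Exons are keyed by their genomic interval; all transcripts must be on
    one contig and strand.  The result is invariant under transcript input
    order.
    """
    transcripts = sorted(transcripts_of_gene, key=lambda t: t.transcript_id)
    if not transcripts:
        raise ValueError("empty transcript set")
    strand = transcripts[0].strand

    tx_exons: dict[str, tuple[Exon, ...]] = {
        t.transcript_id: t.exons_transcription_order for t in transcripts
    }
    all_exons: set[Exon] = {e for exons in tx_exons.values() for e in exons}

    # -- terminal types -------------------------------------------------
    first_exons = {exons[0] for exons in tx_exons.values()}
    last_exons = {exons[-1] for exons in tx_exons.values()}
    distinct_starts = {_tx_key(e, strand)[0] for e in first_exons}
    distinct_ends = {_tx_key(e, strand)[1] for e in last_exons}
    apr_exons = first_exons if len(distinct_starts) >= 2 else set()
    apa_exons = last_exons if len(distinct_ends) >= 2 else set()

    # -- neighbours (for ME and S) --------------------------------------
    neighbours: dict[Exon, set[Exon]] = defaultdict(set)
    adjacent_pairs: set[tuple[Exon, Exon]] = set()
    for exons in tx_exons.values():
        for a, b in zip(exons, exons[1:]):
            neighbours[a].add(b)
            neighbours[b].add(a)
            adjacent_pairs.add((a, b))

    def overlaps(e1: Exon, e2: Exon) -> bool:
        return e1[0] < e2[1] and e2[0] < e1[1]

    me_exons: set[Exon] = set()
    exon_list = sorted(all_exons)
    membership = {
        e: {tid for tid, exons in tx_exons.items() if e in exons} for e in exon_list
    }
    for i, e1 in enumerate(exon_list):
        for e2 in exon_list[i + 1 :]:
            if overlaps(e1, e2):
                continue
            if membership[e1] & membership[e2]:
                continue  # co-occur somewhere
            if not (membership[e1] and membership[e2]):
                continue
            if neighbours[e1] & neighbours[e2]:
                me_exons.update((e1, e2))

    # -- skipped --------------------------------------------------------
    s_exons: set[Exon] = set()
    for exons in tx_exons.values():
        for prev, e, nxt in zip(exons, exons[1:], exons[2:]):
            # e is internal here; skipped if some transcript joins prev-nxt
            # directly without e.
            for tid2, exons2 in tx_exons.items():
                if e in exons2:
                    continue
                if (prev, nxt) in {p for p in zip(exons2, exons2[1:])}:
                    s_exons.add(e)
                    break

    # -- alternative splice-site boundaries -----------------------------
    a5_exons: set[Exon] = set()
    a3_exons: set[Exon] = set()
    by_acceptor: dict[int, set[Exon]] = defaultdict(set)
    by_donor: dict[int, set[Exon]] = defaultdict(set)
    for e in all_exons:
        acc, don = _tx_key(e, strand)  # 5' boundary (acceptor side), 3' (donor)
        by_acceptor[acc].add(e)
        by_donor[don].add(e)
    for variants in by_acceptor.values():
        if len({_tx_key(e, strand)[1] for e in variants}) >= 2:
            a5_exons.update(variants)  # shared acceptor side, donor varies
    for variants in by_donor.values():
        if len({_tx_key(e, strand)[0] for e in variants}) >= 2:
            a3_exons.update(variants)  # shared donor side, acceptor varies

    matches = {
        ExonType.APR: apr_exons,
        ExonType.APA: apa_exons,
        ExonType.ME: me_exons,
        ExonType.S: s_exons,
        ExonType.A5: a5_exons,
        ExonType.A3: a3_exons,
    }
    result: dict[Exon, ExonType] = {}
    for e in exon_list:
        for etype in precedence:
            if e in matches[etype]:
                result[e] = etype
                break
        else:
            result[e] = ExonType.R
    return result


def classify_introns(
    introns: Iterable[IntronRecord],
    exon_types: Mapping[Exon, ExonType],
) -> dict[str, IntronClass]:
    """Class label per unique intron, keyed by ``IntronRecord.intron_id``.

    If transcripts give one intron several flanking pairs the
    lexicographically smallest label is kept (with a warning); on
    pre-filtered input every intron receives one of the 36 labels.
    """
    labels: dict[str, IntronClass] = {}
    for rec in introns:
        up = exon_types[rec.upstream_exon]
        down = exon_types[rec.downstream_exon]
        label = label_intron(up, down)
        prior = labels.get(rec.intron_id)
        if prior is not None and prior != label:
            keep = min(prior, label, key=lambda c: c.value)
            logger.warning(
                "intron %s has conflicting labels %s/%s; keeping %s",
                rec.intron_id,
                prior.value,
                label.value,
                keep.value,
            )
            label = keep
        labels[rec.intron_id] = label
    return labels
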