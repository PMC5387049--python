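"""Interpretation of splice-site point mutations in IVS notation.

A mutation like ``IVS6+5G>A`` changes the fifth intron base of intron 6
(counting the first intron base as +1 from the donor; negative offsets
count inward from the acceptor, -1 being the last intron base).  The
interpreter re-assigns the mutated junction to its most specific paired
consensus and reports which intron classes become enriched that were not
enriched for the wild-type motif — the predicted shift in alternative
splicing behaviour.  When the mutation destroys the motif entirely the
donor-side cryptic-site scan lists alternative splice donor candidates
downstream.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .consensus import PairedConsensus, PairedConsensusTable, assign_motif
from .enrichment import SplicingCodeTable
from .exon_classifier import IntronClass
from .genome_model import IntronRecord

_IVS_RE = re.compile(
    r"^IVS(?P<intron>\d+)(?P<sign>[+\-−])(?P<offset>\d+)"
    r"(?P<ref>[ACGTUacgtu])>(?P<alt>[ACGTUacgtu])$"
)


def _to_rna_base(b: str) -> str:
    b = b.lower()
    return "u" if b == "t" else b


@dataclass(frozen=True)
class MutationSpec:
    """A parsed intronic point mutation."""

    intron_ordinal: int
    offset: int  # +k from donor, -k from acceptor; never 0
    ref_base: str
    alt_base: str

    def __post_init__(self) -> None:
        if self.offset == 0:
            raise ValueError("offset 0 is not a valid intron position")

    @property
    def label(self) -> str:
        sign = "+" if self.offset > 0 else "-"
        return (
            f"IVS{self.intron_ordinal}{sign}{abs(self.offset)}"
            f"{self.ref_base.upper()}>{self.alt_base.upper()}"
        )


def parse_ivs_mutation(text: str) -> MutationSpec:
    """Parse ``IVS<intron>[+|-]<k><REF>><ALT>``; DNA letters become RNA."""
    m = _IVS_RE.match(text.strip())
    if m is None:
        raise ValueError(f"malformed IVS mutation string: {text!r}")
    offset = int(m.group("offset"))
    if offset == 0:
        raise ValueError("intron position 0 does not exist (+1 is the first base)")
    if m.group("sign") != "+":
        offset = -offset
    return MutationSpec(
        intron_ordinal=int(m.group("intron")),
        offset=offset,
        ref_base=_to_rna_base(m.group("ref")),
        alt_base=_to_rna_base(m.group("alt")),
    )


@dataclass
class MutationReport:
    """Predicted splicing consequence of one intronic point mutation."""

    mutation: MutationSpec
    wild_motif: PairedConsensus | None
    mutant_motif: PairedConsensus | None
    wild_enriched: set[IntronClass]
    mutant_enriched: set[IntronClass]
    gained: set[IntronClass] = field(init=False)
    lost: set[IntronClass] = field(init=False)
    cryptic_candidates: list[tuple[int, PairedConsensus]] = field(
        default_factory=list
    )

    def __post_init__(self) -> None:
        self.gained = self.mutant_enriched - self.wild_enriched
        self.lost = self.wild_enriched - self.mutant_enriched

    def to_dict(self) -> dict:
        return {
            "mutation": self.mutation.label,
            "wild_motif": self.wild_motif.motif if self.wild_motif else None,
            "mutant_motif": self.mutant_motif.motif if self.mutant_motif else None,
            "wild_enriched": sorted(c.value for c in self.wild_enriched),
            "mutant_enriched": sorted(c.value for c in self.mutant_enriched),
            "gained": sorted(c.value for c in self.gained),
            "lost": sorted(c.value for c in self.lost),
            "cryptic_candidates": [
                {"position": p, "motif": m.motif} for p, m in self.cryptic_candidates
            ],
        }


def apply_mutation(
    donor_seq: str, acceptor_seq: str, spec: MutationSpec
) -> tuple[str, str]:
    """Mutated (donor, acceptor) pair; the reference base is checked."""
    if spec.offset > 0:
        idx = spec.offset - 1
        if idx >= len(donor_seq):
            raise IndexError(
                f"offset +{spec.offset} beyond extracted donor window "
                f"({len(donor_seq)} bases)"
            )
        observed = donor_seq[idx]
        if observed != spec.ref_base:
            raise ValueError(
                f"reference mismatch at +{spec.offset}: annotation has "
                f"{observed!r}, mutation says {spec.ref_base!r}"
            )
        donor_seq = donor_seq[:idx] + spec.alt_base + donor_seq[idx + 1 :]
    else:
        idx = len(acceptor_seq) + spec.offset  # offset is negative
        if idx < 0:
            raise IndexError(
                f"offset {spec.offset} beyond extracted acceptor window "
                f"({len(acceptor_seq)} bases)"
            )
        observed = acceptor_seq[idx]
        if observed != spec.ref_base:
            raise ValueError(
                f"reference mismatch at {spec.offset}: annotation has "
                f"{observed!r}, mutation says {spec.ref_base!r}"
            )
        acceptor_seq = acceptor_seq[:idx] + spec.alt_base + acceptor_seq[idx + 1 :]
    return donor_seq, acceptor_seq


def cryptic_site_scan(
    intron_sequence: str,
    table: PairedConsensusTable,
    window: int = 100,
    min_motif_length: int = 1,
    scan_acceptors: bool = False,
) -> list[tuple[int, PairedConsensus]]:
    """Donor-motif matches within the first ``window`` intron positions.

    Position 1 is the first intron base; at each position the most
    specific motif (longest donor, then lowest rank) is reported.  Bare
    core motifs can be suppressed with ``min_motif_length``.  With
    ``scan_acceptors`` the same scan runs over acceptor motifs against
    the last ``window`` bases (positions reported as negative offsets
    from the 3' end).
    """
    if window > len(intron_sequence):
        raise ValueError("window longer than the intron")
    hits: list[tuple[int, PairedConsensus]] = []
    for p in range(1, window + 1):
        tail = intron_sequence[p - 1 :]
        best: PairedConsensus | None = None
        for cand in table.motifs:
            if len(cand.donor_motif) < min_motif_length:
                continue
            if not tail.startswith(cand.donor_motif):
                continue
            if best is None or (len(cand.donor_motif), -cand.rank) > (
                len(best.donor_motif),
                -best.rank,
            ):
                best = cand
        if best is not None:
            hits.append((p, best))
    if scan_acceptors:
        for p in range(1, window + 1):
            head = intron_sequence[: len(intron_sequence) - p + 1]
            best = None
            for cand in table.motifs:
                if len(cand.acceptor_motif) < min_motif_length:
                    continue
                if not head.endswith(cand.acceptor_motif):
                    continue
                if best is None or (len(cand.acceptor_motif), -cand.rank) > (
                    len(best.acceptor_motif),
                    -best.rank,
                ):
                    best = cand
            if best is not None:
                hits.append((-p, best))
    return sorted(hits, key=lambda h: (h[0] < 0, abs(h[0])))


def interpret_mutation(
    intron: IntronRecord,
    spec: MutationSpec,
    table: PairedConsensusTable,
    code: SplicingCodeTable,
    cryptic_window: int = 100,
) -> MutationReport:
    """Predict the intron-class shift caused by a splice-site mutation.

    The enriched class sets are looked up in the code table for the wild
    and mutant motif assignments; ``gained`` holds classes uniquely
    enriched after the mutation.  A "no motif" outcome is distinct from
    "motif with no significant class": the former drops the junction off
    the consensus table entirely.  The cryptic scan runs whenever the
    full intron sequence is available on the record.
    """
    wild = assign_motif(intron.donor_seq, intron.acceptor_seq, table)
    mut_donor, mut_acceptor = apply_mutation(
        intron.donor_seq, intron.acceptor_seq, spec
    )
    mutant = assign_motif(mut_donor, mut_acceptor, table)

    wild_enriched = code.enriched_classes(wild.rank) if wild else set()
    mutant_enriched = code.enriched_classes(mutant.rank) if mutant else set()

    cryptic: list[tuple[int, PairedConsensus]] = []
    if intron.sequence is not None:
        mutated_full = intron.sequence
        if spec.offset > 0:
            i = spec.offset - 1
            mutated_full = mutated_full[:i] + spec.alt_base + mutated_full[i + 1 :]
        else:
            i = len(mutated_full) + spec.offset
            mutated_full = mutated_full[:i] + spec.alt_base + mutated_full[i + 1 :]
        window = min(cryptic_window, len(mutated_full))
        cryptic = cryptic_site_scan(mutated_full, table, window=window)

    return MutationReport(
        mutation=spec,
        wild_motif=wild,
        mutant_motif=mutant,
        wild_enriched=wild_enriched,
        mutant_enriched=mutant_enriched,
        cryptic_candidates=cryptic,
    )
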