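"""Fisher-exact enrichment/depletion of consensus motifs per intron class.

For every (motif m, intron class c) pair a 2x2 table is formed over the
full intron universe (introns with no assigned motif stay in the
universe and contribute to the margins):

    a = |m and c|    b = |m, not c|
    c_ = |c, not m|  d = |neither|

Under the hypergeometric null with fixed margins, the upper tail
``p_up = P(X >= a)`` measures enrichment and the lower tail
``p_down = P(X <= a)`` depletion.  Tails are exact (hypergeometric
survival/cumulative functions, computed in floating point from log-space
pmf terms), so genome-scale p-values such as 1e-14 are representable.
Significance is reported at a raw alpha (default 0.001); an optional
Benjamini-Hochberg correction is available but off by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from scipy.stats import hypergeom

from .consensus import PairedConsensus
from .exon_classifier import (
    DOWNSTREAM_ORDER,
    UPSTREAM_ORDER,
    IntronClass,
    enumerate_intron_classes,
)


@dataclass(frozen=True)
class ContingencyCell:
    """2x2 table counts for one (motif, class) pair."""

    a: int  # motif and class
    b: int  # motif, not class
    c_: int  # class, not motif
    d: int  # neither

    @property
    def total(self) -> int:
        return self.a + self.b + self.c_ + self.d

    @property
    def motif_count(self) -> int:
        return self.a + self.b

    @property
    def class_count(self) -> int:
        return self.a + self.c_


def hypergeom_tails(cell: ContingencyCell) -> tuple[float, float]:
    """(p_up, p_down) exact hypergeometric tails at the observed overlap."""
    N, K, n, a = cell.total, cell.motif_count, cell.class_count, cell.a
    p_up = float(hypergeom.sf(a - 1, N, K, n))
    p_down = float(hypergeom.cdf(a, N, K, n))
    return min(p_up, 1.0), min(p_down, 1.0)


@dataclass(frozen=True)
class CodeTableEntry:
    motif_rank: int
    motif: str
    intron_class: IntronClass
    cell: ContingencyCell
    p_up: float
    p_down: float
    significant_up: bool
    significant_down: bool


def fisher_enrichment(
    assignments: Mapping[str, PairedConsensus | None],
    labels: Mapping[str, IntronClass],
    alpha: float = 0.001,
) -> list[CodeTableEntry]:
    """Exact enrichment/depletion tests for every motif x intron class.

    ``assignments`` and ``labels`` must cover the same intron universe
    (keyed by intron id).  Returns one entry per (motif present in the
    assignments, class in the 36-class enumeration).
    """
    if set(assignments) != set(labels):
        raise ValueError("assignments and labels cover different introns")
    if not assignments:
        raise ValueError("empty intron universe")
    total = len(assignments)

    motifs: dict[str, PairedConsensus] = {}
    motif_of: dict[str, str | None] = {}
    for iid, pc in assignments.items():
        motif_of[iid] = pc.motif if pc is not None else None
        if pc is not None:
            motifs.setdefault(pc.motif, pc)

    class_counts: dict[IntronClass, int] = {c: 0 for c in enumerate_intron_classes()}
    overlap: dict[tuple[str, IntronClass], int] = {}
    motif_counts: dict[str, int] = {m: 0 for m in motifs}
    for iid, label in labels.items():
        class_counts[label] += 1
        m = motif_of[iid]
        if m is not None:
            motif_counts[m] += 1
            overlap[(m, label)] = overlap.get((m, label), 0) + 1

    entries: list[CodeTableEntry] = []
    for motif, pc in sorted(motifs.items(), key=lambda kv: kv[1].rank):
        K = motif_counts[motif]
        for klass in enumerate_intron_classes():
            n = class_counts[klass]
            a = overlap.get((motif, klass), 0)
            cell = ContingencyCell(a=a, b=K - a, c_=n - a, d=total - K - n + a)
            p_up, p_down = hypergeom_tails(cell)
            entries.append(
                CodeTableEntry(
                    motif_rank=pc.rank,
                    motif=motif,
                    intron_class=klass,
                    cell=cell,
                    p_up=p_up,
                    p_down=p_down,
                    significant_up=p_up < alpha,
                    significant_down=p_down < alpha,
                )
            )
    return entries


def benjamini_hochberg(pvalues: list[float]) -> list[float]:
    """BH-adjusted p-values (optional; the default reporting uses raw alpha)."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [0.0] * m
    prev = 1.0
    for rank_from_last, i in enumerate(reversed(order)):
        k = m - rank_from_last
        prev = min(prev, pvalues[i] * m / k)
        adjusted[i] = prev
    return adjusted


@dataclass
class SplicingCodeTable:
    """Per intron class: motif ranks significantly enriched and depleted.

    Rendered as a grid of upstream exon types (rows) x downstream types
    (columns) with enriched ranks in the upper cell and depleted ranks in
    the lower cell, mirroring the genetic-code-style layout.
    """

    enriched: dict[IntronClass, list[int]]
    depleted: dict[IntronClass, list[int]]
    alpha: float = 0.001

    def enriched_classes(self, rank: int) -> set[IntronClass]:
        return {c for c, ranks in self.enriched.items() if rank in ranks}

    def depleted_classes(self, rank: int) -> set[IntronClass]:
        return {c for c, ranks in self.depleted.items() if rank in ranks}

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("class\tenriched_ranks\tdepleted_ranks\n")
            for klass in enumerate_intron_classes():
                up = ",".join(map(str, self.enriched.get(klass, []))) or "None"
                down = ",".join(map(str, self.depleted.get(klass, []))) or "None"
                fh.write(f"{klass.value}\t{up}\t{down}\n")

    @classmethod
    def from_tsv(cls, path: str | Path, alpha: float = 0.001) -> "SplicingCodeTable":
        enriched: dict[IntronClass, list[int]] = {}
        depleted: dict[IntronClass, list[int]] = {}
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("class"):
                raise ValueError(f"unexpected header in {path}: {header!r}")
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                label, up, down = line.rstrip("\n").split("\t")
                klass = IntronClass(label)
                enriched[klass] = (
                    [] if up == "None" else [int(r) for r in up.split(",")]
                )
                depleted[klass] = (
                    [] if down == "None" else [int(r) for r in down.split(",")]
                )
        return cls(enriched=enriched, depleted=depleted, alpha=alpha)

    def render_grid(self) -> str:
        """Human-readable code grid (rows upstream, columns downstream)."""
        col_labels = [t.value for t in DOWNSTREAM_ORDER]
        lines = ["UP\t" + "\t".join(col_labels)]
        for up_type in UPSTREAM_ORDER:
            cells_up, cells_down = [], []
            for down_type in DOWNSTREAM_ORDER:
                klass = IntronClass(f"{up_type.value}-{down_type.value}")
                e = self.enriched.get(klass, [])
                d = self.depleted.get(klass, [])
                cells_up.append(",".join(map(str, e)) if e else "None")
                cells_down.append(",".join(map(str, d)) if d else "")
            lines.append(up_type.value + "\t" + "\t".join(cells_up))
            lines.append("\t" + "\t".join(cells_down))
        return "\n".join(lines)


def build_code_table(
    entries: Iterable[CodeTableEntry], alpha: float = 0.001
) -> SplicingCodeTable:
    """Collect significant ranks per class into the splicing-code table."""
    enriched: dict[IntronClass, list[int]] = {
        c: [] for c in enumerate_intron_classes()
    }
    depleted: dict[IntronClass, list[int]] = {
        c: [] for c in enumerate_intron_classes()
    }
    for entry in entries:
        if entry.p_up < alpha:
            enriched[entry.intron_class].append(entry.motif_rank)
        if entry.p_down < alpha:
            depleted[entry.intron_class].append(entry.motif_rank)
    for ranks in enriched.values():
        ranks.sort()
    for ranks in depleted.values():
        ranks.sort()
    return SplicingCodeTable(enriched=enriched, depleted=depleted, alpha=alpha)


def write_entries_tsv(entries: Iterable[CodeTableEntry], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "motif_rank\tmotif\tclass\ta\tmotif_count\tclass_count\ttotal\t"
            "p_up\tp_down\tsignificant_up\tsignificant_down\n"
        )
        for e in entries:
            fh.write(
                f"{e.motif_rank}\t{e.motif}\t{e.intron_class.value}\t{e.cell.a}\t"
                f"{e.cell.motif_count}\t{e.cell.class_count}\t{e.cell.total}\t"
                f"{e.p_up:.6g}\t{e.p_down:.6g}\t"
                f"{int(e.significant_up)}\t{int(e.significant_down)}\n"
            )
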