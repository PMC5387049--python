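"""Paired splice-site consensus discovery via quaternary count trees.

Donor sequences (intron 5' prefixes) populate a prefix tree over the RNA
alphabet {a,c,g,u}; acceptor sequences (intron 3' suffixes) populate a
suffix tree indexed from the 3' end inward.  Each node carries the number
of sequences passing through it, its conditional branch probability
(node count / parent count) and the Shannon entropy (bits) of its
children's count distribution.  Highly conserved branches — high branch
probability, low child entropy, backed by at least ``min_count``
sequences — are selected by empirical percentiles, and conserved donor
and acceptor motifs are paired into ``donor_acceptor`` consensus strings
(e.g. ``guaagu_ag``).

Every intron is then assigned exclusively to the *most specific* pair it
matches: the underscore in ``gu_ag`` stands for any sequence *except*
one matching a more specific consensus in the table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

from .genome_model import IntronRecord

RNA_ALPHABET = "acgu"
DONOR_CORES = ("gu", "gc", "au")
ACCEPTOR_CORES = ("ag", "ac")


@dataclass
class TreeNode:
    """One node of a quaternary tree; ``path`` reads in natural 5'->3' order."""

    path: str
    depth: int
    count: int = 0
    terminating: int = 0
    branch_probability: float = 1.0
    child_entropy: float = 0.0
    children: dict[str, "TreeNode"] = field(default_factory=dict)

    def walk(self) -> Iterator["TreeNode"]:
        yield self
        for symbol in RNA_ALPHABET:
            if symbol in self.children:
                yield from self.children[symbol].walk()


@dataclass
class QuaternaryTree:
    """Prefix (donor) or suffix (acceptor) count tree over {a,c,g,u}."""

    direction: str  # "donor-prefix" | "acceptor-suffix"
    root: TreeNode
    max_depth: int

    def nodes(self) -> Iterator[TreeNode]:
        yield from self.root.walk()

    @property
    def n_sequences(self) -> int:
        return self.root.count


def _shannon_entropy(counts: Sequence[int]) -> float:
    total = sum(counts)
    if total == 0:
        return 0.0
    p = np.asarray([c for c in counts if c > 0], dtype=float) / total
    return float(-(p * np.log2(p)).sum())


def build_quaternary_tree(
    sequences: Iterable[str],
    direction: str,
    max_depth: int = 10,
) -> QuaternaryTree:
    """Count tree from RNA strings; acceptor sequences are read 3'->5'.

    Node paths are always stored in natural 5'->3' reading order, so an
    acceptor node at depth 2 reached by inserting ``...ag`` has path
    ``"ag"``.
    """
    if direction not in ("donor-prefix", "acceptor-suffix"):
        raise ValueError(f"unknown direction {direction!r}")
    root = TreeNode(path="", depth=0)
    n_inserted = 0
    for seq in sequences:
        if any(b not in RNA_ALPHABET for b in seq):
            raise ValueError(f"sequence {seq!r} not over {{a,c,g,u}}")
        n_inserted += 1
        symbols = seq[:max_depth] if direction == "donor-prefix" else seq[::-1][:max_depth]
        node = root
        node.count += 1
        for sym in symbols:
            if sym not in node.children:
                if direction == "donor-prefix":
                    child_path = node.path + sym
                else:
                    child_path = sym + node.path
                node.children[sym] = TreeNode(path=child_path, depth=node.depth + 1)
            node = node.children[sym]
            node.count += 1
        node.terminating += 1
    if n_inserted == 0:
        raise ValueError("no sequences to build tree from")

    for node in root.walk():
        child_counts = [c.count for c in node.children.values()]
        node.child_entropy = _shannon_entropy(child_counts)
        for child in node.children.values():
            child.branch_probability = child.count / node.count
    return QuaternaryTree(direction=direction, root=root, max_depth=max_depth)


def select_conserved_branches(
    tree: QuaternaryTree,
    min_count: int = 100,
    prob_percentile: float = 0.95,
    entropy_percentile: float = 0.05,
) -> set[str]:
    """Motifs of the most conserved branches of a populated tree.

    A branch is the edge into a non-root node with ``count >=
    min_count``.  Its conservation is measured by the node's branch
    probability (how forced the step was) together with the Shannon
    entropy at its parent's branching point (how concentrated the choice
    was).  A branch is kept when its probability is at or above the
    ``prob_percentile`` empirical quantile of all eligible branch
    probabilities *and* its parent entropy is at or below the
    ``entropy_percentile`` quantile of all eligible parent entropies
    (ties inclusive at both thresholds).  The deepest kept node on each
    root-to-leaf path is returned as a motif string, so motif families
    of different lengths coexist: a shorter conserved prefix still names
    the paths on which no deeper branch is conserved.
    """
    # eligible edges: (parent, child) with child count >= min_count
    edges: list[tuple[TreeNode, TreeNode]] = []

    def collect(node: TreeNode) -> None:
        for child in node.children.values():
            if child.count >= min_count:
                edges.append((node, child))
            collect(child)

    collect(tree.root)
    if not edges:
        raise ValueError(f"no branch with at least {min_count} sequences")
    # the cut is the nearest observed value on the kept side, so that
    # "inclusive at the threshold" keeps every tied branch
    probs = np.array([child.branch_probability for _, child in edges])
    ents = np.array([parent.child_entropy for parent, _ in edges])
    prob_cut = float(np.quantile(probs, prob_percentile, method="lower"))
    ent_cut = float(np.quantile(ents, entropy_percentile, method="higher"))
    kept = {
        id(child)
        for parent, child in edges
        if child.branch_probability >= prob_cut
        and parent.child_entropy <= ent_cut
    }

    motifs: set[str] = set()

    def walk(node: TreeNode, deepest_kept: str | None) -> None:
        if id(node) in kept:
            deepest_kept = node.path
        if not node.children:
            if deepest_kept is not None:
                motifs.add(deepest_kept)
            return
        for child in node.children.values():
            walk(child, deepest_kept)
        # sequences terminating here end a path of their own
        if node.terminating and deepest_kept is not None:
            motifs.add(deepest_kept)

    walk(tree.root, None)
    return motifs


@dataclass(frozen=True)
class PairedConsensus:
    """A ``donor_acceptor`` consensus with its exclusive intron count."""

    donor_motif: str
    acceptor_motif: str
    count: int
    rank: int

    @property
    def motif(self) -> str:
        return f"{self.donor_motif}_{self.acceptor_motif}"

    def matches(self, donor_seq: str, acceptor_seq: str) -> bool:
        return donor_seq.startswith(self.donor_motif) and acceptor_seq.endswith(
            self.acceptor_motif
        )


@dataclass
class PairedConsensusTable:
    """Rank-ordered paired consensus motifs (rank 0 "ALL" = total introns)."""

    motifs: list[PairedConsensus]
    total_introns: int

    def __iter__(self) -> Iterator[PairedConsensus]:
        return iter(self.motifs)

    def __len__(self) -> int:
        return len(self.motifs)

    def by_rank(self, rank: int) -> PairedConsensus:
        for m in self.motifs:
            if m.rank == rank:
                return m
        raise KeyError(f"no motif with rank {rank}")

    def by_motif(self, motif: str) -> PairedConsensus:
        for m in self.motifs:
            if m.motif == motif:
                return m
        raise KeyError(f"motif {motif} not in table")

    @property
    def motif_strings(self) -> set[str]:
        return {m.motif for m in self.motifs}

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("rank\tmotif\tcount\n")
            fh.write(f"0\tALL\t{self.total_introns}\n")
            for m in self.motifs:
                fh.write(f"{m.rank}\t{m.motif}\t{m.count}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PairedConsensusTable":
        motifs: list[PairedConsensus] = []
        total = 0
        with open(path) as fh:
            header = fh.readline()
            if not header.lower().startswith("rank"):
                raise ValueError(f"unexpected header in {path}: {header!r}")
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                rank_s, motif, count_s = line.rstrip("\n").split("\t")
                count = int(count_s.replace(",", ""))
                if int(rank_s) == 0:
                    total = count
                    continue
                donor, acceptor = motif.split("_")
                motifs.append(
                    PairedConsensus(donor, acceptor, count=count, rank=int(rank_s))
                )
        return cls(motifs=motifs, total_introns=total)


def assign_motif(
    donor_seq: str,
    acceptor_seq: str,
    table: PairedConsensusTable,
) -> PairedConsensus | None:
    """Most specific consensus pair matched by a donor/acceptor sequence pair.

    "Most specific" maximizes donor motif length, then acceptor motif
    length, then prefers the lower (more common) rank; returns None when
    no pair in the table matches.
    """
    if not table.motifs:
        raise ValueError("empty consensus table")
    best: PairedConsensus | None = None
    for cand in table.motifs:
        if not cand.matches(donor_seq, acceptor_seq):
            continue
        if best is None:
            best = cand
            continue
        key = (len(cand.donor_motif), len(cand.acceptor_motif), -cand.rank)
        best_key = (len(best.donor_motif), len(best.acceptor_motif), -best.rank)
        if key > best_key:
            best = cand
    return best


def _has_valid_cores(donor_motif: str, acceptor_motif: str) -> bool:
    return donor_motif.startswith(DONOR_CORES) and acceptor_motif.endswith(
        ACCEPTOR_CORES
    )


def build_paired_consensus_table(
    introns: Sequence[IntronRecord],
    min_count: int = 100,
    prob_percentile: float = 0.95,
    entropy_percentile: float = 0.05,
    max_depth: int = 10,
) -> PairedConsensusTable:
    """Discover the ranked paired-consensus table from a set of introns.

    Donor and acceptor trees are built over all introns and their
    conserved branches paired (Cartesian product, restricted to motifs
    with a valid splice core: donor gu/gc/au, acceptor ag/ac).  Introns
    are assigned exclusively to their most specific candidate pair; pairs
    falling below ``min_count`` assigned introns are dropped and the
    assignment re-iterated until stable.  Surviving pairs are ranked by
    descending count (ties lexicographic by donor then acceptor motif).
    """
    if len(introns) < min_count:
        raise ValueError(
            f"need at least {min_count} introns, got {len(introns)}"
        )
    donor_tree = build_quaternary_tree(
        (r.donor_seq for r in introns), "donor-prefix", max_depth=max_depth
    )
    acceptor_tree = build_quaternary_tree(
        (r.acceptor_seq for r in introns), "acceptor-suffix", max_depth=max_depth
    )
    donors = select_conserved_branches(
        donor_tree, min_count, prob_percentile, entropy_percentile
    )
    acceptors = select_conserved_branches(
        acceptor_tree, min_count, prob_percentile, entropy_percentile
    )
    candidates = [
        (d, a) for d in sorted(donors) for a in sorted(acceptors)
        if _has_valid_cores(d, a)
    ]

    pairs = set(candidates)
    while True:
        working = PairedConsensusTable(
            motifs=[
                PairedConsensus(d, a, count=0, rank=i + 1)
                for i, (d, a) in enumerate(sorted(pairs))
            ],
            total_introns=len(introns),
        )
        counts: dict[tuple[str, str], int] = {p: 0 for p in pairs}
        if working.motifs:
            for rec in introns:
                hit = assign_motif(rec.donor_seq, rec.acceptor_seq, working)
                if hit is not None:
                    counts[(hit.donor_motif, hit.acceptor_motif)] += 1
        surviving = {p for p, c in counts.items() if c >= min_count}
        if surviving == pairs:
            break
        pairs = surviving

    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    motifs = [
        PairedConsensus(d, a, count=c, rank=i + 1)
        for i, ((d, a), c) in enumerate(ranked)
        if (d, a) in pairs
    ]
    return PairedConsensusTable(motifs=motifs, total_introns=len(introns))


def assign_all(
    introns: Sequence[IntronRecord], table: PairedConsensusTable
) -> dict[str, PairedConsensus | None]:
    """Exclusive motif assignment for every intron, keyed by intron id."""
    return {
        r.intron_id: assign_motif(r.donor_seq, r.acceptor_seq, table)
        for r in introns
    }


def compare_motif_tables(
    table_a: PairedConsensusTable, table_b: PairedConsensusTable
) -> dict[str, object]:
    """Shared-motif overlap between two consensus tables.

    Returns the shared motif set, the fraction of A's motifs shared, the
    symmetric (Jaccard) fraction, and B's perspective.
    """
    if not table_a.motifs or not table_b.motifs:
        raise ValueError("both tables must be non-empty")
    a, b = table_a.motif_strings, table_b.motif_strings
    shared = a & b
    return {
        "shared": shared,
        "fraction_of_a": len(shared) / len(a),
        "fraction_of_b": len(shared) / len(b),
        "jaccard": len(shared) / len(a | b),
    }
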