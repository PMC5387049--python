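"""Within-gene co-occurrence of consensus ranks and its clustering.

If distinct spliceosome subtypes each process most introns of a gene,
genes should reuse a small set of consensus ranks.  The association of
rank i with rank j is measured by the Jaccard index over genes
(|genes with both| / |genes with either|), giving a symmetric matrix
with unit diagonal, which is then clustered agglomeratively (average
linkage on 1 - association).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform


@dataclass
class CooccurrenceMatrix:
    ranks: list[int]
    matrix: np.ndarray  # square, symmetric, values in [0, 1], diag 1

    def value(self, rank_i: int, rank_j: int) -> float:
        i, j = self.ranks.index(rank_i), self.ranks.index(rank_j)
        return float(self.matrix[i, j])

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("rank\t" + "\t".join(map(str, self.ranks)) + "\n")
            for r, row in zip(self.ranks, self.matrix):
                fh.write(str(r) + "\t" + "\t".join(f"{v:.4f}" for v in row) + "\n")


def build_cooccurrence(
    gene_rank_sets: Mapping[str, set[int]],
    measure: str = "jaccard",
) -> CooccurrenceMatrix:
    """Rank-by-rank association across genes.

    ``measure``: ``jaccard`` (default), ``dice``, or ``conditional``
    (symmetrized as max of the two conditional probabilities).
    The diagonal is 1 for every rank present in at least one gene.
    """
    if not gene_rank_sets or not any(gene_rank_sets.values()):
        raise ValueError("no gene has any assigned rank")
    ranks = sorted({r for s in gene_rank_sets.values() for r in s})
    genes_with = {
        r: {g for g, s in gene_rank_sets.items() if r in s} for r in ranks
    }
    n = len(ranks)
    mat = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            gi, gj = genes_with[ranks[i]], genes_with[ranks[j]]
            both = len(gi & gj)
            if measure == "jaccard":
                denom = len(gi | gj)
                v = both / denom if denom else 0.0
            elif measure == "dice":
                denom = len(gi) + len(gj)
                v = 2 * both / denom if denom else 0.0
            elif measure == "conditional":
                v = max(
                    both / len(gi) if gi else 0.0,
                    both / len(gj) if gj else 0.0,
                )
            else:
                raise ValueError(f"unknown measure {measure!r}")
            mat[i, j] = mat[j, i] = v
    return CooccurrenceMatrix(ranks=ranks, matrix=mat)


def cluster_ranks(
    matrix: CooccurrenceMatrix, n_clusters: int | None = None
) -> tuple[dict[int, int], np.ndarray]:
    """Agglomerative clustering of ranks on distance 1 - association.

    With ``n_clusters=None`` the tree is cut at half the maximum merge
    distance.  Returns (rank -> cluster id, scipy linkage matrix).
    Deterministic given the input; invariant to rank relabeling.
    """
    n = len(matrix.ranks)
    if n_clusters is not None and n_clusters > n:
        raise ValueError(f"requested {n_clusters} clusters for {n} ranks")
    if n == 1:
        return {matrix.ranks[0]: 1}, np.empty((0, 4))
    dist = 1.0 - matrix.matrix
    np.fill_diagonal(dist, 0.0)
    Z = average(squareform(dist, checks=False))
    if n_clusters is None:
        cut = Z[:, 2].max() / 2 if len(Z) else 0.0
        labels = fcluster(Z, t=cut, criterion="distance")
    else:
        labels = fcluster(Z, t=n_clusters, criterion="maxclust")
    return dict(zip(matrix.ranks, (int(l) for l in labels))), Z


def intron_count_distribution(
    gene_intron_counts: Mapping[str, int],
    bins: Iterable[tuple[int, int]] = ((1, 5), (6, 10), (11, 15), (16, 10**9)),
) -> list[dict]:
    """Fraction of genes whose intron count falls in each bin."""
    total = len(gene_intron_counts)
    if total == 0:
        raise ValueError("no genes")
    rows = []
    for lo, hi in bins:
        n = sum(1 for c in gene_intron_counts.values() if lo <= c <= hi)
        label = f"{lo}+" if hi >= 10**9 else f"{lo}-{hi}"
        rows.append({"introns_per_gene": label, "n_genes": n, "fraction": n / total})
    return rows
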