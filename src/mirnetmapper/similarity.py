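"""Structural equivalence of miRNAs: Jaccard distances and clustering.

Two miRNAs are structurally equivalent to the extent that they regulate
the same genes.  Dissimilarity is measured by the Jaccard distance

    D(i, j) = 1 - |t_i ∩ t_j| / |t_i ∪ t_j|

over their target sets — a metric on finite sets that counts only mutual
*presence* of targets.  (Coefficients such as simple matching would call
two miRNAs similar merely for sharing a long list of genes neither
targets, which is meaningless in a sparse regulatory network.)

Agglomerative hierarchical clustering over D exposes groups of
cooperative miRNAs.  The merge loop is implemented here rather than
delegated, so that ties in the linkage value resolve by a fixed,
input-order-independent rule; the result is emitted as a standard
linkage matrix that scipy's dendrogram/fcluster utilities consume.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import AbstractSet, Literal

import numpy as np
from scipy.cluster.hierarchy import leaves_list

from .adjacency import AdjacencyMatrix

logger = logging.getLogger("mirnetmapper")

Linkage = Literal["complete", "average", "single"]
LINKAGES = ("complete", "average", "single")


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric Jaccard distance matrix over miRNA target sets."""

    mirna_ids: tuple[str, ...]
    D: np.ndarray  # square, symmetric, zero diagonal, values in [0, 1]

    def __post_init__(self) -> None:
        n = len(self.mirna_ids)
        if self.D.shape != (n, n):
            raise ValueError("distance matrix shape does not match id list")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            self.D, index=list(self.mirna_ids), columns=list(self.mirna_ids)
        )


@dataclass(frozen=True)
class ClusterTree:
    """Rooted binary merge tree over miRNA ids.

    ``merges`` is a standard (n-1) x 4 linkage matrix: each row
    ``[a, b, height, size]`` merges clusters ``a`` and ``b`` (ids 0..n-1
    are leaves, id n+k is the cluster formed at step k) at the given
    linkage height.  Heights are nondecreasing for the supported
    linkages.
    """

    labels: tuple[str, ...]
    merges: np.ndarray
    linkage: Linkage

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2].copy()

    @property
    def leaf_order(self) -> tuple[str, ...]:
        """Left-to-right dendrogram leaf order."""
        if self.n_leaves == 1:
            return self.labels
        return tuple(self.labels[i] for i in leaves_list(self.merges))


def jaccard_distance(ti: AbstractSet[str], tj: AbstractSet[str]) -> float:
    """Jaccard distance between two nonempty target sets."""
    union = len(ti | tj)
    if union == 0:
        raise ValueError("Jaccard distance undefined for two empty sets (0/0)")
    return 1.0 - len(ti & tj) / union


def jaccard_matrix(adj: AdjacencyMatrix) -> DistanceMatrix:
    """All pairwise Jaccard distances between miRNA target columns.

    Columns with no targets (possible after strict intersection against
    the DE list) have an undefined distance to everything and are
    dropped with a warning before the computation.
    """
    col_sums = adj.mirna_sums
    keep = col_sums >= 1
    if not keep.all():
        dropped = [m for m, k in zip(adj.mirna_ids, keep) if not k]
        logger.warning(
            "excluding %d miRNA(s) with zero targets from the distance matrix: %s",
            len(dropped), ", ".join(dropped),
        )
    ids = tuple(m for m, k in zip(adj.mirna_ids, keep) if k)
    if len(ids) < 2:
        raise ValueError("fewer than 2 miRNAs with targets: nothing to cluster")
    cells = adj.cells[:, keep].astype(np.int64)
    inter = cells.T @ cells
    sizes = np.diag(inter)
    union = sizes[:, None] + sizes[None, :] - inter
    D = 1.0 - inter / union
    np.fill_diagonal(D, 0.0)
    return DistanceMatrix(mirna_ids=ids, D=D)


def _lw_update(method: Linkage, d_ik: np.ndarray, d_jk: np.ndarray,
               n_i: int, n_j: int) -> np.ndarray:
    # Lance-Williams update of distances from the merged cluster (i ∪ j)
    # to every other active cluster k.
    if method == "complete":
        return np.maximum(d_ik, d_jk)
    if method == "single":
        return np.minimum(d_ik, d_jk)
    if method == "average":
        return (n_i * d_ik + n_j * d_jk) / (n_i + n_j)
    raise ValueError(f"unknown linkage {method!r}")


def cluster_mirnas(D: DistanceMatrix, linkage: Linkage = "complete") -> ClusterTree:
    """Agglomerative hierarchical clustering of the distance matrix.

    At each step the pair of active clusters with minimal linkage
    distance is merged.  When several pairs tie exactly, the pair whose
    combined, sorted leaf-name tuple is lexicographically smallest wins —
    a deterministic rule that does not depend on input row order.
    """
    if linkage not in LINKAGES:
        raise ValueError(f"linkage must be one of {LINKAGES}, got {linkage!r}")
    n = len(D.mirna_ids)
    if n < 2:
        raise ValueError("need at least 2 miRNAs to cluster")
    if not np.isfinite(D.D).all():
        raise ValueError("non-finite entries in the distance matrix")

    work = D.D.astype(float).copy()
    active: dict[int, tuple[str, ...]] = {
        i: (D.mirna_ids[i],) for i in range(n)
    }  # cluster id -> sorted leaf names
    sizes = {i: 1 for i in range(n)}
    # row index in `work` for each active cluster id (merged clusters reuse
    # one of the two parent rows)
    row_of = {i: i for i in range(n)}
    merges = np.zeros((n - 1, 4))

    for step in range(n - 1):
        ids = sorted(active)
        best: tuple[float, tuple[str, ...], int, int] | None = None
        for a_pos, a in enumerate(ids):
            ra = row_of[a]
            for b in ids[a_pos + 1:]:
                d = work[ra, row_of[b]]
                key = tuple(sorted(active[a] + active[b]))
                cand = (d, key, a, b)
                if best is None or cand < best:
                    best = cand
        assert best is not None
        d, _, a, b = best
        ra, rb = row_of[a], row_of[b]
        other_rows = np.array([row_of[c] for c in ids if c not in (a, b)], dtype=int)
        if other_rows.size:
            new_d = _lw_update(linkage, work[ra, other_rows], work[rb, other_rows],
                               sizes[a], sizes[b])
            work[ra, other_rows] = new_d
            work[other_rows, ra] = new_d
        new_id = n + step
        active[new_id] = tuple(sorted(active[a] + active[b]))
        sizes[new_id] = sizes[a] + sizes[b]
        row_of[new_id] = ra
        merges[step] = [min(a, b), max(a, b), d, sizes[new_id]]
        for stale in (a, b):
            del active[stale], sizes[stale], row_of[stale]

    return ClusterTree(labels=D.mirna_ids, merges=merges, linkage=linkage)


def export_newick(tree: ClusterTree) -> str:
    """Serialise the merge tree as a Newick string with branch lengths.

    Each internal node sits at half its merge height (the dendrogram
    midpoint convention, as when converting an hclust tree to a
    phylogeny); leaves sit at height 0, so a two-leaf tree merged at h
    renders as ``(m1:h/2,m2:h/2);``.
    """
    n = tree.n_leaves
    half = {i: 0.0 for i in range(n)}
    for k, (a, b, h, _) in enumerate(tree.merges):
        half[n + k] = h / 2.0

    def render(node: int, parent_half: float) -> str:
        length = parent_half - half[node]
        if node < n:
            return f"{tree.labels[node]}:{length:g}"
        a, b = int(tree.merges[node - n, 0]), int(tree.merges[node - n, 1])
        return f"({render(a, half[node])},{render(b, half[node])}):{length:g}"

    root = n + len(tree.merges) - 1
    a, b = int(tree.merges[-1, 0]), int(tree.merges[-1, 1])
    return f"({render(a, half[root])},{render(b, half[root])});"
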