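"""Brute-force reference implementations used only for cross-checking.

These deliberately avoid the package's own code paths: Jaccard distances
come from Python set arithmetic over the raw edge list, and the
agglomerative clustering recomputes every inter-cluster linkage from the
original distance matrix at every step (no Lance-Williams updates).
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def jaccard_from_edges(edges) -> tuple[list[str], np.ndarray]:
    """Pairwise Jaccard distances by direct set arithmetic."""
    targets: dict[str, set[str]] = {}
    for m, g in edges:
        targets.setdefault(m, set()).add(g)
    ids = list(targets)
    n = len(ids)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                ti, tj = targets[ids[i]], targets[ids[j]]
                D[i, j] = 1.0 - len(ti & tj) / len(ti | tj)
    return ids, D


def _cluster_dist(D: np.ndarray, a: list[int], b: list[int], method: str) -> float:
    cross = [D[i, j] for i in a for j in b]
    if method == "complete":
        return max(cross)
    if method == "single":
        return min(cross)
    if method == "average":
        return float(np.mean(cross))
    raise ValueError(method)


def naive_agglomerative_heights(
    D: np.ndarray, labels: list[str], method: str
) -> list[float]:
    """Merge heights of agglomerative clustering, O(n^3) from first principles.

    Linkage between clusters is recomputed from the original matrix each
    step.  Ties resolve toward the pair whose combined sorted label
    tuple is lexicographically smallest (the documented rule).
    """
    clusters: list[list[int]] = [[i] for i in range(len(labels))]
    heights: list[float] = []
    while len(clusters) > 1:
        best = None
        for a, b in combinations(clusters, 2):
            d = _cluster_dist(D, a, b, method)
            key = tuple(sorted(labels[i] for i in a + b))
            cand = (d, key, a, b)
            if best is None or cand[:2] < best[:2]:
                best = cand
        d, _, a, b = best
        heights.append(d)
        clusters.remove(a)
        clusters.remove(b)
        clusters.append(a + b)
    return heights
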