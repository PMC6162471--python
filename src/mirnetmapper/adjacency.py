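"""Binary gene x miRNA adjacency matrix and gene degree of centrality.

A gene's degree of centrality is the number of distinct miRNAs predicted
to target it — the row sum of the binary incidence matrix.  Genes hit by
many miRNAs are candidate key genes of the system under study.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import InteractionTable


@dataclass(frozen=True)
class AdjacencyMatrix:
    """Binary genes x miRNAs incidence with per-gene degree sums.

    Rows (genes) are ordered by descending degree then gene id; columns
    (miRNAs) by descending target count then miRNA id.  The ordering is a
    presentation choice — every computation downstream is order-invariant.
    """

    gene_ids: tuple[str, ...]
    mirna_ids: tuple[str, ...]
    cells: np.ndarray  # shape (n_genes, n_mirnas), dtype int8, values {0,1}

    def __post_init__(self) -> None:
        n_g, n_m = self.cells.shape
        if n_g != len(self.gene_ids) or n_m != len(self.mirna_ids):
            raise ValueError("cells shape does not match id lists")

    @property
    def gene_sums(self) -> np.ndarray:
        """Degree of centrality per gene (row sums)."""
        return self.cells.sum(axis=1)

    @property
    def mirna_sums(self) -> np.ndarray:
        """Target count per miRNA (column sums)."""
        return self.cells.sum(axis=0)

    @property
    def n_edges(self) -> int:
        return int(self.cells.sum())

    def to_frame(self) -> pd.DataFrame:
        """Tabular form: gene_id, one 0/1 column per miRNA, final 'Sums' column."""
        frame = pd.DataFrame(self.cells, columns=list(self.mirna_ids))
        frame.insert(0, "gene_id", list(self.gene_ids))
        frame["Sums"] = self.gene_sums
        return frame

    def to_edges(self) -> InteractionTable:
        """Recover the canonical edge list (column-major: per miRNA, its targets)."""
        rows, cols = np.nonzero(self.cells)
        pairs = sorted(zip(cols.tolist(), rows.tolist()))
        edges = tuple((self.mirna_ids[c], self.gene_ids[r]) for c, r in pairs)
        return InteractionTable(edges=edges)


def build_adjacency(interactions: InteractionTable) -> AdjacencyMatrix:
    """Build the binary incidence matrix from a canonical edge list."""
    if interactions.n_edges == 0:
        raise ValueError("cannot build adjacency from an empty interaction table")
    targets = interactions.targets_of()
    gene_count: dict[str, int] = {}
    for _, g in interactions.edges:
        gene_count[g] = gene_count.get(g, 0) + 1
    genes = tuple(sorted(gene_count, key=lambda g: (-gene_count[g], g)))
    mirnas = tuple(sorted(targets, key=lambda m: (-len(targets[m]), m)))
    g_index = {g: i for i, g in enumerate(genes)}
    m_index = {m: j for j, m in enumerate(mirnas)}
    cells = np.zeros((len(genes), len(mirnas)), dtype=np.int8)
    for m, g in interactions.edges:
        cells[g_index[g], m_index[m]] = 1
    return AdjacencyMatrix(gene_ids=genes, mirna_ids=mirnas, cells=cells)


def rank_genes_by_centrality(adj: AdjacencyMatrix) -> pd.DataFrame:
    """Genes sorted by degree of centrality descending, ties lexicographic.

    The top-ranked gene is the one regulated by the most miRNAs — under
    the working assumption, the most crucial gene of the network.
    """
    frame = pd.DataFrame({
        "gene_id": list(adj.gene_ids),
        "degree_of_centrality": adj.gene_sums.astype(int),
    })
    return (
        frame.sort_values(
            ["degree_of_centrality", "gene_id"], ascending=[False, True]
        )
        .reset_index(drop=True)
    )
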