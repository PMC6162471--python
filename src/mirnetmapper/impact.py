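"""Per-miRNA impact: degree of centrality scaled to the target/DE universes.

For each miRNA *m* with *t* predicted targets found among the analysed
genes, two proportions are reported:

* ``t / T`` — share of the *T* distinct genes targeted by at least one
  miRNA in the network (centrality within the regulated set);
* ``t / G`` — share of all *G* differentially expressed genes (overall
  impact on the transcriptional response).

Both are stored as percentages at full precision; rounding is a display
concern (`render_impact_table`).  ``T`` is the number of distinct genes
with degree >= 1 in the adjacency matrix; ``G`` comes from the DE gene
list and falls back to ``T`` when no list is supplied, in which case the
two columns coincide and the second is flagged as derived.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_EVEN, Decimal

import pandas as pd

from .adjacency import AdjacencyMatrix
from .io import DEGeneList

COLUMNS = (
    "miRNA",
    "Predicted_Genes_Found",
    "Percentage_of_Targets",
    "Percentage_of_DE_Genes",
)


@dataclass(frozen=True)
class ImpactTable:
    """Ranked per-miRNA impact table.

    ``frame`` columns: miRNA, Predicted_Genes_Found (t),
    Percentage_of_Targets (100*t/T), Percentage_of_DE_Genes (100*t/G);
    sorted by t descending, ties by miRNA id ascending.
    """

    frame: pd.DataFrame
    T: int
    G: int
    de_list_provided: bool = True


def compute_impact(adj: AdjacencyMatrix, de: DEGeneList | None = None) -> ImpactTable:
    """Compute t, 100*t/T and 100*t/G for every miRNA column of ``adj``."""
    T = int((adj.gene_sums >= 1).sum())
    if T == 0:
        raise ValueError("empty adjacency: no gene is targeted by any miRNA")
    de_provided = de is not None
    G = de.size_G if de is not None else T
    t = adj.mirna_sums.astype(int)
    frame = pd.DataFrame({
        "miRNA": list(adj.mirna_ids),
        "Predicted_Genes_Found": t,
        "Percentage_of_Targets": 100.0 * t / T,
        "Percentage_of_DE_Genes": 100.0 * t / G,
    })
    frame = frame.sort_values(
        ["Predicted_Genes_Found", "miRNA"], ascending=[False, True]
    ).reset_index(drop=True)
    return ImpactTable(frame=frame, T=T, G=G, de_list_provided=de_provided)


def round_half_even(value: float, decimals: int) -> float:
    """Banker's rounding on the decimal representation of ``value``."""
    quantum = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(value))).quantize(quantum, ROUND_HALF_EVEN))


def render_impact_table(impact: ImpactTable, decimals: int = 1) -> pd.DataFrame:
    """Display copy of the impact table with percentages rounded half-even.

    The underlying `ImpactTable` keeps full precision; this produces the
    file/print rendering only.
    """
    frame = impact.frame.copy()
    for col in ("Percentage_of_Targets", "Percentage_of_DE_Genes"):
        frame[col] = [round_half_even(v, decimals) for v in frame[col]]
    return frame
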