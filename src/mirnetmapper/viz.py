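"""Graphical outputs: impact barplot, dendrogram, identity heatmap.

All plots are pure functions of their tabular inputs plus a `PlotSpec`;
for SVG output, timestamps and entropy in element ids are suppressed so
identical inputs give byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from scipy.cluster.hierarchy import dendrogram as _scipy_dendrogram

from .impact import ImpactTable
from .similarity import ClusterTree, DistanceMatrix

PlotFormat = Literal["png", "svg", "pdf"]
PLOT_FORMATS = ("png", "svg", "pdf")

# Fig-caption colors: percentage of targets in red, percentage of DE genes in blue.
TARGET_COLOR = "red"
DE_COLOR = "blue"


@dataclass(frozen=True)
class PlotSpec:
    """Rendering parameters shared by all three plot kinds."""

    output_path: str
    format: PlotFormat = "png"
    dpi: int = 150
    decimals: int = 1

    def __post_init__(self) -> None:
        if self.format not in PLOT_FORMATS:
            raise ValueError(
                f"unsupported plot format {self.format!r}; choose from {PLOT_FORMATS}"
            )


def _save(fig, spec: PlotSpec) -> Path:
    path = Path(spec.output_path)
    kwargs = {"dpi": spec.dpi, "bbox_inches": "tight"}
    if spec.format == "svg":
        kwargs["metadata"] = {"Date": None}
        with matplotlib.rc_context({"svg.hashsalt": "mirnetmapper"}):
            fig.savefig(path, format=spec.format, **kwargs)
    else:
        fig.savefig(path, format=spec.format, **kwargs)
    plt.close(fig)
    return path


def plot_impact_barplot(impact: ImpactTable, spec: PlotSpec) -> Path:
    """Grouped barplot of per-miRNA impact, ordered by targets found.

    Two bars per miRNA: percentage of total targets (red) and percentage
    of total DE genes (blue), y-axis in percent, miRNAs left to right
    from greatest to least number of impacted genes.
    """
    frame = impact.frame
    if frame.empty:
        raise ValueError("empty impact table")
    x = np.arange(len(frame))
    width = 0.4
    fig, ax = plt.subplots(figsize=(max(6.0, 0.8 * len(frame)), 4.5))
    ax.bar(x - width / 2, frame["Percentage_of_Targets"], width,
           color=TARGET_COLOR, label="% of total targets")
    ax.bar(x + width / 2, frame["Percentage_of_DE_Genes"], width,
           color=DE_COLOR, label="% of total DE genes")
    ax.set_xticks(x)
    ax.set_xticklabels(frame["miRNA"], rotation=60, ha="right")
    ax.set_ylabel("Impact (%)")
    ax.set_title("miRNA impact on gene expression")
    ax.legend(frameon=False)
    return _save(fig, spec)


def plot_dendrogram(tree: ClusterTree, spec: PlotSpec) -> Path:
    """Dendrogram of the miRNA clustering; height axis is linkage distance."""
    if tree.n_leaves < 2:
        raise ValueError("dendrogram needs at least 2 leaves")
    fig, ax = plt.subplots(figsize=(max(6.0, 0.6 * tree.n_leaves), 4.5))
    _scipy_dendrogram(tree.merges, labels=list(tree.labels), ax=ax,
                      color_threshold=0.0, above_threshold_color="black")
    ax.set_ylabel(f"Jaccard distance ({tree.linkage} linkage)")
    ax.set_title("miRNA clustering by shared targets")
    plt.setp(ax.get_xticklabels(), rotation=60, ha="right")
    return _save(fig, spec)


def ordered_similarity(
    D: DistanceMatrix, tree: ClusterTree
) -> tuple[list[str], np.ndarray]:
    """Similarity matrix (1 - D) with rows/columns in dendrogram leaf order."""
    if set(D.mirna_ids) != set(tree.labels):
        raise ValueError("distance matrix and tree cover different miRNA sets")
    order = [D.mirna_ids.index(m) for m in tree.leaf_order]
    return [D.mirna_ids[i] for i in order], 1.0 - D.D[np.ix_(order, order)]


def plot_identity(D: DistanceMatrix, tree: ClusterTree, spec: PlotSpec) -> Path:
    """Identity heatmap: Jaccard similarity (1 - D) ordered by the tree.

    The diagonal is self-similarity 1.  Rows and columns follow the
    dendrogram leaf order so cooperative miRNA blocks appear contiguous.
    """
    labels, sim = ordered_similarity(D, tree)
    fig, ax = plt.subplots(figsize=(max(5.0, 0.55 * len(labels)),) * 2)
    im = ax.imshow(sim, vmin=0.0, vmax=1.0, cmap="viridis")
    ax.set_xticks(range(len(labels)))
    ax.set_yticks(range(len(labels)))
    ax.set_xticklabels(labels, rotation=90)
    ax.set_yticklabels(labels)
    fig.colorbar(im, ax=ax, label="Jaccard similarity")
    ax.set_title("miRNA identity plot")
    return _save(fig, spec)
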