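"""End-to-end orchestration: two input files in, five canonical outputs out.

`run_all` mirrors the one-command analysis flow: read and reconcile the
inputs, build the adjacency matrix with gene centralities, compute the
ranked miRNA impact table, compute Jaccard distances and the
hierarchical clustering, and write every tabular and graphical output
plus a JSON manifest describing the run.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .adjacency import build_adjacency
from .impact import compute_impact, render_impact_table
from .io import (
    CasePolicy,
    IntersectionPolicy,
    read_de_genes,
    read_interactions,
    validate_universe,
    write_table,
)
from .similarity import Linkage, cluster_mirnas, export_newick, jaccard_matrix
from .viz import PlotFormat, PlotSpec, plot_dendrogram, plot_identity, plot_impact_barplot

logger = logging.getLogger("mirnetmapper")


@dataclass
class RunConfig:
    """Everything one analysis run needs, gathered in one place."""

    interactions_path: str
    output_dir: str
    de_genes_path: str | None = None
    intersection_policy: IntersectionPolicy = "strict"
    linkage: Linkage = "complete"
    decimals: int = 1
    plot_format: PlotFormat = "png"
    delimiter: str = "\t"
    id_case_policy: CasePolicy = "preserve"
    prefix: str = "mirnetmapper"
    force: bool = False
    table_format: str = "tsv"


@dataclass
class RunManifest:
    """Machine-readable record of one run (also written as JSON)."""

    outputs: dict[str, str]
    parameters: dict[str, object]
    input_digests: dict[str, str]
    T: int
    G: int
    n_edges: int
    n_mirnas: int
    n_genes: int
    n_dropped_edges: int
    mirnas_without_targets: list[str]
    leaf_order: list[str]
    warnings: list[str] = field(default_factory=list)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_all(config: RunConfig) -> RunManifest:
    """Execute the full pipeline and write all outputs under ``output_dir``.

    Files written (with the configured prefix): adjacency matrix,
    impact table and distance matrix as headered tables; barplot,
    identity heatmap and dendrogram images; the tree in Newick form; and
    ``<prefix>_manifest.json``.  Existing outputs are only overwritten
    with ``force=True``.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    ext = "tsv" if config.table_format == "tsv" else "csv"
    names = {
        "adjacency": f"{config.prefix}_adjacency.{ext}",
        "impact": f"{config.prefix}_impact.{ext}",
        "barplot": f"{config.prefix}_barplot.{config.plot_format}",
        "identity": f"{config.prefix}_identity.{config.plot_format}",
        "dendrogram": f"{config.prefix}_dendrogram.{config.plot_format}",
        "distance": f"{config.prefix}_distance.{ext}",
        "newick": f"{config.prefix}_tree.nwk",
        "manifest": f"{config.prefix}_manifest.json",
    }
    paths = {k: out / v for k, v in names.items()}
    if not config.force:
        clashes = [str(p) for p in paths.values() if p.exists()]
        if clashes:
            raise FileExistsError(
                "refusing to overwrite existing outputs (use force): "
                + ", ".join(clashes)
            )

    warnings_seen: list[str] = []

    class _Capture(logging.Handler):
        def emit(self, record: logging.LogRecord) -> None:
            if record.levelno >= logging.WARNING:
                warnings_seen.append(record.getMessage())

    capture = _Capture()
    logger.addHandler(capture)
    try:
        interactions = read_interactions(
            config.interactions_path,
            id_case_policy=config.id_case_policy,
            delimiter=config.delimiter,
        )
        digests = {config.interactions_path: _sha256(config.interactions_path)}
        de = None
        n_dropped = 0
        mirnas_lost: tuple[str, ...] = ()
        if config.de_genes_path:
            de = read_de_genes(config.de_genes_path, id_case_policy=config.id_case_policy)
            digests[config.de_genes_path] = _sha256(config.de_genes_path)
            report = validate_universe(interactions, de, policy=config.intersection_policy)
            interactions = report.interactions
            n_dropped = len(report.dropped_edges)
            mirnas_lost = report.mirnas_lost

        adj = build_adjacency(interactions)
        impact = compute_impact(adj, de)
        D = jaccard_matrix(adj)
        tree = cluster_mirnas(D, linkage=config.linkage)

        write_table(adj.to_frame(), paths["adjacency"], fmt=config.table_format)
        write_table(
            render_impact_table(impact, decimals=config.decimals),
            paths["impact"],
            fmt=config.table_format,
        )
        sep = "\t" if config.table_format == "tsv" else ","
        D.to_frame().to_csv(paths["distance"], sep=sep, index_label="miRNA")
        paths["newick"].write_text(export_newick(tree) + "\n", encoding="utf-8")

        def spec_for(key: str) -> PlotSpec:
            return PlotSpec(
                output_path=str(paths[key]),
                format=config.plot_format,
                decimals=config.decimals,
            )

        plot_impact_barplot(impact, spec_for("barplot"))
        plot_identity(D, tree, spec_for("identity"))
        plot_dendrogram(tree, spec_for("dendrogram"))

        manifest = RunManifest(
            outputs={k: str(v) for k, v in paths.items()},
            parameters={
                "intersection_policy": config.intersection_policy,
                "linkage": config.linkage,
                "decimals": config.decimals,
                "plot_format": config.plot_format,
                "id_case_policy": config.id_case_policy,
                "version": __version__,
            },
            input_digests=digests,
            T=impact.T,
            G=impact.G,
            n_edges=adj.n_edges,
            n_mirnas=len(adj.mirna_ids),
            n_genes=len(adj.gene_ids),
            n_dropped_edges=n_dropped,
            mirnas_without_targets=list(mirnas_lost),
            leaf_order=list(tree.leaf_order),
            warnings=warnings_seen,
        )
        paths["manifest"].write_text(
            json.dumps(manifest.__dict__, indent=2) + "\n", encoding="utf-8"
        )
        return manifest
    finally:
        logger.removeHandler(capture)
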