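"""Synthetic bipartite interaction networks with plantable structure.

The generator emulates the two topological features the analysis is
meant to surface: **hub genes** targeted by unusually many miRNAs, and
**clusters of cooperative miRNAs** that share a common core of targets.
Everything is driven by a single integer seed, and the emitted files are
ordinary interaction-table / DE-list inputs — no special-casing
downstream.

Cluster construction: each planted cluster owns a disjoint core of
genes; every member miRNA targets the full core plus private genes, with
``within_cluster_overlap`` the fraction of each member's target set that
is core.  Pairwise within-cluster Jaccard similarity is then
``w / (2 - w)`` for overlap ``w`` and between-cluster distance is exactly
1 (cores and privates are disjoint across clusters) as long as no
background edges are added.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .adjacency import AdjacencyMatrix, rank_genes_by_centrality
from .io import DEGeneList, InteractionTable, write_gene_list, write_interactions
from .similarity import ClusterTree

try:  # scipy is a hard dependency; the import is grouped here for clarity
    from scipy.cluster.hierarchy import fcluster
except ImportError:  # pragma: no cover
    raise


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic network; identical spec => identical output."""

    n_mirnas: int
    n_genes: int
    edge_density: float = 0.0
    n_hub_genes: int = 0
    hub_degree: int = 0
    n_clusters: int = 0
    within_cluster_overlap: float = 0.0
    cluster_target_count: int = 20
    decoy_fraction: float = 0.1
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mirnas < 1 or self.n_genes < 1:
            raise ValueError("n_mirnas and n_genes must be positive")
        if not (0.0 <= self.edge_density <= 1.0):
            raise ValueError("edge_density must lie in [0, 1]")
        if not (0.0 <= self.within_cluster_overlap <= 1.0):
            raise ValueError("within_cluster_overlap must lie in [0, 1]")
        if self.n_hub_genes and self.hub_degree > self.n_mirnas:
            raise ValueError("infeasible spec: hub_degree exceeds n_mirnas")
        if self.edge_density == 0.0 and self.n_hub_genes == 0 and self.n_clusters == 0:
            raise ValueError("spec generates no edges")
        if not (0.0 <= self.decoy_fraction <= 1.0):
            raise ValueError("decoy_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class GeneratedFixture:
    """A generated network plus the ground truth planted into it."""

    spec: FixtureSpec
    interactions: InteractionTable
    de_genes: DEGeneList
    hub_gene_ids: tuple[str, ...]
    cluster_assignment: dict[str, int]  # miRNA id -> planted cluster index


@dataclass
class RecoveryReport:
    """Did the pipeline recover the structure the generator planted?"""

    hubs_ranked_top: bool
    hub_ranks: tuple[int, ...]  # 0-based ranks of planted hubs by centrality
    separated: bool  # a usable gap exists in the merge heights
    height_gap: float
    recovered_clusters: tuple[frozenset[str], ...]
    clusters_exact: bool
    notes: tuple[str, ...] = field(default=())


def _gene_name(i: int) -> str:
    return f"GENE{i + 1:05d}"


def _mirna_name(i: int) -> str:
    return f"mir-{i + 1:03d}"


def generate_network(spec: FixtureSpec) -> GeneratedFixture:
    """Sample a bipartite edge list plus DE universe from the spec.

    Order of construction: cluster cores and privates (disjoint gene
    blocks), hub genes (own block), then Bernoulli background edges over
    the whole gene pool.  The DE list is every targeted gene plus
    ``decoy_fraction`` as many never-targeted decoys.
    """
    rng = np.random.default_rng(spec.rng_seed)
    mirnas = [_mirna_name(i) for i in range(spec.n_mirnas)]
    edges: dict[tuple[str, str], None] = {}
    next_gene = 0

    def take_genes(k: int) -> list[str]:
        nonlocal next_gene
        if next_gene + k > spec.n_genes:
            raise ValueError(
                "infeasible spec: gene pool too small for the planted structure"
            )
        block = [_gene_name(i) for i in range(next_gene, next_gene + k)]
        next_gene += k
        return block

    cluster_assignment: dict[str, int] = {}
    if spec.n_clusters > 0:
        members = np.array_split(np.arange(spec.n_mirnas), spec.n_clusters)
        for c, idx in enumerate(members):
            if len(idx) == 0:
                raise ValueError("infeasible spec: more clusters than miRNAs")
            k = spec.cluster_target_count
            core_size = int(round(spec.within_cluster_overlap * k))
            core = take_genes(core_size)
            for i in idx:
                cluster_assignment[mirnas[i]] = c
                private = take_genes(k - core_size)
                for g in core + private:
                    edges[(mirnas[i], g)] = None

    hub_genes: list[str] = []
    if spec.n_hub_genes > 0:
        hub_genes = take_genes(spec.n_hub_genes)
        for g in hub_genes:
            chosen = rng.choice(spec.n_mirnas, size=spec.hub_degree, replace=False)
            for i in chosen:
                edges[(mirnas[i], g)] = None

    if spec.edge_density > 0.0:
        mask = rng.random((spec.n_mirnas, spec.n_genes)) < spec.edge_density
        for i, j in zip(*np.nonzero(mask)):
            edges[(mirnas[i], _gene_name(j))] = None

    if not edges:
        raise ValueError("spec generated no edges (density too low?)")

    targeted = sorted({g for _, g in edges})
    targeted_set = set(targeted)
    untargeted = [
        _gene_name(i) for i in range(spec.n_genes) if _gene_name(i) not in targeted_set
    ]
    n_decoys = min(len(untargeted), int(round(spec.decoy_fraction * len(targeted))))
    decoys = (
        [untargeted[i] for i in rng.choice(len(untargeted), n_decoys, replace=False)]
        if n_decoys
        else []
    )
    return GeneratedFixture(
        spec=spec,
        interactions=InteractionTable(edges=tuple(edges)),
        de_genes=DEGeneList(genes=frozenset(targeted) | frozenset(decoys)),
        hub_gene_ids=tuple(hub_genes),
        cluster_assignment=cluster_assignment,
    )


def write_fixture(fixture: GeneratedFixture, out_dir: str | Path) -> dict[str, Path]:
    """Write interaction table, DE list and a self-describing sidecar JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "interactions": out / "interactions.tsv",
        "de_genes": out / "de_genes.txt",
        "spec": out / "fixture_spec.json",
    }
    write_interactions(fixture.interactions, paths["interactions"])
    write_gene_list(sorted(fixture.de_genes.genes), paths["de_genes"])
    sidecar = {
        "spec": asdict(fixture.spec),
        "hub_gene_ids": list(fixture.hub_gene_ids),
        "cluster_assignment": fixture.cluster_assignment,
        "n_edges": fixture.interactions.n_edges,
    }
    paths["spec"].write_text(json.dumps(sidecar, indent=2) + "\n", encoding="utf-8")
    return paths


def cut_at_largest_gap(tree: ClusterTree) -> tuple[tuple[frozenset[str], ...], float]:
    """Cut the tree at the midpoint of the largest jump in merge heights.

    Returns the resulting partition of the leaves and the gap size.  With
    no internal gap (single merge, or uniform heights) the partition
    degenerates to all-singletons or one block.
    """
    heights = np.sort(tree.heights)
    if len(heights) < 2:
        return (frozenset(tree.labels),), float(heights[0]) if len(heights) else 0.0
    jumps = np.diff(heights)
    k = int(np.argmax(jumps))
    gap = float(jumps[k])
    threshold = float((heights[k] + heights[k + 1]) / 2.0)
    flat = fcluster(tree.merges, t=threshold, criterion="distance")
    blocks: dict[int, set[str]] = {}
    for label, c in zip(tree.labels, flat):
        blocks.setdefault(int(c), set()).add(label)
    return tuple(frozenset(b) for b in blocks.values()), gap


def recover_planted_structure(
    fixture: GeneratedFixture,
    adj: AdjacencyMatrix,
    tree: ClusterTree | None = None,
    min_gap: float = 0.25,
) -> RecoveryReport:
    """Compare pipeline output against the fixture's planted ground truth.

    Hubs are recovered when the planted hub genes occupy the top
    centrality ranks; clusters are recovered when cutting the tree at the
    largest merge-height gap reproduces the planted partition exactly.
    A gap below ``min_gap`` is flagged as "no separation" and cluster
    recovery is not asserted.
    """
    notes: list[str] = []
    ranking = rank_genes_by_centrality(adj)
    positions = {g: r for r, g in enumerate(ranking["gene_id"])}
    hub_ranks = tuple(positions[g] for g in fixture.hub_gene_ids if g in positions)
    n_hubs = len(fixture.hub_gene_ids)
    hubs_top = bool(n_hubs) and len(hub_ranks) == n_hubs and max(hub_ranks) < n_hubs
    if not n_hubs:
        notes.append("no hubs planted")

    separated = False
    gap = 0.0
    recovered: tuple[frozenset[str], ...] = ()
    exact = False
    if tree is not None and fixture.cluster_assignment:
        recovered, gap = cut_at_largest_gap(tree)
        separated = gap >= min_gap
        if not separated:
            notes.append("no separation: merge-height gap below threshold")
        planted: dict[int, set[str]] = {}
        for m, c in fixture.cluster_assignment.items():
            planted.setdefault(c, set()).add(m)
        exact = set(recovered) == {frozenset(v) for v in planted.values()}
    elif tree is not None:
        notes.append("no clusters planted")

    return RecoveryReport(
        hubs_ranked_top=hubs_top,
        hub_ranks=hub_ranks,
        separated=separated,
        height_gap=gap,
        recovered_clusters=recovered,
        clusters_exact=exact,
        notes=tuple(notes),
    )
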