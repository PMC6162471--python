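import io as std_io
import logging

import numpy as np
import pytest
from scipy.cluster.hierarchy import linkage as scipy_linkage
from scipy.spatial.distance import squareform

from mirnetmapper.adjacency import build_adjacency
from mirnetmapper.io import InteractionTable
from mirnetmapper.similarity import (
    LINKAGES,
    DistanceMatrix,
    cluster_mirnas,
    export_newick,
    jaccard_distance,
    jaccard_matrix,
)

from .conftest import random_bipartite_edges
from .oracles import jaccard_from_edges


def adjacency_of(*edges):
    return build_adjacency(InteractionTable(edges=tuple(edges)))


class TestJaccardDistance:
    @pytest.mark.parametrize(
        "ti,tj,expected",
        [
            ({"A", "B", "C"}, {"B", "C", "D"}, 0.5),
            ({"A", "B"}, {"A", "B"}, 0.0),
            ({"A"}, {"B"}, 1.0),
            ({"A"}, set(), 1.0),  # one empty set shares nothing
        ],
    )
    def test_known_pairs(self, ti, tj, expected):
        assert jaccard_distance(ti, tj) == expected

    def test_both_empty_is_undefined(self):
        with pytest.raises(ValueError, match="0/0"):
            jaccard_distance(set(), set())


class TestJaccardMatrix:
    def test_identical_columns_have_zero_distance(self):
        adj = adjacency_of(("m1", "gA"), ("m1", "gB"), ("m2", "gA"), ("m2", "gB"),
                           ("m3", "gC"))
        D = jaccard_matrix(adj)
        i, j = D.mirna_ids.index("m1"), D.mirna_ids.index("m2")
        assert D.D[i, j] == 0.0
        k = D.mirna_ids.index("m3")
        assert D.D[i, k] == 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_set_oracle(self, seed):
        table = random_bipartite_edges(np.random.default_rng(seed), 8, 30)
        D = jaccard_matrix(build_adjacency(table))
        ids, ref = jaccard_from_edges(table.edges)
        perm = [ids.index(m) for m in D.mirna_ids]
        assert np.array_equal(D.D, ref[np.ix_(perm, perm)])

    def test_gene_row_permutation_leaves_distances_unchanged(self):
        rng = np.random.default_rng(4)
        table = random_bipartite_edges(rng, 6, 20)
        shuffled = list(table.edges)
        rng.shuffle(shuffled)
        D1 = jaccard_matrix(build_adjacency(table))
        D2 = jaccard_matrix(build_adjacency(InteractionTable(edges=tuple(shuffled))))
        assert D1.mirna_ids == D2.mirna_ids
        assert np.array_equal(D1.D, D2.D)

    def test_zero_target_columns_dropped_with_warning(self, caplog):
        adj = adjacency_of(("m1", "gA"), ("m2", "gB"), ("m3", "gA"))
        trimmed = adj.cells.copy()
        trimmed[:, list(adj.mirna_ids).index("m2")] = 0
        from mirnetmapper.adjacency import AdjacencyMatrix

        adj2 = AdjacencyMatrix(adj.gene_ids, adj.mirna_ids, trimmed)
        with caplog.at_level(logging.WARNING, logger="mirnetmapper"):
            D = jaccard_matrix(adj2)
        assert "m2" not in D.mirna_ids
        assert any("zero targets" in r.message for r in caplog.records)

    def test_fewer_than_two_mirnas_is_hard_error(self):
        with pytest.raises(ValueError, match="nothing to cluster"):
            jaccard_matrix(adjacency_of(("m1", "gA")))

    @pytest.mark.parametrize("seed", range(5))
    def test_metric_properties_on_random_instances(self, seed):
        table = random_bipartite_edges(np.random.default_rng(50 + seed), 10, 40)
        D = jaccard_matrix(build_adjacency(table)).D
        assert np.array_equal(D, D.T)
        assert np.all(np.diag(D) == 0.0)
        assert D.min() >= 0.0 and D.max() <= 1.0
        n = len(D)
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert D[i, j] <= D[i, k] + D[k, j] + 1e-12


class TestClusterMirnas:
    def three_leaf_D(self):
        D = np.array([[0.0, 0.1, 0.9], [0.1, 0.0, 0.9], [0.9, 0.9, 0.0]])
        return DistanceMatrix(mirna_ids=("m1", "m2", "m3"), D=D)

    def test_unique_minimum_merges_first(self):
        tree = cluster_mirnas(self.three_leaf_D())
        assert tree.merges[0, 2] == 0.1
        assert {int(tree.merges[0, 0]), int(tree.merges[0, 1])} == {0, 1}

    def test_identical_mirnas_merge_at_height_zero(self):
        adj = adjacency_of(("m1", "gA"), ("m2", "gA"), ("m3", "gB"))
        tree = cluster_mirnas(jaccard_matrix(adj))
        assert tree.merges[0, 2] == 0.0

    @pytest.mark.parametrize("method", LINKAGES)
    def test_merge_heights_are_monotone(self, method):
        table = random_bipartite_edges(np.random.default_rng(9), 9, 35)
        tree = cluster_mirnas(jaccard_matrix(build_adjacency(table)), linkage=method)
        heights = tree.heights
        assert np.all(np.diff(heights) >= -1e-12)

    @pytest.mark.parametrize("method", LINKAGES)
    @pytest.mark.parametrize("seed", range(3))
    def test_heights_agree_with_scipy_on_tie_free_matrices(self, method, seed):
        """Independent cross-check on matrices with distinct random entries."""
        rng = np.random.default_rng(200 + seed)
        n = 8
        condensed = rng.uniform(0.05, 1.0, size=n * (n - 1) // 2)
        D = DistanceMatrix(
            mirna_ids=tuple(f"m{i}" for i in range(n)), D=squareform(condensed)
        )
        ours = cluster_mirnas(D, linkage=method).heights
        ref = scipy_linkage(condensed, method=method)[:, 2]
        assert np.allclose(np.sort(ours), np.sort(ref))

    def test_clustering_invariant_to_edge_order(self):
        rng = np.random.default_rng(13)
        table = random_bipartite_edges(rng, 7, 25)
        shuffled = list(table.edges)
        rng.shuffle(shuffled)
        t1 = cluster_mirnas(jaccard_matrix(build_adjacency(table)))
        t2 = cluster_mirnas(
            jaccard_matrix(build_adjacency(InteractionTable(edges=tuple(shuffled))))
        )
        assert t1.labels == t2.labels
        assert np.array_equal(t1.merges, t2.merges)

    def test_non_finite_distances_rejected(self):
        D = np.array([[0.0, np.nan], [np.nan, 0.0]])
        with pytest.raises(ValueError, match="non-finite"):
            cluster_mirnas(DistanceMatrix(mirna_ids=("a", "b"), D=D))


class TestNewick:
    def test_two_leaf_midpoint_branch_lengths(self):
        D = DistanceMatrix(mirna_ids=("m1", "m2"), D=np.array([[0.0, 0.5], [0.5, 0.0]]))
        tree = cluster_mirnas(D)
        assert export_newick(tree) == "(m1:0.25,m2:0.25);"

    def test_three_leaf_topology_groups_closest_pair(self):
        D = np.array([[0.0, 0.1, 0.9], [0.1, 0.0, 0.9], [0.9, 0.9, 0.0]])
        tree = cluster_mirnas(DistanceMatrix(mirna_ids=("m1", "m2", "m3"), D=D))
        newick = export_newick(tree)
        assert "(m1:0.05,m2:0.05)" in newick  # closest pair forms a clade
        assert "m3:0.45" in newick  # m3 attaches at the root, outside it

    def test_round_trip_recovers_leaf_set(self):
        from Bio import Phylo

        table = random_bipartite_edges(np.random.default_rng(21), 6, 20)
        tree = cluster_mirnas(jaccard_matrix(build_adjacency(table)))
        parsed = Phylo.read(std_io.StringIO(export_newick(tree)), "newick")
        assert {t.name for t in parsed.get_terminals()} == set(tree.labels)
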