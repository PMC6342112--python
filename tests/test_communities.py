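"""Significance-aware community detection, homeless re-attachment, connectivity."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

import bioregions as br
from bioregions.errors import ParameterError

from conftest import make_block_network, make_clique_in_background


class TestDetectCommunities:
    @pytest.mark.parametrize("method", ["significance_local_opt", "modularity", "ward"])
    def test_disjoint_cliques_are_separated_by_every_method(self, method):
        edges = [(i, j) for i in range(5) for j in range(i + 1, 5)]
        edges += [(i, j) for i in range(5, 10) for j in range(i + 1, 10)]
        net = br.SimilarityNetwork(
            nodes=np.arange(10), edges=np.array(edges), weights=np.ones(len(edges))
        )
        part = br.detect_communities(
            net, method=method, seed=1, n_runs=2, n_clusters=2
        )
        assert part.K == 2
        truth = [0] * 5 + [1] * 5
        assert adjusted_rand_score(truth, part.labels) == 1.0

    @pytest.mark.parametrize("method", ["significance_local_opt", "modularity", "ward"])
    def test_planted_blocks_recovered_exactly(self, method, block_network):
        net, truth = block_network
        part = br.detect_communities(
            net, method=method, seed=42, n_runs=3, n_clusters=4
        )
        assert adjusted_rand_score(truth, part.labels) == 1.0

    def test_uniform_complete_graph_is_one_cluster(self):
        n = 30
        iu = np.triu_indices(n, 1)
        net = br.SimilarityNetwork(
            nodes=np.arange(n),
            edges=np.column_stack(iu),
            weights=np.full(len(iu[0]), 0.5),
        )
        part = br.detect_communities(net, tolerance=0.1, seed=1, n_runs=3)
        assert part.K == 1
        assert part.significance[1] == 1.0

    def test_determinism_under_identical_seed(self, block_network):
        net, _ = block_network
        p1 = br.detect_communities(net, seed=5, n_runs=3)
        p2 = br.detect_communities(net, seed=5, n_runs=3)
        assert np.array_equal(p1.labels, p2.labels)
        assert p1.significance == p2.significance

    def test_permutation_equivariance(self, block_network):
        net, _ = block_network
        rng = np.random.default_rng(3)
        perm = rng.permutation(net.n_nodes)
        inv = np.argsort(perm)
        permuted = br.SimilarityNetwork(
            nodes=np.arange(net.n_nodes),
            edges=inv[net.edges],
            weights=net.weights.copy(),
        )
        p1 = br.detect_communities(net, seed=5, n_runs=3)
        p2 = br.detect_communities(permuted, seed=5, n_runs=3)
        assert adjusted_rand_score(p1.labels[perm], p2.labels[inv][perm]) == 1.0

    def test_ward_requires_cluster_count(self, block_network):
        net, _ = block_network
        with pytest.raises(ParameterError):
            br.detect_communities(net, method="ward")

    def test_invalid_tolerance_rejected(self, block_network):
        net, _ = block_network
        with pytest.raises(ParameterError):
            br.detect_communities(net, tolerance=0.0)
        with pytest.raises(ParameterError):
            br.detect_communities(net, tolerance=1.0)

    def test_null_calibration_on_degree_preserving_randomizations(self):
        """Accepted-cluster rate on weight-shuffled networks stays near tolerance.

        The planted block network's degree sequence is complete, so shuffling
        edge weights is its exact degree-preserving randomization; the
        detector should almost never certify a community on these nulls.
        """
        net, _ = make_block_network()
        rng = np.random.default_rng(5)
        n_nets, tolerance = 20, 0.1
        hits = 0
        for t in range(n_nets):
            shuffled = br.SimilarityNetwork(
                nodes=net.nodes.copy(),
                edges=net.edges.copy(),
                weights=rng.permutation(net.weights),
            )
            part = br.detect_communities(
                shuffled, tolerance=tolerance, seed=int(t), n_runs=3
            )
            if any(v < tolerance for v in part.significance.values()):
                hits += 1
        se = np.sqrt(tolerance * (1 - tolerance) / n_nets)
        assert hits / n_nets <= tolerance + 3 * se


class TestClusterSignificance:
    def test_embedded_clique_is_significant(self):
        net = make_clique_in_background(seed=0)
        assert br.cluster_significance(range(6), net, n_null=1000, seed=3) < 0.05

    def test_random_subsets_are_not_significant(self):
        net = make_clique_in_background(seed=0)
        rng = np.random.default_rng(11)
        scores = [
            br.cluster_significance(
                rng.choice(net.n_nodes, 8, replace=False), net, n_null=300, seed=int(t)
            )
            for t in range(20)
        ]
        assert np.median(scores) > 0.3

    def test_singleton_scores_one(self):
        net = make_clique_in_background(seed=0)
        assert br.cluster_significance([0], net, n_null=200, seed=0) == 1.0

    def test_whole_node_set_scores_one(self):
        net = make_clique_in_background(seed=0)
        assert br.cluster_significance(range(net.n_nodes), net, n_null=200, seed=0) == 1.0

    def test_too_few_null_replicates_rejected(self):
        net = make_clique_in_background(seed=0)
        with pytest.raises(ParameterError):
            br.cluster_significance(range(6), net, n_null=10)


class TestAssignHomeless:
    def build(self, extra, n=7):
        # clusters {0,1,2} -> 1 and {3,4,5} -> 2; remaining nodes unassigned
        base = [(0, 1, 1.0), (0, 2, 1.0), (1, 2, 1.0), (3, 4, 1.0), (3, 5, 1.0), (4, 5, 1.0)]
        all_e = base + extra
        net = br.SimilarityNetwork(
            nodes=np.arange(n),
            edges=np.array([(a, b) for a, b, _ in all_e]),
            weights=np.array([w for _, _, w in all_e]),
        )
        labels = np.array([1, 1, 1, 2, 2, 2] + [0] * (n - 6))
        part = br.Partition(nodes=net.nodes, labels=labels, method="test")
        return net, part

    def test_fully_assigned_is_noop(self):
        net, part = self.build([], n=6)
        out = br.assign_homeless(part, net)
        assert np.array_equal(out.labels, part.labels)

    def test_argmax_weight_wins(self):
        net, part = self.build([(6, 0, 0.1), (6, 3, 0.9)])
        out = br.assign_homeless(part, net)
        assert out.labels[6] == 2

    def test_exact_tie_goes_to_lowest_cluster_id(self):
        net, part = self.build([(6, 0, 0.5), (6, 3, 0.5)])
        out = br.assign_homeless(part, net)
        assert out.labels[6] == 1

    def test_isolated_node_becomes_flagged_singleton(self):
        net, part = self.build([], n=7)  # node 6 has no edges at all
        out = br.assign_homeless(part, net)
        assert out.labels[6] == 3
        assert 6 in out.diagnostics["isolated_singletons"]

    def test_chained_assignment_iterates_to_stability(self):
        # node 6 only touches node 7; node 7 touches cluster 2
        net, part = self.build([(6, 7, 1.0), (7, 3, 0.5)], n=8)
        out = br.assign_homeless(part, net)
        assert out.labels[7] == 2 and out.labels[6] == 2


class TestSpatialConnectivity:
    def grid(self, n_rows=10, n_cols=10):
        return br.GridSpec(0.0, 0.0, 1000.0, n_rows, n_cols)

    def test_contiguous_block_is_one(self):
        grid = self.grid()
        cells = [grid.cell_id(r, c) for r in range(3) for c in range(3)]
        assert br.spatial_connectivity(cells, grid) == 1.0

    def test_two_patches_largest_ratio(self):
        grid = self.grid()
        patch7 = [grid.cell_id(0, c) for c in range(7)]
        patch3 = [grid.cell_id(5, c) for c in range(3)]
        assert br.spatial_connectivity(patch7 + patch3, grid) == pytest.approx(0.7)

    def test_diagonal_contact_is_not_contiguity(self):
        grid = self.grid()
        cells = [grid.cell_id(0, 0), grid.cell_id(1, 1)]
        assert br.spatial_connectivity(cells, grid) == pytest.approx(0.5)

    def test_isolated_cells_give_one_over_m(self):
        grid = self.grid()
        cells = [grid.cell_id(2 * i, 2 * i) for i in range(4)]
        assert br.spatial_connectivity(cells, grid) == pytest.approx(0.25)

    def test_empty_cluster_raises(self):
        with pytest.raises(ParameterError):
            br.spatial_connectivity([], self.grid())
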