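import itertools

import networkx as nx
import numpy as np
import pytest

import ductnet as dn
from conftest import random_connected_graph


def enumerate_cycles(net, max_len=5):
    """Independent oracle: count simple cycles of length 3..5 by
    exhaustive enumeration (networkx simple_cycles with a length bound,
    a completely different algorithm from the trace formulas)."""
    g = net.to_networkx()
    counts = {3: 0, 4: 0, 5: 0}
    for cyc in nx.simple_cycles(g, length_bound=max_len):
        if len(cyc) in counts:
            counts[len(cyc)] += 1
    return counts[3], counts[4], counts[5]


class TestCountPolygons:
    @pytest.mark.parametrize("name,expected", [
        ("triangle", (1, 0, 0)),
        ("cycle4", (0, 1, 0)),
        ("cycle5", (0, 0, 1)),
        ("k4", (4, 3, 0)),
        ("path10", (0, 0, 0)),
        ("star6", (0, 0, 0)),
    ])
    def test_fixture_counts(self, fixtures, name, expected):
        assert dn.count_polygons(fixtures[name]) == expected

    def test_k4_triangle_trace(self, fixtures):
        a, _ = dn.to_adjacency(fixtures["k4"])
        assert np.trace(np.linalg.matrix_power(a, 3)) == pytest.approx(24)

    def test_square_term_is_binomial_not_squared(self, fixtures):
        # on a 4-cycle the binomial reading C(d_i, 2) gives exactly one
        # square; the d_i^2 reading would give a negative count
        net = fixtures["cycle4"]
        a, _ = dn.to_adjacency(net)
        d = a.sum(axis=1)
        tr4 = np.trace(np.linalg.matrix_power(a, 4))
        binomial = (tr4 - 4 * np.sum(d * (d - 1) / 2) - 2 * net.n_edges) / 8
        squared = (tr4 - 4 * np.sum(d**2) - 2 * net.n_edges) / 8
        assert binomial == 1
        assert squared < 0

    def test_matches_enumeration_on_random_graphs(self):
        for seed in range(12):
            net = random_connected_graph(int(5 + seed % 8), seed=seed)
            assert dn.count_polygons(net) == enumerate_cycles(net), net.name


class TestClustering:
    def test_triangle_and_star(self, fixtures):
        assert dn.mean_clustering(fixtures["triangle"]) == 1.0
        assert dn.mean_clustering(fixtures["star6"]) == 0.0

    def test_k4_minus_edge(self):
        # hand computation: two degree-3 nodes have C = 2/3, the two
        # degree-2 nodes sit in one triangle each, C = 1; mean = 5/6
        net = dn.SpatialNetwork(
            [1, 2, 3, 4],
            [[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]],
            [(1, 2), (1, 3), (1, 4), (2, 3), (2, 4)],
            root_id=1)
        assert dn.mean_clustering(net) == pytest.approx(5 / 6)


class TestDegreeDistribution:
    def test_triangle_and_star(self, fixtures):
        assert dn.degree_distribution(fixtures["triangle"]) == {2: 3}
        assert dn.degree_distribution(fixtures["star6"]) == {1: 5, 5: 1}

    def test_counts_sum_and_mean(self, small_plexus):
        dist = dn.degree_distribution(small_plexus)
        assert sum(dist.values()) == small_plexus.n_nodes
        mean = sum(k * v for k, v in dist.items()) / small_plexus.n_nodes
        assert mean == pytest.approx(
            2 * small_plexus.n_edges / small_plexus.n_nodes)

    def test_matches_brute_force_tally(self, plexus320):
        dist = dn.degree_distribution(plexus320)
        tally = {}
        for nid in plexus320.node_ids:
            d = sum(1 for e in plexus320.edges if nid in e)
            tally[d] = tally.get(d, 0) + 1
        assert dist == tally


class TestEuclideanMST:
    def test_unit_square_corners(self, fixtures):
        mst = dn.euclidean_mst(fixtures["square_perimeter"])
        assert mst.n_edges == 3
        assert mst.total_length == pytest.approx(3.0)

    def test_collinear_points(self):
        net = dn.SpatialNetwork(
            [1, 2, 3], [[0, 0, 0], [1, 0, 0], [2, 0, 0]],
            [(1, 3)], root_id=1)
        mst = dn.euclidean_mst(net)
        assert mst.total_length == pytest.approx(2.0)

    def test_against_complete_graph_kruskal(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(0, 5, size=(30, 3))
        net = dn.SpatialNetwork(
            list(range(1, 31)), pts,
            [(i, i + 1) for i in range(1, 30)], root_id=1)
        mst = dn.euclidean_mst(net)
        g = nx.Graph()
        for i, j in itertools.combinations(range(30), 2):
            g.add_edge(i, j, weight=float(np.linalg.norm(pts[i] - pts[j])))
        expected = nx.minimum_spanning_tree(g, algorithm="kruskal")
        assert mst.total_length == pytest.approx(
            expected.size(weight="weight"))

    def test_knn_path_agrees_with_dense(self, plexus320):
        dense = dn.euclidean_mst(plexus320)
        sparse = dn.euclidean_mst(plexus320, dense_limit=10)
        assert sparse.n_edges == plexus320.n_nodes - 1
        assert sparse.total_length == pytest.approx(dense.total_length)


class TestCostPerformance:
    def test_mst_input_is_unit(self, fixtures):
        mst = dn.euclidean_mst(fixtures["square_perimeter"])
        assert dn.cost(mst) == pytest.approx(1.0)
        assert dn.performance(mst) == pytest.approx(1.0)

    def test_square_perimeter_hand_values(self, fixtures):
        # perimeter 4 vs MST 3; all-pairs mean 1.0 vs 1.25 on the MST
        sq = fixtures["square_perimeter"]
        assert dn.cost(sq) == pytest.approx(4 / 3)
        assert dn.performance(sq) == pytest.approx(0.8)

    def test_cost_at_least_one(self, small_plexus, fixtures):
        for net in (small_plexus, fixtures["k4"], fixtures["cycle5"]):
            assert dn.cost(net) >= 1.0

    def test_disconnected_input_rejected(self):
        net = dn.SpatialNetwork(
            [1, 2, 3, 4],
            [[0, 0, 0], [1, 0, 0], [5, 0, 0], [6, 0, 0]],
            [(1, 2), (3, 4)], root_id=1)
        with pytest.raises(ValueError):
            dn.cost(net)
        with pytest.raises(ValueError):
            dn.performance(net)


class TestMeanDistances:
    def test_three_node_chain(self):
        net = dn.SpatialNetwork(
            [1, 2, 3], [[0, 0, 0], [1, 0, 0], [2, 0, 0]],
            [(1, 2), (2, 3)], root_id=1)
        d_root, d_all, ratio = dn.mean_distances(net)
        assert d_root == pytest.approx(1.0)      # (0 + 1 + 2) / 3
        assert d_all == pytest.approx(8 / 9)     # sum 8 over 9 ordered pairs
        assert ratio == pytest.approx(d_root / d_all)

    def test_star_rooted_at_hub(self, fixtures):
        d_root, _, _ = dn.mean_distances(fixtures["star6"])
        assert d_root == pytest.approx(5 / 6)

    def test_ratio_identity(self, small_plexus):
        d_root, d_all, ratio = dn.mean_distances(small_plexus)
        assert ratio * d_all == pytest.approx(d_root)


class TestNetworkDimension:
    def test_chain_is_one_dimensional(self, unit_chain200):
        assert dn.network_dimension(unit_chain200) == pytest.approx(1.0, abs=0.15)

    def test_grid_is_two_dimensional(self, grid20):
        assert dn.network_dimension(grid20) == pytest.approx(2.0, abs=0.2)

    def test_too_small_window_errors(self):
        net = dn.SpatialNetwork(
            [1, 2, 3], [[0, 0, 0], [1, 0, 0], [2, 0, 0]],
            [(1, 2), (2, 3)], root_id=1)
        with pytest.raises(ValueError):
            dn.network_dimension(net)

    def test_scale_invariance(self, grid20):
        scaled = dn.SpatialNetwork(
            grid20.node_ids, grid20.positions * 7.0,
            grid20.edges, root_id=grid20.root_id)
        assert dn.network_dimension(scaled) == pytest.approx(
            dn.network_dimension(grid20), abs=1e-6)


class TestRandomize:
    def test_triangle_unchanged(self, fixtures):
        out = dn.randomize_degree_preserving(fixtures["triangle"], seed=1)
        assert set(out.edges) == set(fixtures["triangle"].edges)

    def test_degree_multiset_and_connectivity_preserved(self):
        for seed in range(10):
            net = random_connected_graph(14, seed=100 + seed)
            out = dn.randomize_degree_preserving(net, seed=seed)
            assert sorted(dn.degree_distribution(out).items()) == \
                sorted(dn.degree_distribution(net).items())
            assert out.is_connected()

    def test_lengths_recomputed_from_positions(self, small_plexus):
        out = dn.randomize_degree_preserving(small_plexus, seed=3)
        for e in out.edges:
            assert out.edge_lengths[e] == pytest.approx(
                out.euclidean_length(*e))

    def test_randomization_shifts_polygon_counts(self):
        # a mesh's short loops are geometric; degree-preserving rewiring
        # destroys most of them (the randomised-counterpart control)
        mesh = dn.make_lattice_mesh(dn.SynthConfig(
            generator="lattice_mesh", n_nodes=100, seed=7))
        orig = sum(dn.count_polygons(mesh))
        rand = [sum(dn.count_polygons(
            dn.randomize_degree_preserving(mesh, seed=s)))
            for s in range(10)]
        assert np.mean(rand) < orig


class TestSummarize:
    def test_mst_summary_is_degenerate(self, fixtures):
        mst = dn.euclidean_mst(fixtures["square_perimeter"])
        s = dn.summarize(mst)
        assert s.cost == pytest.approx(1.0)
        assert s.performance == pytest.approx(1.0)
        assert (s.n_triangles, s.n_squares, s.n_pentagons) == (0, 0, 0)

    def test_square_perimeter_summary(self, fixtures):
        s = dn.summarize(fixtures["square_perimeter"])
        assert s.cost == pytest.approx(4 / 3)
        assert s.performance == pytest.approx(0.8)

    def test_fields_match_individual_operations(self, small_plexus):
        s = dn.summarize(small_plexus)
        assert s.n_nodes == small_plexus.n_nodes
        assert s.n_edges == small_plexus.n_edges
        assert s.total_length == pytest.approx(small_plexus.total_length)
        assert s.mean_degree == pytest.approx(
            2 * small_plexus.n_edges / small_plexus.n_nodes)
        assert s.mean_clustering == pytest.approx(
            dn.mean_clustering(small_plexus))
        assert (s.n_triangles, s.n_squares, s.n_pentagons) == \
            dn.count_polygons(small_plexus)
        assert s.cost == pytest.approx(dn.cost(small_plexus))
        assert s.performance == pytest.approx(dn.performance(small_plexus))
        d_root, d_all, ratio = dn.mean_distances(small_plexus)
        assert s.mean_dist_root == pytest.approx(d_root)
        assert s.mean_pairwise_dist == pytest.approx(d_all)
        assert s.root_ratio == pytest.approx(ratio)


class TestCompareGroups:
    def _summaries(self, means, sd, n, seed):
        rng = np.random.default_rng(seed)
        out = []
        for _ in range(n):
            vals = {m: rng.normal(mu, sd) for m, mu in means.items()}
            base = dict(
                n_nodes=10, n_edges=9, total_length=1.0, mean_degree=1.8,
                mean_clustering=0.0, n_triangles=0, n_squares=0,
                n_pentagons=0, cost=1.0, performance=1.0,
                mean_dist_root=1.0, mean_pairwise_dist=1.0,
                root_ratio=1.0, dimension=1.0)
            base.update(vals)
            out.append(dn.NetworkSummary(**base))
        return out

    def test_identical_groups_not_significant(self):
        a = self._summaries({"cost": 1.5}, 0.1, 5, seed=1)
        for cmp in dn.compare_groups(a, a):
            assert not cmp.significant

    def test_separated_groups_significant_after_bonferroni(self):
        a = self._summaries({"cost": 0.0}, 0.1, 20, seed=1)
        b = self._summaries({"cost": 1.0}, 0.1, 20, seed=2)
        res = {c.measure: c for c in dn.compare_groups(a, b)}
        assert res["cost"].significant

    def test_bonferroni_alpha_is_divided(self):
        a = self._summaries({}, 0.1, 3, seed=1)
        res = dn.compare_groups(a, a, alpha=0.05,
                                measures=["cost", "performance"])
        assert res[0].bonferroni_alpha == pytest.approx(0.025)
        full = dn.compare_groups(a, a, alpha=0.05)
        assert full[0].bonferroni_alpha == pytest.approx(0.05 / 14)

    def test_sem_definition(self):
        a = self._summaries({"cost": 2.0}, 0.3, 8, seed=4)
        res = {c.measure: c for c in dn.compare_groups(a, a)}
        vals = np.array([s.cost for s in a])
        assert res["cost"].sem_a == pytest.approx(
            vals.std(ddof=1) / np.sqrt(len(vals)))

    def test_zero_variance_equal_means_p_one(self):
        a = self._summaries({}, 0.0, 3, seed=1)
        for cmp in dn.compare_groups(a, a):
            assert cmp.p_value == 1.0
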