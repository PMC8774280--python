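import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vsatnet.datatypes import NodeTimeSeriesSet
from vsatnet import network_topology as nt

from _oracles import (
    brute_betweenness,
    brute_clustering,
    brute_global_efficiency,
    brute_local_efficiency,
    brute_nodal_efficiency,
    random_graph,
)


def graph_from_edges(n, edges):
    A = np.zeros((n, n), dtype=bool)
    for i, j in edges:
        A[i, j] = A[j, i] = True
    return nt.BinaryGraph(adjacency=A)


PATH3 = graph_from_edges(3, [(0, 1), (1, 2)])
TRIANGLE = graph_from_edges(3, [(0, 1), (1, 2), (0, 2)])
STAR5 = graph_from_edges(5, [(0, i) for i in range(1, 5)])
K5 = graph_from_edges(5, [(i, j) for i in range(5) for j in range(i + 1, 5)])
EMPTY4 = graph_from_edges(4, [])


class TestFCMatrix:
    def _series(self, X):
        return NodeTimeSeriesSet(
            node_ids=[f"n{i}" for i in range(len(X))],
            series=np.asarray(X, dtype=float),
            sampling_interval=1.0,
        )

    def test_identical_and_negated_series_give_unit_fc(self, rng):
        x = rng.standard_normal(100)
        fc = nt.fc_matrix(self._series([x, x.copy(), -x]))
        assert np.isclose(fc.values[0, 1], 1.0)
        assert np.isclose(fc.values[0, 2], 1.0)  # sign-blind by design

    def test_matches_covariance_formula_oracle(self, rng):
        X = rng.standard_normal((5, 100))
        fc = nt.fc_matrix(self._series(X))
        for i in range(5):
            for j in range(i + 1, 5):
                xi, xj = X[i] - X[i].mean(), X[j] - X[j].mean()
                r = (xi @ xj) / np.sqrt((xi @ xi) * (xj @ xj))
                assert abs(fc.values[i, j] - abs(r)) < 1e-12

    def test_constant_series_rejected_by_name(self):
        X = np.vstack([np.ones(50), np.arange(50.0)])
        with pytest.raises(ValueError, match="n0"):
            nt.fc_matrix(self._series(X))


class TestBinarizeAtCost:
    def test_cost_one_gives_complete_graph(self, rng):
        W = np.abs(np.corrcoef(rng.standard_normal((6, 80))))
        fc = nt.FCMatrix(values=W)
        g = nt.binarize_at_cost(fc, 1.0)
        assert g.n_edges == 6 * 5 // 2

    def test_edge_count_n41_cost_010(self, rng):
        W = np.abs(np.corrcoef(rng.standard_normal((41, 100))))
        g = nt.binarize_at_cost(nt.FCMatrix(values=W), 0.10)
        assert g.n_edges == 82

    def test_tie_break_is_deterministic_lexicographic(self):
        n = 6
        W = np.full((n, n), 0.5)
        np.fill_diagonal(W, 0.0)
        fc = nt.FCMatrix(values=W)
        g = nt.binarize_at_cost(fc, 0.5)
        assert g.n_edges == round(0.5 * 15)
        iu, ju = np.nonzero(np.triu(g.adjacency, 1))
        pairs = list(zip(iu.tolist(), ju.tolist()))
        # the K lexicographically smallest pairs
        all_pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
        assert pairs == sorted(all_pairs)[: g.n_edges]

    def test_zero_edge_cost_rejected(self):
        W = np.zeros((5, 5))
        with pytest.raises(ValueError, match="empty graph"):
            nt.binarize_at_cost(nt.FCMatrix(values=W), 0.01)

    def test_strongest_edges_kept(self, rng):
        W = np.abs(np.corrcoef(rng.standard_normal((10, 60))))
        fc = nt.FCMatrix(values=W)
        g = nt.binarize_at_cost(fc, 0.2)
        iu, ju = np.triu_indices(10, 1)
        kept = fc.values[g.adjacency & np.triu(np.ones((10, 10), bool), 1)]
        dropped = fc.values[(~g.adjacency) & np.triu(np.ones((10, 10), bool), 1)]
        assert kept.min() >= dropped.max()


class TestMetricExamples:
    def test_path_graph(self):
        assert np.isclose(nt.global_efficiency(PATH3), 5 / 6)
        assert np.isclose(nt.nodal_efficiency(PATH3)[1], 1.0)
        assert np.isclose(nt.betweenness(PATH3)[1], 1.0)

    def test_complete_graph(self):
        assert nt.global_efficiency(K5) == 1.0
        assert (nt.nodal_efficiency(K5) == 1.0).all()
        assert (nt.betweenness(K5) == 0.0).all()

    def test_triangle(self):
        assert (nt.clustering(TRIANGLE) == 1.0).all()
        assert (nt.local_efficiency(TRIANGLE) == 1.0).all()

    def test_star_center(self):
        assert nt.local_efficiency(STAR5)[0] == 0.0
        assert nt.clustering(STAR5)[0] == 0.0
        assert (nt.degree(STAR5) == np.array([4, 1, 1, 1, 1])).all()

    def test_empty_graph_efficiency_zero(self):
        assert nt.global_efficiency(EMPTY4) == 0.0
        assert (nt.nodal_efficiency(EMPTY4) == 0.0).all()


class TestBruteForceEquivalence:
    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 10**6))
    def test_all_metrics_match_oracles(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 9))
        A = random_graph(n, float(rng.uniform(0.1, 0.9)), rng)
        g = nt.BinaryGraph(adjacency=A)
        assert np.isclose(nt.global_efficiency(g), brute_global_efficiency(A))
        assert np.allclose(nt.nodal_efficiency(g), brute_nodal_efficiency(A))
        assert np.allclose(nt.local_efficiency(g), brute_local_efficiency(A))
        assert np.allclose(nt.clustering(g), brute_clustering(A))
        assert np.allclose(nt.betweenness(g), brute_betweenness(A))
        assert (nt.degree(g) == A.sum(axis=1)).all()


class TestInvariants:
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10**6))
    def test_metric_bounds(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 15))
        g = nt.BinaryGraph(adjacency=random_graph(n, 0.4, rng))
        for vals in (
            [nt.global_efficiency(g)],
            nt.nodal_efficiency(g),
            nt.local_efficiency(g),
            nt.clustering(g),
            nt.betweenness(g),
        ):
            assert (np.asarray(vals) >= 0).all()
            assert (np.asarray(vals) <= 1).all()

    def test_adding_edge_never_decreases_global_efficiency(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 10))
            A = random_graph(n, 0.3, rng)
            missing = np.argwhere(~A & np.triu(np.ones((n, n), bool), 1))
            if not len(missing):
                continue
            i, j = missing[rng.integers(len(missing))]
            before = nt.global_efficiency(nt.BinaryGraph(adjacency=A))
            A2 = A.copy()
            A2[i, j] = A2[j, i] = True
            after = nt.global_efficiency(nt.BinaryGraph(adjacency=A2))
            assert after >= before - 1e-12

    def test_efficiency_monotone_in_cost(self, rng):
        W = np.abs(np.corrcoef(rng.standard_normal((15, 80))))
        fc = nt.FCMatrix(values=W)
        effs = [
            nt.global_efficiency(nt.binarize_at_cost(fc, c))
            for c in (0.1, 0.2, 0.3, 0.4)
        ]
        assert all(a <= b + 1e-12 for a, b in zip(effs, effs[1:]))


class TestNullModels:
    def test_rewiring_preserves_degree_sequence_exactly(self, rng):
        W = np.abs(np.corrcoef(rng.standard_normal((20, 80))))
        g = nt.binarize_at_cost(nt.FCMatrix(values=W), 0.2)
        null = nt.random_null(g, seed=1)
        assert (nt.degree(null) == nt.degree(g)).all()
        assert null.n_edges == g.n_edges
        assert not null.adjacency.diagonal().any()

    def test_complete_graph_null_is_itself(self):
        null = nt.random_null(K5, seed=0)
        assert np.array_equal(null.adjacency, K5.adjacency)

    def test_lattice_null_preserves_n_and_k(self, rng):
        W = np.abs(np.corrcoef(rng.standard_normal((17, 80))))
        g = nt.binarize_at_cost(nt.FCMatrix(values=W), 0.23)
        lat = nt.lattice_null(g)
        assert lat.n_nodes == g.n_nodes
        assert lat.n_edges == g.n_edges
        # ring lattice: every node degree within 1 of the mean
        deg = nt.degree(lat)
        assert deg.max() - deg.min() <= 2

    def test_ws_efficiency_between_lattice_and_random(self):
        hits = 0
        for seed in range(5):
            fc = nt.benchmark_fc("ws", seed=seed)
            g = nt.binarize_at_cost(fc, 0.15)
            lat = nt.lattice_null(g)
            rnd = nt.random_null(g, seed=seed)
            ok = (
                nt.global_efficiency(lat)
                < nt.global_efficiency(g)
                < nt.global_efficiency(rnd)
            )
            hits += ok
        assert hits >= 4


class TestSmallWorldScan:
    def test_lattice_input_fails_lower_global_bound(self):
        fc = nt.benchmark_fc("lattice", seed=0)
        costs = np.array([0.1, 0.2, 0.3])
        sw = nt.small_world_scan({"g": fc}, costs, seed=0, n_random=2)
        assert not sw["small_world"].any()
        # it IS (up to partial-shell arrangement) the regular null, so the
        # strict lower efficiency bound has no real margin
        assert np.allclose(sw["e_glob"], sw["e_glob_regular"], atol=0.01)

    def test_ws_input_is_small_world_on_most_costs(self):
        fc = nt.benchmark_fc("ws", seed=0)
        costs = np.array([0.1, 0.2, 0.3, 0.4])
        sw = nt.small_world_scan({"g": fc}, costs, seed=0, n_random=2)
        assert sw["small_world"].mean() >= 0.75
        assert sw.attrs["sw_range"]["g"] is not None


class TestProfiles:
    def test_default_grid_has_31_points(self):
        assert len(nt.cost_grid(0.10, 0.40, 0.01)) == 31
        assert len(nt.cost_grid(0.10, 0.50, 0.01)) == 41

    def test_cost_average_equals_mean_of_per_cost_oracle(self, rng):
        W = np.abs(np.corrcoef(rng.standard_normal((10, 60))))
        fc = nt.FCMatrix(values=W)
        costs = nt.cost_grid(0.10, 0.40, 0.05)
        prof = nt.cost_averaged_profile(fc, costs)
        # recompute independently, cost by cost
        eg = [nt.global_efficiency(nt.binarize_at_cost(fc, c)) for c in costs]
        assert np.isclose(prof.global_avg["network_global_efficiency"], np.mean(eg))
        ne = np.mean(
            [nt.nodal_efficiency(nt.binarize_at_cost(fc, c)) for c in costs], axis=0
        )
        assert np.allclose(prof.nodal_avg["nodal_global_efficiency"].to_numpy(), ne)

    def test_profile_contains_all_metrics(self, rng):
        W = np.abs(np.corrcoef(rng.standard_normal((8, 60))))
        prof = nt.cost_averaged_profile(nt.FCMatrix(values=W),
                                        nt.cost_grid(0.2, 0.3, 0.05))
        assert set(prof.global_by_cost.columns) == set(nt.GLOBAL_METRICS)
        assert set(prof.nodal_by_cost) == set(nt.NODAL_METRICS)
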