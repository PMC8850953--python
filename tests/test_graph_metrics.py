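import numpy as np
import pytest

from netcog import (
    NullModelConfig,
    SparsityGrid,
    auc_over_grid,
    characteristic_path_length,
    clustering_coefficient,
    global_efficiency,
    local_efficiency,
    nodal_efficiency,
    normalized_smallworld,
    random_reference,
)
from netcog.graph_metrics import distance_matrix, metric_curves
from netcog.connectome import BinaryNetwork
from netcog.simulate import watts_strogatz

from oracles import (
    clustering_oracle,
    global_efficiency_oracle,
    local_efficiency_oracle,
    nodal_efficiency_oracle,
    path_length_oracle,
    random_graph,
)


def complete(n):
    return (np.ones((n, n)) - np.eye(n)).astype(np.uint8)


def star(n):
    a = np.zeros((n, n), dtype=np.uint8)
    a[0, 1:] = a[1:, 0] = 1
    return a


def path3():
    a = np.zeros((3, 3), dtype=np.uint8)
    a[0, 1] = a[1, 0] = a[1, 2] = a[2, 1] = 1
    return a


class TestClosedFormGraphs:
    def test_complete_graph_metrics(self):
        k4 = complete(4)
        assert clustering_coefficient(k4) == pytest.approx(1.0)
        assert characteristic_path_length(k4) == pytest.approx(1.0)
        assert global_efficiency(k4) == pytest.approx(1.0)
        assert local_efficiency(k4) == pytest.approx(1.0)
        assert np.allclose(nodal_efficiency(k4), 1.0)

    def test_star_graph_has_no_triangles(self):
        s5 = star(6)
        assert clustering_coefficient(s5) == 0.0
        assert local_efficiency(s5) == 0.0

    def test_path_graph_distances(self):
        p3 = path3()
        assert characteristic_path_length(p3) == pytest.approx(4 / 3)
        assert global_efficiency(p3) == pytest.approx((1 + 1 + 0.5) / 3)

    def test_isolated_node_has_zero_nodal_efficiency(self):
        a = np.zeros((4, 4), dtype=np.uint8)
        a[0, 1] = a[1, 0] = 1
        assert nodal_efficiency(a)[3] == 0.0

    def test_edgeless_graph_has_no_reachable_pair(self):
        with pytest.raises(ValueError, match="reachable"):
            characteristic_path_length(np.zeros((4, 4), dtype=np.uint8))


class TestOracleEquivalence:
    @pytest.mark.parametrize("case", range(25))
    def test_all_metrics_match_bruteforce_on_random_graphs(self, case):
        rng = np.random.default_rng(1000 + case)
        n = int(rng.integers(4, 11))
        adj = random_graph(n, float(rng.uniform(0.2, 0.8)), rng)
        if adj.sum() == 0:
            adj[0, 1] = adj[1, 0] = 1
        assert clustering_coefficient(adj) == pytest.approx(clustering_oracle(adj))
        assert global_efficiency(adj) == pytest.approx(global_efficiency_oracle(adj))
        assert local_efficiency(adj) == pytest.approx(local_efficiency_oracle(adj))
        assert np.allclose(nodal_efficiency(adj), nodal_efficiency_oracle(adj))
        try:
            expect_lp = path_length_oracle(adj)
        except ValueError:
            expect_lp = None
        if expect_lp is not None:
            assert characteristic_path_length(adj) == pytest.approx(expect_lp)

    def test_adding_an_edge_never_decreases_global_efficiency(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            adj = random_graph(8, 0.3, rng)
            e0 = global_efficiency(adj)
            free = np.argwhere(np.triu(adj == 0, 1))
            if not len(free):
                continue
            i, j = free[rng.integers(len(free))]
            adj2 = adj.copy()
            adj2[i, j] = adj2[j, i] = 1
            assert global_efficiency(adj2) >= e0 - 1e-12


class TestRandomReference:
    def test_degree_sequence_and_edge_count_preserved(self, rng):
        for _ in range(10):
            adj = random_graph(12, 0.4, rng)
            null = random_reference(adj, NullModelConfig(seed=int(rng.integers(1e6))))
            assert np.array_equal(null.sum(axis=0), adj.sum(axis=0))
            assert null.sum() == adj.sum()
            assert np.array_equal(null, null.T)
            assert not np.any(np.diag(null))

    def test_complete_graph_cannot_be_rewired(self):
        k4 = complete(4)
        assert np.array_equal(random_reference(k4, NullModelConfig(seed=1)), k4)

    def test_fixed_seed_is_deterministic(self, rng):
        adj = random_graph(15, 0.3, np.random.default_rng(3))
        a = random_reference(adj, NullModelConfig(seed=42))
        b = random_reference(adj, NullModelConfig(seed=42))
        assert np.array_equal(a, b)

    def test_actually_randomizes_a_lattice(self):
        ws = watts_strogatz(40, 6, 0.0, np.random.default_rng(0))
        null = random_reference(ws, NullModelConfig(seed=5))
        assert clustering_coefficient(null) < clustering_coefficient(ws)


class TestNormalizedSmallworld:
    def test_complete_graph_normalizes_to_unity(self):
        g, l, s = normalized_smallworld(complete(4), NullModelConfig(10, 5, 0))
        assert (g, l, s) == (1.0, 1.0, 1.0)

    def test_sigma_is_gamma_over_lambda(self, rng):
        adj = random_graph(20, 0.3, rng)
        g, l, s = normalized_smallworld(adj, NullModelConfig(5, 5, 3))
        assert s == pytest.approx(g / l, abs=1e-12)

    def test_smallworld_ring_lattice_has_sigma_above_one(self):
        # Watts-Strogatz regime: high clustering, short paths after rewiring
        hits = 0
        for seed in range(10):
            ws = watts_strogatz(90, 6, 0.1, np.random.default_rng(seed))
            _, _, s = normalized_smallworld(ws, NullModelConfig(5, 5, seed))
            hits += s > 1.0
        assert hits >= 10 * 0.95 - 1e-9

    def test_triangle_free_null_degenerate_case_errors(self):
        # a single edge pair graph whose nulls have Lp fine but Cp zero
        a = np.zeros((4, 4), dtype=np.uint8)
        a[0, 1] = a[1, 0] = a[2, 3] = a[3, 2] = 1
        with pytest.raises(ValueError, match="null"):
            normalized_smallworld(a, NullModelConfig(3, 5, 0))


class TestAUC:
    def test_constant_curve_closed_form(self, grid):
        c = 2.7
        assert auc_over_grid(np.full(31, c), grid) == pytest.approx(0.3 * c)

    def test_linear_ramp_closed_form(self, grid):
        a, b = 1.0, 3.0
        curve = np.linspace(a, b, 31)
        assert auc_over_grid(curve, grid) == pytest.approx(0.3 * (a + b) / 2)

    def test_matches_fine_riemann_sum_on_random_curve(self, grid, rng):
        curve = rng.random(31)
        x = np.array(grid.values)
        # refinement oracle: dense piecewise-linear interpolation
        xs = np.linspace(x[0], x[-1], 30001)
        ys = np.interp(xs, x, curve)
        riemann = float(np.sum((ys[1:] + ys[:-1]) / 2 * np.diff(xs)))
        assert auc_over_grid(curve, grid) == pytest.approx(riemann, rel=1e-6)

    def test_length_mismatch_errors(self, grid):
        with pytest.raises(ValueError, match="length"):
            auc_over_grid(np.ones(30), grid)


class TestMetricCurves:
    def test_bounded_metrics_and_sigma_identity_across_grid(self, rng, light_null):
        grid = SparsityGrid(0.2, 0.4, 0.02)
        from netcog import fisher_z, pearson_fc, threshold_grid

        ts = rng.standard_normal((25, 120))
        nets = threshold_grid(fisher_z(pearson_fc(ts)), grid)
        feats = metric_curves(nets, grid, light_null, rng=rng)
        c = feats.curves
        for col in ("cp", "eglobal", "elocal"):
            assert ((c[col] >= 0) & (c[col] <= 1)).all()
        assert (c["lp"] >= 1).all()
        assert np.allclose(c["sigma"], c["gamma"] / c["lambda"], atol=1e-12)
        assert set(feats.auc.index) == {
            "gamma_auc", "lambda_auc", "sigma_auc", "cp_auc", "lp_auc",
            "eglobal_auc", "elocal_auc",
        }
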