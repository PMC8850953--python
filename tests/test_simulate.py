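import numpy as np
import pytest

from netcog import Group, SimulationConfig, generate_cohort, generate_subject
from netcog.graph_metrics import clustering_coefficient
from netcog.simulate import (
    CohortTruth,
    clique_ring,
    generate_scores,
    hub_attach,
    ring_lattice,
    watts_strogatz,
)


def small_cfg(**kw):
    """Reduced cohort for fast structural tests."""
    defaults = dict(n_patients=6, n_controls=4, n_timepoints=60, seed=7)
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestGraphBuilders:
    def test_ring_lattice_is_k_regular(self):
        a = ring_lattice(20, 6)
        assert np.all(a.sum(axis=0) == 6)
        assert np.array_equal(a, a.T)

    def test_clique_ring_structure(self):
        a = clique_ring(20, 5)
        assert np.array_equal(a, a.T)
        assert not np.any(np.diag(a))
        # each clique is complete internally
        assert np.all(a[:5, :5] + np.eye(5) == 1)
        # ring couplers connect consecutive cliques
        assert a[4, 5] == 1

    def test_clique_ring_handles_remainder_nodes(self):
        a = clique_ring(23, 5)
        assert a.shape == (23, 23)
        assert np.array_equal(a, a.T)

    def test_watts_strogatz_rewiring_reduces_clustering(self):
        rng = np.random.default_rng(0)
        c0 = clustering_coefficient(watts_strogatz(60, 6, 0.0, rng))
        c1 = clustering_coefficient(watts_strogatz(60, 6, 0.5, np.random.default_rng(1)))
        assert c1 < c0

    def test_hub_attach_preserves_symmetry_and_adds_edges(self):
        rng = np.random.default_rng(3)
        base = clique_ring(30, 5)
        out = hub_attach(base, 10, 3, rng)
        assert np.array_equal(out, out.T)
        assert not np.any(np.diag(out))
        assert out.sum() >= base.sum()


class TestGenerateSubject:
    def test_fixed_seed_is_byte_identical(self):
        cfg = small_cfg()
        a = generate_subject("patient", cfg, 99)
        b = generate_subject("patient", cfg, 99)
        assert np.array_equal(a.timeseries, b.timeseries)
        assert a.truth == b.truth
        assert a.score == b.score

    def test_timeseries_shape_and_finiteness(self):
        rec = generate_subject("control", small_cfg(), 5)
        assert rec.timeseries.shape == (90, 60)
        assert np.all(np.isfinite(rec.timeseries))

    def test_zero_coupling_gives_near_zero_correlations(self):
        cfg = small_cfg(coupling_strength=0.0, hub_attach_range=(0.0, 1e-12),
                        n_timepoints=2000)
        rec = generate_subject("patient", cfg, 11)
        r = np.corrcoef(rec.timeseries)
        off = np.abs(r[~np.eye(90, dtype=bool)])
        assert off.mean() < 0.1

    def test_truth_record_carries_ground_truth_graph(self):
        rec = generate_subject("patient", small_cfg(), 2)
        edges = rec.truth["graph_edges"]
        assert len(edges) > 0
        assert all(0 <= i < 90 and 0 <= j < 90 for i, j in edges)
        for key in ("rewire_prob", "gamma_true", "sigma_true", "noiseless_score"):
            assert key in rec.truth

    def test_invalid_coupling_is_rejected(self):
        with pytest.raises(ValueError, match="coupling"):
            generate_subject("patient", small_cfg(coupling_strength=1.5), 1)

    def test_patient_graphs_less_clustered_than_controls_over_seeds(self):
        cfg = small_cfg(hub_attach_range=(0.0, 1e-12))
        diffs = []
        for seed in range(20):
            pat = generate_subject("patient", cfg, 3000 + seed)
            ctl = generate_subject("control", cfg, 6000 + seed)
            to_adj = lambda t: _edges_to_adj(t["graph_edges"], 90)
            diffs.append(
                clustering_coefficient(to_adj(ctl.truth))
                - clustering_coefficient(to_adj(pat.truth))
            )
        assert np.mean(diffs) > 0
        assert sum(d > 0 for d in diffs) >= 16


def _edges_to_adj(edges, n):
    a = np.zeros((n, n), dtype=np.uint8)
    for i, j in edges:
        a[i, j] = a[j, i] = 1
    return a


class TestGenerateScores:
    def test_zero_noise_is_exactly_linear(self):
        cfg = small_cfg(score_noise_sd=0.0, score_intercept=5.0,
                        score_slopes=(10.0, 4.0))
        f = np.array([[0.5, 0.4], [1.0, 0.9]])
        out = generate_scores(f, cfg, np.random.default_rng(0))
        assert np.allclose(out, [5 + 5 + 1.6, 5 + 10 + 3.6])

    def test_zero_slopes_make_scores_independent_of_features(self):
        cfg = small_cfg(score_slopes=(0.0, 0.0), score_intercept=20.0)
        rng = np.random.default_rng(1)
        f = rng.random((50, 2))
        out = generate_scores(f, cfg, np.random.default_rng(2))
        r = np.corrcoef(f[:, 0], out)[0, 1]
        assert abs(r) < 0.35  # pure noise correlation at n=50

    def test_scores_clipped_to_moca_range(self):
        cfg = small_cfg(score_intercept=50.0, score_noise_sd=0.0)
        out = generate_scores(np.array([[1.0, 1.0]]), cfg, np.random.default_rng(0))
        assert out[0] == 30.0

    def test_planted_truth_correlates_with_scores(self):
        # patients only; the gamma AUC truth should drive the score
        cfg = SimulationConfig(n_patients=45, n_controls=1, n_timepoints=20, seed=3)
        subs, truth = generate_cohort(cfg)
        pats = [t for t in truth.subjects if t["group"] == "patient"]
        g = np.array([t["gamma_true"] for t in pats])
        s = np.array([t["score"] for t in pats])
        assert np.corrcoef(g, s)[0, 1] > 0.4


class TestGenerateCohort:
    def test_default_cohort_sizes(self):
        cfg = SimulationConfig(n_timepoints=15, seed=1)
        subs, truth = generate_cohort(cfg)
        groups = [s.group for s in subs]
        assert groups.count(Group.PATIENT) == 45
        assert groups.count(Group.CONTROL) == 30
        assert len(truth.subjects) == 75

    def test_cohort_is_reproducible(self):
        a, ta = generate_cohort(small_cfg())
        b, tb = generate_cohort(small_cfg())
        assert all(np.array_equal(x.timeseries, y.timeseries) for x, y in zip(a, b))
        assert ta.subjects == tb.subjects

    def test_truth_ledger_round_trips_through_json(self, tmp_path):
        _, truth = generate_cohort(small_cfg())
        path = tmp_path / "truth.json"
        truth.to_json(path)
        again = CohortTruth.from_json(path)
        assert again.subjects == truth.subjects
        assert again.config["n_patients"] == truth.config["n_patients"]

    def test_config_validation(self):
        with pytest.raises(ValueError, match="rewire"):
            SimulationConfig(rewire_prob_patient=0.1, rewire_prob_control=0.3)
        with pytest.raises(ValueError, match="clique_size"):
            SimulationConfig(clique_size=2)
        with pytest.raises(ValueError, match="signal_regions"):
            SimulationConfig(signal_regions=(95,))
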