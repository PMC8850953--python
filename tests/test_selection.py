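import numpy as np
import pandas as pd
import pytest
from scipy import stats

from netcog import (
    bonferroni_alpha,
    fuse_features,
    pearson_corr,
    screen_features,
    select_features,
    t_from_summary,
    two_sample_t,
)
from netcog.selection import (
    CorrelationResult,
    GroupTestResult,
    SelectionReport,
    compute_train_stats,
    unfuse_features,
)


class TestTwoSampleT:
    def test_identical_groups_give_zero(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        res = two_sample_t(a, a.copy())
        assert res.t_stat == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_textbook_welch_formula(self, rng):
        a, b = rng.normal(0, 1, 20), rng.normal(0.5, 2, 15)
        res = two_sample_t(a, b, "welch")
        se = np.sqrt(a.var(ddof=1) / 20 + b.var(ddof=1) / 15)
        assert res.t_stat == pytest.approx((a.mean() - b.mean()) / se)

    def test_matches_textbook_pooled_formula(self, rng):
        a, b = rng.normal(0, 1, 12), rng.normal(0.2, 1, 18)
        res = two_sample_t(a, b, "pooled")
        sp2 = ((11 * a.var(ddof=1)) + (17 * b.var(ddof=1))) / 28
        se = np.sqrt(sp2 * (1 / 12 + 1 / 18))
        assert res.t_stat == pytest.approx((a.mean() - b.mean()) / se)

    def test_zero_variance_both_groups_errors(self):
        with pytest.raises(ValueError, match="variance"):
            two_sample_t(np.ones(5), np.full(4, 2.0))


class TestTFromSummary:
    def test_moca_demographics_row(self):
        # published cognitive-score summaries: 21.33 +/- 2.44 (n=45)
        # versus 27.37 +/- 1.33 (n=30); Welch t is -13.809
        res = t_from_summary(21.33, 2.44, 45, 27.37, 1.33, 30, "welch")
        assert res.t_stat == pytest.approx(-13.809, abs=0.01)

    def test_equal_means_give_zero(self):
        assert t_from_summary(5.0, 1.0, 10, 5.0, 2.0, 12).t_stat == 0.0

    def test_agrees_with_raw_data_t_on_matching_samples(self, rng):
        # simulate-then-compare: raw samples standardized to the exact
        # summary statistics must reproduce the summary-based t
        a = rng.normal(size=30)
        a = (a - a.mean()) / a.std(ddof=1) * 1.5 + 10.0
        b = rng.normal(size=25)
        b = (b - b.mean()) / b.std(ddof=1) * 2.5 + 11.0
        t_raw = two_sample_t(a, b, "welch").t_stat
        t_sum = t_from_summary(10.0, 1.5, 30, 11.0, 2.5, 25, "welch").t_stat
        assert t_raw == pytest.approx(t_sum, abs=1e-10)


class TestPearsonCorr:
    def test_affine_relation_gives_unit_correlation(self):
        x = np.array([1.0, 2.0, 3.0, 5.0, 8.0])
        assert pearson_corr(x, 2 * x + 1).r == pytest.approx(1.0)
        assert pearson_corr(x, -x).r == pytest.approx(-1.0)

    def test_toy_data_matches_direct_formula(self):
        x = np.array([1.0, 2.0, 4.0, 5.0, 9.0])
        y = np.array([2.0, 1.0, 5.0, 4.0, 8.0])
        xc, yc = x - x.mean(), y - y.mean()
        expect = (xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc))
        res = pearson_corr(x, y)
        assert res.r == pytest.approx(expect, abs=1e-12)
        t = expect * np.sqrt(3 / (1 - expect**2))
        assert res.p_value == pytest.approx(2 * stats.t.sf(abs(t), 3), rel=1e-6)

    def test_constant_input_errors(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_corr(np.ones(5), np.arange(5.0))


def published_screen_tables():
    """Group-difference and score-correlation statistics as printed for the
    seven AUC features (patients n=45 vs controls n=30)."""
    rows = {
        # name: (t, p_group, r, p_corr)
        "gamma_auc": (-3.473, 0.001, 0.607, 0.000),
        "lambda_auc": (0.289, 0.773, 0.166, 0.395),
        "sigma_auc": (-3.384, 0.001, 0.531, 0.000),
        "cp_auc": (0.313, 0.756, 0.194, 0.268),
        "lp_auc": (0.456, 0.650, 0.139, 0.514),
        "eglobal_auc": (-0.477, 0.635, -0.147, 0.636),
        "elocal_auc": (-0.968, 0.336, 0.353, 0.056),
    }
    group = [
        GroupTestResult(k, t, p, ((0.0, 1.0), (0.0, 1.0)), (45, 30))
        for k, (t, p, _, _) in rows.items()
    ]
    corr = [CorrelationResult(k, r, p) for k, (_, _, r, p) in rows.items()]
    return group, corr


class TestSelectFeatures:
    def test_published_statistics_select_gamma_and_sigma(self):
        group, corr = published_screen_tables()
        report = select_features(group, corr)
        assert sorted(report.selected_features) == ["gamma_auc", "sigma_auc"]

    def test_everything_insignificant_raises(self):
        group = [GroupTestResult("f", 0.1, 1.0, ((0, 1), (0, 1)), (5, 5))]
        corr = [CorrelationResult("f", 0.9, 1.0)]
        with pytest.raises(ValueError, match="no features survive"):
            select_features(group, corr)

    def test_negative_correlation_is_never_selected(self):
        group = [GroupTestResult("f", 4.0, 0.001, ((0, 1), (0, 1)), (5, 5))]
        corr = [CorrelationResult("f", -0.9, 0.0001)]
        with pytest.raises(ValueError, match="no features survive"):
            select_features(group, corr)

    def test_mismatched_feature_sets_rejected(self):
        group, corr = published_screen_tables()
        with pytest.raises(ValueError, match="same features"):
            select_features(group[:-1], corr)

    def test_bonferroni_threshold(self):
        assert bonferroni_alpha(0.05, 15) == pytest.approx(0.0033, abs=5e-5)

    def test_selection_invariant_to_feature_rescaling(self, rng):
        n_pat, n_ctl = 30, 20
        table = pd.DataFrame({
            "group": ["patient"] * n_pat + ["control"] * n_ctl,
            "score": np.r_[rng.normal(20, 2, n_pat), [np.nan] * n_ctl],
        })
        eff = np.r_[rng.normal(0, 1, n_pat), rng.normal(2, 1, n_ctl)]
        table["a"] = eff + np.r_[table["score"][:n_pat] * 0.4, np.zeros(n_ctl)]
        table["b"] = rng.normal(size=n_pat + n_ctl)
        r1 = screen_features(table, ["a", "b"], alpha_corrected=0.01)
        table2 = table.assign(a=table["a"] * 1000 + 7)
        r2 = screen_features(table2, ["a", "b"], alpha_corrected=0.01)
        assert r1.selected_features == r2.selected_features
        assert r1.group_tests[0].t_stat == pytest.approx(r2.group_tests[0].t_stat)

    def test_report_round_trips_through_dict(self):
        group, corr = published_screen_tables()
        report = select_features(group, corr)
        again = SelectionReport.from_dict(report.to_dict())
        assert again.selected_features == report.selected_features
        assert again.group_tests[0].t_stat == report.group_tests[0].t_stat


class TestFusion:
    def test_identity_when_train_stats_are_standard(self):
        table = pd.DataFrame({"f": [0.0, 1.0, -1.0]})
        stats_ = compute_train_stats(pd.DataFrame({"f": [-1.0, 0.0, 1.0]}), ["f"])
        fused = fuse_features(table, ["f"], stats_)
        assert np.allclose(fused.ravel(), table["f"])

    def test_training_block_is_zero_mean_unit_sd(self, rng):
        train = pd.DataFrame({"f": rng.normal(5, 3, 20), "g": rng.normal(-2, 0.5, 20)})
        stats_ = compute_train_stats(train, ["f", "g"])
        fused = fuse_features(train, ["f", "g"], stats_)
        assert np.allclose(fused.mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose(fused.std(axis=0, ddof=1), 1.0, atol=1e-12)

    def test_round_trip_recovers_original_values(self, rng):
        train = pd.DataFrame({"f": rng.normal(size=10), "g": rng.normal(size=10)})
        stats_ = compute_train_stats(train, ["f", "g"])
        fused = fuse_features(train, ["f", "g"], stats_)
        assert np.allclose(unfuse_features(fused, stats_), train[["f", "g"]])

    def test_zero_training_sd_errors(self):
        with pytest.raises(ValueError, match="zero training-set"):
            compute_train_stats(pd.DataFrame({"f": [1.0, 1.0, 1.0]}), ["f"])
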