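"""Two-stage statistical feature screen and linear fusion.

Stage 1: per-feature two-sample t tests (Welch by default) between patients
and controls. Stage 2: Pearson correlation between each feature and the
cognitive score within patients, with a Bonferroni-corrected threshold.
A feature is selected when it differs between groups (p < alpha_group), its
score correlation is significant at the corrected level, and the correlation
is positive. Selected features are then linearly fused: z-scored with
training-set statistics and concatenated into the regression design matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupTestResult",
    "CorrelationResult",
    "SelectionReport",
    "TrainStats",
    "bonferroni_alpha",
    "two_sample_t",
    "t_from_summary",
    "pearson_corr",
    "select_features",
    "screen_features",
    "compute_train_stats",
    "fuse_features",
]

#: Corrected alpha used by default: family-wise 0.05 over 15 comparisons.
DEFAULT_ALPHA_GROUP = 0.05
DEFAULT_ALPHA_CORRECTED = 0.05 / 15


def bonferroni_alpha(alpha: float = 0.05, m: int = 15) -> float:
    """Bonferroni-corrected per-test threshold alpha / m."""
    if m < 1:
        raise ValueError("number of comparisons must be >= 1")
    return alpha / m


@dataclass
class GroupTestResult:
    """Two-sample t test of one feature between patients and controls."""

    feature_name: str
    t_stat: float
    p_value: float
    mean_sd_per_group: tuple[tuple[float, float], tuple[float, float]]
    n_per_group: tuple[int, int]

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")


@dataclass
class CorrelationResult:
    """Pearson correlation of one feature with the cognitive score."""

    feature_name: str
    r: float
    p_value: float

    def __post_init__(self) -> None:
        if not -1.0 <= self.r <= 1.0 + 1e-12:
            raise ValueError(f"r {self.r} outside [-1, 1]")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")


@dataclass
class SelectionReport:
    """Outcome of the two-stage screen."""

    group_tests: list[GroupTestResult]
    correlations: list[CorrelationResult]
    alpha_group: float
    alpha_corrected: float
    selected_features: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "alpha_group": self.alpha_group,
            "alpha_corrected": self.alpha_corrected,
            "selected_features": list(self.selected_features),
            "group_tests": [
                {
                    "feature_name": g.feature_name,
                    "t_stat": g.t_stat,
                    "p_value": g.p_value,
                    "mean_sd_per_group": [list(ms) for ms in g.mean_sd_per_group],
                    "n_per_group": list(g.n_per_group),
                }
                for g in self.group_tests
            ],
            "correlations": [
                {"feature_name": c.feature_name, "r": c.r, "p_value": c.p_value}
                for c in self.correlations
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SelectionReport":
        return cls(
            group_tests=[
                GroupTestResult(
                    feature_name=g["feature_name"],
                    t_stat=g["t_stat"],
                    p_value=g["p_value"],
                    mean_sd_per_group=tuple(tuple(ms) for ms in g["mean_sd_per_group"]),
                    n_per_group=tuple(g["n_per_group"]),
                )
                for g in d["group_tests"]
            ],
            correlations=[
                CorrelationResult(c["feature_name"], c["r"], c["p_value"])
                for c in d["correlations"]
            ],
            alpha_group=d["alpha_group"],
            alpha_corrected=d["alpha_corrected"],
            selected_features=list(d["selected_features"]),
        )


def two_sample_t(
    a: np.ndarray,
    b: np.ndarray,
    variant: str = "welch",
    feature_name: str = "",
) -> GroupTestResult:
    """Two-sided two-sample t test; Welch (default) or pooled-variance."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        raise ValueError("zero variance in both groups; t statistic undefined")
    if variant not in ("welch", "pooled"):
        raise ValueError(f"variant must be 'welch' or 'pooled', got {variant!r}")
    res = stats.ttest_ind(a, b, equal_var=(variant == "pooled"))
    return GroupTestResult(
        feature_name=feature_name,
        t_stat=float(res.statistic),
        p_value=float(res.pvalue),
        mean_sd_per_group=(
            (float(a.mean()), float(a.std(ddof=1))),
            (float(b.mean()), float(b.std(ddof=1))),
        ),
        n_per_group=(int(a.size), int(b.size)),
    )


def t_from_summary(
    mean1: float,
    sd1: float,
    n1: int,
    mean2: float,
    sd2: float,
    n2: int,
    variant: str = "welch",
    feature_name: str = "",
) -> GroupTestResult:
    """t test from printed summary statistics (mean, sd, n per group).

    Lets published group summaries be checked directly, e.g. MoCA
    21.33 +/- 2.44 (n=45) vs 27.37 +/- 1.33 (n=30) gives t = -13.81 (Welch).
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be non-negative")
    if sd1 == 0 and sd2 == 0:
        raise ValueError("zero variance in both groups; t statistic undefined")
    if variant not in ("welch", "pooled"):
        raise ValueError(f"variant must be 'welch' or 'pooled', got {variant!r}")
    res = stats.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=(variant == "pooled")
    )
    return GroupTestResult(
        feature_name=feature_name,
        t_stat=float(res.statistic),
        p_value=float(res.pvalue),
        mean_sd_per_group=((mean1, sd1), (mean2, sd2)),
        n_per_group=(int(n1), int(n2)),
    )


def pearson_corr(x: np.ndarray, y: np.ndarray, feature_name: str = "") -> CorrelationResult:
    """Pearson r with the two-sided p value from its t transform."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("vectors must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant vector; Pearson correlation undefined")
    res = stats.pearsonr(x, y)
    return CorrelationResult(
        feature_name=feature_name, r=float(res.statistic), p_value=float(res.pvalue)
    )


def select_features(
    group_tests: list[GroupTestResult],
    correlations: list[CorrelationResult],
    alpha_group: float = DEFAULT_ALPHA_GROUP,
    alpha_corrected: float = DEFAULT_ALPHA_CORRECTED,
) -> SelectionReport:
    """Apply the two-stage rule: group p < alpha_group AND correlation
    p < alpha_corrected AND r > 0. Errors when nothing survives."""
    g_names = [g.feature_name for g in group_tests]
    c_names = [c.feature_name for c in correlations]
    if set(g_names) != set(c_names):
        raise ValueError("group tests and correlations must cover the same features")
    corr_by_name = {c.feature_name: c for c in correlations}
    selected = [
        g.feature_name
        for g in group_tests
        if g.p_value < alpha_group
        and corr_by_name[g.feature_name].p_value < alpha_corrected
        and corr_by_name[g.feature_name].r > 0
    ]
    if not selected:
        raise ValueError(
            "no features survive the selection rule "
            f"(group p < {alpha_group}, correlation p < {alpha_corrected}, r > 0)"
        )
    return SelectionReport(
        group_tests=group_tests,
        correlations=correlations,
        alpha_group=alpha_group,
        alpha_corrected=alpha_corrected,
        selected_features=selected,
    )


def screen_features(
    table: pd.DataFrame,
    feature_cols: list[str],
    alpha_group: float = DEFAULT_ALPHA_GROUP,
    alpha_corrected: float = DEFAULT_ALPHA_CORRECTED,
    variant: str = "welch",
) -> SelectionReport:
    """Run both test families on a cohort feature table and select.

    Group tests compare patients against controls per feature; correlations
    use patients with non-missing scores.
    """
    pat = table[table["group"] == "patient"]
    ctl = table[table["group"] == "control"]
    if pat.empty or ctl.empty:
        raise ValueError("feature table must contain both patients and controls")
    scored = pat[pat["score"].notna()]
    group_tests = [
        two_sample_t(pat[c].to_numpy(), ctl[c].to_numpy(), variant, feature_name=c)
        for c in feature_cols
    ]
    correlations = [
        pearson_corr(scored[c].to_numpy(), scored["score"].to_numpy(), feature_name=c)
        for c in feature_cols
    ]
    return select_features(group_tests, correlations, alpha_group, alpha_corrected)


@dataclass(frozen=True)
class TrainStats:
    """Training-set means and standard deviations used for fusion."""

    feature_names: tuple[str, ...]
    means: np.ndarray
    sds: np.ndarray


def compute_train_stats(train_table: pd.DataFrame, selected: list[str]) -> TrainStats:
    means = train_table[selected].mean().to_numpy(dtype=float)
    sds = train_table[selected].std(ddof=1).to_numpy(dtype=float)
    if np.any(sds == 0):
        zero = [s for s, sd in zip(selected, sds) if sd == 0]
        raise ValueError(f"zero training-set standard deviation for feature(s) {zero}")
    return TrainStats(feature_names=tuple(selected), means=means, sds=sds)


def fuse_features(
    table: pd.DataFrame, selected: list[str], train_stats: TrainStats
) -> np.ndarray:
    """Linear fusion: z-score each selected feature with the training-set
    statistics and concatenate column-wise into the model input matrix."""
    if tuple(selected) != train_stats.feature_names:
        raise ValueError("selected features do not match the training statistics")
    missing = [s for s in selected if s not in table.columns]
    if missing:
        raise ValueError(f"feature(s) {missing} absent from the table")
    x = table[list(selected)].to_numpy(dtype=float)
    return (x - train_stats.means) / train_stats.sds


def unfuse_features(fused: np.ndarray, train_stats: TrainStats) -> np.ndarray:
    """Inverse of :func:`fuse_features` (original feature scale)."""
    return np.asarray(fused, dtype=float) * train_stats.sds + train_stats.means
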