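"""End-to-end score-prediction model and its fitted results.

:class:`CognitiveScoreModel` is built from a cohort feature table (or
directly from subject records via :meth:`from_cohort`), and ``fit()``
executes the full pipeline: two-stage feature screen (patients versus
controls, then score correlation within patients), chronological hold-out
split of the patients, linear fusion with training-set statistics,
whale-optimization search of the LS-SVR hyperparameters against
cross-validated RMSE on the training set, a final fit, and hold-out
evaluation. The returned :class:`CognitiveScoreResults` carries the
selection report, tuned hyperparameters, per-subject predictions, error
metrics, and a ``summary()`` table.

Controls enter only the group-difference stage of the screen; the
regression itself, its fusion statistics, and the tuning folds see training
patients exclusively.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import lssvr, scoring
from .connectome import SparsityGrid, SubjectRecord
from .features import FEATURE_COLUMNS, feature_table, nodal_efficiency_auc
from .io import RunConfig, load_region_labels
from .selection import (
    SelectionReport,
    compute_train_stats,
    fuse_features,
    pearson_corr,
    screen_features,
)
from .woa import FitnessSpec, WOAConfig, optimize

__all__ = [
    "HoldoutSplit",
    "CognitiveScoreModel",
    "CognitiveScoreResults",
    "RegionRanking",
    "holdout_split",
    "run_pipeline",
    "discriminative_regions",
    "cv_rmse",
]


@dataclass(frozen=True)
class HoldoutSplit:
    """Disjoint train/test partition of the patient ids (cohort order)."""

    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if set(self.train_ids) & set(self.test_ids):
            raise ValueError("train and test ids overlap")


def holdout_split(ids: list[str], n_train: int) -> HoldoutSplit:
    """First ``n_train`` ids (cohort order, mirroring an admission-date
    split) train; the remainder test."""
    if not 0 < n_train < len(ids):
        raise ValueError(
            f"n_train must lie strictly between 0 and {len(ids)}, got {n_train}"
        )
    return HoldoutSplit(train_ids=tuple(ids[:n_train]), test_ids=tuple(ids[n_train:]))


def _kfold_indices(n: int, k: int) -> list[np.ndarray]:
    """Contiguous cohort-order folds: cross-validation then mirrors the
    chronological outer hold-out, so the tuner is scored on the same kind
    of mild extrapolation it will face at test time."""
    return [fold for fold in np.array_split(np.arange(n), k) if fold.size]


def cv_rmse(
    x: np.ndarray,
    y: np.ndarray,
    hp: lssvr.ModelHyperparams,
    folds: list[np.ndarray],
) -> float:
    """Cross-validated RMSE of an LS-SVR on fixed fold indices.

    ``folds`` may contain overlapping partitions (e.g. a 5-fold and a
    7-fold split concatenated); every held-out prediction contributes one
    squared error, so the result averages the partitions."""
    n = x.shape[0]
    sq_sum = 0.0
    count = 0
    for fold in folds:
        mask = np.ones(n, dtype=bool)
        mask[fold] = False
        try:
            model = lssvr.fit(x[mask], y[mask], hp)
        except np.linalg.LinAlgError:
            return np.inf
        pred = lssvr.predict(model, x[fold])
        sq_sum += float(np.sum((pred - y[fold]) ** 2))
        count += fold.size
    return float(np.sqrt(sq_sum / count))


@dataclass
class RegionRanking:
    """Regions ranked by |correlation| of nodal-efficiency AUC with score."""

    entries: list[tuple[int, str, float, float]]
    top_k: int

    def to_dict(self) -> dict:
        return {
            "top_k": self.top_k,
            "entries": [
                {"region_index": i, "region_name": name, "r": r, "p": p}
                for i, name, r, p in self.entries
            ],
        }


@dataclass
class CognitiveScoreResults:
    """Fitted pipeline output (estimates, uncertainty screen, diagnostics)."""

    selection: SelectionReport
    hyperparams: lssvr.ModelHyperparams
    model: lssvr.TrainedLSSVR
    split: HoldoutSplit
    per_subject: pd.DataFrame
    rmse: float
    mae: float
    mape_percent: float
    cv_rmse_best: float
    woa_history: list[float]
    config: RunConfig
    train_stats: object = None
    feature_frame: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def n_test(self) -> int:
        return len(self.per_subject)

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        """Predict scores for new subjects given their AUC feature rows."""
        fused = fuse_features(
            features, list(self.selection.selected_features), self.train_stats
        )
        return lssvr.predict(self.model, fused)

    def to_dict(self) -> dict:
        return {
            "selection": self.selection.to_dict(),
            "hyperparams": {
                "penalty": self.hyperparams.penalty,
                "kernel_width": self.hyperparams.kernel_width,
            },
            "split": {
                "train_ids": list(self.split.train_ids),
                "test_ids": list(self.split.test_ids),
            },
            "per_subject": self.per_subject.to_dict(orient="records"),
            "metrics": {
                "rmse": self.rmse,
                "mae": self.mae,
                "mape_percent": self.mape_percent,
                "n": self.n_test,
            },
            "cv_rmse_best": self.cv_rmse_best,
            "woa_history": list(self.woa_history),
            "seed": self.config.seed,
        }

    def summary(self) -> str:
        sel = ", ".join(self.selection.selected_features)
        lines = [
            "Cognitive score prediction (graph-feature LS-SVR, WOA-tuned)",
            "=" * 62,
            f"Selected features : {sel}",
            f"Train/test split  : {len(self.split.train_ids)}/{len(self.split.test_ids)} patients",
            f"Penalty (gamma)   : {self.hyperparams.penalty:.6g}",
            f"Kernel width      : {self.hyperparams.kernel_width:.6g}",
            f"CV RMSE (train)   : {self.cv_rmse_best:.4f}",
            f"Test RMSE         : {self.rmse:.4f}",
            f"Test MAE          : {self.mae:.4f}",
            f"Test MAPE         : {self.mape_percent:.2f}%",
            "-" * 62,
            f"{'subject':<12}{'actual':>10}{'predicted':>12}",
        ]
        for _, row in self.per_subject.iterrows():
            lines.append(
                f"{row['subject_id']:<12}{row['actual']:>10.2f}{row['predicted']:>12.2f}"
            )
        return "\n".join(lines)

    def plot_predictions(self, ax=None):
        """Actual versus predicted test scores."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        idx = np.arange(self.n_test)
        ax.plot(idx, self.per_subject["actual"], "k-o", label="actual")
        ax.plot(idx, self.per_subject["predicted"], "r-s", label="predicted")
        ax.set_xlabel("test subject")
        ax.set_ylabel("cognitive score (points)")
        ax.legend()
        return ax

    def plot_convergence(self, ax=None):
        """Best cross-validated RMSE per WOA iteration."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.woa_history)
        ax.set_xlabel("iteration")
        ax.set_ylabel("best CV RMSE")
        return ax


class CognitiveScoreModel:
    """Score-prediction model over a cohort AUC feature table.

    Parameters
    ----------
    features : DataFrame with columns ``subject_id``, ``group``, ``score``
        and the seven ``<metric>_auc`` feature columns.
    config : RunConfig
    """

    def __init__(self, features: pd.DataFrame, config: RunConfig | None = None):
        self.config = config or RunConfig()
        required = {"subject_id", "group", "score", *FEATURE_COLUMNS}
        missing = required - set(features.columns)
        if missing:
            raise ValueError(f"feature table missing column(s) {sorted(missing)}")
        self.features = features.reset_index(drop=True)

    @classmethod
    def from_cohort(
        cls, subjects: list[SubjectRecord], config: RunConfig | None = None
    ) -> "CognitiveScoreModel":
        """Run feature extraction on raw subject records and build the model."""
        config = config or RunConfig()
        table = feature_table(
            subjects,
            grid=config.grid,
            null_cfg=config.null_cfg,
            seed=config.seed,
            edge_ranking=config.edge_ranking,
        )
        return cls(table, config)

    def fit(
        self, hyperparams: lssvr.ModelHyperparams | None = None
    ) -> CognitiveScoreResults:
        """Select features, tune (unless ``hyperparams`` is given), train,
        and evaluate on the hold-out test patients."""
        cfg = self.config
        patients = self.features[self.features["group"] == "patient"]
        if patients["score"].isna().any():
            bad = patients.loc[patients["score"].isna(), "subject_id"].tolist()
            raise ValueError(f"patient(s) {bad} lack scores")

        selection = screen_features(
            self.features,
            list(FEATURE_COLUMNS),
            alpha_group=cfg.alpha_group,
            alpha_corrected=cfg.alpha_corrected,
        )
        selected = list(selection.selected_features)

        split = holdout_split(patients["subject_id"].tolist(), cfg.n_train)
        train = patients[patients["subject_id"].isin(split.train_ids)]
        test = patients[patients["subject_id"].isin(split.test_ids)]

        stats = compute_train_stats(train, selected)
        x_train = fuse_features(train, selected, stats)
        x_test = fuse_features(test, selected, stats)
        y_train = train["score"].to_numpy(dtype=float)
        y_test = test["score"].to_numpy(dtype=float)

        history: list[float] = []
        # two blocked partitions (k and k+2) averaged: a lower-variance
        # tuning objective than a single partition
        folds = _kfold_indices(len(y_train), cfg.cv_folds) + _kfold_indices(
            len(y_train), cfg.cv_folds + 2
        )
        if hyperparams is None:

            def objective(v: np.ndarray) -> float:
                hp = lssvr.ModelHyperparams(
                    penalty=10.0 ** v[0], kernel_width=10.0 ** v[1]
                )
                return cv_rmse(x_train, y_train, hp, folds)

            woa_cfg = WOAConfig(
                bounds=(cfg.log_penalty_bounds, cfg.log_width_bounds),
                n_whales=cfg.woa_whales,
                n_iterations=cfg.woa_iterations,
                spiral_b=cfg.woa_spiral_b,
                switch_prob=cfg.woa_switch_prob,
                seed=cfg.seed,
                warm_starts=((0.0, 0.0),),
            )
            result = optimize(
                FitnessSpec(objective, "blocked CV RMSE on training patients"), woa_cfg
            )
            hyperparams = lssvr.ModelHyperparams(
                penalty=10.0 ** result.best_position[0],
                kernel_width=10.0 ** result.best_position[1],
            )
            history = result.history
            cv_best = result.best_fitness
        else:
            cv_best = cv_rmse(x_train, y_train, hyperparams, folds)

        model = lssvr.fit(x_train, y_train, hyperparams)
        pred = lssvr.predict(model, x_test)
        per_subject = pd.DataFrame(
            {
                "subject_id": test["subject_id"].to_numpy(),
                "actual": y_test,
                "predicted": pred,
            }
        )
        return CognitiveScoreResults(
            selection=selection,
            hyperparams=hyperparams,
            model=model,
            split=split,
            per_subject=per_subject,
            rmse=scoring.rmse(y_test, pred),
            mae=scoring.mae(y_test, pred),
            mape_percent=scoring.mape(y_test, pred),
            cv_rmse_best=cv_best,
            woa_history=history,
            config=cfg,
            train_stats=stats,
            feature_frame=self.features,
        )


def run_pipeline(
    subjects: list[SubjectRecord], config: RunConfig | None = None
) -> CognitiveScoreResults:
    """Convenience wrapper: cohort records in, fitted results out."""
    return CognitiveScoreModel.from_cohort(subjects, config).fit()


def discriminative_regions(
    patients: list[SubjectRecord],
    top_k: int = 10,
    grid: SparsityGrid | None = None,
    labels: pd.DataFrame | None = None,
    edge_ranking: str = "positive",
) -> RegionRanking:
    """Rank regions by |Pearson r| between per-region nodal-efficiency AUC
    and the cognitive score across patients."""
    scored = [p for p in patients if p.score is not None]
    if len(scored) < 3:
        raise ValueError("need at least 3 patients with scores")
    grid = grid or SparsityGrid()
    n_regions = scored[0].n_regions
    if not 1 <= top_k <= n_regions:
        raise ValueError(f"top_k must lie in [1, {n_regions}]")
    scores = np.array([p.score for p in scored], dtype=float)
    if scores.std() == 0:
        raise ValueError("constant scores; correlation undefined")
    eff = np.stack([nodal_efficiency_auc(p.timeseries, grid, edge_ranking) for p in scored])
    if labels is None and n_regions == 90:
        labels = load_region_labels()
    names = (
        {int(i) - 1: str(a) for i, a in zip(labels["index"], labels["abbreviation"])}
        if labels is not None
        else {}
    )
    results = []
    for i in range(n_regions):
        col = eff[:, i]
        if col.std() == 0:
            results.append((i, names.get(i, f"region{i + 1}"), 0.0, 1.0))
            continue
        c = pearson_corr(col, scores)
        results.append((i, names.get(i, f"region{i + 1}"), c.r, c.p_value))
    results.sort(key=lambda t: (-abs(t[2]), t[0]))
    return RegionRanking(entries=results[:top_k], top_k=top_k)
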