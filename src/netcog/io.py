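"""Readers, writers, and run configuration shared by all stages.

Tabular data is plain TSV/CSV; reports, models, and truth ledgers are JSON.
Region indices are 1-based in files (atlas convention) and 0-based in
memory; the label loader is the only place this mapping lives.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .connectome import Group, SparsityGrid, SubjectRecord
from .graph_metrics import NullModelConfig
from .selection import DEFAULT_ALPHA_CORRECTED, DEFAULT_ALPHA_GROUP

__all__ = [
    "RunConfig",
    "read_timeseries",
    "write_timeseries",
    "read_manifest",
    "write_manifest",
    "load_subjects",
    "write_json",
    "read_json",
    "load_region_labels",
    "load_config",
]


@dataclass
class RunConfig:
    """Everything a pipeline run needs; every field has a sensible default.

    The pipeline null ensemble is deliberately lighter than the standalone
    :class:`NullModelConfig` default (5 randomizations, 5 swaps per edge
    versus 100 and 10): with 31 thresholds per subject the ensemble mean is
    already averaged over many networks, and the lighter setting keeps a
    full cohort run fast while leaving the normalisation unbiased.
    """

    grid: SparsityGrid = field(default_factory=SparsityGrid)
    null_cfg: NullModelConfig = field(
        default_factory=lambda: NullModelConfig(n_randomizations=5, swaps_per_edge=5)
    )
    edge_ranking: str = "positive"
    alpha_group: float = DEFAULT_ALPHA_GROUP
    alpha_corrected: float = DEFAULT_ALPHA_CORRECTED
    n_train: int = 35
    cv_folds: int = 5
    woa_whales: int = 30
    woa_iterations: int = 100
    woa_spiral_b: float = 1.0
    woa_switch_prob: float = 0.5
    log_penalty_bounds: tuple[float, float] = (-2.0, 5.0)
    log_width_bounds: tuple[float, float] = (-2.0, 3.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.edge_ranking not in ("positive", "absolute"):
            raise ValueError("edge_ranking must be 'positive' or 'absolute'")
        if not 0 < self.alpha_group <= 1 or not 0 < self.alpha_corrected <= 1:
            raise ValueError("alpha thresholds must lie in (0, 1]")
        if self.n_train < 1:
            raise ValueError("n_train must be >= 1")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


def load_config(path: str | Path) -> RunConfig:
    """Build a RunConfig from a YAML file; unknown keys are an error."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    kwargs: dict = {}
    if "grid" in raw:
        g = raw.pop("grid")
        try:
            kwargs["grid"] = SparsityGrid(
                start=g.get("start", 0.10), stop=g.get("stop", 0.40), step=g.get("step", 0.01)
            )
        except (AttributeError, TypeError) as exc:
            raise ValueError(f"{path}: invalid 'grid' section: {exc}") from None
    if "null_model" in raw:
        n = raw.pop("null_model")
        kwargs["null_cfg"] = NullModelConfig(
            n_randomizations=n.get("n_randomizations", 5),
            swaps_per_edge=n.get("swaps_per_edge", 5),
            seed=n.get("seed", 0),
        )
    for key in (
        "edge_ranking", "alpha_group", "alpha_corrected", "n_train", "cv_folds",
        "woa_whales", "woa_iterations", "woa_spiral_b", "woa_switch_prob", "seed",
    ):
        if key in raw:
            kwargs[key] = raw.pop(key)
    for key in ("log_penalty_bounds", "log_width_bounds"):
        if key in raw:
            kwargs[key] = tuple(raw.pop(key))
    if raw:
        raise ValueError(f"{path}: unknown config keys {sorted(raw)}")
    return RunConfig(**kwargs)


def read_timeseries(path: str | Path) -> np.ndarray:
    """Read a region x time matrix from TSV/CSV (rows = regions).

    A header row is auto-detected: if any cell of the first line is not
    numeric it is dropped. Ragged or non-numeric content raises with the
    file name in the message.
    """
    path = Path(path)
    first = path.open().readline()
    sep = "\t" if "\t" in first else ","
    tokens = [t for t in first.strip().split(sep) if t != ""]

    def _numeric(tok: str) -> bool:
        try:
            float(tok)
            return True
        except ValueError:
            return False

    header = 0 if tokens and not all(_numeric(t) for t in tokens) else None
    try:
        df = pd.read_csv(path, sep=sep, header=header)
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: ragged or malformed rows ({exc})") from None
    mat = df.to_numpy()
    if mat.dtype == object or not np.issubdtype(mat.dtype, np.number):
        raise ValueError(f"{path}: non-numeric cells in time-series matrix")
    if np.isnan(mat).any():
        raise ValueError(f"{path}: missing or non-numeric cells in time-series matrix")
    if mat.shape[0] < 3:
        raise ValueError(f"{path}: need at least 3 regions, found {mat.shape[0]}")
    return mat.astype(float)


def write_timeseries(mat: np.ndarray, path: str | Path) -> None:
    np.savetxt(path, np.asarray(mat, dtype=float), delimiter="\t", fmt="%.10g")


MANIFEST_COLUMNS = ("subject_id", "group", "score", "timeseries_path")


def write_manifest(subjects: list[SubjectRecord], directory: str | Path) -> Path:
    """Write per-subject TSV time series plus a manifest CSV; returns the
    manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in subjects:
        fname = f"{rec.subject_id}.tsv"
        write_timeseries(rec.timeseries, directory / fname)
        rows.append(
            {
                "subject_id": rec.subject_id,
                "group": rec.group.value,
                "score": "" if rec.score is None else rec.score,
                "timeseries_path": fname,
            }
        )
    manifest = directory / "manifest.csv"
    pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS)).to_csv(manifest, index=False)
    return manifest


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Validate and return the cohort manifest (paths resolved, not loaded)."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"subject_id": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: manifest missing column(s) {missing}")
    dup = df["subject_id"][df["subject_id"].duplicated()]
    if not dup.empty:
        raise ValueError(f"{path}: duplicate subject id(s) {sorted(set(dup))}")
    bad = set(df["group"]) - {g.value for g in Group}
    if bad:
        raise ValueError(f"{path}: invalid group label(s) {sorted(bad)}")
    for rel in df["timeseries_path"]:
        full = path.parent / rel
        if not full.exists():
            raise ValueError(f"{path}: referenced time-series file {full} does not exist")
    return df


def load_subjects(manifest_path: str | Path) -> list[SubjectRecord]:
    """Load every subject referenced by a manifest."""
    manifest_path = Path(manifest_path)
    df = read_manifest(manifest_path)
    out = []
    for _, row in df.iterrows():
        score = row["score"]
        score = None if pd.isna(score) or score == "" else float(score)
        ts = read_timeseries(manifest_path.parent / row["timeseries_path"])
        out.append(
            SubjectRecord(
                subject_id=str(row["subject_id"]),
                group=Group(row["group"]),
                score=score,
                timeseries=ts,
            )
        )
    return out


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default))


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"cannot serialise {type(o)}")


def load_region_labels(path: str | Path | None = None) -> pd.DataFrame:
    """Region label table: columns ``index`` (1-based), ``abbreviation``,
    ``name``. Defaults to the packaged 90-region AAL table."""
    if path is None:
        source = resources.files("netcog.data").joinpath("aal90.csv")
        with resources.as_file(source) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    required = {"index", "abbreviation", "name"}
    if not required.issubset(df.columns):
        raise ValueError(f"region label table must have columns {sorted(required)}")
    return df
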