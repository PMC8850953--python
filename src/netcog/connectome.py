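"""Functional-connectivity network construction.

A subject's regional time series (rows = brain regions, columns = timepoints)
is turned into a Pearson correlation matrix, variance-stabilised with the
Fisher Z transform, and binarised by proportional thresholding: at sparsity
``S`` exactly ``round(S * n(n-1)/2)`` of the strongest edges are kept. The
sparsity grid (default 0.10 to 0.40 in steps of 0.01, 31 values) defines the
threshold range over which downstream topological metrics are integrated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

__all__ = [
    "Group",
    "SubjectRecord",
    "ConnectivityMatrix",
    "BinaryNetwork",
    "SparsityGrid",
    "pearson_fc",
    "fisher_z",
    "proportional_threshold",
    "threshold_grid",
]


class Group(str, Enum):
    """Cohort arm a subject belongs to."""

    PATIENT = "patient"
    CONTROL = "control"


@dataclass
class SubjectRecord:
    """One subject: identifier, group label, optional cognitive score, and
    the region x time series matrix.

    Scores follow the MoCA convention (0-30 points); controls may lack one.
    ``truth`` is populated by the synthetic-cohort generator with the
    ground-truth network and latent parameters, and is ``None`` for real data.
    """

    subject_id: str
    group: Group
    score: float | None
    timeseries: np.ndarray
    truth: dict | None = None

    def __post_init__(self) -> None:
        self.group = Group(self.group)
        ts = np.asarray(self.timeseries, dtype=float)
        if ts.ndim != 2:
            raise ValueError(f"timeseries must be 2-D, got shape {ts.shape}")
        if ts.shape[0] < 3:
            raise ValueError(f"need at least 3 regions, got {ts.shape[0]}")
        if ts.shape[1] < 10:
            raise ValueError(f"need at least 10 timepoints, got {ts.shape[1]}")
        if not np.all(np.isfinite(ts)):
            raise ValueError(f"non-finite values in timeseries of {self.subject_id!r}")
        if self.score is not None:
            score = float(self.score)
            if not 0.0 <= score <= 30.0:
                raise ValueError(
                    f"score {score} of {self.subject_id!r} outside the 0-30 range"
                )
            self.score = score
        self.timeseries = ts

    @property
    def n_regions(self) -> int:
        return self.timeseries.shape[0]


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Symmetric Fisher-Z connectivity matrix with a zero diagonal."""

    z: np.ndarray

    def __post_init__(self) -> None:
        z = np.asarray(self.z, dtype=float)
        if z.ndim != 2 or z.shape[0] != z.shape[1]:
            raise ValueError(f"connectivity matrix must be square, got {z.shape}")
        if not np.allclose(z, z.T, atol=1e-12):
            raise ValueError("connectivity matrix must be symmetric")
        off = z[~np.eye(z.shape[0], dtype=bool)]
        if not np.all(np.isfinite(off)):
            raise ValueError("non-finite off-diagonal entries in connectivity matrix")
        object.__setattr__(self, "z", z)

    @property
    def n(self) -> int:
        return self.z.shape[0]


@dataclass(frozen=True)
class BinaryNetwork:
    """Undirected binary network at a given sparsity (fraction of possible
    edges retained)."""

    adjacency: np.ndarray
    sparsity: float

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError(f"adjacency must be square, got {a.shape}")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("adjacency diagonal must be zero")
        if not np.all((a == 0) | (a == 1)):
            raise ValueError("adjacency entries must be 0 or 1")
        if not 0.0 < self.sparsity < 1.0:
            raise ValueError(f"sparsity must lie in (0, 1), got {self.sparsity}")
        object.__setattr__(self, "adjacency", a.astype(np.uint8))

    @property
    def n(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def edge_set(self) -> set[tuple[int, int]]:
        i, j = np.nonzero(np.triu(self.adjacency, 1))
        return set(zip(i.tolist(), j.tolist()))


@dataclass(frozen=True)
class SparsityGrid:
    """Strictly increasing grid of sparsity thresholds."""

    start: float = 0.10
    stop: float = 0.40
    step: float = 0.01
    values: tuple[float, ...] = field(default=())

    def __post_init__(self) -> None:
        if not self.values:
            n = int(round((self.stop - self.start) / self.step)) + 1
            vals = tuple(round(self.start + k * self.step, 10) for k in range(n))
            object.__setattr__(self, "values", vals)
        vals = tuple(float(v) for v in self.values)
        if len(vals) < 1 or any(b <= a for a, b in zip(vals, vals[1:])):
            raise ValueError("sparsity grid must be strictly increasing")
        if vals[0] <= 0.0 or vals[-1] >= 1.0:
            raise ValueError("sparsity values must lie in (0, 1)")
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return len(self.values)

    def __iter__(self):
        return iter(self.values)

    @property
    def width(self) -> float:
        return self.values[-1] - self.values[0]


def pearson_fc(timeseries: np.ndarray) -> np.ndarray:
    """Pearson correlation between every pair of regional time series.

    Returns a symmetric matrix with unit diagonal and entries in [-1, 1].
    Raises if any region has zero temporal variance (correlation undefined).
    """
    ts = np.asarray(timeseries, dtype=float)
    if ts.ndim != 2:
        raise ValueError(f"timeseries must be 2-D, got shape {ts.shape}")
    if ts.shape[1] < 2:
        raise ValueError("need at least 2 timepoints to correlate")
    if not np.all(np.isfinite(ts)):
        raise ValueError("non-finite values in timeseries")
    sd = ts.std(axis=1)
    flat = np.nonzero(sd == 0)[0]
    if flat.size:
        raise ValueError(
            f"region(s) {flat.tolist()} have constant time series; "
            "Pearson correlation is undefined"
        )
    r = np.corrcoef(ts)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return r


def fisher_z(r_matrix: np.ndarray, clip: float = 0.999999) -> ConnectivityMatrix:
    """Fisher Z transform (atanh) of a correlation matrix.

    ``|r|`` is clipped at ``clip`` before atanh so perfect correlations stay
    finite. The diagonal is set to zero: self-connections are never edges.
    """
    r = np.asarray(r_matrix, dtype=float)
    if not np.all(np.isfinite(r)):
        raise ValueError("non-finite entries in correlation matrix")
    if np.any(np.abs(r) > 1.0 + 1e-12):
        raise ValueError("correlation entries must lie in [-1, 1]")
    z = np.arctanh(np.clip(r, -clip, clip))
    np.fill_diagonal(z, 0.0)
    return ConnectivityMatrix(z=(z + z.T) / 2.0)


def _ranked_edges(z: np.ndarray, ranking: str) -> tuple[np.ndarray, np.ndarray]:
    """Upper-triangle edge candidates sorted by descending strength, ties by
    ascending (row, column)."""
    n = z.shape[0]
    iu, ju = np.triu_indices(n, 1)
    w = z[iu, ju]
    if ranking == "absolute":
        strength = np.abs(w)
        keepable = np.ones_like(w, dtype=bool)
    elif ranking == "positive":
        strength = w
        keepable = w > 0
    else:
        raise ValueError(f"edge_ranking must be 'positive' or 'absolute', got {ranking!r}")
    # lexsort: last key is primary; negate strength for descending order
    order = np.lexsort((ju, iu, -strength))
    return np.column_stack([iu[order], ju[order]]), keepable[order]


def proportional_threshold(
    z: ConnectivityMatrix | np.ndarray,
    sparsity: float,
    edge_ranking: str = "positive",
) -> BinaryNetwork:
    """Binarise a connectivity matrix by keeping the strongest edges.

    Exactly ``round(sparsity * n(n-1)/2)`` edges (round-half-up) are retained,
    ranked by Z value (default) or by ``|Z|`` with ``edge_ranking="absolute"``.
    With the default ranking negative edges are never kept; an error is raised
    if the requested edge count exceeds the number of positive edges.
    """
    zm = z if isinstance(z, ConnectivityMatrix) else ConnectivityMatrix(np.asarray(z, float))
    if not 0.0 < sparsity < 1.0:
        raise ValueError(f"sparsity must lie in (0, 1), got {sparsity}")
    n = zm.n
    n_possible = n * (n - 1) // 2
    target = int(math.floor(sparsity * n_possible + 0.5))
    edges, keepable = _ranked_edges(zm.z, edge_ranking)
    available = int(keepable.sum())
    if target > available:
        raise ValueError(
            f"sparsity {sparsity} requests {target} edges but only "
            f"{available} {'positive ' if edge_ranking == 'positive' else ''}"
            f"edge candidates are available"
        )
    chosen = edges[keepable][:target]
    adj = np.zeros((n, n), dtype=np.uint8)
    if target:
        adj[chosen[:, 0], chosen[:, 1]] = 1
        adj[chosen[:, 1], chosen[:, 0]] = 1
    return BinaryNetwork(adjacency=adj, sparsity=float(sparsity))


def threshold_grid(
    z: ConnectivityMatrix | np.ndarray,
    grid: SparsityGrid | None = None,
    edge_ranking: str = "positive",
) -> list[BinaryNetwork]:
    """Binarise at every sparsity of the grid (default 0.10-0.40, 31 nets).

    Because the edge ranking is fixed, the networks are nested: every edge
    present at a lower sparsity is present at all higher sparsities.
    """
    grid = grid or SparsityGrid()
    zm = z if isinstance(z, ConnectivityMatrix) else ConnectivityMatrix(np.asarray(z, float))
    return [proportional_threshold(zm, s, edge_ranking) for s in grid]
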