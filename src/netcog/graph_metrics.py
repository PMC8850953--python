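"""Topological metrics of binary brain networks.

Seven whole-network metrics are computed per thresholded network: clustering
coefficient Cp, characteristic path length Lp, global efficiency E_global,
local efficiency E_local, and the small-world triple (gamma, lambda, sigma)
obtained by normalising Cp and Lp against degree-preserving random reference
networks (Maslov-Sneppen edge swaps). Nodal efficiency measures per-region
information-transfer capacity. Each metric curve over the sparsity grid is
summarised by its trapezoidal area under the curve (AUC), giving the
threshold-free features used downstream.

Conventions for disconnected networks: Lp averages finite distances only;
efficiencies use 1/d = 0 for unreachable pairs; nodes of degree < 2
contribute 0 to clustering and local efficiency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._fast import apsp, local_efficiency_sum, ms_rewire
from .connectome import BinaryNetwork, SparsityGrid

__all__ = [
    "NullModelConfig",
    "TopologyFeatures",
    "METRIC_NAMES",
    "clustering_coefficient",
    "characteristic_path_length",
    "global_efficiency",
    "local_efficiency",
    "nodal_efficiency",
    "random_reference",
    "normalized_smallworld",
    "auc_over_grid",
    "network_metrics",
    "metric_curves",
]

#: Canonical feature order used in tables and reports.
METRIC_NAMES = ("gamma", "lambda", "sigma", "cp", "lp", "eglobal", "elocal")


@dataclass(frozen=True)
class NullModelConfig:
    """Random-reference ensemble for small-world normalisation.

    ``n_randomizations`` degree-preserving rewired copies are generated, each
    by ``swaps_per_edge * n_edges`` attempted double-edge swaps.
    """

    n_randomizations: int = 100
    swaps_per_edge: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_randomizations < 1:
            raise ValueError("n_randomizations must be >= 1")
        if self.swaps_per_edge < 1:
            raise ValueError("swaps_per_edge must be >= 1")


@dataclass
class TopologyFeatures:
    """Per-threshold metric curves and their AUC summaries for one subject.

    ``curves`` is indexed by sparsity with one column per metric; ``auc``
    holds the trapezoidal integral of each column over the grid, named
    ``<metric>_auc``.
    """

    curves: pd.DataFrame
    auc: pd.Series

    @property
    def gamma_auc(self) -> float:
        return float(self.auc["gamma_auc"])

    @property
    def sigma_auc(self) -> float:
        return float(self.auc["sigma_auc"])


def _as_adjacency(net: BinaryNetwork | np.ndarray) -> np.ndarray:
    if isinstance(net, BinaryNetwork):
        return net.adjacency.astype(np.uint8)
    a = np.asarray(net)
    if a.ndim != 2 or a.shape[0] != a.shape[1] or not np.array_equal(a, a.T):
        raise ValueError("expected a symmetric square adjacency matrix")
    return a.astype(np.uint8)


def distance_matrix(net: BinaryNetwork | np.ndarray) -> np.ndarray:
    """All-pairs shortest-path lengths (hops); inf for unreachable pairs."""
    adj = _as_adjacency(net)
    hops = apsp(adj)
    dist = hops.astype(float)
    dist[hops < 0] = np.inf
    return dist


def _triangles(adj: np.ndarray) -> np.ndarray:
    a = adj.astype(np.float32)
    return ((a @ a) * a).sum(axis=1).astype(float) / 2.0


def clustering_coefficient(net: BinaryNetwork | np.ndarray) -> float:
    """Mean local clustering: 2*triangles / k(k-1), 0 for degree < 2."""
    adj = _as_adjacency(net)
    k = adj.sum(axis=1).astype(float)
    tri = _triangles(adj)
    denom = k * (k - 1)
    local = np.divide(2.0 * tri, denom, out=np.zeros_like(tri), where=denom > 0)
    return float(local.mean())


def characteristic_path_length(
    net: BinaryNetwork | np.ndarray, distances: np.ndarray | None = None
) -> float:
    """Mean shortest-path length over reachable node pairs."""
    d = distance_matrix(net) if distances is None else distances
    off = d[~np.eye(d.shape[0], dtype=bool)]
    finite = off[np.isfinite(off)]
    if finite.size == 0:
        raise ValueError("no reachable node pair; characteristic path length undefined")
    return float(finite.mean())


def global_efficiency(
    net: BinaryNetwork | np.ndarray, distances: np.ndarray | None = None
) -> float:
    """Mean inverse shortest-path length over pairs (0 for unreachable)."""
    d = distance_matrix(net) if distances is None else distances
    n = d.shape[0]
    if n < 2:
        return 0.0
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def nodal_efficiency(
    net: BinaryNetwork | np.ndarray, distances: np.ndarray | None = None
) -> np.ndarray:
    """Per-node mean inverse distance to every other node, in [0, 1]."""
    d = distance_matrix(net) if distances is None else distances
    n = d.shape[0]
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return inv.sum(axis=1) / (n - 1)


def local_efficiency(net: BinaryNetwork | np.ndarray) -> float:
    """Mean over nodes of the global efficiency of each neighbour subgraph."""
    adj = _as_adjacency(net)
    return float(local_efficiency_sum(np.ascontiguousarray(adj)) / adj.shape[0])


def random_reference(
    net: BinaryNetwork | np.ndarray,
    cfg: NullModelConfig | None = None,
    rng: np.random.Generator | None = None,
    swaps_per_edge: int | None = None,
) -> np.ndarray:
    """Degree-preserving randomised copy via Maslov-Sneppen double-edge swaps.

    Each attempt draws two distinct edges (a,b), (c,d) and proposes the
    replacements (a,d), (c,b); attempts producing self-loops or parallel
    edges are skipped, so the result is always a simple graph with the
    input's exact degree sequence. Rigid graphs (e.g. complete graphs)
    come back unchanged. Deterministic given the generator state.
    """
    cfg = cfg or NullModelConfig()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    spe = cfg.swaps_per_edge if swaps_per_edge is None else swaps_per_edge
    adj = _as_adjacency(net).copy()
    edges = np.ascontiguousarray(np.argwhere(np.triu(adj, 1)), dtype=np.int64)
    m = len(edges)
    if m < 2:
        return adj
    a_bool = np.ascontiguousarray(adj.astype(bool))
    swap_seed = int(rng.integers(2**31))
    ms_rewire(a_bool, edges, spe * m, swap_seed)
    return a_bool.astype(np.uint8)


def normalized_smallworld(
    net: BinaryNetwork | np.ndarray,
    cfg: NullModelConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[float, float, float]:
    """Small-world normalisation (gamma, lambda, sigma).

    gamma = Cp / <Cp_null>, lambda = Lp / <Lp_null>, sigma = gamma / lambda,
    with null means over ``cfg.n_randomizations`` degree-preserving rewired
    references. All three equal 1 when rewiring cannot alter the graph.
    """
    cfg = cfg or NullModelConfig()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    adj = _as_adjacency(net)
    cp = clustering_coefficient(adj)
    lp = characteristic_path_length(adj)
    cps, lps = [], []
    for _ in range(cfg.n_randomizations):
        null = random_reference(adj, cfg, rng=rng)
        cps.append(clustering_coefficient(null))
        lps.append(characteristic_path_length(null))
    cp_null = float(np.mean(cps))
    lp_null = float(np.mean(lps))
    if cp_null == 0 or lp_null == 0:
        raise ValueError("null-model mean Cp or Lp is zero; gamma/lambda undefined")
    gamma = cp / cp_null
    lam = lp / lp_null
    return gamma, lam, gamma / lam


def auc_over_grid(curve: np.ndarray, grid: SparsityGrid) -> float:
    """Trapezoidal integral of a metric curve over the sparsity grid."""
    curve = np.asarray(curve, dtype=float)
    if curve.shape != (len(grid),):
        raise ValueError(
            f"curve length {curve.shape} does not match grid length {len(grid)}"
        )
    return float(np.trapezoid(curve, np.asarray(grid.values)))


def network_metrics(
    net: BinaryNetwork | np.ndarray,
    null_cfg: NullModelConfig | None = None,
    rng: np.random.Generator | None = None,
) -> dict[str, float]:
    """All seven metrics of one network as a name -> value dict."""
    adj = _as_adjacency(net)
    d = distance_matrix(adj)
    gamma, lam, sigma = normalized_smallworld(adj, null_cfg, rng=rng)
    return {
        "gamma": gamma,
        "lambda": lam,
        "sigma": sigma,
        "cp": clustering_coefficient(adj),
        "lp": characteristic_path_length(adj, distances=d),
        "eglobal": global_efficiency(adj, distances=d),
        "elocal": local_efficiency(adj),
    }


def metric_curves(
    networks: list[BinaryNetwork],
    grid: SparsityGrid,
    null_cfg: NullModelConfig | None = None,
    rng: np.random.Generator | None = None,
) -> TopologyFeatures:
    """Metric curves over the thresholded networks of one subject plus AUCs."""
    if len(networks) != len(grid):
        raise ValueError("one network per grid value is required")
    null_cfg = null_cfg or NullModelConfig()
    if rng is None:
        rng = np.random.default_rng(null_cfg.seed)
    rows = [network_metrics(net, null_cfg, rng=rng) for net in networks]
    curves = pd.DataFrame(rows, index=list(grid.values))[list(METRIC_NAMES)]
    curves.index.name = "sparsity"
    auc = pd.Series(
        {f"{m}_auc": auc_over_grid(curves[m].to_numpy(), grid) for m in METRIC_NAMES}
    )
    return TopologyFeatures(curves=curves, auc=auc)
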