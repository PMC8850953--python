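"""Synthetic cohorts with the statistical structure the analysis assumes.

Each subject owns a ground-truth brain-like network built from a ring of
cliques (connected-caveman graph, cliques of ten regions): a modular,
triangle-rich substrate whose adjacency spectrum admits strong positive
couplings before the covariance loses positive-definiteness, so the
planted topology is recoverable from short time series. Disease severity
is the probability of deleting within-clique edges (functional segregation
loss), drawn from a group-specific range: patients lose more, which lowers
their normalised clustering (gamma) and small-worldness (sigma). Patient
severity follows a jittered stratified ramp over admission order, so every
cohort spans the severity spectrum evenly (stabilising the power of the
downstream screen) and later-admitted patients are somewhat sicker, which
makes the chronological hold-out split a mild extrapolation task.

Two independent nuisance dimensions give the non-selected metrics variance
of their own. A per-subject random budget of long-range shortcuts moves
path-length-type metrics (Lp, lambda, E_global) without touching the
clustering signal, and a per-subject amount of triangle-rich hub
attachment (a few hub nodes linked to whole neighbourhoods) concentrates
degree, moving raw clustering-type metrics (Cp, E_local) in a way the
degree-preserving small-world normalisation discounts. The net effect is
the empirical pattern this analysis relies on: gamma and sigma carry the
severity signal; the raw metrics do not.

Regional time series are stationary correlated Gaussian noise with
covariance

    Sigma = I + coupling_strength * W / |lambda_min(W_core)|

where W weights within-clique edges 1.0, hub edges 1.0, and other
long-range edges 0.6; W_core is the pre-hub graph, so clique edges carry
the same correlation strength in every subject, and any indefiniteness
introduced by the hub overlay is repaired by eigenvalue flooring plus
diagonal rescaling.

The planted truth per subject is the population AUC of gamma and sigma:
the measurement pipeline evaluated on the exact correlation matrix implied
by the covariance (the infinite-scan-length limit of the observable
features). Cognitive scores are a linear function of that truth plus
Gaussian noise, clipped to the 0-30 MoCA scale. Optionally, a set of
signal regions is degraded per patient in proportion to a latent severity
that also depresses the score, planting a regional nodal-efficiency signal
for discriminative-region recovery tests.

Time series are plain correlated noise: no hemodynamics, drift, or motion.
The pipeline consumes only correlation structure, so this is sufficient
for testing every downstream stage.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .connectome import (
    ConnectivityMatrix,
    Group,
    SparsityGrid,
    SubjectRecord,
    fisher_z,
    proportional_threshold,
)
from .graph_metrics import (
    NullModelConfig,
    auc_over_grid,
    normalized_smallworld,
)

__all__ = [
    "SimulationConfig",
    "CohortTruth",
    "ring_lattice",
    "clique_ring",
    "rewire_edges",
    "degrade_cliques",
    "hub_attach",
    "watts_strogatz",
    "generate_subject",
    "generate_scores",
    "generate_cohort",
]


def watts_strogatz(n: int, k: int, p: float, rng: np.random.Generator) -> np.ndarray:
    """Classic Watts-Strogatz small-world graph (ring lattice + rewiring)."""
    return rewire_edges(ring_lattice(n, k), p, rng)

#: Sparsity subgrid used for the population (noise-free) AUC ground truth.
TRUTH_GRID = (0.10, 0.40, 0.03)


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort-level generative settings; defaults mirror the study design
    (45 patients, 30 controls, 90 regions, 130 retained timepoints)."""

    n_patients: int = 45
    n_controls: int = 30
    n_regions: int = 90
    n_timepoints: int = 130
    base_topology: str = "caveman"
    clique_size: int = 10
    ring_degree: int = 4
    rewire_prob_control: float = 0.17
    rewire_prob_patient: float = 0.35
    rewire_halfwidth_control: float = 0.05
    rewire_halfwidth_patient: float = 0.13
    early_stage_frac: float = 0.0
    shortcut_range: tuple[int, int] = (100, 400)
    coupling_strength: float = 0.9
    longrange_weight: float = 0.6
    hub_weight: float = 1.0
    hub_attach_range: tuple[float, float] = (0.0, 0.8)
    n_hub_nodes: int = 6
    score_intercept: float = 13.0
    score_slopes: tuple[float, float] = (13.5, 6.75)
    score_noise_sd: float = 1.0
    signal_regions: tuple[int, ...] = ()
    signal_strength: float = 0.0
    signal_score_slope: float = 0.0
    seed: int = 0
    null_cfg: NullModelConfig = field(
        default_factory=lambda: NullModelConfig(n_randomizations=8, swaps_per_edge=5)
    )

    def __post_init__(self) -> None:
        if min(self.n_patients, self.n_controls, self.n_regions, self.n_timepoints) < 1:
            raise ValueError("all cohort counts must be positive")
        for p in (self.rewire_prob_control, self.rewire_prob_patient):
            if not 0.0 <= p <= 1.0:
                raise ValueError("rewiring probabilities must lie in [0, 1]")
        if self.rewire_prob_patient <= self.rewire_prob_control:
            raise ValueError(
                "patients must rewire more than controls "
                "(this is what degrades their clustering and small-worldness)"
            )
        if self.base_topology not in ("caveman", "ring"):
            raise ValueError("base_topology must be 'caveman' or 'ring'")
        if self.ring_degree < 2 or self.ring_degree % 2:
            raise ValueError("ring_degree must be a positive even integer")
        if self.clique_size < 3:
            raise ValueError("clique_size must be >= 3")
        if any(i < 0 or i >= self.n_regions for i in self.signal_regions):
            raise ValueError("signal_regions must be valid 0-based region indices")


def ring_lattice(n: int, k: int) -> np.ndarray:
    """Ring lattice: each node linked to its k/2 nearest neighbours per side."""
    adj = np.zeros((n, n), dtype=np.uint8)
    for d in range(1, k // 2 + 1):
        idx = np.arange(n)
        adj[idx, (idx + d) % n] = 1
        adj[(idx + d) % n, idx] = 1
    return adj


def clique_ring(n: int, q: int) -> np.ndarray:
    """Connected-caveman graph: consecutive cliques of size ``q`` (the last
    clique absorbs any remainder) joined into a ring by single edges."""
    adj = np.zeros((n, n), dtype=np.uint8)
    starts = list(range(0, n, q))
    if len(starts) > 1 and n - starts[-1] < 3:
        starts.pop()  # merge a too-small tail into the previous clique
    for idx, s in enumerate(starts):
        e = starts[idx + 1] if idx + 1 < len(starts) else n
        members = np.arange(s, e)
        adj[np.ix_(members, members)] = 1
    np.fill_diagonal(adj, 0)
    if len(starts) > 1:
        for idx, s in enumerate(starts):
            e = starts[idx + 1] if idx + 1 < len(starts) else n
            nxt = starts[(idx + 1) % len(starts)]
            adj[e - 1, nxt] = adj[nxt, e - 1] = 1
    return adj


def degrade_cliques(adj: np.ndarray, frac: float, clique_id: np.ndarray,
                    rng: np.random.Generator) -> np.ndarray:
    """Delete a fraction of within-module edges (functional segregation loss).

    Only intra-clique edges are candidates, so the shortcut backbone — and
    with it the network's path-length structure — is untouched: severity
    expresses itself in clustering, not in distances.
    """
    adj = adj.copy()
    edges = np.argwhere(np.triu(adj, 1))
    for a, b in edges:
        if clique_id[a] != clique_id[b]:
            continue
        if rng.random() < frac:
            adj[a, b] = adj[b, a] = 0
    return adj


def rewire_edges(adj: np.ndarray, p: float, rng: np.random.Generator) -> np.ndarray:
    """Watts-Strogatz-style rewiring: each edge is redirected with
    probability ``p`` to a uniformly chosen non-neighbour."""
    adj = adj.copy()
    edges = np.argwhere(np.triu(adj, 1))
    for a, b in edges:
        if rng.random() >= p:
            continue
        candidates = np.nonzero(~adj[a].astype(bool))[0]
        candidates = candidates[candidates != a]
        if candidates.size == 0:
            continue
        c = int(rng.choice(candidates))
        adj[a, b] = adj[b, a] = 0
        adj[a, c] = adj[c, a] = 1
    return adj


def hub_attach(adj: np.ndarray, n_events: int, n_hubs: int,
               rng: np.random.Generator) -> np.ndarray:
    """Attach hub nodes to whole neighbourhoods ("rich-club" overlay).

    Each event links one of ``n_hubs`` designated hubs to a random node and
    all of its neighbours, creating triangle-rich hub modules. This models
    inter-subject variability in degree concentration: raw clustering-type
    metrics rise with it while the degree-preserving normalisation, which
    discounts clustering expected under a concentrated degree sequence,
    moves the other way. Its strength is drawn independently of the planted
    severity, so it acts as a nuisance dimension.
    """
    if n_events < 1 or n_hubs < 1:
        return adj
    adj = adj.copy()
    n = adj.shape[0]
    hubs = rng.choice(n, size=min(n_hubs, n), replace=False)
    for _ in range(n_events):
        h = int(hubs[rng.integers(hubs.size)])
        a = int(rng.integers(n))
        if a == h:
            continue
        grp = np.append(np.nonzero(adj[a])[0], a)
        grp = grp[grp != h]
        adj[h, grp] = 1
        adj[grp, h] = 1
    return adj


#: Eigenvalue floor used when repairing an indefinite raw covariance.
_EIG_FLOOR = 0.05


def _covariance(adj: np.ndarray, coupling: float, scale: float) -> np.ndarray:
    """Correlation-like covariance I + coupling * W / scale, made PD.

    ``scale`` is the spectral floor |lambda_min| of the core (pre-hub)
    graph, so clique and shortcut edges carry the same correlation strength
    in every subject. Hub-star components can push the raw matrix slightly
    indefinite; those eigenvalues are floored and the diagonal rescaled to
    one, which selectively attenuates the hub block while leaving the core
    structure intact.
    """
    if coupling >= 1.0 or coupling < 0.0:
        raise ValueError(
            f"coupling_strength must lie in [0, 1), got {coupling} "
            "(the adjacency is normalised by its spectral floor)"
        )
    if scale <= 0:
        raise ValueError("spectral scale must be positive")
    n = adj.shape[0]
    sigma = np.eye(n) + coupling * adj.astype(float) / scale
    eigvals, eigvecs = np.linalg.eigh(sigma)
    if eigvals[0] <= _EIG_FLOOR:
        sigma = (eigvecs * np.maximum(eigvals, _EIG_FLOOR)) @ eigvecs.T
        d = np.sqrt(np.diag(sigma))
        sigma = sigma / np.outer(d, d)
    return sigma


def _spectral_floor(adj: np.ndarray) -> float:
    eigs = np.linalg.eigvalsh(adj.astype(float))
    if eigs[-1] <= 0:
        raise ValueError("ground-truth graph has no edges")
    return float(abs(eigs[0]))


def _clique_labels(cfg: SimulationConfig) -> np.ndarray:
    """Base-module label per region (which clique a region started in)."""
    if cfg.base_topology != "caveman":
        return np.zeros(cfg.n_regions, dtype=int) - np.arange(cfg.n_regions)
    starts = list(range(0, cfg.n_regions, cfg.clique_size))
    if len(starts) > 1 and cfg.n_regions - starts[-1] < 3:
        starts.pop()
    labels = np.zeros(cfg.n_regions, dtype=int)
    for idx, s in enumerate(starts):
        e = starts[idx + 1] if idx + 1 < len(starts) else cfg.n_regions
        labels[s:e] = idx
    return labels


def _edge_weights(adj: np.ndarray, clique_id: np.ndarray, w_lr: float) -> np.ndarray:
    """Weighted adjacency: within-module edges at weight 1, all other edges
    (rewired, shortcut, hub) at ``w_lr`` — short-range within-module
    coupling is stronger than long-range coupling."""
    same = clique_id[:, None] == clique_id[None, :]
    return adj.astype(float) * np.where(same, 1.0, w_lr)


def _population_auc(sigma_cov: np.ndarray, cfg: SimulationConfig,
                    rng: np.random.Generator) -> tuple[float, float, float]:
    """Noise-free (population) gamma/lambda/sigma AUC of a subject.

    Runs the measurement pipeline on the exact correlation matrix implied by
    the subject's covariance — the infinite-scan-length limit of the
    observable features, which is what the cognitive score is tied to. A
    vanishing symmetric jitter breaks the ties among exactly-zero population
    correlations so proportional thresholding is defined above the true
    density. Computed on a coarse subgrid with a small null ensemble; the
    AUC averages the null noise down.
    """
    d = np.sqrt(np.diag(sigma_cov))
    corr = sigma_cov / np.outer(d, d)
    jitter = rng.uniform(0.0, 1e-8, size=corr.shape)
    z = fisher_z(corr).z + (jitter + jitter.T)
    np.fill_diagonal(z, 0.0)
    grid = SparsityGrid(*TRUTH_GRID)
    null = NullModelConfig(n_randomizations=3, swaps_per_edge=5)
    gammas, lambdas = [], []
    for s_level in grid:
        net = proportional_threshold(ConnectivityMatrix(z), s_level)
        g, l, _ = normalized_smallworld(net, null, rng=rng)
        gammas.append(g)
        lambdas.append(l)
    g_auc = auc_over_grid(np.array(gammas), grid)
    l_auc = auc_over_grid(np.array(lambdas), grid)
    s_auc = auc_over_grid(np.array(gammas) / np.array(lambdas), grid)
    return g_auc, l_auc, s_auc


def generate_subject(
    group: Group | str,
    cfg: SimulationConfig,
    subject_seed: int,
    subject_id: str | None = None,
    cohort_position: float = 0.5,
) -> SubjectRecord:
    """One subject: ground-truth graph, time series, score, and truth record."""
    group = Group(group)
    rng = np.random.default_rng(subject_seed)
    if group is Group.PATIENT:
        centre, half = cfg.rewire_prob_patient, cfg.rewire_halfwidth_patient
        # a fraction of patients are early-stage, with control-like topology:
        # the cohort spans a disease-stage spectrum rather than one stratum
        if rng.random() < cfg.early_stage_frac:
            centre, half = cfg.rewire_prob_control, cfg.rewire_halfwidth_control
    else:
        centre, half = cfg.rewire_prob_control, cfg.rewire_halfwidth_control
    # severity is a jittered stratified ramp over admission order: the
    # cohort spans its severity range evenly, and later-admitted patients
    # are somewhat sicker, so the chronological hold-out split is a mild
    # extrapolation task, as it can be for a real consecutively admitted
    # cohort. Stratification keeps the realized severity spread — and with
    # it the cohort-level power of the screen — stable across replicates.
    if group is Group.PATIENT:
        jitter = 0.06 * (rng.random() - 0.5)
        frac = float(np.clip(cohort_position + jitter, 0.0, 1.0))
        p_rewire = float(np.clip(centre - half + 2 * half * frac, 0.0, 0.95))
    else:
        p_rewire = float(np.clip(rng.uniform(centre - half, centre + half), 0.0, 0.95))
    clique_id = _clique_labels(cfg)
    if cfg.base_topology == "caveman":
        base = clique_ring(cfg.n_regions, cfg.clique_size)
        adj = degrade_cliques(base, p_rewire, clique_id, rng)
    else:
        base = ring_lattice(cfg.n_regions, cfg.ring_degree)
        adj = rewire_edges(base, p_rewire, rng)
    # long-range shortcuts: a per-subject random budget, independent of the
    # planted severity, so path-length-type metrics vary for reasons of
    # their own rather than tracking the clustering damage
    n_shortcuts = int(rng.integers(cfg.shortcut_range[0], cfg.shortcut_range[1] + 1))
    added = 0
    while added < n_shortcuts:
        i, j = rng.integers(cfg.n_regions, size=2)
        if i != j and not adj[i, j]:
            adj[i, j] = adj[j, i] = 1
            added += 1

    severity = 0.0
    if cfg.signal_regions and group is Group.PATIENT and cfg.signal_strength > 0:
        severity = float(rng.random())
        drop_p = cfg.signal_strength * severity
        for r in cfg.signal_regions:
            nb = np.nonzero(adj[r])[0]
            drop = nb[rng.random(nb.size) < drop_p]
            adj[r, drop] = adj[drop, r] = 0

    weights = _edge_weights(adj, clique_id, cfg.longrange_weight)
    core_scale = _spectral_floor(weights)
    hub_frac = float(rng.uniform(*cfg.hub_attach_range))
    pre_attach = adj
    adj = hub_attach(adj, round(hub_frac * cfg.n_regions), cfg.n_hub_nodes, rng)
    hub_mask = (adj == 1) & (pre_attach == 0)
    weights = _edge_weights(adj, clique_id, cfg.longrange_weight)
    weights[hub_mask] = cfg.hub_weight
    sigma_cov = _covariance(weights, cfg.coupling_strength, core_scale)
    chol = np.linalg.cholesky(sigma_cov)
    ts = chol @ rng.standard_normal((cfg.n_regions, cfg.n_timepoints))

    g_true, l_true, s_true = _population_auc(sigma_cov, cfg, rng)
    noiseless = (
        cfg.score_intercept
        + cfg.score_slopes[0] * g_true
        + cfg.score_slopes[1] * s_true
        - cfg.signal_score_slope * severity
    )
    score = float(np.clip(noiseless + rng.normal(0.0, cfg.score_noise_sd), 0.0, 30.0))

    sid = subject_id or f"{group.value}-{subject_seed}"
    truth = {
        "graph_edges": np.argwhere(np.triu(adj, 1)).tolist(),
        "rewire_prob": p_rewire,
        "n_shortcuts": n_shortcuts,
        "hub_attach_frac": hub_frac,
        "severity": severity,
        "gamma_true": g_true,
        "lambda_true": l_true,
        "sigma_true": s_true,
        "noiseless_score": float(noiseless),
    }
    return SubjectRecord(
        subject_id=sid, group=group, score=score, timeseries=ts, truth=truth
    )


def generate_scores(
    true_features: np.ndarray, cfg: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    """Scores from an (n, 2) array of true (gamma, sigma) features:
    intercept + slopes . features + Gaussian noise, clipped to [0, 30]."""
    f = np.atleast_2d(np.asarray(true_features, dtype=float))
    if not np.all(np.isfinite(f)):
        raise ValueError("true features must be finite")
    raw = (
        cfg.score_intercept
        + cfg.score_slopes[0] * f[:, 0]
        + cfg.score_slopes[1] * f[:, 1]
        + rng.normal(0.0, cfg.score_noise_sd, size=f.shape[0])
    )
    return np.clip(raw, 0.0, 30.0)


@dataclass
class CohortTruth:
    """Ground-truth ledger for every generated subject."""

    config: dict
    subjects: list[dict]

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps({"config": self.config, "subjects": self.subjects}, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "CohortTruth":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        d = json.loads(text)
        return cls(config=d["config"], subjects=d["subjects"])


def generate_cohort(cfg: SimulationConfig) -> tuple[list[SubjectRecord], CohortTruth]:
    """Reproducible cohort of patients and controls plus the truth ledger."""
    ss = np.random.SeedSequence(cfg.seed)
    subjects: list[SubjectRecord] = []
    ledger: list[dict] = []
    specs = [(Group.PATIENT, i) for i in range(cfg.n_patients)] + [
        (Group.CONTROL, i) for i in range(cfg.n_controls)
    ]
    for idx, (group, i) in enumerate(specs):
        child = np.random.SeedSequence(entropy=ss.entropy, spawn_key=(idx,))
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        sid = f"{'pat' if group is Group.PATIENT else 'ctl'}{i + 1:03d}"
        pos = i / max(cfg.n_patients - 1, 1) if group is Group.PATIENT else 0.5
        rec = generate_subject(group, cfg, sub_seed, subject_id=sid, cohort_position=pos)
        subjects.append(rec)
        entry = {"subject_id": sid, "group": group.value, "score": rec.score}
        entry.update(rec.truth)
        ledger.append(entry)
    cfg_dict = asdict(cfg)
    cfg_dict["null_cfg"] = asdict(cfg.null_cfg)
    truth = CohortTruth(config=cfg_dict, subjects=ledger)
    return subjects, truth
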