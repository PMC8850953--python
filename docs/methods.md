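# Methods

## Pipeline

Per subject, the region × time matrix (90 regions in the default atlas
layout, 130 retained timepoints) is reduced to a Pearson correlation
matrix; the Fisher Z transform (atanh, |r| clipped at 0.999999) stabilises
its variance; proportional thresholding keeps exactly
round(S·n(n−1)/2) of the strongest positive Z edges at each sparsity S of
the grid 0.10–0.40 in steps of 0.01 (31 binary, undirected networks per
subject). Negative edges are never kept under the default ranking; an
`edge_ranking="absolute"` option ranks by |Z| instead. Ties are broken by
ascending (row, column) index, so thresholding is deterministic and the 31
edge sets are nested.

Seven metrics are computed per network: clustering coefficient C_p (mean of
2·triangles/k(k−1), zero for degree < 2), characteristic path length L_p
(mean finite shortest-path length; an error if no pair is reachable),
global efficiency (mean 1/d, zero for unreachable pairs), local efficiency
(mean over nodes of the efficiency of the neighbour-induced subgraph), and
the small-world indices γ, λ, σ. The random reference for γ and λ is the
Maslov–Sneppen ensemble: degree-preserving double-edge swaps
(swaps_per_edge·|E| attempts per randomization), means taken over the
ensemble; σ ≡ γ/λ by construction. Nodal efficiency (mean inverse distance
from one node to the rest) feeds the discriminative-region ranking. Metric
curves are summarised by the trapezoidal AUC over the grid.

Disconnected networks use the conventions: L_p averages finite distances
only; efficiencies treat unreachable pairs as 1/d = 0; degree-< 2 nodes
contribute zero clustering and local efficiency. The standalone null-model
default is 100 randomizations with 10 swaps per edge; the pipeline run
configuration defaults to 5 and 5, because the AUC already averages the
null means over 31 thresholds with independent draws, which empirically
leaves the null-noise contribution to the AUC features at the percent
level while keeping a 75-subject cohort run around half a minute per
subject-equivalent of work.

The BFS, edge-swap and local-efficiency inner loops are JIT-compiled
(numba, `netcog._fast`); the test suite checks every metric against
brute-force Python oracles on random graphs.

## Feature screen and fusion

Stage 1: per-feature two-sample t test, patients versus controls; Welch by
default (it reproduces the published worked example, a pooled variant is
available). Stage 2: Pearson correlation between the feature and the score
within patients, two-sided p from the t transform. A feature is selected
iff group p < 0.05, correlation p < 0.05/15 (the Bonferroni-corrected
threshold printed in the source study; both alphas are parameters), and
r > 0. Selected features are linearly fused: z-scored with training-set
means and SDs (never test statistics) and concatenated.

The screen deliberately uses all patients (the source analysis computed
its group and correlation tables on the full patient set before
splitting); fusion statistics and hyperparameter tuning use training
patients only.

## LS-SVR

The least-squares SVM dual: with RBF kernel
K(u,v) = exp(−‖u−v‖²/2σ²), solve

    [[0, 1ᵀ], [1, K + I/γ]] · [b; λ] = [0; y]

by a dense symmetric solve; the first block row enforces Σλᵢ = 0. A
condition-number guard (10¹²) refuses ill-posed systems, and the solution's
relative residual must be ≤ 1e−8. Predictions are the kernel expansion
Σλᵢ K(x, xᵢ) + b. Models serialise to JSON.

## Whale optimization

Canonical WOA: control scalar a decays linearly 2 → 0 over iterations
(a(t) = 2(1 − t/(T−1))); per whale and iteration, A = 2aq − a and C = 2q′
with q, q′ ~ U(0,1) drawn once per whale (scalars shared across the two
search dimensions); a coin flip (switch_prob = 0.5) chooses the spiral move
(|x−x*|·e^{bl}·cos 2πl + x*, l ~ U(−1,1), b = 1), otherwise |A| < 1 selects
the shrinking-encircling move toward the incumbent best and |A| ≥ 1 the
exploration move toward a random whale. Positions are clipped to bounds;
non-finite objective values count as +∞; the incumbent best is elitist.
Defaults: 30 whales, 100 iterations.

The tuning objective is cross-validated RMSE of the LS-SVR on the fused
training features, searched in log10 space (penalty ∈ [1e−2, 1e5], width ∈
[1e−2, 1e3]); one whale is warm-started at the scale-neutral point
(penalty 1, width 1), and the objective averages two blocked partitions
(five and seven contiguous folds) to reduce selection noise. The folds
are contiguous cohort-order blocks rather than shuffled subsets: the outer evaluation is a chronological hold-out (first
35 patients train, last 10 test, mirroring an admission-date split), and a
cohort admitted over months need not be exchangeable, so blocked folds
score candidate hyperparameters on the same kind of mild extrapolation the
test set poses. With shuffled folds the tuner can favour narrow kernels
that interpolate the interior and fail at the cohort's temporal edge.

## Synthetic cohorts (what the generator emulates, and what it does not)

The generator's job is to produce cohorts with the statistical structure
the analysis assumes: small-world degradation in patients expressed in
γ/σ, scores positively tied to that degradation, and *no* usable signal in
the remaining five metrics — so that the two-stage screen, the tuned
regressor, and the region ranking can each be validated against known
ground truth.

Ground-truth networks. Each subject starts from a connected-caveman graph
(nine 10-cliques joined in a ring): a clique substrate is used instead of a
plain ring lattice because its adjacency spectrum (least eigenvalue near
−1 for complete blocks) admits far stronger positive couplings before the
covariance loses positive-definiteness — with a lattice the recoverable
edge correlation at 130 timepoints is so weak that no measured feature
tracks the planted truth. Disease severity is the deletion probability of
within-clique edges: functional segregation is damaged while the
long-range backbone is untouched. Patient severities follow a jittered
stratified ramp over admission order spanning 0.22–0.48, so every cohort
covers the severity spectrum evenly (stabilising the power of the screen
across replicates) and later-admitted patients are somewhat sicker, making
the chronological hold-out a mild extrapolation task, as it can be for a
real consecutively admitted cohort. Controls draw severity iid from
U(0.12, 0.22). The range tops out at 0.48 because the normalised
clustering of the thresholded networks flattens for heavier damage — the
plateau would contribute compression noise rather than signal.

Nuisance dimensions. Two per-subject dimensions, independent of severity
and of each other, give the non-selected metrics variance of their own:
(i) a random long-range shortcut budget (100–400 extra edges), which moves
path-length-type metrics; (ii) triangle-rich hub attachment — up to
0.8·n_regions events, each connecting one of six hub nodes to a random
node and its whole neighbourhood — which concentrates degree. Raw clustering-type
metrics respond to hub concentration one way while the degree-preserving
normalisation discounts exactly the clustering expected under a
concentrated degree sequence, so γ and σ are the only metrics in which the
planted severity stands out. This mirrors the empirical pattern the method
relies on: significant, score-correlated γ/σ; flat C_p, L_p, E_global,
E_local, λ.

Time series. Stationary correlated Gaussian noise with covariance
Σ = I + c·W/|λ_min(W_core)|, c = 0.9, where W weights within-clique edges
1.0, hub edges 1.0, and other long-range edges 0.6 (short-range
within-module coupling is stronger than long-range coupling). W_core is
the pre-hub graph, so clique edges carry the same correlation in every
subject; if the hub overlay pushes the raw matrix indefinite, its
eigenvalues are floored at 0.05 and the diagonal rescaled to one, which
selectively attenuates the hub block. No hemodynamics, drift, motion, or
non-Gaussianity: the pipeline consumes only correlation structure, so
passing tests validate the statistics of the method, not its robustness to
fMRI artefacts.

Scores. The planted truth for each subject is the population AUC of γ and
σ: the pipeline evaluated on the exact correlation matrix implied by the
subject's covariance (coarse subgrid, small null ensemble, vanishing
jitter to define thresholding above the true density). This is the
noise-free limit of the measured features — the estimand the measurement
estimates — and was chosen over graph-level γ after finding that most of
the 0.10–0.40 grid lies above a sparse graph's true density, making
graph-level truth partly unobservable in principle. The score is
13.0 + 13.5·γAUC + 6.75·σAUC + N(0, 1), clipped to [0, 30]; the defaults
put patients near 21 ± 1.7 points and controls near 24, matching the
magnitude and direction of the published group summaries. With slopes
zeroed the scores are pure noise (a negative control the tests use).

Regional signal. Optionally, a set of signal regions is degraded per
patient in proportion to a latent severity that also subtracts from the
score, planting a nodal-efficiency signal for recovery tests of the
discriminative-region ranking.

Known limitations: the generator's nuisance dimensions are stylised (real
inter-subject topology variation is not two-dimensional); the covariance
repair slightly distorts hub-edge strengths; scores are linear in the
truth by construction, so the tests cannot reward or penalise nonlinear
score models; and time series are white in time, so any method exploiting
autocorrelation would see unrealistically favourable conditions.

## Evaluation

Chronological hold-out (n_train = 35 of 45 patients), RMSE/MAE/MAPE on the
test patients (MAPE in percent, requiring nonzero actual scores — MoCA
scores of interest are positive). Determinism: every stage draws from
seeds derived from one master seed (numpy SeedSequence spawning; subject
streams keyed by a CRC of the subject id, so feature tables do not depend
on cohort order). Problem sizes used by the acceptance suite: 20 replicate
cohorts of 45 + 30 subjects, 90 regions, 130 timepoints, 31 thresholds,
5-null ensembles — the full default conditions.

## Numerical choices

- Fisher-Z clip 0.999999; round-half-up edge counts; index-ordered tie
  breaks.
- Null means of zero (triangle-free nulls) raise an error rather than
  returning infinite γ.
- LS-SVR condition guard 1e12; dual residual tolerance 1e−8.
- WOA bound handling by clipping; fitness non-finite → +∞.
- Eigenvalue floor 0.05 in the covariance repair; PD enforced by
  construction (coupling < 1 of the spectral floor of the core graph).
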