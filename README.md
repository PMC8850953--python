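# netcog

Predicting cognitive-function scores from the topology of functional brain
networks.

In end-stage renal disease and other conditions with diffuse brain
involvement, cognitive screening scores (MoCA, 0–30 points) are noisy and
examiner-dependent. An objective alternative is to predict the score from
resting-state functional connectivity: regional time series are correlated
(Pearson → Fisher Z), the connectivity matrix is binarised over a grid of
proportional thresholds (sparsity S = 0.10…0.40, step 0.01), and each
network is summarised by seven graph-theoretic metrics — clustering
coefficient C_p, characteristic path length L_p, global and local efficiency
E_global/E_local, and the small-world indices γ = C_p/⟨C_p^rand⟩,
λ = L_p/⟨L_p^rand⟩, σ = γ/λ (random reference: degree-preserving edge
swaps). The area under each metric's curve across the sparsity grid (AUC)
gives threshold-free features.

Features are screened in two stages — a two-sample Welch t test against
healthy controls, then Pearson correlation with the score under a
Bonferroni-corrected threshold (p < 0.05/15 ≈ 0.0033), keeping features with
a positive correlation — then linearly fused (z-scored with training-set
statistics). A least-squares support-vector regressor (LS-SVR, RBF kernel)
maps fused features to scores; its dual problem is a single linear system

    [ 0   1ᵀ         ] [ b ]   [ 0 ]
    [ 1   K + I/γ    ] [ λ ] = [ y ],       f(x) = Σᵢ λᵢ K(x, xᵢ) + b

whose hyperparameters (error penalty γ, kernel width σ) are tuned by the
whale optimization algorithm (WOA) against blocked cross-validated RMSE on
the training patients. Evaluation uses a chronological hold-out split
(first 35 patients train, last 10 test) and reports RMSE, MAE and MAPE.
Finally, regions are ranked by the correlation between their nodal-efficiency
AUC and the score, yielding the discriminative-region table.

Because clinical cohorts of this kind are not public, the package ships a
first-class synthetic-cohort generator (`netcog.simulate`) that reproduces
the statistical structure this analysis assumes: patients with degraded
within-module connectivity (lower γ, σ), scores tied to the planted
small-world truth, and nuisance dimensions (hub concentration, long-range
connectivity) that leave the raw metrics uninformative — so every stage of
the pipeline is testable end to end.

## Worked example

```python
from netcog import (CognitiveScoreModel, RunConfig, SimulationConfig,
                    generate_cohort)

subjects, truth = generate_cohort(SimulationConfig(seed=1))   # 45 + 30
results = CognitiveScoreModel.from_cohort(subjects, RunConfig(seed=1)).fit()
print(results.summary())
```

```
Cognitive score prediction (graph-feature LS-SVR, WOA-tuned)
==============================================================
Selected features : gamma_auc, sigma_auc
Train/test split  : 35/10 patients
Penalty (gamma)   : 3157.49
Kernel width      : 5.82818
CV RMSE (train)   : 1.0385
Test RMSE         : 1.3294
Test MAE          : 1.1988
Test MAPE         : 5.95%
--------------------------------------------------------------
subject         actual   predicted
pat036           19.97       21.21
pat037           21.19       20.21
pat038           20.94       19.51
...
pat045           20.78       19.83
```

The screen keeps exactly the two planted features (γ and σ AUC); the tuned
regressor predicts the held-out scores to about 1.3 MoCA points — close to
the generator's score-noise floor of 1.0 point, meaning the model has
recovered most of the planted structure — and MAPE lands in the
few-percent range. `results.plot_predictions()` and
`results.plot_convergence()` draw the test-set fit and the WOA search
trace; `netcog.discriminative_regions(patients)` returns the top-10 region
ranking with atlas labels.

The same pipeline runs from the shell:

```bash
netcog simulate --out cohort/ --seed 1
netcog run-all cohort/manifest.csv --out results/
```

with per-stage subcommands (`features`, `select`, `train`, `predict`,
`evaluate`, `regions`) and a YAML run configuration.

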