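# dyadsync

Analysis pipeline for **dyadic shared-experience studies**: when two people
watch the same video — side by side or alone — how strongly do their
facial expressions, skin conductance, and impressions align, and does that
alignment predict how connected they feel to each other?

The package is aimed at researchers running naturalistic co-viewing
experiments with continuous facial-expression evidence (action units and
emotion predictions at 1 Hz), electrodermal activity, and post-episode
rating questionnaires. It provides, end to end:

* **Synchrony.** Intersubject synchrony of a channel is the Pearson
  correlation of two viewers' time series over an episode, computed under
  three pairing schemes — true dyads (n/2 pairs), pseudo dyads
  (n(n−1)/2 − n/2 pairs of co-viewing-group members who did not sit
  together), and all pairs of solo viewers (n(n−1)/2). Time-resolved
  synchrony uses a centered 30 s moving-window correlation; lagged
  coupling is profiled over ±3 s at 100 ms steps.
* **Nonparametric inference.** Pairwise correlations sharing a subject are
  dependent, so inference resamples subjects: subject-wise bootstrap CIs,
  subject-wise group permutation tests, circular-shift surrogate nulls
  (which preserve each series' autocorrelation exactly), and a
  cluster-based permutation test that locates the moments when two groups'
  windowed synchrony differs, controlling family-wise error with a
  max-cluster null. Correlations are averaged on the Fisher-z scale;
  p-values use the add-one rule.
* **Shared response model.** A deterministic reduced-rank factorization
  X_i ≈ W_i S with per-subject orthonormal spatial maps W_i and common
  latent trajectories S, fit by alternating least squares (Procrustes
  updates), with held-out selection of the latent dimensionality and
  spatial-similarity analysis of how differently two people express the
  same shared trajectory.
* **Impression similarity.** Within-subject demeaned character ratings,
  PCA to ~90% explained variance, per-character intersubject correlation
  of component scores averaged into one similarity per dyad.
* **Connection prediction.** Spearman association of synchrony with
  self-reported connection, and leave-one-dyad-out ridge regression
  (nested 5-fold penalty search over {0.1, 1, 10}) predicting a dyad's
  mean connection rating from its synchrony profile.
* **Synthetic cohorts with ground truth.** A generator that plants a
  stimulus-locked affective drive, dyad-specific shared components,
  orthonormal mixing maps, SCR-like EDA, correlated impressions, and
  connection ratings driven by the planted coupling — so every estimator
  can be tested for recovery of known truth.

See `docs/methods.md` for the models, defaults, and design decisions.

## Worked example

Simulate a cohort of 12 dyads and 10 solo viewers watching a 10-minute
episode, with per-dyad coupling strengths drawn from [0, 0.9]:

```bash
$ cat cfg.yaml
n_dyads: 12
n_alone: 10
duration_s: 600
dyad_coupling_range: [0.0, 0.9]

$ dyadsync simulate --config cfg.yaml --out cohort/ --seed 7
wrote cohort of 34 subjects to cohort/

$ dyadsync sync --in cohort/ --out sync_true.csv --scheme true_dyads --channel joy
12 pairs; mean r = 0.395

$ dyadsync sync --in cohort/ --out sync_alone.csv --scheme alone_all_pairs --channel joy
45 pairs; mean r = 0.221

$ dyadsync predict --in cohort/ --out predictions.csv --seed 3
accuracy r = 0.772 over 12 dyads
```

True dyads synchronize their joy evidence well above the purely
stimulus-driven level of solo pairs (mean r 0.395 vs 0.221), because the
generator planted a dyad-specific shared component on top of the common
stimulus drive. The leave-one-dyad-out model predicts a held-out dyad's
mean connection rating from its synchrony features with r = 0.77 — the
connection ratings were generated from the same planted coupling the
synchrony features recover.

The same steps are available as library calls (`simulate_cohort`,
`group_synchrony`, `subject_bootstrap`, `fit_srm`, `loo_dyad_ridge`, …);
the CLI is a thin wrapper. Analysis outputs are plain delimited tables
shaped for downstream mixed-effects or structural-equation modelling in
external tools.

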