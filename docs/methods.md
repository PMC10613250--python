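# Methods

This note documents the models, algorithms, and design choices behind
`dyadsync`, and what the synthetic-data experiments do and do not
demonstrate about real co-viewing data.

## The setting

Two groups of participants watch the same long video stimulus: solo viewers
("alone" group) and pairs seated together ("dyad" group). Per subject the
pipeline receives 1 Hz facial evidence series (20 action units, seven
emotion-evidence channels), raw electrodermal activity (EDA), post-episode
character-impression ratings (0–100, several questions × characters), and —
for dyads — partner-connection ratings (1–9). The scientific questions:
how strongly do viewers' affective signals synchronize, is synchrony higher
for true co-viewing pairs than for pseudo pairs or solo pairs, and does a
dyad's synchrony predict its self-reported connection?

## Synthetic cohorts

`synthetic.simulate_cohort` plants known structure:

* **Stimulus drive.** Two nonnegative smooth latent trajectories
  (joy-like, fear-like) built from boxcar events convolved with a Hann
  kernel, scaled to unit variance. Every viewer receives them with gain
  `stimulus_coupling` (default 0.5).
* **Dyadic coupling.** Each true dyad shares an additional smooth latent
  pair with gain `dyad_coupling` (default 0.3), or a per-dyad gain drawn
  from `dyad_coupling_range` when between-dyad variation is wanted.
* **Channels.** Action units mix the two latents through per-subject
  random orthonormal maps (QR of Gaussian draws) — the exact generative
  assumption of the shared response model. Joy evidence follows the
  joy-like latent, the five negative emotions follow the fear-like latent
  with decaying gains, surprise an even mixture.
* **Residual noise** is temporally autocorrelated (Hann-smoothed white
  noise, per-subject kernel width drawn from 2–12 s, unit variance).
  Facial-evidence residuals are smooth in reality, and this autocorrelation
  is precisely why the inference layer uses subject-level resampling and
  circular-shift surrogates; white residuals would make those safeguards
  pointless.
* **Social facilitation.** Dyad-group subjects get their stimulus gain
  multiplied by `social_gain` (default 1.3). This reproduces the
  qualitative ordering observed in co-viewing experiments — pseudo pairs
  (dyad-group members who did not sit together) synchronize more than solo
  pairs — which pure stimulus coupling cannot produce (pseudo and alone
  pairs would be exchangeable). Set `social_gain=1` for a generator in
  which the alone group differs from the dyad group only by the absence of
  dyadic coupling.
* **EDA** is a strictly positive tonic level (2.0 ± slow sine) plus
  skin-conductance responses: Poisson event trains (stimulus-common,
  dyad-shared, private; `eda_event_rate` split evenly, default 3/min
  total) convolved with a difference-of-exponentials kernel (1 s rise,
  4 s decay, peak 1), generated at 4 Hz so the downsampler is exercised.
* **Impressions** are a common character × question profile (N(50, 15))
  plus per-subject deviations (sd 10); dyad members' deviations share a
  component so their correlation is `impression_dyad_corr`.
* **Connection ratings** are `3 + connection_slope × coupling_d` plus
  N(0, 0.7) noise per member, rounded and clipped to 1–9.

Default cohort size (28 dyads, 21 solo viewers, 45-min episode) mirrors a
typical analyzed co-viewing sample. A single integer seed drives one
`numpy` Generator; identical configurations give byte-identical cohorts.

What the generator does *not* emulate: head-motion and face-detection
artifact structure (missing masks are available but not planted by
default), nonstationarity across a 4-h session, discrete/ordinal evidence
scales, talking-induced facial motion, or EDA non-responders. Passing
recovery tests therefore show that the estimators do what they claim under
the assumed structure, not that the assumptions hold for any given real
dataset.

## Preprocessing

* **Valence channels**: positive = joy evidence unchanged; negative =
  elementwise max over anger, fear, disgust, sadness, contempt. The max is
  not linear, so valence is always computed at the native rate *before*
  downsampling; the two orders genuinely differ and the tests pin the
  order.
* **Downsampling** is block averaging over non-missing samples; a fully
  missing output bin stays masked. Missing samples are excluded, not
  interpolated.
* **Quality control** excludes a subject iff the missing fraction strictly
  exceeds 10% (exactly 10% is kept).
* **EDA conditioning**: log-transform of the raw (strictly positive)
  conductance, then a zero-phase 4th-order Butterworth bandpass
  (0.005–5 Hz; the upper edge is clipped just below Nyquist with a warning
  when the input rate is too low), then block-mean downsampling to 1 Hz.
  Filtering first and logging second is ill-defined (the bandpass output
  crosses zero), so log-first is the default; the alternative order is
  available via `log_before_filter=False`, which applies a signed
  `log1p` after filtering. The bandpass has zero DC gain; the residual
  mean left by edge transients is removed explicitly, so outputs are
  exactly zero-mean.
* **Crowd-rating densification**: per-timepoint subject means, linear
  interpolation to 1 Hz, centered 30 s moving average truncated at the
  edges.

## Synchrony

Synchrony of a channel for a pair of subjects is the Pearson correlation
over the jointly observed samples (pairwise deletion over the union of
missing masks; at least 30 joint samples required). Zero-variance inputs
raise an error — undefined correlations are never silently coerced to 0 or
NaN into a mean. Pairing schemes: `true_dyads` (n/2 pairs),
`pseudo_dyads` (n(n−1)/2 − n/2), `alone_all_pairs` (n(n−1)/2); the first
two partition all within-dyad-group pairs.

Dynamic synchrony uses a centered 30 s moving window, stepped every 1 s,
truncated at the series edges; constant windows are masked (NaN). The
lagged profile (`crosscorr_offset`) scans ±3 s in 100 ms steps at the
native rate and reports the peak lag, ties broken toward zero lag.

## Nonparametric inference

Correlations are averaged on the Fisher-z scale (`atanh`) and
back-transformed; all p-values use the add-one rule (b+1)/(B+1), so they
are never exactly 0. Pairwise correlations sharing a subject are
dependent, so subjects — not pairs — are the resampling unit:

* **Subject-wise bootstrap**: resample subjects with replacement, rebuild
  the implied pair set (self-pairs from duplicates dropped), average z,
  back-transform; percentile 95% CI and two-sided p versus zero.
  *Known property*: under an exchangeable null the pair correlations have
  no subject-level mean structure, so the bootstrap spread (which budgets
  for subject-level dependence and pair multiplicity) exceeds the true
  sampling spread of the mean — measured inflation ≈1.8× — and the test is
  conservative (empirical type-I ≈ 0.005 at nominal 0.05). This matches
  the reported behaviour of subject-wise bootstrapping for intersubject
  correlation in the methodological literature. Its CI coverage of the
  true mean synchrony is correspondingly ≥ nominal (measured ≈0.96).
* **Group permutation**: the statistic is the difference in mean z
  between the groups, each over its own pair structure (e.g. true-dyad
  pairs vs all alone pairs). Permutations shuffle subjects across the
  fixed design and re-derive both pair sets from the permuted assignment,
  which requires the full all-pairs synchrony table. Exact under subject
  exchangeability; measured type-I 0.04 at nominal 0.05, null p-values
  uniform.
* **Circular-shift surrogates**: every subject's series is rotated by an
  independent uniform offset in [1, T−1]. Rotation preserves each series'
  circular autocorrelation exactly while destroying cross-subject
  alignment; the one-sided p is the exceedance of the observed mean
  pairwise synchrony.
* **Cluster-based permutation test**: windowed correlations are
  z-transformed; a Welch t-statistic is computed per second; samples with
  |t| above the two-sided Welch critical value at α=0.05 form maximal
  consecutive same-sign runs; cluster mass is the summed t; the null is
  the maximum |mass| over permutations. Two permutation units are
  offered: pair rows (the generic two-sample form) and subjects
  (`cluster_permutation_subjectwise`, which re-derives each group's pair
  rows from a permuted subject assignment and matches the design's
  exchangeability; used by the pipeline). Measured family-wise type-I
  0.058 at nominal 0.05; planted 60 s epochs are localized in 100% of
  evaluation runs.

## Shared response model

Deterministic alternating least squares for
`min Σ_i ‖X_i − W_i S‖²` with orthonormal-column `W_i` (channels × k) and
shared `S` (k × time): `S ← (1/N) Σ W_iᵀX_i`, then each `W_i ← UVᵀ` from
the SVD of `X_i Sᵀ` (orthogonal Procrustes). Both half-steps are exact
minimizers, so the recorded objective trace is non-increasing; with one
subject the converged objective equals the truncated-SVD residual.
Channels are z-scored per subject by default (`standardize="zscore"`);
`"center"` preserves exact low-rank structure and is used in the
noiseless recovery checks, because row rescaling destroys an exact shared
factorization. Maps are initialized from QR of seeded Gaussian draws;
n_iter=50 and tol=1e−6 by default.

The factorization is only determined up to a joint rotation of the latent
space. The fit ends with a canonical orientation — rotate `S` to its
principal axes (variance-ordered, uncorrelated trajectories) and fix each
trajectory's sign by its largest-magnitude sample — which identifies the
components whenever the latent variances are distinct. Evaluation against
planted truth additionally matches components greedily by absolute
correlation.

**Choosing k.** The latent dimensionality is selected by split-half,
leave-one-subject-out reconstruction: fit on the first half of the
episode, estimate the shared trajectories on the second half from all
*other* subjects' projections, map them through the held-out subject's
fitted `W_i`, and correlate with that subject's held-out data. A genuine
shared component raises this score; a noise component injects other
subjects' noise and lowers it, so the score peaks at the planted k. The
smallest k within `score_tol=0.02` of the maximum is returned, which also
sends pure-noise data to `k_min`. The in-sample alternative — the mean
pairwise correlation of projected component timecourses, maximized over
k — is *not* used: averaging per-component similarities always favours
keeping only the strongest component (it is monotonically non-increasing
in k on nested structure), and rotation spread makes in-sample
per-component scores uninterpretable; the held-out reconstruction
criterion recovers planted k ∈ {1, 2, 3} reliably where the in-sample
average selects k=1 almost always. Components weaker than `score_tol` in
held-out reconstruction gain are, by construction, not detected.

Spatial similarity of expression configurations is the Pearson
correlation of two subjects' `W_i` columns for a component; shared
trajectories are correlated with dense crowd emotion ratings raw and
linearly detrended.

## Impressions

Ratings are demeaned within subject (per question, across characters),
embedded by PCA treating each subject × character rating vector as a
sample, retaining the smallest number of components whose cumulative
explained variance reaches 90%. Dyad similarity is the per-character
Pearson correlation of the two members' retained score vectors, averaged
over characters (cosine available; components are not variance-weighted —
the simplest reading, with weighting left to the caller). Characters with
zero-variance scores are dropped with a logged warning.

## Connection prediction

Association uses a Spearman rank correlation with a dyad-level bootstrap
CI. Prediction uses ridge regression under leave-one-dyad-out
cross-validation: all of a dyad's rows leave together; a nested 5-fold
grouped CV over the training dyads picks the penalty from {0.1, 1, 10} by
mean squared error; features are z-scored with training-fold statistics
only and the intercept is unpenalized. Accuracy is the Pearson
correlation between actual and predicted mean connection, pooled over
folds. Pooled CV correlation is negatively biased under the null (no
spurious positive skill; measured ≈ −0.29 at 12 dyads), so null checks on
it are one-sided. Episodes enter only through the synchrony features;
mixed-effects and structural-equation modelling of the exported per-dyad
tables are out of scope and left to external tools.

## Evaluation problem sizes

The Monte-Carlo runners in `dyadsync.evaluation` use cohorts of 12–20
subjects viewing 240–400 s for null calibration (500 replicates; binomial
standard error ≈0.01 on a 0.05 rate), 28 dyads at 300 s for the
association power experiment (the default study size), 30 dyads for the
prediction experiment, and 8 subjects × 600 samples × 20 channels for the
shared-response recovery experiments. Planted latents in the
shared-response experiments are orthogonalized with geometrically decaying
variances (ratio 0.75) so the planted model satisfies the identification
conditions exactly.

## Known limitations

* The subject-wise bootstrap is conservative against zero under
  exchangeable nulls (see above); use the group permutation or surrogate
  tests when calibrated size matters.
* `select_k` needs enough time samples for a split-half fit and cannot
  detect components contributing less than `score_tol` of held-out
  reconstruction similarity.
* The cluster test assumes a common time grid and, in its generic form,
  exchangeable pair rows; prefer the subject-wise form whenever the
  all-pairs table is available.
* EDA preprocessing assumes strictly positive raw conductance; hardware
  zero-clipping must be repaired upstream.
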