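# Methods

## Scope and data model

`connage` operates on derived per-subject data: a T × R matrix of regional
resting-state time series, an R × R streamline-count matrix, R node
volumes, 3 × R tissue densities (GM, WM, CSF), and a cohort manifest with
age, gender, education and behavioural scales (Connor-Davidson resilience
and its tenacity/strength/optimism components, MOCA, PSQI, IADL, AD8, GDS,
UCLA loneliness, perceived stress, Lubben social network).  Acquisition and
preprocessing (motion correction, normalisation, tractography, atlas
parcellation) are upstream of this package and out of scope.

## Connectivity

*Static FC* is the Pearson correlation matrix; constant time series raise a
degenerate-input error naming the region rather than propagating NaNs.

*Dynamic FC* uses rectangular (untapered) sliding windows.  The reference
protocol retains 265 volumes and uses 50-TR windows.  **Window step**: the
protocol this package mirrors reports 108 windows from those settings,
which a one-TR step cannot produce (it gives 216); a step of 2 reproduces
the count exactly — floor((265 − 50)/2) + 1 = 108 — so the default step is
2 and the step is an explicit configuration knob.

*Temporal variability* V_k = 1 − mean over ordered window pairs of the
Pearson correlation between region k's windowed connectivity profiles.
The self-entry (diagonal, constantly 1) is removed from each profile before
correlating: keeping it would deflate V_k toward 0 for every region.
V_k ∈ [0, 2]; the vectorized computation is tested to 1e-10 against an
explicit pairwise loop.

*Structural connectivity scaling*: counts(i, j) · 2/(v_i + v_j) — the
inverse of the mean of the two node volumes, the convention of the
construction literature this follows.  The product convention
1/(v_i · v_j) is available via `convention="product"`.

*Synchronization likelihood* embeds each series with dimension m and lag L
(defaults m = 25, L = 20, w1 = 960, w2 = 1959, p_ref = 0.05).  For each
reference point the critical distance per channel is the p_ref-quantile
(k-th smallest, k = round(p_ref · N_valid)) of Euclidean distances to
Theiler-valid partners (w1 < |i − j| < w2); SL is the joint-recurrence
fraction normalised by p_ref, averaged over reference points, clipped to
[0, 1].  An outer window w2 beyond the embedded length simply means no
upper bound, which keeps the stated defaults executable on short series.
Note the default embedding needs T ≥ (m−1)L + 2 = 482 samples; on shorter
series the user must supply smaller m/L (the error message states the
minimum).  Whether the Theiler windows count samples of the original or
embedded series is not fixed by the protocol; this implementation counts
embedded-index separation.

## Graph metrics

Thresholding discards negative weights, then keeps the K =
round(s · R(R−1)/2) largest upper-triangle entries (s = 0.1 default; R =
246 gives K = 3014).  Ties at the cut are broken toward the smaller
(row, column) lexicographic index — deterministic and testable; with
continuous weights ties are measure-zero.  Requesting more edges than
there are positive entries is an error reporting the achievable sparsity.

Betweenness (normalised by (R−1)(R−2)/2 pair count), degree, nodal
efficiency (inverse harmonic mean of shortest-path lengths, unreachable
pairs contributing zero) and clustering (triangle fraction, zero below
degree 2) are computed on the binary graph via networkx; all four are
validated exactly against hand-written exhaustive oracles (BFS distances,
depth-bounded simple-path enumeration, triangle loops) on hundreds of
random ≤ 8-node graphs.  Thresholded networks may fragment; disconnected
pairs are not an error.

## Brain-age model

Features concatenate, in fixed order: SC upper triangle, FC upper
triangle, the dynamic block (R temporal-variability values, or the SL
upper triangle), and GM/WM/CSF densities — p = 2·R(R−1)/2 + R + 3R columns
for the default assembly.  Columns are z-scored within each training fold,
with the held-out fold transformed by the training statistics.

Round 1 (screening): tenfold CV (shuffled KFold, fixed seed 42); per fold a
Lasso is fit on the training portion with its regularization chosen by an
internal 5-fold CV over a 60-point path, then moved to the
one-standard-error point (largest alpha within one SE of the CV minimum).
The 1-SE rule makes the screen conservative: on pure-noise features the
median selected fraction is ~0%, while a genuinely predictive feature
survives every fold.  The selection is the union of non-zero-coefficient
features across folds; each fold tunes its own alpha.

Round 2 (prediction): the same fold partition (same seed and k) restricted
to the selected features; per fold a CV-minimum Lasso (100-point path)
produces held-out predictions, aggregated into out-of-fold MAE and RMSE.
When the CV error indicates an essentially noiseless target the path is
extended below its usual floor with a tighter solver tolerance, so exact
linear relationships are recovered to ~1e-4 years rather than stopping at
the path bottom.  A final all-data refit records the reported alpha.  The
gap is predicted − chronological age, with no post-hoc age-bias
correction — consequently corr(gap, age) ≤ 0 is *expected* (regression
attenuation: the model shrinks predictions toward the mean age), and the
test suite asserts this artifact emerges in simulation.  Negative FC
entries are retained as features; the discard-negatives rule applies only
to network thresholding.

## Inference

*Partial correlation*: both variables residualised on [1, Z] by least
squares after listwise deletion; Spearman (rank-transform first) by
default — the convention behind reporting "rho", and robust at small n —
with Pearson selectable.  p-values from the t distribution on n − c − 2
degrees of freedom.  Gender enters as a 0/1 indicator, education in years.

*FDR*: Benjamini–Hochberg step-up, implemented from the definition and
cross-checked against statsmodels.  For nodal-metric correlations the
family is one metric type per network (8 families of R regions); the
behavioural family is the set of scales tested against the gap.

*CCA*: classical first canonical pair via QR + SVD of the whitened
cross-covariance; columns standardised internally; r ≥ 0 by sign
convention, with the residual (u, v) → (−u, −v) ambiguity fixed by making
the largest-magnitude X-set structure coefficient positive.  Variates have
unit (ddof = 1) variance.  Structure coefficients are correlations of each
original column with its own set's variate.  The permutation p-value
permutes the fixed canonical-variate scores (no refit), p =
(1 + #{|r_null| ≥ |r_obs|})/(B + 1) with B = 10,000 by default; this
matches the described procedure, and a refit-per-permutation variant can
be composed from the public functions if a conservative test is wanted.

*Stratification*: MOCA− is score < 18, MOCA+ is score ≥ 25, everything
else (including missing) excluded.  Group differences use the
pooled-variance t-test (Welch via flag).  k-means classification
standardises the features, runs 1000 random-initialisation iterations of
k = 2 k-means, maps clusters to labels by the better of the two
assignments, and reports the modal per-iteration accuracy, ties broken
toward the larger value.

## Synthetic cohort generator

The generator defines the study conditions the tests exercise: n = 93
subjects (124 when modelling recruitment), ages uniform on 53–76, T = 265
timepoints, and behavioural marginals matched to the emulated cohort's
printed means, SDs and ranges (Gaussian, truncated to range, rounded for
integer scales).  Per-scale missingness matches the emulated per-scale n
(resilience 23/93 missing, LSNS 20/93, PSS 5/93, PSQI 1/93).  Gender is
Bernoulli(33/93) male; education years N(9, 4²) clipped to [0, 22] — a
plausible range, as no education marginal is printed.

*Brain age*: chronological age plus a planted Gaussian gap (gap_sd = 4
years, chosen so model-recoverable error magnitudes land in the few-years
range typical of cohort brain-age models).  Regional time series follow a
3-factor latent model; one factor's loadings over an age-sensitive subset
of regions (the first third) scale linearly with standardised brain age,
mixed against an age-stable component by `signal_strength` (default 0.6).
Streamline counts are Poisson draws around the same low-rank structure, and
GM density in the sensitive regions declines with brain age — so SC, FC
and GM features are all age-decodable, and `planted_features()` names
exactly which columns carry signal (both endpoints age-sensitive for pair
features).

*Planted correlations*: the resilience latent is constructed by
Gram–Schmidt so its sample correlation with the planted gap equals the
target (−0.35) *exactly on the subset that survives missingness* — the rows
a listwise-deleting analysis actually sees; truncation and rounding perturb
the realised value by < 0.01.  MOCA loads negatively on the gap and
positively on resilience (total signal fraction 0.8), so the MOCA extremes
separate on both.  The remaining scales load weakly (±0.3) on the same
latents to give the CCA and k-means stages realistic cross-scale structure.
Exclusion flags are independent per rule.  The depression-screen (GDS)
threshold is exposed as a parameter rather than hard-coded, since the
criterion it mirrors is stated ambiguously in the source protocols this
emulates.

What the generator does **not** emulate: BOLD autocorrelation and
physiological noise spectra, head-motion artifacts, tractography biases,
site/scanner effects, non-Gaussian behavioural distributions, or
informative (non-random) missingness.  Passing tests therefore demonstrate
that the *statistical machinery* recovers planted structure under the
stated conditions — not that the effect sizes printed for any real cohort
would replicate.

## Problem sizes and determinism

Tests and the acceptance script run at desk scale by choice: R = 12–30
regions instead of 246 (feature count grows as R², and a 30-region
assembly already yields 990 features against n = 93 subjects, preserving
the p ≫ n character), T = 60–265 timepoints, 50–500 permutation/seed
replicates.  The recovery suite uses 50 generator seeds at n = 500; the
graph-metric oracle suite uses 500 random ≤ 8-node graphs where exhaustive
enumeration is feasible.  Every stochastic component takes an explicit
seed or Generator; rerunning any pipeline configuration reproduces all
numeric artifacts bit-identically (the run manifest records the full
configuration).

## Known limitations

- The SL default parameters cannot run on series shorter than 482 samples;
  short-series use requires smaller embeddings.
- CCA requires n > p + q complete rows and full-rank sets; no
  regularised/sparse CCA.
- Only the first canonical pair is computed.
- Missing behavioural scores are handled by listwise deletion per
  analysis; no imputation.
- The k-means label mapping is defined for k = 2 only.
- No age-bias correction of the gap is applied anywhere; downstream
  partial correlations control for age instead.
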