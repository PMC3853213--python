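# Methods

## Model and estimation

All three methods solve the same two-class spatial-filtering problem:
maximize the projected variance of class X (label 1) relative to class Y
(label 2) over epoched trials X ∈ ℝ^(N×S).  The per-class covariance is an
arithmetic mean of per-trial *unit-trace* estimates, so every trial
contributes equally regardless of amplitude:

* CSP: per-trial term `X Xᵀ / tr(X Xᵀ)`.
* LTCSP / LTCCSP: per-trial term `X L Xᵀ / tr(X L Xᵀ)`, where `L = D − W`
  is the graph Laplacian of a banded, symmetric, nonnegative temporal
  weight matrix W over the S time points, with D the diagonal of row sums.
  The quadratic form `γᵀ X L Xᵀ γ` equals the weighted sum of pairwise
  projected differences `½ Σ_lm W_lm (γᵀx_l − γᵀx_m)²`, i.e. the weights
  decide which time-point pairs count as locally similar activity.  The
  1/S and 1/2S scalar factors of that expansion are dropped: trace
  normalization cancels them exactly.

Weight kinds (band |l − m| < τ, zero outside):

* correlation (LTCCSP): `W_lm = exp(corr(x_l, x_m))`, Pearson correlation
  across the N channel values.  Bounded in [e⁻¹, e]; invariant to adding
  any constant vector c·1 to a time point (centering removes it), which is
  the mechanism behind its tolerance of baseline shifts and common-mode
  artifacts.
* euclidean (LTCSP): `W_lm = exp(−‖x_l − x_m‖²/σ)`.  The kernel divides by
  σ (not 2σ²); σ defaults to 7σ₀ with σ₀ the *population* standard
  deviation of the pooled squared time-point norms of the training set.
  The pooled-population convention is fixed for reproducibility; at
  S·K ≫ 1 the sample/population distinction is immaterial.
* uniform: all ones on the band.  With τ = S the weighted covariance
  reduces exactly to the row-mean-centered sample covariance — the CSP
  limit, used as an internal consistency oracle in the tests.

Filters come from simultaneous diagonalization: `Γ = U D^(−1/2) V` with
`U D Uᵀ` the eigendecomposition of R_X + R_Y and V the eigenvectors of the
whitened class-X covariance.  Then Γᵀ(R_X + R_Y)Γ = I and the class-X /
class-Y eigenvalue pairs sum to one; columns are ordered by descending
class-X eigenvalue, and the M first plus M last columns feed the features.

## Conventions and numerical choices

* Pearson correlation of a zero-variance (flat) time-point vector with any
  other is defined as 0 (neutral weight e⁰ = 1); the diagonal stays at
  W_ll = e (a vector is perfectly correlated with itself, taken by
  continuity for constant vectors).
* Eigenvector sign: each Γ column is scaled so its largest-magnitude entry
  is positive — models are comparable across runs and platforms.
  Eigenvalue ties break by the eigensolver's stable order (non-semantic).
* PSD tolerances: eigenvalues in [−1e−10·λ_max, 0) are treated as exact
  zeros; anything more negative is rejected as "not a Laplacian".
  Rank-deficient R_X + R_Y (smallest eigenvalue below 1e−10 of the
  largest) raises a conditioning error; an *explicit* ridge δ·I
  (default 0) is the only repair offered — silent regularization would
  contaminate method comparisons.
* Features: the sample variance (denominator S − 1) of the rows of
  `Γ_selᵀ C L^(1/2)` is computed through the algebraically identical
  quadratic form `γᵀ (C L Cᵀ) γ / (S − 1)` — rows of the filtered signal
  are exactly zero-mean because L^(1/2) annihilates the constant vector.
  The explicit square-root route is kept (`laplacian_sqrt`) and the
  identity is asserted in the tests.  For CSP the variance is taken about
  the row mean directly.  No normalization of the log variances across
  filters is applied.
* The test trial's L is built from the test trial's own data — the weight
  matrix is data-dependent by design.
* Band-pass: zero-phase (forward-backward) Butterworth of order 4, 8–30 Hz
  by default; zero-phase filtering avoids distorting variance-based
  features.
* τ selection: stratified k-fold CV (default 10) over τ ∈ {2, …, 12},
  with the *same* seeded fold split reused for every τ (paired
  comparison); ties resolve to the smallest τ.  The CV path caches each
  trial's exp-weight matrix and rebuilds only the band mask and the N×N
  quadratic per τ; it performs identical arithmetic to the public
  fit/extract route (asserted in the tests).  σ for LTCSP is computed once
  from the full training set rather than per fold — it is a global scale
  statistic, not a fitted parameter.
* Classifier: linear-kernel SVM, C = 1, on features standardized by
  training-set mean/std.  "Default" SVM parameters are library-relative;
  a linear kernel on 2M ≈ 6 log-variance features is the conservative
  standard choice, and kernel/C are configurable so the choice is not
  load-bearing.
* Labels are canonicalized to {1, 2}, with 1 = class X (the numerator of
  the variance ratio); the mapping is configurable (`class_x`).
* Units are metadata only; every downstream quantity is trace- or
  variance-normalized.  Epoch cropping is left to the caller (dataset
  metadata, not algorithm).

## Synthetic benchmark

`GeneratorConfig` emulates the variance-difference (ERD/ERS-like)
structure CSP assumes: n_sources band-limited (8–30 Hz) Gaussian sources
with class-dependent variances, mixed through a random orthonormal N ×
n_sources matrix, plus white sensor noise.  Sources are normalized by the
deterministic filter gain, not per trial, so per-trial sample variance
fluctuates naturally around the class value.  Defaults — 15 channels,
500-sample epochs at 250 Hz (a 2 s crop at the sampling rate of common
public motor-imagery recordings), 50 trials per class, a 2:1 variance
contrast on one source pair (a typical ERD/ERS power change), four
common background sources, sensor-noise std 1.0 — put clean-data
accuracies near 98%.

Outlier contamination: round(freq·n) events (n = training-trial count,
freq swept 0…0.4); each event hits one uniformly random (trial,
time-point) slot, adding draws from N(μ + 30σ, (30σ)²) with μ, σ the
pooled mean/std of the clean (band-passed) training data.  Event shapes:
independent per-channel draws (default), one shared draw across channels
("common", a transient baseline shift), or a single-channel spike.
Contamination is additive, applied after band-passing, and only ever to
the training partition.

What the generator does *not* emulate: real EEG nonstationarity, 1/f
background spectra, volume-conduction structure beyond a random
orthonormal mixing, eye/muscle artifacts, or any local temporal
correlation structure that differs between classes.  Consequently the
clean-data advantage that correlation weighting shows on real recordings
has no mechanism to arise here: on this benchmark all three methods are
statistically indistinguishable on clean data, LTCSP's hard kernel
suppression makes it the most outlier-robust, and LTCCSP's bounded
e-fold down-weighting leaves it degrading at about the same rate as CSP.
Passing benchmark tests therefore demonstrate correctness and the
*relative degradation behaviour* of the estimators, not real-data
superiority of any method.

Problem sizes in the test suite and acceptance script (50 random
datasets for the invariant sweep, 10 repetitions for the robustness and
calibration runs, 10 seeds for filter recovery) were chosen to make the
checks statistically meaningful at desk scale.

## Known limitations

* Strictly two-class; no multiclass extension.
* No shrinkage or Riemannian covariance estimation; rank-deficient inputs
  require explicit channel removal or the explicit ridge.
* The Euclidean kernel's σ = 7σ₀ convention follows the published tuning;
  no per-dataset σ search is implemented.
* EDF import is not provided; trials enter via the CSV manifest format or
  in-memory arrays.
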