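# Methods

This note records the scientific conventions, default parameters and design
choices behind `wavetex`, and what the synthetic experiments do and do not
demonstrate.

## Transform conventions

The 2D discrete wavelet transform is separable: rows then columns are
filtered with the decomposition low/high-pass pair and dyadically
downsampled, yielding the approximation `cA` and the horizontal, vertical
and diagonal details `cH`/`cV`/`cD`. Level *k*+1 decomposes level *k*'s
approximation.

Nothing in the problem fixes the boundary mode or downsampling phase, but
coefficient *statistics* depend on both, so they are pinned to a single
auditable convention: half-point symmetric extension with the phase of the
de-facto reference implementation (PyWavelets, `mode="symmetric"`, itself
matching the MATLAB Wavelet Toolbox default). Concretely, a length-*n*
signal is padded by `taps − 1` samples on each side, fully convolved with
the filter, and every second sample kept starting at index `taps`; subband
length is `floor((n + taps − 1)/2)`. The test suite enforces elementwise
agreement with PyWavelets (< 1e-10) on random images for all ten wavelets,
and perfect reconstruction (< 1e-8) through the inverse transform, which
exists only for that verification.

Filter taps are the standard published double-precision tables, frozen as
literals in `filters.py`; the oracle library is a test-only dependency.
Every bank satisfies Σ dec_lo = √2 and Σ dec_hi = 0 to 1e-10. The spellings
`sim2/sim3/sim5` (for the Symlets) and `bior22/bior33` are accepted
aliases, since the flattened forms appear in the feature names.

## Feature definition

Features are named `{wavelet}dec{level}{stat}` with `stat ∈ {mn, md, max,
sd}`: mean, median, signed maximum, and sample SD (n−1). Statistics are
computed over the **approximation** subband of each level. The magnitudes
of published per-feature group means support this reading: an 8-bit image
has approximation values near `2^level × intensity` (e.g. level-1 maxima
around 429 ≈ 2 × 214, level-2 around 866 ≈ 4 ×), whereas detail subbands
centre on zero. A `subband="detail"` switch pools `cH`/`cV`/`cD` instead,
for sensitivity analysis only.

The decomposed region is the tight rectangular bounding box of the ROI
mask, not the irregular masked region — wavelet coefficients have no
one-to-one pixel mapping, so masking coefficients is ill-defined. This is a
documented divergence risk: statistics include any non-tumor pixels inside
the bounding box.

Useful invariants (tested): the feature count is exactly 120 for any valid
image; adding a constant *k* to all pixels shifts level-*L* approximation
mn/md/max by `2^L k` and leaves sd untouched; extraction is bit-for-bit
deterministic.

## Univariate stage

Normality uses the one-sample Kolmogorov–Smirnov statistic with the
Lilliefors correction (via statsmodels), since the normal's parameters are
estimated from the sample. The group comparison defaults to **Welch's**
unequal-variance t-test: on the published summary statistics of the most
significant feature (866.46 ± 1.86, n = 7 vs 860.27 ± 5.51, n = 15) Welch
reproduces the printed p ≈ 0.001 while the pooled form gives ≈ 0.0096, so
Welch is evidently what produced the published table; the pooled variant
remains available. Screening is reporting-only — it never gates the
multivariate stage (published near-significant tables include p = 0.79 and
0.87 variables that enter the final model). Zero-variance features are
reported as degenerate, not dropped silently. No multiplicity correction is
applied by default; a Bonferroni column is included in the report, clearly
an optional extra.

## Discriminant model

`fit_lda` computes the two-class Fisher discriminant with the
unstandardised-canonical-coefficient convention of classical discriminant
software: **w** ∝ S_w⁻¹(μ₊ − μ₋) with S_w the pooled (n−2 denominator)
within-class covariance, scaled so the pooled within-class variance of DS
is 1, constant chosen so the weighted grand-mean DS is 0. This convention
is what makes the shipped reference model's near-zero cutoff (−0.6299) and
symmetric group-mean scores (≈ ±6) interpretable. Classification is
positive at DS ≥ cutoff (the boundary case is positive by convention;
arbitrary but fixed).

The shipped reference model uses the *formula* sign for its `sym5dec2mn`
coefficient (−0.0691719) rather than the positive value in the
accompanying coefficient table: only the negative sign places the two
group-mean scores on opposite sides of the published cutoff, so the table
is read as reporting magnitudes.

Stepwise selection is forward with removal, minimising Wilks' lambda
Λ = det(W)/det(T); entry/removal use the partial-F thresholds 3.84/2.71
(classical defaults, configurable), a within-groups tolerance floor of
1e-3, and an entry cap of n − 4 variables so the subsequent fit stays
well-posed.

Two properties of this procedure matter for interpreting small-cohort
results, and are deliberately documented rather than hidden:

* With ~120 candidates at n = 22, the single-test threshold 3.84 admits
  noise essentially every step (the maximum of >100 null F statistics
  exceeds it with near certainty), so selections fill to the cap. Null
  calibration tests therefore use a Bonferroni-style entry threshold
  (F ≈ 18 for 120 candidates) under which pure-noise tables select nothing
  in ≥ 90% of seeds.
* Planted features carrying the *same* class shift are statistically
  redundant: once two are in, the partial F of the rest is bounded near
  (n−3) × (incremental Mahalanobis gain), which at n = 22 sits below any
  sensible threshold. The planted-recovery simulation therefore runs at a
  60-subject cohort (20 vs 40, preserving the 7:15 class ratio), where
  ≥ 3 of 4 planted 3-SD features are recovered in ≈ 98% of seeds. At the
  clinical n = 22 the same experiment recovers ~2.4 of 4 — a realistic
  caution about stepwise selection on 22 subjects.

## Cutoff selection and validation

ROC thresholds are the midpoints between adjacent sorted unique scores
plus ∓∞ sentinels; the operating cutoff maximises Youden's J, with ties
broken toward the candidate nearest the pooled score median. Optimality is
certified in tests against a brute-force sweep. AUC is the Mann–Whitney
probability with half-weight ties.

LOOCV refits the discriminant coefficients and the cutoff inside every
fold with the feature set fixed (the default), or refits the stepwise
selection per fold as well (`refit_selection=True`, the statistically
honest variant for selection uncertainty). Fold isolation is enforced by a
mutation test: perturbing a held-out subject cannot change that fold's
trained cutoff.

Two cutoff policies exist because they answer different questions:

* `"youden"` (default) — the ROC-optimal balanced cutoff, mirroring the
  main pipeline; under label permutation it yields chance-level (~50%)
  accuracy, as any balanced rule must.
* `"prior"` — the posterior-odds boundary with training priors, the
  classification rule of classical discriminant software; under label
  permutation it predicts the majority class, so null accuracy sits near
  the majority rate (15/22 ≈ 0.68, slightly depressed by leave-one-out
  pessimism). Null-calibration checks use this policy.

## Synthetic data

The generator stands in for clinical images that were never deposited. A
subject image is: Gaussian random field (white noise smoothed by a
Gaussian kernel at the correlation length, rescaled to the contrast
amplitude) + base gray level + white noise, multiplied by a soft
elliptical support (logistic edge, semi-axes 0.44/0.36 of the frame) and
quantised to 8 bits. Defaults: 64×64 frames, negative class at base
intensity 120, contrast 12, correlation length 3 px, noise SD 6;
between-subject base-intensity jitter SD 4 gray levels; cohort 7 positive
vs 15 negative. `effect` interpolates the negative-class parameters toward
the positive-class ones; with the default 4-gray-level offset it reads as
the class separation in between-subject SD units. Pixel clipping at the
defaults is < 1%. Child seeds mix the cohort seed with the subject index
through `numpy.random.SeedSequence(entropy=(seed, index))`, so cohorts are
reproducible across platforms.

The headline synthetic analogue uses `effect = 8` — a deliberately
decisive separation (≈ 8 between-subject SDs of the coarse-scale mean
feature) chosen so that 100% LOOCV accuracy reflects the pipeline
functioning correctly rather than a lucky seed.

What the generator does **not** emulate: MRI physics (bias fields, Rician
noise), anatomically shaped lesions, multi-slice context, scanner and
protocol variability, or the feature correlation structure of real
tumors. Passing the synthetic analogue therefore demonstrates that the
software chain is correct and that a decisively separated cohort is
classified perfectly; it says nothing about whether real post-treatment
rectal MRI separates pCR from non-pCR — on 22 subjects with 120 candidate
features, a perfect apparent classification is exactly what aggressive
stepwise selection can produce by overfitting (see the stepwise notes
above).

The feature-level generator draws 120 unit-variance features with
exchangeable within-class correlation (default ρ = 0.2) and adds a class
mean shift of `effect` SD units to four designated features (the reference
model's variables). It exists to test the statistical stages without the
imaging cost.

## Numerical and degenerate-input policy

Singular pooled covariances raise errors naming collinear or zero-variance
features. Constant samples are untestable for normality and rejected.
Coefficient summary statistics require ≥ 2 values (sd undefined below
that). Decomposition depth beyond what the image supports raises an error
stating the maximum feasible level; for wide filters whose symmetric
extension stops shrinking the size recurrence, depth is effectively
unbounded and capped at 32. Model JSON serialises coefficients via
`repr(float)`, so round-trips preserve every bit; feature CSVs print 17
significant digits and are re-read with round-trip float parsing.

## Problem sizes

Default test and acceptance runs use 64×64 images, 22-subject image
cohorts, 60-subject feature cohorts for the selection simulations, and
50-seed simulation batches; the full suite completes in well under a
minute of CPU, and the acceptance script in a few seconds.
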