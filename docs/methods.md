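# Methods

This note documents the models, defaults and numerical choices behind
`gazerr`, and what the synthetic study does and does not establish.

## Geometry and error definitions

All analysis operates on angles of visual angle, in degrees. The
coordinate convention is: origin at the screen centre, x rightward,
y downward; raw CSVs in top-left display coordinates are shifted at load
(`top_left_origin=True`). The pixel pitch µ = diagonal_mm / diagonal_px
converts pixel offsets to millimetres; the two packaged geometries are a
22-inch 1680×1050 desktop monitor (µ ≈ 0.2821 mm/px) and a 10.1-inch
1920×800 tablet (µ ≈ 0.1233 mm/px).

The binocular average is taken per sample; temporal aggregation happens
only at feature construction. Yaw and pitch divide the millimetre (not
pixel) offsets by Z before the arctangent, so that all three angle
definitions are dimensionally consistent. The frontal angle is
tan⁻¹(OSD/Z), **not** the Euclidean norm of (yaw, pitch) — for off-axis
points these differ by the curvature of the tangent, which matters both
for error definitions and for the simulator (below). The pitch error is
θpitch − AOIpitch, symmetric to the yaw error.

Viewing distances are restricted to 500–800 mm in the simulator: outside
that range consumer trackers typically fail to report data at all.

## Cleaning

Missing samples (NaN in the eye coordinates) are mean-substituted per
column before angular conversion. Outlier removal then operates on the
*angular error traces* (configurable), with three interchangeable rules:

* **median filter** (default): centred window, kernel 41 — the typical
  number of samples recorded during one 3-s AOI dwell — with reflect
  padding at the edges (implemented as `scipy.ndimage.median_filter`,
  `mode="mirror"`, which matches `np.pad(..., "reflect")`);
* **MAD rule**: flag |x − median| > k·MAD, default k = 3 (a common robust
  convention; the multiplier is exposed because no single value is
  canonical). A zero MAD on nonconstant data would flag every off-median
  point, so that case flags nothing and warns;
* **IQR fence**: flag beyond Q3 + 1.5·IQR / Q1 − 1.5·IQR. Quartiles use
  linear interpolation between order statistics; this is stated
  explicitly because fence positions depend on the quantile method.

Flagged points are replaced with the series median rather than dropped, so
cleaned traces stay aligned with the ground-truth AOI schedule that the
per-AOI features require.

## Augmentation

Each cleaned error trace yields exactly ten variants: the original, plus
Gaussian noise (σ = 0.2°), pink-noise jitter, interpolation, raised-cosine
smoothing, a circular 10-sample shift, interpolation + Gaussian,
interpolation + jitter, and horizontal/vertical AOI flips. The recipe uses
each of the seven strategy families at least once and yields the 30
samples per participant-condition (3 error categories × 10) that the
dataset layout assumes.

*Pink jitter* models fixational eye jitter: white N(0, 0.2²) noise is
reshaped in the frequency domain so the PSD falls as 1/f^0.8 above a 2 Hz
cutoff (flat below it — at the ~13.7 Hz effective sampling rate there is
little spectral room below 2 Hz, and an unbounded 1/f^α divergence at DC
would be unphysical), the DC bin is zeroed, and the result rescaled to
σ = 0.2. Uniform rescaling preserves the spectral slope, which is the
tested contract (periodogram log-log slope −0.8 ± 0.15 above the cutoff).

*Interpolation* resamples at half-sample offsets and maps back to the
original grid with linear extrapolation at the two ends, so linear traces
are reproduced exactly and anything else is gently smoothed.

*Raised-cosine smoothing* convolves with the unit-sum Hann window
w(n) = ½(1 − cos(2πn/(N−1))), N = 30, using mirror padding so constant
traces pass through unchanged (zero-padded "same" convolution would bleed
mass at the edges).

*Time shifting* is circular, preserving both the trace length and the
value multiset.

*Flips* are defined on the error magnitudes of the 15 AOIs of the 5×3
grid (row-major AOI-1..15): horizontal swaps the top and bottom rows,
vertical mirrors the columns. On a trace they permute whole dwell blocks,
so the value multiset — hence every whole-trace statistical feature — is
invariant and only the AOI-indexed features permute.

## Features and datasets

Per-AOI features are the mean |error| over each AOI's dwell window, with
dwell assignment taken from the ground-truth AOI schedule (not gaze
proximity). Whole-trace statistics — mean, sample sd, IQR, and a 95 %
confidence interval for the mean — are computed on the absolute error
values. The CI uses the normal approximation mean ± 1.96·sd/√n; nothing
heavier is warranted at n ≈ 615 per trace. The full vector has 20
entries; the reduced set keeps the 5 statistics, which impurity ranking
consistently identifies as the most discriminative.

Scopes: `user_distance` (4 classes), `pose` (4 classes, where the neutral
pose *is* the 60-cm distance condition, stored once), `mixed` (7 classes,
neutral/UD60 counted once). With 20 participants these contain 2400, 2400
and 4200 samples respectively. Standardization is per-column zero-mean
unit-variance (population sd); constant columns are dropped with a
warning. Splits and CV folds are stratified — the classes are balanced by
construction, and stratification keeps them so.

## Classifiers

KNN (Euclidean, k = 3), RBF-SVM (C = 10, γ = 1.0) and an MLP (ReLU, Adam,
constant learning rate 0.001, hidden layers (50, 100, 50)) are wrapped
behind one spec type. KNN and SVM default to the reduced 5-feature set;
the MLP uses all 20 features, which it needs to avoid underfitting.
Reported accuracy is stratified 10-fold CV; the held-out evaluation
reports the confusion matrix and one-vs-rest TPR/FPR/TNR/FNR/precision
per class with macro averages. Grid search is an explicit loop in grid
order with strict improvement, so ties keep the earliest grid point.

## Regression

The regression task maps standardized (θ, θyaw, θpitch) to the frontal
error magnitude (signed errors are available via a flag; magnitude is the
default because the summary statistics of interest are magnitudes). Six
families are provided: OLS, polynomial (degree 2 by default — higher
degrees overfit badly on this 3-input problem), Ridge, Lasso, ElasticNet
and an MLP (1×100 hidden units, α = 0.001). Default regularization
strength is 0.001 with an ElasticNet L1 ratio of 0.5.

The target is centred before fitting and its mean carried as `y_offset`,
so fitted intercepts are numerically zero and the bundled affine models —
eight pre-fitted ElasticNet pose models (four desktop head poses, four
tablet platform poses) with intercepts at the 10⁻¹⁶ level — evaluate as
pure arithmetic `Y = B₀ + B·x`.

## The synthetic study

The simulator emulates a fixation-accuracy experiment: 20 participants ×
{UD50, UD60, UD70, UD80, roll20, pitch20, yaw20} on desktop and tablet; a
dot dwells 3 s at each of 15 AOIs on an equal-margin 5×3 lattice; 41
samples per dwell (615 per session, ≈13.7 Hz — chosen to match the
median-filter kernel's origin as the per-dwell sample count).

Each condition's `ErrorProfile` holds a target mean |frontal error|
(`bias_mean`, degrees), a per-sample dispersion set to IQR/1.349 of the
condition's observed error spread, a between-participant coefficient of
variation of 0.12 (a typical repeated-measures spread for this kind of
accuracy data), anisotropy gains that push the error into yaw or pitch for
the corresponding pose conditions, an outlier rate (0.05 desktop, 0.02
tablet) with 8-dispersion heavy-tailed spikes, and a 2 % dropout rate.
Desktop means decrease monotonically with distance (3.37, 2.04, 1.21,
1.02°); head yaw is the worst desktop condition (8.51°) and platform roll
the worst tablet condition (7.74°). Condition means are pooled over
samples, not averaged over participants' means.

The construction is deliberately analytic: a per-participant radial bias
b ~ N(bias_mean, (0.12·bias_mean)²) plus per-sample scatter is drawn *as a
frontal-angle offset*, and the gaze point is placed on the ray through the
AOI at the pixel radius Z·tan(θgt + δ)/µ, so the downstream frontal error
equals the drawn offset exactly. Median filtering collapses each dwell to
approximately the participant bias, so the pooled post-cleaning mean
|error| converges to `bias_mean` by construction rather than by tuning.
Anisotropic jitter is tangential and zero-mean; it shapes the yaw/pitch
error split while perturbing the frontal error only at second order.

What this does **not** model: saccade/pursuit dynamics, blinks, pupil
physiology, calibration drift over time, correlated binocular noise, or
multi-factor error sources acting simultaneously. Passing tests therefore
demonstrate that the *pipeline* is correct and that conditions with the
encoded statistical separations are recoverable — not that any particular
real tracker is classifiable at the same accuracy. Real-data accuracies
require real recordings.

## Numerical choices and degenerate inputs

* Quantiles: linear interpolation everywhere (features, IQR fence).
* Sample sd uses ddof = 1; standardization uses population sd (ddof = 0),
  matching the respective conventions of CI construction and scaling.
* Frontal angles are clipped to [0°, 89°] in the simulator; an offset that
  would cross the screen centre saturates at zero eccentricity.
* KNN distance/vote ties resolve by scikit-learn's ordering (smallest
  index); documented because no convention is canonical.
* Random-forest importances use `max_features=None` so every split
  considers every feature: importances are then deterministic up to
  tie-breaking in tiny deep nodes, and permuting feature columns permutes
  the informative structure exactly.
* t-SNE is a visualization contract only (shape, seed-determinism,
  cluster sanity); its coordinates are not numerically pinned.
* All randomness flows through `numpy.random.SeedSequence` children of a
  single user seed; augmentation sub-seeds are derived from a CRC of the
  (participant, condition, category) key so they are stable across runs
  and processes.

## Problem sizes

The default study (20 participants, 7 conditions, 615 samples/session)
simulates and cleans in seconds; the full classification experiment
including MLP training runs in under half a minute on one CPU, and the
test suite in well under a minute. These sizes were chosen to match the
emulated experiment's own design, and they keep iteration fast.

## Known limitations

* The pose conditions differ from distance conditions mainly through
  error magnitude, dispersion and anisotropy; real pose-induced errors
  also produce spatially structured patterns across the screen that the
  radial-bias model only partially captures.
* Mean imputation of dropouts injects screen-centre-biased samples; they
  are subsequently removed by the median filter but would survive a
  MAD/IQR-only cleaning configuration at high dropout rates.
* The bundled pose error models apply to standardized inputs of the
  sessions they were fitted on; applying them to other data requires
  standardizing with comparable statistics.
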