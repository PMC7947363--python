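# Methods

## Scope and data model

The pipeline's currency is the `BandStack`: a co-registered five-band raster
(blue, green, red, red-edge, NIR; row-major, 0-based, origin top-left) in one
of two states, `raw` (digital numbers, DN) or `calibrated` (reflectance,
nominally [0, ~1.2] to tolerate slight super-unity from noise). Stacks are
stored as plain multiband TIFF with band order and state in the
ImageDescription tag; no coordinate reference system is attached because the
analysis is entirely in pixel space (orthomosaic stitching and georeferencing
happen upstream and are out of scope).

## Radiometric calibration

Calibration is linear through the origin: per band,
`R = DN · ρ / mean(DN over panel)`, with panel albedo ρ = 0.99 by default.
There is no dark-offset term — the camera model emulated by the generator is
`DN = gain_b · (R + ε)`, and with a purely multiplicative DN model a one-point
panel calibration is exact. Consequences that the tests exploit: calibration
is equivariant under any global rescaling of the DNs, and on a noiseless
scene the generator's spectra are recovered at machine precision. A zero or
non-finite panel mean raises an error naming the band.

## Vegetation indices

NDVI, GNDVI and NDRE are normalized differences (bounded in [−1, 1]);
SAVI = (1+L)(NIR−R)/(NIR+R+L) uses the canonical soil factor L = 0.5
(configurable); TVI is the triangular form ½[120(NIR−G) − 200(R−G)]. Each
formula lives in one small function so alternates can be swapped. Pixels with
a zero denominator become NaN ("missing"), never 0, and are excluded from
every downstream mean and sum. With a positive SAVI threshold, every canopy
pixel necessarily has NIR > 0, so the other indices are always defined on
masked pixels.

## Canopy mask and flower exclusion

The master mask is `SAVI > threshold`, with missing SAVI mapped to
background. The threshold is a required, operator-chosen value — field
thresholds legitimately vary with canopy vigor and illumination — and the
package additionally logs an Otsu suggestion computed on the finite SAVI
values; the suggestion is never applied silently.

White dry-pea flowers reflect strongly and nearly equally in all visible
bands, unlike stipules/tendrils; the exclusion rule removes mask pixels with
`min(blue, green, red) > 0.35` (configurable). For chickpea the operation is
the identity: its flowers are too small to resolve at these ground sampling
distances. The default flower spectrum in the generator keeps flower SAVI
above soil SAVI so the exclusion rule is doing real work rather than
duplicating the threshold.

## Plot segmentation and ROI shrinkage

The field is described by four corners (TL, TR, BR, BL, convex) plus the
grid dimensions. Cell (i, j) corners are bilinear interpolations of the
field corners at fractions (i/n_ranges, j/n_plots); membership of each pixel
is decided at its centre through the closed-form inverse of the bilinear
map, so the cells are exactly pairwise disjoint and their union is exactly
the set of pixel centres inside the quadrilateral. Bilinear cells (rather
than a projective homography) suffice because images are rotated to
near-axis alignment first; rotation uses bilinear interpolation for bands,
nearest-neighbour for masks, an expanded canvas and NaN fill. A rotation
round trip introduces a pure translation of (canvas_growth)/2, which the
processing path applies to the corners and panel region; the panel region is
additionally contracted by 2 px to dodge interpolated border pixels.

Each cell's ROI is its bounding box contracted by `shrink_tb` rows top and
bottom and `shrink_lr` columns left and right, intersected with the cell.
The field presets are (20, 50) px and (11, 28) px for the two
ground-sampling-distance eras (`SHRINK_PRESETS`). Synthetic scenes instead
use `alley_px/2` per side, which maps each cell exactly onto the sown plot
box: all alley pixels excluded, no plot pixel lost, so canopy areas can be
compared to generator truth exactly. Empty ROIs raise an error naming the
plot.

Features per plot: `canopy_area = |ROI ∩ mask|` and, for each index, the
mean and sum over those pixels (missing pixels excluded). The invariant
`sum = mean × area` holds for every row; plots with no canopy report area 0
and missing means.

## Trait statistics

Pearson r uses the product-moment formula with a two-sided t-test on n−2
degrees of freedom; |r| = 1 reports p = 0; constant inputs or fewer than 3
complete pairs report missing with a reason. Missing pairs are deleted
pairwise (not listwise) to maximize n as the feature × trait matrix is
assembled pair by pair. No multiple-testing correction is applied — stars at
0.05/0.01/0.001 follow the conventional raw-α display, and a 11-feature ×
3-trait × multi-date matrix will contain false positives at that rate.
Noisy-plot removal (e.g. cloud shadow) is an explicit exclusion list of plot
ids, never automatic. Cultivar mode averages replicates per (entry,
location[, date, stage]) before correlating.

## Yield model

Normalization standardizes each feature and the yield within a group
(location within year; groups are then pooled for combined-data analyses)
using the sample (n−1) standard deviation; zero variance raises an error
naming the feature. The lasso penalty path has 100 log-spaced values from
λ_max (smallest penalty giving the all-zero model) down by 10⁻⁴; the penalty
is chosen at the minimum of the cross-validated MSE curve averaged over 3
repetitions of 5-fold CV with re-randomized folds (the minimum-MSE rule, not
the 1-SE rule). The solver is scikit-learn coordinate descent (path
tolerance 1e-6, warm-started).

Plot mode: 4 independent iterations of a seeded 3:1 train/test split; within
each training set, every CV repetition averages 5 random 80/20 resample
validation curves, its minimizing penalty is refit on the full training set
(these iteration × repetition fits feed the selection tally), and the
penalty minimizing the all-repetition average gives the iteration's final
model, scored on the held-out quarter. Cultivar mode: leave-one-out, each
holdout predicted by a model tuned and fit on the rest; test R² pools the
holdout predictions. A master seed fans out to independent split/fold
streams; identical seeds give bit-identical evaluations.

Two R² definitions are computed and reported side by side: the squared
Pearson correlation between predicted and observed (the headline number,
matching predicted-vs-observed regression displays) and 1 − SSE/SST. They
differ in two situations worth knowing about. First, correlation² forgives
calibration (scale/offset) errors that 1 − SSE/SST punishes. Second, on
null-signal data the leave-one-out protocol produces *negatively* correlated
predictions (removing an observation shifts the training mean away from it),
which the squared correlation inflates into an apparently positive score
while 1 − SSE/SST correctly lands near zero or below; null checks therefore
use the SSE form.

The reported predictor set is the features with nonzero coefficients in at
least 75% of the tallied fits (iteration × repetition fits in plot mode, all
LOO fits in cultivar mode). Because minimum-MSE penalties over-select, a
fixed dataset's strongest spurious predictor can recur across fits of that
same dataset; the 75% rule is therefore most meaningful aggregated across
independent datasets or seasons, and the acceptance checks pool frequencies
across seeded runs accordingly.

## Synthetic trial generator

The generator emulates what the analysis assumes about real trials, and no
more:

* **Design**: RCBD, 21–40 entries × 3 replicates per location, 1–3
  locations; each replicate occupies a contiguous block of plots in
  range-major order with a seeded within-block permutation, re-randomized
  per replicate and location.
* **Geometry**: plots of fixed pixel size on a regular grid separated by
  even-width alleys, a margin holding a uniform calibration panel, field
  corners recorded for segmentation; optional pre-rotation by a stated angle
  to exercise rotation correction.
* **Spectra** (per-band reflectance): canopy (0.04, 0.08, 0.05, 0.30, 0.50)
  — NIR ≫ red; soil (0.10, 0.15, 0.20, 0.25, 0.30); flowers
  (0.55, 0.55, 0.55, 0.65, 0.85) — white in the visible with NIR above soil
  so flower pixels pass a soil-separating SAVI threshold and must be removed
  by the flower rule. Soil SAVI ≈ 0.15, flower ≈ 0.24, canopy ≈ 0.64.
* **Texture**: canopy pixels are clustered blobs — the n nearest pixels to
  random seed points under a Euclidean distance transform with random
  tie-break — so masking is nontrivial, and the count is exact by
  construction, which makes truth bookkeeping exact.
* **Camera**: `DN = gain_b · (R + N(0, σ))` with per-band gains near 4000
  (12-bit scale) and σ = 0.005 reflectance by default. DNs are kept floating
  point rather than quantized; quantization would add a ±0.5 DN noise floor
  that is not part of the emulated model.
* **Growth**: per-entry vigor (shared across locations) plus location and
  plot effects gives each plot a full-canopy cover fraction, clipped to
  [0.15, 0.95] — the floor guarantees every plot keeps a resolvable canopy
  above the 5% flower fraction; a logistic curve over growing-degree-day
  stage times (early ≈ 0.29, flowering ≈ 0.89, pod/seed ≈ 1.0 of full cover)
  produces multi-date series.
* **Traits**: `yield = β₀ + Σ βk·covariate + N(0, σ²)`, with a helper that
  sizes σ so a chosen fraction of the yield variance (default 0.85) comes
  from the canopy covariates (sum NDVI + canopy area at the first rendered
  stage). Days to 50% flowering declines with early-stage vigor and days to
  maturity rises with late-stage vigor, reproducing the early-negative /
  late-positive correlation structure seen in such trials. Stored
  coefficients and seed reproduce the table exactly.

What the generator does **not** emulate — radiative-transfer effects,
bidirectional reflectance, vignetting, stitching seams, weeds, lodging,
within-field fertility gradients, heterogeneous per-plot spectra — bounds
what passing tests show: they certify the *algorithmic* chain (calibration
arithmetic, index formulas, geometry, bookkeeping, statistical protocol),
not robustness to real-world optical variation. Threshold choice on real
imagery in particular remains an operator judgement.

## Problem sizes and determinism

Default simulated conditions: 21 entries × 3 replicates × 3 locations
(189 plots), plots of 36 × 16 px with 6 px alleys (images ≈ 340 × 250 px),
two acquisition dates. These sizes keep a full simulate→predict run in
seconds while leaving every statistic at realistic n (63 cultivar instances,
189 plot observations). Every random draw — layout, blobs, noise, splits,
folds — descends from explicit seeds; the pipeline writes a manifest of
per-artifact SHA-256 checksums, and two runs with the same master seed are
byte-identical.

## Known limitations

* Corner identification is manual (config/CLI), as in the emulated workflow;
  no automatic field detection.
* The 11-feature set is strongly collinear by construction (sum ≈ mean ×
  area within a stage, stages correlated through shared vigor), so the
  identity of lasso-selected features is unstable even when predictions are
  accurate; the 75% rule reports few features, sometimes none, in any single
  run.
* Pearson correlation and the lasso treat plots as exchangeable; no spatial
  or mixed-model adjustment of field trends is attempted.
* Calibration assumes a linear sensor with zero offset; cameras with a dark
  current would need a two-point calibration the panel workflow here does
  not provide.
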