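# Methods

This note documents the models implemented in `octaquant`, the defaults
and why they were chosen, what the synthetic generators do and do not
emulate, and the numerical conventions that make results bit-reproducible.

## Calibration and FAZ morphometry

En-face scans are treated as calibrated grids: a 320 × 320 px scan over
3 × 3 mm has a scale of 320/3 = 106.67 px/mm (full precision internally,
two decimals in reports; pixel aspect ratio 1.0). Traced regions are
geometric polygons with continuous (sub-pixel) vertex coordinates,
measured as polygons — shoelace area, summed straight edges for the
perimeter — not as rasterized masks. This matches the semantics of manual
tracing tools and makes closed-form checks exact; the pixel-level
difference from a rasterized reading is far below the two-decimal
reporting precision. Anisotropic pixels are supported with per-axis
scales (area uses `scale_x · scale_y`).

The circularity index is the isoperimetric quotient `4πA/P²`. It is
returned unclipped; polygonal discretization can push it marginally above
1 (tolerance 0.01 in validation). Degenerate (zero-area) polygons are
rejected, not coerced.

## Niblack binarization

A pixel is foreground iff (bright polarity)

    I > mean_w + k · sd_w − c

with window statistics over the (2r+1)² neighbourhood, **symmetric**
(edge-including reflective) padding, and the population SD
(`sumsq/n − mean²`). Defaults: r = 15 px, k = 0.2, c = 0 — the common
auto-local-threshold convention; all three are exposed in configuration
and recorded in output provenance. Dark polarity (used for choroidal
lumina) flips the comparison to `I < mean − k·sd + c`.

Implementation: exact integer integral images. For 8-bit input every
window sum and sum of squares is an exactly representable float64
integer, so the vectorized path is bit-identical to a naive per-pixel
loop (this equivalence is asserted in the tests). A constant image yields
an empty mask under either polarity (strict inequality at sd = 0).

Two behaviours of plain Niblack thresholding are inherent and worth
knowing: interior pixels of regions that are constant over a full window
are classified background (the local contrast is zero), and on additive
Gaussian noise a fraction ≈ Φ(−k) of pure-background pixels exceeds the
local threshold. The phantom-recovery guarantees in the tests therefore
hold on noiseless phantoms; on noisy input a positive offset `c` is
advisable.

## Skeletonization and vessel length density

Masks are thinned with Zhang–Suen-style two-pass thinning
(`skimage.morphology.skeletonize`) to 8-connected, 1-px-wide centrelines.
Vessel length is **skeleton pixel count × pixel pitch**, i.e. the plain
pixel-counting estimate; no √2 correction is applied for diagonal runs,
so purely diagonal segments are under-measured by up to ~8%. This
mirrors how the measurement is made in practice (counting pixels in
ImageJ) and is consistent with the generator's ground-truth definition
(below). VLD = length / physical scan area (mm⁻¹). The analysis region
for vessel density defaults to the whole scan (no FAZ exclusion); a
region argument supports alternatives.

## Choroidal vascularity index

The total choroidal area (TCA) polygon is clipped to the subfoveal
column band (default half-width 750 µm, i.e. a 1,500-µm window; the
clip box spans `[x_lo − 0.5, x_hi − 0.5)` so that rasterizing the clipped
polygon by pixel centres selects exactly the integer columns
`[x_lo, x_hi)`). Rasterization uses the pixel-centre-inside rule
(even-odd for simple polygons; boundary points excluded), which is
deterministic and matches the pixel-counting semantics of the protocol.
The luminal area is the dark-polarity Niblack mask intersected with the
TCA raster — the ROI-manager "AND" of the interactive protocol — and
CVI = 100 · LA/TCA. The fovea column and the lateral µm/px calibration
are required inputs: the foveal scan is selected manually and the
calibration is device-specific, so neither is defaulted.

## Synthetic data

**En-face phantoms.** The avascular zone boundary is a truncated Fourier
contour `r(θ) = r₀ + Σ aₖ cos(kθ + φₖ)` sampled at 256 vertices (phases
seeded), giving analytic control of area, perimeter and hence
circularity; circularity is non-increasing in the perturbation
amplitudes. The vessel network grows by *sprouting*: each round seeds a
new vessel at a random point of vessel-free space and extends two smooth
biased random walkers (per-step heading noise σ = 0.10 rad, branching
probability 0.01) in opposite directions; a walker stops when it
anastomoses with — comes within 2 px of — a foreign vessel, leaves the
image, or reaches a keep-out margin around the FAZ contour. Stopping on
contact keeps tubes from running merged in parallel, which is what makes
a skeleton-length ground truth possible: the skeleton of the dilated
network preserves the laid-down centreline to within a few percent at
all supported densities. Near the target fraction the generator switches
to short sprouts so the achieved fraction overshoots by well under the
±20 % (relative) contract. Unreachable targets raise (area precheck,
no-free-space, or iteration budget) rather than silently clipping.

Ground truth is recomputed from the final rasters: the vessel fraction
is the realised mask mean, and `truth_skeleton_length_mm` is the
centreline **pixel count × pixel pitch** — deliberately the same
pixel-counting length metric the pipeline reports, so the recovery
contract compares like with like.

**Choroid phantoms.** Dark circular lumina are centred on a jittered
square grid inside an undulating TCA band; the grid spacing follows from
the requested radius and luminal fraction (`s = r·√(π/f)`), and the
rasterized disk radius is calibrated against actual pixel counts so the
dark fraction inside the TCA lands within ±0.02 of the request (checked;
error otherwise). Keeping disks inside their grid cells guarantees
stromal septa between lumina, so a local threshold can see every lumen
boundary. Fractions above 0.75 are rejected as geometrically degenerate.

**Intensity model.** 8-bit; vessels/stroma at 200, background/lumina at
30, optional additive Gaussian noise clipped to [0, 255]. All generators
are bit-reproducible for a fixed spec and seed.

**Cohorts.** Per-eye records over the six severity groups with default
sizes (42, 30, 22, 23, 42, 15) and per-group metric means/SDs taken from
the reference clinical cohort this package models. Each eye's value is
group mean + patient intercept + residual; the intercept SD τ defaults to
0.3 × the metric's smallest group SD (scalar or per-metric overrides are
accepted; τ greater than any group SD raises, since the residual variance
`sd² − τ²` must stay positive), and eyes of one patient share the
intercept and group. About 60 % of patients contribute both eyes.
Covariates: age and diastolic BP are normal per group (the reference
reports no control-group diastolic BP, so a normotensive 75.5 ± 9.0 mmHg
is used there); sex is Bernoulli with the group's female fraction (coded
0 = female, 1 = male); the signal strength index is N(72, 6) per eye. The
reference's published sex counts are internally inconsistent (the
whole-cohort split is attributed to the diabetic subgroup); the
group-level fractions are used and the inconsistency is simply noted.

What the generators do **not** emulate: OCT speckle statistics,
projection and motion artifacts, segmentation errors, macular edema or
media opacity, cross-metric correlation within an eye, and any
association between metrics and covariates. Passing recovery tests
therefore demonstrates correctness of the measurement chain on networks
and windows with known geometry — not device-level accuracy on clinical
images, and not robustness to artifacts.

## Cohort statistics

* **Quality filter**: keep eyes with signal strength index strictly
  greater than 60 (boundary values are removed); idempotent; removed
  counts are logged.
* **Adjusted trends**: `metric ~ severity + age + sex + dbp` with a
  per-patient random intercept (statsmodels `MixedLM`, REML); severity is
  the ordinal group code 1–6 treated as numeric, so the slope is "per
  severity step". Healthy controls are included by default (configurable)
  to span the full six-group layout. Singular or non-convergent fits fall
  back to OLS with a logged warning; with one eye per patient throughout,
  the GLS weights are uniform and the mixed slope equals OLS exactly.
* **ROC/Youden**: curves sweep every distinct threshold with ties
  grouped, so the trapezoidal AUC equals the tie-corrected Mann–Whitney
  statistic. Each metric is auto-oriented so AUC ≥ 0.5 and a
  `lower_indicates_disease` flag is recorded (true for circularity,
  densities and CVI). AUC confidence intervals use the DeLong
  structural-components variance (bootstrap percentile available);
  intervals are clipped to [0, 1] and collapse at perfect separation.
  The Youden cutoff maximizes J = sens + spec − 1 over midpoints between
  adjacent distinct scores (a clean class gap therefore yields the gap
  midpoint); ties break toward higher sensitivity, then the lower cutoff.
  Sensitivity/specificity intervals are Wilson score. A constant metric
  reports AUC 0.5 with a warning rather than an error.
* **Contrasts**: over diabetic eyes only by default — negatives = no DR
  vs positives = any DR; negatives = no DR/mild/moderate vs positives =
  severe/PDR. Whether healthy controls join the negatives is an explicit
  option, asserted by neither analysis. Both eyes of a patient enter ROC
  analyses as independent units (eye-level analysis; a documented
  limitation). The p-value floor "<0.001" is a formatting concern only;
  numeric p-values are never truncated in results.

## Problem sizes used in validation

The self-tests run on one 320 × 320 phantom per condition, 220 × 320
choroid windows, 50-case oracle batches for the binarizer and the
rank-statistic identities, 2 × 2,000 scores for the closed-form AUC
limit, and 100 replicate cohorts of ~500 eyes (6 × 83) for slope
recovery. These sizes give comfortable statistical margins for every
asserted tolerance while keeping the whole suite fast.

## Known limitations

* Absolute vessel densities depend on the (unpublished) Niblack
  parameters of any interactive analysis being compared against; only
  structure (directions, orderings, recovery of known truth) is asserted.
* Pixel-counting length under-measures diagonal runs (≤ ~8%); both the
  pipeline estimate and the generator truth use the same convention.
* The eye-level ROC treatment ignores the within-patient correlation
  that the trend models do account for.
* Niblack thresholding is blind inside regions that are constant across
  a full window; choose the window radius smaller than the smallest
  structure of interest.
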