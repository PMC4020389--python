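# Methods

This note documents the models, numerical choices and limitations behind
`tonguelab`. It is the design record; empirical claims below are limited to
what the test suite and `scripts/acceptance.py` actually compute.

## Color space

Input images are 8-bit sRGB (the de-facto camera default; no ICC handling).
Conversion to CIE 1976 (L\*, a\*, b\*) uses the standard transfer function
and the IEC 61966-2-1 RGB→XYZ matrix with its rows renormalized so that RGB
white maps *exactly* to the reference white (D65). The published 6-decimal
matrix alone leaves ~2×10⁻³ residuals on a\*/b\* for neutral pixels; the
renormalization makes the neutral axis exact (|a\*|, |b\*| < 10⁻⁶ for any
equal-RGB pixel) and L\* strictly monotone in gray level, which matters
because the achromatic checker patches calibrate L\* alone. The inverse
conversion exists to render synthetic imagery; out-of-gamut values are
clipped with a reported count, and for in-gamut colors the round trip is
exact to one 8-bit quantization step per channel.

## Segmentation

The tongue boundary is found by a closed active contour (snake) driven by a
gradient-vector-flow (GVF) field:

* **Polar edge map** — |∂L\*/∂r| about a center point, computed from a
  σ = 2 px Gaussian-smoothed L\* plane; the center defaults to the centroid
  of the brightest L\* quartile and is overridable. Radial projection
  suppresses edges not oriented across the viewing axis of the tongue.
* **GVF** — the Xu–Prince diffusion of the (peak-normalized) edge-map
  gradient, explicit scheme with dt = min(0.25/μ, 0.9/max|∇f|²) for
  stability; defaults μ = 0.2, 80 iterations. The same diffusion applied to
  the edge map itself yields a smooth *potential* surface used as the
  snake's external energy (the raw edge map is flat away from the ridge
  flanks and cannot monitor progress there).
* **Snake** — semi-implicit evolution with cyclic pentadiagonal internal
  stiffness (tension α = 0.1, rigidity β = 0.05), external force = κ × GVF
  field interpolated at the vertices (κ = 5; the field is unit-normalized,
  so without the weight the force scale would sit at the convergence
  tolerance and weak-field regions would stall). Steps that raise the
  energy (internal + negative potential) are retried with a halved time
  step, making the energy non-increasing across accepted iterations; the
  evolution stops when the maximum vertex displacement drops below 0.1 px
  or after 300 iterations. Vertices are clamped to the image; the interior
  is rasterized by the even-odd rule on integer pixel centers.
* **Initialization** — boundary of a saliency mask: Otsu threshold on the
  smoothed a\* plane (the tongue is the large reddish blob; L\* is used as
  fallback when chroma is flat), largest connected component, hole fill,
  2 px dilation, resampled to 120 vertices. A near-boundary initialization
  is what makes the snake robust: the GVF capture range at 80 iterations is
  roughly √(2·μ·dt·n) ≈ 6 px.

Failures (no luminance contrast, self-intersecting contour, empty interior)
raise a segmentation error so the caller can fall back to a manual mask;
automatic and manual masks merge as (auto ∪ add) \ remove.

## Exclusion

Two artifact classes inside the tongue carry no usable color: the dark band
at the tongue root (low illumination) and specular saliva reflections. Both
are removed by lightness thresholds on the *corrected* L\* (configurable to
raw): pixels with L\* < 30 or L\* > 85 are excluded; equality is retained.
The per-cause counts always partition the tongue mask and are reported with
every result.

## Color correction

Each image carries a 12-patch checker: 6 achromatic patches calibrate L\*
and 6 chromatic patches calibrate a\* and b\*, one ordinary least-squares
affine map per coordinate fit from patch means (reference on measured).
This per-coordinate form follows directly from the achromatic/chromatic
patch split; a joint affine 3×3 cross-channel fit over all 12 patches is
available behind a flag for devices with channel cross-talk. Corrected L\*
is clipped to [0, 100] with a reported count; a\*, b\* are unclipped. The
checker's reference values are a required configuration input; the package
ships a synthetic default card (grays L\* = 20…95; six saturated
primaries/secondaries) used by the phantom generator. Exclusion runs after
correction, but the fit itself uses only checker pixels, so the
segmentation → correction → exclusion order does not affect the fitted
coefficients.

## The histogram and variables

Bins are half-open rectangles [v, v+width) — the only convention under
which 4 lower bounds with widths 5 (L\*) and 6 (a\*) tile each axis into 4
ranges; the upper lattice boundary is exclusive. The normalization
denominator is the post-exclusion valid-pixel count (excluded pixels are
declared measurement artifacts; a pre-exclusion denominator is available by
flag). Pixels outside the lattice remain in the denominator but are counted
in no bin, so the 16 proportions sum to ≤ 1.

The default V1–V7 assignment (see README) satisfies the defining ordering
constraints — V1–V4 in the low-a\* half, V5–V7 in the high-a\* half, V7
maximal in both axes, V1 minimal in L\*, V3's a\* below V5's and V7's — and
is validated on load with the violated constraint named; it is a
configuration choice and is flagged as such in output metadata. VR = V7/V3
is NaN (with a warning) when V3 = 0, and undefined ratios are dropped from
downstream summaries.

## Statistics

* **Lilliefors KS** — KS distance against a normal with sample-estimated
  mean/SD; p from a Monte-Carlo null (default 10⁴ replicates) seeded from
  the sample size only and cached per size, so repeated calls are cheap and
  deterministic. p ≥ 0.2 is reported as the lower bound "0.200" with a
  flag, the convention of packaged significance tables.
* **Shapiro–Wilk** — delegated to scipy (3 ≤ n ≤ 5000).
* **Mann–Whitney U** — mid-ranks, tie-corrected variance,
  continuity-corrected two-sided normal approximation; full enumeration of
  all C(n+m, n) group assignments (ties handled through ranks) whenever
  n·m ≤ 64, so small-sample p values are exact. The worst-case gap between
  the approximation and the exact tail falls below 0.02 once both samples
  have ≥ 5 values; below that the exact path is always taken (the
  approximation's worst case reaches ≈ 0.13 at n = 1–3, which no tolerance
  on the approximation itself can fix).
* **Paired comparison** — one-sample Student's t on per-subject visit
  differences; "two-sample paired t" is the same statistic algebraically
  and is implemented once.
* **Routing** — per variable, both normality tests run per group; the
  comparison is Mann–Whitney if any group fails either screen at α = 0.05,
  otherwise a pooled-variance two-sample t. Summaries are median (IQR) on
  the nonparametric route and mean (SD) on the parametric route, mirroring
  the standard reporting layout. No multiple-testing correction is applied
  by default (seven raw p values); Bonferroni and Benjamini–Hochberg are
  options. Constant variables are reported as per-variable test errors
  without aborting the batch.

## Classification

Stratified seeded 10-fold cross-validation (stratification is required: at
a 402:52 imbalance an unstratified fold can lose the minority class) of
Gaussian Naïve Bayes, KNN (k = 5, Euclidean, standardized features) and an
RBF-kernel SVM (C = 1, standardized features). These hyperparameters are
textbook defaults, chosen once and exposed in the spec object; accuracy is
the mean held-out fraction correct with per-fold detail reported.

## Synthetic data

The phantom generator renders, in Lab and through the inverse color
conversion (so recovery tests exercise the color-space code): an elliptical
tongue whose body pixels are drawn from a configurable mixture over the 16
TDCH bins; a paler low-a\* coating patch in the upper body; specular spots
(L\* = 92) and a dark root band (L\* = 22) covering ~12% of the tongue
height; the 12-patch checker strip; and a per-coordinate affine "device"
distortion of the whole image (defaults: slopes 0.92/0.95/0.90, intercepts
3/1/−1.5). In-bin color jitter (σ = 1) is truncated 0.75 Lab units inside
bin edges so 8-bit quantization cannot flip a pixel's bin — pipeline error
against the known mixture is then purely multinomial. All truths (masks,
per-pixel bin assignment, checker geometry) are exact by construction, and
generation is byte-for-byte seed-deterministic. Out-of-gamut specs are
rejected with the count of offending pixels.

The cohort generator draws each variable from a Beta distribution whose
median and IQR are root-solved to match the target group summaries; the
default parameters are clinically plausible area proportions at the study's
scale (402 normal, 52 sleep-disorder subjects; 18 paired subjects with a
Gaussian-copula within-subject correlation of 0.7) with the characteristic
effect pattern — coating variables V2, V4 higher and tongue-body variables
V5, V7 lower in the sleep-disorder condition. Matching medians (not means)
matters: the families are skewed, and the effect directions are defined on
medians.

What the phantoms do *not* model: papillae texture and specular micro-
structure, vignetting or spatially varying illumination, non-affine device
color error, checker localization error (patch geometry is known exactly),
and any physiological coupling between coating area and body color. Passing
tests therefore demonstrate correctness of the computational chain and its
statistical calibration under these stylized conditions, not clinical
performance on real photographs.

## Problem sizes and runtime choices

Test and acceptance runs use sizes chosen to make every check cheap and
repeatable: 200×224 phantoms (≈15k tongue pixels) for segmentation, one
440×470 phantom (≥10⁵ valid pixels) for the multinomial-recovery bound,
100 random 18×18 rasters for the histogram oracle, 200 seeded replicates
for type-I calibration and direction recovery, and 2×10³–10⁴ Monte-Carlo
replicates for Lilliefors nulls (cached per sample size). The full
acceptance script completes in well under a minute on one CPU.

## Known limitations

* The polar edge operator is a radial L\*-gradient; published "combined"
  polar edge variants mix several channels/operators whose exact recipe is
  not reproduced here.
* Segmentation assumes one tongue-like blob; multiple red regions of
  similar size would mislead the saliency initialization.
* The Lilliefors Monte-Carlo p is itself stochastic (though seeded); at the
  default 10⁴ replicates its standard error near p = 0.05 is ≈ 0.002.
* The exclusion thresholds are interpreted on corrected L\* by default;
  applying them to raw L\* is supported but changes which pixels survive
  when the device distortion is strong.
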