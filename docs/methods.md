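# Methods

This note documents the models, parameter choices and numerical
conventions behind `phenoseed`, and what the synthetic scenes do and do
not establish about behaviour on real images.

## The measurement problem

A belt-fed imaging chamber photographs one singulated seed per frame: a
top-down view of the seed on a white conveyor, plus a partial side view
reflected in a prism mounted beside the lane. From each frame the
pipeline extracts seed size (major/minor axis, height, area, perimeter,
volume, surface area), three dimensionless shape indices, per-channel
coat-colour statistics in CIELab, and a two-cluster description of coat
patterning. Analysis splits into *preprocessing* (colour calibration,
cropping, segmentation — expensive, cacheable) and *main processing*
(measurement — cheap, re-runnable from the cached intermediates).

## Colour calibration

Machine-vision cameras deliver RGB that is neither linear nor
perceptual; in our synthetic distortion model (and in typical hardware)
the chroma response is attenuated to roughly 60% and each channel has a
power-law tone curve. Two calibrations are fitted from colour-checker
patch images:

* **Affine RGB→RGB baseline** — ordinary least squares from measured
  scaled RGB to the reference colour in scaled sRGB, followed by the
  standard sRGB→L\*a\*b\* conversion (D65, 2° observer). The offset term
  is included: it costs nothing and absorbs black-level shifts.
* **MLPR** — a multi-layer perceptron regressor mapping scaled RGB
  directly to L\*a\*b\*, folding the nonlinear camera inverse and the
  nonlinear colour-space transform into one learned function.

Each 200×200 patch is summarised by channel-wise medians of 50
contiguous 800-pixel regions (10 block-rows of 20 px × 5 block-columns
of 40 px — an exact tiling), giving robustness to isolated noisy pixels
and 50 samples per swatch; 117 swatches yield 5850 samples. The split is
70% training pool / 30% test, with 10% of the pool held out for
validation; sizes use exact integer floors (`7n//10`, `pool//10`) so
counts are reproducible.

MLPR architecture: one hidden layer of 100 rectified units, Adam, squared
error on L\*a\*b\* (equivalent to minimising CIE76² — CIEDE2000 is not a
practical training loss), at most 2000 epochs in chunks of 100 with early
stopping when the validation CIE76 has not improved for 4 chunks; the
best-validation weights are restored. The dataset is small and the target
smooth, so a single hidden layer suffices: on the default distorted
camera the held-out mean CIEDE2000 is ≈1.1 (vs ≈7.4 for the affine
baseline and ≈19.6 uncalibrated).

Colour differences use CIE76 (Euclidean) and CIEDE2000 (kL=kC=kH=1) as
implemented in scikit-image; the implementation is pinned in tests
against the published worked-example pairs of the CIEDE2000 standard to
1e-4.

## Size calibration

A millimetre ruler imaged flat on the belt and at the near/far edges of
the prism lane provides three pixel-pitch fits: a Sobel derivative along
the ruler axis is summed across the tick marks, the positive peaks
(white→dark edges) are refined with a three-point parabolic fit, and
cumulative nominal distance (k·1 mm) is regressed on peak position by
OLS. Synthetic rulers with 1 px blur and 2/255 noise recover the slope
within 0.1% with R² > 0.9999.

Side-view magnification depends on the seed's distance from the prism,
proxied by the column of the longest vertical run of the top mask. The
side scale is interpolated linearly in that column between the near and
far fits and **clamped** outside the endpoints — extrapolation could
produce runaway or negative scales for masks near crop edges. At pixel
resolution the longest-run argmax is a plateau (the flat top of an
ellipse), so the lower median of the maximal columns is used: the
plateau centre for symmetric masks, deterministic for any tie pattern.

Physical lengths use slope × pixel length only; the fitted intercept is
retained for diagnostics but never added to a measurement.

## Segmentation

Frames are calibrated to L\*a\*b\* and cropped into the two views. The
segmentation channel is

    M = scale01(|a*|) + scale01(|b*|) − 0.5·scale01(L*)

with per-view min-max normalisation (a constant channel maps to zeros).
Chromatic seeds stand out through |a\*| and |b\*|; dark neutral seeds
remain separable because the white belt dominates L\*, and the 0.5
factor keeps dark belt specks from flipping the threshold. M is
rescaled to [0,1], thresholded by Otsu's method on a 256-bin histogram,
interior holes are filled, and the largest 8-connected component is
kept (background implicitly 4-connected). Masks touching their view
border mean the seed was not fully in the crop — typically not fully
reflected in the prism — and the frame is rejected with a stage-named
reason rather than mismeasured.

Four intermediate items are saved per accepted frame: the calibrated
L\*a\*b\* crop (float32 TIFF), both 1-bit masks (PNG), and the midline
column (JSON). The crop covers the top-view seed bounding box plus a
4 px margin: only top-view colour feeds the downstream statistics, and
storing the dead gap between the views would defeat the purpose of
cropping. For nominal seeds the record is ~15–30% of the raw frame.

## Morphometry

Top-mask area is the pixel count; major/minor axes come from the
second-central-moment ellipse; the perimeter uses the Crofton estimator,
which is accurate to a few tenths of a percent on smooth rasterised
shapes — boundary-step counting over-reads a circle's perimeter by ~5%
and would bias circularity down to ~0.90 for a perfect circle. Height is
twice the longest perpendicular segment from the side-view midline to
the top edge of the side mask (the prism reflects only the upper half of
the seed).

The seed is modelled as a tri-axial ellipsoid with semi-axes
(major/2, minor/2, height/2). Volume is (4/3)πabc; surface area uses the
Thomsen approximation with p = 1.6075 (≤ ~1.06% error, verified against
a quadrature oracle in tests). The shape indices are

    roundness   = 4A / (π·major²)
    circularity = 4πA / P²
    sphericity  = π^(1/3)·(6V)^(2/3) / SA

each 1 for a perfect circle/sphere. Sphericity is written with the
(6V)^(2/3) factor of the standard definition; without the 6 the index of
a sphere would be ≈0.21, contradicting the 0–1 normalisation. Indices
are clipped to [0,1] only against numerical overshoot (≤1e-9); larger
violations raise.

## Coat colour and patterning

Colour statistics (mean/min/max/sd per channel) are computed over the
top-view seed pixels after eroding the mask by 2 px: the anti-aliased
boundary ring consists of seed/belt colour mixtures that would otherwise
form a fake bright mode in the colour distribution.

Patterning is described by clustering the L\*a\*b\* pixels into two
groups: a Gaussian mixture (full covariance, k-means++ init, reg 1e-6,
≤200 EM iterations, tol 1e-4) fitted to a 10% subsample without
replacement, then used to label all pixels. K-means is available for
comparison only. On a unimodal (single-colour) coat, K-means must still
split the cloud and reports a centre separation of ~1.6σ, while the
GMM's overlapping components keep their means nearly coincident — so the
CIEDE2000 distance between centres classifies the seed: below the 2.3
JND → single-coloured; above 10 → patterned; the band between is
reported as indeterminate, since no principled decision rule exists
there. Reports are normalised so the higher-population cluster is first.

## Synthetic scenes

The generator renders the same three target kinds the hardware images:
colour-checker swatches, rulers/cylinders, and seeds, each with exact
ground truth.

* Geometry: 2200×1500 frames; default scales 0.0094 mm/px (top), 0.0093
  (near side), 0.0101 (far side) with depth endpoints at columns
  1000/2200 — representative belt-camera values. Objects are rasterised
  at 4× supersampling with box down-sampling, so edges carry sub-pixel
  information; without anti-aliasing the 0.02 mm cylinder validation
  would not be attainable.
* Camera: clip(M·rgbᵞ + noise) on scaled RGB. The default distortion is
  γ=2.2 per channel, M = 0.6·I + 0.4/3·𝟙 (grey-preserving, ~60% chroma
  response) and noise sd 1/255.
* Chart: a 10×14 grid (140 swatches) with greyscale first row and
  column; dropping both leaves the 117 chromatic swatches used for
  calibration datasets.
* Seed coat: base colour typical of a brown lentil (L\*45, a\*18,
  b\*28), optional spot/marble pattern from thresholded filtered noise,
  cosine-law rim shading (3 L\* at the rim — domed seed under diffuse
  light) and a smooth mottle texture (L\* sd 1.8, quarter-strength on
  a\*/b\*) emulating coat granularity. Together with sensor noise this
  gives the ~2 L\* unimodal within-seed spread under which the
  GMM/K-means contrast above reproduces.
* The side view uses the same linear depth model the analysis assumes,
  so calibration recovery is exact by construction; the seed's height
  and column placement can be varied to test rejection behaviour.

What the synthetic scenes do **not** model: physically based lighting,
motion blur, lens distortion or defocus, debris and broken seeds,
specular highlights, and inter-seed occlusion. Passing tests therefore
demonstrate the correctness of the measurement chain under the stated
image-formation model, not robustness to every artefact of real
hardware; colour-model accuracy on a real camera depends on how well its
response is covered by the chart gamut.

## Problem sizes and determinism

Single-frame fixtures use full 2200×1500 frames; batch tests use a
half-resolution layout (1100×750, ~0.019 mm/px) with 6 frames across 2
samples — enough to exercise discovery, rejection, caching and
parallelism. Every stochastic step takes an explicit seed; per-seed RNG
seeds are derived as crc32 of the frame identity mixed with the base
seed (always < 2³¹), making batch results byte-identical for any worker
count. The acceptance script regenerates all scenes from scratch and
reruns the calibrations; its slowest step is MLPR training (~1 minute on
one CPU).

## Known limitations

* The prism geometry is self-consistent but not a metric replica of any
  particular hardware build; defaults are illustrative.
* One frame is assumed to contain exactly one seed (the hardware
  singulates); multi-seed frames will be measured as their largest blob.
* Classification of pattern *type* (spotted vs marbled) and cluster
  morphology features are out of scope.
* The MLPR can under-fit very dark colours (L\* ≲ 20) where the gamma
  curve is steepest; the training report records per-variant test error
  so such regressions are visible.
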