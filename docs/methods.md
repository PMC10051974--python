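# Methods

## Problem and pipeline

A digitized TMA core is a circular tissue disc on a light, near-achromatic
background. `tmaseg` segments such an image into background (code 0), tumor
(2) and non-tumor tissue (3) by classifying SLIC superpixels described with
texture features, then reassembling the per-superpixel predictions into a
label image. The pipeline has three phases — pre-processing, feature
extraction, machine learning — each exposed as an independent module so any
stage can be run, inspected and tested in isolation.

The label code 1 is deliberately unused: the three-code set {0, 2, 3} is the
convention of the annotated data this package models and is preserved
verbatim throughout (validation, PNG round trips, colorization).

## Pre-processing

* **Rescale** — bilinear, output dimension `max(1, round(d·factor))`.
  Native cores (~6000×6000) are worked at 25% (~1500×1500): tissue-level
  texture survives, per-image cost drops ~16-fold.
* **Normalization** — linear stretch of the (s, 1−s) intensity quantiles to
  (0, 255), clipping outside; default saturation s = 0.0035 per channel (the
  ImageJ enhance-contrast convention). A constant channel is a warned no-op.
* **Histogram equalization** — classical 256-bin mapping
  `out(v) = round((cdf(v) − cdf_min)/(N − cdf_min)·255)` per channel. For a
  full-support ("continuous") noise image the output CDF is uniform to
  within one bin in Kolmogorov distance; for images whose histogram has
  bins heavier than 1/256 the residual distance equals the heaviest bin
  mass (equalization cannot split a bin).
* **Histogram matching** — `m(v) = G⁻¹(F(v))` with empirical CDFs and G⁻¹
  taking the smallest intensity reaching the target mass. Matching an image
  to itself is exactly the identity. The reference defaults to the first
  image of the set; any image can be passed instead.
* **Rounding** is half-up to integers, everywhere, defined once
  (`_util.round_half_up`) and tested.
* Order of operations defaults to rescale → enhance; both stages are pure
  functions, so the opposite order is available by composing them manually.

## SLIC superpixels

Localized k-means over joint color+position. Centers initialize on the
centroids of a regular ⌈H/S⌉×⌈W/S⌉ grid; each pixel is assigned to the
nearest center within a (2S+1)² search window under

    D = d_color + (m/S)·d_xy,   m = 40·r

with Euclidean distances on each term; centers then move to the mean of
their members for a fixed 10 iterations (a fixed cap, not a convergence
tolerance, so runs are exactly reproducible). `r = 0` gives purely
color-driven ("very elastic") regions and `r = 1` near-square tiles on 8-bit
data; the factor 40 is the single documented constant making that range
span those regimes. Color distance is measured in an opponent space
(orthonormal transform: intensity (R+G+B)/√3, red–green (R−G)/√2,
yellow–blue (R+G−2B)/√6); `color_space="rgb"` switches to plain RGB.

After the iterations, connected components of each label smaller than S²/4
are merged into their largest 4-adjacent superpixel (smallest fragments
first) and ids are compacted to 0..K−1, so every superpixel is 4-connected.
On a constant image the procedure reduces exactly to the nearest-grid-
centroid Voronoi partition (e.g. nine 30×30 blocks on a 90×90 image at
S = 30), which is the oracle used in tests.

Two regimes bound what regularization can do: when per-pixel color noise is
far larger than m (heavily speckled texture), superpixels fragment and the
connectivity merge dominates the final partition — K can fall well below
(H·W)/S²; at moderate noise K stays within ±25% of that count and mean
isoperimetric compactness (4π·area/perimeter²) grows monotonically with r.
Tests pin both behaviours with fixed-seed fixtures.

## Texture features (69 per superpixel)

Each RGB channel contributes 23 features.

**17 first-order statistics** (multiset of member intensities only): mean,
population variance, standard deviation, skewness, excess kurtosis, energy
(mean squared intensity), RMS, Shannon entropy (base 2, 256 bins), min, max,
median, range, mean absolute deviation, 25th and 75th percentiles, IQR, and
coefficient of variation (std/mean, 0 at mean 0). Skewness and kurtosis are
defined as 0 for constant regions. The exact member list is frozen in a
name registry (`texture.feature_names`) so tables from different runs are
column-compatible.

**6 Tamura features**, computed on the superpixel's bounding-box crop with
non-member pixels filled by the member mean (mean-fill avoids leaking the
neighboring class's texture into the descriptor — the alternative of
computing on the raw crop was rejected for exactly that reason):

* *coarseness* — per pixel, the window size 2^k (2^k ≤ min(crop)/2)
  maximizing the difference of 2^k-window averages taken 2^(k−1) apart
  horizontally or vertically; the feature is the mask mean of the best
  sizes. Crops too small for any window score 1.
* *contrast* — σ/α₄^¼ with α₄ = μ₄/σ⁴ over member intensities; 0 at σ = 0.
* *directionality* — 1 − normalized entropy of the 16-bin gradient-
  orientation histogram (Sobel, orientations mod π) over member pixels with
  gradient magnitude above the member median; 0 when no pixel qualifies
  (e.g. constant regions).
* *line-likeness* — mean cos(θ_p − θ_q) over qualifying pixels p paired
  with the pixel q four steps along p's gradient direction, when q also
  qualifies; 0 with no valid pairs.
* *regularity* — 1 − mean normalized spread of the first four features over
  a 2×2 partition of the crop, with spread normalized as
  std/(std + |mean|) ∈ [0, 1); 0 for crops under 8×8. The normalization is
  a package choice (the classical weighting constant is data-dependent and
  unspecified); it keeps the feature dimensionless and bounded.
* *roughness* — coarseness + contrast.

First-order features are permutation-invariant within the mask (up to float
summation order); Tamura features are spatial and are not.

## Ground truth and class assignment

Tumor polygons (ImageJ `.roi`, polygon subtype only) are rasterized with a
scanline fill that includes boundary pixels. Background is detected from
the image — brighter than the Otsu threshold of the grayscale mean AND
channel spread (max−min) < 20 — and takes precedence over the polygons, so
a polygon sloppily including background does not poison the tumor class.
Superpixels take the plurality class of their member pixels; ties break by
the fixed priority tumor > non-tumor > background, biasing toward
sensitivity in a diagnostic-support setting (configurable). The
superpixel-resolution ground truth (`quantized_label_image`) replaces each
pixel by its superpixel's majority class; with 3 classes the plurality
guarantees per-superpixel agreement ≥ 1/3 with the raw labels (≥ 1/2
whenever at most two classes meet inside a superpixel, the common case).

## Classifiers and evaluation

The five families are deterministic-seeded scikit-learn analogues of the
classical implementations: random forest (100 trees, √p features per
split), SVM (RBF, features standardized inside the fold-fitted pipeline),
LogitBoost-style additive logistic regression (gradient boosting with
depth-1 stumps and log loss), an entropy-criterion tree with
cost-complexity pruning (C4.5 analogue), and Gaussian naive Bayes (the
minimal Bayesian network). They are analogues, not bit-compatible replicas.
Identifier/position columns are never used as predictors.

Metrics are one-vs-rest per class (PPV, TPR, F1, with a 0 convention for
empty denominators), multiclass accuracy, and macro-averaged F1 (weighted
F1 is reported alongside; macro is the default because per-class F1 is
defined one-vs-rest). Cross-validation is grouped at the image level: one
fold per image, training on the rest, so superpixels of one image never
straddle a split; with 10 images each fold trains on 9. Fold assignments
are recorded in the report.

## Synthetic study data

The generator emulates a digitized core: a centered circular disc
(radius 0.45·size) on light-gray background (220 ± 3 shared luminance
noise, chroma jitter clipped so channel spread stays below the 20-level
background rule), smooth pink non-tumor tissue (base (205,165,175),
low-frequency noise sd 8) and dark, heavily speckled tumor (base
(150,100,60), per-pixel sd 35). Tumor regions come from thresholding a
smoothed Gaussian random field plus one Gaussian bump per blob seed
(default 4), with the threshold set at the disc quantile matching the
target tumor fraction (default 0.35) — boundaries are irregular, the
fraction is exact up to quantile granularity, and the label image is exact
by construction. Default image size is 512 (a scaled-down core that keeps
the full study — 10 images, superpixels, 69 features, cross-validation —
comfortably on one CPU); per-image seeds are base_seed + index.

Separability is by construction: the blue channel separates tumor from
non-tumor means by ≥3 of the larger class standard deviation
(|60−175| ≈ 3.3·35), which is what makes ≥0.90 cross-validated recovery a
fair acceptance bar for every classifier analogue. What passing these tests
does **not** show: robustness to stain variability, nuclear-scale texture,
tissue folds, out-of-focus regions or annotation noise — none of which the
generator models. Results on real cores will be lower and require real
annotated data.

## Known limitations

* No post-processing of segmentations (small misclassified islands remain).
* ROI support is polygon-only; composite/oval/freehand ROIs and ROI zip
  sets are rejected.
* No stain-normalization methods (Macenko/Reinhard) — the three global
  enhancement transforms are the only photometric corrections.
* Multi-expert label fusion is out of scope; one marking per image.
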