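# Methods

## Acquisition model

The pipeline assumes chamber acquisition: a dark, uniform background, fixed
camera and lighting, and two frames per sample — the empty chamber and the
chamber with the fruit. Segmentation is therefore two-frame differencing: a
pixel is foreground iff the channel-summed absolute difference exceeds a
threshold *T* (default 30 on the 0–255 scale). The absolute value matters:
a signed difference cannot detect objects darker than the background. The
threshold, like every other knob, lives in `PipelineConfig`.

## Preprocessing

**Rank-order filter.** A sliding window (default 3×3) replaces each pixel
by the *r*-th smallest value in the window; *r* = 5 of 9 is the median,
which removes salt-and-pepper impulses without smearing edges. Higher ranks
brighten, lower ranks darken; output is monotone in *r*. Borders use
reflect (edge-symmetric) padding so the output size equals the input size
and no dark frame contaminates downstream color sums. By default only the
sample frame is denoised — the empty-chamber frame is acquired clean — but
`denoise_background=True` filters both.

**Mask cleanup.** Frame differencing on noisy frames leaves speckle, so
8-connected components below `min_component_area` (default 64 px) are
dropped and only the largest surviving component (the fruit) is kept. The
mask is then eroded by `mask_erosion_px` (default 3): camera blur blends the
fruit rim with the near-black background, and those mixed pixels would
otherwise form a spurious dark "cluster" and bias the color fractions.

## Features

**Color fractions** are each channel's share of the total masked intensity,
in percent; they sum to 100 by construction. Ripening moves mass from the
green channel to red, so the triple (R%, G%, B%) carries most of the
maturity signal.

**Local entropy** is the Shannon entropy, in bits, of the gray-level
histogram inside a window (default 9×9, 256 levels) around each foreground
pixel. Window contents outside the mask are excluded, otherwise the zeroed
background would inject a spurious gray level at the rim. A constant patch
has entropy exactly 0; the maximum possible value is
log₂(min(levels, window²)) ≈ 6.34 bits for the defaults. The texture
quality coefficient is the mean of the entropy extrema over the fruit. The
windowed pass is computed only on the mask's bounding box (plus a margin of
window⁄2), which is exact and several times faster on 640×480 frames.

**Pattern-weighted area** zero-pads the binary image by one pixel so every
pixel lies in exactly four 2×2 windows, then sums one weight per window:
0 (no on pixels), ¼ (one), ½ (two adjacent), ¾ (two diagonal), ⅞ (three),
1 (four). A single isolated pixel scores 4 × ¼ = 1. The estimate is
translation-invariant and monotone under adding on-pixels. In the pipeline
the binarization input is the grayscale segmented image thresholded by
Otsu's criterion (a fixed threshold is available for reproducibility).

**Chromaticity clustering.** Foreground pixels are converted to CIELAB
(sRGB primaries, D65 white) and clustered with hand-rolled Lloyd k-means,
k = 4 by default. Clustering runs on (a\*, b\*) only so that lightness
variation does not dominate; full-Lab mode is available. Initialization
draws k distinct foreground pixels from a seeded generator; empty clusters
are re-seeded at the point farthest from its centroid (which strictly
decreases the objective); iteration stops when the assignment is stable, so
the returned means are exactly the centroids of their members and the final
assignment is a fixed point. With more than 20,000 foreground pixels a
subsample is clustered first as a warm start and the result refines on the
full data — the fixed-point guarantee is unaffected. Everything is
deterministic given the seed.

**Lesion descriptors and the shading model.** The largest cluster is taken
as the base fruit color. Deciding whether another cluster is a lesion
cannot use raw a\*b\* distance: CIELAB chroma is not invariant to intensity
scaling, so the shaded rim of a saturated red fruit sits ~20 Lab units from
its lit center. Instead each cluster is compared against the base color's
*shading arc* — the Lab images of s·rgb_base for gains s in
[0.55, 1/0.55], the full rim-to-center illumination ratio of a convex fruit
under frontal light. Clusters more than 12 Lab units from every point of
the arc are lesion candidates. Their union yields nine descriptors:
relative coverage, mean L\*/a\*/b\*, mean chroma (gray mold is nearly
achromatic), L\* spread (white halos around dark centers), log component
count and log median component size after discarding fragments under 3 px
(many tiny specks vs few large blotches), and a ring score — the hole
fraction of the largest component, high for concentric-ring lesions.

## Classifiers

All four are implemented from their defining equations on numpy/scipy
linear algebra; scikit-learn appears only in the test suite as an agreement
oracle.

- **PCA** eigendecomposes the ddof-1 covariance of centered data, so the
  eigenvalue sum equals the total variance exactly; components are sorted
  by descending eigenvalue with a deterministic sign convention.
- **LDA** solves the generalized eigenproblem S_b v = λ S_w v for the
  projection directions and classifies by linear scores derived from the
  class means, pooled covariance, and priors. Singular within-class scatter
  is regularized by ε·I with ε = 10⁻⁶·trace/p (escalating tenfold until
  positive-definite).
- **QDA** stores per-class mean, covariance Σ_k = (1/n_k)Σ devᵀdev, and
  prior n_k/n, and minimizes
  (x−μ_k)ᵀΣ_k⁻¹(x−μ_k) − 2 log π_k + log|Σ_k|. The 1/n_k normalization is
  deliberate (it is the stated estimator); reference implementations using
  1/(n_k−1) agree except within O(1/n) of the boundary.
- **KNN** (default k = 5) votes among the k Euclidean-nearest training
  points; vote ties break to the nearest neighbor among the tied classes,
  distance ties to the lower training index, so predictions are fully
  deterministic.

**Decision layer.** Each task (maturity, health, disease) trains a
`TaskModel`: a feature sub-vector selection, a z-score standardization
learned from training data (raw features mix percentages, bits and pixel
areas, so unscaled Euclidean distances would be meaningless), an optional
PCA reduction, and one of the classifiers — KNN by default, the most robust
choice on ~100-sample training sets; LDA/QDA/PCA+KNN are selectable.
Maturity uses the color/entropy sub-vector; health the full 24-vector;
disease the nine lesion descriptors, trained on infected samples only.
Models serialize to versioned JSON — text, portable, byte-deterministic.

## Synthetic data generator

The generator renders what the acquisition model assumes: a uniform dark
background (RGB 6, 6, 8) and a shaded ellipsoidal fruit (semi-axes ~150×180
px on a 480×640 canvas) whose base color follows the ripening trajectory
green (60, 140, 50) → yellow-orange (210, 140, 45) → red (180, 30, 25).
The trajectory passes through a "turning" waypoint because real tomatoes
ripen through orange — a straight green-to-red RGB blend would pass through
a desaturated gray-brown no fruit shows. Radial shading multiplies the base
color by 1 − 0.45ρ² (gain 0.55 at the rim), and a bounded per-pixel jitter
(σ = 2.5, clipped at ±7) provides surface texture so entropy features are
non-degenerate.

Five disease archetypes render their characteristic morphology with fixed,
documented constants: early blight (dark center disk plus concentric
annuli at radii ~12/19/26 px), late blight (clumps of overlapping brown
disks), bacterial canker (2–4 px dark centers with 2–3 px pale halos),
gray mold (clumped achromatic gray disks), bacterial speck (hundreds of
1–2.5 px dark dots). Lesions are drawn unshaded, sized to a target fraction
of fruit area (default 0.10; specks 0.02–0.05, matching their tiny physical
size), and clipped to the fruit. Sample-frame noise is Gaussian blur
(σ = 0.6) plus salt-and-pepper impulses (p = 0.002). Every sample's pixels
and annotations are a pure function of its seed; dataset seeds spawn one
independent stream per sample index, so partial regeneration is stable.

What the generator does **not** emulate: specular highlights, stem and
calyx, shadows cast on the background, camera vignetting or chromatic
noise, natural skin mottling, and the ten further diseases of the field
taxonomy (their labels exist but are not rendered). Passing tests therefore
demonstrate the pipeline's correctness and its discrimination power under
the stated acquisition model, not field robustness on real produce.

## Benchmark protocol

The headline number (scripts/acceptance.py) replicates the study
composition: 62 healthy and 38 infected samples per dataset at 640×480,
ten generator seeds, stratified 70/30 train/test split per seed, default
pipeline configuration, mean held-out healthy-vs-risky accuracy over the
ten seeds. One dataset takes ~40 s to process on a single core.

## Numerical choices and degenerate inputs

- All window operations preserve image dimensions (reflect padding).
- Otsu binarization of a constant image returns an all-off result rather
  than failing.
- Empty segmentation produces a structured report with null labels and a
  diagnostic, not an exception, at the CLI level; library calls raise
  `EmptyRegionError`.
- k-means requires at least k foreground pixels; with identical pixels the
  empty-cluster repair can leave genuinely empty clusters (a measure-zero
  case for noisy renders).
- Reports are timestamp-free by default so identical inputs produce
  byte-identical outputs; a wall-clock stamp is opt-in (`--timestamp`).
- Assignment ties everywhere (k-means, KNN, LDA/QDA argmax/argmin) resolve
  to the lowest index, making every fit and prediction reproducible.

## Known limitations

- The disease head separates the five rendered archetypes at roughly 80–85%
  on held-out synthetic data; gray mold vs canker (both light, low-chroma)
  is the main confusion.
- Brown blotches on orange ("turning") fruit are chromatically close to
  deep shadow; the shading-arc rule recovers most but not all such lesions
  — the residual errors in the health benchmark are of this kind.
- Maturity labels come from color balance, so heavy lesion coverage on a
  green fruit can shift the apparent stage.
- JPEG input is accepted but lossy; PNG/TIFF round-trip bit-exactly and are
  preferred.
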