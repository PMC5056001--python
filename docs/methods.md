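# Methods

## Overview

`gaborvessel` detects and segments tubular, vessel-like structures in
angiogram-style grayscale images in three stages:

1. **Enhancement.** The image (inverted so vessels are bright) is convolved
   with a bank of κ oriented single-scale Gabor kernels; each pixel keeps the
   maximum response over orientations.
2. **Training.** The two free bank parameters — average thickness τ
   (integer, pixels) and elongation l (real) — are chosen to maximize the
   area A_z under the ROC curve of the concatenated training-set responses,
   either by the BUMDA estimation-of-distribution optimizer or by an
   exhaustive grid search.
3. **Segmentation.** The real-valued response is quantized to 8 bits and
   thresholded at the gray level maximizing the interclass (between-class)
   variance of the histogram; pixels above the threshold are vessel.

## The Gabor bank

The kernel is a Gaussian envelope modulated by a cosine,

    g(x, y) = 1/(2π σx σy) · exp(−(x²/σx² + y²/σy²)/2) · cos(2π f0 x),

rotated by evaluating g at analytically rotated coordinates (no image-space
resampling).  The parameterization follows the single-scale vessel-detection
convention: σx = τ / (2√(2 ln 2)), so τ is the full width at half maximum of
the cross-sectional envelope; σy = l·σx stretches the kernel along the
structure; κ orientations are evenly spaced on the half-open interval
[−π/2, π/2) (half-open because θ and θ+π are the same undirected filter),
giving an angular step of 180/κ degrees.

Numerical choices:

* **Modulation frequency f0 = 1/(2τ).**  The central positive lobe of the
  cosine then spans exactly τ pixels, so the excitatory core of the kernel
  covers one structure width and the A_z-optimal τ coincides with the true
  vessel FWHM.  We verified on phantoms that the alternative f0 = 1/τ
  (excitatory lobe τ/2 wide) shifts the A_z optimum to roughly twice the
  true width, which destroys the interpretation of τ as a thickness
  estimate.
* **DC removal.**  The cosine-modulated Gaussian has a nonzero mean; it is
  subtracted after truncation so that flat backgrounds produce exactly zero
  response (and the response is invariant to adding a constant to the
  image).  Without it, the ROC analysis is contaminated by the local mean
  intensity.
* **Support.**  Kernels are truncated at ±⌈3·max(σx, σy)⌉ (odd side, exact
  center); tails beyond 3σ are below 1.2 % of the peak.  Because σy = l·σx
  can reach ~123 px at the corner of the default search box, the natural
  support can exceed a 300×300 field of view; the training objective (and
  the evaluation helpers) therefore cap the kernel half-support at
  (min(H, W) − 1)/2, clipping the elongated Gaussian tail to the image.
  `enhance()` called directly keeps the strict contract and raises if the
  image is smaller than the uncapped kernel, naming the minimum size.
* **Convolution.**  Frequency-domain, with symmetric (mirror) boundary
  padding; results agree with direct spatial convolution to better than
  1e−6 relative.  Mirror padding avoids the spurious dark-frame edge
  responses of zero padding.  Each oriented kernel is Fourier-transformed
  once and reused across all images of a training set, and the padding is
  sized per kernel radius rather than worst-case, which dominates training
  speed.

## ROC area fitness

A sliding threshold on the response classifies a pixel as vessel when its
score is at or above the threshold; the true-positive fraction against the
false-positive fraction yields the ROC curve and A_z is its trapezoidal
Riemann sum.  During training the threshold slides over 256 evenly spaced
levels spanning the response range (matching 8-bit imaging practice), plus
±∞ endpoints; tests also use exact unique-value thresholds, at which the
trapezoidal A_z equals the Mann–Whitney pairwise-concordance statistic to
machine precision.  The 256-level quantization stays within 0.01 of the
exact value.  A trapezoidal rather than left-rectangle sum is used because
the rectangle rule systematically underestimates the area of a concave ROC
curve.

The training fitness concatenates the responses of all training images into
one large sample before computing A_z, so images with more vessel pixels
weigh proportionally; the result is invariant to image order and to
duplicating the set.

## BUMDA

The Boltzmann univariate marginal distribution algorithm maximizes a
fitness g over a box.  Per generation: truncation selection keeps the top
half of the population above a nondecreasing threshold φ (never fewer than
two members); each member is weighted by ḡ(x_i) = g(x_i) − g(worst in S) + 1;
a per-dimension Gaussian is fitted with weighted mean
μ = Σ ḡ x / Σ ḡ and variance v = Σ ḡ (x−μ)² / (1 + Σ ḡ); the next
population is sampled from N(μ, v), clamped to the box; the incumbent best
replaces the worst sampled individual (elitism).  The loop stops when every
dimension's model variance is at or below v_min, or after max_generations.

Choices that matter:

* **Weight offset +1** keeps the worst elite member's weight positive and
  the estimators defined when all fitnesses tie.
* **v_min = 1e−6 (default), max_generations = 50, N = 20.**  The
  1 + Σ ḡ denominator shrinks v by roughly an order of magnitude per
  generation on smooth objectives, so v_min directly trades final accuracy
  for generations: 1e−6 yields ~8 generations and ~1e−2 accuracy on a
  concave quadratic, and ~20 generations on the much flatter A_z landscape.
  A v_min of 0.01 stops after 3–4 generations with noticeably worse optima.
* **Integer dimensions** (τ) are represented as reals, clamped and rounded
  to the nearest integer only at evaluation time.  Their convergence is
  tested against a floor of integer_v_min = 0.05 rather than v_min: within
  one rounding cell the fitness is flat, so the model variance of an
  integer dimension plateaus near 0.01 and a continuous-scale v_min would
  never trigger; a model std of √0.05 ≈ 0.22 already sends ~98 % of samples
  to a single integer.
* **Memoization** on the evaluated (clamped, rounded) coordinate makes
  resampled points free; the pipeline objective additionally rounds l to
  4 decimals for its cache key, below any fitness-relevant resolution.

## Otsu segmentation

The response is min–max rescaled to gray levels 0–255 (round half up;
constant responses map to 0).  The threshold t maximizes
ω0(t)·ω1(t)·(μ0(t) − μ1(t))² over all 256 candidates with classes
{levels ≤ t} and {levels > t}; ties take the smallest t, and foreground is
strictly above t.  The implementation is a vectorized scan verified against
a brute-force oracle and against scikit-image on bimodal data.  The
threshold is computed per image, not on the concatenated set, since test
images are segmented independently.

## Synthetic phantoms

The generator emulates the features of X-ray coronary angiograms that drive
detector behavior: dark, smoothly curving tubular structures of controlled
width and contrast on a bright background with low-frequency shading and
additive noise.  Defaults: 300×300 px, 3 vessels, FWHM 7 px, contrast 0.35
(fractional dip of the local background), background 0.7,
illumination amplitude 0.15 (random second-order polynomial field), noise
σ = 0.03, branch probability 0.3.  Centerlines are unit-step random walks
with Gaussian heading increments (σ = 0.04 rad per step), started at image
borders; the vessel profile is a Gaussian dip whose FWHM equals the nominal
width, so the phantom width and the bank's τ live on the same scale; the
ground-truth mask is exactly the set of pixels within FWHM/2 of a
centerline.  The same configuration (seed included) is byte-identical, and
datasets derive per-image seeds from the master seed, so a manifest
reproduces every file bit-exactly.

What the phantoms do **not** model: structured clutter (ribs, diaphragm,
catheters), vessel caliber variation along the centerline,
stenoses/aneurysms, projection physics, motion blur, and correlated
(quantum) noise.  Passing the synthetic benchmarks therefore demonstrates
the correctness and internal consistency of the method — not clinical-grade
performance.  Two quantitative notes: (i) with i.i.d. Gaussian pixel noise
the oriented filters average noise away very effectively, so the default
task yields A_z ≈ 0.997 — an easier regime than low-contrast clinical
images; (ii) with zero contrast the detector's AUC is chance (0.5) in the
image interior, but mirror padding damps the noise response within one
kernel radius of the border, where centerlines preferentially start, so a
whole-image zero-signal AUC sits slightly below 0.5.

## Problem sizes used by the tests and the acceptance script

The exhaustive grid (16 τ × 43 l = 688 cells) and the statistical bars are
kept at full size.  The phantom experiments run at 96×96 px with 6 training
and 6 test images and κ = 36 orientations — a single-CPU problem size; the
10° angular step is sufficient for the slowly curving phantom vessels, and
none of the acceptance thresholds are relaxed at this scale.  BUMDA training
then takes 280–480 distinct fitness evaluations (well under the 688 of the
exhaustive grid) and recovers τ within ±2 px of the phantom width, with
test-set A_z ≈ 0.99 and mean Otsu accuracy ≈ 0.96.

## Known limitations

* Single-scale: one τ per trained bank; vessels far from the trained
  thickness respond weakly (no multiscale fusion).
* The A_z landscape is extremely flat near its optimum, so the *elongation*
  found by different seeds varies (A_z differences < 1e−3); τ is stable.
* Otsu thresholding assumes a roughly bimodal response histogram; on images
  with very sparse vessels the background mode dominates and the threshold
  can over-segment.
* Whole-image evaluation (no field-of-view mask); border pixels carry
  mirror-padding artifacts within one kernel radius.
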