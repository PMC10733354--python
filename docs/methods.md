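# Methods

This note documents the models and procedures implemented in `btseg`, the
parameters that matter, the numerical choices, and what the synthetic
phantoms do and do not establish about real MRI data.

## Image model and conventions

All rasters are 2-D, 0-based `(row, col)`, row-major. Gray images carry
integer intensities in `[0, L-1]` with `L = 256` by default; loading
min-max rescales to this range (a constant image maps to 0), RGB input is
converted with the standard luminance weights. Masks are boolean, stored as
{0, 255} PNG. Denoising offers a median filter and an averaging filter
(rounded back to integer levels), both with edge replication so the border
histogram is not biased toward artificial dark values.

## Otsu thresholding

The threshold maximizes the between-class variance `sigma_b^2(k)` of the
background/foreground split at level `k` (background = levels `<= k`). Key
numerical choices:

* **Exact maximization.** `sigma_b^2(k)` is proportional to the rational
  `(N M_k - M W_k)^2 / (W_k (N - W_k))` in the integer cumulative counts
  `W_k` and first moments `M_k`. The argmax is taken with exact integer
  arithmetic, so near-ties cannot flip with floating-point round-off and
  the tie rule (smallest maximizing `k`) is unambiguous. The test-suite
  oracle is an independent exhaustive scan in exact rationals.
* **Binarization convention.** The mask rule is `g = 1 iff f >= T` with
  `T = k* + 1`, which makes the background sums `i = 0..k` consistent with
  the `>=` rule.
* **Empty classes.** Class means and variances of an empty class are
  defined as 0 (probability 0), avoiding 0/0 at extreme `k`.

### Two-stage segmentation and the contrast guard

Global Otsu assumes a bimodal histogram; a brain slice has at least three
populations (background, tissue, tumor). The pipeline therefore thresholds
twice: head vs background on the whole image, then tumor vs tissue on
brain-interior pixels only. Each stage checks the separation of the two
class means at the chosen threshold; below `min_gap` (default 25 gray
levels, roughly 5 noise standard deviations of the default phantom) the
stage reports an empty mask. This guard is what routes blank or tumor-free
images into the "no tumor" branch of the pixel-count rule: without it, Otsu
would happily split pure noise and report a spurious region.

## Wavelet transforms

The decimated 2-D DWT filters rows then columns with an orthonormal
analysis pair and keeps even indices; boundaries are periodic. These two
choices make the transform an orthogonal map on even-sized rasters, so
perfect reconstruction and energy conservation hold to round-off and are
asserted at 1e-9 rather than some loose heuristic tolerance. The
undecimated frame transform (a-trous: filters upsampled by `2^(level-1)`,
no downsampling) commutes exactly with circular shifts, so its sub-band
energies are exactly translation-invariant texture features. Haar is the
default family (hand-checkable coefficients); db2/db4 are provided. The
downsampling phase (even indices) is a free convention; the cross-check
against PyWavelets in the test suite maps between the two packages'
conventions explicitly (input reversal plus an index remap) rather than
comparing phase-dependent coefficients loosely.

Admissibility of a sampled mother function is tested numerically: finite
energy integral and a plain integral below `1e-6` times the grid span.

## Texture features

First-order statistics (mean, standard deviation, variance, RMS, histogram
entropy in bits, skewness, excess kurtosis, smoothness
`1 - 1/(1 + sigma_n^2)` with `sigma_n` the std of intensities rescaled to
[0, 1]) are computed on the segmented region, falling back to the whole
image when no region survives — the fallback keeps tumor-free images
classifiable. Skewness and kurtosis are defined as 0 for constant regions
to avoid NaN propagation into the classifier.

GLCM statistics use the standard Haralick definitions with `Ng = 32`
uniform quantization bins, distance 1, the four unit directions averaged,
and symmetric counting; "homogeneity" and "inverse difference moment" are
the same statistic here, exposed once as `idm`. Correlation is defined as 0
when either marginal variance vanishes. Wavelet sub-band energies (mean
squared coefficient; deepest approximation plus H/V/D per level, so
`3 * levels + 1` values) complete the 23-feature default vector; the frame
variant is selectable when shift invariance matters.

## PCA

Features are z-scored (constant columns get unit scale) and the sample
covariance (`ddof = 1`) of the standardized table is eigendecomposed.
Components are sorted by descending eigenvalue; each component's
largest-magnitude loading is made positive, so serialized models reproduce
bit-identically. The retained count is the smallest reaching the requested
cumulative explained-variance fraction (default 0.95). Standardization is
essential here: the raw features span orders of magnitude (entropy in bits
vs approximation-band energy in squared gray levels).

## Nonlocal-regularized fuzzy c-means

The objective couples each pixel's intensity `x_k` and its nonlocal mean
`xbar_k` to the cluster centers through a normalized spatial kernel `K`
over a window `O_k`, with a per-pixel balance `beta_k` and an optional
penalty weight `a_k`:

* **Nonlocal mean.** Patch mean-squared differences over a search window
  (patch radius 1, search radius 2 by default, periodic boundary), weights
  `exp(-d2 / h^2)` with `h` in gray-level units (default 10, about twice
  the default noise sigma), self-weight excluded, normalized to 1.
* **beta_k = (max w - mean w) / mean w** over the pixel's normalized
  nonlocal weights: zero in flat regions (all patches alike), growing near
  structure. A constant-beta mode exists for reductions and ablations.
* **a_k defaults to 0** (the penalty term vanishes), keeping every
  aggregated distance non-negative; a constant mode is available, with
  negative aggregated distances clipped at 1e-12 and logged.
* **Bias field `b` is an input** (default all ones), not an estimated
  quantity: no closed-form update exists for it in this formulation. The
  objective evaluates `b` at the window positions; the updates use the
  center-pixel value, so with a non-constant user-supplied bias the descent
  guarantee is only approximate (exact for constant bias).
* **Updates.** Because `K` is normalized and the update expressions are
  constant over the window, the window sums collapse analytically; the
  implementation uses the collapsed closed forms. Membership rows sum to 1
  by construction; exact zero distances get a crisp assignment split
  equally among the touching clusters.
* **Initialization and convergence.** Centers start at evenly spaced
  intensity quantiles with a tiny seeded jitter (1e-3 of the range);
  iteration stops when `max |du| < 1e-5` or after 100 iterations. The
  objective trace is recorded every iteration and is non-increasing (the
  alternating updates are exact coordinate minimizers); the test suite
  asserts this at 1e-7 relative.
* **Cluster count.** The pipeline default is `c = 2` (tissue vs tumor after
  brain masking with a neutral median fill); an 8-cluster preset mirrors a
  finer tissue decomposition. Empty clusters are re-seeded at the pixel
  with the lowest maximum membership.

## Morphology and the tumor decision

The cleaned mask keeps the largest 8-connected component; its pixel count
drives the decision (zero pixels = "no tumor", classifier skipped). The
module-level cleanup defaults are a disk-element opening of radius 1 plus
removal of components below 16 pixels. The *pipeline* default, however,
applies area filtering only (no opening) and no smoothing prefilter: a 3x3
median or a radius-1 opening each erase single-pixel boundary features of a
rasterized ellipse (opening is the identity only on sets that are
morphologically open with respect to the element, which discrete ellipse
tips are not), which would make even a noiseless image unrecoverable
pixel-exactly. At the phantom noise levels the thresholding stage produces
no speckle for morphology to remove (a spurious foreground pixel would
need an 8-sigma noise excursion), so the conservative default costs
nothing; both knobs remain configurable for noisier data.

## Kernel SVM

Canonical kernel forms (linear `x.y`; polynomial `(g x.y + c0)^d`, with
"quadratic" fixed at `d = 2`; RBF `exp(-g ||x-y||^2)`); defaults `C = 1`,
`gamma = 1/n_features`, `coef0 = 1`. Features are z-scored with
training-set statistics before kernel evaluation. Training delegates the
soft-margin dual to libsvm (via scikit-learn) with a tightened stopping
tolerance of 1e-6; rows are first sorted into a canonical order so the
result is invariant to input row order. Prediction evaluates the stored
decision function with this package's own kernel code against the
serialized support vectors, so saved JSON models are self-contained.
Label-swap antisymmetry of the decision values holds to solver tolerance,
not to machine precision. A seeded stratified 70/30 split and an optional
seeded k-fold grid search over `C` and `gamma` are provided.

## Scores

Recall, precision, F-measure (harmonic mean) and accuracy from confusion
counts; 0/0 ratios return 0 with an explicit `degenerate` flag. Dice of two
empty masks is defined as 1 (flagged at the call site by construction of
the inputs). Report rounding is 3 decimals. One known quirk of the
published comparison table this package's worked examples draw on: one row's
printed precision/recall yield a harmonic mean of 0.772 against a printed
0.773 — a rounding inconsistency in the source, so that row is excluded
from the worked examples.

## The phantom generator

A phantom is an elliptical "brain" (intensity 120) on a dark background
(10) with an optional hyperintense elliptical "tumor" (200), additive
Gaussian noise (sigma 5 by default; Rician optional), an optional smooth
multiplicative bias field (low-order polynomial), and optional within-brain
intensity jitter. Pixels whose centers fall strictly inside an ellipse are
foreground; the ground-truth mask is the exact tumor rasterization,
independent of noise. Labels: "none" without a tumor; otherwise
"malignant" when the tumor reaches 4 % of the brain area, else "benign" —
a size/eccentricity encoding chosen as a test-harness convention, not a
pathological claim. Dataset sampling places tumors uniformly inside the
brain with class-specific axis ranges (benign: 3.5-5 px, nearly round;
malignant: 7-10 px, eccentric), rejecting placements that leave the brain
or fall below 16 pixels.

**What the phantoms show and do not show.** The default study conditions —
64x64 slices, 80-gray-level tumor contrast, noise sigma 5, 100 images per
class — make the tumor/no-tumor problem cleanly separable, and the
pipeline's near-perfect accuracy and Dice on them demonstrate correctness
of the chain, not clinical performance. Real MRI adds partial-volume
boundaries, anatomy that is not piecewise-constant, spatially correlated
(Rician, coil-dependent) noise, and genuine pathological ambiguity; none of
those are emulated, so phantom scores are an upper bound and say nothing
about the accuracy achievable on clinical data.

## Problem sizes

The default test and acceptance runs use 64x64 phantoms (200 images for the
classification study, 20 noiseless images for the exactness check), 1 000
random histograms for the threshold oracle, 50 random 16x16 images for the
wavelet checks, and 20 seeded 24x24 two-region images for fuzzy-c-means
center recovery — sizes at which every property under test is already
fully exercised while the whole suite stays interactive.
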