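# btseg

Brain-MRI tumor **segmentation and classification** for 2-D slices, built
from classical, fully inspectable components: global Otsu thresholding,
wavelet + GLCM texture features, PCA, a nonlocal-regularized fuzzy c-means
segmenter, morphological tumor isolation, and kernel-SVM classification.

The package is aimed at people studying or teaching classical medical-image
analysis pipelines: every stage is a small, tested function with an explicit
contract, and a seeded phantom generator produces synthetic brain slices
with exact ground-truth tumor masks so the whole chain runs and is graded
end to end without any external data.

## The methods in brief

**Otsu thresholding.** For a gray-level histogram `p_i = n_i / N` over
levels `0..L-1`, a candidate threshold `k` splits the levels into background
`{0..k}` and foreground `{k+1..L-1}` with class probabilities `s_x, s_y`,
class means `mu_x, mu_y` and variances `sigma_x^2, sigma_y^2`. The total
variance decomposes as

    sigma^2 = sigma_w^2(k) + sigma_b^2(k),
    sigma_w^2 = s_x sigma_x^2 + s_y sigma_y^2,
    sigma_b^2 = s_x (mu_x - mu)^2 + s_y (mu_y - mu)^2,

and the selected threshold maximizes `sigma_b^2` (computed here in exact
integer arithmetic, ties to the smallest `k`). The binary rule is
`g(x, y) = 1 iff f(x, y) >= T` with `T = k* + 1`. The pipeline applies this
twice: head vs background, then tumor vs normal tissue on brain-interior
intensities only, each stage guarded by a minimum class-mean separation.

**Texture features.** 2-D discrete wavelet transform (orthonormal Haar/db2/
db4, periodic extension, perfect reconstruction to round-off) and its
undecimated frame variant, whose sub-band energies are exactly invariant
under circular shifts; GLCM Haralick statistics (contrast, correlation,
energy, inverse difference moment, entropy) averaged over the four unit
directions; and first-order moments of the segmented region. PCA (on
z-scored features) retains the components explaining 95 % of variance.

**Nonlocal-regularized fuzzy c-means.** Minimizes

    J_m = sum_ik u_ik^m sum_{r in O_k} K(r-k) ||x_k - b(r) v_i||^2
        + sum_ik [ a_k u_ik^m (1 - u_ik^{m-1})
                   + beta_k u_ik^m sum_{r in O_k} K(r-k) ||xbar_k - b(r) v_i||^2 ]

subject to `sum_i u_ik = 1`, where `xbar_k` is a patch-similarity nonlocal
mean and `beta_k` a per-pixel dispersion of the nonlocal weights.
Alternating the closed-form Lagrange updates for memberships and centers
decreases `J_m` monotonically; with `beta = 0`, window radius 0 and unit
bias it reduces exactly to classical fuzzy c-means.

**Decision and scores.** The largest 8-connected component of the cleaned
mask is the tumor candidate; zero pixels means "no tumor" and the classifier
is never invoked. Kernel SVMs (linear, quadratic, polynomial, RBF) classify
the feature vectors; evaluation uses recall, precision, F-measure, accuracy
and the Dice coefficient `2|A∩B| / (|A|+|B|)`.

## Worked example

```python
from btseg import metrics, phantom, pipeline, postseg

spec = phantom.PhantomSpec(seed=1)          # 64x64 slice, noise sigma 5
img, ground_truth, label = phantom.generate_phantom(spec)

cfg = pipeline.PipelineConfig()
mask = pipeline.segment_tumor(img, cfg)
region = postseg.extract_tumor(
    postseg.morphological_clean(mask, cfg.open_radius, cfg.min_area))
print(region.pixel_count, metrics.dice(region.mask, ground_truth))
```

prints `87 1.0`: the two-stage threshold recovers all 87 true tumor pixels
exactly despite the noise. The same flow on 60 phantoms with four SVM
kernels (`examples/04_phantom_experiment.py`) prints

```
42 training / 18 test images, 7 principal components retained
      linear: accuracy=1.000 recall=1.000 precision=1.000 F=1.000
         rbf: accuracy=1.000 recall=1.000 precision=1.000 F=1.000
mean segmentation Dice: 1.000
```

— tumor and tumor-free phantoms are cleanly separable in texture-feature
space at this noise level. The `examples/` directory holds one short script
per capability (thresholding, texture features, fuzzy clustering, the full
experiment); each prints its numbers with a line on what they mean.

A thin CLI mirrors the library:

```sh
btseg phantom --n 100 --seed 7 --out data/
btseg segment data/tumor_0000.png --mask out.png --region-report region.json
btseg experiment --n 100 --seed 7 --out report.json
```

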