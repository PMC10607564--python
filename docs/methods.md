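# Methods

`usdespeckle` studies speckle removal in ultrasound imaging end to end:
simulate speckle on clean images, remove it with classic filters and a
compact convolutional autoencoder, score image quality, and measure the
downstream effect on lesion classification. Because clinical ultrasound
has no noise-free ground truth, all experiments run on synthetic
phantoms with known clean references.

## Speckle model

Speckle arises from coherent interference of scattered ultrasound waves
and multiplies the signal: its magnitude tracks local intensity. We
simulate it with the standard signal-proportional convention, the same
one implemented by `skimage.util.random_noise(mode="speckle")` and
MATLAB `imnoise`:

    O(x, y) = S(x, y) + S(x, y) * M(x, y),

where `S` is the clean image and `M` an i.i.d. Rayleigh(σ) field,
density p(m|σ) = (m/σ²)·exp(−m²/2σ²), sampled by the exact inverse CDF
m = σ·√(−2 ln(1−u)). The purely additive, signal-independent noise
component of the full physical model is negligible in practice and is
omitted with no switch to enable it.

A subtle point forced this convention. The Rayleigh family is closed
under scaling (M_σ = σ·M_1), so a *bare* product S·M differs across σ
only by a global factor. Since every image — original, noised, filtered —
is min–max normalized to [0, 255] before comparison, that factor cancels
exactly and all noise levels would produce the *same* normalized image.
Signal-proportional noise added to the signal breaks this invariance and
yields the graded corruption the σ levels (0.05, 0.1, 0.2, 0.5) are
meant to express. Zeros are preserved exactly and
`add_speckle(α·S) = α·add_speckle(S)` still holds pre-normalization; the
ratio O/S has mean 1 + σ√(π/2).

Normalization is per-image affine min–max rescaling to [0, 255]
(constant images map to 0, the operation is idempotent). It is applied
as data preparation — the normalized originals are both the training
targets and the evaluation references — so all comparisons share one
intensity scale.

## Classic filters

The Median filter replaces each pixel with the median of its square
window. The Lee filter shrinks each pixel toward the local window mean:

    P = K̄ + W·(C − K̄),  W = σ_k² / (σ_k² + σ_i²),

with K̄ and σ_k² the window mean and (population) variance, C the centre
pixel, and σ_i² a single scalar per image. We take σ_i² to be the global
variance of the image being filtered, following the formulation this
package reproduces; the classical alternative (an estimated *noise*
variance) smooths more aggressively and can be obtained via the
`image_variance` override. W ∈ [0, 1] makes every output pixel a convex
combination of K̄ and C, so flat regions return the window mean and
high-variance (edge) regions pass through — the filter's
edge-preserving property. Default window is 7×7 (unreported upstream;
mid-range standard for despeckling), borders reflect-padded.

## Autoencoder

The denoiser is a deliberately small (< 30,000 parameters) convolutional
autoencoder: two conv(3×3, 32, ReLU, same) → max-pool(2×2) encoder
stages, mirrored by two conv → 2× nearest-neighbour upsample decoder
stages, closed by a conv(3×3, 1, linear). At the native 536×232 input
the encoded representation is (134, 58, 32) and the per-layer parameter
counts are 320 + 3·9248 + 289 = 28,353. Inputs must be divisible by 4 so
the two poolings invert exactly; desk-scale runs use 128×128.

Weights are Glorot/Xavier-uniform initialized; training uses Adam
(β₁ = 0.9, β₂ = 0.999, ε = 10⁻⁷, lr = 0.001) on mean squared error —
the loss is not dictated upstream, and MSE is the standard
reconstruction loss consistent with PSNR evaluation. The reference
schedule is 1000 epochs; desk-scale experiments in the tests and the
acceptance script use 50 epochs, 64 training phantoms and batch size 8,
chosen as the smallest configuration at which the directional effects
are measurable. Images are scaled by 1/255 entering the network; the
linear output layer is unbounded, so outputs are rescaled, clipped to
[0, 255] and min–max normalized before any metric sees them. There is no
early stopping: the epoch count is fixed, and training is bit-reproducible
given the seed (weight init, shuffling and dropout all derive from it).

Since no deep-learning framework is part of the dependency set, the
layers (im2col/shift-sum convolution, pooling, upsampling, batch
normalization, dense, dropout), Adam, and Xavier initialization are
implemented directly on numpy in `usdespeckle.nn`; convolutions reduce
to BLAS matrix products, which keeps the desk-scale trainings at roughly
a minute each on one CPU. Gradients are verified against numerical
differentiation in the test suite. Batch-norm running moments are
zero-initialized EMAs debiased by 1 − momentum^t (as Adam debiases its
moments) so that inference statistics are meaningful after few steps.

`train_filter_mimic` trains the same architecture with Lee-filtered
images as targets, measuring how well the network can *reproduce* a
classic filter; it records per-image wall times of the Lee filter and of
network inference (informational only — the network amortizes its cost
at inference, the filter does not).

## Quality metrics

SSIM is computed globally — one set of whole-image moments per pair:

    SSIM(x,y) = (2 μ_x μ_y + c₁)(2 σ_xy + c₂) /
                ((μ_x² + μ_y² + c₁)(σ_x² + σ_y² + c₂)),

with c₁ = (0.01·L)², c₂ = (0.03·L)², L = 255. This is the printed
formula the package reproduces, not the sliding-window mean-SSIM variant
(available via `windowed=True`, backed by scikit-image). PSNR is
10·log₁₀(peak²/MSE) where `peak` is by convention the maximum intensity
*present in the reference image*; pass `peakval=255` for the fixed-range
convention common elsewhere. Identical images raise an explicit
infinite-PSNR signal. Set evaluation reports per-image values plus
mean ± std (population convention).

Classification metrics (accuracy, sensitivity, specificity, PPV, NPV,
F1, MCC) are computed exactly from confusion counts with malignant as
the positive class; any zero-denominator metric is reported as `None`,
never silently 0.

## Phantoms

`generate_phantom` renders clean, seeded, ultrasound-like images:
a background level with a depth (vertical) intensity gradient and a
band-limited large-scale field, both scaled by `gradient_strength`, plus
non-overlapping elliptical lesions (axes 5–25 % of the short side,
contrast ≥ 20 intensity units, hypo- or hyper-echoic). Benign lesions
are smooth ellipses; malignant ones multiply the boundary radius by a
low-order random Fourier series (harmonics 4–8, amplitudes 0.06–0.10),
producing spiculated margins. The classes are separable by the
boundary-irregularity statistic perimeter²/(4π·area) in ≥ 90 % of seeded
pairs, which gives the classifier a learnable signal.

What the phantoms deliberately omit: acoustic point-spread convolution,
beamforming geometry, native speckle texture, and the tissue-dependent
appearance of real ultrasound. Passing tests therefore demonstrate the
correctness and the *directional* behaviour of the machinery — not
clinical performance. Two dataset-scale consequences are worth noting:
on piecewise-smooth phantoms the Median filter is close to ideal (flat
windows make the median an excellent estimator), so it scores higher
than the literal Lee filter at strong noise; and at 50 epochs the
autoencoder cannot beat the filters' ~0.99 SSIM ceiling at σ = 0.05,
although it clearly wins at σ ≥ 0.2. On real ultrasound, with its
textured background and 1000-epoch training, the reported ordering
(autoencoder ≥ Lee ≥ Median everywhere) is the expected one.

## Lesion classifier

`preprocess` clips each image at its own 5th/95th intensity percentiles,
min–max normalizes to [0, 255] and resizes to 256×256 (bilinear;
configurable so desk-scale runs can use smaller inputs). The classifier
is four blocks of conv → batch-norm → ReLU → max-pool with kernels
9/7/5/3 and 16/32/64/128 channels, then flatten → dense(128, ReLU) →
dropout(0.5) → dense(1), a single logit thresholded at 0.5 (sigmoid
equivalence). Parameter accounting uses the standard formulas; batch
norm counts 4 parameters per channel (scale/shift plus moving moments).
The printed source table gives 78,356 for the fourth convolution where
the standard formula 3·3·64·128 + 128 yields 73,856 — a suspected digit
transposition; the standard layer is implemented.

Evaluation is stratified k-fold cross-validation (k = 5 by default,
sklearn `StratifiedKFold`, seeded), each fold keeping class proportions
within one item. `run_variant_experiment` trains the classifier once per
input variant — original, autoencoder-denoised at each σ, Median- or
Lee-filtered, or noised at σ = 0.5 — applying each transform identically
to all images at native size before preprocessing, and reports the seven
metrics as mean ± std over folds. Classifier training hyperparameters
are not specified upstream; the Adam constants above are reused with a
desk-scale epoch default.

## Numerical and design choices

- Population (divide-by-n) convention for all variances (filters, SSIM,
  aggregation), matching the plain "variance of the window/image" reading.
- Min–max normalization divides before scaling so extremes map to 0/255
  exactly; constant images map to 0 by convention.
- Rayleigh sampling by inverse CDF rather than a backend's native
  sampler: exact, and reproducible across random-number backends.
- Max-pool gradients go to the first maximal entry of each window
  (deterministic tie-break).
- Dataset splits: 70/30 train/validation by default; grouped items
  (frames of one video) never straddle the split (`GroupShuffleSplit`).
- Float32 throughout the network; float64 in metrics and filters.
- Image I/O: float32 TIFF for metric-bearing intermediates, 8-bit PNG
  for display, so quantization never contaminates SSIM/PSNR.

## Limitations

- Phantom realism is heuristic (see above); absolute metric values are
  not comparable to clinical results, only directions and mechanisms.
- The literal Lee weighting with σ_i² = global image variance
  under-smooths heavily textured or high-contrast images; the classical
  noise-variance interpretation is available but not default.
- Desk-scale training (50 epochs, 64 images) leaves the autoencoder
  short of its asymptotic quality; the fixed reference schedule is 20×
  longer on ~14× more images.
- The global SSIM statistic saturates near 1 on large smooth images;
  windowed SSIM is available where localized structure matters.
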