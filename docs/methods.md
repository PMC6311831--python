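# Methods

This note documents the models and procedures implemented in `macuseg`,
the parameters that matter, the numerical conventions, and the known
limits of validating the pipeline on synthetic scenes.

## Color-space conventions

All three transforms act pixel-wise on raw 8-bit RGB; no gamma decoding
or ICC management is applied anywhere.

* **HSV** (`colorspaces.rgb_to_hsv`): channels are normalized to [0, 1];
  value is the channel maximum, saturation `(V − X)/V` with `X` the
  minimum; hue follows the six-case hexcone rule divided by 6 so
  `H ∈ [0, 1)`. Degenerate pixels use `S = 0` at `V = 0` and `H = 0`
  when all channels are equal. The implementation agrees with the
  textbook hexcone definition to 1e-9 (tested against `colorsys` on
  1000 random colors).
* **YCbCr** (`rgb_to_ycbcr`): affine map on the [0, 255] scale with a
  BT.601-style matrix and (0, 128, 128) offset, clipped to [0, 255].
  Gray maps exactly to `Cb = Cr = 128`.
* **CIE L\*a\*b\*** (`rgb_to_lab`): a fixed linear RGB→XYZ matrix on
  [0, 1] channels; the reference white is the image of `r = g = b = 1`
  under that matrix (its row sums), which makes the transform
  self-consistent: gray has `a = b = 0` exactly and white `L = 100`.
  L uses the two-branch rule (cube-root law above `Y/Yn = 0.008856`,
  linear `903.3·Y/Yn` below). Because the input is not gamma-decoded,
  mid-gray (128) has `L ≈ 76.2` rather than the ≈53.6 of an
  sRGB-decoded pipeline; only the ordering of L matters downstream
  (the Stage 2 stretch is affine and the PCA projection is fitted per
  image), so this convention has no effect on segmentation behavior.

## Stage 1 — skin segmentation

The skin mask is the conjunction of the fixed hue band
`0.01 ≤ H ≤ 0.1` (closed interval; all interval endpoints in the
package are inclusive) and the dynamic chroma box
`[min Cb, mean Cb] × [mean Cr, max Cr]`, with statistics over every
pixel of the image. Skin occupies the low-Cb/high-Cr corner of the
chroma plane relative to common backgrounds, so anchoring the box at
the per-image mean adapts it to the subject's tone; an optional switch
excludes exact-black border pixels from the statistics for images with
scanner frames.

Cleanup is plumbing, not part of the thresholding rule: morphological
closing with a disk of radius 5 px (the mask is padded first so regions
touching the frame are not eroded), removal of connected components
below 0.1% of image area, and hole filling. All three are configurable
(`PipelineConfig.close_radius`, `min_object_frac`).

## Stage 2 — lesion extraction

Statistics for this stage are computed **over skin pixels only**, not
over the whole frame: the background would otherwise dominate both the
luminosity histogram and the PCA fit. This is a deliberate divergence
from computing "over the image" and is configurable only in the sense
that the skin mask can be set to all-ones.

1. *Luminosity saturation*: the L plane is linearly stretched so that
   its 2nd/98th skin-pixel percentiles map to 0/100, then clipped.
   The percentile (rather than min/max) anchoring makes the stretch
   robust to a few extreme pixels. A constant L plane passes through
   unchanged with a warning.
2. *PCA grayscale*: the first principal component of the (L, a, b)
   values of skin pixels, computed from the exact 3×3 covariance
   eigendecomposition. The component sign is chosen so the score
   correlates positively with L (dark lesions end up in the low tail);
   scores are affinely rescaled so skin pixels span [0, 1].
3. *Threshold*: a skin pixel is flagged when its grayscale value is
   `≤` the `fraction` quantile (default 0.10) of skin-pixel values.
   The tie rule is inclusive, so on heavily quantized images the
   flagged share can exceed the nominal fraction; on a macule-free
   scene the flagged share equals the fraction almost exactly by
   construction. Masks are nested in `fraction`.

The damage percentage is `100·|lesion|/|skin|`. Note that with the
default 10% fraction this is a *relative* measure: a lesion-free limb
still reports ≈10%, and the number only becomes clinically meaningful
relative to that floor.

## Stage 3 — characterization

Macule candidates are 8-connected lesion components with at least
`min_area = 5` px (small enough to keep pinhead petechiae, whose
published mean area is 18.5 px). The healthy reference for each
candidate is a ring: the component dilated by `ring_width = 5` px,
minus **all** lesion pixels, intersected with the skin mask — so the
reference never contains lesion tissue, even from a neighboring macule.

Feature conventions:

* **area** — pixel count;
* **major/minor axis** — axis lengths of the ellipse with the same
  normalized second central moments as the region (via
  `skimage.measure.regionprops`);
* **perimeter** — length of the traced outer boundary polygon
  (`find_contours` at level 0.5 on the padded mask). Published
  perimeter values cannot be re-derived without the original data, so
  only internal consistency is claimed for this estimator;
* **solidity** — `100 · area / hull_area`, where the hull is the
  continuous convex hull of the region's pixel *squares* (each pixel
  contributes its four corners). A single pixel has solidity 100 and a
  plus-shaped pentomino exactly 500/7 ≈ 71.4%; large convex regions
  measure ≥ 98% (the hull of squares slightly over-bounds a digitized
  convex set);
* **max/min intensity** — extrema of the Stage 2 PCA grayscale over the
  region (the published values' [0, 1] scale supports this choice over
  8-bit luminance);
* **shade indices** — means over the raw 8-bit channels of the macule
  vs its ring. Indices are exactly 1 for a macule whose color equals
  its ring and are invariant to global multiplicative illumination.

## Classifier

Architecture 11→4→4→4: tanh on both hidden layers, logistic sigmoid on
the four outputs (the conventional assignment for a classification
network of this family), one-hot targets in {0, 1}, sum-squared-error
loss. Training is Levenberg–Marquardt: damped normal equations
`(JᵀJ + λI)δ = −Jᵀr` with the Jacobian assembled by backpropagation
(one row per sample × output unit, 88 parameters), λ₀ = 1e-3,
factor-10 damping schedule, steps accepted only when they reduce the
SSE, at most 200 epochs. Weights initialize uniformly in [−0.5, 0.5]
under a seeded generator; 3 random restarts keep the net with the
lowest training SSE. A BFGS trainer on the same objective is available
behind the same interface (`TrainConfig(optimizer="bfgs")`) as a
robustness fallback; LM is the default and the reference.

Features are z-scored with training-split statistics (the scales span
three orders of magnitude); the split is stratified 60/40 per class.
Evaluation reports the 4×4 confusion matrix, held-out accuracy, pooled
train+test accuracy (of interest because the canonical experiment has
only 16 test vectors), and the Pearson correlation R between flattened
one-hot targets and raw network outputs.

## Group statistics

`compare_groups` runs a two-sided two-sample t-test per feature per
unordered class pair (6 pairs × 11 features). The pooled-variance
Student's test is the default, Welch's variant is behind a flag, and
no multiple-testing correction is applied. Results agree with the
statsmodels pooled t-test to 1e-10.

## Synthetic scenes and feature sampling

The generator emulates the photographs the pipeline is designed for:

* **leg**: a tapered vertical capsule (radius 0.30→0.22 of the image
  width) over a blue-gray background (70, 90, 130);
* **palette**: six skin tones from (236, 188, 160) to (110, 64, 36),
  each verified to fall inside the Stage 1 hue band and to show the
  low-Cb/high-Cr chroma pattern;
* **illumination**: a multiplicative horizontal gradient of amplitude
  0.15 by default (±7.5% across the frame), applied to the whole image;
* **noise**: additive per-channel Gaussian, SD 4 (8-bit units), clipped;
* **macules**: roughened ellipses (3-harmonic boundary modulation)
  whose pixels are the local skin color multiplied by per-channel shade
  factors — the painted factor is therefore exactly what the shade
  indices should recover. Per-class geometry (area distribution,
  eccentricity, roughness) and default factors come from the published
  per-class feature statistics; `scatter_macules` truncates area draws
  to what the leg interior can contain (this only binds for the large
  trophic/trauma classes on small frames) and rejects placements that
  overlap or leave the leg.

Scenes are bit-reproducible for a given spec. Default scene size is
320×240 (≈39k skin pixels), which keeps the full validation suite and
the reproduction script in the tens of seconds while leaving every
mask statistic well resolved.

`sample_feature_vectors` draws the 11 features independently per class
from Gaussians with the published class means/SDs, truncated to
validity (area ≥ 1, solidity ∈ (0, 100], intensities ∈ [0, 1], indices
> 0), with `minor ≤ major` and `min ≤ max intensity` enforced by
resampling the offending pairs.

What the generator does **not** model: hair, specular highlights,
shadows with chromatic shifts, camera vignetting or compression
artifacts, textured backgrounds, and — most importantly — the
correlations between features within a class (area, axes and perimeter
are nearly deterministic functions of one another in real regions, and
sizes co-vary with shade). Passing tests therefore establish the
internal correctness and self-tuning behavior of the pipeline, not its
clinical accuracy on photographs.

## Known limitations

* **Threshold floor**: the fixed-fraction quantile flags ~10% of skin
  even on a healthy limb; detected regions therefore include noise
  clusters, and downstream consumers should filter by ground truth,
  size, or a trained classifier.
* **Area bias**: measured macule areas run ~15–20% above the painted
  truth because threshold-adjacent noise pixels attach to true regions;
  this is visible in the petechiae recovery experiment (22 px measured
  vs 18.9 px painted).
* **Classifier ceiling under independent sampling**: sampling features
  independently per class erases the correlation structure that makes
  real macules separable. The reference experiment's own model-based
  ceiling (`model_accuracy_ceiling_percent`, the Bayes classifier that
  knows the exact sampling densities, Monte Carlo n = 20 000) is ≈84%,
  and the trained network reaches ≈58–60% held-out (≈85% over the
  pooled 40 vectors) with target/output R ≈ 0.45. These numbers
  measure the synthetic experiment, not the method's capability on
  real, correlated feature vectors, where a small network can separate
  the four classes almost perfectly.
* **Perimeter/solidity conventions** are estimator choices; absolute
  comparability with other implementations is limited to regions large
  enough that discretization effects vanish.
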