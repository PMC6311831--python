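# macuseg

Segmentation, characterization and classification of **skin macules** —
flat discolored lesions (vascular, petechial, trophic, traumatic) that
appear on the lower limbs of people with type-II diabetes, often years
before ulcers develop. The package is aimed at researchers building
image-based screening tools for diabetic skin manifestations: it turns a
color photograph of a leg into a skin mask, a candidate-lesion mask, a
per-macule feature table and, optionally, a predicted macule type.

## Method

The pipeline has three stages followed by a classifier.

**Stage 1 — skin region.** Two binary masks are AND-ed:
a fixed hue-band mask on hexcone HSV, `0.01 ≤ H ≤ 0.1` (the red-orange
band where skin of all tones lives), and a *dynamic* chroma mask on
YCbCr,

```
min(Cb) ≤ Cb ≤ mean(Cb)   and   mean(Cr) ≤ Cr ≤ max(Cr),
```

whose bounds are recomputed per image, so the threshold self-tunes to
the subject's skin tone. Morphological cleanup (closing, small-object
removal, hole filling) produces a solid leg mask.

**Stage 2 — lesion region.** Inside the skin mask the image is taken to
CIE L\*a\*b\*, the L plane is percentile-stretched to [0, 100]
("luminosity saturation"), every pixel's (L, a, b) value is projected
onto the first principal component of the skin-pixel colors, and the
darkest ~10% of the skin-pixel grayscale distribution is flagged as the
lesion region. The *damage percentage* is
`100 · |lesion| / |skin|`.

**Stage 3 — characterization.** Each 8-connected lesion component with
≥ 5 px becomes a macule candidate and is described by 11 features:
area, major/minor axis, perimeter, solidity (morphologic); max/min PCA
grayscale (intensity); and four **shade indices** against a ring of
healthy skin around the macule,

```
ShI_R = mean(M_red) / mean(HS_red)        (green, blue analogous)
ShI_BR = (mean(M_red) + mean(M_blue)) / (mean(HS_red) + mean(HS_blue)),
```

which cancel illumination and skin-tone differences between subjects.

**Classifier.** An 11-input feedforward network with two hidden layers
of 4 tanh neurons and 4 logistic outputs, trained by Levenberg–Marquardt
on sum-squared error against one-hot targets, with a stratified 60/40
train/test split and z-scored features.

Because the clinical photographs behind the method are access
restricted, the package ships a synthetic lower-limb scene generator
(leg silhouette, 6-tone skin palette, multiplicative illumination,
Gaussian pixel noise, macules painted as per-channel shade factors) with
full ground truth, plus a sampler of 11-feature vectors from the
published per-class statistics. Everything downstream is validated
against that generator.

## Worked example

```python
import numpy as np
from macuseg import (SceneSpec, make_scene, scatter_macules,
                     analyze_image, petechiae_recovery_experiment)

rng = np.random.default_rng(0)
specs = scatter_macules("petechiae", 12, (320, 240), rng)
img, truth = make_scene(SceneSpec(shape=(320, 240), seed=0,
                                  illumination=0.0, macules=specs))
result = analyze_image(img)
print(f"skin pixels      : {result.damage.n_skin}")
print(f"damage percentage: {result.damage.damage_percent:.1f}%")

rec = petechiae_recovery_experiment(n_legs=5, per_leg=12, seed=0)
print(f"detected         : {rec['n_detected']}/{rec['n_painted']}")
print(f"mean ShI_R       : {rec['mean_shi_r']:.3f}")
print(f"mean area        : {rec['mean_area']:.1f} px")
```

prints

```
skin pixels      : 39290
damage percentage: 10.0%
detected         : 60/60
mean ShI_R       : 0.955
mean area        : 22.2 px
```

The damage percentage sits at the configured 10% histogram fraction
(the scene has only ~0.5% true macule area, so most flagged pixels are
the dark tail of normal skin noise). All 60 painted petechiae are
recovered; their measured red shade index (0.955) matches the painted
factor 0.95, and their measured area (22.2 px) tracks the true painted
mean (18.9 px) with a small dilation bias from threshold-adjacent noise
pixels.

The same pipeline is available from the shell:

```
macuseg synth scene --seed 0 --macules 8 --out leg.png --truth truth.json
macuseg run leg.png --outdir out/          # skin/lesion masks, features.csv, report.json
macuseg synth features --n 10 --seed 0 --out fv.csv
macuseg train fv.csv --seed 0 --out model.json --report fit.json
macuseg compare fv.csv --out pvalues.csv
```

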