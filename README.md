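# panseg

Anatomy-guided 3D segmentation of **pancreatic subregions** — head, body and
tail — in abdominal CT, given a pre-delineated pancreas mask.

Subregional analysis of the pancreas matters clinically because tumor biology,
symptoms, drug response and prognosis differ between the head, body and tail,
yet the three parts have no visible boundaries on CT: any segmentation must
come from anatomical context rather than edges.  `panseg` targets researchers
who already have whole-pancreas delineations (manual or from a whole-organ
segmentation model) and need reproducible subregion labels for radiomics or
morphology studies.

## Method

The pancreas is a curved, J-shaped organ whose head, body and tail cover
roughly 40%, 33% and 26% of its length, in that order along the organ.  The
pipeline turns this prior into a per-voxel probability and combines it with a
learned appearance model:

1. **Anatomy features.** From the head endpoint `y_f` (in training: the head
   voxel geodesically farthest from the body and tail; at inference: a
   pseudo-diameter endpoint chosen by the left-to-right laterality convention)
   every pancreas voxel `x` gets two dimensionless features:

   - the *length fraction*  α′(x) = d(y_f, x) / l,  where `d` is the
     mask-constrained (geodesic) shortest-path distance on the 26-connected
     voxel graph with physical edge lengths, and `l = d(y_f, z_f)` is the
     organ length to the farthest voxel `z_f`;
   - the *volume fraction*  β′(x) = |{v : d(y_f, v) ≤ d(y_f, x)}| / A,  the
     share of the organ volume swept while travelling from `y_f` to `x`
     (`A` = total voxel count).

2. **Naive Bayes soft labels.**  Per subregion `s ∈ {H, B, T}`, univariate
   Gaussians `N(μ_αs, σ_αs)` and `N(μ_βs, σ_βs)` are fitted on labelled
   training voxels; the per-voxel posterior
   `X_s(x) ∝ N(α′; μ_αs, σ_αs)·N(β′; μ_βs, σ_βs)·p(s)²` (flat priors, one per
   feature) is renormalized so the three channels sum to 1.

3. **Network + fusion.**  A compact 3D encoder–decoder network (configurable
   down/up-sampling depth, Dice + focal loss at 1:1, Adam) produces a second
   probability map `Y`; in every training epoch and at inference the two maps
   are fused multiplicatively, `Ŷ_s ∝ Y_s · X_s` with per-voxel
   renormalization, and the final labels are the masked argmax of `Ŷ`.

4. **Evaluation.**  Per-class Dice coefficients `DSC = 2TP/(2TP+FP+FN)` over
   pancreas voxels, k-fold cross-validation with a leakage guard, external
   (frozen-model) validation, and failure diagnostics: the fraction of errors
   near the body/tail border and the count of head↔tail confusions.

A synthetic **phantom generator** produces connected tubular organs
(straight / J / U curvature presets, tapering radius, jittered size and
fractions, optional tumor-like texture) so the whole pipeline is testable
end-to-end without any imaging data.

## Worked example

```python
import numpy as np
from panseg import (PhantomSpec, generate_phantom, preprocess, compute_features,
                    fit_gaussians, posterior_map, bayes_segment, dsc_percentages)

vol, labels = generate_phantom(PhantomSpec(preset="J", seed=7))
vol, labels, _ = preprocess(vol, labels, padding=2)   # crop, zero, normalize

feats = compute_features(vol.mask, labels, spacing=vol.spacing)
print(f"head endpoint y_f = {feats.y_f}, length l = {feats.length_mm:.1f} mm, "
      f"volume A = {feats.area} voxels")

params = fit_gaussians(feats, labels)
print("alpha means (H, B, T):", np.round(params.mu_alpha, 3))

feats_test = compute_features(vol.mask, None, spacing=vol.spacing)  # no labels
soft = posterior_map(feats_test, params)
pred = bayes_segment(soft, vol.mask)
h, b, t, o = dsc_percentages(pred, labels, vol.mask)
print(f"Bayes-only DSC%: head {h:.1f}, body {b:.1f}, tail {t:.1f}, overall {o:.1f}")
```

prints

```
head endpoint y_f = (1, 19, 5), length l = 46.3 mm, volume A = 1350 voxels
alpha means (H, B, T): [0.247 0.6   0.842]
Bayes-only DSC%: head 97.4, body 91.2, tail 94.2, overall 94.3
```

The fitted α′ means land near the midpoints of the 40/33/26 length fractions
(0.20, 0.57, 0.87), and the Bayes posterior alone — fitted and evaluated on a
single phantom here — already recovers the three subregions with ≳90% Dice.
The full pipeline (network training, fusion, cross-validation) is driven
through `evaluate_pipeline` or the CLI:

```bash
panseg phantom --n 8 --preset J --seed 7 --out data/
panseg crossval --data data/ --out runs/cv --folds 4 --preset desk-test --ablation
```

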