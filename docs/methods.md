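# Methods

This note documents the models implemented in `panseg`, the choices made
where the design was genuinely open, and what the synthetic phantoms do and
do not establish about behavior on real CT data.

## Problem setting and assumptions

The package segments the head (H), body (B) and tail (T) of the pancreas
inside a given whole-pancreas delineation.  Assumptions baked into the
model:

- the mask contains **one whole pancreas** as a single 26-connected
  component (fragmented masks are a hard error; `keep_largest` exists for
  masks with stray islands, but a post-surgical partial pancreas will
  violate the anatomical proportions the model relies on);
- the three subregions are arranged **H–B–T along the organ**, head at the
  expanded end, with head, body and tail occupying on the order of
  40/33/26% of organ length;
- image laterality is known (on the axial view the head is the leftmost
  subregion), so that an unlabelled mask's head end can be disambiguated.

## Preprocessing

Volumes are cropped to the padded bounding box of the mask (default padding
8 voxels; the desk-scale pipelines use 2), non-pancreas voxels are set to
exactly 0, and pancreas intensities are min–max rescaled to [0, 1] using
pancreas-voxel statistics only.  Cropping and normalization commute here
because the statistics never involve background voxels; the implementation
crops first.  A constant-intensity pancreas maps to all zeros rather than
raising, so degenerate synthetic fixtures stay usable.  No resampling to a
fixed grid is performed: the features are dimensionless and the network is
fully convolutional, so nothing downstream depends on a specific volume
shape.

## Geodesic anatomy features

Distances are shortest paths on the 26-connected voxel graph restricted to
the mask, with each step weighted by its physical Euclidean length (mm), so
anisotropic voxels are handled and the path can never leave the organ —
essential for a curved organ where the straight head–tail chord exits the
gland.  The implementation rides on `skimage.graph.MCP_Geometric`; the test
suite checks it voxel-for-voxel against an independently built explicit
edge-list Dijkstra on dozens of random connected masks.  The sub-voxel
error of the 26-neighbor chamfer approximation (≤ ~4% of path length) is
accepted; it cancels almost entirely in the α′ ratio.

- **Head endpoint `y_f`.**  Training: the head voxel maximizing the minimum
  geodesic distance to any body-or-tail voxel.  Inference: a double-sweep
  pseudo-diameter (farthest voxel from an arbitrary start, then farthest
  from that) yields the two organ endpoints; the head end is the one with
  the smaller coordinate along the configured laterality axis (axis 0,
  `head_side="min"` by default; both configurable).  On strongly U-shaped
  organs whose two ends nearly align along that axis the rule can pick the
  wrong end — the phantom presets keep the head end clearly lateral, and
  real use should set the axis from the image orientation descriptor.
- **α′** = geodesic distance from `y_f`, divided by the organ length `l`
  (distance from `y_f` to the farthest voxel `z_f`); clipped to [0, 1].
- **β′** is implemented as the *cumulative swept volume*: the number of
  pancreas voxels geodesically no farther from `y_f` than the query voxel,
  over the total count `A`.  A literal axis-aligned reading ("voxels
  between `x` and `y_f` on all three axes") is ill-defined on curved
  organs; the cumulative definition is well-defined everywhere, reduces to
  the axis-aligned count on straight tubes, and is co-monotone with α′ by
  construction.  A bounding-box variant is available via
  `beta_feature(..., mode="bbox")` for comparison, as is a straight-line α
  (`alpha_feature(..., mode="straight")`).
- Argmax ties (endpoint selection, `z_f`) break to the lexicographically
  smallest voxel index, making every geometric quantity deterministic.

## Naive Bayes soft labels

Class-conditionals are univariate Gaussians per feature per subregion —
the minimal family consistent with a (μ, σ) parameterization — fitted by
pooled sample mean and unbiased standard deviation over all labelled
training voxels, with σ floored at `1e-3` (fraction scale) to avoid
degenerate spikes from tiny subregions.  Priors default to a flat 1/3 and
are applied once per feature; because posteriors are renormalized per
voxel, any constant prior cancels exactly, so the flat-prior choice is
cosmetic.  All density evaluation happens in log space with log-sum-exp
normalization; a direct-space route exists for cross-checking and agrees
to 1e-8 wherever it does not underflow.  Voxels where every class
underflows to zero fall back to a uniform posterior.  After fitting, the
α′ means are checked for the anatomical H < B < T ordering and a warning
is raised if violated (a symptom of mislabelled data or a wrong laterality
setting).

## Network and fusion

The appearance model is a compact U-shaped 3D fully convolutional network
implemented in numpy: per level one 3×3×3 convolution + ReLU, 2× average
pooling down and nearest-neighbour upsampling with skip concatenation up,
and a 1×1×1 classification head; channel widths double per level from
`base_channels`.  The numpy implementation (im2col convolutions, manual
backward pass, Adam) keeps the package dependency-light and makes training
bit-for-bit reproducible from the seed; at the volume sizes this package
targets it trains in seconds per epoch on one CPU.  Backprop correctness
is pinned by finite-difference tests on every parameter group.

Default wiring feeds the network 4 channels (normalized image + the 3
Bayes channels) *and* fuses its softmax output with the Bayes map
(`Ŷ ∝ Y·X`, renormalized per voxel) inside every training epoch, so the
loss is computed on the fused map; `use_bayes_input=False` and
`fuse=False` give the ablation paths (a plain network trained on intensity
alone).  Voxels where the fused product is zero in all three channels fall
back to uniform — this affects only voxels both models reject, and never
masked-loss voxels in practice.

The loss is mean soft-Dice over the three classes plus focal loss
(γ = 2, no α-balancing) at 1:1, computed over pancreas voxels only.
Training defaults mirror the reference recipe — Adam, lr 1e-4, batch 2,
up to 500 epochs, three down/up-sampling steps — while the `desk_test`
preset (depth 2, 8 base channels, 15 epochs, lr 1e-3) is sized so a full
4-fold cross-validation on 8 phantoms finishes in minutes on one CPU.
Checkpoint selection keeps the epoch with the best mean training DSC.

## Evaluation conventions

DSC is computed per class over pancreas voxels (the class is positive, the
other two subregions negative), 1.0 when both sets are empty.  "Overall"
is the **unweighted mean of the three class DSCs** — the convention that
reproduces the published summary columns within rounding — with a
voxel-weighted variant behind a flag.  Cross-validation partitions cases
into folds differing by ≤ 1 in size, deterministically from the seed, and
a guard aborts if any test id reaches a training set.  External validation
runs prediction only; tests assert the model parameters are untouched.
Failure diagnostics report the fraction of misclassified voxels within 3
geodesic voxels of the reference body/tail interface (the border where
human raters disagree most) and the count of head↔tail confusions, which
the H–B–T adjacency makes anatomically impossible for a sound model.

## Phantoms: what they emulate, and what they do not

Phantoms are tubes around a cubic-spline centerline (straight, ~90° J, and
~160° U presets), radius tapering linearly from head (4 vox) to tail
(2 vox), labels cut at the 40/33/26 arc-length fractions, per-region
intensity means (110/90/70 raw units, noise σ 8, background 25) chosen so
regions differ in texture but overlap under noise.  Raw units are
deliberate: phantoms must pass through the real crop/zero/normalize path.
Dataset generation jitters size (grid and radii together, ±30%), length
fractions (±5%), noise, and can add a tumor-like intensity blob that never
deforms the mask.  Generation is deterministic from the master seed, and
every phantom is validated for connectivity and H–T non-adjacency.

Phantoms establish internal correctness — feature identities, co-monotone
α′/β′, recoverable Gaussians, fusion behavior, leakage-free
cross-validation — not clinical performance.  They lack surrounding
organs, partial-volume effects, contrast-phase variability, and realistic
inter-subject shape statistics; DSC values on phantoms are therefore upper
bounds of convenience, not claims about CT.

## Desk-scale study design

The acceptance script and the end-to-end tests run 8 phantoms (mixed
straight/J/U), 4 folds, desk-test network preset.  At this scale the plain
network — 15 epochs on 6 small volumes — is a weak baseline, so the
fusion gain it implies is much larger than what full-scale training would
show; the number documents the wiring, not a clinical effect size.  The
Bayes-only baseline, in contrast, is nearly scale-independent (it fits 12
scalars) and lands in the same DSC range as the fused model.

## Known limitations

- Inference-time head detection relies on the laterality convention; a
  pancreas whose two ends align along the configured axis can flip H/T.
- The Gaussian class-conditionals are unimodal; pancreases with strongly
  non-proportional subregions (disease, resection) violate the prior.
- The numpy network is CPU-bound and meant for small cropped volumes; it
  is not a route to full-resolution GPU training.
- β′'s cumulative definition ties its information content to α′
  (co-monotone); its value over α′ alone comes from its different
  distribution shape (volume-weighted), not independent information.
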