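# Methods

## Problem setting

Given an 8-bit RGB histology patch, the package predicts (i) a per-pixel
nuclear probability, (ii) a two-channel horizontal/vertical (HV) distance
map, and (iii) a per-pixel class distribution over K nucleus types plus
background.  Post-processing converts (i)–(ii) into an instance label map
and (iii) into one type per instance.  The underlying assumption of the HV
representation is that each nucleus is a roughly star-convex pixel set
around its centre of mass, so signed offsets to the centre vary smoothly
inside a nucleus and jump sharply across the interface between touching
nuclei — exactly where a segmentation boundary must be placed.

## HV target encoding

For every instance, each pixel stores `(c − c_com, r − r_com)` scaled per
instance so the extreme offsets map to ±1.  The scaling is applied
separately to the negative and positive side of each axis, so the centre
of mass always encodes exactly (0, 0) even for asymmetric shapes.  The
convention is mirror-equivariant: flipping the image horizontally negates
the horizontal channel exactly, which the augmentation module exploits
(sign flip instead of recomputation).  Gradient targets for the
gradient-MSE loss use central differences in the interior and one-sided
differences at borders (`numpy.gradient`); the Sobel operator is reserved
for post-processing, where a smoothing derivative is wanted.

## Architecture

* **Encoder** — ResNet-50-style bottleneck stack, stage depths
  (3, 4, 6, 3) by default.  The stem is a stride-1 7×7 convolution and
  there is no initial pooling, so stage 1 works at full resolution and
  stages 2–4 halve it; this preserves the small-object detail nuclei
  require.  Every stage ends with channel attention (global average + max
  pooling through a shared bottleneck MLP, reduction 16, sigmoid gate)
  followed by spatial attention (channel-pooled mean/max through a 7×7
  conv).  Both gates multiply the features; a test hook can force gates to
  ~1 to verify the identity limit.
* **Decoders** — three identical branches (2, 2 and K+1 output channels).
  Each upsamples ×2 three times (nearest neighbour), with dense blocks of
  8 and 4 preactivated dense units (1×1 to 4g, then 3×3 to growth g) after
  the first and second upsampling, and merges the encoder's per-stage
  features by elementwise addition, 1×1-projected when channel counts
  differ.
* **ARRM refinement** — per branch, a compact encoder–decoder over the
  coarse prediction map alone: entry 3×3 conv; N ∈ {2, 3, 4} stages of
  (3×3 conv → BN → ReLU → channel attention) each followed by 2×2 max
  pooling; a channel-attention-conv bridge; N stages of (×2 upsample → 3×3
  conv → BN → ReLU); exit 3×3 conv back to the branch's channel count.
  The module's output is added to the coarse map (`refined = coarse +
  ARRM(coarse)`).  Feeding only the prediction map (not decoder features)
  keeps the head a pure prediction refiner; the alternative wiring is a
  known open design point.  The three heads do not share weights.

### Geometry

In `same` mode, outputs match inputs (inputs must be divisible by 8; an
optional centre `output_crop` yields e.g. 256→164, where the refinement
head runs with 2 pooling stages so 164 = 4·41 divides evenly).  The
270→80 valid-convolution geometry of the original design is not
reconstructible layer by layer from its description, so `valid` mode is
realized as same-padding interior computation followed by a centre crop
with a fixed margin of 190 px; odd interior sizes (270/2 = 135) use
ceil-division downsampling with asymmetric padding, and decoder upsamplings
crop to the skip's size.

## Losses

`L = α·L1 + L2` with L1 on coarse and L2 on refined maps (α default 1).
Per stage: probability branch `β3·CE + β4·Dice` (ε = 0.001), HV branch
`β1·MSE + β2·gradient-MSE` (the gradient-MSE averages over the nuclear
pixel set M only, per channel; an empty M returns 0 with a warning, since
nucleus-free patches occur when sampling), classification branch
`β5·CE + β6·GDL`.  All β default to 1; β2 = 2 is the documented choice for
the 270→80 regime.  Numerical choices: CE floors probabilities at 1e-8;
CE's pixel normalizer counts pixels, not pixels×channels; GDL weights
`w_l = 1/(Σ_n r_ln)²` are constants of the truth, and classes absent from
the truth are skipped (their weight is undefined).  The gradient operator
inside the gradient-MSE is identical to the target generator's, so perfect
predictions score exactly zero.

## Post-processing

Sobel responses of the predicted HV channels are taken **in magnitude**
and min–max rescaled to [0, 1] per map before the pixelwise max that forms
the energy `Sm`.  The magnitude is deliberate: boundary jumps (+1 → −1)
produce strongly *negative* raw derivatives, and a signed rescale would
map them to 0 rather than 1.  The rescale calibrates the fixed threshold
`k` across images.  Markers are the connected components (8-connectivity)
of `relu(τ(q,h) − τ(Sm,k))` with components under `min_instance_px`
removed; the watershed energy is the foreground-masked ridge indicator
`τ(Sm,k)·τ(q,h)`, so the ascending flood fills nucleus interiors first and
fronts meet mid-ridge between touching nuclei.  Flooding is confined to
`τ(q,h)`; output instances below `min_instance_px` are dropped and ids
canonicalized.  Defaults: `h = 0.5`, `k = 0.4`, `min_instance_px = 10`,
`sobel_ksize = 5` — `h`/`k` are reported only as "set according to
experience" in the source design, so the defaults here were chosen to pass
the ground-truth round-trip property on synthetic scenes and are exposed in
`PostprocConfig`.  Typing is a per-instance majority vote of the pixelwise
class argmax, background votes excluded, ties broken by summed
probability, with a fallback to the strongest summed non-background class
when every pixel votes background.

## Metrics

Instances pair when IoU > 0.5; above that threshold the pairing is
provably unique, so greedy collection equals optimal assignment (asserted
against a Hungarian-algorithm oracle in the tests).  PQ = DQ·SQ with
DQ = TP/(TP + FP/2 + FN/2) and SQ the mean matched IoU;
Fd = 2TP/(2TP + FP + FN); per-type
Ft = 2(TPt+TNt) / (2(TPt+TNt) + 2FPt + 2FNt + FPd + FNd).  The detection
pairing for Fd reuses the IoU matching for consistency.  Multi-image
evaluation pools raw counts before forming ratios, the stable convention
for small test sets.  Zero-denominator conventions: empty-vs-empty scores
1; otherwise a zero denominator scores 0.

## Synthetic scenes

The generator renders rotated, shaded ellipses with class-dependent hue on
a textured pale background with Gaussian noise, a skewed type distribution
(default 70/15/10/5 over four types), and optional touching (later nuclei
may abut but never overwrite earlier ones, keeping the partition
well-defined).  It emulates the geometric failure modes the method targets
— curved boundaries, clusters, imbalance — but none of the appearance
variability of real H&E: no stain variation, no texture inside nuclei, no
out-of-focus blur, no mimicking structures.  Tests passing on these scenes
therefore validate the machinery (encoding, optimization, watershed,
scoring), not clinical-grade accuracy on real slides.

## Desk-scale configurations

The full-size model (base width 64) is far too slow for CPU-only testing,
so the package fixes reduced presets (`aernet.presets`).  Scenes are 64×64
patches with 4 nuclei of radius 8–13 px — diameters of 16–26 px, the scale
the HV representation is designed for (much smaller nuclei leave too few
interior pixels for the boundary ridge to stand out of the regression
smear).  The toy objective uses β2 = 2, the gradient-fidelity setting also
documented for the valid-mode regime.  Two model sizes are used:

* **Overfit-one-batch** (base width 2, ≈40k parameters) — 200 Adam steps
  (lr 2e-3, batch 2) on 4 fixed patches must drive the total loss below
  25% of its initial value; this verifies gradient flow through attention
  gates and refinement residuals and is cheap enough to repeat over many
  seeds.
* **Toy generalization** (base width 4, ≈150k parameters) — training on 64
  synthetic patches (two 15-epoch stages, Adam lr 1e-3 stepped to 3e-4
  mid-stage, batch 4, flips + blur augmentation) then held-out evaluation
  on 16 scenes.  Width 2 regresses the foreground well but its HV maps are
  too noisy for stable watershed separation; width 4 is the smallest
  preset whose distance maps stay smooth across seeds.  The 1e-3 rate,
  higher than the 1e-4 used at full scale, matches the reduced model and
  the small easy dataset.

Full-scale defaults (stage depths 3-4-6-3, two 50-epoch stages, Adam 1e-4
stepped to 1e-5 at epoch 25, batch 4, encoder never frozen) remain in
`TrainConfig`/`ModelConfig` for reference and are exercised structurally
(scheduler and checkpoint tests) rather than to convergence.

## Numerical and engineering notes

* The network runs on a package-local numpy reverse-mode autodiff engine;
  convolution uses numba-compiled direct kernels (with an im2col numpy
  fallback), float32 parameters, He-normal seeded initialization.
  Eval-mode forwards build no graph, so inference memory stays flat.
* Eval-mode forwards are bit-deterministic for fixed weights and inputs.
  Training is deterministic per seed on a given build; exact bitwise
  reproducibility across numba/BLAS builds is not guaranteed.
* Batch norm uses batch statistics in training and running averages
  (momentum 0.1) in eval; small-batch training therefore shows some
  train/eval gap, visible as softer probability maps early in training.
* Checkpoints are `.npz` archives embedding the model config as JSON;
  save → load → forward is bit-identical.

## Known limitations

* No stain normalization, tiling/stitching of whole-slide images, or
  test-time augmentation; the pipeline consumes pre-cut patches.
* The valid-mode geometry reproduces the published input/output contract,
  not the original layer-by-layer cropping arithmetic, so weights are not
  interchangeable with implementations that use true valid convolutions.
* Pretrained-backbone loading is a hook only; no weights ship with the
  package.
* The watershed separates touching convex-ish nuclei; heavily overlapping
  or ring-shaped instances violate the star-convexity assumption of the HV
  encoding.
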