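# aernet

Simultaneous **nuclei instance segmentation and classification** for H&E
histology patches, built around an attention-enhanced residual refinement
network of the HoVer-Net family.

Accurately separating clustered nuclei and typing them (epithelial,
inflammatory, spindle-shaped, ...) is a core step in computational
pathology for colorectal and pan-cancer cohorts.  Two obstacles dominate:
touching nuclei with ambiguous boundaries, and heavy class imbalance (one
nucleus type often outnumbers another fifty-fold).  This package implements
an architecture and training objective aimed at both, together with the
full downstream pipeline: distance-map target encoding, watershed
post-processing, and instance-level evaluation.

## The model

One shared encoder feeds three structurally identical decoder branches:

* a **nuclear probability** branch (foreground/background),
* an **HV-distance regression** branch predicting, per nucleus pixel, the
  horizontal and vertical offset to its instance's centre of mass,
  normalized per instance to [−1, 1],
* a **classification** branch over K nucleus types plus background.

The encoder is a ResNet-50-style stack whose stem keeps full resolution
(stride-1 7×7 conv, no initial pooling) and whose four stages each end with
a channel- then spatial-attention block (CBAM-style).  Decoders upsample ×2
three times with dense blocks of 8 and 4 dense units after the first two
upsamplings, merging encoder skips by elementwise addition.  Each branch
head carries a compact encoder–decoder **attention-enhanced residual
refinement module (ARRM)** that emits an additive correction:
`refined = coarse + ARRM(coarse)`.  Both predictions are supervised:

```
L = α·L1 + L2,   Li = Li,a + Li,b + Li,c
La = β3·Lce + β4·Ldice          (probability branch)
Lb = β1·Lmse + β2·Lmsge         (HV regression branch)
Lc = β5·Lce + β6·GDL            (classification branch)
```

where `Lmsge` is a gradient MSE over nuclear pixels and `GDL` is the
generalized Dice loss with per-class weights `w_l = 1/(Σ_n r_ln)²`, which
up-weights rare nucleus types.

At inference, Sobel responses of the predicted HV maps ridge along
instance boundaries; thresholding probability (`h`) and Sobel energy (`k`)
yields markers and an energy landscape for a marker-controlled watershed,
and each instance takes the majority-vote class of its pixels.  Evaluation
uses unique IoU > 0.5 matching, Panoptic Quality (PQ = DQ × SQ), the
detection F-score `Fd` and per-type classification F-scores `Ft`.

Everything runs on a self-contained numpy reverse-mode autodiff engine
(`aernet.nn`) with numba-compiled convolution kernels — no GPU or deep
learning framework required.  A synthetic-scene generator (elliptical
nuclei, controllable counts/sizes/touching, skewed type distribution)
makes the whole pipeline testable without external datasets.

## Worked example

```python
import numpy as np
from aernet import (SceneSpec, generate_scene, compute_hv_map,
                    watershed_instances, match_instances, panoptic_quality)

# a seeded synthetic patch with 10 separated nuclei
_, instances, classes = generate_scene(SceneSpec(n_nuclei=10, seed=3))

# encode ground truth the way the regression branch learns it,
# then run the watershed round trip on the ideal maps
hv = compute_hv_map(instances)
recovered = watershed_instances((instances > 0).astype(float), hv)

m = match_instances(instances, recovered)
dq, sq, pq = panoptic_quality(m)
print(f"TP={m.tp} FP={m.fp} FN={m.fn}  DQ={dq:.3f} SQ={sq:.3f} PQ={pq:.3f}")
```

Output:

```
TP=10 FP=0 FN=0  DQ=1.000 SQ=1.000 PQ=1.000
```

All ten nuclei are recovered as unique IoU > 0.5 matches (DQ = 1) with
pixel-perfect masks on this scene (SQ, the mean IoU over matched pairs, is
1); on touching clusters SQ drops slightly as the watershed places the
split line inside the boundary ridge.

Training a width-reduced model on synthetic patches end to end:

```bash
aernet fixtures --n-images 8 --seed 0 --out scenes/
aernet train --checkpoint model.npz --n-images 16 --seed 0
aernet infer --checkpoint model.npz --image-dir scenes/ --out preds/
aernet eval --gt-dir scenes/ --pred-dir preds/
```

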