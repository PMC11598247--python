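"""Shared data model: configuration dataclasses and label-map containers.

Conventions used throughout the package:

* **Images** are ``H x W x 3`` uint8 arrays (channels last).
* **Instance label maps** are ``H x W`` non-negative integer arrays; 0 is
  background and positive ids enumerate nuclei.  After canonicalization the
  ids form ``{1..N}`` with no gaps.
* **Class label maps** are ``H x W`` integer arrays in ``{0..K}``; 0 is
  background, ``1..K`` are nucleus types, and every instance carries exactly
  one type.
* **HV maps** are ``H x W x 2`` float arrays; channel 0 holds the horizontal
  and channel 1 the vertical signed offset of each nucleus pixel to its
  instance's centre of mass, normalized per instance to ``[-1, 1]``.
  Background is exactly 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = [
    "SceneSpec",
    "ModelConfig",
    "LossWeights",
    "PostprocConfig",
    "TrainConfig",
    "MatchResult",
    "validate_image",
    "validate_instance_map",
    "validate_class_map",
    "validate_hv_map",
]

MIN_PATCH_SIZE = 64  # four pooling stages downstream need >= 64 px


@dataclass
class SceneSpec:
    """Parameters of one synthetic histology scene."""

    height: int = 256
    width: int = 256
    n_nuclei: int = 10
    radius_range: tuple[float, float] = (8.0, 16.0)
    class_probabilities: tuple[float, ...] = (0.70, 0.15, 0.10, 0.05)
    allow_touching: bool = False
    seed: int = 0

    def __post_init__(self):
        probs = np.asarray(self.class_probabilities, dtype=float)
        if probs.min() < 0 or abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("class_probabilities must be a simplex vector")
        rmin, rmax = self.radius_range
        if not (0 < rmin <= rmax):
            raise ValueError("radius_range must satisfy 0 < min <= max")
        if rmax >= min(self.height, self.width) / 2:
            raise ValueError("radius_max must be < min(H, W) / 2")
        if self.n_nuclei < 0:
            raise ValueError("n_nuclei must be non-negative")

    @property
    def num_classes(self) -> int:
        return len(self.class_probabilities)


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    Defaults mirror the full-size network: a ResNet-50-style encoder with
    stage depths (3, 4, 6, 3), CBAM-style attention with reduction 16,
    decoder dense blocks of 8 and 4 units, and a 4-pool refinement head.
    ``base_width`` scales every channel count so desk-scale models are cheap.
    """

    residual_units_per_stage: tuple[int, int, int, int] = (3, 4, 6, 3)
    attention_reduction: int = 16
    num_classes: int = 4
    padding_mode: str = "same"  # {"same", "valid"}
    valid_margin: int = 190  # valid mode: output = input - margin (270 -> 80)
    output_crop: int | None = None  # same mode: optional centre crop of outputs
    arrm_pool_stages: int = 4
    arrm_width: int = 32
    base_width: int = 64
    dense_growth: int = 32
    use_arrm: bool = True
    seed: int = 0

    def __post_init__(self):
        if len(self.residual_units_per_stage) != 4 or min(self.residual_units_per_stage) < 1:
            raise ValueError("residual_units_per_stage needs 4 entries, all >= 1")
        if self.arrm_pool_stages not in (2, 3, 4):
            raise ValueError("arrm_pool_stages must be in {2, 3, 4}")
        if self.padding_mode not in ("same", "valid"):
            raise ValueError("padding_mode must be 'same' or 'valid'")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["residual_units_per_stage"] = list(self.residual_units_per_stage)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        d["residual_units_per_stage"] = tuple(d["residual_units_per_stage"])
        return cls(**d)


@dataclass
class LossWeights:
    """Weights of the composite objective.

    ``alpha`` scales the auxiliary (coarse-prediction) loss; ``beta1``/
    ``beta2`` weight MSE / gradient-MSE in the distance branch, ``beta3``/
    ``beta4`` cross-entropy / dice in the probability branch and ``beta5``/
    ``beta6`` cross-entropy / generalized dice in the classification branch.
    ``epsilon`` is the dice smoothing constant.
    """

    alpha: float = 1.0
    beta1: float = 1.0
    beta2: float = 1.0
    beta3: float = 1.0
    beta4: float = 1.0
    beta5: float = 1.0
    beta6: float = 1.0
    epsilon: float = 0.001

    def __post_init__(self):
        ws = (self.alpha, self.beta1, self.beta2, self.beta3,
              self.beta4, self.beta5, self.beta6)
        if min(ws) < 0:
            raise ValueError("loss weights must be >= 0")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")


@dataclass
class PostprocConfig:
    """Watershed post-processing parameters.

    ``h`` thresholds the foreground probability, ``k`` thresholds the Sobel
    energy of the HV maps; components smaller than ``min_instance_px`` are
    discarded as debris.
    """

    h: float = 0.5
    k: float = 0.4
    min_instance_px: int = 10
    sobel_ksize: int = 5

    def __post_init__(self):
        if not (0 < self.h < 1 and 0 < self.k < 1):
            raise ValueError("h and k must lie in (0, 1)")
        if self.min_instance_px < 1:
            raise ValueError("min_instance_px must be >= 1")
        if self.sobel_ksize < 3 or self.sobel_ksize % 2 == 0:
            raise ValueError("sobel_ksize must be an odd integer >= 3")


@dataclass
class TrainConfig:
    """Optimization schedule: two identical stages, Adam, stepped lr."""

    epochs_per_stage: int = 50
    n_stages: int = 2
    lr_initial: float = 1e-4
    lr_final: float = 1e-5
    lr_step_epoch: int = 25  # within each stage
    batch_size: int = 4
    seed: int = 0


@dataclass
class MatchResult:
    """Unique IoU > 0.5 instance matching between truth and prediction."""

    tp_pairs: list[tuple[int, int, float]] = field(default_factory=list)
    fp_ids: list[int] = field(default_factory=list)
    fn_ids: list[int] = field(default_factory=list)

    @property
    def tp(self) -> int:
        return len(self.tp_pairs)

    @property
    def fp(self) -> int:
        return len(self.fp_ids)

    @property
    def fn(self) -> int:
        return len(self.fn_ids)

    @property
    def iou_sum(self) -> float:
        return float(sum(iou for _, _, iou in self.tp_pairs))


# -- validation helpers ------------------------------------------------------


def validate_image(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("image must be H x W x 3")
    if img.dtype != np.uint8:
        raise ValueError("image must be uint8")
    if img.shape[0] < MIN_PATCH_SIZE or img.shape[1] < MIN_PATCH_SIZE:
        raise ValueError(f"image sides must be >= {MIN_PATCH_SIZE} px")
    return img


def validate_instance_map(m: np.ndarray) -> np.ndarray:
    m = np.asarray(m)
    if m.ndim != 2:
        raise ValueError("instance map must be 2-D")
    if not np.issubdtype(m.dtype, np.integer):
        raise ValueError("instance map must be integer-typed")
    if m.min() < 0:
        raise ValueError("instance ids must be non-negative")
    return m


def validate_class_map(classes: np.ndarray, instances: np.ndarray) -> np.ndarray:
    classes = np.asarray(classes)
    instances = validate_instance_map(instances)
    if classes.shape != instances.shape:
        raise ValueError("class map and instance map shapes differ")
    if np.any((classes > 0) & (instances == 0)):
        raise ValueError("class labels present on background pixels")
    for iid in np.unique(instances):
        if iid == 0:
            continue
        vals = np.unique(classes[instances == iid])
        if len(vals) != 1:
            raise ValueError(f"instance {iid} has more than one class")
    return classes


def validate_hv_map(hv: np.ndarray, instances: np.ndarray | None = None) -> np.ndarray:
    hv = np.asarray(hv, dtype=float)
    if hv.ndim != 3 or hv.shape[2] != 2:
        raise ValueError("HV map must be H x W x 2")
    if np.abs(hv).max(initial=0.0) > 1.0 + 1e-9:
        raise ValueError("HV values must lie in [-1, 1]")
    if instances is not None and np.any(hv[instances == 0] != 0):
        raise ValueError("HV map must be exactly 0 on background")
    return hv
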