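"""Desk-scale presets: a width-reduced model and small synthetic scenes.

The full-size architecture (base width 64, stage depths 3-4-6-3) is far too
expensive for CPU-only smoke training, so the package ships one agreed
reduced configuration used by its own end-to-end checks: 64 x 64 patches
with ~6 small nuclei, a base width of 2 with depth-1 stages, dense growth 2
and a 2-pool refinement head.  Optimization for these runs uses Adam at
1e-3 (stepped down mid-schedule), a higher rate than full-scale training
since the reduced model sees only dozens of easy patches.
"""

from __future__ import annotations

from .types import LossWeights, ModelConfig, SceneSpec, TrainConfig

__all__ = [
    "toy_model_config",
    "toy_segmenter_config",
    "toy_scene_spec",
    "toy_train_config",
    "toy_loss_weights",
]


def toy_model_config(seed: int = 0, **overrides) -> ModelConfig:
    """Minimal width-2 model: cheap enough for repeated-seed diagnostics."""
    base = dict(
        residual_units_per_stage=(1, 1, 1, 1),
        base_width=2,
        dense_growth=2,
        arrm_width=4,
        arrm_pool_stages=2,
        num_classes=4,
        seed=seed,
    )
    base.update(overrides)
    return ModelConfig(**base)


def toy_segmenter_config(seed: int = 0, **overrides) -> ModelConfig:
    """Width-4 model for the trained-segmenter checks.

    Width 2 can regress the foreground probability well but produces HV
    maps too noisy for stable watershed separation; width 4 is the smallest
    preset whose distance maps stay smooth enough across seeds.
    """
    return toy_model_config(
        seed=seed, base_width=4, dense_growth=4, arrm_width=8, **overrides
    )


def toy_scene_spec(seed: int = 0, **overrides) -> SceneSpec:
    """64x64 patches with 4 well-sized nuclei (16-26 px across).

    Nucleus diameters match the scale the HV representation is designed
    for; much smaller nuclei leave too few interior pixels for the
    boundary ridge to stand out of the regression smear.
    """
    base = dict(
        height=64,
        width=64,
        n_nuclei=4,
        radius_range=(8.0, 13.0),
        class_probabilities=(0.70, 0.15, 0.10, 0.05),
        allow_touching=False,
        seed=seed,
    )
    base.update(overrides)
    return SceneSpec(**base)


def toy_train_config(seed: int = 0, **overrides) -> TrainConfig:
    base = dict(
        epochs_per_stage=15,
        n_stages=2,
        lr_initial=1e-3,
        lr_final=3e-4,
        lr_step_epoch=8,
        batch_size=4,
        seed=seed,
    )
    base.update(overrides)
    return TrainConfig(**base)


def toy_loss_weights() -> LossWeights:
    """Toy objective: gradient-MSE weight 2, the documented setting for the
    valid-mode regime; sharper HV gradients are what the watershed needs."""
    return LossWeights(beta2=2.0)
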