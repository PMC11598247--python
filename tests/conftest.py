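import numpy as np
import pytest

from aernet import ModelConfig, SceneSpec, generate_scene


@pytest.fixture(scope="session")
def toy_config() -> ModelConfig:
    """Width-reduced architecture used throughout the CPU test suite."""
    return ModelConfig(
        residual_units_per_stage=(1, 1, 1, 1),
        base_width=2,
        dense_growth=2,
        arrm_width=4,
        arrm_pool_stages=2,
        num_classes=4,
        seed=0,
    )


@pytest.fixture(scope="session")
def small_scene():
    """One 96x96 scene with 5 separated nuclei (image, instances, classes)."""
    spec = SceneSpec(height=96, width=96, n_nuclei=5, radius_range=(6, 10), seed=7)
    return generate_scene(spec)


def perturbed_prediction(instances: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """A plausible imperfect prediction: shifts, dropouts and spurious blobs."""
    from scipy import ndimage

    h, w = instances.shape
    pred = np.zeros_like(instances)
    next_id = 1
    for iid in np.unique(instances):
        if iid == 0:
            continue
        if rng.random() < 0.15:  # missed detection
            continue
        mask = instances == iid
        dy, dx = rng.integers(-2, 3, size=2)
        mask = np.roll(np.roll(mask, dy, axis=0), dx, axis=1)
        if rng.random() < 0.5:
            mask = ndimage.binary_dilation(mask)
        free = mask & (pred == 0)
        if free.sum() < 4:
            continue
        pred[free] = next_id
        next_id += 1
    for _ in range(rng.integers(0, 3)):  # spurious blobs
        cy, cx = rng.integers(5, h - 5), rng.integers(5, w - 5)
        yy, xx = np.mgrid[0:h, 0:w]
        blob = (yy - cy) ** 2 + (xx - cx) ** 2 <= rng.integers(4, 30)
        free = blob & (pred == 0)
        if free.sum() >= 4:
            pred[free] = next_id
            next_id += 1
    return pred
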