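"""Seeded synthetic histology scenes.

Generates patches that emulate the geometry of H&E-stained tissue at the
level the segmentation pipeline cares about: darkly stained elliptical
nuclei with curved boundaries and optional touching clusters, on a pale
textured background, with a skewed type distribution (most real cohorts are
dominated by one or two nucleus types).  It makes no attempt at realistic
stain physics — colours are flat class-dependent hues with shading and
Gaussian noise.
"""

from __future__ import annotations

import numpy as np

from .types import SceneSpec, validate_class_map

__all__ = ["generate_scene", "canonicalize_instances"]

# muted H&E-like palette: background pinkish, nuclei blue-purple with a
# class-dependent hue shift
_BACKGROUND_RGB = np.array([232.0, 220.0, 228.0])
_CLASS_RGB = [
    np.array([88.0, 60.0, 132.0]),   # type 1: blue-purple
    np.array([60.0, 76.0, 148.0]),   # type 2: bluer
    np.array([120.0, 56.0, 108.0]),  # type 3: magenta-leaning
    np.array([70.0, 96.0, 110.0]),   # type 4: grey-blue
    np.array([140.0, 90.0, 70.0]),   # extra types cycle warm hues
    np.array([96.0, 120.0, 72.0]),
]


def canonicalize_instances(m: np.ndarray) -> np.ndarray:
    """Relabel positive ids to 1..N (ascending original id), background 0."""
    m = np.asarray(m)
    if m.ndim != 2 or not np.issubdtype(m.dtype, np.integer):
        raise ValueError("instance map must be a 2-D integer array")
    if m.size and m.min() < 0:
        raise ValueError("instance ids must be non-negative")
    ids = np.unique(m)
    ids = ids[ids > 0]
    lut = np.zeros(int(m.max(initial=0)) + 1, dtype=np.int32)
    lut[ids] = np.arange(1, len(ids) + 1, dtype=np.int32)
    return lut[m]


def _ellipse_mask(height, width, cy, cx, ry, rx, theta):
    """Boolean mask of a rotated ellipse, clipped to the canvas."""
    yy, xx = np.mgrid[0:height, 0:width]
    dy, dx = yy - cy, xx - cx
    ct, st = np.cos(theta), np.sin(theta)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    return (u / rx) ** 2 + (v / ry) ** 2 <= 1.0


def generate_scene(spec: SceneSpec):
    """Render one scene.

    Returns ``(image, instance_map, class_map)``.  Placement draws random
    centres, radii and orientations; when ``allow_touching`` is false a
    candidate overlapping an existing nucleus is rejected (so fewer than
    ``n_nuclei`` instances may be placed), otherwise later nuclei may abut
    earlier ones but never overwrite their pixels (first-come ownership).
    Identical specs (including seed) give bit-identical outputs.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    rmin, rmax = spec.radius_range
    instances = np.zeros((h, w), dtype=np.int32)
    class_map = np.zeros((h, w), dtype=np.int32)
    inst_classes: dict[int, int] = {}
    k = spec.num_classes

    placed = 0
    attempts = 0
    max_attempts = max(50 * spec.n_nuclei, 1)
    while placed < spec.n_nuclei and attempts < max_attempts:
        attempts += 1
        ry = rng.uniform(rmin, rmax)
        rx = rng.uniform(rmin, rmax)
        margin = max(ry, rx) + 1
        cy = rng.uniform(margin, h - margin)
        cx = rng.uniform(margin, w - margin)
        theta = rng.uniform(0, np.pi)
        cls = 1 + rng.choice(k, p=np.asarray(spec.class_probabilities))
        mask = _ellipse_mask(h, w, cy, cx, ry, rx, theta)
        if not mask.any():
            continue
        if spec.allow_touching:
            free = mask & (instances == 0)
            # a nucleus buried under earlier ones is not a valid instance
            if free.sum() < 0.5 * mask.sum():
                continue
            mask = free
        elif (instances[mask] > 0).any():
            continue
        placed += 1
        instances[mask] = placed
        class_map[mask] = cls
        inst_classes[placed] = int(cls)

    image = _render(instances, class_map, rng)
    validate_class_map(class_map, instances)
    return image, instances, class_map


def _render(instances: np.ndarray, class_map: np.ndarray, rng) -> np.ndarray:
    h, w = instances.shape
    img = np.empty((h, w, 3))
    img[:] = _BACKGROUND_RGB
    # low-frequency background texture
    texture = rng.normal(0, 1, size=(h // 8 + 1, w // 8 + 1))
    texture = np.kron(texture, np.ones((8, 8)))[:h, :w]
    img += 6.0 * texture[:, :, None]

    for iid in np.unique(instances):
        if iid == 0:
            continue
        mask = instances == iid
        cls = int(class_map[mask][0])
        base = _CLASS_RGB[(cls - 1) % len(_CLASS_RGB)]
        ys, xs = np.nonzero(mask)
        cy, cx = ys.mean(), xs.mean()
        r = np.sqrt((ys - cy) ** 2 + (xs - cx) ** 2)
        shade = 1.0 - 0.35 * r / max(r.max(), 1.0)  # darker core, lighter rim
        img[ys, xs] = base[None, :] * shade[:, None] + 30.0 * (1 - shade[:, None])

    img += rng.normal(0, 3.0, size=img.shape)
    return np.clip(img, 0, 255).astype(np.uint8)
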