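"""From predicted maps to instance segmentations.

The HV distance maps jump sharply between adjacent nuclei, so their Sobel
responses ridge along instance boundaries.  Thresholding the foreground
probability at ``h`` and the Sobel energy at ``k`` yields markers (foreground
minus boundary ridges) and an energy landscape; a marker-controlled
watershed confined to the foreground then separates touching nuclei.
Instance types follow by majority vote of the per-pixel class argmax within
each instance.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.segmentation import watershed as _watershed

from .synthetic import canonicalize_instances
from .types import PostprocConfig

__all__ = [
    "sobel_energy",
    "threshold",
    "markers_and_energy",
    "watershed_instances",
    "assign_types",
]


def _sobel_kernels(ksize: int) -> tuple[np.ndarray, np.ndarray]:
    """Separable Sobel derivative kernels of odd size >= 3.

    Built the classical way: a binomial smoothing vector crossed with a
    derivative-of-binomial vector (ksize 3 gives the familiar [-1,0,1] x
    [1,2,1]).
    """
    smooth = np.array([1.0])
    for _ in range(ksize - 1):
        smooth = np.convolve(smooth, [1.0, 1.0])
    deriv = np.array([1.0])
    for _ in range(ksize - 2):
        deriv = np.convolve(deriv, [1.0, 1.0])
    deriv = np.convolve(deriv, [1.0, -1.0])
    hx = np.outer(smooth, deriv)  # d/dx: derivative across columns
    hy = np.outer(deriv, smooth)  # d/dy: derivative across rows
    return hx, hy


def _rescale01(a: np.ndarray) -> np.ndarray:
    lo, hi = a.min(), a.max()
    if hi - lo <= 0:
        return np.zeros_like(a)
    return (a - lo) / (hi - lo)


def sobel_energy(pred_hv: np.ndarray, ksize: int = 5) -> np.ndarray:
    """Boundary-highlighting energy Sm = max(Hx(px), Hy(py)).

    Each Sobel response is taken in magnitude and min–max rescaled to [0,1]
    before the pixelwise max, so a fixed threshold k is meaningful across
    images regardless of the raw response scale.
    """
    hv = np.asarray(pred_hv, dtype=np.float64)
    if hv.ndim != 3 or hv.shape[2] != 2:
        raise ValueError("HV map must be H x W x 2")
    hx, hy = _sobel_kernels(ksize)
    gx = np.abs(ndimage.convolve(hv[:, :, 0], hx, mode="nearest"))
    gy = np.abs(ndimage.convolve(hv[:, :, 1], hy, mode="nearest"))
    return np.maximum(_rescale01(gx), _rescale01(gy))


def threshold(a: np.ndarray, b: float) -> np.ndarray:
    """tau(a, b): 1 where a > b, else 0 (strict inequality)."""
    return (np.asarray(a) > b).astype(np.uint8)


def markers_and_energy(
    q: np.ndarray, sm: np.ndarray, cfg: PostprocConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Watershed seeds and energy landscape from probability and Sobel maps.

    Markers M = relu(tau(q, h) - tau(Sm, k)), connected-component labeled
    (8-connectivity) with components below ``min_instance_px`` dropped.

    The energy landscape is the foreground-masked boundary indicator
    E = tau(Sm, k) * tau(q, h): zero on ridge-free foreground so the
    ascending flood fills nucleus interiors first and ridge pixels last,
    with fronts meeting mid-ridge between touching nuclei.
    """
    cfg = cfg or PostprocConfig()
    fg = threshold(q, cfg.h).astype(np.int8)
    ridge = threshold(sm, cfg.k).astype(np.int8)
    marker_mask = np.maximum(fg - ridge, 0).astype(bool)
    markers, n = ndimage.label(marker_mask, structure=np.ones((3, 3)))
    if n:
        sizes = np.bincount(markers.ravel())
        small = np.flatnonzero(sizes < cfg.min_instance_px)
        markers[np.isin(markers, small[small > 0])] = 0
        markers = canonicalize_instances(markers)
    energy = (ridge & fg).astype(np.float64)
    return markers, energy


def watershed_instances(
    q: np.ndarray, pred_hv: np.ndarray, cfg: PostprocConfig | None = None
) -> np.ndarray:
    """Marker-controlled watershed segmentation of the predicted maps."""
    cfg = cfg or PostprocConfig()
    q = np.asarray(q, dtype=np.float64)
    if q.shape != pred_hv.shape[:2]:
        raise ValueError("probability and HV maps must share spatial shape")
    sm = sobel_energy(pred_hv, cfg.sobel_ksize)
    markers, energy = markers_and_energy(q, sm, cfg)
    fg = threshold(q, cfg.h).astype(bool)
    if markers.max() == 0:
        return np.zeros_like(markers)
    labels = _watershed(energy, markers=markers, mask=fg)
    sizes = np.bincount(labels.ravel())
    small = np.flatnonzero(sizes < cfg.min_instance_px)
    labels[np.isin(labels, small[small > 0])] = 0
    return canonicalize_instances(labels)


def assign_types(
    instances: np.ndarray, class_probs: np.ndarray
) -> tuple[dict[int, int], np.ndarray]:
    """Per-instance type by majority vote of the pixelwise class argmax.

    ``class_probs`` is H x W x (K+1) with channel 0 = background.
    Background votes are excluded; if every pixel of an instance votes
    background, the type falls back to the highest summed non-background
    probability.  Ties break by highest summed probability of the tied
    types.  Returns the instance -> type table and the painted class map.
    """
    instances = np.asarray(instances)
    probs = np.asarray(class_probs, dtype=np.float64)
    if probs.ndim != 3 or probs.shape[:2] != instances.shape:
        raise ValueError("class probabilities must be H x W x (K+1)")
    k = probs.shape[2] - 1
    argmax = probs.argmax(axis=2)
    types: dict[int, int] = {}
    class_map = np.zeros_like(instances, dtype=np.int32)
    for iid in np.unique(instances):
        if iid == 0:
            continue
        mask = instances == iid
        votes = np.bincount(argmax[mask], minlength=k + 1)
        votes[0] = 0  # background does not vote
        summed = probs[mask].sum(axis=0)
        if votes.max() == 0:
            t = int(summed[1:].argmax()) + 1
        else:
            tied = np.flatnonzero(votes == votes.max())
            t = int(tied[summed[tied].argmax()])
        types[int(iid)] = t
        class_map[mask] = t
    return types, class_map
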