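"""Horizontal/vertical distance-map targets.

Each nucleus pixel stores its signed horizontal and vertical offset to the
instance's centre of mass, normalized per instance so the extreme offsets
map to -1 and +1.  Scaling is done separately for the negative and positive
side of each axis, so the centre of mass itself always maps to 0 even for
asymmetric instances.  Gradients of these maps peak between touching nuclei,
which is what post-processing exploits to split clusters.
"""

from __future__ import annotations

import numpy as np

__all__ = ["compute_hv_map", "hv_gradient_targets"]


def _normalize_side(offsets: np.ndarray) -> np.ndarray:
    """Scale signed offsets so min -> -1 and max -> +1 (per side)."""
    out = np.zeros_like(offsets, dtype=np.float64)
    neg = offsets < 0
    pos = offsets > 0
    if neg.any():
        out[neg] = offsets[neg] / -offsets[neg].min()
    if pos.any():
        out[pos] = offsets[pos] / offsets[pos].max()
    return out


def compute_hv_map(instances: np.ndarray) -> np.ndarray:
    """Encode an instance label map as an H x W x 2 HV map.

    Channel 0 is horizontal (column offsets), channel 1 vertical (row
    offsets); background pixels are exactly 0.  A single-pixel instance
    encodes (0, 0).
    """
    instances = np.asarray(instances)
    if instances.ndim != 2:
        raise ValueError("instance map must be 2-D")
    hv = np.zeros(instances.shape + (2,), dtype=np.float64)
    for iid in np.unique(instances):
        if iid == 0:
            continue
        ys, xs = np.nonzero(instances == iid)
        cy, cx = ys.mean(), xs.mean()
        hv[ys, xs, 0] = _normalize_side(xs - cx)
        hv[ys, xs, 1] = _normalize_side(ys - cy)
    return hv


def hv_gradient_targets(hv: np.ndarray) -> np.ndarray:
    """Per-pixel gradients of the HV map used by the gradient-MSE loss.

    Returns an H x W x 2 array: channel 0 is the horizontal derivative of
    the horizontal map, channel 1 the vertical derivative of the vertical
    map.  Central differences in the interior, one-sided at the borders.
    """
    hv = np.asarray(hv, dtype=np.float64)
    if hv.ndim != 3 or hv.shape[2] != 2:
        raise ValueError("HV map must be H x W x 2")
    out = np.empty_like(hv)
    out[:, :, 0] = np.gradient(hv[:, :, 0], axis=1)
    out[:, :, 1] = np.gradient(hv[:, :, 1], axis=0)
    return out
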