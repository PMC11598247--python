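"""Composite training objective.

The network emits coarse and refined predictions for three branches and the
total loss is ``L = alpha * L1 + L2`` where ``L1`` is computed from the
coarse maps and ``L2`` from the refined ones.  Each ``Li`` sums three branch
losses:

* probability branch: ``beta3 * CE + beta4 * Dice``
* distance branch:    ``beta1 * MSE + beta2 * gradient-MSE``
* classification:     ``beta5 * CE + beta6 * generalized Dice``

Every public loss accepts either plain numpy arrays (channels-last, as the
rest of the library uses; a float is returned) or autograd ``Tensor``s in
NCHW layout (a differentiable ``Tensor`` is returned) — the same expression
graph drives both, so training optimizes exactly the documented formulas.
"""

from __future__ import annotations

import warnings

import numpy as np

from .nn.autograd import Tensor, as_tensor, concat
from .types import LossWeights

__all__ = [
    "mse_loss",
    "msge_loss",
    "dice_loss",
    "ce_loss",
    "generalized_dice_loss",
    "branch_losses",
    "softmax",
]

LOG_FLOOR = 1e-8  # cross-entropy is undefined at 0 probability


def _prepare(*arrays):
    """Wrap inputs as Tensors; remember whether everything was numpy."""
    numeric = all(not isinstance(a, Tensor) for a in arrays if a is not None)
    return [None if a is None else as_tensor(a) for a in arrays], numeric


def _finish(out: Tensor, numeric: bool):
    return out.item() if numeric else out


def mse_loss(pred_hv, true_hv):
    """Mean squared error over all pixels and both HV channels."""
    (p, t), numeric = _prepare(pred_hv, true_hv)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    return _finish(((p - t) ** 2).mean(), numeric)


def _central_diff(t: Tensor, axis: int) -> Tensor:
    """np.gradient equivalent built from differentiable slice ops."""
    n = t.shape[axis]
    if n < 2:
        return t * 0.0

    def sl(a, b):
        idx = [slice(None)] * t.ndim
        idx[axis] = slice(a, b)
        return t[tuple(idx)]

    first = sl(1, 2) - sl(0, 1)
    last = sl(n - 1, n) - sl(n - 2, n - 1)
    if n == 2:
        return concat([first, last], axis)
    interior = (sl(2, n) - sl(0, n - 2)) * 0.5
    return concat([first, interior, last], axis)


def _hv_channels(hv: Tensor):
    """Split an HV container into (horizontal, vertical, h-axis, v-axis).

    Accepts H x W x 2 (channels last) or N x 2 x H x W (channels first).
    """
    if hv.ndim == 3 and hv.shape[2] == 2:
        return hv[:, :, 0], hv[:, :, 1], 1, 0
    if hv.ndim == 4 and hv.shape[1] == 2:
        return hv[:, 0], hv[:, 1], 2, 1
    raise ValueError("HV container must be HxWx2 or Nx2xHxW")


def msge_loss(pred_hv, true_hv, nuclear_mask):
    """Gradient MSE restricted to the nuclear pixel set M.

    Mean over M of the squared horizontal-gradient error of the horizontal
    channel plus mean over M of the squared vertical-gradient error of the
    vertical channel.  An empty mask (nucleus-free patch) yields 0.
    """
    (p, t), numeric = _prepare(pred_hv, true_hv)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    mask = np.asarray(
        nuclear_mask.data if isinstance(nuclear_mask, Tensor) else nuclear_mask
    ).astype(np.float64)
    m = mask.sum()
    if m == 0:
        warnings.warn("msge_loss: empty nuclear mask, returning 0", stacklevel=2)
        return 0.0 if numeric else as_tensor(0.0)
    ph, pv, hax, vax = _hv_channels(p)
    th, tv, _, _ = _hv_channels(t)
    if mask.shape != ph.shape:
        raise ValueError("mask shape must match one HV channel")
    dh = _central_diff(ph, hax) - _central_diff(th, hax)
    dv = _central_diff(pv, vax) - _central_diff(tv, vax)
    out = (as_tensor(mask) * dh**2).sum() * (1.0 / m) + (
        as_tensor(mask) * dv**2
    ).sum() * (1.0 / m)
    return _finish(out, numeric)


def dice_loss(pred_prob, true_mask, epsilon: float = 0.001):
    """Soft dice: 1 - (2*sum(X*Xhat) + eps) / (sum(X) + sum(Xhat) + eps)."""
    (p, t), numeric = _prepare(pred_prob, true_mask)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    inter = (p * t).sum()
    out = 1.0 - (2.0 * inter + epsilon) / (p.sum() + t.sum() + epsilon)
    return _finish(out, numeric)


def _channel_axis(t: Tensor, channels_last_ndim=3) -> int:
    """Channels-last for numpy-style rank-3 input, axis 1 for NCHW."""
    return t.ndim - 1 if t.ndim == channels_last_ndim else 1


def ce_loss(pred_probs, true_onehot):
    """Pixel-averaged cross-entropy: -(1/N) sum_i sum_m truth * log(pred).

    N counts pixels (each pixel contributes one inner sum over channels);
    predictions are floored at 1e-8 before the log.
    """
    (p, t), numeric = _prepare(pred_probs, true_onehot)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    cax = _channel_axis(p)
    n_pixels = p.data.size // p.shape[cax]
    out = -(as_tensor(t.data) * p.clip_min(LOG_FLOOR).log()).sum() * (1.0 / n_pixels)
    return _finish(out, numeric)


def generalized_dice_loss(pred_probs, true_onehot):
    """Generalized dice over K classes with weights w_l = 1 / (sum_n r_ln)^2.

    Classes absent from the truth get weight 0 (their w_l is undefined);
    weights are treated as constants of the truth, so gradients flow only
    through the predictions.
    """
    (p, t), numeric = _prepare(pred_probs, true_onehot)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    cax = _channel_axis(p)
    axes = tuple(a for a in range(p.ndim) if a != cax)
    r_sums = t.data.sum(axis=axes)  # per-class truth volume
    w = np.where(r_sums > 0, 1.0 / np.maximum(r_sums, 1.0) ** 2, 0.0)
    numer = (as_tensor(t.data) * p).sum(axis=axes)
    denom = (as_tensor(t.data) + p).sum(axis=axes)
    w_t = as_tensor(w)
    out = 1.0 - 2.0 * (w_t * numer).sum() / (w_t * denom).sum()
    return _finish(out, numeric)


def softmax(logits: Tensor, axis: int) -> Tensor:
    """Numerically stable softmax along ``axis`` (differentiable)."""
    logits = as_tensor(logits)
    shift = as_tensor(logits.data.max(axis=axis, keepdims=True))
    e = (logits - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)


def _stage_loss(prob_logits, hv_pred, class_logits, targets, w: LossWeights) -> dict:
    """One stage (coarse or refined) of the composite loss, NCHW Tensors."""
    prob = softmax(prob_logits, axis=1)
    cls = softmax(class_logits, axis=1)
    fg_onehot = targets["fg_onehot"]
    terms = {
        "ce_prob": ce_loss(prob, as_tensor(fg_onehot)),
        "dice": dice_loss(prob[:, 1], as_tensor(fg_onehot[:, 1]), w.epsilon),
        "mse": mse_loss(hv_pred, as_tensor(targets["hv"])),
        "msge": msge_loss(hv_pred, as_tensor(targets["hv"]), targets["mask"]),
        "ce_class": ce_loss(cls, as_tensor(targets["class_onehot"])),
        "gdl": generalized_dice_loss(cls, as_tensor(targets["class_onehot"])),
    }
    terms["La"] = w.beta3 * terms["ce_prob"] + w.beta4 * terms["dice"]
    terms["Lb"] = w.beta1 * terms["mse"] + w.beta2 * terms["msge"]
    terms["Lc"] = w.beta5 * terms["ce_class"] + w.beta6 * terms["gdl"]
    terms["L"] = terms["La"] + terms["Lb"] + terms["Lc"]
    return terms


def branch_losses(outputs, targets: dict, w: LossWeights | None = None):
    """Total objective L = alpha * L1 + L2 over coarse and refined maps.

    ``outputs`` is a BranchOutputs-like object with NCHW Tensors; ``targets``
    holds ``fg_onehot`` (N,2,H,W), ``hv`` (N,2,H,W), ``class_onehot``
    (N,K+1,H,W) and ``mask`` (N,H,W binary nuclear pixels) as numpy arrays.
    Returns ``(total, terms)`` where ``terms`` maps term names to values
    (with ``L1``/``L2`` stage subtotals).
    """
    w = w or LossWeights()
    coarse = _stage_loss(
        outputs.prob_coarse, outputs.hv_coarse, outputs.class_coarse, targets, w
    )
    refined = _stage_loss(
        outputs.prob_refined, outputs.hv_refined, outputs.class_refined, targets, w
    )
    total = w.alpha * coarse["L"] + refined["L"]
    terms = {f"{k}_coarse": v for k, v in coarse.items()}
    terms.update({f"{k}_refined": v for k, v in refined.items()})
    terms["L1"] = coarse["L"]
    terms["L2"] = refined["L"]
    return total, terms
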