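"""Instance-level evaluation: unique IoU matching, Panoptic Quality and
detection / per-type classification F-scores.

A ground-truth and a predicted segment match when their IoU exceeds 0.5;
the threshold makes the pairing mathematically unique (two segments cannot
both overlap the same segment with IoU > 0.5).  Panoptic Quality factors
into Detection Quality ``TP / (TP + FP/2 + FN/2)`` and Segmentation Quality
(mean IoU over matched pairs).  Multi-image evaluation pools raw counts
(TP/FP/FN and IoU sums) across images before forming ratios.
"""

from __future__ import annotations

import numpy as np

from .types import MatchResult

__all__ = [
    "match_instances",
    "panoptic_quality",
    "detection_f1",
    "classification_f1",
    "aggregate_matches",
    "evaluate_pairs",
]


def match_instances(gt: np.ndarray, pred: np.ndarray) -> MatchResult:
    """Pair instances with IoU > 0.5; the rest are FN (truth) / FP (pred)."""
    gt = np.asarray(gt)
    pred = np.asarray(pred)
    if gt.shape != pred.shape:
        raise ValueError("maps must share shape")
    gt_ids, gt_areas = np.unique(gt[gt > 0], return_counts=True)
    pred_ids, pred_areas = np.unique(pred[pred > 0], return_counts=True)
    gt_area = dict(zip(gt_ids.tolist(), gt_areas.tolist()))
    pred_area = dict(zip(pred_ids.tolist(), pred_areas.tolist()))

    overlap = (gt > 0) & (pred > 0)
    pairs, inters = np.unique(
        np.stack([gt[overlap], pred[overlap]]), axis=1, return_counts=True
    )
    result = MatchResult()
    matched_gt: set[int] = set()
    matched_pred: set[int] = set()
    for (g, p), inter in zip(pairs.T.tolist(), inters.tolist()):
        union = gt_area[g] + pred_area[p] - inter
        iou = inter / union
        if iou > 0.5:
            result.tp_pairs.append((int(g), int(p), float(iou)))
            matched_gt.add(g)
            matched_pred.add(p)
    result.tp_pairs.sort()
    result.fn_ids = sorted(int(g) for g in gt_ids if g not in matched_gt)
    result.fp_ids = sorted(int(p) for p in pred_ids if p not in matched_pred)
    return result


def panoptic_quality(match: MatchResult) -> tuple[float, float, float]:
    """(DQ, SQ, PQ) from a match result; empty-vs-empty scores 1."""
    tp, fp, fn = match.tp, match.fp, match.fn
    if tp == 0 and fp == 0 and fn == 0:
        return 1.0, 1.0, 1.0
    denom = tp + 0.5 * fp + 0.5 * fn
    dq = tp / denom if denom else 0.0
    sq = match.iou_sum / tp if tp else 0.0
    return dq, sq, dq * sq


def detection_f1(match: MatchResult) -> float:
    """Fd = 2 TPd / (2 TPd + FPd + FNd)."""
    tp, fp, fn = match.tp, match.fp, match.fn
    if tp == 0 and fp == 0 and fn == 0:
        return 1.0
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom else 0.0


def classification_f1(
    match: MatchResult,
    gt_types: dict[int, int],
    pred_types: dict[int, int],
    t: int,
) -> float:
    """Per-type score combining typing errors on matches with FPd/FNd.

    Over matched pairs: TPt (both type t), TNt (both non-t), FPt (pred t,
    truth non-t), FNt (truth t, pred non-t); then
    Ft = 2(TPt+TNt) / (2(TPt+TNt) + 2 FPt + 2 FNt + FPd + FNd).
    """
    tpt = tnt = fpt = fnt = 0
    for g, p, _ in match.tp_pairs:
        if g not in gt_types:
            raise KeyError(f"ground-truth instance {g} missing from type table")
        if p not in pred_types:
            raise KeyError(f"predicted instance {p} missing from type table")
        g_is_t = gt_types[g] == t
        p_is_t = pred_types[p] == t
        if g_is_t and p_is_t:
            tpt += 1
        elif not g_is_t and not p_is_t:
            tnt += 1
        elif p_is_t:
            fpt += 1
        else:
            fnt += 1
    if match.tp == 0 and match.fp == 0 and match.fn == 0:
        return 1.0
    denom = 2 * (tpt + tnt) + 2 * fpt + 2 * fnt + match.fp + match.fn
    return 2 * (tpt + tnt) / denom if denom else 0.0


def aggregate_matches(matches: list[MatchResult]) -> MatchResult:
    """Pool raw counts across images (ids are namespaced per image)."""
    pooled = MatchResult()
    for i, m in enumerate(matches):
        offset = i * 10_000_000
        pooled.tp_pairs.extend((g + offset, p + offset, iou) for g, p, iou in m.tp_pairs)
        pooled.fp_ids.extend(p + offset for p in m.fp_ids)
        pooled.fn_ids.extend(g + offset for g in m.fn_ids)
    return pooled


def evaluate_pairs(
    pairs: list[tuple[np.ndarray, np.ndarray]],
    type_tables: list[tuple[dict[int, int], dict[int, int]]] | None = None,
    num_types: int | None = None,
) -> dict:
    """Full report over (gt, pred) instance-map pairs.

    Returns {"DQ", "SQ", "PQ", "Fd"} and, when type tables are supplied,
    ``F_type_t`` for every type ``t`` in 1..num_types.
    """
    matches = [match_instances(g, p) for g, p in pairs]
    pooled = aggregate_matches(matches)
    dq, sq, pq = panoptic_quality(pooled)
    report = {"DQ": dq, "SQ": sq, "PQ": pq, "Fd": detection_f1(pooled)}
    if type_tables is not None:
        gt_all: dict[int, int] = {}
        pred_all: dict[int, int] = {}
        for i, (gt_t, pred_t) in enumerate(type_tables):
            offset = i * 10_000_000
            gt_all.update({g + offset: v for g, v in gt_t.items()})
            pred_all.update({p + offset: v for p, v in pred_t.items()})
        if num_types is None:
            num_types = max([*gt_all.values(), *pred_all.values()], default=0)
        for t in range(1, num_types + 1):
            report[f"F_type_{t}"] = classification_f1(pooled, gt_all, pred_all, t)
    return report
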