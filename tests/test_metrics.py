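"""Instance matching, Panoptic Quality and F-scores."""

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from aernet import (
    SceneSpec,
    classification_f1,
    detection_f1,
    generate_scene,
    match_instances,
    panoptic_quality,
)
from aernet.metrics import aggregate_matches, evaluate_pairs
from aernet.types import MatchResult

from conftest import perturbed_prediction


def brute_force_match(gt, pred):
    """Optimal-assignment oracle: maximize total IoU, keep pairs > 0.5."""
    gt_ids = [int(i) for i in np.unique(gt) if i > 0]
    pred_ids = [int(i) for i in np.unique(pred) if i > 0]
    if not gt_ids or not pred_ids:
        return set()
    iou = np.zeros((len(gt_ids), len(pred_ids)))
    for a, g in enumerate(gt_ids):
        gm = gt == g
        for b, p in enumerate(pred_ids):
            pm = pred == p
            inter = (gm & pm).sum()
            if inter:
                iou[a, b] = inter / (gm.sum() + pm.sum() - inter)
    rows, cols = linear_sum_assignment(-iou)
    return {
        (gt_ids[r], pred_ids[c])
        for r, c in zip(rows, cols)
        if iou[r, c] > 0.5
    }


class TestMatchInstances:
    def test_identical_maps_match_perfectly(self, small_scene):
        _, inst, _ = small_scene
        m = match_instances(inst, inst)
        n = len(np.unique(inst)) - 1
        assert m.tp == n and m.fp == 0 and m.fn == 0
        assert all(iou == 1.0 for _, _, iou in m.tp_pairs)

    def test_empty_prediction_counts_all_fn(self, small_scene):
        _, inst, _ = small_scene
        m = match_instances(inst, np.zeros_like(inst))
        assert m.tp == 0 and m.fn == len(np.unique(inst)) - 1

    def test_partial_overlap_iou_arithmetic(self):
        gt = np.zeros((20, 20), dtype=np.int32)
        gt[0:10, 0:10] = 1  # 100 px
        pred = np.zeros((20, 20), dtype=np.int32)
        pred[2:12, 0:10] = 1  # 80 px overlap, union 120
        m = match_instances(gt, pred)
        assert m.tp == 1
        assert m.tp_pairs[0][2] == pytest.approx(80 / 120, rel=1e-12)

    def test_iou_below_half_is_not_a_match(self):
        gt = np.zeros((10, 10), dtype=np.int32)
        gt[:, :5] = 1
        pred = np.zeros((10, 10), dtype=np.int32)
        pred[:, 3:8] = 1  # IoU = 20/80 = 0.25
        m = match_instances(gt, pred)
        assert m.tp == 0 and m.fp == 1 and m.fn == 1

    @pytest.mark.parametrize("seed", range(10))
    def test_greedy_match_equals_optimal_assignment_oracle(self, seed):
        """IoU > 0.5 makes the pairing unique, so both routes agree."""
        rng = np.random.default_rng(seed)
        _, inst, _ = generate_scene(
            SceneSpec(
                height=96, width=96, n_nuclei=int(rng.integers(2, 13)),
                radius_range=(4, 9), allow_touching=True, seed=seed,
            )
        )
        pred = perturbed_prediction(inst, rng)
        got = {(g, p) for g, p, _ in match_instances(inst, pred).tp_pairs}
        assert got == brute_force_match(inst, pred)


class TestPanopticQuality:
    def test_perfect_match_scores_one(self, small_scene):
        _, inst, _ = small_scene
        dq, sq, pq = panoptic_quality(match_instances(inst, inst))
        assert dq == sq == pq == 1.0

    def test_single_pair_pq_equals_its_iou(self):
        m = MatchResult(tp_pairs=[(1, 1, 80 / 120)])
        dq, sq, pq = panoptic_quality(m)
        assert dq == 1.0 and pq == pytest.approx(80 / 120, rel=1e-12)

    def test_fp_and_fn_halve_detection_quality(self):
        m = MatchResult(tp_pairs=[(1, 1, 0.8)], fp_ids=[2], fn_ids=[3])
        dq, sq, pq = panoptic_quality(m)
        assert dq == pytest.approx(0.5)
        assert pq == pytest.approx(0.4)

    @pytest.mark.parametrize("seed", range(5))
    def test_pq_is_product_and_bounded(self, seed):
        rng = np.random.default_rng(seed)
        _, inst, _ = generate_scene(
            SceneSpec(height=96, width=96, n_nuclei=8, radius_range=(4, 8), seed=seed)
        )
        m = match_instances(inst, perturbed_prediction(inst, rng))
        dq, sq, pq = panoptic_quality(m)
        assert pq == pytest.approx(dq * sq, rel=1e-12)
        assert 0 <= pq <= 1 and 0 <= detection_f1(m) <= 1


class TestDetectionF1:
    def test_arithmetic_example(self):
        m = MatchResult(
            tp_pairs=[(i, i, 0.9) for i in range(8)],
            fp_ids=[100, 101],
            fn_ids=[200, 201],
        )
        assert detection_f1(m) == pytest.approx(16 / 20)

    def test_no_predictions_scores_zero(self):
        m = MatchResult(fn_ids=[1, 2])
        assert detection_f1(m) == 0.0

    def test_perfect_scores_one(self):
        m = MatchResult(tp_pairs=[(1, 1, 1.0)])
        assert detection_f1(m) == 1.0

    def test_invariant_to_relabeling_and_translation(self, small_scene):
        _, inst, _ = small_scene
        rng = np.random.default_rng(0)
        pred = perturbed_prediction(inst, rng)
        base = detection_f1(match_instances(inst, pred))
        # relabel prediction ids
        perm = rng.permutation(np.arange(1, pred.max() + 1))
        relabeled = np.zeros_like(pred)
        for old, new in zip(range(1, pred.max() + 1), perm):
            relabeled[pred == old] = new
        assert detection_f1(match_instances(inst, relabeled)) == base
        # translate both maps together
        shifted = detection_f1(
            match_instances(np.roll(inst, 5, axis=1), np.roll(pred, 5, axis=1))
        )
        assert shifted == base


class TestClassificationF1:
    def test_perfect_detection_and_typing(self):
        m = MatchResult(tp_pairs=[(i, i, 1.0) for i in range(1, 11)])
        types = {i: 1 + (i % 3) for i in range(1, 11)}
        for t in (1, 2, 3):
            assert classification_f1(m, types, types, t) == 1.0

    def test_mixed_example_arithmetic(self):
        """3 TPs typed (t,t),(t,u),(u,u) plus one FPd: Ft = 4/7."""
        m = MatchResult(
            tp_pairs=[(1, 1, 0.9), (2, 2, 0.9), (3, 3, 0.9)], fp_ids=[9]
        )
        gt_types = {1: 1, 2: 1, 3: 2}
        pred_types = {1: 1, 2: 2, 3: 2, 9: 1}
        assert classification_f1(m, gt_types, pred_types, t=1) == pytest.approx(4 / 7)

    def test_unknown_instance_id_raises(self):
        m = MatchResult(tp_pairs=[(1, 1, 1.0)])
        with pytest.raises(KeyError):
            classification_f1(m, {}, {1: 1}, t=1)


class TestAggregation:
    def test_counts_pool_across_images(self, small_scene):
        _, inst, _ = small_scene
        rng = np.random.default_rng(1)
        preds = [perturbed_prediction(inst, rng) for _ in range(3)]
        matches = [match_instances(inst, p) for p in preds]
        pooled = aggregate_matches(matches)
        assert pooled.tp == sum(m.tp for m in matches)
        assert pooled.fp == sum(m.fp for m in matches)
        assert pooled.fn == sum(m.fn for m in matches)

    def test_evaluate_pairs_reports_all_metrics(self, small_scene):
        _, inst, cls = small_scene
        types = {
            int(i): int(cls[inst == i][0]) for i in np.unique(inst) if i > 0
        }
        report = evaluate_pairs([(inst, inst)], [(types, types)], num_types=4)
        assert report["PQ"] == 1.0 and report["Fd"] == 1.0
        assert all(report[f"F_type_{t}"] == 1.0 for t in range(1, 5))
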