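"""Loss terms against independently scripted brute-force oracles.

Every oracle below evaluates its formula with explicit Python loops over
pixels and channels, independent of the vectorized implementations.
"""

import warnings

import numpy as np
import pytest

from aernet import (
    LossWeights,
    ce_loss,
    dice_loss,
    generalized_dice_loss,
    mse_loss,
    msge_loss,
)
from aernet.hv import hv_gradient_targets
from aernet.losses import branch_losses, softmax
from aernet.model import BranchOutputs
from aernet.nn.autograd import Tensor

RNG = np.random.default_rng(20240101)


# -- brute-force oracles -----------------------------------------------------


def oracle_mse(pred, true):
    acc = 0.0
    flat_p, flat_t = pred.ravel(), true.ravel()
    for i in range(flat_p.size):
        acc += (flat_p[i] - flat_t[i]) ** 2
    return acc / flat_p.size


def oracle_dice(pred, true, eps):
    inter = s_p = s_t = 0.0
    for p, t in zip(pred.ravel(), true.ravel()):
        inter += p * t
        s_p += p
        s_t += t
    return 1.0 - (2 * inter + eps) / (s_p + s_t + eps)


def oracle_ce(pred, true):
    h, w, m = pred.shape
    acc = 0.0
    for r in range(h):
        for c in range(w):
            for ch in range(m):
                acc -= true[r, c, ch] * np.log(max(pred[r, c, ch], 1e-8))
    return acc / (h * w)


def oracle_gdl(pred, true):
    k = pred.shape[2]
    num = den = 0.0
    for l in range(k):
        r_sum = true[:, :, l].sum()
        if r_sum == 0:
            continue
        w = 1.0 / r_sum**2
        num += w * (true[:, :, l] * pred[:, :, l]).sum()
        den += w * (true[:, :, l] + pred[:, :, l]).sum()
    return 1.0 - 2.0 * num / den


def oracle_msge(pred, true, mask):
    gp = hv_gradient_targets(pred)
    gt = hv_gradient_targets(true)
    m = mask.sum()
    acc_h = acc_v = 0.0
    ys, xs = np.nonzero(mask)
    for y, x in zip(ys, xs):
        acc_h += (gp[y, x, 0] - gt[y, x, 0]) ** 2
        acc_v += (gp[y, x, 1] - gt[y, x, 1]) ** 2
    return acc_h / m + acc_v / m


# -- oracle agreement on random inputs ---------------------------------------


@pytest.mark.parametrize("trial", range(25))
def test_all_losses_match_oracles_on_random_inputs(trial):
    rng = np.random.default_rng(trial)
    h, w, k = rng.integers(2, 7), rng.integers(2, 7), rng.integers(2, 5)
    hv_p = rng.uniform(-1, 1, size=(h, w, 2))
    hv_t = rng.uniform(-1, 1, size=(h, w, 2))
    mask = rng.random((h, w)) < 0.6
    if not mask.any():
        mask[0, 0] = True
    prob = rng.random((h, w))
    binmask = (rng.random((h, w)) < 0.5).astype(float)
    probs_k = rng.dirichlet(np.ones(k), size=(h, w))
    onehot = np.eye(k)[rng.integers(0, k, size=(h, w))]

    assert mse_loss(hv_p, hv_t) == pytest.approx(oracle_mse(hv_p, hv_t), rel=1e-10)
    assert dice_loss(prob, binmask, 0.001) == pytest.approx(
        oracle_dice(prob, binmask, 0.001), rel=1e-10
    )
    assert ce_loss(probs_k, onehot) == pytest.approx(
        oracle_ce(probs_k, onehot), rel=1e-10
    )
    assert generalized_dice_loss(probs_k, onehot) == pytest.approx(
        oracle_gdl(probs_k, onehot), rel=1e-10
    )
    assert msge_loss(hv_p, hv_t, mask) == pytest.approx(
        oracle_msge(hv_p, hv_t, mask), rel=1e-10
    )


# -- closed-form spot checks -------------------------------------------------


class TestMSE:
    def test_perfect_prediction_is_zero(self):
        hv = RNG.uniform(-1, 1, size=(5, 5, 2))
        assert mse_loss(hv, hv) == 0.0

    def test_constant_offset_gives_squared_offset(self):
        hv = RNG.uniform(-1, 1, size=(5, 5, 2))
        assert mse_loss(hv + 0.5, hv) == pytest.approx(0.25, rel=1e-12)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError, match="mismatch"):
            mse_loss(np.zeros((3, 3, 2)), np.zeros((4, 3, 2)))


class TestMSGE:
    def test_translation_invariance_but_mse_is_not(self):
        hv = RNG.uniform(-1, 1, size=(6, 6, 2))
        mask = np.ones((6, 6), dtype=bool)
        assert msge_loss(hv + 0.3, hv, mask) == pytest.approx(0.0, abs=1e-12)
        assert mse_loss(hv + 0.3, hv) > 0

    def test_doubled_ramp_penalty(self):
        """pred = 2*true on a linear ramp: gradient error equals the slope^2."""
        hv = np.zeros((5, 7, 2))
        hv[:, :, 0] = 0.1 * np.arange(7)[None, :]
        hv[:, :, 1] = 0.2 * np.arange(5)[:, None]
        mask = np.zeros((5, 7), dtype=bool)
        mask[1:4, 2:5] = True  # interior: central differences exact
        got = msge_loss(2 * hv, hv, mask)
        assert got == pytest.approx(0.1**2 + 0.2**2, rel=1e-10)

    def test_empty_mask_warns_and_returns_zero(self):
        hv = RNG.uniform(-1, 1, size=(4, 4, 2))
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            out = msge_loss(hv, hv * 0.5, np.zeros((4, 4), dtype=bool))
        assert out == 0.0
        assert any("empty" in str(w.message) for w in caught)


class TestDice:
    def test_perfect_overlap_is_zero(self):
        ones = np.ones((10, 10))
        assert dice_loss(ones, ones, 0.001) == pytest.approx(0.0, abs=1e-12)

    def test_total_miss_approaches_one(self):
        pred = np.zeros((10, 10))
        true = np.ones((10, 10))
        assert dice_loss(pred, true, 0.001) == pytest.approx(
            1 - 0.001 / (100 + 0.001), rel=1e-12
        )

    def test_empty_empty_is_rescued_by_epsilon(self):
        zeros = np.zeros((10, 10))
        assert dice_loss(zeros, zeros, 0.001) == 0.0


class TestCE:
    def test_perfect_one_hot_prediction_is_zero(self):
        onehot = np.eye(3)[RNG.integers(0, 3, size=(4, 4))]
        assert ce_loss(onehot, onehot) == pytest.approx(0.0, abs=1e-6)

    def test_uniform_binary_prediction_is_log2(self):
        pred = np.full((5, 5, 2), 0.5)
        truth = np.eye(2)[RNG.integers(0, 2, size=(5, 5))]
        assert ce_loss(pred, truth) == pytest.approx(np.log(2), rel=1e-12)


class TestGDL:
    def test_perfect_prediction_is_zero(self):
        onehot = np.eye(3)[RNG.integers(0, 3, size=(6, 6))]
        assert generalized_dice_loss(onehot, onehot) == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_supports_score_one(self):
        truth = np.zeros((4, 4, 2))
        truth[:, :, 0] = 1
        pred = np.zeros((4, 4, 2))
        pred[:, :, 1] = 1
        assert generalized_dice_loss(pred, truth) == pytest.approx(1.0)

    def test_90_10_perfect_on_majority_only(self):
        """Hand arithmetic with w = (1/90^2, 1/10^2)."""
        truth = np.zeros((10, 10, 2))
        truth[:9, :, 0] = 1  # 90 px majority
        truth[9:, :, 1] = 1  # 10 px minority
        pred = np.zeros((10, 10, 2))
        pred[:, :, 0] = 1  # everything called majority
        w1, w2 = 1 / 90**2, 1 / 10**2
        expected = 1 - 2 * (w1 * 90) / (w1 * (90 + 100) + w2 * (10 + 0))
        assert generalized_dice_loss(pred, truth) == pytest.approx(expected, rel=1e-12)

    def test_equal_class_sizes_reduce_to_plain_multiclass_dice(self):
        rng = np.random.default_rng(9)
        truth = np.zeros((8, 8, 2))
        truth[:4, :, 0] = 1
        truth[4:, :, 1] = 1
        pred = rng.dirichlet(np.ones(2), size=(8, 8))
        plain = 1 - 2 * (truth * pred).sum() / (truth + pred).sum()
        assert generalized_dice_loss(pred, truth) == pytest.approx(plain, rel=1e-12)

    def test_imbalance_penalty_exceeds_unweighted_dice(self):
        """Missing the minority class hurts GDL more than plain dice."""
        truth = np.zeros((10, 10, 2))
        truth[:9, :, 0] = 1
        truth[9:, :, 1] = 1
        pred = truth.copy()
        pred[9:, :, :] = [1.0, 0.0]  # minority misclassified as majority
        plain = 1 - 2 * (truth * pred).sum() / (truth + pred).sum()
        assert generalized_dice_loss(pred, truth) > plain


# -- composite objective -----------------------------------------------------


def _random_outputs_and_targets(rng, n=1, h=8, w=8, k=3, refined_equals_coarse=False):
    def logits(c):
        return Tensor(rng.normal(size=(n, c, h, w)))

    prob_c, hv_c, cls_c = logits(2), logits(2), logits(k + 1)
    if refined_equals_coarse:
        prob_r, hv_r, cls_r = prob_c, hv_c, cls_c
    else:
        prob_r, hv_r, cls_r = logits(2), logits(2), logits(k + 1)
    outputs = BranchOutputs(prob_c, prob_r, hv_c, hv_r, cls_c, cls_r)
    mask = (rng.random((n, h, w)) < 0.5).astype(float)
    targets = {
        "fg_onehot": np.stack([1 - mask, mask], axis=1),
        "hv": rng.uniform(-1, 1, size=(n, 2, h, w)) * mask[:, None],
        "class_onehot": np.eye(k + 1)[rng.integers(0, k + 1, size=(n, h, w))]
        .transpose(0, 3, 1, 2)
        .astype(float),
        "mask": mask,
    }
    return outputs, targets


class TestBranchLosses:
    def test_total_is_alpha_weighted_sum_of_stages(self):
        rng = np.random.default_rng(3)
        outputs, targets = _random_outputs_and_targets(rng)
        for alpha in (0.0, 0.2, 0.4, 0.6, 0.8, 1.0):
            w = LossWeights(alpha=alpha)
            total, terms = branch_losses(outputs, targets, w)
            assert total.item() == pytest.approx(
                alpha * terms["L1"].item() + terms["L2"].item(), rel=1e-12
            )

    def test_refined_equals_coarse_collapses_to_one_plus_alpha(self):
        rng = np.random.default_rng(4)
        outputs, targets = _random_outputs_and_targets(rng, refined_equals_coarse=True)
        w = LossWeights(alpha=0.7)
        total, terms = branch_losses(outputs, targets, w)
        assert total.item() == pytest.approx(1.7 * terms["L1"].item(), rel=1e-12)

    def test_alpha_zero_gives_refined_loss_only(self):
        rng = np.random.default_rng(5)
        outputs, targets = _random_outputs_and_targets(rng)
        total, terms = branch_losses(outputs, targets, LossWeights(alpha=0.0))
        assert total.item() == pytest.approx(terms["L2"].item(), rel=1e-12)

    def test_stage_terms_follow_beta_weights(self):
        rng = np.random.default_rng(6)
        outputs, targets = _random_outputs_and_targets(rng)
        w = LossWeights(beta1=1.0, beta2=2.0, beta3=0.5, beta4=1.5, beta5=2.0, beta6=3.0)
        _, terms = branch_losses(outputs, targets, w)
        for stage in ("coarse", "refined"):
            assert terms[f"La_{stage}"].item() == pytest.approx(
                0.5 * terms[f"ce_prob_{stage}"].item()
                + 1.5 * terms[f"dice_{stage}"].item(),
                rel=1e-12,
            )
            assert terms[f"Lb_{stage}"].item() == pytest.approx(
                terms[f"mse_{stage}"].item() + 2.0 * terms[f"msge_{stage}"].item(),
                rel=1e-12,
            )
            assert terms[f"Lc_{stage}"].item() == pytest.approx(
                2.0 * terms[f"ce_class_{stage}"].item()
                + 3.0 * terms[f"gdl_{stage}"].item(),
                rel=1e-12,
            )

    def test_all_terms_nonnegative_and_dice_like_bounded(self):
        rng = np.random.default_rng(7)
        outputs, targets = _random_outputs_and_targets(rng)
        _, terms = branch_losses(outputs, targets, LossWeights())
        for name, value in terms.items():
            v = value.item() if hasattr(value, "item") else value
            assert v >= 0, name
            if name.startswith(("dice", "gdl")):
                assert v <= 1 + 1e-9, name

    def test_perfect_predictions_give_zero_total(self):
        rng = np.random.default_rng(8)
        _, targets = _random_outputs_and_targets(rng, k=3)
        big = 200.0  # drives softmax to one-hot saturation

        def as_logits(onehot):
            return Tensor(big * onehot)

        hv = Tensor(targets["hv"])
        outputs = BranchOutputs(
            as_logits(targets["fg_onehot"]),
            as_logits(targets["fg_onehot"]),
            hv,
            hv,
            as_logits(targets["class_onehot"]),
            as_logits(targets["class_onehot"]),
        )
        total, _ = branch_losses(outputs, targets, LossWeights())
        assert total.item() == pytest.approx(0.0, abs=1e-6)


def test_softmax_normalizes_and_matches_scipy():
    from scipy.special import softmax as scipy_softmax

    rng = np.random.default_rng(10)
    x = rng.normal(size=(2, 5, 3, 3))
    out = softmax(Tensor(x), axis=1).data
    np.testing.assert_allclose(out, scipy_softmax(x, axis=1), atol=1e-12)
    np.testing.assert_allclose(out.sum(axis=1), 1.0, atol=1e-12)


# -- property tests ----------------------------------------------------------

from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp


@settings(deadline=None, max_examples=30, derandomize=True)
@given(
    pred=hnp.arrays(np.float64, (5, 6), elements=st.floats(0, 1)),
    truth=hnp.arrays(np.float64, (5, 6), elements=st.sampled_from([0.0, 1.0])),
)
def test_dice_loss_stays_in_unit_interval(pred, truth):
    value = dice_loss(pred, truth, 0.001)
    assert -1e-12 <= value <= 1 + 1e-12


@settings(deadline=None, max_examples=30, derandomize=True)
@given(
    hv=hnp.arrays(np.float64, (4, 5, 2), elements=st.floats(-1, 1)),
    offset=st.floats(-2, 2),
)
def test_msge_ignores_constant_offsets_mse_does_not(hv, offset):
    mask = np.ones((4, 5), dtype=bool)
    assert msge_loss(hv + offset, hv, mask) == pytest.approx(0.0, abs=1e-9)
    assert mse_loss(hv + offset, hv) == pytest.approx(offset**2, abs=1e-9)
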