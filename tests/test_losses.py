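"""Focal Tversky loss and multitask combinations against counting oracles."""

import numpy as np
import pytest

from mammodensity import nn
from mammodensity.losses import (NaiveWeights, TaskUncertainty, TverskyParams,
                                 adaptive_mtl_loss, focal_tversky_loss,
                                 naive_mtl_loss, tversky_index)
from conftest import random_mask_pair


def oracle_tversky(pred, target, alpha, beta, phi):
    """Independent pixel-counting Tversky index (hard or soft pred)."""
    pred = np.asarray(pred, dtype=float)
    target = np.asarray(target, dtype=float)
    tp = np.sum(pred * target)
    fn = np.sum((1 - pred) * target)
    fp = np.sum(pred * (1 - target))
    return (tp + phi) / (tp + alpha * fn + beta * fp + phi)


def oracle_ftl(pred_fg, target_fg, params):
    """Two-class focal Tversky loss from raw pixel counts."""
    total = 0.0
    for p, t in ((1 - np.asarray(pred_fg, dtype=float), 1 - np.asarray(target_fg)),
                 (np.asarray(pred_fg, dtype=float), np.asarray(target_fg))):
        ti = oracle_tversky(p, t, params.alpha, params.beta, params.phi)
        total += (1.0 - ti) ** (1.0 / params.gamma)
    return total


def as_probmap(fg):
    fg = np.asarray(fg, dtype=float)
    return np.stack([1.0 - fg, fg])


TWO_BY_TWO_TARGET = np.array([[1, 0], [0, 0]], dtype=np.uint8)
TWO_BY_TWO_PRED = np.array([[1, 1], [0, 0]], dtype=float)


def test_worked_2x2_tversky_index():
    """TP=1, FN=0, FP=1 with alpha=.3, beta=.7 gives 1/1.7."""
    ti = tversky_index(TWO_BY_TWO_PRED, TWO_BY_TWO_TARGET, TverskyParams())
    assert ti == pytest.approx(1.0 / 1.7, abs=1e-5)


def test_worked_2x2_focal_loss_components():
    params = TverskyParams()
    loss = focal_tversky_loss(as_probmap(TWO_BY_TWO_PRED), TWO_BY_TWO_TARGET, params)
    # foreground term 1 - 1/1.7 = 0.41176; background TI = 2/2.3 -> 0.13043
    assert float(loss) == pytest.approx(0.41176 + 0.13043, abs=1e-4)
    assert float(loss) == pytest.approx(
        oracle_ftl(TWO_BY_TWO_PRED, TWO_BY_TWO_TARGET, params), abs=1e-12)


def test_perfect_prediction_zero_loss():
    t = (np.random.default_rng(3).random((6, 6)) > 0.4).astype(np.uint8)
    assert float(focal_tversky_loss(as_probmap(t), t)) == 0.0
    assert float(tversky_index(t.astype(float), t)) == 1.0


def test_matches_counting_oracle_on_random_masks(rng):
    params = TverskyParams()
    worst = 0.0
    for _ in range(300):
        pred, target = random_mask_pair(rng)
        ours = float(focal_tversky_loss(as_probmap(pred), target, params))
        worst = max(worst, abs(ours - oracle_ftl(pred, target, params)))
    assert worst < 1e-6


def test_dice_reduction(rng):
    """alpha = beta = 0.5 turns the index into the Dice coefficient."""
    params = TverskyParams(alpha=0.5, beta=0.5)
    for _ in range(100):
        pred, target = random_mask_pair(rng)
        ti = float(tversky_index(pred.astype(float), target, params))
        inter = np.sum(pred * target)
        denom = pred.sum() + target.sum()
        dice = (2 * inter + 2 * params.phi) / (denom + 2 * params.phi)
        assert ti == pytest.approx(dice, abs=1e-9)


def test_focal_exponent_monotonicity(rng):
    pred, target = random_mask_pair(rng)
    if np.array_equal(pred, target):  # ensure an imperfect pair
        pred = 1 - pred
    l1 = float(focal_tversky_loss(as_probmap(pred), target, TverskyParams(gamma=1)))
    l2 = float(focal_tversky_loss(as_probmap(pred), target, TverskyParams(gamma=2)))
    assert l2 > l1  # t^(1/2) > t on (0,1)


def test_soft_gradient_finite_difference(rng):
    p = rng.uniform(0.05, 0.95, size=(2, 5, 5))
    p /= p.sum(axis=0, keepdims=True)
    t = (rng.random((5, 5)) > 0.5).astype(np.uint8)
    pt = nn.Tensor(p, requires_grad=True)
    focal_tversky_loss(pt, t).backward()
    eps = 1e-6
    for idx in [(0, 0, 0), (1, 2, 3), (0, 4, 4), (1, 0, 2)]:
        plus, minus = p.copy(), p.copy()
        plus[idx] += eps
        minus[idx] -= eps
        fd = (float(focal_tversky_loss(plus, t)) -
              float(focal_tversky_loss(minus, t))) / (2 * eps)
        assert pt.grad[idx] == pytest.approx(fd, rel=1e-4, abs=1e-8)


def test_target_validation():
    with pytest.raises(ValueError, match="binary"):
        tversky_index(np.zeros((2, 2)), np.full((2, 2), 0.5))
    with pytest.raises(ValueError, match="mismatch"):
        tversky_index(np.zeros((2, 2)), np.zeros((3, 3), dtype=np.uint8))


class TestNaive:
    def test_symmetric(self):
        assert naive_mtl_loss(0.7, 0.7, NaiveWeights(0.5)) == pytest.approx(0.7)

    def test_worked_example(self):
        assert naive_mtl_loss(0.5, 1.0, NaiveWeights(0.3)) == pytest.approx(0.85)

    @pytest.mark.parametrize("lam", [0.0, 1.0, -0.2, 1.5])
    def test_bounds_rejected(self, lam):
        with pytest.raises(ValueError):
            NaiveWeights(lam)


class TestAdaptive:
    def test_unit_sigma_reduces_to_sum(self):
        u = TaskUncertainty(0.0, 0.0, trainable=False)
        assert adaptive_mtl_loss(0.4, 0.2, u) == pytest.approx(0.6, abs=1e-15)

    def test_worked_example(self):
        # L_b=0.4 sigma_b=1; L_d=0.2 sigma_d=2 -> 0.4 + 0.05 + log 2
        u = TaskUncertainty(0.0, np.log(4.0), trainable=False)
        expected = 0.4 + 0.05 + np.log(2.0)
        assert adaptive_mtl_loss(0.4, 0.2, u) == pytest.approx(expected, abs=1e-10)

    def test_stationary_point_is_sigma_sq_2L(self):
        """Optimizing only s against constant losses gives sigma^2 = 2L."""
        lb, ld = 0.8, 0.25
        u = TaskUncertainty()
        opt = nn.Adam(u.parameters(), lr=0.05)
        for _ in range(800):
            loss = adaptive_mtl_loss(lb, ld, u)
            opt.zero_grad()
            loss.backward()
            opt.step()
        assert u.sigma_b ** 2 == pytest.approx(2 * lb, abs=1e-3)
        assert u.sigma_d ** 2 == pytest.approx(2 * ld, abs=1e-3)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            adaptive_mtl_loss(np.nan, 0.1, TaskUncertainty())
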