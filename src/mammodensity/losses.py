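"""Per-task focal Tversky loss and multitask loss combinations.

The Tversky index generalizes Dice overlap with asymmetric penalties on
false negatives (``alpha``) and false positives (``beta``):

    TI_c = (TP_c + phi) / (TP_c + alpha * FN_c + beta * FP_c + phi)

with pixel sums TP = sum(p_c * y_c), FN = sum((1 - p_c) * y_c),
FP = sum(p_c * (1 - y_c)) over all N pixels, and ``phi`` a smoothing
constant preventing division by zero.  The focal Tversky loss sums
``(1 - TI_c) ** (1 / gamma)`` over the two class labels (region of
interest and background); ``gamma`` emphasizes hard, low-overlap cases.
Defaults alpha=0.3, beta=0.7, gamma=1 favor recall under the strong
foreground/background imbalance of dense-tissue masks.

Two multitask combinations are provided: the naive fixed-weight sum
``lambda * L_breast + (1 - lambda) * L_dense`` and the weight-adaptive
(homoscedastic-uncertainty) form with one learnable uncertainty per task:

    L_total = L_b / sigma_b^2 + log sigma_b + L_d / sigma_d^2 + log sigma_d

parameterized by s = log sigma^2 for unconstrained optimization, i.e.
``exp(-s) * L + s / 2`` per task.

All operations accept plain numpy values or :class:`~mammodensity.nn.Tensor`
objects, so the same code path is used for training (differentiable) and
for oracle-style evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Tensor

__all__ = [
    "TverskyParams",
    "NaiveWeights",
    "TaskUncertainty",
    "tversky_index",
    "focal_tversky_loss",
    "naive_mtl_loss",
    "adaptive_mtl_loss",
]

# class-channel convention: index 1 = region of interest, index 0 = background
ROI_CHANNEL = 1


@dataclass(frozen=True)
class TverskyParams:
    """Hyperparameters of the focal Tversky loss."""

    alpha: float = 0.3   # weight on false negatives
    beta: float = 0.7    # weight on false positives
    gamma: float = 1.0   # focal exponent (loss term is (1-TI)^(1/gamma))
    phi: float = 1e-6    # smoothing constant

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be non-negative")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.phi <= 0:
            raise ValueError("phi must be positive")


@dataclass(frozen=True)
class NaiveWeights:
    """Fixed task weight lambda for the naive multitask sum."""

    lam: float = 0.3

    def __post_init__(self):
        if not 0.0 < self.lam < 1.0:
            raise ValueError(f"lambda must lie strictly in (0, 1), got {self.lam}")


class TaskUncertainty:
    """Learnable per-task log-variances s = log sigma^2 (init sigma = 1)."""

    def __init__(self, s_b: float = 0.0, s_d: float = 0.0, trainable: bool = True):
        self.trainable = trainable
        if trainable:
            self.s_b = Tensor(np.float64(s_b), requires_grad=True)
            self.s_d = Tensor(np.float64(s_d), requires_grad=True)
        else:
            self.s_b = float(s_b)
            self.s_d = float(s_d)

    @staticmethod
    def _value(s) -> float:
        return float(s.data) if isinstance(s, Tensor) else float(s)

    @property
    def sigma_b(self) -> float:
        return float(np.exp(0.5 * self._value(self.s_b)))

    @property
    def sigma_d(self) -> float:
        return float(np.exp(0.5 * self._value(self.s_d)))

    def parameters(self):
        return [self.s_b, self.s_d] if self.trainable else []


def _as_float(x):
    return float(x.data) if isinstance(x, Tensor) else float(x)


def _sum_all(x):
    return x.sum() if isinstance(x, Tensor) else float(np.sum(x))


def tversky_index(pred, target, params: TverskyParams = TverskyParams()):
    """Tversky index for one class channel; soft predictions allowed.

    `pred` holds per-pixel predicted probability (or hard {0,1} value) of
    the class; `target` is the binary ground truth of that class.  Returns
    a scalar in (0, 1] (a Tensor if `pred` is a Tensor).
    """
    tgt = np.asarray(target.data if isinstance(target, Tensor) else target)
    if not np.all(np.isin(np.unique(tgt), (0, 1))):
        raise ValueError("target must be binary")
    pshape = pred.shape if isinstance(pred, Tensor) else np.shape(pred)
    if tuple(pshape) != tgt.shape:
        raise ValueError(f"dimension mismatch: pred {pshape} vs target {tgt.shape}")
    tgt = tgt.astype(np.float64)
    tp = _sum_all(pred * tgt)
    fn = _sum_all((1.0 - pred) * tgt)
    fp = _sum_all(pred * (1.0 - tgt))
    return (tp + params.phi) / (tp + params.alpha * fn + params.beta * fp + params.phi)


def _class_channel(pred, c: int):
    """Slice class channel c out of a (..., 2, H, W) probability map."""
    if isinstance(pred, Tensor):
        nd = pred.ndim
    else:
        pred = np.asarray(pred, dtype=np.float64)
        nd = pred.ndim
    if nd == 3:      # (2, H, W)
        return pred[c]
    if nd == 4:      # (B, 2, H, W)
        return pred[:, c]
    raise ValueError("probability map must have shape (2,H,W) or (B,2,H,W)")


def focal_tversky_loss(pred, target, params: TverskyParams = TverskyParams()):
    """Focal Tversky loss summed over the two class channels.

    `pred`: two-class probability map, shape (2, H, W) or (B, 2, H, W),
    channel 1 = region of interest.  `target`: binary mask of the ROI with
    matching spatial (and batch) shape, or an explicit one-hot map shaped
    like `pred`.  Differentiable when `pred` is a Tensor.
    """
    tgt = np.asarray(target.data if isinstance(target, Tensor) else target)
    pshape = tuple(pred.shape)
    if tgt.shape == pshape:               # one-hot provided
        onehot = tgt.astype(np.float64)
    else:
        roi = tgt.astype(np.float64)
        expect = pshape[:-3] + pshape[-2:]
        if roi.shape != expect:
            raise ValueError(
                f"target shape {roi.shape} incompatible with prediction {pshape}")
        onehot = np.stack([1.0 - roi, roi], axis=-3)

    total = None
    for c in (0, ROI_CHANNEL):
        ti = tversky_index(_class_channel(pred, c), _class_channel(onehot, c), params)
        term = (1.0 - ti) ** (1.0 / params.gamma)
        total = term if total is None else total + term
    return total


def naive_mtl_loss(loss_b, loss_d, w: NaiveWeights):
    """Fixed-weight multitask sum lambda * L_b + (1 - lambda) * L_d."""
    if _as_float(loss_b) < 0 or _as_float(loss_d) < 0:
        raise ValueError("task losses must be non-negative")
    return w.lam * loss_b + (1.0 - w.lam) * loss_d


def adaptive_mtl_loss(loss_b, loss_d, u: TaskUncertainty):
    """Uncertainty-weighted multitask loss.

    exp(-s_b) L_b + s_b/2 + exp(-s_d) L_d + s_d/2, with s = log sigma^2 —
    identical to L/sigma^2 + log sigma per task.  Differentiable in the
    losses and in the uncertainties.
    """
    for val in (loss_b, loss_d):
        if not np.isfinite(_as_float(val)):
            raise ValueError("task losses must be finite")
    s_b, s_d = u.s_b, u.s_d
    if isinstance(s_b, Tensor):
        return ((-s_b).exp() * loss_b + 0.5 * s_b
                + (-s_d).exp() * loss_d + 0.5 * s_d)
    return (np.exp(-s_b) * loss_b + 0.5 * s_b
            + np.exp(-s_d) * loss_d + 0.5 * s_d)
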