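"""Loss functions for imbalance-weighted multi-label training.

The training loss is a class-weighted binary cross-entropy: class i
carries weight ``w_i = 1 / log(n_i)`` (natural log), where ``n_i`` is the
number of records positive for class i in the training data, so rare
classes cost more to misclassify. The loss value is the mean over
(record, class) pairs of ``-w_i (y_i log x_i + (1 - y_i) log(1 - x_i))``.

Networks with auxiliary heads combine the three head losses as
``loss_main + 0.3 * loss_aux1 + 0.3 * loss_aux0``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "EPS",
    "ClassWeights",
    "LossInputs",
    "class_weights",
    "weighted_bce",
    "weighted_bce_grad",
    "composite_loss",
]

#: Probability clipping inside logs.
EPS = 1e-7


@dataclass(frozen=True)
class ClassWeights:
    w: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.w, dtype=np.float64)
        object.__setattr__(self, "w", w)
        if not (np.isfinite(w).all() and (w > 0).all()):
            raise ValueError("class weights must be finite and positive")


@dataclass(frozen=True)
class LossInputs:
    """Predicted probabilities, binary targets and class weights."""

    x: np.ndarray
    y: np.ndarray
    w: ClassWeights


def class_weights(counts: np.ndarray) -> ClassWeights:
    """``w_i = 1 / ln(n_i)``; requires every count >= 2 (else log <= 0).

    Callers with empty classes should clamp counts to 2 first; the weight
    is monotone decreasing in n, so frequent classes are down-weighted.
    """
    counts = np.asarray(counts)
    if (counts < 2).any():
        raise ValueError("all class counts must be >= 2 for 1/log(n) weights")
    return ClassWeights(1.0 / np.log(counts.astype(np.float64)))


def _as_arrays(x, y, w):
    x = np.atleast_2d(np.asarray(x, dtype=np.float64))
    y = np.atleast_2d(np.asarray(y, dtype=np.float64))
    wv = w.w if isinstance(w, ClassWeights) else np.asarray(w, dtype=np.float64)
    if x.shape != y.shape or x.shape[1] != wv.shape[0]:
        raise ValueError(
            f"shape mismatch: x{x.shape}, y{y.shape}, w{wv.shape}"
        )
    return x, y, wv


def weighted_bce(x, y, w, eps: float = EPS) -> float:
    """Mean over (record, class) of the weighted binary cross-entropy."""
    x, y, wv = _as_arrays(x, y, w)
    xc = np.clip(x, eps, 1.0 - eps)
    ll = y * np.log(xc) + (1.0 - y) * np.log(1.0 - xc)
    return float(np.mean(-wv[None, :] * ll))


def weighted_bce_grad(x, y, w, eps: float = EPS) -> np.ndarray:
    """d(loss)/d(x): gradient of :func:`weighted_bce` w.r.t. probabilities."""
    x, y, wv = _as_arrays(x, y, w)
    xc = np.clip(x, eps, 1.0 - eps)
    g = -wv[None, :] * (y / xc - (1.0 - y) / (1.0 - xc))
    return g / x.size


def composite_loss(loss2: float, loss1: float, loss0: float) -> float:
    """Main-head loss plus 0.3 x each auxiliary-head loss."""
    return loss2 + 0.3 * loss1 + 0.3 * loss0
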