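"""Multi-label evaluation: per-class confusion tallies and pooled
precision / recall / F1.

With per-class true positives, false positives and false negatives,

    P = TP / (TP + FP),  R = TP / (TP + FN),  F1 = 2 P R / (P + R).

Micro averaging pools TP/FP/FN over all classes before applying the
formulas (the default; one record can contribute to several classes);
macro averaging applies them per class and averages the scores. All
0/0 cases resolve to 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["EvalCounts", "EvalReport", "confusion_counts", "prf1", "f1_from_pr"]


@dataclass(frozen=True)
class EvalCounts:
    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn"):
            v = np.asarray(getattr(self, name), dtype=np.int64)
            object.__setattr__(self, name, v)
            if (v < 0).any():
                raise ValueError(f"{name} must be non-negative")
        if not (self.tp.shape == self.fp.shape == self.fn.shape):
            raise ValueError("tp/fp/fn must share one shape")

    @property
    def n_classes(self) -> int:
        return self.tp.shape[0]


@dataclass
class EvalReport:
    precision: float
    recall: float
    f1: float
    average: str
    per_class: dict = field(default_factory=dict)
    scheme: str = ""
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "scheme": self.scheme,
            "average": self.average,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "per_class": self.per_class,
            **self.extra,
        }


def confusion_counts(pred: np.ndarray, truth: np.ndarray) -> EvalCounts:
    """Per-class TP/FP/FN over ``[n_records, C]`` binary matrices."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape or pred.ndim != 2:
        raise ValueError(f"shape mismatch: pred{pred.shape} vs truth{truth.shape}")
    pred = pred.astype(bool)
    truth = truth.astype(bool)
    tp = (pred & truth).sum(axis=0)
    fp = (pred & ~truth).sum(axis=0)
    fn = (~pred & truth).sum(axis=0)
    return EvalCounts(tp, fp, fn)


def f1_from_pr(precision: float, recall: float) -> float:
    """Harmonic mean ``2PR / (P + R)``; 0 when both vanish."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def _safe_div(num, den):
    num = np.asarray(num, dtype=np.float64)
    den = np.asarray(den, dtype=np.float64)
    return np.divide(num, den, out=np.zeros_like(num), where=den > 0)


def prf1(counts: EvalCounts, average: str = "micro") -> EvalReport:
    """Precision / recall / F1 from confusion tallies."""
    if average not in ("micro", "macro"):
        raise ValueError("average must be 'micro' or 'macro'")
    p_cls = _safe_div(counts.tp, counts.tp + counts.fp)
    r_cls = _safe_div(counts.tp, counts.tp + counts.fn)
    f_cls = _safe_div(2 * p_cls * r_cls, p_cls + r_cls)
    per_class = {
        "tp": counts.tp.tolist(),
        "fp": counts.fp.tolist(),
        "fn": counts.fn.tolist(),
        "precision": p_cls.tolist(),
        "recall": r_cls.tolist(),
        "f1": f_cls.tolist(),
    }
    if average == "micro":
        tp, fp, fn = counts.tp.sum(), counts.fp.sum(), counts.fn.sum()
        p = float(_safe_div(tp, tp + fp))
        r = float(_safe_div(tp, tp + fn))
        return EvalReport(p, r, f1_from_pr(p, r), "micro", per_class)
    return EvalReport(
        float(p_cls.mean()), float(r_cls.mean()), float(f_cls.mean()),
        "macro", per_class,
    )
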