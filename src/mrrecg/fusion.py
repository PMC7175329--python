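"""Multi-resolution representation (MRR) fusion and voting.

Each record's MRR is the fixed-order concatenation of

* the deep feature vector of every channel model (default: the last
  dense layer's pre-sigmoid outputs),
* the nine lead-II HRV indices,
* age (years / 100),
* gender as a one-hot pair (unknown encodes as two zeros).

A gradient-boosted classifier (LightGBM, leaf-wise growth) is trained
per fold on the MRR — realized as one one-vs-rest boosted model per
label — and per-label probabilities are thresholded at 0.5. The k
fold-level classifiers each predict every record and the final label is
the strict per-label majority (k=5 needs >= 3 votes; for even k a tie
resolves negative).

The fold plan used to train the channel models is hash-verified before
the classifier stage trains, so the two stages provably share one split.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hrv import HRV_FEATURE_NAMES, HRVFeatures
from .metrics import EvalReport, confusion_counts, prf1
from .training import FoldPlan, LeakageError

__all__ = [
    "MRRSchema",
    "FusionClassifier",
    "build_mrr",
    "build_mrr_matrix",
    "train_fusion_classifier",
    "vote",
]


@dataclass(frozen=True)
class MRRSchema:
    """Recorded column layout of the fused representation."""

    deep_parts: tuple[tuple[str, int], ...]  # (model name, feature dim)
    hrv_dim: int = len(HRV_FEATURE_NAMES)

    @property
    def total_dim(self) -> int:
        return sum(d for _, d in self.deep_parts) + self.hrv_dim + 1 + 2

    def column_names(self) -> list[str]:
        names = [
            f"{model}:{i}" for model, d in self.deep_parts for i in range(d)
        ]
        names += [f"hrv:{n}" for n in HRV_FEATURE_NAMES[: self.hrv_dim]]
        names += ["age", "gender:male", "gender:female"]
        return names


def _encode_gender(gender: str) -> np.ndarray:
    return np.array(
        [1.0 if gender == "male" else 0.0, 1.0 if gender == "female" else 0.0]
    )


def build_mrr(
    deep: list[np.ndarray],
    hrv: HRVFeatures,
    age: int,
    gender: str,
    schema: MRRSchema,
) -> np.ndarray:
    """One record's fused vector, validated against the recorded schema."""
    deep = [np.asarray(d, dtype=np.float64).ravel() for d in deep]
    if len(deep) != len(schema.deep_parts):
        raise ValueError(
            f"{len(deep)} deep parts but schema declares "
            f"{len(schema.deep_parts)}"
        )
    for vec, (name, dim) in zip(deep, schema.deep_parts):
        if vec.shape[0] != dim:
            raise ValueError(
                f"deep part {name!r} has dim {vec.shape[0]}, schema says {dim}"
            )
    out = np.concatenate(
        deep + [hrv.to_array(), [age / 100.0], _encode_gender(gender)]
    )
    if out.shape[0] != schema.total_dim:
        raise ValueError("fused vector does not match schema dimension")
    if not np.isfinite(out).all():
        raise ValueError("fused vector contains non-finite entries")
    return out


def build_mrr_matrix(
    deep: list[np.ndarray],
    hrv_rows: list[HRVFeatures],
    ages: np.ndarray,
    genders: list[str],
    schema: MRRSchema,
) -> np.ndarray:
    """Stack :func:`build_mrr` over records; ``deep`` holds one
    ``[n_records, dim]`` matrix per channel model."""
    n = len(hrv_rows)
    return np.stack(
        [
            build_mrr(
                [m[i] for m in deep], hrv_rows[i], int(ages[i]), genders[i], schema
            )
            for i in range(n)
        ]
    )


@dataclass
class FusionClassifier:
    """One-vs-rest gradient-boosted models over C labels for one fold."""

    boosters: list  # per class: lgb.Booster or a constant float
    fold: int
    plan_hash: str
    n_features: int
    threshold: float = 0.5
    extra: dict = field(default_factory=dict)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        if x.shape[1] != self.n_features:
            raise ValueError(
                f"{x.shape[1]} features, classifier expects {self.n_features}"
            )
        cols = []
        for b in self.boosters:
            if isinstance(b, float):
                cols.append(np.full(x.shape[0], b))
            else:
                cols.append(np.asarray(b.predict(x)))
        return np.stack(cols, axis=1)

    def predict(self, x: np.ndarray) -> np.ndarray:
        return (self.predict_proba(x) >= self.threshold).astype(np.int8)


def train_fusion_classifier(
    mrr: np.ndarray,
    labels: np.ndarray,
    plan: FoldPlan,
    fold: int,
    record_ids: list[str],
    *,
    channel_plan_hash: str | None = None,
    seed: int = 0,
    n_estimators: int = 80,
    num_leaves: int = 15,
    learning_rate: float = 0.1,
) -> FusionClassifier:
    """Train the fold's boosted classifier on all records outside the
    test fold. ``record_ids`` aligns MRR rows with the fold plan;
    ``channel_plan_hash`` must match ``plan.hash()`` when given — it
    proves the MRR came from channel models trained on the same plan.
    """
    import lightgbm as lgb

    if channel_plan_hash is not None and channel_plan_hash != plan.hash():
        raise LeakageError(
            "fold-plan hash mismatch between channel-model and classifier stages"
        )
    mrr = np.asarray(mrr, dtype=np.float64)
    labels = np.asarray(labels)
    if len(record_ids) != mrr.shape[0]:
        raise ValueError("record_ids must align with MRR rows")
    train_idx = np.array(
        [i for i, r in enumerate(record_ids) if plan.assignments[r] != fold],
        dtype=np.int64,
    )
    x_tr, y_tr = mrr[train_idx], labels[train_idx]

    boosters: list = []
    for c in range(labels.shape[1]):
        yc = y_tr[:, c]
        if yc.min() == yc.max():  # degenerate: constant label in training data
            boosters.append(float(yc[0]))
            continue
        data = lgb.Dataset(x_tr, label=yc)
        params = {
            "objective": "binary",
            "num_leaves": num_leaves,
            "learning_rate": learning_rate,
            "min_data_in_leaf": 5,
            "verbosity": -1,
            "num_threads": 1,
            "deterministic": True,
            "seed": (seed + 1009 * c) % 2**31,
            "feature_fraction": 1.0,
            "bagging_fraction": 1.0,
        }
        boosters.append(
            lgb.train(params, data, num_boost_round=n_estimators)
        )
    return FusionClassifier(
        boosters=boosters,
        fold=fold,
        plan_hash=plan.hash(),
        n_features=mrr.shape[1],
    )


def vote(preds: np.ndarray) -> np.ndarray:
    """Strict-majority vote over ``[k, n_records, C]`` binary predictions.

    A label is positive iff at least ``ceil((k+1)/2)`` models predict it
    (k=5 -> 3). For even k a tie breaks negative. k=1 passes through.
    Monotone: flipping one model's 0 to 1 never turns a fused 1 into 0.
    """
    preds = np.asarray(preds)
    if preds.ndim != 3:
        raise ValueError("expected [k, n_records, C] predictions")
    if not np.isin(preds, (0, 1)).all():
        raise ValueError("votes must be binary")
    k = preds.shape[0]
    needed = int(np.ceil((k + 1) / 2))
    return (preds.sum(axis=0) >= needed).astype(np.int8)


def evaluate_predictions(
    pred: np.ndarray, truth: np.ndarray, scheme: str, **extra
) -> EvalReport:
    """Micro-averaged report with per-class tallies for a scheme's output."""
    report = prf1(confusion_counts(pred, truth), average="micro")
    report.scheme = scheme
    report.extra = extra
    return report
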