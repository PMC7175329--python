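"""Fold planning and channel-model training.

The same k-fold plan is reused by both training stages (deep channel
models first, then the fused gradient-boosted classifier), so the
second stage provably sees the same splits — the plan carries a content
hash that downstream stages verify.

Folds come from iterative multi-label stratification: classes are
processed from rarest to most frequent, and each positive record is
assigned to the fold that most needs that class, subject to near-equal
fold sizes. Within one cross-validation round, the fold under test is
held out, one of the remaining folds validates (model selection by
micro-F1), and the rest train; augmentation touches training folds only.

Training defaults mirror the usual regime for this task: Adam at
lr=0.001 for 50 epochs with x0.1 drops when the epoch count reaches 35
and 45, batch normalization after every convolution, dropout before the
classification head. Desk-scale runs override epochs/width, not the
schedule logic.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace

import numpy as np

from .io import DatasetManifest
from .nets.layers import Adam
from .nets.losses import class_weights, composite_loss, weighted_bce, weighted_bce_grad
from .nets.models import ChannelModel, ModelConfig, build_model
from .metrics import confusion_counts, prf1
from .preprocess import AugmentConfig, random_augment

__all__ = [
    "FoldPlan",
    "TrainConfig",
    "TrainedChannelModel",
    "LeakageError",
    "make_folds",
    "train_channel_model",
    "lr_at_epoch",
]


class LeakageError(RuntimeError):
    """A stage tried to mix records across train/test roles."""


@dataclass(frozen=True)
class FoldPlan:
    k: int
    assignments: dict[str, int]  # record_id -> fold index
    seed: int

    def fold_ids(self, fold: int) -> list[str]:
        return [r for r, f in self.assignments.items() if f == fold]

    def fold_indices(self, record_ids: list[str], fold: int) -> np.ndarray:
        return np.array(
            [i for i, r in enumerate(record_ids) if self.assignments[r] == fold],
            dtype=np.int64,
        )

    def hash(self) -> str:
        payload = json.dumps(
            {"k": self.k, "assignments": sorted(self.assignments.items())},
            separators=(",", ":"),
        )
        return hashlib.sha256(payload.encode()).hexdigest()

    def to_json(self) -> str:
        return json.dumps(
            {"k": self.k, "seed": self.seed, "assignments": self.assignments},
            indent=1, sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "FoldPlan":
        d = json.loads(text)
        return cls(d["k"], dict(d["assignments"]), d["seed"])


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 50
    lr: float = 0.001
    lr_drops: tuple[int, ...] = (35, 45)
    lr_factor: float = 0.1
    batch_size: int = 32
    seed: int = 0
    augment: AugmentConfig | None = field(default_factory=AugmentConfig)

    def __post_init__(self) -> None:
        drops = tuple(self.lr_drops)
        object.__setattr__(self, "lr_drops", drops)
        if any(b <= a for a, b in zip(drops, drops[1:])):
            raise ValueError("lr_drops must be strictly increasing")
        if drops and drops[-1] >= self.epochs:
            # permitted only when epochs were shrunk below the default drops
            object.__setattr__(
                self, "lr_drops", tuple(d for d in drops if d < self.epochs)
            )


def lr_at_epoch(cfg: TrainConfig, epoch: int) -> float:
    """Learning rate during ``epoch`` (1-based): one x``lr_factor`` per
    drop threshold the epoch count has reached."""
    n_drops = sum(epoch >= d for d in cfg.lr_drops)
    return cfg.lr * cfg.lr_factor**n_drops


def make_folds(manifest: DatasetManifest, k: int = 5, seed: int = 0) -> FoldPlan:
    """Iterative multi-label stratified fold assignment.

    Deterministic given ``seed``; fold sizes within +-1 of n/k; each
    class's positives spread as evenly as the counts allow.
    """
    if k < 2:
        raise ValueError("need k >= 2 folds")
    n = len(manifest)
    if n < k:
        raise ValueError(f"cannot split {n} records into {k} folds")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x666F6C64]))
    y = manifest.label_matrix.astype(bool)
    ids = manifest.record_ids

    capacity = np.full(k, n // k, dtype=np.float64)
    capacity[: n % k] += 1
    desired = y.sum(axis=0)[None, :].repeat(k, axis=0) / k  # per fold per class
    assigned = np.full(n, -1, dtype=np.int64)

    while (assigned < 0).any():
        unassigned = assigned < 0
        counts_left = y[unassigned].sum(axis=0)
        if counts_left.sum() == 0:
            break  # only label-free records remain
        # rarest class that still has unassigned positives
        c = int(
            np.argmin(np.where(counts_left > 0, counts_left, np.inf))
        )
        rows = np.where(unassigned & y[:, c])[0]
        rng.shuffle(rows)
        for i in rows:
            # fold that most needs class c, then most spare capacity
            score = desired[:, c] + 1e-3 * capacity + 1e-6 * rng.random(k)
            score[capacity <= 0] = -np.inf
            f = int(np.argmax(score))
            assigned[i] = f
            capacity[f] -= 1
            desired[f, y[i]] -= 1
    for i in np.where(assigned < 0)[0]:
        f = int(np.argmax(capacity + 1e-6 * rng.random(k)))
        assigned[i] = f
        capacity[f] -= 1
    return FoldPlan(k, {ids[i]: int(assigned[i]) for i in range(n)}, seed)


@dataclass
class TrainedChannelModel:
    """A trained channel model plus its provenance."""

    model: ChannelModel
    family: str
    fold: int
    plan_hash: str
    best_epoch: int
    val_f1: float
    history: list[dict]


def _roles(plan: FoldPlan, fold: int) -> tuple[int, list[int]]:
    """(validation fold, training folds) for a given test fold."""
    val_fold = (fold + 1) % plan.k
    train_folds = [f for f in range(plan.k) if f not in (fold, val_fold)]
    return val_fold, train_folds


def train_channel_model(
    cfg: ModelConfig,
    tcfg: TrainConfig,
    plan: FoldPlan,
    fold: int,
    manifest: DatasetManifest,
) -> TrainedChannelModel:
    """Train one channel model for one cross-validation round.

    The test fold is untouched; one fold validates; the remaining k-2
    folds train with augmentation. Returns the epoch checkpoint with the
    best validation micro-F1.
    """
    if not 0 <= fold < plan.k:
        raise ValueError(f"fold {fold} out of range for k={plan.k}")
    ids = manifest.record_ids
    if set(ids) != set(plan.assignments):
        raise LeakageError("fold plan does not cover this manifest")
    val_fold, train_folds = _roles(plan, fold)
    train_idx = np.concatenate(
        [plan.fold_indices(ids, f) for f in train_folds]
    )
    val_idx = plan.fold_indices(ids, val_fold)
    test_idx = plan.fold_indices(ids, fold)
    if set(train_idx) & set(test_idx) or set(val_idx) & set(test_idx):
        raise LeakageError("train/validation and test folds overlap")

    y = manifest.label_matrix.astype(np.float64)
    counts = np.maximum(y[train_idx].sum(axis=0), 2).astype(np.int64)
    weights = class_weights(counts)

    ss = np.random.SeedSequence([tcfg.seed, fold, 0x747261696E])
    rng_batch, rng_aug, rng_model = [
        np.random.default_rng(s) for s in ss.spawn(3)
    ]
    model = build_model(
        replace(cfg, seed=int(ss.generate_state(1)[0] % 2**31)),
        n_leads=manifest.records[0].n_leads,
    )
    model.dropout.rng = rng_model
    opt = Adam(model.params(), lr=tcfg.lr)

    records = manifest.records
    x_val = np.stack([records[i].signal for i in val_idx])
    y_val = y[val_idx]

    best = (-1.0, None, 0)  # (val f1, state, epoch)
    history: list[dict] = []
    for epoch in range(1, tcfg.epochs + 1):
        opt.lr = lr_at_epoch(tcfg, epoch)
        order = rng_batch.permutation(train_idx)
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, len(order), tcfg.batch_size):
            batch_idx = order[start : start + tcfg.batch_size]
            batch_recs = [records[i] for i in batch_idx]
            if tcfg.augment is not None:
                batch_recs = [
                    random_augment(r, rng_aug, tcfg.augment) for r in batch_recs
                ]
            xb = np.stack([r.signal for r in batch_recs])
            yb = y[batch_idx]
            probs, aux = model.forward(xb, train=True)
            losses = [weighted_bce(probs, yb, weights)] + [
                weighted_bce(a, yb, weights) for a in aux
            ]
            loss = (
                composite_loss(*losses[:3])
                if len(losses) == 3
                else losses[0] + 0.3 * sum(losses[1:])
            )
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"divergent loss at epoch {epoch} "
                    f"(fold {fold}, family {cfg.family}): {loss}"
                )
            opt.zero_grad()
            d_main = weighted_bce_grad(probs, yb, weights)
            d_aux = [0.3 * weighted_bce_grad(a, yb, weights) for a in aux]
            model.backward(d_main, d_aux)
            opt.step()
            epoch_loss += loss
            n_batches += 1
        val_pred = (model.predict_proba(x_val) >= 0.5).astype(np.int8)
        val_f1 = prf1(confusion_counts(val_pred, y_val)).f1
        history.append(
            {
                "epoch": epoch,
                "lr": opt.lr,
                "train_loss": epoch_loss / max(n_batches, 1),
                "val_micro_f1": val_f1,
            }
        )
        if val_f1 > best[0]:
            best = (val_f1, model.get_state(), epoch)

    if best[1] is not None:
        model.set_state(best[1])
    model.trained = True
    return TrainedChannelModel(
        model=model,
        family=cfg.family,
        fold=fold,
        plan_hash=plan.hash(),
        best_epoch=best[2],
        val_f1=best[0],
        history=history,
    )
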