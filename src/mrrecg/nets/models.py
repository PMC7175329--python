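"""Channel-model architectures: inception- and residual-style 1-D CNNs,
with optional squeeze-and-excitation gating and auxiliary heads.

Four families feed the fusion stage:

* ``googlenet`` — a 1-D GoogLeNet adaptation: stem convolutions, nine
  inception modules (at reference depth) over a 22-weighted-layer stack,
  global average pooling instead of a large dense head, and two
  auxiliary classifiers tapped mid-network (weighted-layer depths 10 and
  16 in the reference stack, i.e. after the 3rd and 6th inception
  module);
* ``se_inception`` — the same with an SE gate after every inception
  concatenation;
* ``resnet`` — stages of residual blocks;
* ``se_resnet`` — residual blocks whose F(x) is SE-gated.

``width`` scales every channel count, yielding tiny desk-scale variants;
``n_inception`` / ``stage_blocks`` scale depth. Global average pooling
removes any coupling to the input length, so a model accepts any
``n_samples`` its pooling chain does not collapse below one sample
(>= 64 samples is safe for all reference and tiny profiles).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .blocks import AuxHead, ConvBNAct, InceptionModule, ResidualBlock
from .layers import (
    BatchNorm1d,
    Dense,
    Dropout,
    GlobalAvgPool,
    MaxPool1d,
    Parameter,
    Sigmoid,
    iter_layers,
)

__all__ = [
    "FAMILIES",
    "ModelConfig",
    "ChannelModel",
    "build_model",
    "count_params",
    "extract_features",
    "tiny_config",
]

FAMILIES = ("googlenet", "resnet", "se_inception", "se_resnet")


@dataclass(frozen=True)
class ModelConfig:
    family: str
    n_classes: int
    width: float = 1.0
    n_inception: int = 9  # inception families
    stage_blocks: tuple[int, ...] = (2, 2, 2, 2)  # residual families
    se_variant: str | None = None  # None -> "fc" for se_* families
    se_reduction: int = 16
    aux_after: tuple[int, ...] = (3, 6)  # aux taps, after these inception modules
    dropout: float = 0.4
    feature_source: str = "logits"  # or "pooled"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; one of {FAMILIES}")
        if self.n_classes < 1 or self.width <= 0:
            raise ValueError("need n_classes >= 1 and width > 0")
        if self.feature_source not in ("logits", "pooled"):
            raise ValueError("feature_source must be 'logits' or 'pooled'")
        if self.se_variant is None and self.family.startswith("se_"):
            object.__setattr__(self, "se_variant", "fc")

    @property
    def has_aux(self) -> bool:
        return self.family in ("googlenet", "se_inception") and bool(self.aux_after)


def tiny_config(family: str, n_classes: int, seed: int = 0) -> ModelConfig:
    """Desk-scale profile: quarter width, two inception modules or two
    single-block residual stages, one auxiliary tap."""
    return ModelConfig(
        family=family,
        n_classes=n_classes,
        width=0.25,
        n_inception=2,
        stage_blocks=(1, 1),
        aux_after=(1,),
        dropout=0.2,
        seed=seed,
    )


def _c(base: int, width: float) -> int:
    return max(int(round(base * width)), 1)


def _inception_channel_plan(n_modules: int, width: float) -> list[dict]:
    """Per-module branch widths; totals grow with depth like the 2-D
    reference (256 .. 832 channels over nine modules)."""
    totals = np.linspace(256, 832, n_modules)
    plan = []
    for t in totals:
        plan.append(
            dict(
                c1=_c(t / 4, width),
                c3r=_c(t / 8, width),
                c3=_c(t / 2, width),
                c5r=_c(t / 16, width),
                c5=_c(t / 8, width),
                cp=_c(t / 8, width),
            )
        )
    return plan


class ChannelModel:
    """A trainable 1-D CNN mapping ``[B, n_leads, n_samples]`` to
    per-class probabilities (independent sigmoids: multi-label)."""

    def __init__(self, cfg: ModelConfig, n_leads: int = 8):
        self.cfg = cfg
        self.n_leads = n_leads
        self.trained = False
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x6E657473]))
        self._rng = rng
        se = cfg.se_variant if cfg.family.startswith("se_") else None

        path: list = []
        taps: dict[int, tuple[AuxHead, Sigmoid]] = {}
        if cfg.family in ("googlenet", "se_inception"):
            path.append(ConvBNAct(n_leads, _c(64, cfg.width), 7, stride=2, rng=rng))
            path.append(MaxPool1d(3, 2))
            path.append(ConvBNAct(_c(64, cfg.width), _c(96, cfg.width), 3, rng=rng))
            path.append(MaxPool1d(3, 2))
            c_prev = _c(96, cfg.width)
            plan = _inception_channel_plan(cfg.n_inception, cfg.width)
            for i, spec in enumerate(plan, start=1):
                mod = InceptionModule(
                    c_prev, **spec,
                    se_variant=se, se_reduction=cfg.se_reduction, rng=rng,
                )
                path.append(mod)
                c_prev = mod.c_out
                if cfg.has_aux and i in cfg.aux_after:
                    taps[len(path) - 1] = (
                        AuxHead(c_prev, cfg.n_classes, rng=rng),
                        Sigmoid(),
                    )
                if i in (len(plan) // 3, 2 * len(plan) // 3):
                    path.append(MaxPool1d(3, 2))
        else:
            path.append(ConvBNAct(n_leads, _c(64, cfg.width), 7, stride=2, rng=rng))
            path.append(MaxPool1d(3, 2))
            c_prev = _c(64, cfg.width)
            for stage, n_blocks in enumerate(cfg.stage_blocks):
                c_out = _c(64 * 2**stage, cfg.width)
                for b in range(n_blocks):
                    stride = 2 if (b == 0 and stage > 0) else 1
                    path.append(
                        ResidualBlock(
                            c_prev, c_out, stride,
                            se_variant=se, se_reduction=cfg.se_reduction, rng=rng,
                        )
                    )
                    c_prev = c_out

        self.path = path
        self.taps = taps
        self.pool = GlobalAvgPool()
        self.dropout = Dropout(cfg.dropout, rng=rng)
        self.fc = Dense(c_prev, cfg.n_classes, rng=rng)
        self.out = Sigmoid()
        self.pooled_dim = c_prev

    @property
    def feature_dim(self) -> int:
        if self.cfg.feature_source == "logits":
            return self.cfg.n_classes
        return self.pooled_dim

    # -- plumbing ---------------------------------------------------------
    def _modules(self):
        for layer in self.path:
            yield layer
        for head, _ in self.taps.values():
            yield head
        yield from (self.pool, self.dropout, self.fc, self.out)

    def params(self) -> list[Parameter]:
        return [p for m in self._modules() for p in m.params()]

    def set_train(self, mode: bool) -> None:
        for m in self._modules():
            m.set_train(mode)

    def count_params(self) -> int:
        return int(sum(p.size for p in self.params()))

    # -- forward / backward ----------------------------------------------
    def forward(self, x: np.ndarray, train: bool = True):
        """Main-head probabilities, plus one per auxiliary head when
        training (ordered deepest tap last)."""
        self.set_train(train)
        aux_out = []
        for i, layer in enumerate(self.path):
            x = layer.forward(x)
            if train and i in self.taps:
                head, act = self.taps[i]
                aux_out.append(act.forward(head.forward(x)))
        pooled = self.pool.forward(x)
        logits = self.fc.forward(self.dropout.forward(pooled))
        probs = self.out.forward(logits)
        if train:
            return probs, aux_out
        return probs

    def backward(self, d_main: np.ndarray, d_aux: Sequence[np.ndarray] = ()):
        """Backpropagate loss gradients w.r.t. the head probabilities."""
        dy = self.fc.backward(self.out.backward(d_main))
        dy = self.pool.backward(self.dropout.backward(dy))
        d_aux = list(d_aux)
        tap_order = sorted(self.taps)  # aux_out order
        for i in reversed(range(len(self.path))):
            if i in self.taps and d_aux:
                head, act = self.taps[i]
                j = tap_order.index(i)
                if j < len(d_aux):
                    dy = dy + head.backward(act.backward(d_aux[j]))
            dy = self.path[i].backward(dy)
        return dy

    # -- inference --------------------------------------------------------
    def predict_proba(self, x: np.ndarray, batch: int = 64) -> np.ndarray:
        out = [self.forward(x[i : i + batch], train=False)
               for i in range(0, len(x), batch)]
        return np.concatenate(out, axis=0)

    def features(self, x: np.ndarray, batch: int = 64) -> np.ndarray:
        """Deterministic per-record deep features (evaluation mode).

        ``logits`` source: the last dense layer's pre-sigmoid outputs;
        ``pooled``: the global-average-pooled representation before it.
        """
        if not self.trained:
            raise RuntimeError("extract_features requires a trained model")
        self.set_train(False)
        chunks = []
        for i in range(0, len(x), batch):
            h = x[i : i + batch]
            for layer in self.path:
                h = layer.forward(h)
            pooled = self.pool.forward(h)
            if self.cfg.feature_source == "pooled":
                chunks.append(pooled)
            else:
                chunks.append(self.fc.forward(pooled))
        feats = np.concatenate(chunks, axis=0)
        if not np.isfinite(feats).all():
            raise FloatingPointError("non-finite deep features")
        return feats

    # -- state ------------------------------------------------------------
    def _batchnorms(self):
        return [
            l for m in self._modules() for l in iter_layers(m)
            if isinstance(l, BatchNorm1d)
        ]

    def get_state(self) -> list[np.ndarray]:
        """Trainable parameters plus batch-norm running statistics."""
        state = [p.value.copy() for p in self.params()]
        for bn in self._batchnorms():
            state.append(bn.running_mean.copy())
            state.append(bn.running_var.copy())
        return state

    def set_state(self, state: list[np.ndarray]) -> None:
        params = self.params()
        for p, v in zip(params, state[: len(params)]):
            p.value[...] = v
        rest = state[len(params) :]
        for i, bn in enumerate(self._batchnorms()):
            bn.running_mean[...] = rest[2 * i]
            bn.running_var[...] = rest[2 * i + 1]


def build_model(cfg: ModelConfig, n_leads: int = 8) -> ChannelModel:
    """Construct a channel model from its config (untrained)."""
    return ChannelModel(cfg, n_leads=n_leads)


def count_params(model: ChannelModel) -> int:
    """Exact number of trainable scalars in the model."""
    return model.count_params()


def extract_features(model: ChannelModel, batch_signals: np.ndarray) -> np.ndarray:
    """Per-record deep feature vectors (see :meth:`ChannelModel.features`)."""
    return model.features(batch_signals)
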