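"""Composite network blocks: conv units, squeeze-and-excitation,
inception modules, residual blocks and auxiliary classifier heads.

Each composite routes gradients explicitly (concat splits, residual adds,
and the product rule inside SE gating)."""

from __future__ import annotations

import numpy as np

from .layers import (
    BatchNorm1d,
    Conv1d,
    Dense,
    GlobalAvgPool,
    Layer,
    MaxPool1d,
    Parameter,
    ReLU,
    Sequential,
    Sigmoid,
)

__all__ = ["ConvBNAct", "SEBlock", "InceptionModule", "ResidualBlock", "AuxHead"]


class ConvBNAct(Sequential):
    """conv -> batch norm -> ReLU (batch norm after every convolution)."""

    def __init__(self, c_in, c_out, kernel, stride=1, rng=None):
        super().__init__(
            Conv1d(c_in, c_out, kernel, stride, bias=False, rng=rng),
            BatchNorm1d(c_out),
            ReLU(),
        )
        self.c_out = c_out


class SEBlock(Layer):
    """Channel gating: squeeze (global average) -> bottleneck (reduction
    16 by default) -> sigmoid gates in (0,1), one scalar per channel.

    ``variant="fc"`` uses two dense layers on the squeezed vector;
    ``variant="conv"`` realizes the same bottleneck with 1-D convolutions
    (kernel size configurable) applied to the squeezed map.
    """

    def __init__(self, c, reduction=16, variant="fc", conv_kernel=1, rng=None):
        if variant not in ("fc", "conv"):
            raise ValueError(f"unknown SE variant {variant!r}")
        self.c = c
        self.variant = variant
        cr = max(c // reduction, 1)
        if variant == "fc":
            self.body = Sequential(Dense(c, cr, rng=rng), ReLU(), Dense(cr, c, rng=rng))
        else:
            self.body = Sequential(
                Conv1d(c, cr, conv_kernel, rng=rng),
                ReLU(),
                Conv1d(cr, c, conv_kernel, rng=rng),
            )
        self.gate = Sigmoid()

    def params(self) -> list[Parameter]:
        return self.body.params()

    def set_train(self, mode: bool) -> None:
        super().set_train(mode)
        self.body.set_train(mode)

    def gates(self, x: np.ndarray) -> np.ndarray:
        """The per-channel scalars in (0,1) for a batch (no caching)."""
        z = x.mean(axis=2)
        if self.variant == "fc":
            return self.gate.forward(self.body.forward(z))
        return self.gate.forward(self.body.forward(z[:, :, None]))[:, :, 0]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        z = x.mean(axis=2)  # squeeze
        if self.variant == "fc":
            s = self.gate.forward(self.body.forward(z))
        else:
            s = self.gate.forward(self.body.forward(z[:, :, None]))[:, :, 0]
        self._s = s
        return x * s[:, :, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, s = self._x, self._s
        length = x.shape[2]
        dx_direct = dy * s[:, :, None]
        ds = (dy * x).sum(axis=2)
        if self.variant == "fc":
            dz = self.body.backward(self.gate.backward(ds))
        else:
            dz = self.body.backward(self.gate.backward(ds[:, :, None]))[:, :, 0]
        return dx_direct + dz[:, :, None] / length


class InceptionModule(Layer):
    """Parallel 1/3/5-kernel convolutions plus a pooled 1x1 branch,
    concatenated along channels; optionally SE-gated."""

    def __init__(
        self, c_in, c1, c3r, c3, c5r, c5, cp,
        se_variant=None, se_reduction=16, rng=None,
    ):
        self.b1 = ConvBNAct(c_in, c1, 1, rng=rng)
        self.b3 = Sequential(
            ConvBNAct(c_in, c3r, 1, rng=rng), ConvBNAct(c3r, c3, 3, rng=rng)
        )
        self.b5 = Sequential(
            ConvBNAct(c_in, c5r, 1, rng=rng), ConvBNAct(c5r, c5, 5, rng=rng)
        )
        self.bp = Sequential(MaxPool1d(3, 1), ConvBNAct(c_in, cp, 1, rng=rng))
        self.c_out = c1 + c3 + c5 + cp
        self._splits = np.cumsum([c1, c3, c5])
        self.se = (
            SEBlock(self.c_out, se_reduction, se_variant, rng=rng)
            if se_variant
            else None
        )

    def _branches(self):
        return (self.b1, self.b3, self.b5, self.bp)

    def params(self) -> list[Parameter]:
        out = [p for br in self._branches() for p in br.params()]
        if self.se is not None:
            out += self.se.params()
        return out

    def set_train(self, mode: bool) -> None:
        super().set_train(mode)
        for br in self._branches():
            br.set_train(mode)
        if self.se is not None:
            self.se.set_train(mode)

    def forward(self, x: np.ndarray) -> np.ndarray:
        outs = [br.forward(x) for br in self._branches()]
        y = np.concatenate(outs, axis=1)
        if self.se is not None:
            y = self.se.forward(y)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self.se is not None:
            dy = self.se.backward(dy)
        parts = np.split(dy, self._splits, axis=1)
        dx = None
        for br, part in zip(self._branches(), parts):
            d = br.backward(part)
            dx = d if dx is None else dx + d
        return dx


class ResidualBlock(Layer):
    """Two 3-kernel conv layers with identity (or projected) skip; the
    block output is ReLU(F(x) + x). SE, when present, gates F(x)."""

    def __init__(
        self, c_in, c_out, stride=1, se_variant=None, se_reduction=16, rng=None
    ):
        self.main = Sequential(
            ConvBNAct(c_in, c_out, 3, stride, rng=rng),
            Conv1d(c_out, c_out, 3, bias=False, rng=rng),
            BatchNorm1d(c_out),
        )
        self.proj = None
        if stride != 1 or c_in != c_out:
            self.proj = Sequential(
                Conv1d(c_in, c_out, 1, stride, bias=False, rng=rng),
                BatchNorm1d(c_out),
            )
        self.se = (
            SEBlock(c_out, se_reduction, se_variant, rng=rng) if se_variant else None
        )
        self.relu = ReLU()
        self.c_out = c_out

    def _parts(self):
        parts = [self.main]
        if self.proj is not None:
            parts.append(self.proj)
        if self.se is not None:
            parts.append(self.se)
        return parts

    def params(self) -> list[Parameter]:
        return [p for part in self._parts() for p in part.params()]

    def set_train(self, mode: bool) -> None:
        super().set_train(mode)
        for part in self._parts():
            part.set_train(mode)

    def forward(self, x: np.ndarray) -> np.ndarray:
        f = self.main.forward(x)
        if self.se is not None:
            f = self.se.forward(f)
        skip = x if self.proj is None else self.proj.forward(x)
        return self.relu.forward(f + skip)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        d = self.relu.backward(dy)
        df = self.se.backward(d) if self.se is not None else d
        dx = self.main.backward(df)
        dx += d if self.proj is None else self.proj.backward(d)
        return dx


class AuxHead(Layer):
    """Auxiliary classifier tapped mid-network: global average pool ->
    hidden dense -> logits. Regularizes deep training (loss weight 0.3)."""

    def __init__(self, c_in, n_classes, hidden=32, rng=None):
        self.body = Sequential(
            GlobalAvgPool(), Dense(c_in, hidden, rng=rng), ReLU(),
            Dense(hidden, n_classes, rng=rng),
        )

    def params(self) -> list[Parameter]:
        return self.body.params()

    def set_train(self, mode: bool) -> None:
        super().set_train(mode)
        self.body.set_train(mode)

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.body.forward(x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return self.body.backward(dy)
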