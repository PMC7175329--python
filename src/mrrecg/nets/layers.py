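"""Minimal 1-D neural-network layer framework (numpy, explicit backprop).

Implements exactly the pieces the channel models need: 1-D convolution
(im2col/matmul), batch normalization, ReLU/sigmoid, max and global
average pooling, dense layers, dropout, and the Adam optimizer. Every
layer caches what its backward pass needs; composites (inception,
residual, squeeze-and-excitation) route gradients explicitly in
``blocks.py``. Arrays are ``[batch, channels, length]`` float64.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Parameter",
    "Layer",
    "Conv1d",
    "BatchNorm1d",
    "ReLU",
    "Sigmoid",
    "Dense",
    "Dropout",
    "MaxPool1d",
    "GlobalAvgPool",
    "Sequential",
    "Adam",
]


class Parameter:
    """A trainable tensor with its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)

    @property
    def size(self) -> int:
        return self.value.size


class Layer:
    train_mode: bool = True

    def params(self) -> list[Parameter]:
        return []

    def set_train(self, mode: bool) -> None:
        self.train_mode = mode

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int):
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Conv1d(Layer):
    """Same-padded strided 1-D convolution over ``[B, C, L]``."""

    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel: int,
        stride: int = 1,
        bias: bool = True,
        rng: np.random.Generator | None = None,
    ):
        rng = rng or np.random.default_rng(0)
        self.c_in, self.c_out, self.kernel, self.stride = c_in, c_out, kernel, stride
        self.weight = Parameter(_he_init(rng, (c_out, c_in, kernel), c_in * kernel))
        self.bias = Parameter(np.zeros(c_out)) if bias else None
        self._cache: tuple | None = None

    def params(self) -> list[Parameter]:
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, length = x.shape
        k, s = self.kernel, self.stride
        pad_total = max((int(np.ceil(length / s)) - 1) * s + k - length, 0)
        lo, hi = pad_total // 2, pad_total - pad_total // 2
        xp = np.pad(x, ((0, 0), (0, 0), (lo, hi)))
        l_out = (xp.shape[2] - k) // s + 1
        win = np.lib.stride_tricks.sliding_window_view(xp, k, axis=2)[:, :, ::s]
        cols = np.ascontiguousarray(win.transpose(0, 2, 1, 3)).reshape(
            b * l_out, c * k
        )
        w2 = self.weight.value.reshape(self.c_out, c * k)
        y = cols @ w2.T
        if self.bias is not None:
            y += self.bias.value
        self._cache = (cols, (b, c, length), (lo, xp.shape[2], l_out))
        return y.reshape(b, l_out, self.c_out).transpose(0, 2, 1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, (b, c, length), (lo, padded_len, l_out) = self._cache
        k, s = self.kernel, self.stride
        dy2 = dy.transpose(0, 2, 1).reshape(b * l_out, self.c_out)
        self.weight.grad += (dy2.T @ cols).reshape(self.weight.value.shape)
        if self.bias is not None:
            self.bias.grad += dy2.sum(axis=0)
        dcols = (dy2 @ self.weight.value.reshape(self.c_out, c * k)).reshape(
            b, l_out, c, k
        ).transpose(0, 2, 1, 3)
        dxp = np.zeros((b, c, padded_len))
        for i in range(k):
            dxp[:, :, i : i + s * l_out : s] += dcols[:, :, :, i]
        return dxp[:, :, lo : lo + length]


class BatchNorm1d(Layer):
    """Per-channel batch normalization over batch and time."""

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(c))
        self.beta = Parameter(np.zeros(c))
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)
        self.momentum, self.eps = momentum, eps
        self._cache: tuple | None = None

    def params(self) -> list[Parameter]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.train_mode:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None]) * inv[None, :, None]
        self._cache = (xhat, inv, x.shape)
        return self.gamma.value[None, :, None] * xhat + self.beta.value[None, :, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv, shape = self._cache
        n = shape[0] * shape[2]
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2))
        self.beta.grad += dy.sum(axis=(0, 2))
        g = self.gamma.value[None, :, None]
        if not self.train_mode:
            return dy * g * inv[None, :, None]
        dxhat = dy * g
        term = (
            dxhat
            - dxhat.mean(axis=(0, 2), keepdims=True)
            - xhat * (dxhat * xhat).sum(axis=(0, 2), keepdims=True) / n
        )
        return term * inv[None, :, None]


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class Sigmoid(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._y = 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))
        return self._y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._y * (1.0 - self._y)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.weight = Parameter(_he_init(rng, (n_in, n_out), n_in))
        self.bias = Parameter(np.zeros(n_out))

    def params(self) -> list[Parameter]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.weight.value + self.bias.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.weight.grad += self._x.T @ dy
        self.bias.grad += dy.sum(axis=0)
        return dy @ self.weight.value.T


class Dropout(Layer):
    """Inverted dropout; identity in eval mode."""

    def __init__(self, p: float, rng: np.random.Generator | None = None):
        self.p = p
        self.rng = rng or np.random.default_rng(0)
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        if not self.train_mode or self.p <= 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy if self._mask is None else dy * self._mask


class MaxPool1d(Layer):
    """Same-padded max pooling (pad value -inf)."""

    def __init__(self, kernel: int, stride: int):
        self.kernel, self.stride = kernel, stride

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, length = x.shape
        k, s = self.kernel, self.stride
        pad_total = max((int(np.ceil(length / s)) - 1) * s + k - length, 0)
        lo = pad_total // 2
        xp = np.pad(x, ((0, 0), (0, 0), (lo, pad_total - lo)), constant_values=-np.inf)
        win = np.lib.stride_tricks.sliding_window_view(xp, k, axis=2)[:, :, ::s]
        self._argmax = win.argmax(axis=3)
        self._geom = (x.shape, lo, xp.shape[2])
        return win.max(axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        (b, c, length), lo, pad_len = self._geom
        s = self.stride
        l_out = dy.shape[2]
        dxp = np.zeros((b, c, pad_len))
        # flat position of each window's max inside the padded signal
        starts = np.arange(l_out) * s
        pos = starts[None, None, :] + self._argmax
        bi = np.arange(b)[:, None, None]
        ci = np.arange(c)[None, :, None]
        np.add.at(dxp, (bi, ci, pos), dy)
        return dxp[:, :, lo : lo + length]


class GlobalAvgPool(Layer):
    """[B, C, L] -> [B, C] by averaging over time."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._length = x.shape[2]
        return x.mean(axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.repeat(dy[:, :, None], self._length, axis=2) / self._length


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self) -> list[Parameter]:
        return [p for l in self.layers for p in l.params()]

    def set_train(self, mode: bool) -> None:
        for l in self.layers:
            l.set_train(mode)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for l in self.layers:
            x = l.forward(x)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy


def iter_layers(root) -> "list[Layer]":
    """All :class:`Layer` instances reachable from ``root`` (depth-first),
    including ``root`` itself when it is a Layer. Used for state capture
    (e.g. batch-norm running statistics live on nested layers)."""
    seen: list[Layer] = []

    def visit(obj):
        if isinstance(obj, Layer):
            seen.append(obj)
            for v in vars(obj).values():
                visit(v)
        elif isinstance(obj, (list, tuple)):
            for v in obj:
                visit(v)
        elif isinstance(obj, dict):
            for v in obj.values():
                visit(v)

    visit(root)
    return seen


class Adam:
    """Adam with per-parameter first/second moment estimates."""

    def __init__(
        self,
        params: list[Parameter],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            m += (1 - self.b1) * (p.grad - m)
            v += (1 - self.b2) * (p.grad**2 - v)
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
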