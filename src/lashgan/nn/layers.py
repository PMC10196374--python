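"""Trainable layers with explicit forward/backward passes.

Each layer caches what its backward pass needs during ``forward(..., train=True)``
and releases it on ``backward``.  A layer therefore supports one in-flight
forward at a time, which is all the training loop requires.  Evaluation-mode
forwards cache nothing and are deterministic.
"""

from __future__ import annotations

import numpy as np

from .functional import conv2d, conv2d_grad_input, conv2d_grad_weight

_DTYPE = np.float32


class Parameter:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.asarray(data, dtype=_DTYPE)
        self.grad = np.zeros_like(self.data)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    def parameters(self) -> list[Parameter]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _he_scale(fan_in: int) -> float:
    return float(np.sqrt(2.0 / fan_in))


class Conv2d(Layer):
    """4x4-style strided convolution with zero padding."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int, pad: int,
                 rng: np.random.Generator, weight_scale: float = 0.02):
        self.kernel, self.stride, self.pad = kernel, stride, pad
        self.w = Parameter(rng.normal(0.0, weight_scale, (out_ch, in_ch, kernel, kernel)))
        self.b = Parameter(np.zeros(out_ch))
        self._x: np.ndarray | None = None

    def parameters(self) -> list[Parameter]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._x = x
        y = conv2d(x, self.w.data, self.stride, self.pad)
        return y + self.b.data[None, :, None, None]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        x, self._x = self._x, None
        self.b.grad += gy.sum(axis=(0, 2, 3))
        self.w.grad += conv2d_grad_weight(x, gy, self.kernel, self.stride, self.pad)
        return conv2d_grad_input(gy, self.w.data, x.shape[2:], self.stride, self.pad)


class ConvTranspose2d(Layer):
    """Fractionally strided convolution (exact adjoint of :class:`Conv2d`).

    With kernel 4, stride 2, pad 1 the spatial size doubles exactly.  Weight
    layout is (in_ch, out_ch, k, k): the layer's forward is the input-gradient
    of a virtual convolution mapping the (large) output back to the input.
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int, pad: int,
                 rng: np.random.Generator, weight_scale: float = 0.02):
        self.kernel, self.stride, self.pad = kernel, stride, pad
        self.w = Parameter(rng.normal(0.0, weight_scale, (in_ch, out_ch, kernel, kernel)))
        self.b = Parameter(np.zeros(out_ch))
        self._x: np.ndarray | None = None

    def parameters(self) -> list[Parameter]:
        return [self.w, self.b]

    def _out_hw(self, h: int, w: int) -> tuple[int, int]:
        k, s, p = self.kernel, self.stride, self.pad
        return (h - 1) * s + k - 2 * p, (w - 1) * s + k - 2 * p

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._x = x
        out_hw = self._out_hw(*x.shape[2:])
        y = conv2d_grad_input(x, self.w.data, out_hw, self.stride, self.pad)
        return y + self.b.data[None, :, None, None]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        x, self._x = self._x, None
        self.b.grad += gy.sum(axis=(0, 2, 3))
        self.w.grad += conv2d_grad_weight(gy, x, self.kernel, self.stride, self.pad)
        return conv2d(gy, self.w.data, self.stride, self.pad)


class BatchNorm2d(Layer):
    """Per-channel batch normalization with running statistics.

    When a channel has fewer than two elements per batch (e.g. a 1x1
    bottleneck with batch size 1) the statistics are degenerate and the layer
    passes its input through unchanged.
    """

    def __init__(self, ch: int, eps: float = 1e-5, momentum: float = 0.1):
        self.eps, self.momentum = eps, momentum
        self.gamma = Parameter(np.ones(ch))
        self.beta = Parameter(np.zeros(ch))
        self.running_mean = np.zeros(ch, dtype=_DTYPE)
        self.running_var = np.ones(ch, dtype=_DTYPE)
        self._cache = None

    def parameters(self) -> list[Parameter]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, h, w = x.shape
        m = n * h * w
        if train:
            if m < 2:
                self._cache = ("bypass",)
                return x
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
            inv = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
            self._cache = ("norm", xhat, inv, m)
        else:
            inv = 1.0 / np.sqrt(self.running_var + self.eps)
            xhat = (x - self.running_mean[None, :, None, None]) * inv[None, :, None, None]
        return self.gamma.data[None, :, None, None] * xhat + self.beta.data[None, :, None, None]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        cache, self._cache = self._cache, None
        if cache[0] == "bypass":
            return gy
        _, xhat, inv, m = cache
        self.beta.grad += gy.sum(axis=(0, 2, 3))
        self.gamma.grad += (gy * xhat).sum(axis=(0, 2, 3))
        g = self.gamma.data[None, :, None, None]
        gxhat = gy * g
        # standard batchnorm input gradient
        t1 = gxhat.sum(axis=(0, 2, 3), keepdims=True)
        t2 = (gxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
        return (inv[None, :, None, None] / m) * (m * gxhat - t1 - xhat * t2)


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.2):
        self.slope = slope
        self._mask = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        mask = x > 0
        if train:
            self._mask = mask
        return np.where(mask, x, self.slope * x)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        mask, self._mask = self._mask, None
        return np.where(mask, gy, self.slope * gy)


class ReLU(LeakyReLU):
    def __init__(self):
        super().__init__(slope=0.0)


class Tanh(Layer):
    def __init__(self):
        self._y = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        y = np.tanh(x)
        if train:
            self._y = y
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        y, self._y = self._y, None
        return gy * (1.0 - y * y)


class Sigmoid(Layer):
    def __init__(self):
        self._y = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        y = 1.0 / (1.0 + np.exp(-x))
        if train:
            self._y = y
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        y, self._y = self._y, None
        return gy * y * (1.0 - y)


class Dropout(Layer):
    """Inverted dropout; identity in evaluation mode."""

    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate = rate
        self.rng = rng
        self._mask = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.rate <= 0.0:
            return x
        keep = 1.0 - self.rate
        mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        self._mask = mask
        return x * mask

    def backward(self, gy: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return gy
        mask, self._mask = self._mask, None
        return gy * mask
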