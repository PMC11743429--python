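"""Minimal numpy neural-network core: layers, backprop, residual blocks, AdamW.

Everything operates on float32 NCHW batches.  Each layer caches what its
backward pass needs during ``forward``; ``backward`` consumes the upstream
gradient and returns the gradient with respect to the layer input while
accumulating parameter gradients in :class:`Param` objects.

The core provides exactly what the tongue-analysis models need: strided
convolution (im2col), batch normalization, ReLU, max/global-average pooling,
linear layers, bottleneck residual blocks, and an AdamW optimizer with
decoupled weight decay.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Param", "Layer", "Sequential", "Conv2d", "BatchNorm2d", "ReLU",
    "MaxPool2d", "GlobalAvgPool", "Linear", "Bottleneck", "AdamW", "sigmoid",
]


def sigmoid(z: np.ndarray) -> np.ndarray:
    """Numerically stable logistic function."""
    z = np.asarray(z)
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class Param:
    """A trainable tensor with its accumulated gradient."""

    __slots__ = ("data", "grad", "name")

    def __init__(self, data: np.ndarray, name: str = "") -> None:
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = np.zeros_like(self.data)
        self.name = name

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    training: bool = True

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def train(self, mode: bool = True) -> None:
        self.training = mode

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)


class Sequential(Layer):
    def __init__(self, *layers: Layer) -> None:
        self.layers = list(layers)

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def train(self, mode: bool = True) -> None:
        self.training = mode
        for layer in self.layers:
            layer.train(mode)


class Conv2d(Layer):
    """2-D convolution via im2col.  Weight shape (C_out, C_in, k, k)."""

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int = 1,
                 pad: int = 0, rng: np.random.Generator | None = None,
                 bias: bool = True) -> None:
        rng = rng or np.random.default_rng()
        fan_in = c_in * kernel * kernel
        scale = np.sqrt(2.0 / fan_in)  # He init for ReLU stacks
        self.w = Param(rng.normal(0.0, scale, (c_out, c_in, kernel, kernel)), "conv.w")
        self.b = Param(np.zeros(c_out), "conv.b") if bias else None
        self.kernel, self.stride, self.pad = kernel, stride, pad
        self._cache: tuple | None = None

    def params(self) -> list[Param]:
        return [self.w] + ([self.b] if self.b is not None else [])

    def forward(self, x: np.ndarray) -> np.ndarray:
        k, s, p = self.kernel, self.stride, self.pad
        n, c, h, w = x.shape
        if p:
            x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        windows = sliding_window_view(x, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        # (n, c, ho, wo, k, k) -> (n, ho, wo, c*k*k)
        n_, _, ho, wo, _, _ = windows.shape
        cols = windows.transpose(0, 2, 3, 1, 4, 5).reshape(n_, ho, wo, c * k * k)
        wmat = self.w.data.reshape(self.w.data.shape[0], -1)  # (c_out, c*k*k)
        out = cols @ wmat.T
        if self.b is not None:
            out += self.b.data
        self._cache = (cols, (n, c, h, w), (ho, wo))
        return np.ascontiguousarray(out.transpose(0, 3, 1, 2), dtype=np.float32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, (n, c, h, w), (ho, wo) = self._cache
        k, s, p = self.kernel, self.stride, self.pad
        c_out = self.w.data.shape[0]
        dyt = dy.transpose(0, 2, 3, 1)  # (n, ho, wo, c_out)
        flat_cols = cols.reshape(-1, c * k * k)
        flat_dy = dyt.reshape(-1, c_out)
        self.w.grad += (flat_dy.T @ flat_cols).reshape(self.w.data.shape)
        if self.b is not None:
            self.b.grad += flat_dy.sum(axis=0)
        wmat = self.w.data.reshape(c_out, -1)
        dcols = (flat_dy @ wmat).reshape(n, ho, wo, c, k, k).transpose(0, 3, 4, 5, 1, 2)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=np.float32)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + s * ho:s, j:j + s * wo:s] += dcols[:, :, i, j]
        if p:
            dxp = dxp[:, :, p:-p, p:-p]
        return dxp


class BatchNorm2d(Layer):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5) -> None:
        self.gamma = Param(np.ones(channels), "bn.gamma")
        self.beta = Param(np.zeros(channels), "bn.beta")
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum, self.eps = momentum, eps
        self._cache: tuple | None = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray) -> np.ndarray:
        axes = (0, 2, 3)
        if self.training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean).astype(np.float32)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._cache = (xhat, inv, x.shape)
        return (self.gamma.data[None, :, None, None] * xhat
                + self.beta.data[None, :, None, None]).astype(np.float32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv, shape = self._cache
        n, c, h, w = shape
        m = n * h * w
        axes = (0, 2, 3)
        self.gamma.grad += (dy * xhat).sum(axis=axes)
        self.beta.grad += dy.sum(axis=axes)
        if not self.training:
            return (dy * self.gamma.data[None, :, None, None]
                    * inv[None, :, None, None]).astype(np.float32)
        dxhat = dy * self.gamma.data[None, :, None, None]
        term1 = dxhat
        term2 = dxhat.mean(axis=axes)[None, :, None, None]
        term3 = xhat * (dxhat * xhat).mean(axis=axes)[None, :, None, None]
        return ((term1 - term2 - term3) * inv[None, :, None, None]).astype(np.float32)


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(np.float32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, 0.0).astype(np.float32)


class MaxPool2d(Layer):
    def __init__(self, kernel: int = 3, stride: int = 2, pad: int = 1) -> None:
        self.kernel, self.stride, self.pad = kernel, stride, pad

    def forward(self, x: np.ndarray) -> np.ndarray:
        k, s, p = self.kernel, self.stride, self.pad
        if p:
            x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)),
                       constant_values=-np.inf)
        windows = sliding_window_view(x, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        n, c, ho, wo, _, _ = windows.shape
        flat = windows.reshape(n, c, ho, wo, k * k)
        idx = flat.argmax(axis=-1)
        out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
        self._cache = (idx, x.shape, (ho, wo))
        return out.astype(np.float32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        idx, padded_shape, (ho, wo) = self._cache
        k, s, p = self.kernel, self.stride, self.pad
        n, c, hp, wp = padded_shape
        dxp = np.zeros(padded_shape, dtype=np.float32)
        ki, kj = np.divmod(idx, k)
        rows = (np.arange(ho)[None, None, :, None] * s) + ki
        cols = (np.arange(wo)[None, None, None, :] * s) + kj
        nn_idx = np.arange(n)[:, None, None, None]
        cc_idx = np.arange(c)[None, :, None, None]
        np.add.at(dxp, (nn_idx, cc_idx, rows, cols), dy)
        if p:
            dxp = dxp[:, :, p:-p, p:-p]
        return dxp


class GlobalAvgPool(Layer):
    """(N, C, H, W) -> (N, C) spatial mean."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3)).astype(np.float32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        return (np.broadcast_to(dy[:, :, None, None], self._shape) / (h * w)).astype(np.float32)


class Linear(Layer):
    def __init__(self, d_in: int, d_out: int,
                 rng: np.random.Generator | None = None) -> None:
        rng = rng or np.random.default_rng()
        scale = np.sqrt(2.0 / d_in)
        self.w = Param(rng.normal(0.0, scale, (d_in, d_out)), "linear.w")
        self.b = Param(np.zeros(d_out), "linear.b")

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return (x @ self.w.data + self.b.data).astype(np.float32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.w.grad += self._x.T @ dy
        self.b.grad += dy.sum(axis=0)
        return (dy @ self.w.data.T).astype(np.float32)


class Bottleneck(Layer):
    """Residual bottleneck block: 1x1 / 3x3(stride) / 1x1 convs with batchnorm.

    A 1x1 projection shortcut is inserted when stride > 1 or the channel
    count changes.
    """

    def __init__(self, c_in: int, c_mid: int, c_out: int, stride: int = 1,
                 rng: np.random.Generator | None = None) -> None:
        self.main = Sequential(
            Conv2d(c_in, c_mid, 1, rng=rng, bias=False), BatchNorm2d(c_mid), ReLU(),
            Conv2d(c_mid, c_mid, 3, stride=stride, pad=1, rng=rng, bias=False),
            BatchNorm2d(c_mid), ReLU(),
            Conv2d(c_mid, c_out, 1, rng=rng, bias=False), BatchNorm2d(c_out),
        )
        if stride != 1 or c_in != c_out:
            self.proj: Sequential | None = Sequential(
                Conv2d(c_in, c_out, 1, stride=stride, rng=rng, bias=False),
                BatchNorm2d(c_out),
            )
        else:
            self.proj = None
        self.relu = ReLU()

    def params(self) -> list[Param]:
        ps = self.main.params()
        if self.proj is not None:
            ps += self.proj.params()
        return ps

    def train(self, mode: bool = True) -> None:
        self.training = mode
        self.main.train(mode)
        if self.proj is not None:
            self.proj.train(mode)

    def forward(self, x: np.ndarray) -> np.ndarray:
        y = self.main.forward(x)
        s = self.proj.forward(x) if self.proj is not None else x
        return self.relu.forward(y + s)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        d = self.relu.backward(dy)
        dx = self.main.backward(d)
        if self.proj is not None:
            dx = dx + self.proj.backward(d)
        else:
            dx = dx + d
        return dx


class AdamW:
    """Adam with decoupled weight decay."""

    def __init__(self, params: list[Param], lr: float = 5e-4,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 1e-2) -> None:
        self.params = params
        self.lr, self.betas, self.eps, self.weight_decay = lr, betas, eps, weight_decay
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if self.lr == 0.0:
                continue
            m[...] = b1 * m + (1.0 - b1) * p.grad
            v[...] = b2 * v + (1.0 - b2) * p.grad ** 2
            update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            p.data -= self.lr * (update + self.weight_decay * p.data)
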