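"""Minimal CNN building blocks on NumPy with explicit backpropagation.

Layout convention is NCHW, float32. Each layer caches what its backward
pass needs during ``forward`` and releases it after ``backward``; gradients
accumulate into ``Param.grad`` so a layer can be shared only if gradients
are zeroed between steps. Buffers follow the dtype of their inputs, which
lets tests run the same code in float64 for finite-difference checks.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    """A trainable tensor and its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)


def he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Layer:
    training: bool = True

    def params(self) -> list[Param]:
        return []

    def set_training(self, flag: bool) -> None:
        self.training = flag


class Conv2d(Layer):
    """Same-padded stride-1 convolution via im2col + BLAS matmul."""

    def __init__(self, in_c: int, out_c: int, kernel: int, rng: np.random.Generator,
                 bias: bool = False):
        if kernel not in (1, 3):
            raise ValueError(f"unsupported kernel size {kernel}")
        self.in_c, self.out_c, self.k = in_c, out_c, kernel
        self.pad = kernel // 2
        self.w = Param(he_init(rng, (out_c, in_c * kernel * kernel), in_c * kernel * kernel))
        self.b = Param(np.zeros(out_c)) if bias else None
        self._cols = None
        self._xshape = None

    def params(self):
        return [self.w] + ([self.b] if self.b is not None else [])

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        if c != self.in_c:
            raise ValueError(f"expected {self.in_c} input channels, got {c}")
        if self.k == 1:
            cols = x.reshape(n, c, h * w)
        else:
            xp = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad), (self.pad, self.pad)))
            v = sliding_window_view(xp, (self.k, self.k), axis=(2, 3))  # n,c,h,w,k,k
            cols = np.ascontiguousarray(
                v.transpose(0, 1, 4, 5, 2, 3)).reshape(n, c * self.k * self.k, h * w)
        self._cols, self._xshape = cols, x.shape
        out = np.matmul(self.w.value.astype(x.dtype), cols)
        if self.b is not None:
            out = out + self.b.value.astype(x.dtype)[:, None]
        return out.reshape(n, self.out_c, h, w)

    def backward(self, g: np.ndarray) -> np.ndarray:
        n, c, h, w = self._xshape
        go = g.reshape(n, self.out_c, h * w)
        self.w.grad += np.tensordot(go, self._cols, axes=([0, 2], [0, 2])).astype(np.float32)
        if self.b is not None:
            self.b.grad += go.sum(axis=(0, 2)).astype(np.float32)
        dcols = np.matmul(self.w.value.T.astype(g.dtype), go)
        self._cols = None
        if self.k == 1:
            return dcols.reshape(n, c, h, w)
        dcols = dcols.reshape(n, c, self.k, self.k, h, w)
        dxp = np.zeros((n, c, h + 2 * self.pad, w + 2 * self.pad), dtype=g.dtype)
        for ki in range(self.k):
            for kj in range(self.k):
                dxp[:, :, ki:ki + h, kj:kj + w] += dcols[:, :, ki, kj]
        return dxp[:, :, self.pad:self.pad + h, self.pad:self.pad + w]


class BatchNorm2d(Layer):
    """Per-channel batch normalization with affine scale/shift.

    Batch statistics use the biased variance; running statistics (used in
    eval mode) are updated with momentum 0.1.
    """

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum, self.eps = momentum, eps
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.training:
            mu = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mu.astype(np.float32) - self.running_mean)
            self.running_var += self.momentum * (var.astype(np.float32) - self.running_var)
        else:
            mu = self.running_mean.astype(x.dtype)
            var = self.running_var.astype(x.dtype)
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu[None, :, None, None]) * inv_std[None, :, None, None]
        self._cache = (xhat, inv_std)
        g = self.gamma.value.astype(x.dtype)
        b = self.beta.value.astype(x.dtype)
        return g[None, :, None, None] * xhat + b[None, :, None, None]

    def backward(self, g: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._cache
        self._cache = None
        m = g.shape[0] * g.shape[2] * g.shape[3]
        dbeta = g.sum(axis=(0, 2, 3))
        dgamma = (g * xhat).sum(axis=(0, 2, 3))
        self.gamma.grad += dgamma.astype(np.float32)
        self.beta.grad += dbeta.astype(np.float32)
        gam = self.gamma.value.astype(g.dtype)
        if self.training:
            dx = (gam * inv_std)[None, :, None, None] * (
                g - dbeta[None, :, None, None] / m - xhat * dgamma[None, :, None, None] / m)
        else:
            dx = (gam * inv_std)[None, :, None, None] * g
        return dx


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, g: np.ndarray) -> np.ndarray:
        out = g * self._mask
        self._mask = None
        return out


class ConvBlock(Layer):
    """Convolution (no bias) -> batch normalization -> rectifier."""

    def __init__(self, in_c: int, out_c: int, kernel: int, rng: np.random.Generator):
        self.conv = Conv2d(in_c, out_c, kernel, rng, bias=False)
        self.bn = BatchNorm2d(out_c)
        self.act = ReLU()

    def params(self):
        return self.conv.params() + self.bn.params()

    def set_training(self, flag):
        self.bn.set_training(flag)

    def forward(self, x):
        return self.act.forward(self.bn.forward(self.conv.forward(x)))

    def backward(self, g):
        return self.conv.backward(self.bn.backward(self.act.backward(g)))


class MaxPool2d(Layer):
    """2x2 max pooling, stride 2; records argmax indices for unpooling."""

    @staticmethod
    def forward(x: np.ndarray):
        n, c, h, w = x.shape
        ho, wo = h // 2, w // 2
        xr = x.reshape(n, c, ho, 2, wo, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, ho, wo, 4)
        idx = xr.argmax(axis=-1)
        out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        return out, idx

    @staticmethod
    def backward(g: np.ndarray, idx: np.ndarray) -> np.ndarray:
        return MaxPool2d.scatter(g, idx)

    @staticmethod
    def scatter(values: np.ndarray, idx: np.ndarray) -> np.ndarray:
        """Place pooled-resolution values at their argmax positions (zeros elsewhere)."""
        n, c, ho, wo = values.shape
        buf = np.zeros((n, c, ho, wo, 4), dtype=values.dtype)
        np.put_along_axis(buf, idx[..., None], values[..., None], axis=-1)
        return buf.reshape(n, c, ho, wo, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
            n, c, 2 * ho, 2 * wo)

    @staticmethod
    def gather(full: np.ndarray, idx: np.ndarray) -> np.ndarray:
        """Inverse of scatter: read values at the recorded argmax positions."""
        n, c, h, w = full.shape
        ho, wo = h // 2, w // 2
        xr = full.reshape(n, c, ho, 2, wo, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
            n, c, ho, wo, 4)
        return np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]


class MaxUnpool2d(Layer):
    """Index-based 2x upsampling (the SegNet decoder primitive)."""

    @staticmethod
    def forward(x: np.ndarray, idx: np.ndarray) -> np.ndarray:
        return MaxPool2d.scatter(x, idx)

    @staticmethod
    def backward(g: np.ndarray, idx: np.ndarray) -> np.ndarray:
        return MaxPool2d.gather(g, idx)


class GlobalAvgPool(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, g: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        return np.broadcast_to(g[:, :, None, None] / (h * w), self._shape).astype(g.dtype)


class Linear(Layer):
    def __init__(self, in_f: int, out_f: int, rng: np.random.Generator):
        self.w = Param(he_init(rng, (out_f, in_f), in_f))
        self.b = Param(np.zeros(out_f))

    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w.value.T.astype(x.dtype) + self.b.value.astype(x.dtype)

    def backward(self, g: np.ndarray) -> np.ndarray:
        self.w.grad += (g.T @ self._x).astype(np.float32)
        self.b.grad += g.sum(axis=0).astype(np.float32)
        self._x = None
        return g @ self.w.value.astype(g.dtype)


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Adam:
    """Adam optimizer with bias correction (Kingma & Ba defaults)."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m += (1 - self.b1) * (p.grad - m)
            v += (1 - self.b2) * (p.grad * p.grad - v)
            p.value -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


def count_params(layers_or_params) -> int:
    """Total number of trainable scalars in a list of layers or Params."""
    total = 0
    for item in layers_or_params:
        if isinstance(item, Param):
            total += item.value.size
        else:
            total += sum(p.value.size for p in item.params())
    return total
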