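"""Minimal CPU neural-network layers with manual backpropagation.

Just enough machinery for a 2-D U-Net generator and a patch-based
convolutional discriminator: strided convolution / transposed
convolution (im2col-based), instance normalization, the usual
activations, and an Adam optimizer.  All arrays are NCHW; compute runs
in ``DTYPE`` (float32 by default, which roughly halves CPU wall time
per training step relative to float64).

Every layer caches what its backward pass needs from the most recent
forward call, so a forward/backward pair must not be interleaved with
another forward on the same layer instance.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "DTYPE", "Param", "Layer", "Conv2d", "ConvTranspose2d", "InstanceNorm2d",
    "ReLU", "LeakyReLU", "Sigmoid", "Sequential", "Adam",
]

#: compute dtype for all layers; module-level so numerical experiments
#: (e.g. finite-difference gradient checks) can switch to float64.
DTYPE = np.float32


class Param:
    """A trainable tensor and its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _im2col(xp: np.ndarray, k: int, s: int, ho: int, wo: int) -> np.ndarray:
    """(B, C, Hp, Wp) -> (B, C, k, k, ho, wo) patch view (copied)."""
    b, c = xp.shape[:2]
    cols = np.empty((b, c, k, k, ho, wo), dtype=xp.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i, j] = xp[:, :, i : i + s * ho : s, j : j + s * wo : s]
    return cols


def _col2im(dcols: np.ndarray, shape, k: int, s: int, ho: int, wo: int) -> np.ndarray:
    """Scatter-add inverse of :func:`_im2col`."""
    dxp = np.zeros(shape, dtype=dcols.dtype)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i : i + s * ho : s, j : j + s * wo : s] += dcols[:, :, i, j]
    return dxp


class Conv2d(Layer):
    def __init__(self, c_in: int, c_out: int, k: int = 4, stride: int = 2,
                 pad: int = 1, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.c_in, self.c_out, self.k, self.s, self.p = c_in, c_out, k, stride, pad
        self.w = Param(rng.normal(0.0, 0.02, size=(c_out, c_in * k * k)))
        self.b = Param(np.zeros(c_out))

    def params(self):
        return [self.w, self.b]

    def forward(self, x):
        x = np.asarray(x, dtype=self.w.value.dtype)
        b, c, h, w = x.shape
        k, s, p = self.k, self.s, self.p
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        ho = (h + 2 * p - k) // s + 1
        wo = (w + 2 * p - k) // s + 1
        cols = _im2col(xp, k, s, ho, wo).reshape(b, c * k * k, ho * wo)
        y = np.matmul(self.w.value, cols)
        y += self.b.value[None, :, None]
        self._cache = (cols, (b, c, h, w), ho, wo)
        return y.reshape(b, self.c_out, ho, wo)

    def backward(self, dy):
        cols, (b, c, h, w), ho, wo = self._cache
        k, s, p = self.k, self.s, self.p
        dyf = np.asarray(dy, dtype=self.w.value.dtype).reshape(b, self.c_out, ho * wo)
        self.w.grad += np.matmul(dyf, cols.transpose(0, 2, 1)).sum(axis=0)
        self.b.grad += dyf.sum(axis=(0, 2))
        dcols = np.matmul(self.w.value.T, dyf)
        dcols = dcols.reshape(b, c, k, k, ho, wo)
        dxp = _col2im(dcols, (b, c, h + 2 * p, w + 2 * p), k, s, ho, wo)
        return dxp[:, :, p : p + h, p : p + w]


class ConvTranspose2d(Layer):
    def __init__(self, c_in: int, c_out: int, k: int = 4, stride: int = 2,
                 pad: int = 1, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.c_in, self.c_out, self.k, self.s, self.p = c_in, c_out, k, stride, pad
        self.w = Param(rng.normal(0.0, 0.02, size=(c_in, c_out * k * k)))
        self.b = Param(np.zeros(c_out))

    def params(self):
        return [self.w, self.b]

    def forward(self, x):
        x = np.asarray(x, dtype=self.w.value.dtype)
        b, c, h, w = x.shape
        k, s, p = self.k, self.s, self.p
        ho = (h - 1) * s - 2 * p + k
        wo = (w - 1) * s - 2 * p + k
        xf = x.reshape(b, c, h * w)
        cols = np.matmul(self.w.value.T, xf)
        cols = cols.reshape(b, self.c_out, k, k, h, w)
        yp = _col2im(cols, (b, self.c_out, ho + 2 * p, wo + 2 * p), k, s, h, w)
        y = yp[:, :, p : p + ho, p : p + wo] + self.b.value[None, :, None, None]
        self._cache = (xf, (b, c, h, w), ho, wo)
        return y

    def backward(self, dy):
        xf, (b, c, h, w), ho, wo = self._cache
        k, s, p = self.k, self.s, self.p
        dyp = np.pad(np.asarray(dy, dtype=self.w.value.dtype),
                     ((0, 0), (0, 0), (p, p), (p, p)))
        dcols = _im2col(dyp, k, s, h, w)  # (b, c_out, k, k, h, w)
        dcolsf = dcols.reshape(b, self.c_out * k * k, h * w)
        self.w.grad += np.matmul(xf, dcolsf.transpose(0, 2, 1)).sum(axis=0)
        self.b.grad += dy.sum(axis=(0, 2, 3))
        dx = np.matmul(self.w.value, dcolsf)
        return dx.reshape(b, c, h, w)


class InstanceNorm2d(Layer):
    """Per-sample, per-channel normalization over the spatial axes."""

    def __init__(self, c: int, eps: float = 1e-5, affine: bool = True):
        self.eps = eps
        self.affine = affine
        self.gamma = Param(np.ones(c)) if affine else None
        self.beta = Param(np.zeros(c)) if affine else None

    def params(self):
        return [self.gamma, self.beta] if self.affine else []

    def forward(self, x):
        mean = x.mean(axis=(2, 3), keepdims=True)
        var = x.var(axis=(2, 3), keepdims=True)
        invstd = 1.0 / np.sqrt(var + self.eps)
        xn = (x - mean) * invstd
        self._cache = (xn, invstd, x.shape)
        if self.affine:
            return self.gamma.value[None, :, None, None] * xn + self.beta.value[None, :, None, None]
        return xn

    def backward(self, dy):
        xn, invstd, shape = self._cache
        n = shape[2] * shape[3]
        if self.affine:
            self.gamma.grad += (dy * xn).sum(axis=(0, 2, 3))
            self.beta.grad += dy.sum(axis=(0, 2, 3))
            dxn = dy * self.gamma.value[None, :, None, None]
        else:
            dxn = dy
        s1 = dxn.sum(axis=(2, 3), keepdims=True)
        s2 = (dxn * xn).sum(axis=(2, 3), keepdims=True)
        return (invstd / n) * (n * dxn - s1 - xn * s2)


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy):
        return np.where(self._mask, dy, 0.0)


class LeakyReLU(Layer):
    def __init__(self, alpha: float = 0.2):
        self.alpha = alpha

    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, self.alpha * x)

    def backward(self, dy):
        return np.where(self._mask, dy, self.alpha * dy)


class Sigmoid(Layer):
    def forward(self, x):
        y = 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))
        self._y = y
        return y

    def backward(self, dy):
        return dy * self._y * (1.0 - self._y)


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def forward(self, x):
        for l in self.layers:
            x = l.forward(x)
        return x

    def backward(self, dy):
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy


class Adam:
    """Adam with the beta1=0.5 convention common for GAN training."""

    def __init__(self, params: list[Param], lr: float = 2e-4,
                 betas: tuple[float, float] = (0.5, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.eps = lr, eps
        self.b1, self.b2 = betas
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * p.grad
            v *= self.b2
            v += (1.0 - self.b2) * p.grad ** 2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def state(self) -> dict:
        return {"t": self.t, "m": [m.copy() for m in self.m],
                "v": [v.copy() for v in self.v]}
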