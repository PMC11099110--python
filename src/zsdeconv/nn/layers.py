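"""Layer primitives with explicit forward/backward passes.

Tensors are channel-first batches: (N, C, H, W) in 2D and
(N, C, D, H, W) in 3D.  Each layer caches what its backward pass needs;
``backward`` consumes the gradient w.r.t. its output and returns the
gradient w.r.t. its input while accumulating parameter gradients.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2d(Layer):
    """Same-padded (zero) 2D convolution via im2col + GEMM."""

    def __init__(self, cin: int, cout: int, k: int = 3, rng=None, dtype=np.float32):
        rng = rng or np.random.default_rng()
        fan_in = cin * k * k
        self.w = Param(
            (rng.standard_normal((cout, fan_in)) * np.sqrt(2.0 / fan_in)).astype(dtype)
        )
        self.b = Param(np.zeros(cout, dtype=dtype))
        self.k = k
        self.cin = cin
        self.cout = cout

    def params(self):
        return [self.w, self.b]

    def forward(self, x):
        n, c, h, w = x.shape
        k = self.k
        p = k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = sliding_window_view(xp, (k, k), axis=(2, 3))  # (N,C,H,W,k,k)
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            n * h * w, c * k * k
        )
        out = cols @ self.w.value.T + self.b.value
        self._cache = (cols, x.shape)
        return np.ascontiguousarray(out.reshape(n, h, w, self.cout).transpose(0, 3, 1, 2))

    def backward(self, g):
        cols, xshape = self._cache
        n, c, h, w = xshape
        k = self.k
        p = k // 2
        gmat = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(-1, self.cout)
        self.w.grad += gmat.T @ cols
        self.b.grad += gmat.sum(axis=0)
        dcols = (gmat @ self.w.value).reshape(n, h, w, c, k, k)
        # accumulate channels-last (contiguous inner axis), transpose once
        dxp = np.zeros((n, h + 2 * p, w + 2 * p, c), dtype=g.dtype)
        for i in range(k):
            for j in range(k):
                dxp[:, i : i + h, j : j + w, :] += dcols[:, :, :, :, i, j]
        dxp = dxp.transpose(0, 3, 1, 2)
        return dxp[:, :, p : p + h, p : p + w] if p else dxp


class Conv3d(Layer):
    """Same-padded (zero) 3D convolution via im2col + GEMM."""

    def __init__(self, cin: int, cout: int, k: int = 3, rng=None, dtype=np.float32):
        rng = rng or np.random.default_rng()
        fan_in = cin * k**3
        self.w = Param(
            (rng.standard_normal((cout, fan_in)) * np.sqrt(2.0 / fan_in)).astype(dtype)
        )
        self.b = Param(np.zeros(cout, dtype=dtype))
        self.k = k
        self.cin = cin
        self.cout = cout

    def params(self):
        return [self.w, self.b]

    def forward(self, x):
        n, c, d, h, w = x.shape
        k = self.k
        p = k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
        win = sliding_window_view(xp, (k, k, k), axis=(2, 3, 4))
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 4, 1, 5, 6, 7)).reshape(
            n * d * h * w, c * k**3
        )
        out = cols @ self.w.value.T + self.b.value
        self._cache = (cols, x.shape)
        return np.ascontiguousarray(
            out.reshape(n, d, h, w, self.cout).transpose(0, 4, 1, 2, 3)
        )

    def backward(self, g):
        cols, xshape = self._cache
        n, c, d, h, w = xshape
        k = self.k
        p = k // 2
        gmat = np.ascontiguousarray(g.transpose(0, 2, 3, 4, 1)).reshape(-1, self.cout)
        self.w.grad += gmat.T @ cols
        self.b.grad += gmat.sum(axis=0)
        dcols = (gmat @ self.w.value).reshape(n, d, h, w, c, k, k, k)
        dxp = np.zeros((n, d + 2 * p, h + 2 * p, w + 2 * p, c), dtype=g.dtype)
        for i in range(k):
            for j in range(k):
                for l in range(k):
                    dxp[:, i : i + d, j : j + h, l : l + w, :] += dcols[
                        :, :, :, :, :, i, j, l
                    ]
        dxp = dxp.transpose(0, 4, 1, 2, 3)
        return dxp[:, :, p : p + d, p : p + h, p : p + w] if p else dxp


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.1):
        self.slope = slope

    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, g):
        return np.where(self._mask, g, self.slope * g)


class AvgPool2d(Layer):
    """2x2 average pooling over the lateral (last two) axes."""

    def forward(self, x):
        self._shape = x.shape
        h, w = x.shape[-2] // 2, x.shape[-1] // 2
        return x.reshape(x.shape[:-2] + (h, 2, w, 2)).mean(axis=(-3, -1))

    def backward(self, g):
        up = np.repeat(np.repeat(g, 2, axis=-2), 2, axis=-1) / 4.0
        return up.astype(g.dtype)


class Upsample2d(Layer):
    """Nearest-neighbor upsampling over the lateral axes."""

    def __init__(self, factor: int = 2):
        self.factor = factor

    def forward(self, x):
        f = self.factor
        return np.repeat(np.repeat(x, f, axis=-2), f, axis=-1)

    def backward(self, g):
        f = self.factor
        h, w = g.shape[-2] // f, g.shape[-1] // f
        return g.reshape(g.shape[:-2] + (h, f, w, f)).sum(axis=(-3, -1))


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self):
        out = []
        for l in self.layers:
            out.extend(l.params())
        return out

    def forward(self, x):
        for l in self.layers:
            x = l.forward(x)
        return x

    def backward(self, g):
        for l in reversed(self.layers):
            g = l.backward(g)
        return g


def upsample_nearest(x: np.ndarray, factor: int) -> np.ndarray:
    return np.repeat(np.repeat(x, factor, axis=-2), factor, axis=-1)


def upsample_nearest_adjoint(g: np.ndarray, factor: int) -> np.ndarray:
    h, w = g.shape[-2] // factor, g.shape[-1] // factor
    return g.reshape(g.shape[:-2] + (h, factor, w, factor)).sum(axis=(-3, -1))


class Adam:
    """Adam optimizer with optional global-norm gradient clipping."""

    def __init__(
        self,
        params: list[Param],
        lr: float = 5e-5,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
        clip_norm: float | None = 1.0,
    ):
        self.params = params
        self.lr = lr
        self.b1 = beta1
        self.b2 = beta2
        self.eps = eps
        self.clip_norm = clip_norm
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self, lr: float | None = None):
        lr = self.lr if lr is None else lr
        if self.clip_norm is not None:
            sq = sum(float(np.sum(p.grad.astype(np.float64) ** 2)) for p in self.params)
            norm = np.sqrt(sq)
            if norm > self.clip_norm:
                scale = self.clip_norm / (norm + 1e-12)
                for p in self.params:
                    p.grad *= scale
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * p.grad
            v *= self.b2
            v += (1.0 - self.b2) * p.grad**2
            p.value -= lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
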