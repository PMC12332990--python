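"""Minimal 3-D conv-net building blocks with explicit forward/backward.

NumPy-only: convolutions are lowered to GEMM through strided window views,
so a small encoder-decoder trains in minutes on one CPU.  Layers cache what
backward needs; ``backward`` must be called after the matching ``forward``.
All arrays are (N, C, D, H, W) float32.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Layer", "Conv3d", "ConvTranspose3d", "InstanceNorm3d", "ReLU"]


class Layer:
    """Base: parameters live in ``self.params``; gradients in ``self.grads``."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def zero_grad(self):
        for k in self.grads:
            self.grads[k][...] = 0.0


def _he_init(rng, shape, fan_in):
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Conv3d(Layer):
    """3-D convolution, kernel k, stride s, zero padding k//2 ("same" at s=1)."""

    def __init__(self, c_in, c_out, kernel=3, stride=1, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.c_in, self.c_out = c_in, c_out
        self.k, self.s = kernel, stride
        self.pad = kernel // 2
        fan_in = c_in * kernel**3
        self.params["W"] = _he_init(rng, (c_out, c_in, kernel, kernel, kernel), fan_in)
        self.params["b"] = np.zeros(c_out, dtype=np.float32)
        self.grads["W"] = np.zeros_like(self.params["W"])
        self.grads["b"] = np.zeros_like(self.params["b"])
        self._xp = None

    def _cols(self, xp):
        v = sliding_window_view(xp, (self.k, self.k, self.k), axis=(2, 3, 4))
        if self.s > 1:
            v = v[:, :, :: self.s, :: self.s, :: self.s]
        return v  # (N, C, Do, Ho, Wo, k, k, k) view

    def forward(self, x):
        p = self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p))) if p else x
        self._xp = xp
        cols = self._cols(xp)
        out = np.tensordot(cols, self.params["W"], axes=([1, 5, 6, 7], [1, 2, 3, 4]))
        out += self.params["b"]
        return np.ascontiguousarray(np.moveaxis(out, -1, 1))

    def backward(self, dout):
        xp, s, p = self._xp, self.s, self.pad
        cols = self._cols(xp)
        d = np.moveaxis(dout, 1, -1)  # (N, Do, Ho, Wo, C_out)
        self.grads["W"] += np.tensordot(
            d, cols, axes=([0, 1, 2, 3], [0, 2, 3, 4])
        ).astype(np.float32)
        self.grads["b"] += d.sum(axis=(0, 1, 2, 3)).astype(np.float32)
        # (N, Do, Ho, Wo, C_in, k, k, k)
        dcols = np.tensordot(d, self.params["W"], axes=([4], [0]))
        dcols = np.moveaxis(dcols, 4, 1)
        dxp = np.zeros_like(xp)
        Do, Ho, Wo = dout.shape[2:]
        for i in range(self.k):
            for j in range(self.k):
                for l in range(self.k):
                    dxp[
                        :, :, i : i + s * Do : s, j : j + s * Ho : s, l : l + s * Wo : s
                    ] += dcols[..., i, j, l]
        self._xp = None
        if p:
            return dxp[:, :, p:-p, p:-p, p:-p]
        return dxp


class ConvTranspose3d(Layer):
    """Transposed convolution, kernel 2, stride 2: exact 2x upsampling."""

    def __init__(self, c_in, c_out, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.c_in, self.c_out = c_in, c_out
        self.params["W"] = _he_init(rng, (c_in, c_out, 2, 2, 2), c_in * 8)
        self.params["b"] = np.zeros(c_out, dtype=np.float32)
        self.grads["W"] = np.zeros_like(self.params["W"])
        self.grads["b"] = np.zeros_like(self.params["b"])
        self._x = None

    def forward(self, x):
        self._x = x
        N, C, D, H, W = x.shape
        t = np.tensordot(x, self.params["W"], axes=([1], [0]))
        # (N, D, H, W, C_out, 2, 2, 2) -> (N, C_out, D, 2, H, 2, W, 2)
        t = t.transpose(0, 4, 1, 5, 2, 6, 3, 7)
        out = t.reshape(N, self.c_out, 2 * D, 2 * H, 2 * W)
        return np.ascontiguousarray(out) + self.params["b"].reshape(1, -1, 1, 1, 1)

    def backward(self, dout):
        x = self._x
        N, C, D, H, W = x.shape
        dt = dout.reshape(N, self.c_out, D, 2, H, 2, W, 2)
        dt = dt.transpose(0, 2, 4, 6, 1, 3, 5, 7)  # (N, D, H, W, C_out, 2, 2, 2)
        self.grads["W"] += np.tensordot(
            x, dt, axes=([0, 2, 3, 4], [0, 1, 2, 3])
        ).astype(np.float32)
        self.grads["b"] += dout.sum(axis=(0, 2, 3, 4)).astype(np.float32)
        dx = np.tensordot(dt, self.params["W"], axes=([4, 5, 6, 7], [1, 2, 3, 4]))
        self._x = None
        return np.ascontiguousarray(np.moveaxis(dx, -1, 1))


class InstanceNorm3d(Layer):
    """Per-sample per-channel normalization over the spatial axes."""

    def __init__(self, channels, eps=1e-5):
        super().__init__()
        self.eps = eps
        self.params["g"] = np.ones(channels, dtype=np.float32)
        self.params["b"] = np.zeros(channels, dtype=np.float32)
        self.grads["g"] = np.zeros_like(self.params["g"])
        self.grads["b"] = np.zeros_like(self.params["b"])
        self._cache = None

    def forward(self, x):
        axes = (2, 3, 4)
        mu = x.mean(axis=axes, keepdims=True)
        var = x.var(axis=axes, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        self._cache = (xhat, inv)
        return self.params["g"].reshape(1, -1, 1, 1, 1) * xhat + self.params[
            "b"
        ].reshape(1, -1, 1, 1, 1)

    def backward(self, dout):
        xhat, inv = self._cache
        axes = (2, 3, 4)
        self.grads["g"] += (dout * xhat).sum(axis=(0, 2, 3, 4)).astype(np.float32)
        self.grads["b"] += dout.sum(axis=(0, 2, 3, 4)).astype(np.float32)
        dxhat = dout * self.params["g"].reshape(1, -1, 1, 1, 1)
        m = dxhat.mean(axis=axes, keepdims=True)
        mx = (dxhat * xhat).mean(axis=axes, keepdims=True)
        self._cache = None
        return inv * (dxhat - m - xhat * mx)


class ReLU(Layer):
    def __init__(self):
        super().__init__()
        self._mask = None

    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dout):
        out = dout * self._mask
        self._mask = None
        return out
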