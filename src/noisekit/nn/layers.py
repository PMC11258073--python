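"""Layers with explicit forward/backward passes.

Tensor layout is ``(N, C, D, H, W)`` throughout.  Each layer caches what its
backward pass needs on ``forward`` and exposes trainable arrays through
``params()`` as ``(name, value, grad)`` triples; the optimizer updates the
value arrays in place.
"""

from __future__ import annotations

import numpy as np


class Layer:
    def params(self):
        return []

    def forward(self, x, train=False):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy):  # pragma: no cover - interface
        raise NotImplementedError


class Conv3d(Layer):
    """k x k x k convolution, stride 1, 'same' zero padding.

    Implemented by offset accumulation: the output is the sum over the k^3
    kernel offsets of a (C_out, C_in) matmul applied to the correspondingly
    shifted input — the same arithmetic as im2col but with cheap contiguous
    copies, which is what matters for CPU throughput.
    """

    def __init__(self, c_in: int, c_out: int, k: int = 3, rng=None):
        if k % 2 != 1:
            raise ValueError("kernel size must be odd")
        rng = rng or np.random.default_rng(0)
        fan_in = c_in * k ** 3
        # He initialisation for ReLU nets; layout (C_in, k, k, k, C_out)
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                            (c_in, k, k, k, c_out)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self.c_in, self.c_out, self.k = c_in, c_out, k
        self._xp = None
        self._shape = None

    def params(self):
        return [("w", self.w, self.dw), ("b", self.b, self.db)]

    @staticmethod
    def _shift(padded, off, spatial):
        i, j, l = off
        d, h, w = spatial
        view = padded[:, :, i:i + d, j:j + h, l:l + w]
        n, c = view.shape[:2]
        return np.ascontiguousarray(view).reshape(n, c, d * h * w)

    def forward(self, x, train=False):
        n, c, d, h, w = x.shape
        assert c == self.c_in, (c, self.c_in)
        self._shape = x.shape
        if self.k == 1:
            out = np.matmul(self.w[:, 0, 0, 0, :].T[None],
                            x.reshape(n, c, -1))
            self._xp = x if train else None
        else:
            p = self.k // 2
            xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
            self._xp = xp if train else None
            out = np.zeros((n, self.c_out, d * h * w), dtype=np.float32)
            for i in range(self.k):
                for j in range(self.k):
                    for l in range(self.k):
                        xv = self._shift(xp, (i, j, l), (d, h, w))
                        out += np.matmul(self.w[:, i, j, l, :].T[None], xv)
        out += self.b[None, :, None]
        return out.reshape(n, self.c_out, d, h, w)

    def backward(self, dy):
        n, _, d, h, w = self._shape
        s = d * h * w
        dy_flat = np.ascontiguousarray(dy).reshape(n, self.c_out, s)
        self.db[...] = dy_flat.sum(axis=(0, 2))
        if self.k == 1:
            x_flat = self._xp.reshape(n, self.c_in, s)
            self.dw[:, 0, 0, 0, :] = np.matmul(
                x_flat, dy_flat.transpose(0, 2, 1)).sum(axis=0)
            dx = np.matmul(self.w[:, 0, 0, 0, :][None], dy_flat)
            return dx.reshape(self._shape)
        k, p = self.k, self.k // 2
        for i in range(k):
            for j in range(k):
                for l in range(k):
                    xv = self._shift(self._xp, (i, j, l), (d, h, w))
                    self.dw[:, i, j, l, :] = np.matmul(
                        xv, dy_flat.transpose(0, 2, 1)).sum(axis=0)
        # input gradient: 'full' correlation of dy with the flipped kernel,
        # realised with the same offset loop on a padded dy
        dyp = np.pad(dy_flat.reshape(n, self.c_out, d, h, w),
                     ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
        dx = np.zeros((n, self.c_in, s), dtype=np.float32)
        for i in range(k):
            for j in range(k):
                for l in range(k):
                    dyv = self._shift(dyp, (i, j, l), (d, h, w))
                    dx += np.matmul(self.w[:, k - 1 - i, k - 1 - j, k - 1 - l, :][None],
                                    dyv)
        return dx.reshape(self._shape)


class InstanceNorm3d(Layer):
    """Per-sample, per-channel normalisation over the spatial axes."""

    def __init__(self, c: int, eps: float = 1e-5):
        self.gamma = np.ones(c, dtype=np.float32)
        self.beta = np.zeros(c, dtype=np.float32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.eps = eps
        self._cache = None

    def params(self):
        return [("gamma", self.gamma, self.dgamma), ("beta", self.beta, self.dbeta)]

    def forward(self, x, train=False):
        axes = (2, 3, 4)
        mu = x.mean(axis=axes, keepdims=True)
        var = x.var(axis=axes, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        if train:
            self._cache = (xhat, inv)
        g = self.gamma.reshape(1, -1, 1, 1, 1)
        return (xhat * g + self.beta.reshape(1, -1, 1, 1, 1)).astype(np.float32)

    def backward(self, dy):
        xhat, inv = self._cache
        axes = (2, 3, 4)
        m = float(np.prod(dy.shape[2:]))
        self.dgamma[...] = (dy * xhat).sum(axis=(0, 2, 3, 4))
        self.dbeta[...] = dy.sum(axis=(0, 2, 3, 4))
        g = self.gamma.reshape(1, -1, 1, 1, 1)
        dxhat = dy * g
        dx = (dxhat - dxhat.mean(axis=axes, keepdims=True)
              - xhat * (dxhat * xhat).mean(axis=axes, keepdims=True)) * inv
        return dx.astype(np.float32)


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class MaxPool2(Layer):
    """2x2x2 max pooling, stride 2; spatial dims must be even."""

    def forward(self, x, train=False):
        n, c, d, h, w = x.shape
        if d % 2 or h % 2 or w % 2:
            raise ValueError(f"spatial dims must be even for 2x pooling, got {x.shape}")
        xr = x.reshape(n, c, d // 2, 2, h // 2, 2, w // 2, 2)
        out = xr.max(axis=(3, 5, 7))
        if train:
            self._mask = (xr == out[:, :, :, None, :, None, :, None])
            # break ties: keep only the first maximal element per pool window
            flat = self._mask.transpose(0, 1, 2, 4, 6, 3, 5, 7).reshape(
                n, c, d // 2, h // 2, w // 2, 8)
            first = np.cumsum(flat, axis=-1) == 1
            flat &= first
            self._mask = flat.reshape(n, c, d // 2, h // 2, w // 2, 2, 2, 2
                                      ).transpose(0, 1, 2, 5, 3, 6, 4, 7)
            self._in_shape = x.shape
        return out

    def backward(self, dy):
        n, c, d, h, w = self._in_shape
        dyr = dy[:, :, :, None, :, None, :, None]
        dx = (self._mask * dyr).reshape(n, c, d, h, w)
        return dx


class Upsample2(Layer):
    """Nearest-neighbour 2x upsampling; backward sums each 2x2x2 block."""

    def forward(self, x, train=False):
        return x.repeat(2, axis=2).repeat(2, axis=3).repeat(2, axis=4)

    def backward(self, dy):
        n, c, d, h, w = dy.shape
        return dy.reshape(n, c, d // 2, 2, h // 2, 2, w // 2, 2).sum(axis=(3, 5, 7))


class Dropout(Layer):
    """Inverted dropout; identity in eval mode. RNG is supplied per call site."""

    def __init__(self, rate: float, rng=None):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng or np.random.default_rng(0)

    def forward(self, x, train=False):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask
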