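"""Minimal numpy neural-network layers with manual gradients.

Only what the tile classifier needs: strided convolutions and transposed
convolutions (implemented as kernel-offset einsums so the heavy lifting is
BLAS), ReLU/sigmoid, dense layers, pooling, a residual block for the
resnet-style encoder, and Adam.  Tensors are NCHW float32; every layer caches
what its backward pass needs, so instances are not reentrant across batches.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer",
    "Conv2d",
    "ConvTranspose2d",
    "Dense",
    "ReLU",
    "Sigmoid",
    "GlobalAvgPool",
    "MaxPool2x2",
    "Reshape",
    "Flatten",
    "Sequential",
    "ResidualBlock",
    "Adam",
]


class Layer:
    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def parameters(self) -> list[np.ndarray]:
        return []

    def gradients(self) -> list[np.ndarray]:
        return []


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return (rng.normal(0.0, np.sqrt(2.0 / fan_in), shape)).astype(np.float32)


class Conv2d(Layer):
    """kxk convolution with stride and symmetric zero padding."""

    def __init__(self, c_in: int, c_out: int, k: int = 3, stride: int = 1,
                 pad: int = 1, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.k, self.stride, self.pad = k, stride, pad
        self.W = _he_init(rng, (c_out, c_in, k, k), c_in * k * k)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        k, s, p = self.k, self.stride, self.pad
        B, C, H, W = x.shape
        OH = (H + 2 * p - k) // s + 1
        OW = (W + 2 * p - k) // s + 1
        if OH < 1 or OW < 1:
            raise ValueError("input too small for this convolution")
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        sB, sC, sH, sW = xp.strides
        win = np.lib.stride_tricks.as_strided(
            xp, (B, C, k, k, OH, OW), (sB, sC, sH, sW, s * sH, s * sW)
        )
        # im2col: one big BLAS matmul instead of per-offset loops
        cols = np.ascontiguousarray(win).reshape(B, C * k * k, OH * OW)
        self._cols, self._xshape, self._out_hw = cols, x.shape, (OH, OW)
        Wf = self.W.reshape(self.W.shape[0], -1)  # (F, C*k*k)
        out = np.matmul(Wf, cols)  # (B, F, OH*OW)
        out += self.b[None, :, None]
        return out.reshape(B, -1, OH, OW)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        k, s, p = self.k, self.stride, self.pad
        B, C, H, W = self._xshape
        OH, OW = self._out_hw
        F = self.W.shape[0]
        dflat = dout.reshape(B, F, OH * OW)
        self.db[:] = dflat.sum(axis=(0, 2))
        self.dW[:] = np.matmul(
            dflat, self._cols.transpose(0, 2, 1)
        ).sum(axis=0).reshape(self.W.shape)
        Wf = self.W.reshape(F, -1)
        dcols = np.matmul(Wf.T, dflat).reshape(B, C, k, k, OH, OW)
        dxp = np.zeros((B, C, H + 2 * p, W + 2 * p), dtype=np.float32)
        for ki in range(k):
            for kj in range(k):
                dxp[:, :, ki : ki + s * OH : s, kj : kj + s * OW : s] += \
                    dcols[:, :, ki, kj]
        return dxp[:, :, p : p + H, p : p + W]

    def parameters(self):
        return [self.W, self.b]

    def gradients(self):
        return [self.dW, self.db]


class ConvTranspose2d(Layer):
    """Transposed convolution with k=stride (exact non-overlapping upsampling)."""

    def __init__(self, c_in: int, c_out: int, k: int = 2, stride: int = 2,
                 rng: np.random.Generator | None = None):
        if k != stride:
            raise ValueError("this implementation requires k == stride")
        rng = rng or np.random.default_rng(0)
        self.k = k
        self.W = _he_init(rng, (c_in, c_out, k, k), c_in)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        k = self.k
        B, C, H, W = x.shape
        F = self.W.shape[1]
        xf = x.reshape(B, C, H * W)
        self._xf, self._hw = xf, (H, W)
        Wf = self.W.reshape(C, F * k * k)
        y = np.matmul(Wf.T, xf)  # (B, F*k*k, H*W)
        y = y.reshape(B, F, k, k, H, W).transpose(0, 1, 4, 2, 5, 3)
        out = np.ascontiguousarray(y).reshape(B, F, H * k, W * k)
        out += self.b[None, :, None, None]
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        k = self.k
        H, W = self._hw
        B = dout.shape[0]
        F = self.W.shape[1]
        C = self.W.shape[0]
        self.db[:] = dout.sum(axis=(0, 2, 3))
        d = dout.reshape(B, F, H, k, W, k).transpose(0, 1, 3, 5, 2, 4)
        d = np.ascontiguousarray(d).reshape(B, F * k * k, H * W)
        self.dW[:] = np.matmul(self._xf, d.transpose(0, 2, 1)).sum(axis=0) \
            .reshape(C, F, k, k)
        Wf = self.W.reshape(C, F * k * k)
        dx = np.matmul(Wf, d)  # (B, C, H*W)
        return dx.reshape(B, C, H, W)

    def parameters(self):
        return [self.W, self.b]

    def gradients(self):
        return [self.dW, self.db]


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.W = _he_init(rng, (n_in, n_out), n_in)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dW[:] = self._x.T @ dout
        self.db[:] = dout.sum(axis=0)
        return dout @ self.W.T

    def parameters(self):
        return [self.W, self.b]

    def gradients(self):
        return [self.dW, self.db]


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dout):
        return np.where(self._mask, dout, 0.0)


class Sigmoid(Layer):
    def forward(self, x):
        self._y = 1.0 / (1.0 + np.exp(-np.clip(x, -60.0, 60.0)))
        return self._y

    def backward(self, dout):
        return dout * self._y * (1.0 - self._y)


class GlobalAvgPool(Layer):
    def forward(self, x):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout):
        B, C, H, W = self._shape
        return np.broadcast_to(
            dout[:, :, None, None] / (H * W), self._shape
        ).astype(np.float32).copy()


class MaxPool2x2(Layer):
    def forward(self, x):
        B, C, H, W = x.shape
        xr = x.reshape(B, C, H // 2, 2, W // 2, 2)
        self._xr = xr
        out = xr.max(axis=(3, 5))
        self._out = out
        return out

    def backward(self, dout):
        mask = self._xr == self._out[:, :, :, None, :, None]
        # split ties evenly so the gradient check stays exact
        counts = mask.sum(axis=(3, 5), keepdims=True)
        d = mask * (dout[:, :, :, None, :, None] / counts)
        B, C, Hh, _, Wh, _ = self._xr.shape
        return d.reshape(B, C, Hh * 2, Wh * 2).astype(np.float32)


class Reshape(Layer):
    def __init__(self, shape: tuple[int, ...]):
        self.shape = shape

    def forward(self, x):
        self._in = x.shape
        return x.reshape((x.shape[0],) + self.shape)

    def backward(self, dout):
        return dout.reshape(self._in)


class Flatten(Layer):
    def forward(self, x):
        self._in = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._in)


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def parameters(self):
        return [p for l in self.layers for p in l.parameters()]

    def gradients(self):
        return [g for l in self.layers for g in l.gradients()]


class ResidualBlock(Layer):
    """y = relu(f(x) + proj(x)); proj is identity or a 1x1 strided conv."""

    def __init__(self, body: Sequential, projection: Layer | None = None):
        self.body = body
        self.projection = projection
        self.relu = ReLU()

    def forward(self, x):
        fx = self.body.forward(x)
        sx = self.projection.forward(x) if self.projection else x
        return self.relu.forward(fx + sx)

    def backward(self, dout):
        d = self.relu.backward(dout)
        dx = self.body.backward(d)
        if self.projection:
            dx = dx + self.projection.backward(d)
        else:
            dx = dx + d
        return dx

    def parameters(self):
        out = self.body.parameters()
        if self.projection:
            out += self.projection.parameters()
        return out

    def gradients(self):
        out = self.body.gradients()
        if self.projection:
            out += self.projection.gradients()
        return out


class Adam:
    """Adam optimizer over a fixed parameter/gradient list."""

    def __init__(self, params: list[np.ndarray], grads: list[np.ndarray],
                 lr: float = 1e-4, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.params, self.grads = params, grads
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.beta1 ** self.t
        b2t = 1 - self.beta2 ** self.t
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
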