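"""Minimal CNN training engine on numpy.

Implements exactly the layer vocabulary the architecture specs use — 3x3 and
1x1 convolutions, batch normalisation, ReLU, 2x2 max pooling, global average
pooling and fully connected layers — with explicit backpropagation, softmax
cross-entropy, and a decoupled-weight-decay Adam optimiser (AdamW).  All
arithmetic is float32; convolutions use an im2col/GEMM formulation so the
heavy lifting lands in BLAS.

Determinism: every source of randomness (weight init, batch shuffling) is a
``numpy.random.Generator`` seeded by the caller, so identical seeds give
bit-identical runs on the same platform.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv2d", "BatchNorm2d", "ReLU", "MaxPool2d", "GlobalAvgPool", "Linear",
    "Sequential", "AdamW", "softmax_cross_entropy",
]


class Layer:
    """Base class: params/grads are parallel lists of float32 arrays."""

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def decay_mask(self) -> list[bool]:
        """Per-parameter: apply weight decay? (weights yes; biases/BN no)."""
        return [False] * len(self.params())

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """(N,C,H,W) -> (N*Ho*Wo, C*k*k) patch matrix, stride 1."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    n, c, h, w = x.shape
    ho, wo = h - k + 1, w - k + 1
    s0, s1, s2, s3 = x.strides
    cols = np.lib.stride_tricks.as_strided(
        x, (n, ho, wo, c, k, k), (s0, s2, s3, s1, s2, s3))
    return np.ascontiguousarray(cols).reshape(n * ho * wo, c * k * k)


def _col2im(gcols: np.ndarray, shape: tuple, k: int, pad: int) -> np.ndarray:
    """Adjoint of :func:`_im2col`: scatter-add patches back to an image."""
    n, c, h, w = shape
    hp, wp = h + 2 * pad, w + 2 * pad
    ho, wo = hp - k + 1, wp - k + 1
    g = gcols.reshape(n, ho, wo, c, k, k).transpose(0, 3, 4, 5, 1, 2)
    gx = np.zeros((n, c, hp, wp), dtype=gcols.dtype)
    for i in range(k):
        for j in range(k):
            gx[:, :, i:i + ho, j:j + wo] += g[:, :, i, j]
    if pad:
        gx = gx[:, :, pad:-pad, pad:-pad]
    return gx


class Conv2d(Layer):
    """Stride-1 convolution; odd kernels are 'same'-padded (pad = k // 2)."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, bias: bool,
                 rng: np.random.Generator):
        self.in_ch, self.out_ch, self.k = in_ch, out_ch, kernel
        self.pad = kernel // 2
        fan_in = in_ch * kernel * kernel
        scale = np.sqrt(2.0 / fan_in)  # He init for ReLU nets
        self.w = (rng.standard_normal((out_ch, fan_in)) * scale).astype(np.float32)
        self.b = np.zeros(out_ch, dtype=np.float32) if bias else None
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b) if bias else None

    def params(self):
        return [self.w] + ([self.b] if self.b is not None else [])

    def grads(self):
        return [self.gw] + ([self.gb] if self.gb is not None else [])

    def decay_mask(self):
        return [True] + ([False] if self.b is not None else [])

    def forward(self, x, train):
        self._xshape = x.shape
        cols = _im2col(x, self.k, self.pad)
        self._cols = cols if train else None
        y = cols @ self.w.T
        if self.b is not None:
            y += self.b
        n, _, h, w = x.shape
        return y.reshape(n, h, w, self.out_ch).transpose(0, 3, 1, 2)

    def backward(self, gy):
        n, _, h, w = gy.shape
        g2 = np.ascontiguousarray(gy.transpose(0, 2, 3, 1)).reshape(-1, self.out_ch)
        self.gw[...] = g2.T @ self._cols
        if self.gb is not None:
            self.gb[...] = g2.sum(axis=0)
        gcols = g2 @ self.w
        self._cols = None
        return _col2im(gcols, self._xshape, self.k, self.pad)


class BatchNorm2d(Layer):
    """Batch norm over (N, H, W) per channel, with running statistics."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(channels, dtype=np.float32)
        self.beta = np.zeros(channels, dtype=np.float32)
        self.ggamma = np.zeros_like(self.gamma)
        self.gbeta = np.zeros_like(self.beta)
        self.run_mean = np.zeros(channels, dtype=np.float32)
        self.run_var = np.ones(channels, dtype=np.float32)
        self.momentum, self.eps = momentum, eps

    def params(self):
        return [self.gamma, self.beta]

    def grads(self):
        return [self.ggamma, self.gbeta]

    def forward(self, x, train):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.run_mean += self.momentum * (mean - self.run_mean)
            self.run_var += self.momentum * (var - self.run_var)
        else:
            mean, var = self.run_mean, self.run_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[:, None, None]) * inv[:, None, None]
        if train:
            self._xhat, self._inv = xhat, inv
        return self.gamma[:, None, None] * xhat + self.beta[:, None, None]

    def backward(self, gy):
        xhat, inv = self._xhat, self._inv
        m = gy.shape[0] * gy.shape[2] * gy.shape[3]
        self.ggamma[...] = (gy * xhat).sum(axis=(0, 2, 3))
        self.gbeta[...] = gy.sum(axis=(0, 2, 3))
        gxhat = gy * self.gamma[:, None, None]
        gx = (gxhat
              - gxhat.mean(axis=(0, 2, 3), keepdims=True)
              - xhat * (gxhat * xhat).sum(axis=(0, 2, 3), keepdims=True) / m
              ) * inv[:, None, None]
        self._xhat = None
        return gx.astype(np.float32)


class ReLU(Layer):
    def forward(self, x, train):
        y = np.maximum(x, 0)
        if train:
            self._mask = x > 0
        return y

    def backward(self, gy):
        g = gy * self._mask
        self._mask = None
        return g


class MaxPool2d(Layer):
    """2x2, stride 2.  Requires even spatial dims (the specs guarantee it)."""

    def forward(self, x, train):
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"max_pool needs even spatial dims, got {h}x{w}")
        win = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        win = win.reshape(n, c, h // 2, w // 2, 4)
        idx = win.argmax(axis=-1)
        y = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]
        if train:
            self._idx, self._xshape = idx, x.shape
        return y

    def backward(self, gy):
        n, c, h, w = self._xshape
        gwin = np.zeros((n, c, h // 2, w // 2, 4), dtype=gy.dtype)
        np.put_along_axis(gwin, self._idx[..., None], gy[..., None], axis=-1)
        gx = gwin.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        self._idx = None
        return np.ascontiguousarray(gx.reshape(n, c, h, w))


class GlobalAvgPool(Layer):
    """(N,C,H,W) -> (N,C)."""

    def forward(self, x, train):
        self._xshape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, gy):
        n, c, h, w = self._xshape
        return np.broadcast_to(
            gy[:, :, None, None] / (h * w), (n, c, h, w)).astype(gy.dtype).copy()


class Linear(Layer):
    """Fully connected; flattens (N,C,H,W) input automatically."""

    def __init__(self, in_f: int, out_f: int, bias: bool, rng: np.random.Generator):
        scale = np.sqrt(2.0 / in_f)
        self.w = (rng.standard_normal((out_f, in_f)) * scale).astype(np.float32)
        self.b = np.zeros(out_f, dtype=np.float32) if bias else None
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b) if bias else None

    def params(self):
        return [self.w] + ([self.b] if self.b is not None else [])

    def grads(self):
        return [self.gw] + ([self.gb] if self.gb is not None else [])

    def decay_mask(self):
        return [True] + ([False] if self.b is not None else [])

    def forward(self, x, train):
        self._xshape = x.shape
        x2 = x.reshape(x.shape[0], -1)
        self._x = x2 if train else None
        y = x2 @ self.w.T
        if self.b is not None:
            y += self.b
        return y

    def backward(self, gy):
        self.gw[...] = gy.T @ self._x
        if self.gb is not None:
            self.gb[...] = gy.sum(axis=0)
        gx = gy @ self.w
        self._x = None
        return gx.reshape(self._xshape)


class Sequential:
    """A layer stack with forward/backward and a trainable-parameter count."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, gy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            gy = layer.backward(gy)
        return gy

    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params()]

    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads()]

    def decay_mask(self) -> list[bool]:
        return [m for layer in self.layers for m in layer.decay_mask()]

    @property
    def trainable_count(self) -> int:
        return int(sum(p.size for p in self.params()))


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray
                          ) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    p = ez / ez.sum(axis=1, keepdims=True)
    n = logits.shape[0]
    loss = float(-np.log(p[np.arange(n), labels] + 1e-12).mean())
    g = p
    g[np.arange(n), labels] -= 1.0
    return loss, (g / n).astype(np.float32)


class AdamW:
    """Adam with decoupled weight decay applied to weight matrices only."""

    def __init__(self, model: Sequential, lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 1e-2):
        self.model = model
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.wd = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p) for p in model.params()]
        self.v = [np.zeros_like(p) for p in model.params()]

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        mask = self.model.decay_mask()
        for p, g, m, v, decay in zip(self.model.params(), self.model.grads(),
                                     self.m, self.v, mask):
            m += (1.0 - self.b1) * (g - m)
            v += (1.0 - self.b2) * (g * g - v)
            update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            if decay and self.wd:
                p -= self.lr * self.wd * p
            p -= self.lr * update
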