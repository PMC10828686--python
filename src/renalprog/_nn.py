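"""Minimal numpy neural-network layers with explicit backward passes.

This module exists because the runtime image ships no deep-learning
framework; it implements exactly the pieces the package needs: dense and 3D
convolutional layers (grouped only as depthwise), batch normalization,
SiLU/ReLU/sigmoid activations, dropout, squeeze-excitation, global average
pooling, the MBConv block, and an Adam optimizer.  All arrays are float32
and all randomness flows through an explicit ``numpy.random.Generator``,
so results are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import itertools
from typing import Sequence

import numpy as np

__all__ = [
    "Param", "Layer", "Sequential", "Linear", "Conv3d", "BatchNorm",
    "ReLU", "SiLU", "Sigmoid", "Dropout", "GlobalAvgPool3d", "Flatten",
    "SqueezeExcite", "MBConv", "Adam", "softmax", "cross_entropy_logits",
]

_F32 = np.float32


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Param:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=_F32)
        self.grad = np.zeros_like(self.value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def buffers(self) -> list[np.ndarray]:
        """Non-trainable state (e.g. batch-norm running stats) that must be
        part of a checkpoint."""
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Sequential(Layer):
    def __init__(self, layers: Sequence[Layer]):
        self.layers = list(layers)

    def params(self):
        out = []
        for l in self.layers:
            out.extend(l.params())
        return out

    def buffers(self):
        out = []
        for l in self.layers:
            out.extend(l.buffers())
        return out

    def forward(self, x, train=False):
        for l in self.layers:
            x = l.forward(x, train)
        return x

    def backward(self, grad):
        for l in reversed(self.layers):
            grad = l.backward(grad)
        return grad


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        std = np.sqrt(2.0 / in_features)
        self.W = Param(rng.normal(0.0, std, (in_features, out_features)))
        self.b = Param(np.zeros(out_features))
        self._x = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=False):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, grad):
        self.W.grad += self._x.T @ grad
        self.b.grad += grad.sum(axis=0)
        return grad @ self.W.value.T


class Conv3d(Layer):
    """'Same'-padded 3D convolution; ``groups`` must be 1 or ``in_ch`` (depthwise)."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 groups: int = 1, rng: np.random.Generator | None = None):
        if groups not in (1, in_ch) or (groups == in_ch and out_ch != in_ch and groups != 1):
            raise ValueError("groups must be 1 or equal to in_ch (depthwise)")
        self.in_ch, self.out_ch = in_ch, out_ch
        self.k, self.stride, self.groups = kernel, stride, groups
        fan_in = (in_ch // groups) * kernel ** 3
        std = np.sqrt(2.0 / fan_in)
        self.W = Param(rng.normal(0.0, std, (out_ch, in_ch // groups,
                                             kernel, kernel, kernel)))
        self._xp = None

    def params(self):
        return [self.W]

    def _out_shape(self, sp):
        p, k, s = self.k // 2, self.k, self.stride
        return tuple((d + 2 * p - k) // s + 1 for d in sp)

    def forward(self, x, train=False):
        k, s, p = self.k, self.stride, self.k // 2
        n, c = x.shape[:2]
        do, ho, wo = self._out_shape(x.shape[2:])
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
        self._xp = xp if train else None
        self._in_spatial = x.shape[2:]
        w = self.W.value
        out = np.zeros((n, self.out_ch, do, ho, wo), dtype=_F32)
        for i, j, l in itertools.product(range(k), repeat=3):
            sl = xp[:, :, i:i + s * do:s, j:j + s * ho:s, l:l + s * wo:s]
            if self.groups == 1:
                out += np.einsum("ncdhw,oc->nodhw", sl, w[:, :, i, j, l],
                                 optimize=True)
            else:  # depthwise
                out += w[:, 0, i, j, l][None, :, None, None, None] * sl
        return out

    def backward(self, grad):
        k, s, p = self.k, self.stride, self.k // 2
        do, ho, wo = grad.shape[2:]
        xp, w = self._xp, self.W.value
        gxp = np.zeros_like(xp)
        for i, j, l in itertools.product(range(k), repeat=3):
            sl = xp[:, :, i:i + s * do:s, j:j + s * ho:s, l:l + s * wo:s]
            tgt = gxp[:, :, i:i + s * do:s, j:j + s * ho:s, l:l + s * wo:s]
            if self.groups == 1:
                self.W.grad[:, :, i, j, l] += np.einsum(
                    "ncdhw,nodhw->oc", sl, grad, optimize=True)
                tgt += np.einsum("nodhw,oc->ncdhw", grad, w[:, :, i, j, l],
                                 optimize=True)
            else:
                self.W.grad[:, 0, i, j, l] += np.einsum(
                    "ncdhw,ncdhw->c", grad, sl, optimize=True)
                tgt += w[:, 0, i, j, l][None, :, None, None, None] * grad
        d, h, ww = self._in_spatial
        return gxp[:, :, p:p + d, p:p + h, p:p + ww]


class BatchNorm(Layer):
    """Batch normalization over (N,) or (N, spatial) per channel."""

    def __init__(self, channels: int, spatial: bool, momentum: float = 0.1,
                 eps: float = 1e-5):
        self.spatial = spatial
        self.eps, self.momentum = eps, momentum
        shape = (1, channels, 1, 1, 1) if spatial else (1, channels)
        self.gamma = Param(np.ones(shape))
        self.beta = Param(np.zeros(shape))
        self.running_mean = np.zeros(shape, dtype=_F32)
        self.running_var = np.ones(shape, dtype=_F32)
        self._axes = (0, 2, 3, 4) if spatial else (0,)

    def params(self):
        return [self.gamma, self.beta]

    def buffers(self):
        return [self.running_mean, self.running_var]

    def forward(self, x, train=False):
        if train:
            mu = x.mean(axis=self._axes, keepdims=True)
            var = x.var(axis=self._axes, keepdims=True)
            self.running_mean += self.momentum * (mu.astype(_F32)
                                                  - self.running_mean)
            self.running_var += self.momentum * (var.astype(_F32)
                                                 - self.running_var)
        else:
            mu, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps)
        xhat = (x - mu) / std
        self._cache = (xhat, std) if train else None
        return self.gamma.value * xhat + self.beta.value

    def backward(self, grad):
        xhat, std = self._cache
        axes = self._axes
        self.gamma.grad += (grad * xhat).sum(axis=axes, keepdims=True)
        self.beta.grad += grad.sum(axis=axes, keepdims=True)
        g = grad * self.gamma.value
        return (g - g.mean(axis=axes, keepdims=True)
                - xhat * (g * xhat).mean(axis=axes, keepdims=True)) / std


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class SiLU(Layer):
    def forward(self, x, train=False):
        s = _sigmoid(x)
        self._cache = (x, s)
        return x * s

    def backward(self, grad):
        x, s = self._cache
        return grad * (s + x * s * (1.0 - s))


class Sigmoid(Layer):
    def forward(self, x, train=False):
        self._y = _sigmoid(x)
        return self._y

    def backward(self, grad):
        y = self._y
        return grad * y * (1.0 - y)


class Dropout(Layer):
    def __init__(self, p: float, rng: np.random.Generator):
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.p, self.rng = p, rng

    def forward(self, x, train=False):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask.astype(_F32)

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class GlobalAvgPool3d(Layer):
    """Adaptive average pooling to 1x1x1, flattened: (N,C,D,H,W) -> (N,C)."""

    def forward(self, x, train=False):
        self._shape = x.shape
        return x.mean(axis=(2, 3, 4))

    def backward(self, grad):
        n, c, d, h, w = self._shape
        g = grad[:, :, None, None, None] / (d * h * w)
        return np.broadcast_to(g, self._shape).astype(_F32)


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class SqueezeExcite(Layer):
    def __init__(self, channels: int, se_channels: int, rng: np.random.Generator):
        self.W1 = Param(rng.normal(0, np.sqrt(2.0 / channels), (channels, se_channels)))
        self.b1 = Param(np.zeros(se_channels))
        self.W2 = Param(rng.normal(0, np.sqrt(2.0 / se_channels), (se_channels, channels)))
        self.b2 = Param(np.zeros(channels))

    def params(self):
        return [self.W1, self.b1, self.W2, self.b2]

    def forward(self, x, train=False):
        z = x.mean(axis=(2, 3, 4))
        a1 = z @ self.W1.value + self.b1.value
        s1 = _sigmoid(a1)
        h = a1 * s1
        s = _sigmoid(h @ self.W2.value + self.b2.value)
        self._cache = (x, z, a1, s1, h, s)
        return x * s[:, :, None, None, None]

    def backward(self, grad):
        x, z, a1, s1, h, s = self._cache
        v = np.prod(x.shape[2:])
        gs = (grad * x).sum(axis=(2, 3, 4))
        gx = grad * s[:, :, None, None, None]
        ga2 = gs * s * (1.0 - s)
        self.W2.grad += h.T @ ga2
        self.b2.grad += ga2.sum(axis=0)
        gh = ga2 @ self.W2.value.T
        ga1 = gh * (s1 + a1 * s1 * (1.0 - s1))
        self.W1.grad += z.T @ ga1
        self.b1.grad += ga1.sum(axis=0)
        gz = ga1 @ self.W1.value.T
        gx += gz[:, :, None, None, None] / v
        return gx


class MBConv(Layer):
    """Mobile inverted bottleneck: expand -> depthwise -> SE -> project.

    Residual connection when stride is 1 and channel counts match.
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int,
                 expand: int, rng: np.random.Generator, se_ratio: float = 0.25):
        mid = in_ch * expand
        body: list[Layer] = []
        if expand != 1:
            body += [Conv3d(in_ch, mid, 1, rng=rng),
                     BatchNorm(mid, spatial=True), SiLU()]
        body += [Conv3d(mid, mid, kernel, stride=stride, groups=mid, rng=rng),
                 BatchNorm(mid, spatial=True), SiLU(),
                 SqueezeExcite(mid, max(1, int(in_ch * se_ratio)), rng),
                 Conv3d(mid, out_ch, 1, rng=rng),
                 BatchNorm(out_ch, spatial=True)]
        self.body = Sequential(body)
        self.skip = stride == 1 and in_ch == out_ch

    def params(self):
        return self.body.params()

    def buffers(self):
        return self.body.buffers()

    def forward(self, x, train=False):
        y = self.body.forward(x, train)
        return x + y if self.skip else y

    def backward(self, grad):
        g = self.body.backward(grad)
        return grad + g if self.skip else g


class Adam:
    def __init__(self, params: Sequence[Param], lr: float,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        if self.lr == 0.0:
            return
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m += (1.0 - self.b1) * (p.grad - m)
            v += (1.0 - self.b2) * (p.grad ** 2 - v)
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy_logits(logits: np.ndarray, onehot: np.ndarray):
    """Mean cross-entropy over the batch; returns (loss, grad_wrt_logits)."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = -(onehot * np.log(np.clip(p, 1e-12, None))).sum() / n
    return float(loss), ((p - onehot) / n).astype(_F32)


def state_arrays(root: Layer) -> list[np.ndarray]:
    """All checkpointable arrays of a layer tree: parameters plus buffers."""
    return [p.value for p in root.params()] + list(root.buffers())


def snapshot(arrays: Sequence[np.ndarray]) -> list[np.ndarray]:
    return [a.copy() for a in arrays]


def restore(arrays: Sequence[np.ndarray], values: Sequence[np.ndarray]) -> None:
    for a, v in zip(arrays, values):
        a[...] = v
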