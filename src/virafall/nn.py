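"""Minimal tensor layers for spatio-temporal graph convolution.

Activations are ``(N, C, T, V)`` arrays — batch, channels, frames, joints.
Each layer implements an explicit ``forward``/``backward`` pair; gradients
are verified against finite differences in the test suite.  Everything is
plain numpy in single precision, deterministic given the initialisation
seed.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "GraphConv",
    "TemporalConv",
    "BatchNorm",
    "ReLU",
    "Dropout",
    "GlobalAvgPool",
    "Linear",
    "softmax",
    "cross_entropy_with_grad",
    "SGD",
    "Adam",
]

_DTYPE = np.float32


def _mix(w: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Channel mix (o,c) x (n,c,t,v) -> (n,o,t,v) through BLAS."""
    return np.moveaxis(np.tensordot(w, x, axes=([1], [1])), 0, 1)


def _mix_t(w: np.ndarray, g: np.ndarray) -> np.ndarray:
    """Transposed mix (o,c) x (n,o,t,v) -> (n,c,t,v)."""
    return np.moveaxis(np.tensordot(w, g, axes=([0], [1])), 0, 1)


def _outer(g: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Weight gradient (n,o,t,v) x (n,c,t,v) -> (o,c)."""
    return np.tensordot(g, x, axes=([0, 2, 3], [0, 2, 3]))


class Param:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("name", "value", "grad")

    def __init__(self, name: str, value: np.ndarray):
        self.name = name
        self.value = np.asarray(value, dtype=_DTYPE)
        self.grad = np.zeros_like(self.value)

    @property
    def size(self) -> int:
        return self.value.size


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class GraphConv(Layer):
    """Spatial graph convolution over a partitioned adjacency stack.

    ``y = sum_k (W_k x) A_k + b`` with one 1x1 channel mix ``W_k`` per
    partition operator ``A_k`` of shape (V, V).
    """

    def __init__(self, c_in: int, c_out: int, a_stack: np.ndarray, rng):
        self.a = np.asarray(a_stack, dtype=_DTYPE)
        k = self.a.shape[0]
        sd = np.sqrt(2.0 / (c_in * k))
        self.w = Param("gc_w", rng.normal(0.0, sd, size=(k, c_out, c_in)))
        self.b = Param("gc_b", np.zeros(c_out))
        self._x = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x, training):
        self._x = x
        y = np.zeros(
            (x.shape[0], self.w.value.shape[1], x.shape[2], x.shape[3]), dtype=_DTYPE
        )
        for k in range(self.a.shape[0]):
            t1 = _mix(self.w.value[k], x)
            y += t1 @ self.a[k]
        return y + self.b.value[None, :, None, None]

    def backward(self, g):
        x = self._x
        dx = np.zeros_like(x)
        for k in range(self.a.shape[0]):
            dt1 = g @ self.a[k].T
            self.w.grad[k] += _outer(dt1, x)
            dx += _mix_t(self.w.value[k], dt1)
        self.b.grad += g.sum(axis=(0, 2, 3))
        return dx


class TemporalConv(Layer):
    """1D convolution along the frame axis with full channel mixing."""

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int, rng):
        if kernel % 2 == 0:
            raise ValueError("temporal kernel must be odd")
        sd = np.sqrt(2.0 / (c_in * kernel))
        self.w = Param("tc_w", rng.normal(0.0, sd, size=(c_out, c_in, kernel)))
        self.b = Param("tc_b", np.zeros(c_out))
        self.kernel = kernel
        self.stride = stride
        self.pad = (kernel - 1) // 2
        self._xp = None

    def params(self):
        return [self.w, self.b]

    def _t_out(self, t: int) -> int:
        return (t + 2 * self.pad - self.kernel) // self.stride + 1

    def forward(self, x, training):
        n, c, t, v = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad), (0, 0)))
        self._xp = xp
        t_out = self._t_out(t)
        y = np.zeros((n, self.w.value.shape[0], t_out, v), dtype=_DTYPE)
        for k in range(self.kernel):
            seg = xp[:, :, k : k + self.stride * t_out : self.stride]
            y += _mix(self.w.value[:, :, k], seg)
        return y + self.b.value[None, :, None, None]

    def backward(self, g):
        xp = self._xp
        t_out = g.shape[2]
        dxp = np.zeros_like(xp)
        for k in range(self.kernel):
            sl = slice(k, k + self.stride * t_out, self.stride)
            self.w.grad[:, :, k] += _outer(g, xp[:, :, sl])
            dxp[:, :, sl] += _mix_t(self.w.value[:, :, k], g)
        self.b.grad += g.sum(axis=(0, 2, 3))
        t = xp.shape[2] - 2 * self.pad
        return dxp[:, :, self.pad : self.pad + t]


class BatchNorm(Layer):
    """Per-channel batch normalisation over (N, T, V) with running stats."""

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param("bn_gamma", np.ones(c))
        self.beta = Param("bn_beta", np.zeros(c))
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(c, dtype=_DTYPE)
        self.running_var = np.ones(c, dtype=_DTYPE)
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, training):
        axes = (0, 2, 3)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mean
            ).astype(_DTYPE)
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var
            ).astype(_DTYPE)
        else:
            mean, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) / std[None, :, None, None]
        self._cache = (xhat, std) if training else None
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[
            None, :, None, None
        ]

    def backward(self, g):
        xhat, std = self._cache
        axes = (0, 2, 3)
        m = g.shape[0] * g.shape[2] * g.shape[3]
        self.gamma.grad += (g * xhat).sum(axis=axes)
        self.beta.grad += g.sum(axis=axes)
        dxhat = g * self.gamma.value[None, :, None, None]
        s1 = dxhat.sum(axis=axes)
        s2 = (dxhat * xhat).sum(axis=axes)
        dx = (
            dxhat
            - s1[None, :, None, None] / m
            - xhat * s2[None, :, None, None] / m
        ) / std[None, :, None, None]
        return dx.astype(_DTYPE)


class ReLU(Layer):
    def forward(self, x, training):
        self._mask = x > 0
        return x * self._mask

    def backward(self, g):
        return g * self._mask


class Dropout(Layer):
    """Inverted dropout; identity when p == 0 or in eval mode."""

    def __init__(self, p: float, rng):
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout p must lie in [0, 1)")
        self.p = p
        self.rng = rng
        self._mask = None

    def forward(self, x, training):
        if not training or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return (x * self._mask).astype(_DTYPE)

    def backward(self, g):
        if self._mask is None:
            return g
        return (g * self._mask).astype(_DTYPE)


class GlobalAvgPool(Layer):
    """Mean over frames and joints: (N, C, T, V) -> (N, C)."""

    def forward(self, x, training):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, g):
        n, c, t, v = self._shape
        return np.broadcast_to(g[:, :, None, None], self._shape) / (t * v)


class Linear(Layer):
    def __init__(self, c_in: int, c_out: int, rng):
        sd = np.sqrt(2.0 / c_in)
        self.w = Param("fc_w", rng.normal(0.0, sd, size=(c_out, c_in)))
        self.b = Param("fc_b", np.zeros(c_out))
        self._x = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x, training):
        self._x = x
        return x @ self.w.value.T + self.b.value

    def backward(self, g):
        self.w.grad += g.T @ self._x
        self.b.grad += g.sum(axis=0)
        return g @ self.w.value


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy_with_grad(
    logits: np.ndarray, y: np.ndarray, class_weights: np.ndarray | None = None
) -> tuple[float, np.ndarray]:
    """Weighted softmax cross-entropy; returns (loss, dlogits)."""
    n = logits.shape[0]
    p = softmax(logits.astype(np.float64))
    w = np.ones(n) if class_weights is None else class_weights[y]
    logp = np.log(np.maximum(p[np.arange(n), y], 1e-30))
    wsum = w.sum()
    loss = float(-(w * logp).sum() / wsum)
    grad = p.copy()
    grad[np.arange(n), y] -= 1.0
    grad *= (w / wsum)[:, None]
    return loss, grad.astype(_DTYPE)


class SGD:
    """SGD with momentum and optional step decay of the learning rate."""

    def __init__(self, params: list[Param], lr: float, momentum: float = 0.9,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._vel = [np.zeros_like(p.value) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        for p, v in zip(self.params, self._vel):
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.value
            v *= self.momentum
            v += g
            p.value -= (self.lr * v).astype(_DTYPE)


class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self._m = [np.zeros_like(p.value) for p in params]
        self._v = [np.zeros_like(p.value) for p in params]
        self._t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self._t += 1
        b1t = 1 - self.b1**self._t
        b2t = 1 - self.b2**self._t
        for p, m, v in zip(self.params, self._m, self._v):
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad**2
            p.value -= (
                self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
            ).astype(_DTYPE)
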