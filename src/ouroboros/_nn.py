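"""Minimal reverse-mode autodiff engine on numpy float32 arrays.

Implements exactly the operations the conditional GAN needs: broadcasting
arithmetic, (batched) matmul, 3x3 same-padding convolution in NHWC layout,
nearest-neighbour 2x up-sampling, 2x average pooling, per-sample channel
normalisation, softmax attention and the usual pointwise nonlinearities.
Convolution is evaluated as nine shifted GEMMs, which keeps both the forward
and backward passes inside BLAS without an im2col memory blow-up.

Gradients accumulate into ``Tensor.grad`` during ``backward`` over a
topologically sorted tape. All computation is CPU/float32 and deterministic
for a fixed ``numpy.random.Generator``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor", "Parameter", "add", "sub", "mul", "matmul", "bmm", "concat",
    "relu", "leaky_relu", "tanh", "reshape", "mean", "conv3x3", "upsample2x",
    "avgpool2x", "channel_norm", "softmax_lastdim", "swap_last2", "scale",
    "softplus",
    "global_avg_pool", "Adam",
]

_F32 = np.float32

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def _as_f32(x) -> np.ndarray:
    a = np.asarray(x, dtype=_F32)
    return a


class Tensor:
    """A node in the computation graph holding a value and its gradient."""

    __slots__ = ("data", "grad", "parents", "bwd", "requires_grad")

    def __init__(self, data, parents=(), bwd=None, requires_grad=False):
        self.data = _as_f32(data)
        self.grad = None
        if not _GRAD_ENABLED:
            parents, bwd, requires_grad = (), None, False
        self.parents = parents
        self.bwd = bwd
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)

    @property
    def shape(self):
        return self.data.shape

    def backward(self):
        order: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs get deep at high step counts
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node.parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(order):
            if node.bwd is not None and node.grad is not None:
                node.bwd(node.grad)

    def _accum(self, g):
        if self.grad is None:
            self.grad = g.astype(_F32, copy=True) if g.base is not None or g.dtype != _F32 else g
        else:
            self.grad = self.grad + g

    def item(self) -> float:
        return float(self.data)


class Parameter(Tensor):
    """A leaf tensor updated by the optimizer."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)
        self.requires_grad = True  # immune to no_grad at construction time


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce gradient ``g`` back to ``shape`` after numpy broadcasting."""
    if g.shape == shape:
        return g
    nd = g.ndim - len(shape)
    if nd > 0:
        g = g.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


def add(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data + b.data, (a, b))

    def bwd(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g, b.data.shape))

    out.bwd = bwd
    return out


def sub(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data - b.data, (a, b))

    def bwd(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(-g, b.data.shape))

    out.bwd = bwd
    return out


def mul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data * b.data, (a, b))

    def bwd(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g * a.data, b.data.shape))

    out.bwd = bwd
    return out


def scale(a: Tensor, s: float) -> Tensor:
    out = Tensor(a.data * _F32(s), (a,))

    def bwd(g):
        if a.requires_grad:
            a._accum(g * _F32(s))

    out.bwd = bwd
    return out


def matmul(a: Tensor, b: Tensor) -> Tensor:
    """2-D matrix product: (n, k) @ (k, m)."""
    out = Tensor(a.data @ b.data, (a, b))

    def bwd(g):
        if a.requires_grad:
            a._accum(g @ b.data.T)
        if b.requires_grad:
            b._accum(a.data.T @ g)

    out.bwd = bwd
    return out


def bmm(a: Tensor, b: Tensor) -> Tensor:
    """Batched matmul on stacked matrices: (..., n, k) @ (..., k, m)."""
    out = Tensor(a.data @ b.data, (a, b))

    def bwd(g):
        if a.requires_grad:
            a._accum(g @ np.swapaxes(b.data, -1, -2))
        if b.requires_grad:
            b._accum(np.swapaxes(a.data, -1, -2) @ g)

    out.bwd = bwd
    return out


def swap_last2(a: Tensor) -> Tensor:
    out = Tensor(np.swapaxes(a.data, -1, -2), (a,))

    def bwd(g):
        if a.requires_grad:
            a._accum(np.swapaxes(g, -1, -2))

    out.bwd = bwd
    return out


def concat(a: Tensor, b: Tensor) -> Tensor:
    """Concatenate along the last axis."""
    na = a.data.shape[-1]
    out = Tensor(np.concatenate([a.data, b.data], axis=-1), (a, b))

    def bwd(g):
        if a.requires_grad:
            a._accum(g[..., :na])
        if b.requires_grad:
            b._accum(g[..., na:])

    out.bwd = bwd
    return out


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0
    out = Tensor(a.data * mask, (a,))

    def bwd(g):
        if a.requires_grad:
            a._accum(g * mask)

    out.bwd = bwd
    return out


def leaky_relu(a: Tensor, slope: float = 0.2) -> Tensor:
    factor = np.where(a.data > 0, _F32(1.0), _F32(slope))
    out = Tensor(a.data * factor, (a,))

    def bwd(g):
        if a.requires_grad:
            a._accum(g * factor)

    out.bwd = bwd
    return out


def tanh(a: Tensor) -> Tensor:
    y = np.tanh(a.data)
    out = Tensor(y, (a,))

    def bwd(g):
        if a.requires_grad:
            a._accum(g * (1.0 - y * y))

    out.bwd = bwd
    return out


def softplus(a: Tensor) -> Tensor:
    """log(1 + exp(x)) in the overflow-safe log-sum-exp form."""
    x = a.data
    y = np.maximum(x, 0) + np.log1p(np.exp(-np.abs(x)))
    out = Tensor(y, (a,))
    sig = 1.0 / (1.0 + np.exp(-x.astype(np.float64)))

    def bwd(g):
        if a.requires_grad:
            a._accum((g * sig).astype(_F32))

    out.bwd = bwd
    return out


def reshape(a: Tensor, shape) -> Tensor:
    orig = a.data.shape
    out = Tensor(a.data.reshape(shape), (a,))

    def bwd(g):
        if a.requires_grad:
            a._accum(g.reshape(orig))

    out.bwd = bwd
    return out


def mean(a: Tensor, axis=None) -> Tensor:
    out = Tensor(a.data.mean(axis=axis), (a,))
    n = a.data.size if axis is None else np.prod([a.data.shape[i] for i in np.atleast_1d(axis)])

    def bwd(g):
        if a.requires_grad:
            if axis is None:
                ge = np.broadcast_to(g / n, a.data.shape)
            else:
                ge = np.broadcast_to(np.expand_dims(g, axis=axis) / n, a.data.shape)
            a._accum(np.ascontiguousarray(ge, dtype=_F32))

    out.bwd = bwd
    return out


def conv3x3(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """3x3, stride-1, zero-padded convolution in NHWC layout.

    ``w`` has shape (3, 3, c_in, c_out). Computed as nine shifted GEMMs so
    every heavy operation is a dense matmul; the padded input is cached on
    the tape for the backward pass.
    """
    n, h, ww, cin = x.data.shape
    cout = w.data.shape[-1]
    xp = np.zeros((n, h + 2, ww + 2, cin), dtype=_F32)
    xp[:, 1:-1, 1:-1, :] = x.data
    y = np.zeros((n, h, ww, cout), dtype=_F32)
    for di in range(3):
        for dj in range(3):
            y += xp[:, di:di + h, dj:dj + ww, :] @ w.data[di, dj]
    if b is not None:
        y += b.data
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(y, parents)

    def bwd(g):
        g2 = g.reshape(-1, cout)
        if w.requires_grad:
            dw = np.empty_like(w.data)
            for di in range(3):
                for dj in range(3):
                    xs = xp[:, di:di + h, dj:dj + ww, :].reshape(-1, cin)
                    dw[di, dj] = xs.T @ g2
            w._accum(dw)
        if b is not None and b.requires_grad:
            b._accum(g2.sum(axis=0))
        if x.requires_grad:
            dxp = np.zeros_like(xp)
            for di in range(3):
                for dj in range(3):
                    dxp[:, di:di + h, dj:dj + ww, :] += g @ w.data[di, dj].T
            x._accum(dxp[:, 1:-1, 1:-1, :])

    out.bwd = bwd
    return out


def upsample2x(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x spatial up-sampling (NHWC)."""
    y = x.data.repeat(2, axis=1).repeat(2, axis=2)
    out = Tensor(y, (x,))
    n, h, w, c = x.data.shape

    def bwd(g):
        if x.requires_grad:
            gr = g.reshape(n, h, 2, w, 2, c).sum(axis=(2, 4))
            x._accum(gr)

    out.bwd = bwd
    return out


def avgpool2x(x: Tensor) -> Tensor:
    n, h, w, c = x.data.shape
    y = x.data.reshape(n, h // 2, 2, w // 2, 2, c).mean(axis=(2, 4))
    out = Tensor(y, (x,))

    def bwd(g):
        if x.requires_grad:
            ge = g[:, :, None, :, None, :] * _F32(0.25)
            x._accum(np.broadcast_to(ge, (n, h // 2, 2, w // 2, 2, c)).reshape(n, h, w, c).astype(_F32))

    out.bwd = bwd
    return out


def global_avg_pool(x: Tensor) -> Tensor:
    """NHWC -> (N, C) spatial mean."""
    return mean(x, axis=(1, 2))


def channel_norm(x: Tensor, eps: float = 1e-5) -> Tensor:
    """Per-sample, per-channel normalisation over spatial axes (instance norm).

    Deterministic at train and eval time (no running statistics), which keeps
    small-batch training stable and generation reproducible.
    """
    mu = x.data.mean(axis=(1, 2), keepdims=True)
    xc = x.data - mu
    var = (xc * xc).mean(axis=(1, 2), keepdims=True)
    inv = 1.0 / np.sqrt(var + _F32(eps))
    xhat = xc * inv
    out = Tensor(xhat, (x,))
    m = x.data.shape[1] * x.data.shape[2]

    def bwd(g):
        if x.requires_grad:
            gsum = g.sum(axis=(1, 2), keepdims=True)
            gx = g * xhat
            gxs = gx.sum(axis=(1, 2), keepdims=True)
            dx = inv * (g - gsum / m - xhat * gxs / m)
            x._accum(dx.astype(_F32))

    out.bwd = bwd
    return out


def softmax_lastdim(a: Tensor) -> Tensor:
    z = a.data - a.data.max(axis=-1, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=-1, keepdims=True)
    out = Tensor(s, (a,))

    def bwd(g):
        if a.requires_grad:
            dot = (g * s).sum(axis=-1, keepdims=True)
            a._accum(s * (g - dot))

    out.bwd = bwd
    return out


class Adam:
    """Adam optimizer over a flat list of Parameters."""

    def __init__(self, params: list[Parameter], lr: float = 1e-4,
                 beta1: float = 0.5, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad.astype(np.float64)
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            p.data = (p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(_F32)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
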