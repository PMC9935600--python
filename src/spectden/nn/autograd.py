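"""Minimal reverse-mode automatic differentiation over numpy arrays.

This is the compute engine behind the denoising networks: a define-by-run
graph of :class:`Tensor` nodes, each remembering its parents and a closure
that propagates the output gradient.  3D convolutions are evaluated as 27
(kernel-offset) shifted matmuls, which runs at essentially BLAS speed in
float32 and needs no im2col buffer.

Only the operations the U-Net / GAN architectures require are implemented.
Gradients are checked against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

from . import _convops

__all__ = [
    "Tensor", "add", "sub", "mul", "scale", "sum_", "mean_", "abs_",
    "relu", "leaky_relu", "concat", "conv3d", "conv1x1", "maxpool2",
    "upsample2", "batchnorm", "dropout", "softmax_spatial", "softmax_channel",
    "broadcast_spatial", "narrow_views", "bce_with_logits_mean", "l1_mean",
]

class Tensor:
    """A numpy array plus the bookkeeping needed for backpropagation."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def item(self) -> float:
        return float(self.data)

    def backward(self) -> None:
        """Accumulate gradients of this (scalar) tensor w.r.t. all leaves."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = None
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def _accum(self, g):
        if self.grad is None:
            self.grad = g.copy() if isinstance(g, np.ndarray) else np.asarray(g)
        else:
            self.grad += g


def _needs(*ts):
    return any(t.requires_grad or t._backward is not None for t in ts)


def _unbroadcast(grad, shape):
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


def _make(data, parents, backward):
    if any(_needs(p) for p in parents) or any(p.requires_grad for p in parents):
        return Tensor(data, parents=parents, backward=backward)
    return Tensor(data)


# --------------------------------------------------------------------------
# elementwise / reduction ops

def add(a: Tensor, b: Tensor) -> Tensor:
    out = a.data + b.data

    def bw(g):
        a._accum(_unbroadcast(g, a.data.shape))
        b._accum(_unbroadcast(g, b.data.shape))

    return _make(out, (a, b), bw)


def sub(a: Tensor, b: Tensor) -> Tensor:
    out = a.data - b.data

    def bw(g):
        a._accum(_unbroadcast(g, a.data.shape))
        b._accum(_unbroadcast(-g, b.data.shape))

    return _make(out, (a, b), bw)


def mul(a: Tensor, b: Tensor) -> Tensor:
    out = a.data * b.data

    def bw(g):
        a._accum(_unbroadcast(g * b.data, a.data.shape))
        b._accum(_unbroadcast(g * a.data, b.data.shape))

    return _make(out, (a, b), bw)


def scale(a: Tensor, s: float) -> Tensor:
    out = a.data * s

    def bw(g):
        a._accum(g * s)

    return _make(out, (a,), bw)


def sum_(a: Tensor, axis=None, keepdims=False) -> Tensor:
    out = a.data.sum(axis=axis, keepdims=keepdims)

    def bw(g):
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        a._accum(np.broadcast_to(g, a.data.shape))

    return _make(out, (a,), bw)


def mean_(a: Tensor) -> Tensor:
    n = a.data.size
    out = a.data.mean()

    def bw(g):
        a._accum(np.broadcast_to(g / n, a.data.shape))

    return _make(np.asarray(out), (a,), bw)


def abs_(a: Tensor) -> Tensor:
    out = np.abs(a.data)
    sign = np.sign(a.data)

    def bw(g):
        a._accum(g * sign)

    return _make(out, (a,), bw)


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0
    out = a.data * mask

    def bw(g):
        a._accum(g * mask)

    return _make(out, (a,), bw)


def leaky_relu(a: Tensor, alpha: float = 0.2) -> Tensor:
    mask = a.data > 0
    out = np.where(mask, a.data, alpha * a.data)

    def bw(g):
        a._accum(g * np.where(mask, 1.0, alpha).astype(a.data.dtype))

    return _make(out, (a,), bw)


def concat(tensors, axis: int = -1) -> Tensor:
    out = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accum(piece)

    return _make(out, tuple(tensors), bw)


# --------------------------------------------------------------------------
# convolutions (channels-last: x is (B, D, H, W, C))

def conv3d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1) -> Tensor:
    """3x3x3 convolution with 'same'-style padding of 1.

    ``w`` has shape (27, C_in, C_out), one (C_in, C_out) matrix per kernel
    offset.  The 27 shifted input slabs are gathered once into a column
    buffer so forward, weight-gradient and input-gradient passes are each a
    single BLAS gemm; the buffer is reused by the backward closure.
    """
    B, D, H, W_, C = x.data.shape
    k, p, s = 3, 1, stride
    Do, Ho, Wo = ((D + 2 * p - k) // s + 1, (H + 2 * p - k) // s + 1,
                  (W_ + 2 * p - k) // s + 1)
    F = w.data.shape[2]
    xp = np.pad(x.data, ((0, 0), (p, p), (p, p), (p, p), (0, 0)))
    n_pos = B * Do * Ho * Wo
    cols = _convops.gather27(xp, (B, Do, Ho, Wo, 27, C), s)
    cols2 = cols.reshape(n_pos, 27 * C)
    wmat = w.data.reshape(27 * C, F)
    out = (cols2 @ wmat).reshape(B, Do, Ho, Wo, F)
    if b is not None:
        out += b.data

    def bw(g):
        g2 = g.reshape(n_pos, F)
        if w.requires_grad:
            w._accum((cols2.T @ g2).reshape(w.data.shape))
        if b is not None and b.requires_grad:
            b._accum(g2.sum(axis=0))
        if _needs(x) or x.requires_grad:
            dcols = (g2 @ wmat.T).reshape(B, Do, Ho, Wo, 27, C)
            dxp = np.zeros_like(xp)
            _convops.scatter27(dxp, dcols, s)
            x._accum(dxp[:, p:p + D, p:p + H, p:p + W_, :])

    parents = (x, w) if b is None else (x, w, b)
    return _make(out, parents, bw)


def conv1x1(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Pointwise (1x1x1) convolution: a matmul over the channel axis."""
    out = x.data @ w.data
    if b is not None:
        out += b.data

    def bw(g):
        if w.requires_grad:
            w._accum(np.tensordot(x.data, g, axes=(list(range(x.data.ndim - 1)),) * 2))
        if b is not None and b.requires_grad:
            b._accum(g.reshape(-1, g.shape[-1]).sum(axis=0))
        if _needs(x) or x.requires_grad:
            x._accum(g @ w.data.T)

    parents = (x, w) if b is None else (x, w, b)
    return _make(out, parents, bw)


# --------------------------------------------------------------------------
# pooling / resampling

def maxpool2(x: Tensor) -> Tensor:
    """2x2x2 max pooling; spatial dims must be even."""
    B, D, H, W_, C = x.data.shape
    if D % 2 or H % 2 or W_ % 2:
        raise ValueError(f"maxpool2 needs even spatial dims, got {(D, H, W_)}")
    blocks = (x.data.reshape(B, D // 2, 2, H // 2, 2, W_ // 2, 2, C)
              .transpose(0, 1, 3, 5, 7, 2, 4, 6)
              .reshape(B, D // 2, H // 2, W_ // 2, C, 8))
    idx = blocks.argmax(axis=-1)
    out = np.take_along_axis(blocks, idx[..., None], axis=-1)[..., 0]

    def bw(g):
        db = np.zeros(blocks.shape, dtype=g.dtype)
        np.put_along_axis(db, idx[..., None], g[..., None], axis=-1)
        dx = (db.reshape(B, D // 2, H // 2, W_ // 2, C, 2, 2, 2)
              .transpose(0, 1, 5, 2, 6, 3, 7, 4)
              .reshape(B, D, H, W_, C))
        x._accum(dx)

    return _make(out, (x,), bw)


def upsample2(x: Tensor) -> Tensor:
    """Nearest-neighbour x2 upsampling along the three spatial axes."""
    out = x.data.repeat(2, axis=1).repeat(2, axis=2).repeat(2, axis=3)

    def bw(g):
        B, D, H, W_, C = x.data.shape
        dx = (g.reshape(B, D, 2, H, 2, W_, 2, C)
              .sum(axis=(2, 4, 6)))
        x._accum(dx)

    return _make(out, (x,), bw)


# --------------------------------------------------------------------------
# normalization / regularization

def batchnorm(x: Tensor, gamma: Tensor, beta: Tensor, mean, var, training: bool,
              eps: float = 1e-5) -> Tensor:
    """Batch normalization over all axes except the channel (last) axis.

    In training mode ``mean``/``var`` are the batch statistics of ``x`` (the
    caller computes them so it can also maintain running averages) and the
    backward pass accounts for their dependence on ``x``; in eval mode they
    are constants.
    """
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean) * inv
    out = gamma.data * xhat + beta.data

    def bw(g):
        axes = tuple(range(x.data.ndim - 1))
        if gamma.requires_grad:
            gamma._accum((g * xhat).sum(axis=axes))
        if beta.requires_grad:
            beta._accum(g.sum(axis=axes))
        if _needs(x) or x.requires_grad:
            dxhat = g * gamma.data
            if training:
                n = x.data.size // x.data.shape[-1]
                dx = (inv / n) * (n * dxhat
                                  - dxhat.sum(axis=axes)
                                  - xhat * (dxhat * xhat).sum(axis=axes))
            else:
                dx = dxhat * inv
            x._accum(dx.astype(x.data.dtype))

    return _make(out.astype(x.data.dtype), (x, gamma, beta), bw)


def dropout(x: Tensor, rate: float, rng: np.random.Generator, training: bool) -> Tensor:
    if not training or rate <= 0.0:
        return x
    keep = 1.0 - rate
    mask = (rng.random(x.data.shape, dtype=np.float32) < keep).astype(x.data.dtype)
    mask /= keep
    out = x.data * mask

    def bw(g):
        x._accum(g * mask)

    return _make(out, (x,), bw)


# --------------------------------------------------------------------------
# attention / losses

def _softmax(x: Tensor, ax) -> Tensor:
    m = x.data.max(axis=ax, keepdims=True)
    e = np.exp(x.data - m)
    r = e / e.sum(axis=ax, keepdims=True)

    def bw(g):
        dot = (g * r).sum(axis=ax, keepdims=True)
        x._accum(r * (g - dot))

    return _make(r, (x,), bw)


def softmax_spatial(x: Tensor) -> Tensor:
    """Softmax over the spatial axes (1, 2, 3), independently per batch/channel."""
    return _softmax(x, (1, 2, 3))


def softmax_channel(x: Tensor) -> Tensor:
    """Softmax over the channel (last) axis, independently per position."""
    return _softmax(x, -1)


def broadcast_spatial(x: Tensor, shape) -> Tensor:
    """Broadcast a (B, 1, 1, 1, C) tensor over the spatial axes."""
    out = np.broadcast_to(x.data, shape).copy()

    def bw(g):
        x._accum(_unbroadcast(g, x.data.shape))

    return _make(out, (x,), bw)


def narrow_views(x: Tensor, n: int) -> Tensor:
    """Keep the first ``n`` entries along axis 1 (the view axis)."""
    out = x.data[:, :n]

    def bw(g):
        gg = np.zeros_like(x.data)
        gg[:, :n] = g
        x._accum(gg)

    return _make(out, (x,), bw)


def bce_with_logits_mean(z: Tensor, target) -> Tensor:
    """Numerically stable mean binary cross-entropy on logits.

    ``target`` is a constant label (scalar) or an array broadcastable to the
    logit shape (e.g. per-batch-element real/fake labels).
    """
    zd = z.data
    target = np.asarray(target, dtype=zd.dtype)
    loss = np.maximum(zd, 0) - zd * target + np.log1p(np.exp(-np.abs(zd)))
    out = loss.mean()
    n = zd.size

    def bw(g):
        sig = 1.0 / (1.0 + np.exp(-zd))
        z._accum((g * (sig - target) / n).astype(zd.dtype))

    return _make(np.asarray(out), (z,), bw)


def l1_mean(a: Tensor, b: Tensor) -> Tensor:
    """Mean absolute error between two tensors."""
    return mean_(abs_(sub(a, b)))
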