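"""Minimal reverse-mode automatic differentiation on numpy arrays.

Implements exactly the operations the package's two networks need:
elementwise arithmetic with broadcasting, matmul, same-padded 2D
convolution (odd kernel sizes only), 2x2 max pooling, nearest-neighbour
2x upsampling, relu/sigmoid, channel concatenation, reductions, and a
numerically stable binary-cross-entropy-with-logits head.

Gradients flow through a topologically sorted tape; every ``Tensor``
holds its value, an optional gradient, and a closure that scatters the
incoming gradient to its parents.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor",
    "conv2d",
    "maxpool2",
    "upsample2",
    "relu",
    "sigmoid",
    "concat",
    "bce_with_logits",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an autograd tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @classmethod
    def _from_op(cls, data, parents: Iterable["Tensor"], backward) -> "Tensor":
        out = cls(data)
        parents = tuple(parents)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = parents
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)
        out_data = self.data + other.data

        def backward(g):
            return (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))

        return Tensor._from_op(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return Tensor._from_op(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out_data = self.data * other.data

        def backward(g):
            return (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            )

        return Tensor._from_op(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        out_data = self.data / other.data

        def backward(g):
            return (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / other.data**2, other.shape),
            )

        return Tensor._from_op(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def matmul(self, other: "Tensor") -> "Tensor":
        other = self._wrap(other)
        out_data = self.data @ other.data

        def backward(g):
            return (g @ other.data.T, self.data.T @ g)

        return Tensor._from_op(out_data, (self, other), backward)

    __matmul__ = matmul

    # -- reductions / reshaping ----------------------------------------------
    def sum(self) -> "Tensor":
        def backward(g):
            return (np.broadcast_to(g, self.shape).copy(),)

        return Tensor._from_op(self.data.sum(), (self,), backward)

    def mean(self) -> "Tensor":
        n = self.data.size

        def backward(g):
            return (np.broadcast_to(g / n, self.shape).copy(),)

        return Tensor._from_op(self.data.mean(), (self,), backward)

    def reshape(self, *shape) -> "Tensor":
        old = self.shape

        def backward(g):
            return (g.reshape(old),)

        return Tensor._from_op(self.data.reshape(*shape), (self,), backward)

    # -- backprop driver ------------------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is None:
                continue
            grads = node._backward(node.grad)
            for parent, g in zip(node._parents, grads):
                if not parent.requires_grad or g is None:
                    continue
                if parent.grad is None:
                    parent.grad = g.copy()
                else:
                    parent.grad += g
            # free the tape as we go
            node._parents = ()
            node._backward = None

    def zero_grad(self):
        self.grad = None


# -- neural-network primitives ------------------------------------------------


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    return Tensor._from_op(x.data * mask, (x,), lambda g: (g * mask,))


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-np.clip(x.data, -60, 60)))
    return Tensor._from_op(s, (x,), lambda g: (g * s * (1 - s),))


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._from_op(
        np.concatenate([t.data for t in tensors], axis=axis), tensors, backward
    )


def conv2d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Same-padded 2D convolution (cross-correlation).

    x: (N, C, H, W); w: (F, C, kh, kw) with kh, kw odd; b: (F,).
    """
    kh, kw = w.shape[2], w.shape[3]
    if kh % 2 == 0 or kw % 2 == 0:
        raise ValueError("conv2d supports odd kernel sizes only")
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))  # (N,C,H,W,kh,kw)
    out = np.tensordot(win, w.data, axes=[(1, 4, 5), (1, 2, 3)])  # (N,H,W,F)
    out = np.ascontiguousarray(out.transpose(0, 3, 1, 2)) + b.data[None, :, None, None]

    def backward(g):
        # weights: correlate input windows with the output gradient
        dw = np.tensordot(g, win, axes=[(0, 2, 3), (0, 2, 3)])  # (F,C,kh,kw)
        db = g.sum(axis=(0, 2, 3))
        # input: same-padded correlation of g with the flipped, transposed kernel
        w_rot = w.data[:, :, ::-1, ::-1]
        gp = np.pad(g, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
        gwin = sliding_window_view(gp, (kh, kw), axis=(2, 3))  # (N,F,H,W,kh,kw)
        dx = np.tensordot(gwin, w_rot, axes=[(1, 4, 5), (0, 2, 3)])  # (N,H,W,C)
        dx = np.ascontiguousarray(dx.transpose(0, 3, 1, 2))
        return (dx, dw, db)

    return Tensor._from_op(out, (x, w, b), backward)


def maxpool2(x: Tensor) -> Tensor:
    """2x2 max pooling, stride 2; H and W must be even."""
    n, c, h, w = x.shape
    if h % 2 or w % 2:
        raise ValueError(f"maxpool2 needs even spatial dims, got {h}x{w}")
    blocks = x.data.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    blocks = blocks.reshape(n, c, h // 2, w // 2, 4)
    idx = blocks.argmax(axis=-1)
    out = np.take_along_axis(blocks, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        gb = np.zeros((n, c, h // 2, w // 2, 4))
        np.put_along_axis(gb, idx[..., None], g[..., None], axis=-1)
        gb = gb.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return (gb.reshape(n, c, h, w),)

    return Tensor._from_op(out, (x,), backward)


def upsample2(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x spatial upsampling."""
    out = x.data.repeat(2, axis=2).repeat(2, axis=3)
    n, c, h, w = x.shape

    def backward(g):
        return (g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)),)

    return Tensor._from_op(out, (x,), backward)


def bce_with_logits(z: Tensor, target: np.ndarray) -> Tensor:
    """Mean binary cross-entropy on logits; stable for large |z|."""
    t = np.asarray(target, dtype=np.float64)
    zd = z.data
    loss = np.maximum(zd, 0) - zd * t + np.log1p(np.exp(-np.abs(zd)))
    n = zd.size
    s = 1.0 / (1.0 + np.exp(-np.clip(zd, -60, 60)))

    def backward(g):
        return (g * (s - t) / n,)

    return Tensor._from_op(loss.mean(), (z,), backward)
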