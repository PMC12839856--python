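"""Minimal reverse-mode automatic differentiation over numpy arrays.

This is the tensor engine behind the tiny hybrid classifier scaffold and the
class-activation-map gradients: a :class:`Tensor` wraps an ``ndarray``, records
the operations applied to it, and :meth:`Tensor.backward` accumulates exact
gradients by walking the tape in reverse topological order.  Only the
operations the scaffold needs are provided (broadcast arithmetic, matmul,
conv2d, pooling reductions, sigmoid/relu/exp/log, reshape/transpose/concat/
slicing, layer-norm building blocks).  Everything is float64 and eager; there
is no graph pruning, no in-place mutation, and no device abstraction.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Tensor", "concat", "conv2d", "sigmoid", "relu", "softmax"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, inverting numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum away prepended axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the autodiff tape.

    Parameters
    ----------
    data : array_like
        Values, converted to a float64 ndarray.
    parents : tuple of (Tensor, callable)
        Each callable maps the output gradient to that parent's gradient
        contribution.
    """

    __slots__ = ("data", "grad", "_parents")

    def __init__(self, data, parents=()):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self._parents = parents

    # ---- construction helpers -------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape})"

    # ---- arithmetic ------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, parents=(
            (self, lambda g: _unbroadcast(g, self.data.shape)),
            (other, lambda g: _unbroadcast(g, other.data.shape)),
        ))
        return out

    __radd__ = __add__

    def __neg__(self):
        return Tensor(-self.data, parents=((self, lambda g: -g),))

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, parents=(
            (self, lambda g: _unbroadcast(g * other.data, self.data.shape)),
            (other, lambda g: _unbroadcast(g * self.data, other.data.shape)),
        ))
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out = Tensor(self.data / other.data, parents=(
            (self, lambda g: _unbroadcast(g / other.data, self.data.shape)),
            (other, lambda g: _unbroadcast(-g * self.data / other.data**2,
                                           other.data.shape)),
        ))
        return out

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, k: float):
        out = Tensor(self.data ** k, parents=(
            (self, lambda g: g * k * self.data ** (k - 1)),
        ))
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        a, b = self.data, other.data

        def ga(g):
            grad = g @ np.swapaxes(b, -1, -2)
            return _unbroadcast(grad, a.shape)

        def gb(g):
            grad = np.swapaxes(a, -1, -2) @ g
            return _unbroadcast(grad, b.shape)

        return Tensor(a @ b, parents=((self, ga), (other, gb)))

    # ---- pointwise nonlinearities ---------------------------------------
    def exp(self):
        y = np.exp(self.data)
        return Tensor(y, parents=((self, lambda g: g * y),))

    def log(self):
        return Tensor(np.log(self.data),
                      parents=((self, lambda g: g / self.data),))

    def sqrt(self):
        return self ** 0.5

    def relu(self):
        mask = self.data > 0
        return Tensor(self.data * mask, parents=((self, lambda g: g * mask),))

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-self.data))
        return Tensor(y, parents=((self, lambda g: g * y * (1.0 - y)),))

    def softplus(self):
        # log(1 + exp(x)), overflow-safe; d/dx = sigmoid(x)
        y = np.logaddexp(0.0, self.data)
        s = 1.0 / (1.0 + np.exp(-self.data))
        return Tensor(y, parents=((self, lambda g: g * s),))

    def tanh(self):
        y = np.tanh(self.data)
        return Tensor(y, parents=((self, lambda g: g * (1.0 - y * y)),))

    # ---- reductions ------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def gfn(g):
            if axis is None:
                return np.broadcast_to(g, self.data.shape).copy()
            g2 = g if keepdims else np.expand_dims(g, axis)
            return np.broadcast_to(g2, self.data.shape).copy()

        return Tensor(out_data, parents=((self, gfn),))

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis: int, keepdims=False):
        out_data = self.data.max(axis=axis, keepdims=keepdims)
        expanded = self.data.max(axis=axis, keepdims=True)
        mask = (self.data == expanded)
        # split ties evenly so the gradient stays exact for gradcheck
        mask = mask / mask.sum(axis=axis, keepdims=True)

        def gfn(g):
            g2 = g if keepdims else np.expand_dims(g, axis)
            return g2 * mask

        return Tensor(out_data, parents=((self, gfn),))

    # ---- shape ops -------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape
        return Tensor(self.data.reshape(shape),
                      parents=((self, lambda g: g.reshape(old)),))

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        return Tensor(self.data.transpose(axes),
                      parents=((self, lambda g: g.transpose(inv)),))

    def __getitem__(self, idx):
        def gfn(g):
            out = np.zeros_like(self.data)
            np.add.at(out, idx, g)
            return out

        return Tensor(self.data[idx], parents=((self, gfn),))

    # ---- backward --------------------------------------------------------
    def backward(self, seed: np.ndarray | None = None):
        """Accumulate gradients of this tensor into every ancestor's `.grad`.

        `seed` defaults to ones (so a scalar loss needs no argument).
        """
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for parent, _ in node._parents:
                if id(parent) not in seen:
                    stack.append((parent, False))

        grads: dict[int, np.ndarray] = {
            id(self): np.ones_like(self.data) if seed is None
            else np.asarray(seed, dtype=np.float64)
        }
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.grad is None:
                node.grad = g.copy()
            else:
                node.grad = node.grad + g
            for parent, gfn in node._parents:
                contribution = gfn(g)
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + contribution
                else:
                    grads[id(parent)] = contribution

    def zero_grad(self):
        self.grad = None


# ---- free functions ------------------------------------------------------

def sigmoid(x: Tensor) -> Tensor:
    return x.sigmoid()


def relu(x: Tensor) -> Tensor:
    return x.relu()


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x - Tensor(x.data.max(axis=axis, keepdims=True))
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    out_data = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    parents = []
    for i, t in enumerate(tensors):
        lo, hi = offsets[i], offsets[i + 1]

        def gfn(g, lo=lo, hi=hi):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            return g[tuple(sl)]

        parents.append((t, gfn))
    return Tensor(out_data, parents=tuple(parents))


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """2-D cross-correlation, NCHW layout, square kernel.

    x: (B, C, H, W); w: (O, C, k, k); b: (O,).
    """
    k = w.data.shape[-1]
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding),
                         (padding, padding)))
    windows = sliding_window_view(xp, (k, k), axis=(2, 3))
    windows = windows[:, :, ::stride, ::stride]  # (B,C,Ho,Wo,k,k)
    out_data = np.einsum("bcijmn,ocmn->boij", windows, w.data,
                         optimize=True)
    ho, wo = out_data.shape[2], out_data.shape[3]

    def gx(g):
        gxp = np.zeros_like(xp)
        # scatter one kernel tap at a time; k is small (3 or 7)
        for ki in range(k):
            for kj in range(k):
                contrib = np.einsum("boij,oc->bcij", g, w.data[:, :, ki, kj],
                                    optimize=True)
                gxp[:, :, ki:ki + stride * ho:stride,
                    kj:kj + stride * wo:stride] += contrib
        if padding:
            gxp = gxp[:, :, padding:-padding, padding:-padding]
        return gxp

    def gw(g):
        return np.einsum("bcijmn,boij->ocmn", windows, g, optimize=True)

    parents = [(x, gx), (w, gw)]
    if b is not None:
        out_data = out_data + b.data[None, :, None, None]
        parents.append((b, lambda g: g.sum(axis=(0, 2, 3))))
    return Tensor(out_data, parents=tuple(parents))
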