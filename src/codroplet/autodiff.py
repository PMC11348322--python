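"""Minimal reverse-mode automatic differentiation over numpy arrays.

The network in :mod:`codroplet.network` is small enough that a light
tape-based engine is sufficient: every operation records its parents and a
closure that accumulates gradients into them.  Only the primitives the
architecture needs are provided (linear algebra, elementwise nonlinearities,
softmax, layer normalisation, concatenation/slicing and reductions).

All arrays are float64.  Gradients are checked against central finite
differences in the test suite.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = ["Tensor", "concat", "matmul", "relu", "sigmoid", "softplus", "softmax", "layer_norm"]


class Tensor:
    """A node in the computation graph wrapping an ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 parents: Sequence["Tensor"] = (),
                 backward: Callable[[np.ndarray], None] | None = None):
        data = np.asarray(data)
        if not np.issubdtype(data.dtype, np.floating):
            data = data.astype(np.float64)
        self.data = data
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = tuple(parents)
        self._backward = backward

    # -- graph -----------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Back-propagate from this node (default seed: ones)."""
        if grad is None:
            grad = np.ones_like(self.data)
        # topological order by depth-first post-order
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                order.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray) -> None:
        # parents may alias the incoming array; grads are never mutated in
        # place downstream, so no defensive copy is taken
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = np.asarray(grad)
        else:
            self.grad = self.grad + grad

    # -- arithmetic ------------------------------------------------------
    def __add__(self, other):
        if isinstance(other, (int, float)):
            def bwd_s(g):
                self._accum(g)
            return Tensor(self.data + other, parents=(self,), backward=bwd_s)
        other = _as_tensor(other)
        out_data = self.data + other.data

        def bwd(g):
            self._accum(_unbroadcast(g, self.shape))
            other._accum(_unbroadcast(g, other.shape))

        return Tensor(out_data, parents=(self, other), backward=bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g):
            self._accum(-g)
        return Tensor(-self.data, parents=(self,), backward=bwd)

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        if isinstance(other, (int, float)):
            def bwd_s(g):
                self._accum(g * other)
            return Tensor(self.data * other, parents=(self,), backward=bwd_s)
        other = _as_tensor(other)
        out_data = self.data * other.data

        def bwd(g):
            self._accum(_unbroadcast(g * other.data, self.shape))
            other._accum(_unbroadcast(g * self.data, other.shape))

        return Tensor(out_data, parents=(self, other), backward=bwd)

    __rmul__ = __mul__

    def __truediv__(self, scalar):
        if isinstance(scalar, Tensor):
            raise TypeError("tensor/tensor division not supported; multiply by reciprocal")
        return self * (1.0 / float(scalar))

    # -- shape ops -------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.shape

        def bwd(g):
            self._accum(g.reshape(orig))

        return Tensor(self.data.reshape(shape), parents=(self,), backward=bwd)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def bwd(g):
            self._accum(np.transpose(g, inv))

        return Tensor(np.transpose(self.data, axes), parents=(self,), backward=bwd)

    def __getitem__(self, idx):
        def bwd(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)

        return Tensor(self.data[idx], parents=(self,), backward=bwd)

    # -- reductions ------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape).copy())
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accum(np.broadcast_to(gg, self.shape).copy())

        return Tensor(out_data, parents=(self,), backward=bwd)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / n


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, dim in enumerate(shape):
        if dim == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


def matmul(a: Tensor, b: Tensor) -> Tensor:
    """Matrix product with standard (optionally batched) semantics."""
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data @ b.data

    def bwd(g):
        ga = g @ np.swapaxes(b.data, -1, -2)
        gb = np.swapaxes(a.data, -1, -2) @ g
        a._accum(_unbroadcast(ga, a.shape))
        b._accum(_unbroadcast(gb, b.shape))

    return Tensor(out_data, parents=(a, b), backward=bwd)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def bwd(g):
        x._accum(g * mask)

    return Tensor(x.data * mask, parents=(x,), backward=bwd)


def sigmoid(x: Tensor) -> Tensor:
    s = _sigmoid_np(x.data)

    def bwd(g):
        x._accum(g * s * (1.0 - s))

    return Tensor(s, parents=(x,), backward=bwd)


def _sigmoid_np(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def softplus(x: Tensor) -> Tensor:
    """log(1 + exp(x)), numerically stable; gradient is sigmoid(x)."""
    z = x.data
    out_data = np.maximum(z, 0.0) + np.log1p(np.exp(-np.abs(z)))

    def bwd(g):
        x._accum(g * _sigmoid_np(z))

    return Tensor(out_data, parents=(x,), backward=bwd)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    s = e / e.sum(axis=axis, keepdims=True)

    def bwd(g):
        dot = (g * s).sum(axis=axis, keepdims=True)
        x._accum(s * (g - dot))

    return Tensor(s, parents=(x,), backward=bwd)


def layer_norm(x: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-5) -> Tensor:
    """Normalise over the last (channel) axis with learnable gain and bias."""
    mu = x.data.mean(axis=-1, keepdims=True)
    xc = x.data - mu
    var = (xc ** 2).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out_data = xhat * gain.data + bias.data

    def bwd(g):
        gxhat = g * gain.data
        # d/dx of (x - mu) / sqrt(var + eps)
        gx = inv * (gxhat
                    - gxhat.mean(axis=-1, keepdims=True)
                    - xhat * (gxhat * xhat).mean(axis=-1, keepdims=True))
        x._accum(gx)
        axes = tuple(range(g.ndim - 1))
        gain._accum((g * xhat).sum(axis=axes) if axes else g * xhat)
        bias._accum(g.sum(axis=axes) if axes else g)

    return Tensor(out_data, parents=(x, gain, bias), backward=bwd)


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accum(piece)

    return Tensor(out_data, parents=tuple(tensors), backward=bwd)
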