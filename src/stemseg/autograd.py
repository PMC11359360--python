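"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the segmentation network needs: broadcasted
arithmetic, batched matrix products, reductions, max-pooling, point gathering
(fancy indexing with scatter-add backward), reshaping, concatenation and the
elementwise nonlinearities. Gradients are accumulated into ``Tensor.grad`` by
``Tensor.backward()`` via a topological sort of the recorded graph.

The engine is deliberately small; every op is gradient-checked against central
finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "no_grad"]


class _NoGrad:
    """Context manager disabling graph recording (evaluation mode)."""

    _active = False

    def __enter__(self):
        self._prev = _NoGrad._active
        _NoGrad._active = True
        return self

    def __exit__(self, *exc):
        _NoGrad._active = self._prev
        return False


def no_grad() -> _NoGrad:
    return _NoGrad()


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


def _as_tensor(x, like: np.ndarray | None = None) -> "Tensor":
    if isinstance(x, Tensor):
        return x
    # bare Python scalars adopt the partner's dtype so float64 math stays exact
    dtype = like.dtype if like is not None and np.isscalar(x) else np.float32
    return Tensor(np.asarray(x, dtype=dtype), requires_grad=False)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward", "name")

    def __init__(self, data, requires_grad: bool = False, name: str = ""):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad) and not _NoGrad._active
        self._parents: tuple = ()
        self._backward = None
        self.name = name

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if not _NoGrad._active and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other, self.data)
        out_data = self.data + other.data

        def backward(g):
            return (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))

        return Tensor._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return Tensor._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-_as_tensor(other, self.data))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other, self.data)
        out_data = self.data * other.data

        def backward(g):
            return (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            )

        return Tensor._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other, self.data)
        out_data = self.data / other.data

        def backward(g):
            return (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / other.data**2, other.shape),
            )

        return Tensor._make(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return _as_tensor(other) / self

    def __pow__(self, p: float):
        out_data = self.data**p

        def backward(g):
            return (g * p * self.data ** (p - 1),)

        return Tensor._make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = _as_tensor(other)
        out_data = np.matmul(self.data, other.data)

        def backward(g):
            ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
            gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
            return (_unbroadcast(ga, self.shape), _unbroadcast(gb, other.shape))

        return Tensor._make(out_data, (self, other), backward)

    # -- elementwise nonlinearities -------------------------------------------
    def relu(self):
        mask = self.data > 0
        return Tensor._make(self.data * mask, (self,), lambda g: (g * mask,))

    def sigmoid(self):
        from scipy.special import expit

        s = expit(self.data)
        return Tensor._make(s, (self,), lambda g: (g * s * (1.0 - s),))

    def exp(self):
        e = np.exp(self.data)
        return Tensor._make(e, (self,), lambda g: (g * e,))

    def log(self):
        return Tensor._make(np.log(self.data), (self,), lambda g: (g / self.data,))

    def sqrt(self):
        r = np.sqrt(self.data)
        return Tensor._make(r, (self,), lambda g: (g * 0.5 / r,))

    def clamp_min(self, lo: float):
        mask = self.data > lo
        return Tensor._make(np.maximum(self.data, lo), (self,), lambda g: (g * mask,))

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.shape).copy(),)

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis: int, keepdims: bool = False):
        """Max along one axis; ties share the gradient equally."""
        out_data = self.data.max(axis=axis, keepdims=True)
        mask = (self.data == out_data).astype(self.data.dtype)
        mask /= mask.sum(axis=axis, keepdims=True)

        def backward(g):
            g = np.asarray(g)
            if not keepdims:
                g = np.expand_dims(g, axis)
            return (g * mask,)

        return Tensor._make(out_data if keepdims else out_data.squeeze(axis), (self,), backward)

    def softmax(self, axis: int):
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        s = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            dot = (g * s).sum(axis=axis, keepdims=True)
            return ((g - dot) * s,)

        return Tensor._make(s, (self,), backward)

    # -- shape ops ------------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape
        return Tensor._make(
            self.data.reshape(shape), (self,), lambda g: (g.reshape(old),)
        )

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        return Tensor._make(
            self.data.transpose(axes), (self,), lambda g: (g.transpose(inv),)
        )

    def swapaxes(self, a: int, b: int):
        return Tensor._make(
            np.swapaxes(self.data, a, b), (self,), lambda g: (np.swapaxes(g, a, b),)
        )

    def gather_points(self, idx: np.ndarray):
        """Gather along the last (point) axis of a (..., C, N) tensor.

        idx has shape (B, *sel) with integer entries in [0, N); the output has
        shape (B, C, *sel). Backward scatter-adds into the source positions,
        so repeated indices accumulate correctly.
        """
        b = self.shape[0]
        sel_shape = idx.shape[1:]
        bi = np.arange(b).reshape((b,) + (1,) * len(sel_shape))
        out_data = self.data[bi, :, idx]  # (B, *sel, C) via advanced indexing
        # move channel axis back to position 1
        out_data = np.moveaxis(out_data, -1, 1)

        def backward(g):
            grad = np.zeros_like(self.data)
            g_flat = np.moveaxis(g, 1, -1).reshape(b, -1, self.shape[1])  # (B, S, C)
            idx_flat = idx.reshape(b, -1)  # (B, S)
            grad_view = np.swapaxes(grad, 1, 2)  # (B, N, C) view into grad
            np.add.at(grad_view, (np.arange(b)[:, None], idx_flat), g_flat)
            return (grad,)

        return Tensor._make(out_data, (self,), backward)

    # -- autodiff driver ------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen = set()

        def visit(t: Tensor):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        grads = {id(self): np.asarray(grad, dtype=self.data.dtype)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if t._backward is None:
                t.grad = g if t.grad is None else t.grad + g
                continue
            parent_grads = t._backward(g)
            for p, pg in zip(t._parents, parent_grads):
                if not p.requires_grad or pg is None:
                    continue
                if id(p) in grads:
                    grads[id(p)] = grads[id(p)] + pg
                else:
                    grads[id(p)] = pg

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)


def concat(tensors: list, axis: int) -> Tensor:
    """Concatenate tensors along `axis`, splitting the gradient back."""
    datas = [t.data for t in tensors]
    out_data = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        return tuple(
            np.take(g, np.arange(offsets[i], offsets[i + 1]), axis=axis)
            for i in range(len(sizes))
        )

    return Tensor._make(out_data, tuple(tensors), backward)
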