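"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the encoders need: broadcast arithmetic,
(batched) matmul, exp/log/tanh/sqrt, axis reductions, reshape/transpose,
concatenation, row gathering and basic slicing. Gradients for broadcast
operations are un-broadcast by summation; gathered rows accumulate with
``np.add.at`` so repeated indices are handled correctly.

All data is float64. The engine is intentionally small: correctness is
established by numerical gradient checks in the test suite rather than by
breadth of features.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["Tensor", "Adam", "concat", "gather_rows", "softmax", "gelu", "relu"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast from ``shape``."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    for _ in range(extra):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents: tuple = ()
        self._backward = None

    # -- graph construction -------------------------------------------------

    @staticmethod
    def _result(data, parents, backward):
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    # -- arithmetic ---------------------------------------------------------

    def __add__(self, other):
        other = self._wrap(other)
        out_data = self.data + other.data

        def backward(grad, a=self, b=other):
            if a.requires_grad:
                a._accumulate(_unbroadcast(grad, a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(grad, b.data.shape))

        return self._result(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(grad, a=self):
            if a.requires_grad:
                a._accumulate(-grad)

        return self._result(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out_data = self.data * other.data

        def backward(grad, a=self, b=other):
            if a.requires_grad:
                a._accumulate(_unbroadcast(grad * b.data, a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(grad * a.data, b.data.shape))

        return self._result(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * self._wrap(other) ** -1.0

    def __rtruediv__(self, other):
        return self._wrap(other) * self ** -1.0

    def __pow__(self, exponent: float):
        out_data = self.data**exponent

        def backward(grad, a=self, p=exponent):
            if a.requires_grad:
                a._accumulate(grad * p * a.data ** (p - 1))

        return self._result(out_data, (self,), backward)

    def __matmul__(self, other):
        other = self._wrap(other)
        out_data = np.matmul(self.data, other.data)

        def backward(grad, a=self, b=other):
            if a.requires_grad:
                ga = np.matmul(grad, np.swapaxes(b.data, -1, -2))
                a._accumulate(_unbroadcast(ga, a.data.shape))
            if b.requires_grad:
                gb = np.matmul(np.swapaxes(a.data, -1, -2), grad)
                b._accumulate(_unbroadcast(gb, b.data.shape))

        return self._result(out_data, (self, other), backward)

    # -- elementwise functions ----------------------------------------------

    def exp(self):
        out_data = np.exp(self.data)

        def backward(grad, a=self, od=out_data):
            if a.requires_grad:
                a._accumulate(grad * od)

        return self._result(out_data, (self,), backward)

    def log(self):
        def backward(grad, a=self):
            if a.requires_grad:
                a._accumulate(grad / a.data)

        return self._result(np.log(self.data), (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(grad, a=self, od=out_data):
            if a.requires_grad:
                a._accumulate(grad * (1.0 - od * od))

        return self._result(out_data, (self,), backward)

    def sqrt(self):
        return self**0.5

    def maximum0(self):
        """Elementwise max(x, 0); subgradient 0 at 0."""
        mask = self.data > 0

        def backward(grad, a=self, m=mask):
            if a.requires_grad:
                a._accumulate(grad * m)

        return self._result(self.data * mask, (self,), backward)

    # -- reductions ----------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(grad, a=self, ax=axis, kd=keepdims):
            if not a.requires_grad:
                return
            g = np.asarray(grad)
            if ax is not None and not kd:
                g = np.expand_dims(g, ax)
            a._accumulate(np.broadcast_to(g, a.data.shape).copy())

        return self._result(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- shape ops -----------------------------------------------------------

    def reshape(self, *shape):
        old_shape = self.data.shape

        def backward(grad, a=self, s=old_shape):
            if a.requires_grad:
                a._accumulate(grad.reshape(s))

        return self._result(self.data.reshape(*shape), (self,), backward)

    def transpose(self, *axes):
        inv = np.argsort(axes)

        def backward(grad, a=self, i=inv):
            if a.requires_grad:
                a._accumulate(grad.transpose(*i))

        return self._result(self.data.transpose(*axes), (self,), backward)

    def __getitem__(self, key):
        out_data = self.data[key]

        def backward(grad, a=self, k=key):
            if a.requires_grad:
                full = np.zeros_like(a.data)
                np.add.at(full, k, grad)
                a._accumulate(full)

        return self._result(out_data, (self,), backward)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- backward pass -------------------------------------------------------

    def _accumulate(self, grad: np.ndarray):
        if self.grad is None:
            self.grad = np.array(grad, dtype=np.float64)
        else:
            self.grad += grad

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
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
            for parent in node._parents:
                if parent.requires_grad and id(parent) not in seen:
                    stack.append((parent, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)


# -- free functions ----------------------------------------------------------


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(grad, ts=tensors, offs=offsets, ax=axis):
        for t, start, stop in zip(ts, offs[:-1], offs[1:]):
            if t.requires_grad:
                idx = [slice(None)] * grad.ndim
                idx[ax] = slice(start, stop)
                t._accumulate(grad[tuple(idx)])

    return Tensor._result(out_data, tensors, backward)


def gather_rows(table: Tensor, indices) -> Tensor:
    """Select rows ``table[indices]``; gradients scatter-add into the table."""
    indices = np.asarray(indices, dtype=np.intp)
    out_data = table.data[indices]

    def backward(grad, t=table, idx=indices):
        if t.requires_grad:
            full = np.zeros_like(t.data)
            np.add.at(full, idx, grad)
            t._accumulate(full)

    return Tensor._result(out_data, (table,), backward)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shift = Tensor(x.data.max(axis=axis, keepdims=True))  # constant; no grad
    e = (x - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)


_GELU_C = math.sqrt(2.0 / math.pi)


def gelu(x: Tensor) -> Tensor:
    inner = (x + x**3.0 * 0.044715) * _GELU_C
    return x * 0.5 * (inner.tanh() + 1.0)


def relu(x: Tensor) -> Tensor:
    return x.maximum0()


class Adam:
    """Adam optimizer over a list of parameter tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
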