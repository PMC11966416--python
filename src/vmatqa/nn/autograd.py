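"""A small reverse-mode autodiff engine over NumPy arrays.

Supports exactly the operations the QA models need: broadcast arithmetic,
batched matmul, reductions, activations, reshaping/indexing, concatenation
and cumulative sums.  Gradients are accumulated by topological-order
backpropagation from a scalar loss.
"""

from __future__ import annotations

import contextlib

import numpy as np

_GRAD_ENABLED = [True]

#: Default array dtype; float32 for training throughput.  Switch to float64
#: (``set_default_dtype``) for finite-difference gradient verification.
_DTYPE = [np.float32]


def set_default_dtype(dtype) -> None:
    _DTYPE[0] = np.dtype(dtype).type


def get_default_dtype():
    return _DTYPE[0]


@contextlib.contextmanager
def default_dtype(dtype):
    prev = _DTYPE[0]
    set_default_dtype(dtype)
    try:
        yield
    finally:
        _DTYPE[0] = prev


@contextlib.contextmanager
def no_grad():
    _GRAD_ENABLED.append(False)
    try:
        yield
    finally:
        _GRAD_ENABLED.pop()


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev=()):
        self.data = np.asarray(data, dtype=_DTYPE[0])
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad and _GRAD_ENABLED[-1]
        self._backward = None
        self._prev = _prev if self.requires_grad else ()

    # ------------------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # ------------------------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data, parents, backward) -> "Tensor":
        req = _GRAD_ENABLED[-1] and any(p.requires_grad for p in parents)
        out = Tensor(data, requires_grad=req,
                     _prev=tuple(p for p in parents if p.requires_grad))
        if req:
            out._backward = backward
        return out

    def _acc(self, grad: np.ndarray, own: bool = False) -> None:
        """Accumulate a gradient; ``own=True`` when the caller hands over a
        buffer (or view) that no other accumulator will also receive.

        Handing over views of a child's finalized gradient is safe: backward
        runs in topological order, so a node's gradient is complete before
        its own backward fires and is never read again afterwards.
        """
        if self.grad is None:
            self.grad = grad if own else grad.copy()
        else:
            self.grad += grad

    # ------------------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                ga = _unbroadcast(g, self.data.shape)
                self._acc(ga, own=ga is not g)
            if other.requires_grad:
                gb = _unbroadcast(g, other.data.shape)
                other._acc(gb, own=gb is not g)

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __mul__(self, other):
        other = self._lift(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._acc(_unbroadcast(g * other.data, self.data.shape), own=True)
            if other.requires_grad:
                other._acc(_unbroadcast(g * self.data, other.data.shape), own=True)

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __truediv__(self, other):
        other = self._lift(other)
        return self * other.pow(-1.0)

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def pow(self, exponent: float) -> "Tensor":
        out_data = self.data**exponent

        def backward(g):
            if self.requires_grad:
                self._acc(g * exponent * self.data ** (exponent - 1.0), own=True)

        return self._make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = self._lift(other)
        out_data = np.matmul(self.data, other.data)

        def backward(g):
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._acc(_unbroadcast(ga, self.data.shape), own=True)
            if other.requires_grad:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other._acc(_unbroadcast(gb, other.data.shape), own=True)

        return self._make(out_data, (self, other), backward)

    # ------------------------------------------------------------------
    def sum(self, axis=None, keepdims=False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if not self.requires_grad:
                return
            gg = g
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            self._acc(np.broadcast_to(gg, self.data.shape).copy(), own=True)

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims=False) -> "Tensor":
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def cumsum(self, axis: int) -> "Tensor":
        out_data = np.cumsum(self.data, axis=axis)

        def backward(g):
            if self.requires_grad:
                rev = np.flip(np.cumsum(np.flip(g, axis=axis), axis=axis), axis=axis)
                self._acc(rev, own=True)

        return self._make(out_data, (self,), backward)

    # ------------------------------------------------------------------
    def relu(self) -> "Tensor":
        mask = self.data > 0
        out_data = self.data * mask

        def backward(g):
            if self.requires_grad:
                self._acc(g * mask, own=True)

        return self._make(out_data, (self,), backward)

    def elu(self, alpha: float = 1.0) -> "Tensor":
        pos = self.data > 0
        out_data = np.where(pos, self.data, alpha * (np.exp(np.minimum(self.data, 0)) - 1))

        def backward(g):
            if self.requires_grad:
                self._acc(g * np.where(pos, 1.0, out_data + alpha), own=True)

        return self._make(out_data, (self,), backward)

    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))

        def backward(g):
            if self.requires_grad:
                self._acc(g * s * (1.0 - s), own=True)

        return self._make(s, (self,), backward)

    def tanh(self) -> "Tensor":
        t = np.tanh(self.data)

        def backward(g):
            if self.requires_grad:
                self._acc(g * (1.0 - t * t), own=True)

        return self._make(t, (self,), backward)

    def exp(self) -> "Tensor":
        e = np.exp(np.clip(self.data, -700, 700))

        def backward(g):
            if self.requires_grad:
                self._acc(g * e, own=True)

        return self._make(e, (self,), backward)

    def log(self) -> "Tensor":
        out_data = np.log(self.data)

        def backward(g):
            if self.requires_grad:
                self._acc(g / self.data, own=True)

        return self._make(out_data, (self,), backward)

    def sqrt(self) -> "Tensor":
        return self.pow(0.5)

    def abs(self) -> "Tensor":
        sign = np.sign(self.data)

        def backward(g):
            if self.requires_grad:
                self._acc(g * sign, own=True)

        return self._make(np.abs(self.data), (self,), backward)

    # ------------------------------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out_data = self.data.reshape(shape)
        old = self.data.shape

        def backward(g):
            if self.requires_grad:
                self._acc(g.reshape(old), own=True)

        return self._make(out_data, (self,), backward)

    def transpose(self, *axes) -> "Tensor":
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out_data = self.data.transpose(axes)

        def backward(g):
            if self.requires_grad:
                self._acc(g.transpose(inv), own=True)

        return self._make(out_data, (self,), backward)

    def swapaxes(self, a: int, b: int) -> "Tensor":
        out_data = np.swapaxes(self.data, a, b)

        def backward(g):
            if self.requires_grad:
                self._acc(np.swapaxes(g, a, b), own=True)

        return self._make(out_data, (self,), backward)

    def __getitem__(self, idx) -> "Tensor":
        out_data = self.data[idx]

        def backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._acc(full, own=True)

        return self._make(out_data, (self,), backward)

    def softmax(self, axis: int = -1) -> "Tensor":
        shifted = self - Tensor(self.data.max(axis=axis, keepdims=True))
        e = shifted.exp()
        return e / e.sum(axis=axis, keepdims=True)

    # ------------------------------------------------------------------
    def backward(self) -> None:
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
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def cat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    """Concatenate along ``axis`` with gradient routing back to the parts."""
    tensors = [Tensor._lift(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    req = _GRAD_ENABLED[-1] and any(t.requires_grad for t in tensors)
    out = Tensor(out_data, requires_grad=req,
                 _prev=tuple(t for t in tensors if t.requires_grad))
    if req:
        def backward(g):
            parts = np.split(g, splits, axis=axis)
            for t, p in zip(tensors, parts):
                if t.requires_grad:
                    t._acc(p, own=True)
        out._backward = backward
    return out


def make_op(data: np.ndarray, parents: tuple, backward) -> Tensor:
    """Create a graph node with a hand-written backward (for fused ops).

    ``backward(g)`` must call ``p._acc(...)`` on each parent that requires
    gradients.
    """
    parents = tuple(parents)
    req = _GRAD_ENABLED[-1] and any(p.requires_grad for p in parents)
    out = Tensor(data, requires_grad=req,
                 _prev=tuple(p for p in parents if p.requires_grad))
    if req:
        out._backward = backward
    return out


def stack(tensors: list[Tensor], axis: int = 0) -> Tensor:
    return cat([t.reshape(t.shape[:axis] + (1,) + t.shape[axis:]) for t in tensors],
               axis=axis)
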