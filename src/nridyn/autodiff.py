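"""Reverse-mode automatic differentiation over numpy arrays.

A deliberately small tape-based engine: each operation returns a new
:class:`Tensor` holding the result and a closure that routes the output
gradient to the operands.  Only the operations needed by the message-passing
encoder and the recurrent decoder are provided (broadcast arithmetic, batched
matmul, ELU/sigmoid/tanh, log-softmax, reductions, indexing, concat/stack).

All data is float32 (single precision is ample for gradient training and
roughly halves both memory traffic and BLAS time).  Gradients are plain
numpy arrays accumulated into ``Tensor.grad``; correctness is pinned by
finite-difference tests.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32

__all__ = [
    "Tensor",
    "concat",
    "stack",
    "log_softmax",
    "softmax",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` over broadcast dimensions so it matches `shape`."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


def _as_tensor(value) -> "Tensor":
    return value if isinstance(value, Tensor) else Tensor(value)


class Tensor:
    """An n-d array plus the bookkeeping needed for backpropagation."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=DTYPE)
        self.requires_grad = requires_grad
        self.grad: np.ndarray | None = None
        self._parents: tuple = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------

    @classmethod
    def _from_op(cls, data, parents, backward) -> "Tensor":
        out = cls(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @staticmethod
    def _accumulate(tensor: "Tensor", grad: np.ndarray) -> None:
        if not tensor.requires_grad:
            return
        if tensor.grad is None:
            tensor.grad = grad.copy()
        else:
            tensor.grad += grad

    # -- basic info -----------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic -----------------------------------------------------------

    def __add__(self, other):
        other = _as_tensor(other)
        out_data = self.data + other.data

        def backward(g):
            Tensor._accumulate(self, _unbroadcast(g, self.shape))
            Tensor._accumulate(other, _unbroadcast(g, other.shape))

        return Tensor._from_op(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            Tensor._accumulate(self, -g)

        return Tensor._from_op(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)
        out_data = self.data * other.data

        def backward(g):
            Tensor._accumulate(self, _unbroadcast(g * other.data, self.shape))
            Tensor._accumulate(other, _unbroadcast(g * self.data, other.shape))

        return Tensor._from_op(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other)
        out_data = self.data / other.data

        def backward(g):
            Tensor._accumulate(self, _unbroadcast(g / other.data, self.shape))
            Tensor._accumulate(
                other, _unbroadcast(-g * self.data / other.data**2, other.shape)
            )

        return Tensor._from_op(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return _as_tensor(other) / self

    def __pow__(self, exponent: float):
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")
        out_data = self.data**exponent

        def backward(g):
            Tensor._accumulate(self, g * exponent * self.data ** (exponent - 1))

        return Tensor._from_op(out_data, (self,), backward)

    def __matmul__(self, other):
        other = _as_tensor(other)
        out_data = np.matmul(self.data, other.data)

        def backward(g):
            ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
            gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
            Tensor._accumulate(self, _unbroadcast(ga, self.shape))
            Tensor._accumulate(other, _unbroadcast(gb, other.shape))

        return Tensor._from_op(out_data, (self, other), backward)

    # -- elementwise nonlinearities -------------------------------------------

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            Tensor._accumulate(self, g * out_data)

        return Tensor._from_op(out_data, (self,), backward)

    def log(self):
        def backward(g):
            Tensor._accumulate(self, g / self.data)

        return Tensor._from_op(np.log(self.data), (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            Tensor._accumulate(self, g * (1.0 - out_data**2))

        return Tensor._from_op(out_data, (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            Tensor._accumulate(self, g * out_data * (1.0 - out_data))

        return Tensor._from_op(out_data, (self,), backward)

    def elu(self):
        # branch-free: max(x,0) + expm1(min(x,0)) equals x (x>0) / expm1(x) (x<=0)
        neg = np.expm1(np.minimum(self.data, 0.0))
        out_data = np.maximum(self.data, 0.0) + neg

        def backward(g):
            Tensor._accumulate(self, g * (neg + 1.0))

        return Tensor._from_op(out_data, (self,), backward)

    # -- reductions -----------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            Tensor._accumulate(self, np.broadcast_to(g, self.shape).copy())

        return Tensor._from_op(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        count = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(count)

    # -- shape manipulation ---------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old_shape = self.shape
        out_data = self.data.reshape(shape)

        def backward(g):
            Tensor._accumulate(self, g.reshape(old_shape))

        return Tensor._from_op(out_data, (self,), backward)

    def transpose(self, axes):
        inverse = np.argsort(axes)

        def backward(g):
            Tensor._accumulate(self, g.transpose(inverse))

        return Tensor._from_op(self.data.transpose(axes), (self,), backward)

    def __getitem__(self, index):
        out_data = self.data[index]
        parts = index if isinstance(index, tuple) else (index,)
        basic = all(isinstance(p, (slice, int)) or p is Ellipsis for p in parts)

        def backward(g):
            full = np.zeros_like(self.data)
            if basic:  # basic indexing selects disjoint views; += suffices
                full[index] += g
            else:
                np.add.at(full, index, g)
            Tensor._accumulate(self, full)

        return Tensor._from_op(out_data, (self,), backward)

    # -- backward pass --------------------------------------------------------

    def backward(self, grad=None) -> None:
        """Backpropagate from this tensor through the recorded graph."""
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack_ = [(self, False)]
        while stack_:
            node, processed = stack_.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack_.append((node, True))
            for parent in node._parents:
                if id(parent) not in visited:
                    stack_.append((parent, False))

        if grad is None:
            grad = np.ones_like(self.data)
        self.grad = np.asarray(grad, dtype=DTYPE)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())


# -- free functions ------------------------------------------------------------


def concat(tensors, axis: int = -1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            Tensor._accumulate(t, g[tuple(sl)])

    return Tensor._from_op(out_data, tensors, backward)


def stack(tensors, axis: int = 0) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out_data = np.stack([t.data for t in tensors], axis=axis)

    def backward(g):
        for k, t in enumerate(tensors):
            Tensor._accumulate(t, np.take(g, k, axis=axis))

    return Tensor._from_op(out_data, tensors, backward)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    x = _as_tensor(x)
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    log_z = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
    out_data = shifted - log_z
    soft = np.exp(out_data)

    def backward(g):
        Tensor._accumulate(x, g - soft * g.sum(axis=axis, keepdims=True))

    return Tensor._from_op(out_data, (x,), backward)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    x = _as_tensor(x)
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    out_data = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        inner = (g * out_data).sum(axis=axis, keepdims=True)
        Tensor._accumulate(x, out_data * (g - inner))

    return Tensor._from_op(out_data, (x,), backward)
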