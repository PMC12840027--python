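"""Minimal reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operations applied to
it; :meth:`Tensor.backward` walks the recorded graph in reverse topological
order and accumulates gradients.  The op set is exactly what the drying
predictor needs (dense algebra, gate nonlinearities, softmax, slicing and
concatenation along the time axis) — this is not a general deep-learning
framework and does not try to be one.

Gradients of broadcasting ops are reduced back to the operand shape with
:func:`_unbroadcast`.  All arrays are kept in float64 so that analytic
gradients can be compared against central finite differences at tight
tolerances.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = ["Tensor", "concatenate", "maximum", "sigmoid", "softmax"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over axes that were introduced or stretched by broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        _parents: tuple["Tensor", ...] = (),
        _backward: Callable[[np.ndarray], None] | None = None,
    ) -> None:
        arr = np.asarray(data)
        if arr.dtype != np.float32:  # float32 opt-in; everything else -> float64
            arr = np.asarray(arr, dtype=np.float64)
        self.data = arr
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = _parents
        self._backward = _backward

    # ------------------------------------------------------------------ infra
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            if (isinstance(grad, np.ndarray) and grad.base is None
                    and grad.dtype == self.data.dtype and grad.shape == self.data.shape):
                # freshly allocated by an op backward: take ownership, no copy
                self.grad = grad
            else:
                self.grad = np.array(grad, dtype=self.data.dtype, copy=True)
        else:
            self.grad += grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor (defaults to d(self)/d(self) = 1)."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
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
                if id(parent) not in seen:
                    stack.append((parent, False))
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without an explicit gradient needs a scalar")
            grad = np.ones_like(self.data)
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def _make(self, data: np.ndarray, parents: Sequence["Tensor"],
              backward: Callable[[np.ndarray], None]) -> "Tensor":
        tracked = tuple(p for p in parents if p.requires_grad or p._parents)
        if not tracked:
            return Tensor(data)
        return Tensor(data, requires_grad=False, _parents=tracked, _backward=backward)

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other) -> "Tensor":
        other = self._lift(other)
        out_data = self.data + other.data

        def backward(g: np.ndarray) -> None:
            if self.requires_grad or self._parents:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad or other._parents:
                other._accumulate(_unbroadcast(g, other.shape))

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        def backward(g: np.ndarray) -> None:
            self._accumulate(-g)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other) -> "Tensor":
        return self + (-self._lift(other))

    def __rsub__(self, other) -> "Tensor":
        return self._lift(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = self._lift(other)
        out_data = self.data * other.data

        def backward(g: np.ndarray) -> None:
            if self.requires_grad or self._parents:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad or other._parents:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = self._lift(other)
        out_data = self.data / other.data

        def backward(g: np.ndarray) -> None:
            if self.requires_grad or self._parents:
                self._accumulate(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad or other._parents:
                other._accumulate(
                    _unbroadcast(-g * self.data / other.data**2, other.shape)
                )

        return self._make(out_data, (self, other), backward)

    def __pow__(self, exponent: float) -> "Tensor":
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")
        out_data = self.data**exponent

        def backward(g: np.ndarray) -> None:
            self._accumulate(g * exponent * self.data ** (exponent - 1))

        return self._make(out_data, (self,), backward)

    def __matmul__(self, other) -> "Tensor":
        other = self._lift(other)
        out_data = np.matmul(self.data, other.data)

        def backward(g: np.ndarray) -> None:
            if self.requires_grad or self._parents:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._accumulate(_unbroadcast(ga, self.shape))
            if other.requires_grad or other._parents:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other._accumulate(_unbroadcast(gb, other.shape))

        return self._make(out_data, (self, other), backward)

    # ------------------------------------------------------------ elementwise
    def tanh(self) -> "Tensor":
        out_data = np.tanh(self.data)

        def backward(g: np.ndarray) -> None:
            self._accumulate(g * (1.0 - out_data**2))

        return self._make(out_data, (self,), backward)

    def sigmoid(self) -> "Tensor":
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g: np.ndarray) -> None:
            self._accumulate(g * out_data * (1.0 - out_data))

        return self._make(out_data, (self,), backward)

    def relu(self) -> "Tensor":
        out_data = np.maximum(self.data, 0.0)

        def backward(g: np.ndarray) -> None:
            self._accumulate(g * (self.data > 0.0))

        return self._make(out_data, (self,), backward)

    def exp(self) -> "Tensor":
        out_data = np.exp(self.data)

        def backward(g: np.ndarray) -> None:
            self._accumulate(g * out_data)

        return self._make(out_data, (self,), backward)

    def log(self) -> "Tensor":
        out_data = np.log(self.data)

        def backward(g: np.ndarray) -> None:
            self._accumulate(g / self.data)

        return self._make(out_data, (self,), backward)

    # ------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g: np.ndarray) -> None:
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape))
                return
            g_exp = g if keepdims else np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g_exp, self.shape))

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # ---------------------------------------------------------------- shaping
    def reshape(self, *shape) -> "Tensor":
        out_data = self.data.reshape(*shape)

        def backward(g: np.ndarray) -> None:
            self._accumulate(g.reshape(self.shape))

        return self._make(out_data, (self,), backward)

    def swapaxes(self, a: int, b: int) -> "Tensor":
        out_data = np.swapaxes(self.data, a, b)

        def backward(g: np.ndarray) -> None:
            self._accumulate(np.swapaxes(g, a, b))

        return self._make(out_data, (self,), backward)

    def __getitem__(self, key) -> "Tensor":
        out_data = self.data[key]
        parts = key if isinstance(key, tuple) else (key,)
        basic = all(isinstance(p, (slice, int)) or p is Ellipsis for p in parts)

        def backward(g: np.ndarray) -> None:
            full = np.zeros_like(self.data)
            if basic:  # basic indexing never aliases: direct add is safe & fast
                full[key] += g
            else:
                np.add.at(full, key, g)
            self._accumulate(full)

        return self._make(out_data, (self,), backward)

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"


def concatenate(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g: np.ndarray) -> None:
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad or t._parents:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accumulate(g[tuple(idx)])

    tracked = tuple(t for t in tensors if t.requires_grad or t._parents)
    if not tracked:
        return Tensor(out_data)
    return Tensor(out_data, _parents=tracked, _backward=backward)


def split(x: Tensor, sections: int, axis: int) -> list[Tensor]:
    """Split ``x`` into equal sections along ``axis``.

    The pieces share one lazily allocated gradient buffer that is flushed
    to the parent once every piece's backward has fired — so every piece
    MUST participate in the graph that ``backward()`` is called on.  Used
    internally for gate/timestep slicing where that always holds.
    """
    x = Tensor._lift(x)
    size = x.data.shape[axis]
    if size % sections != 0:
        raise ValueError("axis not divisible into equal sections")
    step = size // sections
    pieces = np.split(x.data, sections, axis=axis)
    if not (x.requires_grad or x._parents):
        return [Tensor(p) for p in pieces]
    state: dict = {"buf": None, "fired": 0}

    def make_backward(i: int):
        sl = [slice(None)] * x.data.ndim
        sl[axis] = slice(i * step, (i + 1) * step)
        sl = tuple(sl)

        def backward(g: np.ndarray) -> None:
            if state["buf"] is None:
                state["buf"] = np.zeros_like(x.data)
            state["buf"][sl] += g
            state["fired"] += 1
            if state["fired"] == sections:
                x._accumulate(state["buf"])
                state["buf"] = None
                state["fired"] = 0

        return backward

    return [Tensor(p, _parents=(x,), _backward=make_backward(i))
            for i, p in enumerate(pieces)]


def maximum(a: Tensor, b: Tensor) -> Tensor:
    """Elementwise maximum; ties route the full gradient to the first operand."""
    a, b = Tensor._lift(a), Tensor._lift(b)
    out_data = np.maximum(a.data, b.data)
    a_wins = a.data >= b.data

    def backward(g: np.ndarray) -> None:
        if a.requires_grad or a._parents:
            a._accumulate(_unbroadcast(g * a_wins, a.shape))
        if b.requires_grad or b._parents:
            b._accumulate(_unbroadcast(g * ~a_wins, b.shape))

    tracked = tuple(t for t in (a, b) if t.requires_grad or t._parents)
    if not tracked:
        return Tensor(out_data)
    return Tensor(out_data, _parents=tracked, _backward=backward)


def sigmoid(x: Tensor) -> Tensor:
    return Tensor._lift(x).sigmoid()


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax along ``axis``."""
    x = Tensor._lift(x)
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    out_data = e / e.sum(axis=axis, keepdims=True)

    def backward(g: np.ndarray) -> None:
        inner = (g * out_data).sum(axis=axis, keepdims=True)
        x._accumulate(out_data * (g - inner))

    if not (x.requires_grad or x._parents):
        return Tensor(out_data)
    return Tensor(out_data, _parents=(x,), _backward=backward)
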