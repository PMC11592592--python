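"""Minimal reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps an ndarray together with the closure that
propagates its gradient to its parents; :meth:`Tensor.backward` runs a
topological sweep and then frees the graph. Only the operations needed by
the networks in this package are implemented, each with an analytically
derived adjoint (checked against central finite differences in the
test-suite). The float dtype is process-wide and switchable: float32 for
training speed, float64 for numerical verification.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "log_softmax", "softplus",
           "set_default_dtype", "get_default_dtype"]

_DEFAULT_DTYPE = np.float64


def set_default_dtype(dtype) -> None:
    """Set the float dtype for all subsequently created tensors.

    float32 roughly halves training time and memory; float64 is used for
    finite-difference gradient verification.
    """
    global _DEFAULT_DTYPE
    dtype = np.dtype(dtype)
    if dtype not in (np.float32, np.float64):
        raise ValueError("dtype must be float32 or float64")
    _DEFAULT_DTYPE = dtype.type


def get_default_dtype():
    return _DEFAULT_DTYPE


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=_DEFAULT_DTYPE)
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in parents)
        self.grad = None
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, iter(self._parents))]
        in_stack = {id(self)}
        # iterative DFS post-order (graphs can be deep)
        while stack:
            node, it = stack[-1]
            advanced = False
            for p in it:
                if id(p) not in seen and id(p) not in in_stack and p.requires_grad:
                    stack.append((p, iter(p._parents)))
                    in_stack.add(id(p))
                    advanced = True
                    break
            if not advanced:
                stack.pop()
                in_stack.discard(id(node))
                seen.add(id(node))
                topo.append(node)
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
        # free the graph (closures hold large intermediate arrays) and drop
        # interior-node gradients; leaf gradients are kept for the optimizer
        for node in topo:
            interior = bool(node._parents)
            node._backward = None
            node._parents = ()
            if interior and node is not self:
                node.grad = None

    # ------------------------------------------------------------- arithmetic
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))

        def bw(g):
            self._accumulate(-g)

        out._backward = bw
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out = Tensor(self.data / other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        out._backward = bw
        return out

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, p: float):
        out = Tensor(self.data**p, parents=(self,))

        def bw(g):
            self._accumulate(g * p * self.data ** (p - 1))

        out._backward = bw
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data @ other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g @ other.data.T)
            if other.requires_grad:
                other._accumulate(self.data.T @ g)

        out._backward = bw
        return out

    # ------------------------------------------------------------ elementwise
    def exp(self):
        out_data = np.exp(self.data)
        out = Tensor(out_data, parents=(self,))

        def bw(g):
            self._accumulate(g * out_data)

        out._backward = bw
        return out

    def log(self):
        out = Tensor(np.log(self.data), parents=(self,))

        def bw(g):
            self._accumulate(g / self.data)

        out._backward = bw
        return out

    def tanh(self):
        out_data = np.tanh(self.data)
        out = Tensor(out_data, parents=(self,))

        def bw(g):
            self._accumulate(g * (1.0 - out_data**2))

        out._backward = bw
        return out

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(out_data, parents=(self,))

        def bw(g):
            self._accumulate(g * out_data * (1.0 - out_data))

        out._backward = bw
        return out

    def elu(self, alpha: float = 1.0):
        neg = self.data < 0
        out_data = self.data.copy()
        out_data[neg] = alpha * np.expm1(self.data[neg])
        out = Tensor(out_data, parents=(self,))

        def bw(g):
            scale = np.ones_like(out_data)
            scale[neg] = out_data[neg] + alpha
            self._accumulate(g * scale)

        out._backward = bw
        return out

    # --------------------------------------------------------------- shaping
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), parents=(self,))

        def bw(g):
            self._accumulate(g.reshape(self.data.shape))

        out._backward = bw
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), parents=(self,))

        def bw(g):
            self._accumulate(g.transpose(inv))

        out._backward = bw
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], parents=(self,))

        def bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accumulate(full)

        out._backward = bw
        return out

    # ------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def bw(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis), parents=tuple(tensors))
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    out._backward = bw
    return out


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    m = x.data.max(axis=axis, keepdims=True)
    shifted = x.data - m
    lse = np.log(np.exp(shifted).sum(axis=axis, keepdims=True)) + m
    out_data = x.data - lse
    out = Tensor(out_data, parents=(x,))

    def bw(g):
        x._accumulate(g - np.exp(out_data) * g.sum(axis=axis, keepdims=True))

    out._backward = bw
    return out


def softplus(x: Tensor) -> Tensor:
    out = Tensor(np.logaddexp(0.0, x.data), parents=(x,))

    def bw(g):
        x._accumulate(g / (1.0 + np.exp(-x.data)))

    out._backward = bw
    return out
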