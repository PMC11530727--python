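"""Reverse-mode automatic differentiation on numpy arrays.

A minimal vectorized autograd: each operation builds a node holding its
parents and a closure that maps the node's output gradient to parent
gradients.  ``Tensor.backward()`` runs a topological sort and accumulates
gradients into every reachable tensor with ``requires_grad=True``.

Only the operations needed by the mood-monitoring models are provided
(affine maps, batched matmul, pointwise nonlinearities, reductions,
softmax, concatenation/stacking, row gathering).  Everything is float64.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter", "concat", "stack", "take_rows"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, n in enumerate(shape) if n == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- plumbing ---------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        flag = ", grad" if self.requires_grad else ""
        return f"Tensor(shape={self.data.shape}{flag})"

    def numpy(self) -> np.ndarray:
        return self.data

    def zero_grad(self):
        self.grad = None

    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @classmethod
    def _node(cls, data, parents, backward) -> "Tensor":
        out = cls(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, g: np.ndarray):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad: np.ndarray | None = None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [self]
        while stack:  # iterative DFS; graphs can be deep
            node = stack[-1]
            if id(node) in seen:
                stack.pop()
                continue
            unvisited = [p for p in node._parents if id(p) not in seen]
            if unvisited:
                stack.extend(unvisited)
            else:
                seen.add(id(node))
                topo.append(node)
                stack.pop()
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad and node._backward is None:
                node._accum(g)  # leaf
            if node._backward is not None:
                for parent, pg in node._backward(g):
                    if not parent.requires_grad:
                        continue
                    key = id(parent)
                    if key in grads:
                        grads[key] = grads[key] + pg
                    else:
                        grads[key] = pg

    # -- arithmetic -------------------------------------------------------

    def __add__(self, other):
        other = self._wrap(other)
        a, b = self, other
        return self._node(
            a.data + b.data, (a, b),
            lambda g: ((a, _unbroadcast(g, a.shape)), (b, _unbroadcast(g, b.shape))),
        )

    __radd__ = __add__

    def __neg__(self):
        a = self
        return self._node(-a.data, (a,), lambda g: ((a, -g),))

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        a, b = self, other
        return self._node(
            a.data * b.data, (a, b),
            lambda g: (
                (a, _unbroadcast(g * b.data, a.shape)),
                (b, _unbroadcast(g * a.data, b.shape)),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        a, b = self, other
        return self._node(
            a.data / b.data, (a, b),
            lambda g: (
                (a, _unbroadcast(g / b.data, a.shape)),
                (b, _unbroadcast(-g * a.data / (b.data ** 2), b.shape)),
            ),
        )

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __pow__(self, exponent: float):
        a, p = self, float(exponent)
        return self._node(
            a.data ** p, (a,),
            lambda g: ((a, g * p * a.data ** (p - 1)),),
        )

    def __matmul__(self, other):
        other = self._wrap(other)
        a, b = self, other

        def backward(g):
            ga = g @ np.swapaxes(b.data, -1, -2)
            gb = np.swapaxes(a.data, -1, -2) @ g
            return ((a, _unbroadcast(ga, a.shape)), (b, _unbroadcast(gb, b.shape)))

        return self._node(a.data @ b.data, (a, b), backward)

    # -- pointwise --------------------------------------------------------

    def exp(self):
        a = self
        out_data = np.exp(a.data)
        return self._node(out_data, (a,), lambda g: ((a, g * out_data),))

    def log(self):
        a = self
        return self._node(np.log(a.data), (a,), lambda g: ((a, g / a.data),))

    def tanh(self):
        a = self
        out_data = np.tanh(a.data)
        return self._node(out_data, (a,), lambda g: ((a, g * (1.0 - out_data ** 2)),))

    def relu(self):
        a = self
        mask = a.data > 0
        return self._node(a.data * mask, (a,), lambda g: ((a, g * mask),))

    def sigmoid(self):
        a = self
        out_data = np.where(
            a.data >= 0,
            1.0 / (1.0 + np.exp(-np.clip(a.data, None, 500))),
            np.exp(np.clip(a.data, -500, None))
            / (1.0 + np.exp(np.clip(a.data, -500, None))),
        )
        return self._node(out_data, (a,), lambda g: ((a, g * out_data * (1.0 - out_data)),))

    def sqrt(self):
        return self ** 0.5

    # -- reductions -------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        a = self

        def backward(g):
            gg = np.asarray(g)
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            return ((a, np.broadcast_to(gg, a.shape).copy()),)

        return self._node(a.data.sum(axis=axis, keepdims=keepdims), (a,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[ax] for ax in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- shape ------------------------------------------------------------

    def reshape(self, *shape):
        a = self
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return self._node(
            a.data.reshape(shape), (a,), lambda g: ((a, g.reshape(a.shape)),)
        )

    def transpose(self, axes):
        a = self
        inv = np.argsort(axes)
        return self._node(
            a.data.transpose(axes), (a,), lambda g: ((a, g.transpose(inv)),)
        )

    def swapaxes(self, ax1: int, ax2: int):
        a = self
        return self._node(
            np.swapaxes(a.data, ax1, ax2), (a,),
            lambda g: ((a, np.swapaxes(g, ax1, ax2)),),
        )

    # -- softmax ----------------------------------------------------------

    def softmax(self, axis: int = -1):
        a = self
        shifted = a.data - a.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        out_data = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            dot = (g * out_data).sum(axis=axis, keepdims=True)
            return ((a, out_data * (g - dot)),)

        return self._node(out_data, (a,), backward)

    def maximum(self, other):
        other = self._wrap(other)
        a, b = self, other
        mask = a.data >= b.data
        return self._node(
            np.maximum(a.data, b.data), (a, b),
            lambda g: (
                (a, _unbroadcast(g * mask, a.shape)),
                (b, _unbroadcast(g * ~mask, b.shape)),
            ),
        )


class Parameter(Tensor):
    """A trainable tensor (always ``requires_grad``)."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        out = []
        for t, start, stop in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(start, stop)
            out.append((t, g[tuple(idx)]))
        return tuple(out)

    return Tensor._node(
        np.concatenate([t.data for t in tensors], axis=axis), tensors, backward
    )


def stack(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]

    def backward(g):
        slabs = np.moveaxis(g, axis, 0)
        return tuple((t, slabs[i]) for i, t in enumerate(tensors))

    return Tensor._node(
        np.stack([t.data for t in tensors], axis=axis), tensors, backward
    )


def take_rows(t: Tensor, index) -> Tensor:
    """Gather rows ``t[index]`` along axis 0 (integer-array indexing)."""
    t = Tensor._wrap(t)
    index = np.asarray(index, dtype=np.intp)

    def backward(g):
        out = np.zeros_like(t.data)
        np.add.at(out, index, g)
        return ((t, out),)

    return Tensor._node(t.data[index], (t,), backward)
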