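"""Reverse-mode automatic differentiation over NumPy arrays.

A deliberately small tape-based engine: each operation returns a new
:class:`Tensor` holding the forward value and a closure that propagates
gradients to its parents.  ``Tensor.backward()`` runs a topological sort and
accumulates gradients.  Everything is float64; molecular graphs and motif
graphs are small enough that double precision costs little and keeps the
oracle comparisons tight.

Only the operations the model needs are implemented.  Segment reductions
(:func:`segment_sum`, :func:`segment_max`) are the workhorses of message
passing over batched disjoint graphs.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "concat",
    "stack",
    "relu",
    "sigmoid",
    "tanh",
    "exp",
    "log",
    "softplus",
    "softmax",
    "layer_norm",
    "segment_sum",
    "segment_max",
    "gather_rows",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An ndarray with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents = tuple(_parents)
        self._backward = _backward

    # -- introspection ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def numpy(self) -> np.ndarray:
        return self.data

    # -- autograd ---------------------------------------------------------
    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [self]
        # iterative DFS post-order; molecules can chain thousands of ops
        while stack:
            node = stack[-1]
            if id(node) in seen:
                stack.pop()
                continue
            pending = [p for p in node._parents if id(p) not in seen and p.requires_grad]
            if pending:
                stack.extend(pending)
            else:
                seen.add(id(node))
                stack.pop()
                topo.append(node)
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out = _make(self.data + other.data, (self, other))

        def back(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        out._backward = back
        return out

    __radd__ = __add__

    def __neg__(self):
        out = _make(-self.data, (self,))

        def back(g):
            if self.requires_grad:
                self._accumulate(-g)

        out._backward = back
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = _make(self.data * other.data, (self, other))

        def back(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        out._backward = back
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = _make(self.data / other.data, (self, other))

        def back(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(-g * self.data / other.data**2, other.shape))

        out._backward = back
        return out

    def __pow__(self, exponent: float):
        out = _make(self.data**exponent, (self,))

        def back(g):
            if self.requires_grad:
                self._accumulate(g * exponent * self.data ** (exponent - 1))

        out._backward = back
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = _make(self.data @ other.data, (self, other))

        def back(g):
            if self.requires_grad:
                self._accumulate(g @ np.swapaxes(other.data, -1, -2))
            if other.requires_grad:
                other._accumulate(np.swapaxes(self.data, -1, -2) @ g)

        out._backward = back
        return out

    # -- shaping ----------------------------------------------------------
    def reshape(self, *shape):
        out = _make(self.data.reshape(*shape), (self,))

        def back(g):
            if self.requires_grad:
                self._accumulate(g.reshape(self.shape))

        out._backward = back
        return out

    def transpose(self, *axes):
        axes = axes or None
        out = _make(self.data.transpose(*axes) if axes else self.data.T, (self,))

        def back(g):
            if self.requires_grad:
                inv = np.argsort(axes) if axes else None
                self._accumulate(g.transpose(*inv) if inv is not None else g.T)

        out._backward = back
        return out

    @property
    def T(self):
        return self.transpose()

    def __getitem__(self, index):
        out = _make(self.data[index], (self,))

        def back(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, index, g)
                self._accumulate(full)

        out._backward = back
        return out

    # -- reductions -------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = _make(self.data.sum(axis=axis, keepdims=keepdims), (self,))

        def back(g):
            if self.requires_grad:
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(g, self.shape).copy())

        out._backward = back
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(n)


def _make(data: np.ndarray, parents) -> Tensor:
    req = any(p.requires_grad for p in parents)
    return Tensor(data, requires_grad=req, _parents=[p for p in parents if p.requires_grad])


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# ---------------------------------------------------------------------------
# elementwise nonlinearities


def relu(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out = _make(np.maximum(x.data, 0.0), (x,))

    def back(g):
        if x.requires_grad:
            x._accumulate(g * (x.data > 0))

    out._backward = back
    return out


def sigmoid(x: Tensor) -> Tensor:
    x = as_tensor(x)
    z = np.exp(-np.abs(x.data))
    s = np.where(x.data >= 0, 1.0 / (1.0 + z), z / (1.0 + z))
    out = _make(s, (x,))

    def back(g):
        if x.requires_grad:
            x._accumulate(g * s * (1.0 - s))

    out._backward = back
    return out


def tanh(x: Tensor) -> Tensor:
    x = as_tensor(x)
    t = np.tanh(x.data)
    out = _make(t, (x,))

    def back(g):
        if x.requires_grad:
            x._accumulate(g * (1.0 - t * t))

    out._backward = back
    return out


def exp(x: Tensor) -> Tensor:
    x = as_tensor(x)
    e = np.exp(x.data)
    out = _make(e, (x,))

    def back(g):
        if x.requires_grad:
            x._accumulate(g * e)

    out._backward = back
    return out


def log(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out = _make(np.log(x.data), (x,))

    def back(g):
        if x.requires_grad:
            x._accumulate(g / x.data)

    out._backward = back
    return out


def softplus(x: Tensor) -> Tensor:
    """log(1 + exp(x)), computed stably (used by the BCE-with-logits loss)."""
    x = as_tensor(x)
    val = np.maximum(x.data, 0.0) + np.log1p(np.exp(-np.abs(x.data)))
    out = _make(val, (x,))

    def back(g):
        if x.requires_grad:
            z = np.exp(-np.abs(x.data))
            x._accumulate(g * np.where(x.data >= 0, 1.0 / (1.0 + z), z / (1.0 + z)))

    out._backward = back
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    x = as_tensor(x)
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    s = e / e.sum(axis=axis, keepdims=True)
    out = _make(s, (x,))

    def back(g):
        if x.requires_grad:
            inner = (g * s).sum(axis=axis, keepdims=True)
            x._accumulate(s * (g - inner))

    out._backward = back
    return out


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Normalize over the last axis, then scale and shift."""
    x, gamma, beta = as_tensor(x), as_tensor(gamma), as_tensor(beta)
    mu = x.data.mean(axis=-1, keepdims=True)
    var = x.data.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    out = _make(xhat * gamma.data + beta.data, (x, gamma, beta))
    d = x.data.shape[-1]

    def back(g):
        if gamma.requires_grad:
            gamma._accumulate(_unbroadcast(g * xhat, gamma.shape))
        if beta.requires_grad:
            beta._accumulate(_unbroadcast(g, beta.shape))
        if x.requires_grad:
            gx = g * gamma.data
            term = gx - gx.mean(axis=-1, keepdims=True) - xhat * (gx * xhat).mean(axis=-1, keepdims=True)
            x._accumulate(term * inv)

    out._backward = back
    return out


# ---------------------------------------------------------------------------
# gather / segment ops (message passing primitives)


def gather_rows(x: Tensor, index: np.ndarray) -> Tensor:
    """Row gather ``x[index]`` with scatter-add backward."""
    x = as_tensor(x)
    index = np.asarray(index, dtype=np.intp)
    out = _make(x.data[index], (x,))

    def back(g):
        if x.requires_grad:
            full = np.zeros_like(x.data)
            np.add.at(full, index, g)
            x._accumulate(full)

    out._backward = back
    return out


def segment_sum(x: Tensor, segment_ids: np.ndarray, num_segments: int) -> Tensor:
    """Sum rows of ``x`` into ``num_segments`` buckets; empty buckets are zero."""
    x = as_tensor(x)
    segment_ids = np.asarray(segment_ids, dtype=np.intp)
    res = np.zeros((num_segments,) + x.data.shape[1:], dtype=np.float64)
    np.add.at(res, segment_ids, x.data)
    out = _make(res, (x,))

    def back(g):
        if x.requires_grad:
            x._accumulate(g[segment_ids])

    out._backward = back
    return out


def segment_max(x: Tensor, segment_ids: np.ndarray, num_segments: int) -> Tensor:
    """Elementwise max of rows per bucket; empty buckets are zero.

    Gradient is split evenly across ties within a bucket/feature slot.
    """
    x = as_tensor(x)
    segment_ids = np.asarray(segment_ids, dtype=np.intp)
    res = np.full((num_segments,) + x.data.shape[1:], -np.inf, dtype=np.float64)
    np.maximum.at(res, segment_ids, x.data)
    empty = np.isinf(res)
    res[empty] = 0.0
    out = _make(res, (x,))

    def back(g):
        if x.requires_grad:
            is_max = (x.data == res[segment_ids]).astype(np.float64)
            counts = np.zeros_like(res)
            np.add.at(counts, segment_ids, is_max)
            counts[counts == 0] = 1.0
            x._accumulate(is_max * (g / counts)[segment_ids])

    out._backward = back
    return out


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = _make(np.concatenate([t.data for t in tensors], axis=axis), tensors)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def back(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accumulate(piece)

    out._backward = back
    return out


def stack(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = _make(np.stack([t.data for t in tensors], axis=axis), tensors)

    def back(g):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accumulate(np.take(g, i, axis=axis))

    out._backward = back
    return out
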