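"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Supports exactly the operations the graph encoders and prediction head
need: elementwise arithmetic with broadcasting, matrix products, the
usual activations, reductions, concatenation, row gathering and
segment-wise scatter reductions (the message-passing primitives).
Gradients are accumulated in float64 for run-to-run determinism.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse

__all__ = [
    "Tensor",
    "concat",
    "gather",
    "segment_sum",
    "segment_mean",
    "segment_max",
    "spmm",
]


def _scatter_add(n: int, index: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Row-wise scatter-add via sort + reduceat (much faster than ufunc.at)."""
    out = np.zeros((n,) + values.shape[1:], dtype=np.float64)
    if index.size == 0:
        return out
    order = np.argsort(index, kind="stable")
    si = index[order]
    sv = values[order]
    starts = np.concatenate(([0], np.flatnonzero(np.diff(si)) + 1))
    out[si[starts]] = np.add.reduceat(sv, starts, axis=0)
    return out


def _scatter_max(n: int, index: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Row-wise scatter-max; segments with no member stay 0."""
    out = np.zeros((n,) + values.shape[1:], dtype=np.float64)
    if index.size == 0:
        return out
    order = np.argsort(index, kind="stable")
    si = index[order]
    sv = values[order]
    starts = np.concatenate(([0], np.flatnonzero(np.diff(si)) + 1))
    out[si[starts]] = np.maximum.reduceat(sv, starts, axis=0)
    return out


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing NumPy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A NumPy array with a gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers -------------------------------------------
    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad or p._parents for p in parents):
            out._parents = parents
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape})"

    # -- arithmetic ------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)
        out_data = self.data + other.data

        def backward(g):
            return (_unbroadcast(g, self.data.shape),
                    _unbroadcast(g, other.data.shape))

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return self._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out_data = self.data * other.data

        def backward(g):
            return (_unbroadcast(g * other.data, self.data.shape),
                    _unbroadcast(g * self.data, other.data.shape))

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out_data = self.data / other.data

        def backward(g):
            return (_unbroadcast(g / other.data, self.data.shape),
                    _unbroadcast(-g * self.data / other.data ** 2,
                                 other.data.shape))

        return self._make(out_data, (self, other), backward)

    def __matmul__(self, other):
        other = self._lift(other)
        out_data = self.data @ other.data

        def backward(g):
            a, b = self.data, other.data
            if a.ndim == 1 and b.ndim == 2:
                return (g @ b.T, np.outer(a, g))
            if a.ndim == 2 and b.ndim == 1:
                return (np.outer(g, b), a.T @ g)
            if a.ndim == 1 and b.ndim == 1:
                return (g * b, g * a)
            return (g @ b.T, a.T @ g)

        return self._make(out_data, (self, other), backward)

    # -- activations -----------------------------------------------------
    def relu(self):
        mask = self.data > 0
        return self._make(self.data * mask, (self,), lambda g: (g * mask,))

    def leaky_relu(self, slope: float = 0.2):
        mask = np.where(self.data > 0, 1.0, slope)
        return self._make(self.data * mask, (self,), lambda g: (g * mask,))

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))
        return self._make(out_data, (self,),
                          lambda g: (g * out_data * (1.0 - out_data),))

    def tanh(self):
        out_data = np.tanh(self.data)
        return self._make(out_data, (self,),
                          lambda g: (g * (1.0 - out_data ** 2),))

    def exp(self):
        out_data = np.exp(self.data)
        return self._make(out_data, (self,), lambda g: (g * out_data,))

    # -- reductions ------------------------------------------------------
    def sum(self, axis=None):
        out_data = self.data.sum(axis=axis)

        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, self.data.shape).copy(),)
            return (np.broadcast_to(np.expand_dims(g, axis),
                                    self.data.shape).copy(),)

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis) * (1.0 / n)

    def reshape(self, *shape):
        old = self.data.shape
        return self._make(self.data.reshape(*shape), (self,),
                          lambda g: (g.reshape(old),))

    # -- autodiff driver -------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
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
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad:
                node.grad = g if node.grad is None else node.grad + g
            if node._backward is None:
                continue
            for parent, pg in zip(node._parents, node._backward(g)):
                if pg is None:
                    continue
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + pg
                else:
                    grads[id(parent)] = pg


# -- structural ops ------------------------------------------------------

def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._make(out_data, tuple(tensors), backward)


def gather(t: Tensor, index: np.ndarray) -> Tensor:
    """Select rows of `t` (axis 0) at integer positions `index`."""
    index = np.asarray(index, dtype=np.intp)
    out_data = t.data[index]

    def backward(g):
        return (_scatter_add(t.data.shape[0], index, g),)

    return Tensor._make(out_data, (t,), backward)


def segment_sum(t: Tensor, segment_ids: np.ndarray, num_segments: int) -> Tensor:
    """Scatter-add rows of `t` into `num_segments` buckets."""
    segment_ids = np.asarray(segment_ids, dtype=np.intp)
    out_data = _scatter_add(num_segments, segment_ids, t.data)

    def backward(g):
        return (g[segment_ids],)

    return Tensor._make(out_data, (t,), backward)


def segment_mean(t: Tensor, segment_ids: np.ndarray, num_segments: int) -> Tensor:
    segment_ids = np.asarray(segment_ids, dtype=np.intp)
    counts = np.bincount(segment_ids, minlength=num_segments).astype(np.float64)
    counts = np.maximum(counts, 1.0)
    s = segment_sum(t, segment_ids, num_segments)
    return s * (1.0 / counts)[:, None] if t.data.ndim > 1 else s * (1.0 / counts)


def spmm(values, src: np.ndarray, dst: np.ndarray, num_out: int,
         X: Tensor) -> Tensor:
    """Sparse message aggregation: out[d] = sum over edges e with dst_e=d
    of values_e * X[src_e].  ``values`` may be a Tensor (learned edge
    coefficients, e.g. attention) or a plain array (fixed normalization)."""
    src = np.asarray(src, dtype=np.intp)
    dst = np.asarray(dst, dtype=np.intp)
    val_t = values if isinstance(values, Tensor) else None
    vdata = val_t.data if val_t is not None else np.asarray(values,
                                                            dtype=np.float64)
    S = sparse.csr_matrix((vdata, (dst, src)),
                          shape=(num_out, X.data.shape[0]))

    def backward(g):
        gX = S.T @ g
        if val_t is not None:
            gv = np.einsum("ef,ef->e", g[dst], X.data[src])
            return (gv, gX)
        return (gX,)

    parents = (val_t, X) if val_t is not None else (X,)
    return Tensor._make(S @ X.data, parents, backward)


def segment_max(t: Tensor, segment_ids: np.ndarray, num_segments: int) -> Tensor:
    """Per-segment elementwise maximum; ties share the subgradient."""
    segment_ids = np.asarray(segment_ids, dtype=np.intp)
    out_data = _scatter_max(num_segments, segment_ids, t.data)

    def backward(g):
        mask = (t.data == out_data[segment_ids])
        counts = np.maximum(
            _scatter_add(num_segments, segment_ids, mask.astype(np.float64)),
            1.0)
        return (mask * (g / counts)[segment_ids],)

    return Tensor._make(out_data, (t,), backward)
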