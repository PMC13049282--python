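"""Minimal reverse-mode automatic differentiation on numpy arrays.

The pipeline's networks (segmentation U-Net, affine and non-rigid
registration heads) are small 2-D models that must train on a single CPU,
so the engine favours clarity and exact reproducibility over throughput:
float64 throughout, deterministic numpy kernels, no threading.

A :class:`Tensor` wraps an ``ndarray`` and records the operation that
produced it; ``backward()`` runs a topological sweep accumulating
gradients into ``grad``.  Only the operations the networks need are
implemented; each fused op (conv2d, pooling, bilinear sampling, batch
norm) carries a hand-written backward closure that is finite-difference
checked in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "stack"]


def _as_array(x) -> np.ndarray:
    if isinstance(x, np.ndarray):
        return x.astype(np.float64, copy=False)
    return np.asarray(x, dtype=np.float64)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 _parents: tuple = (), _backward=None):
        self.data = _as_array(data)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in _parents)
        self._parents = _parents
        self._backward = _backward

    # -- basic introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- autodiff driver -----------------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def _accum(self, g: np.ndarray):
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data + other.data

        def back(g):
            self._accum(_unbroadcast(g, self.data.shape))
            other._accum(_unbroadcast(g, other.data.shape))

        return Tensor(out_data, _parents=(self, other), _backward=back)

    __radd__ = __add__

    def __neg__(self):
        def back(g):
            self._accum(-g)
        return Tensor(-self.data, _parents=(self,), _backward=back)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data * other.data

        def back(g):
            self._accum(_unbroadcast(g * other.data, self.data.shape))
            other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor(out_data, _parents=(self, other), _backward=back)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data / other.data

        def back(g):
            self._accum(_unbroadcast(g / other.data, self.data.shape))
            other._accum(_unbroadcast(-g * self.data / other.data ** 2,
                                      other.data.shape))

        return Tensor(out_data, _parents=(self, other), _backward=back)

    def __rtruediv__(self, other):
        return Tensor(other) / self

    def __pow__(self, k: float):
        out_data = self.data ** k

        def back(g):
            self._accum(g * k * self.data ** (k - 1))

        return Tensor(out_data, _parents=(self,), _backward=back)

    # -- elementwise functions -----------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def back(g):
            self._accum(g * out_data)

        return Tensor(out_data, _parents=(self,), _backward=back)

    def log(self):
        def back(g):
            self._accum(g / self.data)
        return Tensor(np.log(self.data), _parents=(self,), _backward=back)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def back(g):
            self._accum(g * 0.5 / out_data)

        return Tensor(out_data, _parents=(self,), _backward=back)

    def abs(self):
        sign = np.sign(self.data)

        def back(g):
            self._accum(g * sign)

        return Tensor(np.abs(self.data), _parents=(self,), _backward=back)

    def leaky_relu(self, slope: float = 0.01):
        mask = np.where(self.data > 0, 1.0, slope)

        def back(g):
            self._accum(g * mask)

        return Tensor(self.data * mask, _parents=(self,), _backward=back)

    def relu(self):
        return self.leaky_relu(0.0)

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def back(g):
            gg = g
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accum(np.broadcast_to(gg, self.data.shape).copy())

        return Tensor(out_data, _parents=(self,), _backward=back)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis=None, keepdims=False):
        out_data = self.data.max(axis=axis, keepdims=True)
        mask = (self.data == out_data)
        mask = mask / mask.sum(axis=axis, keepdims=True)
        final = out_data if keepdims else np.squeeze(out_data, axis=axis)

        def back(g):
            gg = g if keepdims or axis is None else np.expand_dims(g, axis)
            self._accum(mask * gg)

        return Tensor(final, _parents=(self,), _backward=back)

    # -- shape ops -----------------------------------------------------------
    def reshape(self, *shape):
        orig = self.data.shape

        def back(g):
            self._accum(g.reshape(orig))

        return Tensor(self.data.reshape(*shape), _parents=(self,),
                      _backward=back)

    def transpose(self, axes):
        inv = np.argsort(axes)

        def back(g):
            self._accum(g.transpose(inv))

        return Tensor(self.data.transpose(axes), _parents=(self,),
                      _backward=back)

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def back(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)

        return Tensor(out_data, _parents=(self,), _backward=back)

    # -- linear algebra ------------------------------------------------------
    def matmul(self, other: "Tensor"):
        out_data = self.data @ other.data

        def back(g):
            self._accum(g @ other.data.swapaxes(-1, -2))
            other._accum(self.data.swapaxes(-1, -2) @ g)

        return Tensor(out_data, _parents=(self, other), _backward=back)

    __matmul__ = matmul


def concat(tensors, axis: int = 0) -> Tensor:
    datas = [t.data for t in tensors]
    out_data = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def back(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t._accum(g[tuple(sl)])

    return Tensor(out_data, _parents=tuple(tensors), _backward=back)


def stack(tensors, axis: int = 0) -> Tensor:
    out_data = np.stack([t.data for t in tensors], axis=axis)

    def back(g):
        for i, t in enumerate(tensors):
            t._accum(np.take(g, i, axis=axis))

    return Tensor(out_data, _parents=tuple(tensors), _backward=back)
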