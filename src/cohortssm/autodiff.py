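"""Minimal reverse-mode automatic differentiation over numpy arrays.

All model computation in this package runs in 32-bit floating point through
the :class:`Tensor` tape.  The engine supports exactly the operations the
population model needs (affine maps, smooth nonlinearities, row gathers for
permutations, sequence flips, reductions) plus a custom-gradient hook used by
the selective scan.  It is intentionally small: no graphs survive across
calls, no in-place mutation of tracked arrays, gradients accumulate by sum.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat"]

_DTYPE = np.float32


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
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
    """A numpy array with an optional gradient tape behind it."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data, dtype=_DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents = _parents
        self._backward = _backward

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def as_tensor(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- tape -----------------------------------------------------------------
    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        req = any(p.requires_grad for p in parents)
        return Tensor(data, requires_grad=req,
                      _parents=tuple(p for p in parents if p.requires_grad) if req else (),
                      _backward=backward if req else None)

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.astype(_DTYPE, copy=True)
        else:
            self.grad = self.grad + grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor (default seed: ones)."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs can be thousands of nodes deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        if grad is None:
            grad = np.ones_like(self.data)
        self._accumulate(np.asarray(grad, dtype=_DTYPE))
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = Tensor.as_tensor(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accumulate(-g)
        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-Tensor.as_tensor(other))

    def __rsub__(self, other):
        return Tensor.as_tensor(other) + (-self)

    def __mul__(self, other):
        other = Tensor.as_tensor(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor.as_tensor(other)
        return self * other ** -1.0

    def __pow__(self, exponent: float):
        out_data = self.data ** exponent

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * exponent * self.data ** (exponent - 1.0))

        return Tensor._make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = Tensor.as_tensor(other)
        out_data = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(g @ other.data.T)
            if other.requires_grad:
                other._accumulate(self.data.T @ g)

        return Tensor._make(out_data, (self, other), backward)

    # -- elementwise nonlinearities -------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * out_data)

        return Tensor._make(out_data, (self,), backward)

    def log(self):
        def backward(g):
            if self.requires_grad:
                self._accumulate(g / self.data)
        return Tensor._make(np.log(self.data), (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (self,), backward)

    def softplus(self):
        # numerically stable: log1p(exp(-|x|)) + max(x, 0)
        out_data = np.log1p(np.exp(-np.abs(self.data))) + np.maximum(self.data, 0.0)
        sig = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * sig)

        return Tensor._make(out_data.astype(_DTYPE), (self,), backward)

    def silu(self):
        sig = 1.0 / (1.0 + np.exp(-self.data))
        out_data = self.data * sig

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * sig * (1.0 + self.data * (1.0 - sig)))

        return Tensor._make(out_data, (self,), backward)

    def maximum(self, floor: float):
        """Elementwise max with a constant; gradient passes where self wins (ties included)."""
        mask = self.data >= floor

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * mask)

        return Tensor._make(np.maximum(self.data, floor), (self,), backward)

    # -- reductions and shape ops ---------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape).copy())

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        def backward(g):
            if self.requires_grad:
                self._accumulate(g.reshape(self.data.shape))
        return Tensor._make(self.data.reshape(*shape), (self,), backward)

    def transpose(self):
        def backward(g):
            if self.requires_grad:
                self._accumulate(g.T)
        return Tensor._make(self.data.T, (self,), backward)

    @property
    def T(self):
        return self.transpose()

    def take_rows(self, index) -> "Tensor":
        """Gather rows along axis 0; backward scatter-adds (handles repeats)."""
        index = np.asarray(index)
        out_data = self.data[index]

        def backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, index, g)
                self._accumulate(full)

        return Tensor._make(out_data, (self,), backward)

    def flip0(self) -> "Tensor":
        def backward(g):
            if self.requires_grad:
                self._accumulate(g[::-1].copy())
        return Tensor._make(self.data[::-1].copy(), (self,), backward)

    def slice_rows(self, start: int, stop: int) -> "Tensor":
        def backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                full[start:stop] = g
                self._accumulate(full)
        return Tensor._make(self.data[start:stop].copy(), (self,), backward)

    # -- composite layers ------------------------------------------------------
    def layer_norm(self, gamma: "Tensor", beta: "Tensor", eps: float = 1e-5) -> "Tensor":
        """Per-row layer normalization over the last axis."""
        mu = self.mean(axis=-1, keepdims=True)
        centered = self - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        inv = (var + eps) ** -0.5
        return centered * inv * gamma + beta

    def log_softmax(self) -> "Tensor":
        """Row-wise log-softmax over the last axis (shift by detached max)."""
        shift = self - Tensor(self.data.max(axis=-1, keepdims=True))
        lse = shift.exp().sum(axis=-1, keepdims=True).log()
        return shift - lse

    def softmax(self) -> "Tensor":
        return self.log_softmax().exp()


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    """Concatenate along ``axis`` (only axis 0 is used in practice)."""
    tensors = [Tensor.as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accumulate(g[tuple(sl)])

    return Tensor._make(out_data, tuple(tensors), backward)
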