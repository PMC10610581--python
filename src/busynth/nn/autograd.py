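"""Minimal reverse-mode automatic differentiation on NumPy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operations applied to
it; :meth:`Tensor.backward` walks the tape in reverse topological order and
accumulates gradients.  The op set is exactly what the adversarial models in
this package need: elementwise arithmetic with broadcasting, matmul, 2-D
(transposed) convolution, the usual activations, reductions, padding,
concatenation and per-sample integer translation.  Everything is dtype
preserving, so float64 inputs give float64 gradients (the closed-form loss
tests rely on this) while training runs in float32.
"""

from __future__ import annotations

import contextlib

import numpy as np

__all__ = ["Tensor", "as_tensor", "concat", "stack_scalars", "no_grad"]

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable tape recording (inference / discriminator-side generator runs)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


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
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        if parents and not _GRAD_ENABLED:
            parents, backward = (), None
        self.requires_grad = (bool(requires_grad) and _GRAD_ENABLED) or any(
            p.requires_grad for p in parents
        )
        self._parents = tuple(parents)
        self._backward = backward

    # ------------------------------------------------------------------ basics
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # --------------------------------------------------------------- autograd
    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without an explicit gradient needs a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: deep graphs (residual stacks) overflow recursion
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
        self.grad = np.asarray(grad, dtype=self.data.dtype).reshape(self.data.shape)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
            if node._parents:
                # interior activations: free gradient memory eagerly
                node_grad = node.grad

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.copy() if grad.base is not None else grad
        else:
            self.grad = self.grad + grad

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accum(-g)

        out._backward = backward
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data / other.data, parents=(self, other))

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(-g * self.data / other.data**2, other.data.shape))

        out._backward = backward
        return out

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, exponent: float):
        out = Tensor(self.data**exponent, parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accum(g * exponent * self.data ** (exponent - 1))

        out._backward = backward
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data @ other.data, parents=(self, other))

        def backward(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        out._backward = backward
        return out

    # ------------------------------------------------------------ elementwise
    def relu(self):
        out = Tensor(np.maximum(self.data, 0), parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accum(g * (self.data > 0))

        out._backward = backward
        return out

    def leaky_relu(self, slope: float = 0.2):
        out = Tensor(np.where(self.data > 0, self.data, slope * self.data), parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accum(g * np.where(self.data > 0, 1.0, slope).astype(self.data.dtype))

        out._backward = backward
        return out

    def tanh(self):
        y = np.tanh(self.data)
        out = Tensor(y, parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accum(g * (1 - y**2))

        out._backward = backward
        return out

    def sigmoid(self):
        y = np.empty_like(self.data)
        pos = self.data >= 0
        y[pos] = 1.0 / (1.0 + np.exp(-self.data[pos]))
        e = np.exp(self.data[~pos])
        y[~pos] = e / (1.0 + e)
        out = Tensor(y, parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accum(g * y * (1 - y))

        out._backward = backward
        return out

    def log(self):
        out = Tensor(np.log(self.data), parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accum(g / self.data)

        out._backward = backward
        return out

    def exp(self):
        y = np.exp(self.data)
        out = Tensor(y, parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accum(g * y)

        out._backward = backward
        return out

    def abs(self):
        out = Tensor(np.abs(self.data), parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accum(g * np.sign(self.data))

        out._backward = backward
        return out

    def clip(self, lo: float, hi: float):
        out = Tensor(np.clip(self.data, lo, hi), parents=(self,))

        def backward(g):
            if self.requires_grad:
                inside = (self.data > lo) & (self.data < hi)
                self._accum(g * inside)

        out._backward = backward
        return out

    # -------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).astype(self.data.dtype))
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).astype(self.data.dtype))

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # ------------------------------------------------------------ shape / view
    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(self.data.shape))

        out._backward = backward
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], parents=(self,))

        def backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)

        out._backward = backward
        return out

    def pad2d(self, pad: int):
        """Zero-pad the trailing two (spatial) axes symmetrically."""
        if pad == 0:
            return self
        width = [(0, 0)] * (self.data.ndim - 2) + [(pad, pad), (pad, pad)]
        out = Tensor(np.pad(self.data, width), parents=(self,))

        def backward(g):
            if self.requires_grad:
                sl = (Ellipsis, slice(pad, -pad), slice(pad, -pad))
                self._accum(g[sl])

        out._backward = backward
        return out

    def translate2d(self, shifts: np.ndarray):
        """Per-sample integer translation with zero padding.

        ``shifts`` is an integer array of shape (N, 2) holding (dy, dx) per
        sample; applied identically to every channel.  Differentiable with
        respect to the input (the gradient is the inverse translation).
        """
        x = self.data
        n = x.shape[0]
        shifts = np.asarray(shifts, dtype=int)
        out_data = np.zeros_like(x)
        H, W = x.shape[-2], x.shape[-1]
        slices = []
        for i in range(n):
            dy, dx = int(shifts[i, 0]), int(shifts[i, 1])
            ys_dst = slice(max(dy, 0), min(H, H + dy))
            xs_dst = slice(max(dx, 0), min(W, W + dx))
            ys_src = slice(max(-dy, 0), min(H, H - dy))
            xs_src = slice(max(-dx, 0), min(W, W - dx))
            out_data[i, :, ys_dst, xs_dst] = x[i, :, ys_src, xs_src]
            slices.append((ys_dst, xs_dst, ys_src, xs_src))
        out = Tensor(out_data, parents=(self,))

        def backward(g):
            if not self.requires_grad:
                return
            gx = np.zeros_like(x)
            for i, (ys_dst, xs_dst, ys_src, xs_src) in enumerate(slices):
                gx[i, :, ys_src, xs_src] = g[i, :, ys_dst, xs_dst]
            self._accum(gx)

        out._backward = backward
        return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    out._backward = backward
    return out


def stack_scalars(tensors: list[Tensor]) -> Tensor:
    """Stack scalar tensors into a 1-D tensor (used by a few reductions)."""
    out = Tensor(np.array([t.data.reshape(()) for t in tensors]), parents=tuple(tensors))

    def backward(g):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accum(np.asarray(g[i], dtype=t.data.dtype).reshape(t.data.shape))

    out._backward = backward
    return out
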