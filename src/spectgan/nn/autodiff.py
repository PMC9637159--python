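"""Reverse-mode automatic differentiation on NumPy arrays.

A small tape-based engine sufficient for training convolutional
generative-adversarial networks on CPU: tensors track their parents and a
backward closure; :meth:`Tensor.backward` walks the graph in reverse
topological order accumulating gradients.  Only the operations the networks
in this package need are provided (elementwise arithmetic, matmul, 2-D
convolution via im2col, nearest-neighbour upsampling, slicing,
concatenation, reductions and the usual activations).

All tensors are float32 (DTYPE); convolutions use the NCHW layout.
"""

from __future__ import annotations

from typing import Callable, Optional, Sequence

import numpy as np

__all__ = [
    "DTYPE",
    "Tensor",
    "concat",
    "conv2d",
    "upsample_nearest",
]


DTYPE = np.float32  # training dtype; float32 keeps CPU convolutions fast


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast to reach ``grad.shape``."""
    if grad.shape == shape:
        return grad
    # sum leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """An array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        parents: Sequence["Tensor"] = (),
        backward: Optional[Callable[[np.ndarray], None]] = None,
    ):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = tuple(parents)
        self._backward = backward

    # -- basic introspection -------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- gradient bookkeeping ------------------------------------------------
    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = (
                grad.copy() if grad.dtype == DTYPE else grad.astype(DTYPE)
            )
        else:
            self.grad += grad

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        """Backpropagate from this tensor (scalar unless ``grad`` given)."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
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
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=DTYPE))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic ----------------------------------------------------------
    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other) -> "Tensor":
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

    def __neg__(self) -> "Tensor":
        out = Tensor(-self.data, parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(-g)
        return out

    def __sub__(self, other) -> "Tensor":
        return self + (-self._lift(other))

    def __rsub__(self, other) -> "Tensor":
        return self._lift(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = self._lift(other)
        out = Tensor(self.data * other.data, parents=(self, other))
        # capture forward-time arrays: parameter .data may be rebound by an
        # optimizer step between forward and backward
        a, b = self.data, other.data

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * b, a.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * a, b.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = self._lift(other)
        out = Tensor(self.data / other.data, parents=(self, other))
        a, b = self.data, other.data

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / b, a.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(-g * a / b**2, b.shape))

        out._backward = bw
        return out

    def __pow__(self, exponent: float) -> "Tensor":
        out = Tensor(self.data**exponent, parents=(self,))
        a = self.data

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * exponent * a ** (exponent - 1))

        out._backward = bw
        return out

    def __matmul__(self, other) -> "Tensor":
        other = self._lift(other)
        out = Tensor(self.data @ other.data, parents=(self, other))
        a, b = self.data, other.data

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g @ np.swapaxes(b, -1, -2), a.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(np.swapaxes(a, -1, -2) @ g, b.shape))

        out._backward = bw
        return out

    # -- shape manipulation ----------------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.data.shape
        out = Tensor(self.data.reshape(shape), parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(
            g.reshape(orig)
        )
        return out

    def transpose(self, *axes) -> "Tensor":
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(
            g.transpose(inv)
        )
        return out

    def __getitem__(self, idx) -> "Tensor":
        out = Tensor(self.data[idx], parents=(self,))

        def bw(g):
            if self.requires_grad:
                # basic (slice) indexing only: slice views never alias the
                # same element twice, so += is a valid scatter-add
                full = np.zeros_like(self.data)
                full[idx] += g
                self._accumulate(full)

        out._backward = bw
        return out

    # -- reductions ------------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def bw(g):
            if not self.requires_grad:
                return
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape).copy())

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- nonlinearities ----------------------------------------------------------
    def tanh(self) -> "Tensor":
        y = np.tanh(self.data)
        out = Tensor(y, parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(
            g * (1.0 - y**2)
        )
        return out

    def sigmoid(self) -> "Tensor":
        y = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(y, parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(
            g * y * (1.0 - y)
        )
        return out

    def leaky_relu(self, slope: float = 0.1) -> "Tensor":
        mask = self.data >= 0
        out = Tensor(np.where(mask, self.data, slope * self.data), parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(
            g * np.where(mask, 1.0, slope)
        )
        return out

    def abs(self) -> "Tensor":
        sign = np.sign(self.data)
        out = Tensor(np.abs(self.data), parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(g * sign)
        return out

    def minimum(self, other: float) -> "Tensor":
        """Elementwise min with a constant (used by the hinge losses)."""
        mask = self.data <= other
        out = Tensor(np.minimum(self.data, other), parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(g * mask)
        return out


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = list(tensors)
    data = np.concatenate([t.data for t in tensors], axis=axis)
    out = Tensor(data, parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(a, b)
                t._accumulate(g[tuple(idx)])

    out._backward = bw
    return out


def upsample_nearest(x: Tensor, factor: int) -> Tensor:
    """Nearest-neighbour upsampling of an NCHW tensor by ``factor``."""
    n, c, h, w = x.data.shape
    y = x.data.repeat(factor, axis=2).repeat(factor, axis=3)
    out = Tensor(y, parents=(x,))

    def bw(g):
        if x.requires_grad:
            g = g.reshape(n, c, h, factor, w, factor).sum(axis=(3, 5))
            x._accumulate(g)

    out._backward = bw
    return out


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int) -> np.ndarray:
    """(N, C, H, W) -> (N, C*kh*kw, L) column matrix of sliding patches."""
    view = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
    view = view[:, :, ::stride, ::stride, :, :]  # N, C, oh, ow, kh, kw
    n, c, oh, ow, _, _ = view.shape
    cols = view.transpose(0, 1, 4, 5, 2, 3).reshape(n, c * kh * kw, oh * ow)
    return np.ascontiguousarray(cols)


def _col2im(
    cols: np.ndarray,
    x_shape: tuple[int, ...],
    kh: int,
    kw: int,
    stride: int,
    oh: int,
    ow: int,
) -> np.ndarray:
    """Adjoint of :func:`_im2col` — scatter-add patches back to the image."""
    n, c, h, w = x_shape
    x = np.zeros(x_shape, dtype=cols.dtype)
    cols = cols.reshape(n, c, kh, kw, oh, ow)
    for i in range(kh):
        hi = i + stride * oh
        for j in range(kw):
            wj = j + stride * ow
            x[:, :, i:hi:stride, j:wj:stride] += cols[:, :, i, j]
    return x


def conv2d(x: Tensor, weight: Tensor, bias: Optional[Tensor], stride: int = 1,
           padding: int = 0) -> Tensor:
    """2-D convolution (cross-correlation) in NCHW layout.

    ``weight`` has shape (F, C, kh, kw); ``bias`` shape (F,) or None.
    """
    n, c, h, w = x.data.shape
    f, c_w, kh, kw = weight.data.shape
    if c != c_w:
        raise ValueError(f"conv2d channel mismatch: input {c}, weight {c_w}")
    xp = (
        np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
        if padding
        else x.data
    )
    hp, wp = xp.shape[2], xp.shape[3]
    oh = (hp - kh) // stride + 1
    ow = (wp - kw) // stride + 1
    cols = _im2col(xp, kh, kw, stride)  # N, C*kh*kw, L
    w_mat = weight.data.reshape(f, -1)  # F, C*kh*kw
    y = np.matmul(w_mat, cols).reshape(n, f, oh, ow)
    if bias is not None:
        y += bias.data.reshape(1, f, 1, 1)
    parents = (x, weight) if bias is None else (x, weight, bias)
    out = Tensor(y, parents=parents)

    def bw(g):
        g_mat = np.ascontiguousarray(g.reshape(n, f, oh * ow))
        if weight.requires_grad:
            dw = np.matmul(g_mat, cols.transpose(0, 2, 1)).sum(axis=0)
            weight._accumulate(dw.reshape(weight.data.shape))
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dcols = np.matmul(w_mat.T, g_mat)
            dxp = _col2im(dcols, xp.shape, kh, kw, stride, oh, ow)
            if padding:
                dxp = dxp[:, :, padding:-padding, padding:-padding]
            x._accumulate(dxp)

    out._backward = bw
    return out
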