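"""Minimal reverse-mode automatic differentiation on numpy arrays.

Only the operators the fusion network actually needs are implemented:
elementwise arithmetic, slicing/reshape/concat, reductions, sigmoid/GELU,
axis softmax, 2-D convolution (im2col), 2x transposed convolution, and
batch normalization. Everything runs in float64 on CPU; graphs are built
eagerly and freed after ``backward``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import erf

__all__ = ["Tensor", "concat", "softmax", "conv2d", "conv_transpose2x", "batch_norm2d"]

# python-float constants: numpy float64 scalars would promote float32 arrays
_INV_SQRT2 = float(1.0 / np.sqrt(2.0))
_INV_SQRT2PI = float(1.0 / np.sqrt(2.0 * np.pi))


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        data = np.asarray(data)
        if data.dtype not in (np.float32, np.float64):
            data = data.astype(np.float64)
        self.data = data
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------
    @classmethod
    def _from_op(cls, data, parents, backward):
        out = cls(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def _accumulate(self, grad: np.ndarray) -> None:
        # grad arrays are never mutated in place, so views are safe to keep
        if self.grad is None:
            self.grad = np.asarray(grad)
        else:
            self.grad = self.grad + grad

    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative topological sort; graphs can be deep
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
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic -----------------------------------------------------------
    def _lift(self, other) -> "Tensor":
        if isinstance(other, Tensor):
            return other
        # cast constants to our dtype so float32 graphs stay float32
        return Tensor(np.asarray(other, dtype=self.data.dtype))

    def __add__(self, other):
        other = self._lift(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        return Tensor._from_op(out_data, (self, other), backward)

    __radd__ = __add__

    def __mul__(self, other):
        other = self._lift(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        return Tensor._from_op(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __truediv__(self, other):
        other = self._lift(other)
        out_data = self.data / other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / (other.data**2), other.shape)
                )

        return Tensor._from_op(out_data, (self, other), backward)

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accumulate(full)

        return Tensor._from_op(out_data, (self,), backward)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out_data = self.data.reshape(shape)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g.reshape(self.shape))

        return Tensor._from_op(out_data, (self,), backward)

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape))
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape))

        return Tensor._from_op(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            count = self.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            count = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    # -- elementwise nonlinearities -------------------------------------------
    def abs(self):
        out_data = np.abs(self.data)
        sign = np.sign(self.data)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * sign)

        return Tensor._from_op(out_data, (self,), backward)

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * out_data)

        return Tensor._from_op(out_data, (self,), backward)

    def log(self):
        out_data = np.log(self.data)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g / self.data)

        return Tensor._from_op(out_data, (self,), backward)

    def sigmoid(self):
        out_data = np.where(
            self.data >= 0,
            1.0 / (1.0 + np.exp(-np.abs(self.data))),
            np.exp(-np.abs(self.data)) / (1.0 + np.exp(-np.abs(self.data))),
        )

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * out_data * (1.0 - out_data))

        return Tensor._from_op(out_data, (self,), backward)

    def gelu(self):
        # exact GELU: x * Phi(x); derivative Phi(x) + x * phi(x)
        x = self.data
        phi_cdf = 0.5 * (1.0 + erf(x * _INV_SQRT2))
        out_data = x * phi_cdf

        def backward(g):
            if self.requires_grad:
                pdf = _INV_SQRT2PI * np.exp(-0.5 * x * x)
                self._accumulate(g * (phi_cdf + x * pdf))

        return Tensor._from_op(out_data, (self,), backward)

    def clip(self, lo: float, hi: float):
        out_data = np.clip(self.data, lo, hi)
        mask = (self.data > lo) & (self.data < hi)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * mask)

        return Tensor._from_op(out_data, (self,), backward)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accumulate(g[tuple(idx)])

    return Tensor._from_op(out_data, tuple(tensors), backward)


def softmax(t: Tensor, axis: int = -1) -> Tensor:
    """Numerically stabilized softmax along ``axis``."""
    shifted = t.data - t.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    out_data = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        if t.requires_grad:
            dot = (g * out_data).sum(axis=axis, keepdims=True)
            t._accumulate(out_data * (g - dot))

    return Tensor._from_op(out_data, (t,), backward)


# -- convolution --------------------------------------------------------------


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    """Return (cols, padded_shape): cols is (B, OH*OW, C*kh*kw)."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    b, c, h, w = x.shape
    view = sliding_window_view(x, (kh, kw), axis=(2, 3))[:, :, ::stride, :: stride]
    oh, ow = view.shape[2], view.shape[3]
    cols = view.transpose(0, 2, 3, 1, 4, 5).reshape(b, oh * ow, c * kh * kw)
    return np.ascontiguousarray(cols), (b, c, h, w), (oh, ow)


def _col2im(dcols: np.ndarray, padded_shape, out_hw, kh, kw, stride, pad):
    """Scatter-add column gradients back to the (unpadded) input."""
    b, c, h, w = padded_shape
    oh, ow = out_hw
    dxp = np.zeros(padded_shape, dtype=dcols.dtype)
    d6 = dcols.reshape(b, oh, ow, c, kh, kw).transpose(0, 3, 4, 5, 1, 2)
    for i in range(kh):
        for j in range(kw):
            dxp[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride] += d6[
                :, :, i, j, :, :
            ]
    if pad:
        return dxp[:, :, pad:-pad, pad:-pad]
    return dxp


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1, pad: int = 0) -> Tensor:
    """2-D convolution (cross-correlation); x (B,C,H,W), w (O,C,kh,kw)."""
    o, c, kh, kw = w.shape
    cols, padded_shape, (oh, ow) = _im2col(x.data, kh, kw, stride, pad)
    wmat = w.data.reshape(o, c * kh * kw)
    y = cols @ wmat.T  # (B, OH*OW, O)
    if b is not None:
        y = y + b.data[None, None, :]
    out_data = y.transpose(0, 2, 1).reshape(x.shape[0], o, oh, ow)

    def backward(g):
        gc = g.reshape(x.shape[0], o, oh * ow).transpose(0, 2, 1)  # (B, OH*OW, O)
        if w.requires_grad:
            dw = np.tensordot(gc, cols, axes=([0, 1], [0, 1]))  # (O, C*kh*kw)
            w._accumulate(dw.reshape(w.shape))
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dcols = gc @ wmat  # (B, OH*OW, C*kh*kw)
            x._accumulate(_col2im(dcols, padded_shape, (oh, ow), kh, kw, stride, pad))

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._from_op(out_data, parents, backward)


def conv_transpose2x(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Transposed convolution with kernel 2, stride 2 (exact 2x upsampling).

    x (B,C,H,W), w (C,O,2,2) -> (B,O,2H,2W); non-overlapping, so it is a
    per-pixel outer product followed by a block interleave.
    """
    bsz, c, h, wd = x.shape
    o = w.shape[1]
    y6 = np.einsum("bchw,cokl->bohkwl", x.data, w.data, optimize=True)
    out_data = y6.reshape(bsz, o, 2 * h, 2 * wd)
    if b is not None:
        out_data = out_data + b.data[None, :, None, None]

    def backward(g):
        g6 = g.reshape(bsz, o, h, 2, wd, 2).transpose(0, 1, 2, 4, 3, 5)  # (B,O,H,W,2,2)
        if x.requires_grad:
            x._accumulate(np.einsum("bohwkl,cokl->bchw", g6, w.data, optimize=True))
        if w.requires_grad:
            w._accumulate(np.einsum("bchw,bohwkl->cokl", x.data, g6, optimize=True))
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._from_op(out_data, parents, backward)


def batch_norm2d(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """Batch normalization over (B,H,W) per channel; updates running stats in place."""
    if training:
        mu = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean *= 1.0 - momentum
        running_mean += momentum * mu
        running_var *= 1.0 - momentum
        running_var += momentum * var
    else:
        mu, var = running_mean, running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu[None, :, None, None]) * inv_std[None, :, None, None]
    out_data = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]

    def backward(g):
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)))
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=(0, 2, 3)))
        if not x.requires_grad:
            return
        gs = gamma.data[None, :, None, None]
        if training:
            m = x.shape[0] * x.shape[2] * x.shape[3]
            dxhat = g * gs
            istd = inv_std[None, :, None, None]
            sum_dxhat = dxhat.sum(axis=(0, 2, 3), keepdims=True)
            sum_dxhat_xhat = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
            dx = istd / m * (m * dxhat - sum_dxhat - xhat * sum_dxhat_xhat)
            x._accumulate(dx)
        else:
            x._accumulate(g * gs * inv_std[None, :, None, None])

    return Tensor._from_op(out_data, (x, gamma, beta), backward)
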