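"""Reverse-mode automatic differentiation on numpy arrays.

A deliberately small tape-based engine: each :class:`Tensor` wraps an
ndarray and, when gradients are enabled, remembers the tensors it was
computed from together with a closure that routes the incoming gradient
to them.  ``Tensor.backward()`` topologically sorts the tape and runs the
closures.  The op set is exactly what a 3D encoder-decoder segmentation
network with a patch transformer needs: broadcast arithmetic, matmul,
reductions, shape ops, a handful of nonlinearities, a stable softmax,
3D convolution (stride / padding / dilation) and a linear map applied
along one axis (used for trilinear upsampling).

Dtype policy: floating inputs keep their dtype (float32 for network
weights, float64 wherever callers want tighter accumulation); integer
input is promoted to float32.
"""

from __future__ import annotations

import itertools
import math
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy import fft as _sp_fft
from scipy import special as _sp_special

__all__ = ["Tensor", "no_grad", "is_grad_enabled", "cat", "conv3d", "axis_matmul"]

_GRAD_ENABLED = True


class no_grad:
    """Context manager that suspends tape construction (e.g. teacher forwards)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


def _as_array(data) -> np.ndarray:
    a = np.asarray(data)
    if not np.issubdtype(a.dtype, np.floating):
        a = a.astype(np.float32)
    return a


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # leading broadcast axes
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, n in enumerate(shape) if n == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[np.ndarray], None] | None = None

    # ------------------------------------------------------------------ basics
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, dtype={self.dtype}, grad={self.requires_grad})"

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad += g

    # ------------------------------------------------------------------ engine
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar tensor")
            grad = np.ones_like(self.data)
        # iterative topological sort
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in visited:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ---------------------------------------------------------------- op maker
    @staticmethod
    def _make(data: np.ndarray, parents: Sequence["Tensor"],
              backward: Callable[[np.ndarray], None]) -> "Tensor":
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # ------------------------------------------------------------- arithmetic
    @staticmethod
    def _coerce(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        if isinstance(other, (int, float, np.floating, np.integer)):
            a, c = self, float(other)

            def bwd_s(g):
                if a.requires_grad:
                    a._accumulate(g)

            return Tensor._make(a.data + c, (a,), bwd_s)
        other = Tensor._coerce(other)
        a, b = self, other

        def bwd(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g, b.shape))

        return Tensor._make(a.data + b.data, (a, b), bwd)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def bwd(g):
            if a.requires_grad:
                a._accumulate(-g)

        return Tensor._make(-a.data, (a,), bwd)

    def __sub__(self, other):
        if isinstance(other, (int, float, np.floating, np.integer)):
            return self + (-float(other))
        return self + (-Tensor._coerce(other))

    def __rsub__(self, other):
        if isinstance(other, (int, float, np.floating, np.integer)):
            return (-self) + float(other)
        return Tensor._coerce(other) + (-self)

    def __mul__(self, other):
        if isinstance(other, (int, float, np.floating, np.integer)):
            a, c = self, float(other)

            def bwd_s(g):
                if a.requires_grad:
                    a._accumulate(g * c)

            return Tensor._make(a.data * c, (a,), bwd_s)
        other = Tensor._coerce(other)
        a, b = self, other

        def bwd(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g * b.data, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g * a.data, b.shape))

        return Tensor._make(a.data * b.data, (a, b), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._coerce(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return Tensor._coerce(other) * self ** -1.0

    def __pow__(self, exponent: float):
        if isinstance(exponent, Tensor):
            raise TypeError("tensor exponents are not supported")
        a = self
        out_data = a.data ** exponent

        def bwd(g):
            if a.requires_grad:
                a._accumulate(g * exponent * a.data ** (exponent - 1.0))

        return Tensor._make(out_data, (a,), bwd)

    # ------------------------------------------------------------ elementwise
    def exp(self):
        a = self
        out_data = np.exp(a.data)

        def bwd(g):
            if a.requires_grad:
                a._accumulate(g * out_data)

        return Tensor._make(out_data, (a,), bwd)

    def log(self):
        a = self

        def bwd(g):
            if a.requires_grad:
                a._accumulate(g / a.data)

        return Tensor._make(np.log(a.data), (a,), bwd)

    def sqrt(self):
        return self ** 0.5

    def relu(self):
        a = self
        mask = a.data > 0

        def bwd(g):
            if a.requires_grad:
                a._accumulate(g * mask)

        return Tensor._make(np.where(mask, a.data, 0.0), (a,), bwd)

    def sigmoid(self):
        a = self
        out_data = _sp_special.expit(a.data)

        def bwd(g):
            if a.requires_grad:
                a._accumulate(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (a,), bwd)

    def gelu(self):
        """Exact (erf-based) Gaussian error linear unit."""
        a = self
        x = a.data
        cdf = 0.5 * (1.0 + _sp_special.erf(x * (1.0 / math.sqrt(2.0))))

        def bwd(g):
            if a.requires_grad:
                pdf = np.exp(-0.5 * x * x) * (1.0 / math.sqrt(2.0 * math.pi))
                a._accumulate(g * (cdf + x * pdf))

        return Tensor._make(x * cdf, (a,), bwd)

    def softmax(self, axis: int = -1):
        a = self
        shifted = a.data - a.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        out_data = e / e.sum(axis=axis, keepdims=True)

        def bwd(g):
            if a.requires_grad:
                dot = (g * out_data).sum(axis=axis, keepdims=True)
                a._accumulate(out_data * (g - dot))

        return Tensor._make(out_data, (a,), bwd)

    # -------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        a = self
        out_data = a.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g):
            if not a.requires_grad:
                return
            if axis is None:
                a._accumulate(np.broadcast_to(g, a.shape).copy())
                return
            gg = g
            if not keepdims:
                axes = axis if isinstance(axis, tuple) else (axis,)
                axes = tuple(ax % a.ndim for ax in axes)
                gg = np.expand_dims(gg, axis=tuple(sorted(axes)))
            a._accumulate(np.broadcast_to(gg, a.shape).copy())

        return Tensor._make(out_data, (a,), bwd)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[ax] for ax in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # --------------------------------------------------------------- shape ops
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        old_shape = a.shape

        def bwd(g):
            if a.requires_grad:
                a._accumulate(g.reshape(old_shape))

        return Tensor._make(a.data.reshape(shape), (a,), bwd)

    def transpose(self, axes: Sequence[int]):
        a = self
        axes = tuple(axes)
        inv = tuple(np.argsort(axes))

        def bwd(g):
            if a.requires_grad:
                a._accumulate(g.transpose(inv))

        return Tensor._make(a.data.transpose(axes), (a,), bwd)

    def __getitem__(self, index):
        a = self

        def bwd(g):
            if a.requires_grad:
                full = np.zeros_like(a.data)
                np.add.at(full, index, g)
                a._accumulate(full)

        return Tensor._make(a.data[index], (a,), bwd)

    def __matmul__(self, other):
        other = Tensor._coerce(other)
        a, b = self, other

        def bwd(g):
            if a.requires_grad:
                if b.ndim == 1:
                    ga = np.expand_dims(g, -1) * b.data
                else:
                    ga = g @ np.swapaxes(b.data, -1, -2)
                a._accumulate(_unbroadcast(ga, a.shape))
            if b.requires_grad:
                if a.ndim == 1:
                    gb = np.expand_dims(a.data, -1) * g
                else:
                    gb = np.swapaxes(a.data, -1, -2) @ g
                b._accumulate(_unbroadcast(gb, b.shape))

        return Tensor._make(a.data @ b.data, (a, b), bwd)


# ---------------------------------------------------------------------- free ops

def cat(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._coerce(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        parts = np.split(g, splits, axis=axis)
        for t, p in zip(tensors, parts):
            if t.requires_grad:
                t._accumulate(p)

    return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis),
                        tensors, bwd)


def _conv_out_size(n: int, k: int, stride: int, pad: int, dil: int) -> int:
    eff = dil * (k - 1) + 1
    return (n + 2 * pad - eff) // stride + 1


def _im2col(xp: np.ndarray, ksize, stride, dilation, out_dims) -> np.ndarray:
    """Stack shifted views of the padded input: (B, Ci*K, Do*Ho*Wo)."""
    B, Ci = xp.shape[:2]
    Do, Ho, Wo = out_dims
    kd, kh, kw = ksize
    sd, sh, sw = stride
    dd, dh, dw = dilation
    cols = np.empty((B, Ci, kd * kh * kw, Do, Ho, Wo), dtype=xp.dtype)
    for idx, (i, j, l) in enumerate(itertools.product(range(kd), range(kh), range(kw))):
        cols[:, :, idx] = xp[:, :,
                             i * dd: i * dd + (Do - 1) * sd + 1: sd,
                             j * dh: j * dh + (Ho - 1) * sh + 1: sh,
                             l * dw: l * dw + (Wo - 1) * sw + 1: sw]
    return cols.reshape(B, Ci * kd * kh * kw, Do * Ho * Wo)


def _conv3d_im2col(x: Tensor, w: Tensor, b, stride, padding, dilation,
                   out_dims) -> Tensor:
    """Direct im2col + batched GEMM path (reference implementation)."""
    B, Ci, D, H, W = x.shape
    Co = w.shape[0]
    kd, kh, kw = w.shape[2:]
    pads = ((0, 0), (0, 0)) + tuple((p, p) for p in padding)
    xp = np.pad(x.data, pads)
    col = _im2col(xp, (kd, kh, kw), stride, dilation, out_dims)
    out = np.matmul(w.data.reshape(Co, -1), col)            # (B, Co, V)
    out = out.reshape(B, Co, *out_dims)
    if b is not None:
        out = out + b.data.reshape(1, Co, 1, 1, 1)
    parents = (x, w) if b is None else (x, w, b)

    def bwd(g):
        gy = g.reshape(B, Co, -1)
        if b is not None and b.requires_grad:
            b._accumulate(gy.sum(axis=(0, 2)))
        if w.requires_grad or x.requires_grad:
            col_b = _im2col(np.pad(x.data, pads), (kd, kh, kw), stride, dilation,
                            out_dims)
        if w.requires_grad:
            gw = np.matmul(gy, col_b.transpose(0, 2, 1)).sum(axis=0)
            w._accumulate(gw.reshape(w.shape))
        if x.requires_grad:
            gcol = np.matmul(w.data.reshape(Co, -1).T, gy)  # (B, Ci*K, V)
            gcol = gcol.reshape(B, Ci, kd * kh * kw, *out_dims)
            gxp = np.zeros_like(xp)
            Do, Ho, Wo = out_dims
            sd, sh, sw = stride
            dd, dh, dw = dilation
            for idx, (i, j, l) in enumerate(
                    itertools.product(range(kd), range(kh), range(kw))):
                gxp[:, :,
                    i * dd: i * dd + (Do - 1) * sd + 1: sd,
                    j * dh: j * dh + (Ho - 1) * sh + 1: sh,
                    l * dw: l * dw + (Wo - 1) * sw + 1: sw] += gcol[:, :, idx]
            pd, ph, pw = padding
            gx = gxp[:, :, pd: pd + D, ph: ph + H, pw: pw + W]
            x._accumulate(gx)

    return Tensor._make(out, parents, bwd)


def _conv3d_pointwise(x: Tensor, w: Tensor, b, stride) -> Tensor:
    """1x1x1 kernels reduce to a channel-mixing GEMM (after optional striding)."""
    xd = x.data
    if stride != (1, 1, 1):
        xd = xd[:, :, ::stride[0], ::stride[1], ::stride[2]]
    B, Ci = xd.shape[:2]
    spatial = xd.shape[2:]
    Co = w.shape[0]
    wm = w.data.reshape(Co, Ci)
    out = np.matmul(wm, xd.reshape(B, Ci, -1)).reshape(B, Co, *spatial)
    if b is not None:
        out = out + b.data.reshape(1, Co, 1, 1, 1)
    parents = (x, w) if b is None else (x, w, b)

    def bwd(g):
        gy = g.reshape(B, Co, -1)
        if b is not None and b.requires_grad:
            b._accumulate(gy.sum(axis=(0, 2)))
        xv = x.data
        if stride != (1, 1, 1):
            xv = xv[:, :, ::stride[0], ::stride[1], ::stride[2]]
        if w.requires_grad:
            gw = np.matmul(gy, xv.reshape(B, Ci, -1).transpose(0, 2, 1)).sum(axis=0)
            w._accumulate(gw.reshape(w.shape))
        if x.requires_grad:
            gxs = np.matmul(wm.T, gy).reshape(B, Ci, *spatial)
            if stride == (1, 1, 1):
                x._accumulate(gxs)
            else:
                gx = np.zeros_like(x.data)
                gx[:, :, ::stride[0], ::stride[1], ::stride[2]] = gxs
                x._accumulate(gx)

    return Tensor._make(out, parents, bwd)


def _conv3d_fft(x: Tensor, w: Tensor, b, stride, padding, dilation,
                out_dims) -> Tensor:
    """Spectral path: cross-correlation via rFFT over the padded grid.

    Avoids the K-fold data replication of im2col, which dominates on
    memory-bound hosts.  Exactness (up to float rounding) against the
    direct path is enforced by tests.
    """
    B, Ci, D, H, W = x.shape
    Co = w.shape[0]
    ksize = w.shape[2:]
    eff = tuple(d * (k - 1) + 1 for k, d in zip(ksize, dilation))
    pads = ((0, 0), (0, 0)) + tuple((p, p) for p in padding)
    xp = np.pad(x.data, pads)
    # transform on 5-smooth sizes; the extra zero tail never aliases back into
    # the valid correlation window
    S = tuple(_sp_fft.next_fast_len(n) for n in xp.shape[2:])
    axes = (2, 3, 4)
    Xf = _sp_fft.rfftn(xp, s=S, axes=axes)
    wd = w.data
    if dilation != (1, 1, 1):
        wdil = np.zeros((Co, Ci) + eff, dtype=wd.dtype)
        wdil[:, :, ::dilation[0], ::dilation[1], ::dilation[2]] = wd
        wd = wdil
    Wf = _sp_fft.rfftn(wd, s=S, axes=axes)
    Yf = np.einsum("bcdhw,ocdhw->bodhw", Xf, Wf.conj())
    y = _sp_fft.irfftn(Yf, s=S, axes=axes)
    Do, Ho, Wo = out_dims
    sd, sh, sw = stride
    out = np.ascontiguousarray(
        y[:, :, 0:(Do - 1) * sd + 1:sd, 0:(Ho - 1) * sh + 1:sh,
          0:(Wo - 1) * sw + 1:sw])
    if b is not None:
        out = out + b.data.reshape(1, Co, 1, 1, 1)
    parents = (x, w) if b is None else (x, w, b)

    def bwd(g):
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3, 4)))
        dy_emb = np.zeros((B, Co) + S, dtype=g.dtype)
        dy_emb[:, :, 0:(Do - 1) * sd + 1:sd, 0:(Ho - 1) * sh + 1:sh,
               0:(Wo - 1) * sw + 1:sw] = g
        DYf = _sp_fft.rfftn(dy_emb, axes=axes)
        if x.requires_grad:
            dxp = _sp_fft.irfftn(
                np.einsum("bodhw,ocdhw->bcdhw", DYf, Wf), s=S, axes=axes)
            pd_, ph_, pw_ = padding
            x._accumulate(np.ascontiguousarray(
                dxp[:, :, pd_: pd_ + D, ph_: ph_ + H, pw_: pw_ + W]))
        if w.requires_grad:
            dWf = np.einsum("bodhw,bcdhw->ocdhw", DYf.conj(), Xf)
            dw_full = _sp_fft.irfftn(dWf, s=S, axes=axes)
            dw = dw_full[:, :, 0:eff[0]:dilation[0], 0:eff[1]:dilation[1],
                         0:eff[2]:dilation[2]]
            w._accumulate(np.ascontiguousarray(dw))

    return Tensor._make(out, parents, bwd)


def conv3d(x: Tensor, w: Tensor, b: Tensor | None = None, *,
           stride: int | tuple[int, int, int] = 1,
           padding: int | tuple[int, int, int] = 0,
           dilation: int | tuple[int, int, int] = 1,
           method: str = "auto") -> Tensor:
    """3D cross-correlation of ``x`` (B,Ci,D,H,W) with ``w`` (Co,Ci,kd,kh,kw).

    ``method`` selects the compute path: ``"im2col"`` (direct, reference),
    ``"fft"`` (spectral), or ``"auto"`` (pointwise GEMM for 1x1x1 kernels,
    FFT otherwise).  All paths share the same contract and agree to float
    rounding.
    """
    x = Tensor._coerce(x)
    w = Tensor._coerce(w)
    if b is not None:
        b = Tensor._coerce(b)
    stride = (stride,) * 3 if isinstance(stride, int) else tuple(stride)
    padding = (padding,) * 3 if isinstance(padding, int) else tuple(padding)
    dilation = (dilation,) * 3 if isinstance(dilation, int) else tuple(dilation)
    B, Ci, D, H, W = x.shape
    Co, Ci_w, kd, kh, kw = w.shape
    if Ci != Ci_w:
        raise ValueError(f"input has {Ci} channels but kernel expects {Ci_w}")
    out_dims = tuple(_conv_out_size(n, k, s, p, d) for n, k, s, p, d in
                     zip((D, H, W), (kd, kh, kw), stride, padding, dilation))
    if min(out_dims) < 1:
        raise ValueError("spatial dims smaller than the (dilated) kernel footprint")
    if method == "auto":
        if (kd, kh, kw) == (1, 1, 1) and padding == (0, 0, 0):
            return _conv3d_pointwise(x, w, b, stride)
        # small grids: direct gather beats FFT overhead
        if D * H * W <= 512:
            return _conv3d_im2col(x, w, b, stride, padding, dilation, out_dims)
        return _conv3d_fft(x, w, b, stride, padding, dilation, out_dims)
    if method == "fft":
        return _conv3d_fft(x, w, b, stride, padding, dilation, out_dims)
    if method == "im2col":
        return _conv3d_im2col(x, w, b, stride, padding, dilation, out_dims)
    raise ValueError(f"unknown conv3d method {method!r}")


def axis_matmul(x: Tensor, m: np.ndarray, axis: int) -> Tensor:
    """Apply the constant linear map ``m`` (n_out, n_in) along one axis of ``x``.

    Used for fixed-weight resampling (trilinear upsampling factors as one such
    map per spatial axis); the backward pass applies ``m.T`` along the same axis.
    """
    x = Tensor._coerce(x)
    m = np.asarray(m, dtype=x.dtype)
    axis = axis % x.ndim

    def apply(mat, arr):
        moved = np.moveaxis(arr, axis, -1)
        out = moved @ mat.T
        return np.moveaxis(out, -1, axis)

    def bwd(g):
        if x.requires_grad:
            x._accumulate(apply(m.T, g))

    return Tensor._make(apply(m, x.data), (x,), bwd)
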