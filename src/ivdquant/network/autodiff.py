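"""Minimal reverse-mode automatic differentiation over NumPy arrays.

A tape-based engine in the micrograd style, sized for the small
encoder-decoder segmentation models in this package: each operation builds
a :class:`Tensor` holding the forward value and a closure that accumulates
gradients into its parents.  Convolutions and their transposes are
implemented with explicit kernel-offset loops (9 strided slice-adds for a
3×3 kernel), which is fast enough at the feature-map sizes used here and
keeps forward and backward exactly adjoint.

All data is float64; broadcasting follows NumPy semantics, with gradients
summed back to the parent shape.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "conv2d", "depthwise_conv2d",
           "conv_transpose2d", "adaptive_avg_pool2d", "resize_nearest",
           "softmax"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev=()):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _prev)
        self._backward = None
        self._prev = _prev

    # -- infrastructure ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accum(self, grad):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def backward(self, grad=None):
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data) if grad is None else np.asarray(grad)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def item(self) -> float:
        return float(self.data)

    # -- arithmetic --------------------------------------------------------
    @staticmethod
    def _lift(x):
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, _prev=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))
        out._backward = bw
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, _prev=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))
        out._backward = bw
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __truediv__(self, other):
        return self * self._lift(other) ** (-1.0)

    def __rtruediv__(self, other):
        return self._lift(other) * self ** (-1.0)

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, _prev=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1.0))
        out._backward = bw
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data @ other.data, _prev=(self, other))

        def bw(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.data.shape))
        out._backward = bw
        return out

    # -- elementwise nonlinearities ---------------------------------------
    def exp(self):
        out = Tensor(np.exp(self.data), _prev=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * out.data)
        out._backward = bw
        return out

    def log(self):
        out = Tensor(np.log(self.data), _prev=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g / self.data)
        out._backward = bw
        return out

    def tanh(self):
        out = Tensor(np.tanh(self.data), _prev=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * (1.0 - out.data ** 2))
        out._backward = bw
        return out

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), _prev=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * (self.data > 0))
        out._backward = bw
        return out

    def gelu(self):
        """tanh approximation of the Gaussian error linear unit."""
        c = np.sqrt(2.0 / np.pi)
        return 0.5 * self * (1.0 + (c * (self + 0.044715 * self * self * self)).tanh())

    def sqrt(self):
        return self ** 0.5

    # -- shape ops ---------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), _prev=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g.reshape(self.data.shape))
        out._backward = bw
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), _prev=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))
        out._backward = bw
        return out

    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _prev=(self,))

        def bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy()
                            if np.ndim(g) else np.full_like(self.data, g))
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())
        out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = (self.data.size if axis is None
             else np.prod([self.data.shape[a] for a in np.atleast_1d(axis)]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], _prev=(self,))

        def bw(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)
        out._backward = bw
        return out

    def roll(self, shift, axis):
        out = Tensor(np.roll(self.data, shift, axis=axis), _prev=(self,))

        def bw(g):
            if self.requires_grad:
                neg = tuple(-s for s in shift) if isinstance(shift, tuple) else -shift
                self._accum(np.roll(g, neg, axis=axis))
        out._backward = bw
        return out


def concat(tensors, axis=0):
    tensors = [Tensor._lift(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 _prev=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accum(g[tuple(sl)])
    out._backward = bw
    return out


def softmax(x: Tensor, axis: int) -> Tensor:
    shift = Tensor(np.max(x.data, axis=axis, keepdims=True))  # constant
    e = (x - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)


# ---------------------------------------------------------------------------
# convolution family (NCHW layout)

def _out_size(n, k, stride, pad, dil):
    return (n + 2 * pad - dil * (k - 1) - 1) // stride + 1


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1,
           padding: int = 0, dilation: int = 1) -> Tensor:
    """2-D convolution (cross-correlation); x (N,C,H,W), w (O,C,kh,kw)."""
    N, C, H, W = x.shape
    O, Cw, kh, kw = w.shape
    assert C == Cw, (C, Cw)
    Ho = _out_size(H, kh, stride, padding, dilation)
    Wo = _out_size(W, kw, stride, padding, dilation)
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    cols = np.empty((N, C, kh, kw, Ho, Wo))
    for a in range(kh):
        ra = a * dilation
        for c in range(kw):
            rc = c * dilation
            cols[:, :, a, c] = xp[:, :, ra:ra + (Ho - 1) * stride + 1:stride,
                                  rc:rc + (Wo - 1) * stride + 1:stride]
    out_data = np.einsum("ocab,ncabhw->nohw", w.data, cols, optimize=True)
    if b is not None:
        out_data = out_data + b.data[None, :, None, None]
    prev = (x, w) + ((b,) if b is not None else ())
    out = Tensor(out_data, _prev=prev)

    def bw(g):
        if w.requires_grad:
            w._accum(np.einsum("ncabhw,nohw->ocab", cols, g, optimize=True))
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dxp = np.zeros_like(xp)
            dcols = np.einsum("ocab,nohw->ncabhw", w.data, g, optimize=True)
            for a in range(kh):
                ra = a * dilation
                for c in range(kw):
                    rc = c * dilation
                    dxp[:, :, ra:ra + (Ho - 1) * stride + 1:stride,
                        rc:rc + (Wo - 1) * stride + 1:stride] += dcols[:, :, a, c]
            if padding:
                dxp = dxp[:, :, padding:-padding, padding:-padding]
            x._accum(dxp)
    out._backward = bw
    return out


def depthwise_conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
                     stride: int = 1, padding: int = 0,
                     dilation: int = 1) -> Tensor:
    """Depthwise convolution: w (C, kh, kw), one kernel per input channel."""
    N, C, H, W = x.shape
    Cw, kh, kw = w.shape
    assert C == Cw
    Ho = _out_size(H, kh, stride, padding, dilation)
    Wo = _out_size(W, kw, stride, padding, dilation)
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    cols = np.empty((N, C, kh, kw, Ho, Wo))
    for a in range(kh):
        ra = a * dilation
        for c in range(kw):
            rc = c * dilation
            cols[:, :, a, c] = xp[:, :, ra:ra + (Ho - 1) * stride + 1:stride,
                                  rc:rc + (Wo - 1) * stride + 1:stride]
    out_data = np.einsum("cab,ncabhw->nchw", w.data, cols, optimize=True)
    if b is not None:
        out_data = out_data + b.data[None, :, None, None]
    prev = (x, w) + ((b,) if b is not None else ())
    out = Tensor(out_data, _prev=prev)

    def bw(g):
        if w.requires_grad:
            w._accum(np.einsum("ncabhw,nchw->cab", cols, g, optimize=True))
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dxp = np.zeros_like(xp)
            dcols = np.einsum("cab,nchw->ncabhw", w.data, g, optimize=True)
            for a in range(kh):
                ra = a * dilation
                for c in range(kw):
                    rc = c * dilation
                    dxp[:, :, ra:ra + (Ho - 1) * stride + 1:stride,
                        rc:rc + (Wo - 1) * stride + 1:stride] += dcols[:, :, a, c]
            if padding:
                dxp = dxp[:, :, padding:-padding, padding:-padding]
            x._accum(dxp)
    out._backward = bw
    return out


def conv_transpose2d(x: Tensor, w: Tensor, b: Tensor | None = None,
                     stride: int = 2, padding: int = 0) -> Tensor:
    """Transpose convolution (adjoint of conv2d); x (N,C,H,W), w (C,O,kh,kw).

    Output spatial size is (H−1)·stride − 2·padding + k.
    """
    N, C, H, W = x.shape
    Cw, O, kh, kw = w.shape
    assert C == Cw
    Hf = (H - 1) * stride + kh
    Wf = (W - 1) * stride + kw
    full = np.zeros((N, O, Hf, Wf))
    for a in range(kh):
        for c in range(kw):
            full[:, :, a:a + (H - 1) * stride + 1:stride,
                 c:c + (W - 1) * stride + 1:stride] += np.einsum(
                     "nchw,co->nohw", x.data, w.data[:, :, a, c], optimize=True)
    if padding:
        full = full[:, :, padding:-padding, padding:-padding]
    if b is not None:
        full = full + b.data[None, :, None, None]
    prev = (x, w) + ((b,) if b is not None else ())
    out = Tensor(full, _prev=prev)

    def bw(g):
        gp = np.pad(g, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        dx = np.zeros_like(x.data) if x.requires_grad else None
        dw = np.zeros_like(w.data) if w.requires_grad else None
        for a in range(kh):
            for c in range(kw):
                sl = gp[:, :, a:a + (H - 1) * stride + 1:stride,
                        c:c + (W - 1) * stride + 1:stride]
                if dx is not None:
                    dx += np.einsum("nohw,co->nchw", sl, w.data[:, :, a, c],
                                    optimize=True)
                if dw is not None:
                    dw[:, :, a, c] += np.einsum("nchw,nohw->co", x.data, sl,
                                                optimize=True)
        if dx is not None:
            x._accum(dx)
        if dw is not None:
            w._accum(dw)
    out._backward = bw
    return out


def adaptive_avg_pool2d(x: Tensor, out_hw: int) -> Tensor:
    """Average pooling to an ``out_hw × out_hw`` grid (cells may be uneven)."""
    N, C, H, W = x.shape
    oh = ow = out_hw

    def edges(n, o):
        return [((i * n) // o, max(-(-((i + 1) * n) // o), (i * n) // o + 1))
                for i in range(o)]

    re, ce = edges(H, oh), edges(W, ow)
    out_data = np.empty((N, C, oh, ow))
    for i, (r0, r1) in enumerate(re):
        for j, (c0, c1) in enumerate(ce):
            out_data[:, :, i, j] = x.data[:, :, r0:r1, c0:c1].mean(axis=(2, 3))
    out = Tensor(out_data, _prev=(x,))

    def bw(g):
        if not x.requires_grad:
            return
        dx = np.zeros_like(x.data)
        for i, (r0, r1) in enumerate(re):
            for j, (c0, c1) in enumerate(ce):
                dx[:, :, r0:r1, c0:c1] += (g[:, :, i, j, None, None]
                                           / ((r1 - r0) * (c1 - c0)))
        x._accum(dx)
    out._backward = bw
    return out


def resize_nearest(x: Tensor, out_h: int, out_w: int) -> Tensor:
    """Nearest-neighbour resize to (out_h, out_w) (NCHW)."""
    N, C, H, W = x.shape
    ri = (np.arange(out_h) * H) // out_h
    ci = (np.arange(out_w) * W) // out_w
    out = Tensor(x.data[:, :, ri][:, :, :, ci], _prev=(x,))

    def bw(g):
        if not x.requires_grad:
            return
        gcols = np.zeros((N, C, out_h, W))
        np.add.at(gcols, (Ellipsis, ci), g)
        dx = np.zeros_like(x.data)
        np.add.at(dx.transpose(0, 1, 3, 2), (Ellipsis, ri),
                  gcols.transpose(0, 1, 3, 2))
        x._accum(dx)
    out._backward = bw
    return out
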