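"""A small reverse-mode automatic differentiation engine on numpy arrays.

The super-resolution network in this package is trained on CPU with plain
numpy; this module provides the tensor type and the differentiable
operations the architecture needs (dense/batched matmul, 2-D convolution via
im2col, windowed reshapes, softmax, layer norm, pooling, bilinear
resampling, gather).  Everything is float64 and deterministic.  Gradients
are checked against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import erf

__all__ = ["Tensor", "concat"]


def _as_array(x) -> np.ndarray:
    if isinstance(x, np.ndarray):
        return x.astype(np.float64, copy=False)
    return np.asarray(x, dtype=np.float64)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
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

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple = ()

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def item(self) -> float:
        return float(self.data)

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        # topological order
        topo, seen = [], set()
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
        self.grad = _as_array(grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, g: np.ndarray):
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    def zero_grad(self):
        self.grad = None

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = self._lift(other)
        a, b = self, other

        def bw(g):
            a._accum(_unbroadcast(g, a.shape))
            b._accum(_unbroadcast(g, b.shape))

        return self._make(a.data + b.data, (a, b), bw)

    __radd__ = __add__

    def __neg__(self):
        a = self
        return self._make(-a.data, (a,), lambda g: a._accum(-g))

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        a, b = self, other

        def bw(g):
            a._accum(_unbroadcast(g * b.data, a.shape))
            b._accum(_unbroadcast(g * a.data, b.shape))

        return self._make(a.data * b.data, (a, b), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        a, b = self, other

        def bw(g):
            a._accum(_unbroadcast(g / b.data, a.shape))
            b._accum(_unbroadcast(-g * a.data / (b.data ** 2), b.shape))

        return self._make(a.data / b.data, (a, b), bw)

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, p: float):
        a = self
        return self._make(
            a.data ** p, (a,), lambda g: a._accum(g * p * a.data ** (p - 1))
        )

    def exp(self):
        a = self
        out_data = np.exp(a.data)
        return self._make(out_data, (a,), lambda g: a._accum(g * out_data))

    def log(self):
        a = self
        return self._make(np.log(a.data), (a,), lambda g: a._accum(g / a.data))

    def sqrt(self):
        a = self
        out_data = np.sqrt(a.data)
        return self._make(out_data, (a,), lambda g: a._accum(g * 0.5 / out_data))

    def abs(self):
        a = self
        sign = np.sign(a.data)
        return self._make(np.abs(a.data), (a,), lambda g: a._accum(g * sign))

    # ------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims=False):
        a = self

        def bw(g):
            if axis is None:
                a._accum(np.broadcast_to(g, a.shape).copy())
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(g, axis if isinstance(axis, int) else tuple(axis))
            a._accum(np.broadcast_to(gg, a.shape).copy())

        return self._make(a.data.sum(axis=axis, keepdims=keepdims), (a,), bw)

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.shape[ax] for ax in axes]))
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def max(self, axis: int, keepdims=False):
        a = self
        out_data = a.data.max(axis=axis, keepdims=True)
        mask = (a.data == out_data)
        # distribute ties evenly so the subgradient stays bounded
        counts = mask.sum(axis=axis, keepdims=True)

        def bw(g):
            gg = g if keepdims else np.expand_dims(g, axis)
            a._accum(mask * (gg / counts))

        res = out_data if keepdims else np.squeeze(out_data, axis=axis)
        return self._make(res, (a,), bw)

    # ------------------------------------------------------------- structural
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        old = a.shape
        return self._make(
            a.data.reshape(shape), (a,), lambda g: a._accum(g.reshape(old))
        )

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        a = self
        inv = np.argsort(axes)
        return self._make(
            a.data.transpose(axes), (a,), lambda g: a._accum(g.transpose(inv))
        )

    def __getitem__(self, idx):
        a = self

        def bw(g):
            gx = np.zeros_like(a.data)
            gx[idx] = g
            a._accum(gx)

        return self._make(a.data[idx], (a,), bw)

    def roll(self, shift, axis):
        a = self
        if isinstance(shift, int):
            inv = -shift
        else:
            inv = tuple(-s for s in shift)
        return self._make(
            np.roll(a.data, shift, axis=axis),
            (a,),
            lambda g: a._accum(np.roll(g, inv, axis=axis)),
        )

    def pad2d(self, p: int, mode: str = "zeros"):
        """Pad the trailing two axes of an NCHW tensor by `p` on each side."""
        a = self
        n, c, h, w = a.shape
        spec = ((0, 0), (0, 0), (p, p), (p, p))
        if mode == "zeros":
            out_data = np.pad(a.data, spec)

            def bw(g):
                a._accum(g[:, :, p:p + h, p:p + w])

            return self._make(out_data, (a,), bw)
        if mode == "reflect":
            out_data = np.pad(a.data, spec, mode="reflect")
            idx = np.pad(np.arange(h * w).reshape(h, w), p, mode="reflect").ravel()

            def bw(g):
                g2 = g.reshape(n * c, -1)
                gx = np.zeros((n * c, h * w))
                np.add.at(gx, (np.arange(n * c)[:, None], idx[None, :]), g2)
                a._accum(gx.reshape(a.shape))

            return self._make(out_data, (a,), bw)
        raise ValueError(f"unknown pad mode {mode!r}")

    def pad_axis_zero(self, axis: int, before: int, after: int):
        a = self
        spec = [(0, 0)] * a.ndim
        spec[axis] = (before, after)
        sl = [slice(None)] * a.ndim
        sl[axis] = slice(before, before + a.shape[axis])
        sl = tuple(sl)
        return self._make(
            np.pad(a.data, spec), (a,), lambda g: a._accum(g[sl])
        )

    # ------------------------------------------------------------ activations
    def relu(self):
        a = self
        mask = a.data > 0
        return self._make(a.data * mask, (a,), lambda g: a._accum(g * mask))

    def sigmoid(self):
        a = self
        s = 1.0 / (1.0 + np.exp(-a.data))
        return self._make(s, (a,), lambda g: a._accum(g * s * (1 - s)))

    def gelu(self):
        a = self
        x = a.data
        cdf = 0.5 * (1.0 + erf(x / np.sqrt(2.0)))
        pdf = np.exp(-0.5 * x * x) / np.sqrt(2.0 * np.pi)
        return self._make(x * cdf, (a,), lambda g: a._accum(g * (cdf + x * pdf)))

    def softmax(self, axis: int = -1):
        a = self
        z = a.data - a.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)

        def bw(g):
            a._accum(s * (g - (g * s).sum(axis=axis, keepdims=True)))

        return self._make(s, (a,), bw)

    # ---------------------------------------------------------------- algebra
    def matmul(self, other: "Tensor"):
        other = self._lift(other)
        a, b = self, other

        def bw(g):
            ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
            gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
            a._accum(_unbroadcast(ga, a.shape))
            b._accum(_unbroadcast(gb, b.shape))

        return self._make(np.matmul(a.data, b.data), (a, b), bw)

    __matmul__ = matmul

    def take0(self, idx: np.ndarray):
        """Gather along axis 0 with an integer index array (e.g. bias tables)."""
        a = self

        def bw(g):
            gt = np.zeros_like(a.data)
            np.add.at(gt, idx, g)
            a._accum(gt)

        return self._make(a.data[idx], (a,), bw)

    # --------------------------------------------------------------- fused nn
    def layernorm(self, gamma: "Tensor", beta: "Tensor", eps: float = 1e-5):
        """Layer normalisation over the last axis."""
        a, g_, b_ = self, gamma, beta
        mu = a.data.mean(axis=-1, keepdims=True)
        var = a.data.var(axis=-1, keepdims=True)
        std = np.sqrt(var + eps)
        xhat = (a.data - mu) / std

        def bw(g):
            red = tuple(range(a.ndim - 1))
            g_._accum((g * xhat).sum(axis=red))
            b_._accum(g.sum(axis=red))
            gm = g * g_.data
            m1 = gm.mean(axis=-1, keepdims=True)
            m2 = (gm * xhat).mean(axis=-1, keepdims=True)
            a._accum((gm - m1 - xhat * m2) / std)

        return self._make(xhat * g_.data + b_.data, (a, g_, b_), bw)

    def conv2d(self, w: "Tensor", b: "Tensor | None", padding: int = 0,
               pad_mode: str = "zeros"):
        """2-D convolution (cross-correlation), stride 1, NCHW layout."""
        x = self
        if padding > 0:
            x = x.pad2d(padding, mode=pad_mode)
        a = x
        n, c, hp, wp = a.shape
        co, ci, kh, kw = w.shape
        if ci != c:
            raise ValueError(f"conv2d channel mismatch: input {c}, weight {ci}")
        ho, wo = hp - kh + 1, wp - kw + 1
        win = sliding_window_view(a.data, (kh, kw), axis=(2, 3))  # n,c,ho,wo,kh,kw
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n, ho * wo, c * kh * kw)
        wmat = w.data.reshape(co, -1)
        out_data = cols @ wmat.T  # n, L, co
        if b is not None:
            out_data = out_data + b.data
        out_data = out_data.reshape(n, ho, wo, co).transpose(0, 3, 1, 2)
        parents = (a, w) if b is None else (a, w, b)

        def bw(g):
            g2 = g.transpose(0, 2, 3, 1).reshape(n, ho * wo, co)
            if b is not None:
                b._accum(g2.sum(axis=(0, 1)))
            gw = np.einsum("nlc,nlk->ck", g2, cols).reshape(w.shape)
            w._accum(gw)
            dcols = (g2 @ wmat).reshape(n, ho, wo, c, kh, kw).transpose(0, 3, 4, 5, 1, 2)
            gx = np.zeros_like(a.data)
            for i in range(kh):
                for j in range(kw):
                    gx[:, :, i:i + ho, j:j + wo] += dcols[:, :, i, j]
            a._accum(gx)

        return self._make(out_data, parents, bw)

    def avg_pool2d(self, k: int):
        n, c, h, w = self.shape
        if h % k or w % k:
            raise ValueError("avg_pool2d requires divisible spatial dims")
        return (self.reshape(n, c, h // k, k, w // k, k).mean(axis=(3, 5)))

    def max_pool2d(self, k: int):
        n, c, h, w = self.shape
        if h % k or w % k:
            raise ValueError("max_pool2d requires divisible spatial dims")
        return self.reshape(n, c, h // k, k, w // k, k).max(axis=5).max(axis=3)

    def pixel_shuffle(self, r: int):
        n, crr, h, w = self.shape
        c = crr // (r * r)
        if c * r * r != crr:
            raise ValueError("channel count not divisible by r^2")
        x = self.reshape(n, c, r, r, h, w)
        x = x.transpose(0, 1, 4, 2, 5, 3)
        return x.reshape(n, c, h * r, w * r)

    def upsample_bilinear(self, factor: int):
        """Bilinear upsampling by an integer factor (align_corners=False)."""
        a = self
        n, c, h, w = a.shape

        def make_idx(size, f):
            out = np.arange(size * f)
            src = (out + 0.5) / f - 0.5
            i0 = np.clip(np.floor(src).astype(int), 0, size - 1)
            i1 = np.clip(i0 + 1, 0, size - 1)
            t = np.clip(src - np.floor(src), 0.0, 1.0)
            t[src < 0] = 0.0
            t[src > size - 1] = 0.0
            return i0, i1, t

        i0, i1, th = make_idx(h, factor)
        j0, j1, tw = make_idx(w, factor)
        thc = th[:, None]
        tmp = a.data[:, :, i0, :] * (1 - thc) + a.data[:, :, i1, :] * thc
        out_data = tmp[:, :, :, j0] * (1 - tw) + tmp[:, :, :, j1] * tw

        def bw(g):
            gtmp = np.zeros((n, c, h * factor, w))
            np.add.at(gtmp, (slice(None), slice(None), slice(None), j0), g * (1 - tw))
            np.add.at(gtmp, (slice(None), slice(None), slice(None), j1), g * tw)
            gx = np.zeros_like(a.data)
            np.add.at(gx, (slice(None), slice(None), i0, slice(None)), gtmp * (1 - thc))
            np.add.at(gx, (slice(None), slice(None), i1, slice(None)), gtmp * thc)
            a._accum(gx)

        return self._make(out_data, (a,), bw)


def concat(tensors: list, axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)
    out_data = np.concatenate([t.data for t in tensors], axis=axis)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t._accum(g[tuple(sl)])

    out = Tensor(out_data)
    if any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._parents = tuple(tensors)
        out._backward = bw
    return out
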