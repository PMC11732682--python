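"""Minimal reverse-mode automatic differentiation on numpy arrays.

The registration model needs gradients through 3-D convolutions, trilinear
warping (the spatial-transformer sampler), window-sum filters (for local
normalized cross-correlation) and finite differences (for the smoothness
penalty).  This module provides exactly those primitives as a small tape:
each op returns a :class:`Tensor` holding the forward value and a closure
that scatters the incoming gradient to its parents.  ``Tensor.backward()``
runs the closures in reverse topological order.

Float32 is used throughout for speed; callers that need tighter numerics
(e.g. oracle comparisons) should pass float64 arrays — dtypes are preserved.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi

__all__ = [
    "Tensor", "as_tensor", "add", "sub", "mul", "div", "neg", "scale",
    "leaky_relu", "concat", "tsum", "tmean", "crop3", "fdiff",
    "conv3d", "upsample2_linear", "box_sum", "warp3d",
]


class Tensor:
    """A node in the computation graph: value, gradient, backward closure."""

    __slots__ = ("data", "grad", "parents", "_backward", "requires_grad")

    def __init__(self, data, parents=(), backward=None, requires_grad=None):
        self.data = np.asarray(data)
        self.parents = tuple(parents)
        self._backward = backward
        if requires_grad is None:
            requires_grad = any(p.requires_grad for p in self.parents)
        self.requires_grad = requires_grad
        self.grad = None

    @property
    def shape(self):
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    def accumulate(self, g):
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self):
        """Backpropagate from this (scalar) tensor through the tape."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        order: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                order.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node.parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def as_tensor(x, requires_grad=False) -> Tensor:
    if isinstance(x, Tensor):
        return x
    return Tensor(np.asarray(x), requires_grad=requires_grad)


def parameter(x) -> Tensor:
    return Tensor(np.asarray(x), requires_grad=True)


# ---------------------------------------------------------------- elementwise

def add(a, b):
    a, b = as_tensor(a), as_tensor(b)
    out = Tensor(a.data + b.data, (a, b))

    def bw(g):
        if a.requires_grad:
            a.accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b.accumulate(_unbroadcast(g, b.data.shape))
    out._backward = bw
    return out


def sub(a, b):
    return add(a, neg(b))


def neg(a):
    a = as_tensor(a)
    out = Tensor(-a.data, (a,))

    def bw(g):
        if a.requires_grad:
            a.accumulate(-g)
    out._backward = bw
    return out


def mul(a, b):
    a, b = as_tensor(a), as_tensor(b)
    out = Tensor(a.data * b.data, (a, b))

    def bw(g):
        if a.requires_grad:
            a.accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b.accumulate(_unbroadcast(g * a.data, b.data.shape))
    out._backward = bw
    return out


def div(a, b):
    a, b = as_tensor(a), as_tensor(b)
    out = Tensor(a.data / b.data, (a, b))

    def bw(g):
        if a.requires_grad:
            a.accumulate(_unbroadcast(g / b.data, a.data.shape))
        if b.requires_grad:
            b.accumulate(_unbroadcast(-g * a.data / (b.data * b.data),
                                      b.data.shape))
    out._backward = bw
    return out


def scale(a, c: float):
    a = as_tensor(a)
    out = Tensor(a.data * c, (a,))

    def bw(g):
        if a.requires_grad:
            a.accumulate(g * c)
    out._backward = bw
    return out


def leaky_relu(a, slope: float = 0.2):
    a = as_tensor(a)
    mask = a.data > 0
    out = Tensor(np.where(mask, a.data, a.data * slope), (a,))

    def bw(g):
        if a.requires_grad:
            a.accumulate(np.where(mask, g, g * slope))
    out._backward = bw
    return out


def _unbroadcast(g, shape):
    """Sum g down to `shape` (inverse of numpy broadcasting)."""
    if g.shape == shape:
        return g
    nd = g.ndim - len(shape)
    if nd > 0:
        g = g.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g.reshape(shape)


# ---------------------------------------------------------------- reductions

def tsum(a):
    a = as_tensor(a)
    out = Tensor(np.asarray(a.data.sum()), (a,))

    def bw(g):
        if a.requires_grad:
            a.accumulate(np.broadcast_to(g, a.data.shape))
    out._backward = bw
    return out


def tmean(a):
    a = as_tensor(a)
    n = a.data.size
    out = Tensor(np.asarray(a.data.mean()), (a,))

    def bw(g):
        if a.requires_grad:
            a.accumulate(np.broadcast_to(g / n, a.data.shape))
    out._backward = bw
    return out


# ----------------------------------------------------------- shape / slicing

def concat(tensors, axis=0):
    ts = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in ts], axis=axis), ts)
    sizes = [t.data.shape[axis] for t in ts]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(ts, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t.accumulate(g[tuple(sl)])
    out._backward = bw
    return out


def crop3(a, r: int):
    """Crop the trailing three axes by r voxels on every side."""
    a = as_tensor(a)
    if r == 0:
        return a
    sl = (Ellipsis, slice(r, -r), slice(r, -r), slice(r, -r))
    out = Tensor(a.data[sl], (a,))

    def bw(g):
        if a.requires_grad:
            full = np.zeros_like(a.data)
            full[sl] = g
            a.accumulate(full)
    out._backward = bw
    return out


def fdiff(a, axis: int):
    """Forward difference along `axis` (output one shorter on that axis)."""
    a = as_tensor(a)
    nd = a.data.ndim
    hi = [slice(None)] * nd
    lo = [slice(None)] * nd
    hi[axis] = slice(1, None)
    lo[axis] = slice(None, -1)
    hi, lo = tuple(hi), tuple(lo)
    out = Tensor(a.data[hi] - a.data[lo], (a,))

    def bw(g):
        if a.requires_grad:
            full = np.zeros_like(a.data)
            full[hi] += g
            full[lo] -= g
            a.accumulate(full)
    out._backward = bw
    return out


# -------------------------------------------------------------- convolution

_COL_INDEX_CACHE: dict = {}


def _col_indices(cin, shape, k, stride, pad):
    """Flat indices into the zero-padded input for im2col, cached."""
    key = (cin, shape, k, stride, pad)
    hit = _COL_INDEX_CACHE.get(key)
    if hit is not None:
        return hit
    D, H, W = shape
    Dp, Hp, Wp = D + 2 * pad, H + 2 * pad, W + 2 * pad
    od = (Dp - k) // stride + 1
    oh = (Hp - k) // stride + 1
    ow = (Wp - k) // stride + 1
    d0 = np.arange(od) * stride
    h0 = np.arange(oh) * stride
    w0 = np.arange(ow) * stride
    kd, kh, kw = np.meshgrid(np.arange(k), np.arange(k), np.arange(k),
                             indexing="ij")
    # voxel index within padded channel
    dd = d0[:, None, None, None] + kd.ravel()[None, None, None, :]
    hh = h0[None, :, None, None] + kh.ravel()[None, None, None, :]
    ww = w0[None, None, :, None] + kw.ravel()[None, None, None, :]
    vox = (dd * Hp + hh) * Wp + ww          # (od, oh, ow, k^3)
    vox = vox.reshape(-1, k ** 3)
    chan = np.arange(cin) * (Dp * Hp * Wp)
    idx = (chan[None, :, None] + vox[:, None, :]).reshape(
        vox.shape[0], cin * k ** 3).astype(np.int64)
    out = (idx, (od, oh, ow), (Dp, Hp, Wp))
    _COL_INDEX_CACHE[key] = out
    return out


def conv3d(x, w, b, stride: int = 1, pad: int = 1):
    """3-D convolution (cross-correlation): x (Cin,D,H,W) -> (Cout,do,dh,dw)."""
    x, w, b = as_tensor(x), as_tensor(w), as_tensor(b)
    cin = x.data.shape[0]
    k = w.data.shape[-1]
    idx, oshape, pshape = _col_indices(cin, x.data.shape[1:], k, stride, pad)
    if pad:
        xp = np.zeros((cin,) + pshape, dtype=x.data.dtype)
        xp[:, pad:-pad, pad:-pad, pad:-pad] = x.data
    else:
        xp = x.data
    cols = xp.reshape(-1)[idx]                     # (nvox, cin*k^3)
    wmat = w.data.reshape(w.data.shape[0], -1)     # (cout, cin*k^3)
    out_mat = cols @ wmat.T + b.data               # (nvox, cout)
    out = Tensor(out_mat.T.reshape((w.data.shape[0],) + oshape), (x, w, b))

    def bw(g):
        gmat = g.reshape(g.shape[0], -1).T         # (nvox, cout)
        if b.requires_grad:
            b.accumulate(gmat.sum(axis=0))
        if w.requires_grad:
            w.accumulate((gmat.T @ cols).reshape(w.data.shape))
        if x.requires_grad:
            gcols = gmat @ wmat                    # (nvox, cin*k^3)
            gxp = np.zeros(cin * pshape[0] * pshape[1] * pshape[2],
                           dtype=x.data.dtype)
            np.add.at(gxp, idx.ravel(), gcols.ravel())
            gxp = gxp.reshape((cin,) + pshape)
            if pad:
                gxp = gxp[:, pad:-pad, pad:-pad, pad:-pad]
            x.accumulate(gxp)
    out._backward = bw
    return out


# ------------------------------------------------------------- interpolation

_UP_WEIGHT_CACHE: dict = {}


def _up_matrix(n: int, dtype):
    """(2n, n) linear-interpolation matrix, endpoints aligned."""
    key = (n, np.dtype(dtype).name)
    w = _UP_WEIGHT_CACHE.get(key)
    if w is None:
        m = 2 * n
        src = np.arange(m) * (n - 1) / (m - 1)
        lo = np.floor(src).astype(int)
        hi = np.minimum(lo + 1, n - 1)
        frac = src - lo
        w = np.zeros((m, n), dtype=dtype)
        w[np.arange(m), lo] += 1 - frac
        w[np.arange(m), hi] += frac
        _UP_WEIGHT_CACHE[key] = w
    return w


def upsample2_linear(x):
    """Trilinear 2x upsampling of (C,D,H,W) with aligned endpoints."""
    x = as_tensor(x)
    mats = [_up_matrix(n, x.data.dtype) for n in x.data.shape[1:]]

    def apply(arr, transpose=False):
        for ax, m in enumerate(mats, start=1):
            mm = m.T if transpose else m
            arr = np.moveaxis(np.tensordot(mm, arr, axes=(1, ax)), 0, ax)
        return arr

    out = Tensor(apply(x.data), (x,))

    def bw(g):
        if x.requires_grad:
            x.accumulate(apply(g, transpose=True))
    out._backward = bw
    return out


def box_sum(x, d: int):
    """Sum over the centered d^3 window (zero outside) on trailing 3 axes.

    Self-adjoint for odd d, so the backward pass is the same filter.
    """
    x = as_tensor(x)
    kernel = np.ones(d, dtype=x.data.dtype)

    def filt(arr):
        for ax in range(arr.ndim - 3, arr.ndim):
            arr = ndi.correlate1d(arr, kernel, axis=ax, mode="constant")
        return arr

    out = Tensor(filt(x.data), (x,))

    def bw(g):
        if x.requires_grad:
            x.accumulate(filt(g))
    out._backward = bw
    return out


def warp3d(img, field):
    """Trilinear resampling: out(x) = img(x + field(x)), border-clamped.

    img: (C, D, H, W); field: (3, D, H, W) displacements in voxels.
    Differentiable in both arguments (field gradient is zero where the
    sample point is clamped to the domain boundary).
    """
    img, field = as_tensor(img), as_tensor(field)
    C = img.data.shape[0]
    D, H, W = img.data.shape[1:]
    base = np.indices((D, H, W), dtype=field.data.dtype)
    coords = base + field.data
    lims = np.array([D - 1, H - 1, W - 1], dtype=field.data.dtype)
    clamped = coords > lims.reshape(3, 1, 1, 1)
    clamped |= coords < 0
    np.clip(coords, 0, lims.reshape(3, 1, 1, 1), out=coords)
    lo = np.floor(coords).astype(np.int64)
    np.clip(lo, 0, (lims - 1).astype(np.int64).reshape(3, 1, 1, 1), out=lo)
    frac = coords - lo
    fz, fy, fx = frac
    flat = img.data.reshape(C, -1)
    strides = np.array([H * W, W, 1])

    corner_idx = []
    corner_w = []
    for dz in (0, 1):
        for dy in (0, 1):
            for dx in (0, 1):
                iz, iy, ix = lo[0] + dz, lo[1] + dy, lo[2] + dx
                corner_idx.append((iz * H + iy) * W + ix)
                wz = fz if dz else 1 - fz
                wy = fy if dy else 1 - fy
                wx = fx if dx else 1 - fx
                corner_w.append(wz * wy * wx)

    vals = [flat[:, ci.ravel()].reshape(C, D, H, W) for ci in corner_idx]
    out_data = np.zeros_like(img.data)
    for v, wgt in zip(vals, corner_w):
        out_data += v * wgt
    out = Tensor(out_data, (img, field))

    def bw(g):
        if img.requires_grad:
            gimg = np.zeros_like(flat)
            for ci, wgt in zip(corner_idx, corner_w):
                np.add.at(gimg.T, ci.ravel(),
                          (g * wgt).reshape(C, -1).T)
            img.accumulate(gimg.reshape(img.data.shape))
        if field.requires_grad:
            # derivative of the trilinear interpolant w.r.t. each coordinate
            gz = np.zeros((D, H, W), dtype=g.dtype)
            gy = np.zeros((D, H, W), dtype=g.dtype)
            gx = np.zeros((D, H, W), dtype=g.dtype)
            i = 0
            for dz in (0, 1):
                for dy in (0, 1):
                    for dx in (0, 1):
                        v = vals[i]
                        sz = 1.0 if dz else -1.0
                        sy = 1.0 if dy else -1.0
                        sx = 1.0 if dx else -1.0
                        wz = fz if dz else 1 - fz
                        wy = fy if dy else 1 - fy
                        wx = fx if dx else 1 - fx
                        gv = (g * v).sum(axis=0)
                        gz += gv * sz * wy * wx
                        gy += gv * wz * sy * wx
                        gx += gv * wz * wy * sx
                        i += 1
            gfield = np.stack([gz, gy, gx])
            gfield[clamped] = 0.0
            field.accumulate(gfield)
    out._backward = bw
    return out
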