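"""2-D convolution primitives with autograd hooks.

Patches are gathered/scattered in channel-major layout (C, k, k, N, H, W)
by numba kernels so each convolution reduces to ONE large GEMM — on a
single core that runs close to BLAS peak, unlike a loop of small batched
matmuls.  Transposed convolution is the data-gradient of convolution and
shares the same helpers.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor

try:  # numba accelerates the gather/scatter ~5-10x; NumPy slicing is the fallback
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*a, **k):
        def deco(f):
            return f

        return deco


__all__ = ["conv2d", "conv_transpose2d"]


@njit(cache=True)
def _gather_kernel(xpad, k, stride, out):
    # out layout: (C, k, k, N, Ho, Wo)
    n, c = xpad.shape[0], xpad.shape[1]
    ho, wo = out.shape[4], out.shape[5]
    for cc in range(c):
        for i in range(k):
            for j in range(k):
                for nn in range(n):
                    for y in range(ho):
                        base = i + stride * y
                        for x in range(wo):
                            out[cc, i, j, nn, y, x] = xpad[nn, cc, base, j + stride * x]


@njit(cache=True)
def _scatter_kernel(cols, k, stride, buf):
    # cols layout: (C, k, k, N, Ho, Wo); buf: (N, C, Hp, Wp)
    n, c = buf.shape[0], buf.shape[1]
    ho, wo = cols.shape[4], cols.shape[5]
    for cc in range(c):
        for i in range(k):
            for j in range(k):
                for nn in range(n):
                    for y in range(ho):
                        base = i + stride * y
                        for x in range(wo):
                            buf[nn, cc, base, j + stride * x] += cols[cc, i, j, nn, y, x]


def _gather(xpad: np.ndarray, k: int, stride: int, ho: int, wo: int) -> np.ndarray:
    n, c = xpad.shape[:2]
    out = np.empty((c, k, k, n, ho, wo), dtype=xpad.dtype)
    if _HAVE_NUMBA:
        _gather_kernel(np.ascontiguousarray(xpad), k, stride, out)
        return out
    for i in range(k):
        for j in range(k):
            out[:, i, j] = xpad[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride].transpose(
                1, 0, 2, 3
            )
    return out


def _scatter(cols: np.ndarray, k: int, stride: int, n: int, c: int, hp: int, wp: int) -> np.ndarray:
    buf = np.zeros((n, c, hp, wp), dtype=cols.dtype)
    ho, wo = cols.shape[-2:]
    if _HAVE_NUMBA:
        _scatter_kernel(np.ascontiguousarray(cols), k, stride, buf)
        return buf
    for i in range(k):
        for j in range(k):
            buf[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += cols[
                :, i, j
            ].transpose(1, 0, 2, 3)
    return buf


def _pad(x: np.ndarray, p: int) -> np.ndarray:
    if p == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1, padding: int = 0) -> Tensor:
    """Cross-correlation of NCHW input with OIkk weights."""
    n, c, h, wd = x.data.shape
    o, ci, k, k2 = w.data.shape
    if ci != c or k != k2:
        raise ValueError(f"weight shape {w.data.shape} incompatible with input {x.data.shape}")
    ho = (h + 2 * padding - k) // stride + 1
    wo = (wd + 2 * padding - k) // stride + 1
    if ho < 1 or wo < 1:
        raise ValueError("convolution output would be empty")
    patches = _gather(_pad(x.data, padding), k, stride, ho, wo)
    pmat = patches.reshape(c * k * k, n * ho * wo)
    w2 = w.data.reshape(o, c * k * k)
    y = np.ascontiguousarray((w2 @ pmat).reshape(o, n, ho, wo).transpose(1, 0, 2, 3))
    if b is not None:
        y += b.data.reshape(1, o, 1, 1)
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(y, parents=parents)

    def backward(g):
        g2 = np.ascontiguousarray(g.transpose(1, 0, 2, 3)).reshape(o, n * ho * wo)
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if w.requires_grad:
            w._accum((g2 @ pmat.T).reshape(w.data.shape))
        if x.requires_grad:
            dcols = (w2.T @ g2).reshape(c, k, k, n, ho, wo)
            dxpad = _scatter(dcols, k, stride, n, c, h + 2 * padding, wd + 2 * padding)
            if padding:
                dxpad = dxpad[:, :, padding:-padding, padding:-padding]
            x._accum(dxpad)

    out._backward = backward
    return out


def conv_transpose2d(
    x: Tensor,
    w: Tensor,
    b: Tensor | None,
    stride: int = 2,
    padding: int = 1,
    output_padding: int = 0,
) -> Tensor:
    """Transposed convolution; weights are IOkk (input-channel major).

    Output side = stride*(H-1) + k - 2*padding + output_padding, with
    output_padding <= padding.
    """
    n, c, h, wd = x.data.shape
    ci, o, k, k2 = w.data.shape
    if ci != c or k != k2:
        raise ValueError(f"weight shape {w.data.shape} incompatible with input {x.data.shape}")
    if output_padding > padding:
        raise ValueError("output_padding must not exceed padding")
    hb, wb = stride * (h - 1) + k, stride * (wd - 1) + k
    crop_lo, crop_hi = padding, padding - output_padding
    w2 = w.data.reshape(c, o * k * k)
    x2 = np.ascontiguousarray(x.data.transpose(1, 0, 2, 3)).reshape(c, n * h * wd)
    cols = (w2.T @ x2).reshape(o, k, k, n, h, wd)
    buf = _scatter(cols, k, stride, n, o, hb, wb)
    y = np.ascontiguousarray(buf[:, :, crop_lo : hb - crop_hi, crop_lo : wb - crop_hi])
    if b is not None:
        y += b.data.reshape(1, o, 1, 1)
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(y, parents=parents)

    def backward(g):
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        gbuf = np.pad(g, ((0, 0), (0, 0), (crop_lo, crop_hi), (crop_lo, crop_hi)))
        gcols = _gather(gbuf, k, stride, h, wd).reshape(o * k * k, n * h * wd)
        if w.requires_grad:
            w._accum((x2 @ gcols.T).reshape(w.data.shape))
        if x.requires_grad:
            dx2 = (w2 @ gcols).reshape(c, n, h, wd)
            x._accum(np.ascontiguousarray(dx2.transpose(1, 0, 2, 3)))

    out._backward = backward
    return out
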