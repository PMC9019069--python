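"""Spatial operations: convolution, pooling and upsampling.

Convolution is implemented by im2col (patch extraction with strided slicing)
followed by a batched matrix product, which keeps both the forward and the
backward pass inside numpy's BLAS.  All tensors use the NCHW layout.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor

__all__ = ["conv2d", "max_pool2d", "avg_pool2d", "global_avg_pool", "upsample_nearest2x"]


def _out_size(size: int, k: int, s: int, p: int) -> int:
    return (size + 2 * p - k) // s + 1


def _im2col(x: np.ndarray, kh: int, kw: int, sh: int, sw: int, ph: int, pw: int):
    """Return patches of shape (N, C, kh, kw, Ho, Wo)."""
    if ph or pw:
        x = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    n, c, h, w = x.shape
    ho, wo = (h - kh) // sh + 1, (w - kw) // sw + 1
    cols = np.empty((n, c, kh, kw, ho, wo), dtype=x.dtype)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, i, j] = x[:, :, i : i + sh * ho : sh, j : j + sw * wo : sw]
    return cols, ho, wo


def _col2im(gcols: np.ndarray, shape, kh, kw, sh, sw, ph, pw) -> np.ndarray:
    """Scatter-add patch gradients back onto the (padded) image grid."""
    n, c, h, w = shape
    gx = np.zeros((n, c, h + 2 * ph, w + 2 * pw), dtype=gcols.dtype)
    ho, wo = gcols.shape[-2:]
    for i in range(kh):
        for j in range(kw):
            gx[:, :, i : i + sh * ho : sh, j : j + sw * wo : sw] += gcols[:, :, i, j]
    if ph or pw:
        gx = gx[:, :, ph : ph + h, pw : pw + w]
    return gx


def conv2d(
    x: Tensor,
    weight: Tensor,
    bias: Tensor | None = None,
    stride: int = 1,
    padding: int = 0,
    groups: int = 1,
) -> Tensor:
    """2-D cross-correlation. ``weight`` has shape (Cout, Cin/groups, kh, kw)."""
    n, cin, h, w = x.data.shape
    cout, cin_g, kh, kw = weight.data.shape
    if cin != cin_g * groups:
        raise ValueError(f"channel mismatch: input {cin}, weight expects {cin_g * groups}")
    cols, ho, wo = _im2col(x.data, kh, kw, stride, stride, padding, padding)
    if groups == 1:
        flat = cols.reshape(n, cin * kh * kw, ho * wo)
        wmat = weight.data.reshape(cout, -1)
        out = np.matmul(wmat[None], flat)
    else:
        cg, og = cin // groups, cout // groups
        flat = cols.reshape(n, groups, cg * kh * kw, ho * wo)
        wmat = weight.data.reshape(groups, og, cg * kh * kw)
        out = np.matmul(wmat[None], flat).reshape(n, cout, ho * wo)
        flat = flat.reshape(n, groups * cg * kh * kw, ho * wo)
    out = out.reshape(n, cout, ho, wo)
    if bias is not None:
        out = out + bias.data.reshape(1, cout, 1, 1)

    def backward(g):
        gflat = g.reshape(n, cout, ho * wo)
        if groups == 1:
            if weight.requires_grad:
                gw = np.matmul(gflat, flat.transpose(0, 2, 1)).sum(0)
                weight._accumulate(gw.reshape(weight.data.shape))
            if x.requires_grad:
                gcols = np.matmul(wmat.T[None], gflat)
        else:
            gflat_g = gflat.reshape(n, groups, og, ho * wo)
            flat_g = flat.reshape(n, groups, cg * kh * kw, ho * wo)
            if weight.requires_grad:
                gw = np.matmul(gflat_g, flat_g.transpose(0, 1, 3, 2)).sum(0)
                weight._accumulate(gw.reshape(weight.data.shape))
            if x.requires_grad:
                gcols = np.matmul(wmat.transpose(0, 2, 1)[None], gflat_g)
        if x.requires_grad:
            gcols = gcols.reshape(n, cin, kh, kw, ho, wo)
            x._accumulate(_col2im(gcols, x.data.shape, kh, kw, stride, stride, padding, padding))
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3)))

    parents = (x, weight) if bias is None else (x, weight, bias)
    return Tensor._from_op(out, parents, backward)


def max_pool2d(x: Tensor, kernel: int, stride: int | None = None, padding: int = 0) -> Tensor:
    stride = stride or kernel
    n, c = x.data.shape[:2]
    if padding:
        # pad with -inf so padded cells never win the max
        xp = np.pad(x.data, ((0, 0), (0, 0), (padding,) * 2, (padding,) * 2),
                    constant_values=-np.inf)
        cols, ho, wo = _im2col(xp, kernel, kernel, stride, stride, 0, 0)
    else:
        cols, ho, wo = _im2col(x.data, kernel, kernel, stride, stride, 0, 0)
    flat = cols.reshape(n, c, kernel * kernel, ho, wo)
    arg = flat.argmax(axis=2)
    out = np.take_along_axis(flat, arg[:, :, None], axis=2)[:, :, 0]

    def backward(g):
        gcols = np.zeros_like(flat)
        np.put_along_axis(gcols, arg[:, :, None], g[:, :, None], axis=2)
        gcols = gcols.reshape(n, c, kernel, kernel, ho, wo)
        x._accumulate(
            _col2im(gcols, x.data.shape, kernel, kernel, stride, stride, padding, padding)
        )

    return Tensor._from_op(out, (x,), backward)


def avg_pool2d(x: Tensor, kernel: int, stride: int | None = None, padding: int = 0) -> Tensor:
    stride = stride or kernel
    cols, ho, wo = _im2col(x.data, kernel, kernel, stride, stride, padding, padding)
    n, c = x.data.shape[:2]
    out = cols.reshape(n, c, kernel * kernel, ho, wo).mean(axis=2)
    scale = 1.0 / (kernel * kernel)

    def backward(g):
        gcols = np.broadcast_to(
            (g * scale)[:, :, None, None], (n, c, kernel, kernel, ho, wo)
        ).copy()
        x._accumulate(
            _col2im(gcols, x.data.shape, kernel, kernel, stride, stride, padding, padding)
        )

    return Tensor._from_op(out, (x,), backward)


def global_avg_pool(x: Tensor) -> Tensor:
    """Mean over the spatial grid, keeping (N, C)."""
    return x.mean(axis=(2, 3))


def upsample_nearest2x(x: Tensor) -> Tensor:
    out = x.data.repeat(2, axis=2).repeat(2, axis=3)

    def backward(g):
        n, c, h2, w2 = g.shape
        x._accumulate(g.reshape(n, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5)))

    return Tensor._from_op(out, (x,), backward)
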