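"""Convolutional / pooling / normalization primitives with hand-derived backwards.

All spatial operators work on (N, C, H, W) arrays.  Convolution is implemented
by an im2col view (numpy stride tricks) followed by a BLAS contraction; its
gradient scatters through the same window geometry.  Each primitive's backward
is verified against numerical differentiation in the test suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import as_strided

from .tensor import Tensor

__all__ = [
    "conv2d",
    "conv_transpose2d",
    "max_pool2d",
    "avg_pool2d",
    "upsample_bilinear",
    "batch_norm",
    "bce_with_logits",
]


def _pad_hw(x: np.ndarray, p: int, value: float = 0.0) -> np.ndarray:
    if p == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)), constant_values=value)


def _windows(xp: np.ndarray, kh: int, kw: int, stride: int, dilation: int) -> np.ndarray:
    """Read-only (N, C, OH, OW, kh, kw) view of sliding dilated windows."""
    n, c, h, w = xp.shape
    oh = (h - dilation * (kh - 1) - 1) // stride + 1
    ow = (w - dilation * (kw - 1) - 1) // stride + 1
    sn, sc, sh, sw = xp.strides
    return as_strided(
        xp,
        shape=(n, c, oh, ow, kh, kw),
        strides=(sn, sc, sh * stride, sw * stride, sh * dilation, sw * dilation),
        writeable=False,
    )


def conv2d(
    x: Tensor,
    weight: Tensor,
    bias: Tensor | None = None,
    stride: int = 1,
    padding: int = 0,
    dilation: int = 1,
) -> Tensor:
    """2-D convolution (cross-correlation); weight is (O, C, kh, kw)."""
    o, c, kh, kw = weight.shape
    if x.shape[1] != c:
        raise ValueError(f"conv2d channel mismatch: input {x.shape[1]}, weight {c}")
    if kh == kw == 1 and stride == 1 and padding == 0:
        return _conv2d_1x1(x, weight, bias)
    xp = _pad_hw(x.data, padding)
    win = _windows(xp, kh, kw, stride, dilation)
    out = np.tensordot(win, weight.data, axes=([1, 4, 5], [1, 2, 3]))  # (N,OH,OW,O)
    out = np.ascontiguousarray(out.transpose(0, 3, 1, 2))
    if bias is not None:
        out += bias.data[None, :, None, None]
    parents = (x, weight) if bias is None else (x, weight, bias)
    n, _, oh, ow = out.shape

    def backward(g):
        if weight.requires_grad:
            gw = np.tensordot(g, win, axes=([0, 2, 3], [0, 2, 3]))  # (O,C,kh,kw)
            weight._accumulate(gw.astype(weight.dtype, copy=False))
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3)).astype(bias.dtype, copy=False))
        if x.requires_grad:
            # (N,OH,OW,C,kh,kw) contributions, scattered back through the windows
            gcol = np.tensordot(g, weight.data, axes=([1], [0]))
            gx = np.zeros_like(xp)
            for i in range(kh):
                hi = slice(i * dilation, i * dilation + oh * stride, stride)
                for j in range(kw):
                    wj = slice(j * dilation, j * dilation + ow * stride, stride)
                    gx[:, :, hi, wj] += gcol[:, :, :, :, i, j].transpose(0, 3, 1, 2)
            if padding:
                gx = gx[:, :, padding:-padding, padding:-padding]
            x._accumulate(gx.astype(x.dtype, copy=False))

    return Tensor._make(out, parents, backward)


def _conv2d_1x1(x: Tensor, weight: Tensor, bias: Tensor | None) -> Tensor:
    """Pointwise convolution: a single channel contraction, no window copies."""
    w = weight.data[:, :, 0, 0]  # (O, C)
    out = np.tensordot(x.data, w, axes=([1], [1])).transpose(0, 3, 1, 2)
    if bias is not None:
        out = out + bias.data[None, :, None, None]
    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        if weight.requires_grad:
            gw = np.tensordot(g, x.data, axes=([0, 2, 3], [0, 2, 3]))  # (O, C)
            weight._accumulate(gw[:, :, None, None].astype(weight.dtype, copy=False))
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3)).astype(bias.dtype, copy=False))
        if x.requires_grad:
            gx = np.tensordot(g, w, axes=([1], [0])).transpose(0, 3, 1, 2)
            x._accumulate(gx.astype(x.dtype, copy=False))

    return Tensor._make(out, parents, backward)


def conv_transpose2d(
    x: Tensor,
    weight: Tensor,
    bias: Tensor | None = None,
    stride: int = 1,
    padding: int = 0,
    output_padding: int = 0,
) -> Tensor:
    """2-D transpose convolution; weight is (C_in, C_out, kh, kw)."""
    c, o, kh, kw = weight.shape
    if x.shape[1] != c:
        raise ValueError(f"conv_transpose2d channel mismatch: input {x.shape[1]}, weight {c}")
    n, _, h, w = x.shape
    h_full = (h - 1) * stride + kh + output_padding
    w_full = (w - 1) * stride + kw + output_padding
    h_out = h_full - 2 * padding
    w_out = w_full - 2 * padding
    tmp = np.tensordot(x.data, weight.data, axes=([1], [0]))  # (N,H,W,O,kh,kw)
    y_full = np.zeros((n, o, h_full, w_full), dtype=x.dtype)
    for i in range(kh):
        for j in range(kw):
            y_full[:, :, i : i + h * stride : stride, j : j + w * stride : stride] += (
                tmp[:, :, :, :, i, j].transpose(0, 3, 1, 2)
            )
    out = np.ascontiguousarray(y_full[:, :, padding : padding + h_out, padding : padding + w_out])
    if bias is not None:
        out += bias.data[None, :, None, None]
    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        g_full = np.zeros((n, o, h_full, w_full), dtype=g.dtype)
        g_full[:, :, padding : padding + h_out, padding : padding + w_out] = g
        gcols = np.empty((n, h, w, o, kh, kw), dtype=g.dtype)
        for i in range(kh):
            for j in range(kw):
                gcols[:, :, :, :, i, j] = g_full[
                    :, :, i : i + h * stride : stride, j : j + w * stride : stride
                ].transpose(0, 2, 3, 1)
        if weight.requires_grad:
            gw = np.tensordot(x.data, gcols, axes=([0, 2, 3], [0, 1, 2]))
            weight._accumulate(gw.astype(weight.dtype, copy=False))
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3)).astype(bias.dtype, copy=False))
        if x.requires_grad:
            gx = np.tensordot(gcols, weight.data, axes=([3, 4, 5], [1, 2, 3]))  # (N,H,W,C)
            x._accumulate(gx.transpose(0, 3, 1, 2).astype(x.dtype, copy=False))

    return Tensor._make(out, parents, backward)


def max_pool2d(x: Tensor, kernel_size: int, stride: int, padding: int = 0) -> Tensor:
    """Max pooling; padded positions are -inf and can never win."""
    k = kernel_size
    xp = _pad_hw(x.data, padding, value=-np.inf)
    win = _windows(xp, k, k, stride, dilation=1)
    n, c, oh, ow = win.shape[:4]
    flat = win.reshape(n, c, oh, ow, k * k)
    idx = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        if not x.requires_grad:
            return
        gx = np.zeros_like(xp)
        ni, ci, hi, wi = np.indices((n, c, oh, ow), sparse=True)
        rows = hi * stride + idx // k
        cols = wi * stride + idx % k
        np.add.at(gx, (ni, ci, rows, cols), g)
        if padding:
            gx = gx[:, :, padding:-padding, padding:-padding]
        x._accumulate(gx.astype(x.dtype, copy=False))

    return Tensor._make(np.ascontiguousarray(out), (x,), backward)


def avg_pool2d(x: Tensor) -> Tensor:
    """2x2 stride-2 average pooling; spatial dims must be even."""
    n, c, h, w = x.shape
    if h % 2 or w % 2:
        raise ValueError(f"avg_pool2d needs even spatial dims, got {h}x{w}")
    out = x.data.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))

    def backward(g):
        if x.requires_grad:
            gx = np.repeat(np.repeat(g, 2, axis=2), 2, axis=3) * 0.25
            x._accumulate(gx.astype(x.dtype, copy=False))

    return Tensor._make(out, (x,), backward)


_interp_cache: dict[tuple[int, int], np.ndarray] = {}


def _interp_matrix(size_in: int, size_out: int) -> np.ndarray:
    """Dense 1-D bilinear interpolation matrix (size_out, size_in), half-pixel centers."""
    key = (size_in, size_out)
    mat = _interp_cache.get(key)
    if mat is None:
        scale = size_in / size_out
        src = np.clip((np.arange(size_out) + 0.5) * scale - 0.5, 0, size_in - 1)
        i0 = np.floor(src).astype(int)
        i1 = np.minimum(i0 + 1, size_in - 1)
        t = src - i0
        mat = np.zeros((size_out, size_in))
        np.add.at(mat, (np.arange(size_out), i0), 1.0 - t)
        np.add.at(mat, (np.arange(size_out), i1), t)
        _interp_cache[key] = mat
    return mat


def upsample_bilinear(x: Tensor, scale: int = 2, size: tuple[int, int] | None = None) -> Tensor:
    """Bilinear upsampling (half-pixel-centred); separable dense matrices + BLAS."""
    n, c, h, w = x.shape
    ho, wo = size if size is not None else (h * scale, w * scale)
    ah = _interp_matrix(h, ho).astype(x.dtype)
    aw = _interp_matrix(w, wo).astype(x.dtype)
    t1 = np.tensordot(x.data, aw, axes=([3], [1]))  # (N,C,H,Wo)
    out = np.tensordot(t1, ah, axes=([2], [1])).transpose(0, 1, 3, 2)  # (N,C,Ho,Wo)

    def backward(g):
        if x.requires_grad:
            t = np.tensordot(g, ah, axes=([2], [0]))  # (N,C,Wo,H) after contracting Ho
            gx = np.tensordot(t.transpose(0, 1, 3, 2), aw, axes=([3], [0]))
            x._accumulate(gx.astype(x.dtype, copy=False))

    return Tensor._make(np.ascontiguousarray(out), (x,), backward)


def batch_norm(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """Per-channel batch normalization over (N, H, W); updates running stats in place."""
    if training:
        m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
        mu = x.data.mean(axis=(0, 2, 3))
        # E[x^2] - E[x]^2 in one extra pass instead of numpy's two-pass var
        var = np.einsum("nchw,nchw->c", x.data, x.data) / m - mu * mu
        np.maximum(var, 0.0, out=var)
        running_mean *= 1.0 - momentum
        running_mean += momentum * mu
        running_var *= 1.0 - momentum
        running_var += momentum * var * (m / max(m - 1, 1))  # unbiased for running stats
    else:
        mu = running_mean
        var = running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu[None, :, None, None]) * inv_std[None, :, None, None]
    out = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]

    def backward(g):
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)).astype(gamma.dtype, copy=False))
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=(0, 2, 3)).astype(beta.dtype, copy=False))
        if x.requires_grad:
            scale = (gamma.data * inv_std)[None, :, None, None]
            if training:
                gm = g.mean(axis=(0, 2, 3), keepdims=True)
                gx_hat = (g * xhat).mean(axis=(0, 2, 3), keepdims=True)
                gx = scale * (g - gm - xhat * gx_hat)
            else:
                gx = scale * g
            x._accumulate(gx.astype(x.dtype, copy=False))

    return Tensor._make(out, (x, gamma, beta), backward)


def bce_with_logits(logits: Tensor, target: np.ndarray) -> Tensor:
    """Mean binary cross-entropy computed stably from logits."""
    z = logits.data
    t = np.asarray(target, dtype=z.dtype)
    loss = np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))
    out = np.asarray(loss.mean())

    def backward(g):
        if logits.requires_grad:
            p = np.where(z >= 0, 1.0 / (1.0 + np.exp(-np.abs(z))),
                         np.exp(-np.abs(z)) / (1.0 + np.exp(-np.abs(z))))
            logits._accumulate((g * (p - t) / z.size).astype(logits.dtype, copy=False))

    return Tensor._make(out, (logits,), backward)
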