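"""Differentiable spatial operations: 3D convolution (strided / dilated),
3D transposed convolution, trilinear resampling and dropout.

Feature tensors are **channels-last**: ``(N, D, H, W, C)``. With this
layout the im2col column matrix, the GEMM operands and the results are all
naturally contiguous, so a convolution is one gather plus one BLAS matrix
product with no layout transposes. Weights keep the conventional
``(C_out, C_in, kd, kh, kw)`` shape. The input gradient of a stride-1
convolution is computed as a full correlation of the output gradient with
the spatially flipped kernel (one more gather + GEMM); non-overlapping
strided convolutions (the 2x2x2 stride-2 transitions) use a per-tap gather
because each kernel tap owns a disjoint set of input voxels. Trilinear
resampling is a cached sparse matrix built as a Kronecker product of 1-D
corner-aligned interpolation matrices, so forward and backward are exact
transposes of each other.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import sparse

from .autograd import Tensor, _as_tensor, make_node

__all__ = [
    "conv3d",
    "conv_transpose3d",
    "interp_trilinear",
    "dropout",
    "conv_output_size",
]


def _triple(v) -> tuple[int, int, int]:
    if np.isscalar(v):
        return (int(v),) * 3
    t = tuple(int(x) for x in v)
    if len(t) != 3:
        raise ValueError(f"expected scalar or length-3 value, got {v!r}")
    return t


def conv_output_size(n: int, k: int, stride: int, padding: int, dilation: int) -> int:
    eff = dilation * (k - 1) + 1
    return (n + 2 * padding - eff) // stride + 1


def _im2col(xp: np.ndarray, kernel, stride, dilation):
    """Gather sliding windows of a padded channels-last input.

    Returns ``(col, out_spatial)`` with ``col`` of shape
    ``(N * prod(out), C * prod(kernel))`` and inner order ``(C, taps)``.
    """
    kd, kh, kw = kernel
    sd, sh, sw = stride
    dd, dh, dw = dilation
    win = ((kd - 1) * dd + 1, (kh - 1) * dh + 1, (kw - 1) * dw + 1)
    v = sliding_window_view(xp, win, axis=(1, 2, 3))
    v = v[:, ::sd, ::sh, ::sw, :, ::dd, ::dh, ::dw]
    n, od, oh, ow, c = v.shape[:5]
    col = np.ascontiguousarray(v).reshape(n * od * oh * ow, c * kd * kh * kw)
    return col, (od, oh, ow)


def conv3d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           stride=1, padding=0, dilation=1) -> Tensor:
    """Cross-correlation of ``x`` (N,D,H,W,C) with ``weight`` (Co,Ci,kd,kh,kw)."""
    x = _as_tensor(x)
    weight = _as_tensor(weight)
    stride = _triple(stride)
    padding = _triple(padding)
    dilation = _triple(dilation)
    co, ci, kd, kh, kw = weight.data.shape
    n = x.data.shape[0]
    if x.data.shape[-1] != ci:
        raise ValueError(f"conv3d: input has {x.data.shape[-1]} channels, "
                         f"weight expects {ci}")
    pd, ph, pw = padding
    if (kd, kh, kw) == (1, 1, 1) and stride == (1, 1, 1) and padding == (0, 0, 0):
        # pointwise conv: plain matrix product, no window gather needed
        col = x.data.reshape(-1, ci)
        out_sp = x.data.shape[1:4]
        xp = x.data
    else:
        if any(p > 0 for p in padding):
            xp = np.pad(x.data, ((0, 0), (pd, pd), (ph, ph), (pw, pw), (0, 0)))
        else:
            xp = x.data
        col, out_sp = _im2col(xp, (kd, kh, kw), stride, dilation)
    wmat = weight.data.reshape(co, -1)  # inner order (Ci, taps) matches col
    y = col @ wmat.T
    if bias is not None:
        bias = _as_tensor(bias)
        y += bias.data
    od, oh, ow = out_sp
    out = y.reshape(n, od, oh, ow, co)
    in_shape = x.data.shape

    def backward(g):
        gmat = g.reshape(n * od * oh * ow, co)
        if bias is not None:
            bias.accumulate(gmat.sum(axis=0))
        weight.accumulate((gmat.T @ col).reshape(weight.data.shape))
        if stride == (1, 1, 1):
            # dL/dx = full correlation of g with the flipped kernel
            eff = tuple(dl * (k - 1) for k, dl in zip((kd, kh, kw), dilation))
            gp = np.pad(g, ((0, 0),
                            (eff[0] - pd, eff[0] - pd),
                            (eff[1] - ph, eff[1] - ph),
                            (eff[2] - pw, eff[2] - pw), (0, 0)))
            wflip = np.ascontiguousarray(
                weight.data[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4))
            gcol, _ = _im2col(gp, (kd, kh, kw), (1, 1, 1), dilation)
            x.accumulate((gcol @ wflip.reshape(ci, -1).T).reshape(in_shape))
        elif stride == (kd, kh, kw) and padding == (0, 0, 0) and dilation == (1, 1, 1):
            dxp = np.zeros(in_shape, dtype=np.float32)
            for a in range(kd):
                for b in range(kh):
                    for cc in range(kw):
                        piece = gmat @ weight.data[:, :, a, b, cc]
                        dxp[:, a:a + od * kd:kd, b:b + oh * kh:kh,
                            cc:cc + ow * kw:kw, :] = piece.reshape(n, od, oh, ow, ci)
            x.accumulate(dxp)
        else:
            # general fallback: scatter column gradients per kernel tap
            dcol = (gmat @ wmat).reshape(n, od, oh, ow, ci, kd, kh, kw)
            dxp = np.zeros(xp.shape, dtype=np.float32)
            sd, sh, sw = stride
            dd, dh, dw = dilation
            for a in range(kd):
                for b in range(kh):
                    for cc in range(kw):
                        dxp[:,
                            a * dd:a * dd + od * sd:sd,
                            b * dh:b * dh + oh * sh:sh,
                            cc * dw:cc * dw + ow * sw:sw, :] += \
                            dcol[:, :, :, :, :, a, b, cc]
            if any(p > 0 for p in padding):
                dxp = dxp[:, pd:xp.shape[1] - pd, ph:xp.shape[2] - ph,
                          pw:xp.shape[3] - pw, :]
            x.accumulate(dxp)

    parents = (x, weight, bias) if bias is not None else (x, weight)
    return make_node(out, parents, backward)


def conv_transpose3d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
                     stride=2) -> Tensor:
    """Transposed convolution, ``weight`` of shape (Ci, Co, kd, kh, kw).

    Output size is ``(n-1)*stride + k`` per axis (no padding); the 2x2x2
    kernel / stride-2 used by the decoder exactly doubles each axis.
    """
    x = _as_tensor(x)
    weight = _as_tensor(weight)
    stride = _triple(stride)
    ci, co, kd, kh, kw = weight.data.shape
    n, d, h, w = x.data.shape[:4]
    if x.data.shape[-1] != ci:
        raise ValueError(f"conv_transpose3d: input has {x.data.shape[-1]} "
                         f"channels, weight expects {ci}")
    sd, sh, sw = stride
    out_sp = ((d - 1) * sd + kd, (h - 1) * sh + kh, (w - 1) * sw + kw)
    xmat = x.data.reshape(-1, ci)
    wmat = weight.data.reshape(ci, -1)  # inner order (Co, taps)
    ymat = (xmat @ wmat).reshape(n, d, h, w, co, kd, kh, kw)
    out = np.zeros((n,) + out_sp + (co,), dtype=np.float32)
    for a in range(kd):
        for b in range(kh):
            for cc in range(kw):
                out[:, a:a + d * sd:sd, b:b + h * sh:sh,
                    cc:cc + w * sw:sw, :] += ymat[:, :, :, :, :, a, b, cc]
    if bias is not None:
        bias = _as_tensor(bias)
        out += bias.data

    def backward(g):
        if bias is not None:
            bias.accumulate(g.sum(axis=(0, 1, 2, 3)))
        gtaps = np.empty((n, d, h, w, co, kd, kh, kw), dtype=np.float32)
        for a in range(kd):
            for b in range(kh):
                for cc in range(kw):
                    gtaps[:, :, :, :, :, a, b, cc] = g[:, a:a + d * sd:sd,
                                                       b:b + h * sh:sh,
                                                       cc:cc + w * sw:sw, :]
        gmat = gtaps.reshape(-1, co * kd * kh * kw)
        weight.accumulate((xmat.T @ gmat).reshape(weight.data.shape))
        x.accumulate((gmat @ wmat.T).reshape(x.data.shape))

    parents = (x, weight, bias) if bias is not None else (x, weight)
    return make_node(out, parents, backward)


# -- trilinear resampling ----------------------------------------------------

_INTERP_CACHE: dict[tuple, sparse.csr_matrix] = {}


def _interp_matrix_1d(n_in: int, n_out: int) -> sparse.csr_matrix:
    """Corner-aligned linear interpolation matrix of shape (n_out, n_in)."""
    if n_in == n_out:
        return sparse.identity(n_in, format="csr", dtype=np.float32)
    if n_out == 1:
        return sparse.csr_matrix(
            (np.array([1.0], dtype=np.float32), ([0], [0])), shape=(1, n_in))
    if n_in == 1:
        return sparse.csr_matrix(np.ones((n_out, 1), dtype=np.float32))
    src = np.arange(n_out, dtype=np.float64) * (n_in - 1) / (n_out - 1)
    lo = np.minimum(np.floor(src).astype(int), n_in - 2)
    frac = src - lo
    rows = np.repeat(np.arange(n_out), 2)
    cols = np.stack([lo, lo + 1], axis=1).ravel()
    vals = np.stack([1.0 - frac, frac], axis=1).ravel()
    return sparse.csr_matrix(
        (vals.astype(np.float32), (rows, cols)), shape=(n_out, n_in))


def trilinear_matrix(in_shape, out_shape) -> sparse.csr_matrix:
    """Sparse (prod(out), prod(in)) trilinear resampling operator."""
    key = (tuple(in_shape), tuple(out_shape))
    if key not in _INTERP_CACHE:
        mats = [_interp_matrix_1d(i, o) for i, o in zip(in_shape, out_shape)]
        _INTERP_CACHE[key] = sparse.kron(
            sparse.kron(mats[0], mats[1]), mats[2]).tocsr().astype(np.float32)
    return _INTERP_CACHE[key]


def interp_trilinear(x: Tensor, out_shape) -> Tensor:
    """Trilinear resampling of (N,D,H,W,C) to spatial ``out_shape``.

    Uses the corner-aligned convention throughout the package: input and
    output corner voxels coincide, so equal shapes give the identity map.
    """
    x = _as_tensor(x)
    out_shape = _triple(out_shape)
    in_shape = x.data.shape[1:4]
    if tuple(in_shape) == out_shape:
        def backward_id(g):
            x.accumulate(g)
        return make_node(x.data, (x,), backward_id)
    p = trilinear_matrix(in_shape, out_shape)
    tkey = (tuple(out_shape), tuple(in_shape), "T")
    if tkey not in _INTERP_CACHE:
        _INTERP_CACHE[tkey] = p.T.tocsr()
    pt = _INTERP_CACHE[tkey]
    n, c = x.data.shape[0], x.data.shape[-1]
    y = np.empty((n,) + out_shape + (c,), dtype=np.float32)
    in_vox = int(np.prod(in_shape))
    out_vox = int(np.prod(out_shape))
    for i in range(n):
        y[i] = (p @ x.data[i].reshape(in_vox, c)).reshape(out_shape + (c,))

    def backward(g):
        dx = np.empty(x.data.shape, dtype=np.float32)
        for i in range(n):
            dx[i] = (pt @ g[i].reshape(out_vox, c)).reshape(in_shape + (c,))
        x.accumulate(dx)

    return make_node(y, (x,), backward)


def dropout(x: Tensor, p: float, rng: np.random.Generator,
            training: bool = True) -> Tensor:
    """Inverted Bernoulli dropout: zero with probability ``p``, scale by 1/(1-p)."""
    x = _as_tensor(x)
    if not training or p <= 0.0:
        return x
    keep = (rng.random(x.data.shape, dtype=np.float32) >= p).astype(np.float32) \
        / np.float32(1.0 - p)
    out = x.data * keep

    def backward(g):
        x.accumulate(g * keep)

    return make_node(out, (x,), backward)
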