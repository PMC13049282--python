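"""Fused network operations (conv, pooling, normalization, warping).

Each op returns a :class:`~renalmpr.nn.autograd.Tensor` carrying a
hand-written backward closure.  Gradients are validated against central
finite differences in the test suite.

Array layout is ``(B, C, H, W)``.  Displacement fields are ``(B, 2, H, W)``
with channel 0 the row displacement and channel 1 the column displacement,
in pixels, backward/sampling convention: ``out(x) = img(x + u(x))``.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Same-padding stride-1 2-D convolution (cross-correlation).

    ``x``: (B, Cin, H, W); ``w``: (Cout, Cin, kh, kw) with odd kh, kw.
    """
    B, Cin, H, W = x.shape
    Cout, Cin2, kh, kw = w.shape
    if Cin != Cin2:
        raise ValueError(f"channel mismatch: input {Cin}, kernel {Cin2}")
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    # im2col: (B, H, W, Cin*kh*kw)
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(B * H * W, Cin * kh * kw)
    wmat = w.data.reshape(Cout, -1)
    out = cols @ wmat.T
    if b is not None:
        out = out + b.data
    out = out.reshape(B, H, W, Cout).transpose(0, 3, 1, 2)

    def back(g):
        gmat = g.transpose(0, 2, 3, 1).reshape(B * H * W, Cout)
        w._accum((gmat.T @ cols).reshape(w.shape))
        if b is not None:
            b._accum(gmat.sum(axis=0))
        if x.requires_grad:
            gcols = (gmat @ wmat).reshape(B, H, W, Cin, kh, kw)
            gxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    gxp[:, :, i:i + H, j:j + W] += gcols[:, :, :, :, i, j] \
                        .transpose(0, 3, 1, 2)
            x._accum(gxp[:, :, ph:ph + H, pw:pw + W])

    parents = (x, w) if b is None else (x, w, b)
    return Tensor(out, _parents=parents, _backward=back)


def maxpool2x2(x: Tensor) -> Tensor:
    B, C, H, W = x.shape
    if H % 2 or W % 2:
        raise ValueError("maxpool2x2 requires even spatial dims")
    blocks = x.data.reshape(B, C, H // 2, 2, W // 2, 2) \
        .transpose(0, 1, 2, 4, 3, 5).reshape(B, C, H // 2, W // 2, 4)
    arg = blocks.argmax(axis=-1)
    out = np.take_along_axis(blocks, arg[..., None], axis=-1)[..., 0]

    def back(g):
        gb = np.zeros_like(blocks)
        np.put_along_axis(gb, arg[..., None], g[..., None], axis=-1)
        gx = gb.reshape(B, C, H // 2, W // 2, 2, 2) \
            .transpose(0, 1, 2, 4, 3, 5).reshape(B, C, H, W)
        x._accum(gx)

    return Tensor(out, _parents=(x,), _backward=back)


def upsample2x2(x: Tensor) -> Tensor:
    """2×2 nearest-neighbor upsampling."""
    out = x.data.repeat(2, axis=2).repeat(2, axis=3)
    B, C, H, W = x.shape

    def back(g):
        x._accum(g.reshape(B, C, H, 2, W, 2).sum(axis=(3, 5)))

    return Tensor(out, _parents=(x,), _backward=back)


def batchnorm2d(x: Tensor, gamma: Tensor, beta: Tensor,
                running: dict | None = None, training: bool = True,
                momentum: float = 0.1, eps: float = 1e-5) -> Tensor:
    """Per-channel batch normalization over (B, H, W).

    ``running`` is a dict with "mean"/"var" arrays updated in place during
    training and consumed in eval mode.
    """
    B, C, H, W = x.shape
    n = B * H * W
    if training or running is None:
        mean = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        if running is not None:
            running["mean"] = (1 - momentum) * running["mean"] + momentum * mean
            running["var"] = (1 - momentum) * running["var"] + momentum * var
    else:
        mean, var = running["mean"], running["var"]
    ivstd = 1.0 / np.sqrt(var + eps)
    xc = x.data - mean[None, :, None, None]
    xhat = xc * ivstd[None, :, None, None]
    out = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]

    def back(g):
        gamma._accum((g * xhat).sum(axis=(0, 2, 3)))
        beta._accum(g.sum(axis=(0, 2, 3)))
        if not x.requires_grad:
            return
        dxhat = g * gamma.data[None, :, None, None]
        if training or running is None:
            iv = ivstd[None, :, None, None]
            t1 = dxhat.sum(axis=(0, 2, 3), keepdims=True)
            t2 = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
            x._accum(iv / n * (n * dxhat - t1 - xhat * t2))
        else:
            x._accum(dxhat * ivstd[None, :, None, None])

    return Tensor(out, _parents=(x, gamma, beta), _backward=back)


def linear(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Dense layer: x (B, F) @ w.T (F, U) + b."""
    return x.matmul(w.transpose((1, 0))) + b


def softmax_channels(x: Tensor) -> Tensor:
    """Softmax over axis 1 (classes/channels)."""
    shift = Tensor(x.data.max(axis=1, keepdims=True))
    e = (x - shift).exp()
    return e / e.sum(axis=1, keepdims=True)


def _corner_values(img: np.ndarray, r: np.ndarray, c: np.ndarray,
                   valid: np.ndarray) -> np.ndarray:
    """Gather img[b, :, r, c] with zeros outside (img (B,C,H,W); r,c (B,H,W))."""
    B, C, H, W = img.shape
    rc = np.clip(r, 0, H - 1)
    cc = np.clip(c, 0, W - 1)
    bidx = np.arange(B)[:, None, None, None]
    vals = img[bidx, np.arange(C)[None, :, None, None],
               rc[:, None], cc[:, None]]
    return vals * valid[:, None]


def grid_sample_bilinear(img: Tensor, u: Tensor) -> Tensor:
    """Backward-warp ``img`` by displacement ``u``: out(x) = img(x + u(x)).

    Bilinear interpolation, zero padding outside the grid.  Differentiable
    w.r.t. both the image and the displacement field.
    """
    B, C, H, W = img.shape
    rr = np.arange(H, dtype=np.float64)[None, :, None] + u.data[:, 0]
    cc = np.arange(W, dtype=np.float64)[None, None, :] + u.data[:, 1]
    r0 = np.floor(rr).astype(np.int64)
    c0 = np.floor(cc).astype(np.int64)
    fr = rr - r0
    fc = cc - c0
    corners = []
    for dr, dc in ((0, 0), (0, 1), (1, 0), (1, 1)):
        r, c = r0 + dr, c0 + dc
        valid = ((r >= 0) & (r < H) & (c >= 0) & (c < W)).astype(np.float64)
        wgt = (fr if dr else 1 - fr) * (fc if dc else 1 - fc)
        corners.append((r, c, valid, wgt))
    vals = [_corner_values(img.data, r, c, v) for r, c, v, _ in corners]
    out = sum(v * w[:, None] for v, (_, _, _, w) in zip(vals, corners))

    def back(g):
        if img.requires_grad:
            gimg = np.zeros_like(img.data)
            bidx = np.arange(B)[:, None, None, None]
            cidx = np.arange(C)[None, :, None, None]
            for (r, c, valid, wgt) in corners:
                rc = np.clip(r, 0, H - 1)[:, None]
                ccl = np.clip(c, 0, W - 1)[:, None]
                np.add.at(gimg, (bidx, cidx, rc, ccl),
                          g * (wgt * valid)[:, None])
            img._accum(gimg)
        if u.requires_grad:
            v00, v01, v10, v11 = vals
            # d out / d rr and d out / d cc, summed over channels
            dr = ((v10 - v00) * (1 - fc)[:, None]
                  + (v11 - v01) * fc[:, None])
            dc = ((v01 - v00) * (1 - fr)[:, None]
                  + (v11 - v10) * fr[:, None])
            gu = np.stack([(g * dr).sum(axis=1), (g * dc).sum(axis=1)], axis=1)
            u._accum(gu)

    return Tensor(out, _parents=(img, u), _backward=back)
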