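"""Minimal reverse-mode autodiff on numpy arrays.

Just enough machinery to train the compact detect-and-segment network on a
CPU: float32 tensors, broadcast-aware add, matmul, ReLU, im2col
convolution, nearest-neighbour upsampling, row gathering, RoIAlign with a
bilinear scatter backward, and closed-form loss nodes (binary cross-entropy
with logits, smooth L1).  Gradients flow through a topologically sorted
tape; parameters are updated with Adam.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Adam", "conv2d", "matmul", "relu", "add",
           "upsample_nearest2x", "gather_rows", "roi_align",
           "bce_with_logits", "smooth_l1_loss", "scale", "reshape",
           "transpose", "sigmoid"]


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev: tuple["Tensor", ...] = ()

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen = set()

        def visit(t: "Tensor"):
            stack = [(t, iter(t._prev))]
            seen.add(id(t))
            while stack:
                node, it = stack[-1]
                advanced = False
                for child in it:
                    if id(child) not in seen:
                        seen.add(id(child))
                        stack.append((child, iter(child._prev)))
                        advanced = True
                        break
                if not advanced:
                    topo.append(node)
                    stack.pop()

        visit(self)
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self):
        self.grad = None


def _node(data, parents, backward) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad or p._prev for p in parents):
        out.requires_grad = True
        out._prev = tuple(parents)
        out._backward = backward
    return out


def _unbroadcast(g: np.ndarray, shape) -> np.ndarray:
    """Sum gradient over broadcast axes to recover ``shape``."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def add(a: Tensor, b: Tensor) -> Tensor:
    data = a.data + b.data

    def backward(g):
        a._accumulate(_unbroadcast(g, a.data.shape))
        b._accumulate(_unbroadcast(g, b.data.shape))

    return _node(data, (a, b), backward)


def scale(a: Tensor, k: float) -> Tensor:
    def backward(g):
        a._accumulate(g * k)

    return _node(a.data * k, (a,), backward)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    data = a.data @ b.data

    def backward(g):
        a._accumulate(g @ b.data.T)
        b._accumulate(a.data.T @ g)

    return _node(data, (a, b), backward)


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0

    def backward(g):
        a._accumulate(g * mask)

    return _node(a.data * mask, (a,), backward)


def sigmoid(a: Tensor) -> Tensor:
    s = _sigmoid_np(a.data)

    def backward(g):
        a._accumulate(g * s * (1.0 - s))

    return _node(s, (a,), backward)


def reshape(a: Tensor, shape) -> Tensor:
    old = a.data.shape

    def backward(g):
        a._accumulate(g.reshape(old))

    return _node(a.data.reshape(shape), (a,), backward)


def transpose(a: Tensor, axes) -> Tensor:
    inv = np.argsort(axes)

    def backward(g):
        a._accumulate(g.transpose(inv))

    return _node(a.data.transpose(axes), (a,), backward)


def gather_rows(a: Tensor, idx: np.ndarray) -> Tensor:
    idx = np.asarray(idx, dtype=np.intp)

    def backward(g):
        da = np.zeros_like(a.data)
        np.add.at(da, idx, g)
        a._accumulate(da)

    return _node(a.data[idx], (a,), backward)


def upsample_nearest2x(a: Tensor) -> Tensor:
    """(N, C, H, W) -> (N, C, 2H, 2W) by pixel repetition."""
    data = a.data.repeat(2, axis=2).repeat(2, axis=3)

    def backward(g):
        N, C, H2, W2 = g.shape
        gg = g.reshape(N, C, H2 // 2, 2, W2 // 2, 2).sum(axis=(3, 5))
        a._accumulate(gg)

    return _node(data, (a,), backward)


# ---------------------------------------------------------------- conv2d

def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    N, C, H, W = x.shape
    Ho = (H + 2 * pad - kh) // stride + 1
    Wo = (W + 2 * pad - kw) // stride + 1
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    s0, s1, s2, s3 = xp.strides
    cols = np.lib.stride_tricks.as_strided(
        xp,
        shape=(N, C, kh, kw, Ho, Wo),
        strides=(s0, s1, s2, s3, s2 * stride, s3 * stride),
        writeable=False,
    )
    return np.ascontiguousarray(cols).reshape(N, C * kh * kw, Ho * Wo), Ho, Wo


def _col2im(dcols: np.ndarray, xshape, kh, kw, stride, pad, Ho, Wo):
    N, C, H, W = xshape
    dxp = np.zeros((N, C, H + 2 * pad, W + 2 * pad), dtype=np.float32)
    d6 = dcols.reshape(N, C, kh, kw, Ho, Wo)
    for i in range(kh):
        for j in range(kw):
            dxp[:, :, i : i + stride * Ho : stride, j : j + stride * Wo : stride] += d6[:, :, i, j]
    if pad:
        return dxp[:, :, pad:-pad, pad:-pad]
    return dxp


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, pad: int = 1) -> Tensor:
    """2-D convolution, ``x`` (N,C,H,W), ``w`` (F,C,kh,kw), ``b`` (F,)."""
    F, C, kh, kw = w.data.shape
    cols, Ho, Wo = _im2col(x.data, kh, kw, stride, pad)
    wmat = w.data.reshape(F, -1)
    out = np.einsum("fk,nkp->nfp", wmat, cols, optimize=True)
    out = out.reshape(x.data.shape[0], F, Ho, Wo)
    if b is not None:
        out = out + b.data[None, :, None, None]

    def backward(g):
        gmat = g.reshape(g.shape[0], F, -1)  # (N, F, Ho*Wo)
        dw = np.einsum("nfp,nkp->fk", gmat, cols, optimize=True).reshape(w.data.shape)
        w._accumulate(dw)
        if b is not None:
            b._accumulate(gmat.sum(axis=(0, 2)))
        dcols = np.einsum("fk,nfp->nkp", wmat, gmat, optimize=True)
        dx = _col2im(dcols, x.data.shape, kh, kw, stride, pad, Ho, Wo)
        x._accumulate(dx)

    parents = (x, w) if b is None else (x, w, b)
    return _node(out, parents, backward)


# -------------------------------------------------------------- RoIAlign

def roi_align(feat: Tensor, rois: np.ndarray, out_size: int,
              spatial_scale: float, sampling: int = 2) -> Tensor:
    """RoIAlign on a single feature map.

    ``feat`` is (1, C, H, W); ``rois`` is (R, 4) half-open boxes
    ``(r0, c0, r1, c1)`` in input-image pixels; ``spatial_scale`` maps image
    pixels to feature-map pixels.  Each output bin averages ``sampling**2``
    bilinear samples.  Returns (R, C, out_size, out_size).
    """
    _, C, H, W = feat.data.shape
    rois = np.asarray(rois, dtype=np.float64) * spatial_scale
    R = rois.shape[0]
    S = sampling
    P = out_size
    if R == 0:
        return Tensor(np.zeros((0, C, P, P), dtype=np.float32))

    # sample coordinates: (R, P, P, S, S)
    r0, c0, r1, c1 = rois[:, 0], rois[:, 1], rois[:, 2], rois[:, 3]
    bh = np.maximum(r1 - r0, 1e-3) / P
    bw = np.maximum(c1 - c0, 1e-3) / P
    ii = np.arange(P)
    ss = (np.arange(S) + 0.5) / S
    yy = r0[:, None, None] + (ii[None, :, None] + ss[None, None, :]) * bh[:, None, None]
    xx = c0[:, None, None] + (ii[None, :, None] + ss[None, None, :]) * bw[:, None, None]
    # continuous coords -> pixel-centre convention: sample at y - 0.5
    yy = np.clip(yy - 0.5, 0, H - 1)
    xx = np.clip(xx - 0.5, 0, W - 1)
    y0 = np.floor(yy).astype(np.intp)
    x0 = np.floor(xx).astype(np.intp)
    y1 = np.minimum(y0 + 1, H - 1)
    x1 = np.minimum(x0 + 1, W - 1)
    wy1 = (yy - y0).astype(np.float32)
    wx1 = (xx - x0).astype(np.float32)
    wy0 = 1.0 - wy1
    wx0 = 1.0 - wx1

    fmap = feat.data[0].reshape(C, H * W)

    # full (R, P, S, P, S) corner index/weight arrays (rows x row-samples x
    # cols x col-samples); weights are the bilinear corner products
    Y0 = y0[:, :, :, None, None]
    Y1 = y1[:, :, :, None, None]
    X0 = x0[:, None, None, :, :]
    X1 = x1[:, None, None, :, :]
    WY0 = wy0[:, :, :, None, None]
    WY1 = wy1[:, :, :, None, None]
    WX0 = wx0[:, None, None, :, :]
    WX1 = wx1[:, None, None, :, :]

    corners = [
        (Y0 * W + X0, WY0 * WX0),
        (Y0 * W + X1, WY0 * WX1),
        (Y1 * W + X0, WY1 * WX0),
        (Y1 * W + X1, WY1 * WX1),
    ]
    n_samp = R * P * S * P * S
    out = np.zeros((C, n_samp), dtype=np.float32)
    flat_idx = []
    flat_w = []
    for idx, wgt in corners:
        idx = np.broadcast_to(idx, (R, P, S, P, S)).reshape(-1)
        wgt = np.broadcast_to(wgt, (R, P, S, P, S)).reshape(-1).astype(np.float32)
        out += fmap[:, idx] * wgt[None, :]
        flat_idx.append(idx)
        flat_w.append(wgt)
    # average the S*S samples per bin
    out = out.reshape(C, R, P, S, P, S).mean(axis=(3, 5))  # (C, R, P, P)
    out = np.ascontiguousarray(out.transpose(1, 0, 2, 3))  # (R, C, P, P)

    def backward(g):
        # g: (R, C, P, P) -> per-sample gradient (C, n_samp)
        gs = g.transpose(1, 0, 2, 3)[:, :, :, None, :, None] / (S * S)
        gs = np.broadcast_to(gs, (C, R, P, S, P, S)).reshape(C, n_samp)
        dmap = np.zeros((C, H * W), dtype=np.float32)
        for idx, wgt in zip(flat_idx, flat_w):
            contrib = gs * wgt[None, :]
            np.add.at(dmap.T, idx, contrib.T)
        feat._accumulate(dmap.reshape(1, C, H, W))

    return _node(out, (feat,), backward)


# ----------------------------------------------------------------- losses

def _sigmoid_np(z):
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out.astype(np.float32)


def bce_with_logits(logits: Tensor, targets: np.ndarray, weight: float = 1.0) -> Tensor:
    """Mean binary cross-entropy with logits; numerically stable."""
    z = logits.data.astype(np.float64)
    t = np.asarray(targets, dtype=np.float64)
    n = max(z.size, 1)
    loss = np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))
    val = weight * loss.sum() / n

    def backward(g):
        grad = weight * (_sigmoid_np(z) - t) / n
        logits._accumulate(g * grad.astype(np.float32))

    return _node(np.float32(val), (logits,), backward)


def smooth_l1_loss(pred: Tensor, targets: np.ndarray, weight: float = 1.0,
                   beta: float = 1.0) -> Tensor:
    """Mean smooth-L1 (Huber) loss: quadratic within ``beta``, linear beyond."""
    d = pred.data.astype(np.float64) - np.asarray(targets, dtype=np.float64)
    n = max(d.size, 1)
    absd = np.abs(d)
    loss = np.where(absd < beta, 0.5 * d * d / beta, absd - 0.5 * beta)
    val = weight * loss.sum() / n

    def backward(g):
        grad = weight * np.clip(d / beta, -1.0, 1.0) / n
        pred._accumulate(g * grad.astype(np.float32))

    return _node(np.float32(val), (pred,), backward)


# -------------------------------------------------------------- optimiser

class Adam:
    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mh = self.m[i] / (1 - self.b1**self.t)
            vh = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mh / (np.sqrt(vh) + self.eps)
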