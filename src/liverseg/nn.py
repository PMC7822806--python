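"""Minimal NumPy layer library with reverse-mode gradients.

Implements exactly the pieces the segmentation networks need — 2D convolution
(stride 1, "same" padding), batch normalization, ReLU, 2x2 max-pooling with
argmax indices, index-guided max-unpooling, channel concatenation, elementwise
addition and a class-weighted softmax cross-entropy — on ``(N, C, H, W)``
arrays, with a small tape so gradients flow through arbitrary skip topologies.

Convolutions are evaluated as tensor contractions over sliding windows
(``numpy.lib.stride_tricks.sliding_window_view``), which keeps both the
forward pass and the gradient computation inside BLAS.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor",
    "Conv2d",
    "BatchNorm2d",
    "relu",
    "add",
    "concat",
    "max_pool2x2",
    "max_unpool2x2",
    "upsample_nearest2x2",
    "ConvTranspose2x2",
    "softmax",
    "weighted_cross_entropy",
    "SGD",
]


class Tensor:
    """A node on the gradient tape: an ndarray plus a backward closure."""

    __slots__ = ("data", "grad", "parents", "_bwd")

    def __init__(self, data, parents=(), bwd=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.parents = tuple(parents)
        self._bwd = bwd

    @property
    def shape(self):
        return self.data.shape

    def backward(self):
        """Reverse-mode sweep seeded with d(self)/d(self) = 1."""
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t.parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = None
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._bwd is not None and t.grad is not None:
                t._bwd(t.grad)


def _accum(t: Tensor, g: np.ndarray) -> None:
    if t.grad is None:
        t.grad = g.copy()
    else:
        t.grad += g


def _conv2d_raw(x: np.ndarray, w: np.ndarray, pad: int) -> np.ndarray:
    """Cross-correlate (N,C,H,W) with (O,C,kh,kw), stride 1."""
    kh, kw = w.shape[2], w.shape[3]
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(x, (kh, kw), axis=(2, 3))  # (N,C,Ho,Wo,kh,kw)
    # out[n,o,h,w] = sum_{c,i,j} win[n,c,h,w,i,j] * w[o,c,i,j]
    out = np.tensordot(win, w, axes=([1, 4, 5], [1, 2, 3]))  # (N,Ho,Wo,O)
    return np.ascontiguousarray(out.transpose(0, 3, 1, 2))


def _conv2d_grad_w(x: np.ndarray, grad: np.ndarray, kh: int, kw: int, pad: int) -> np.ndarray:
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    ho, wo = grad.shape[2], grad.shape[3]
    win = sliding_window_view(x, (ho, wo), axis=(2, 3))  # (N,C,kh,kw,Ho,Wo)
    # dW[o,c,i,j] = sum_{n,h,w} grad[n,o,h,w] * x_pad[n,c,h+i,w+j]
    dw = np.tensordot(grad, win, axes=([0, 2, 3], [0, 4, 5]))  # (O,C,kh,kw)
    return dw


class Conv2d:
    """3x3 or 1x1 convolution, stride 1, same padding, He-initialized.

    ``bias`` defaults to off (a following batch norm absorbs it); the final
    classifier layer enables it.
    """

    def __init__(self, cin: int, cout: int, kernel: int, rng: np.random.Generator, bias: bool = False):
        if kernel % 2 == 0:
            raise ValueError("kernel size must be odd for same padding")
        self.cin, self.cout, self.kernel = cin, cout, kernel
        self.pad = (kernel - 1) // 2
        std = np.sqrt(2.0 / (cin * kernel * kernel))
        self.W = rng.normal(0.0, std, size=(cout, cin, kernel, kernel))
        self.b = np.zeros(cout) if bias else None
        self.Wt: Tensor | None = None
        self.bt: Tensor | None = None

    def __call__(self, x: Tensor) -> Tensor:
        if x.data.shape[1] != self.cin:
            raise ValueError(f"expected {self.cin} input channels, got {x.data.shape[1]}")
        self.Wt = Tensor(self.W)
        y = _conv2d_raw(x.data, self.W, self.pad)
        parents = [x, self.Wt]
        if self.b is not None:
            self.bt = Tensor(self.b)
            y = y + self.b[None, :, None, None]
            parents.append(self.bt)
        wt, bt, xt = self.Wt, self.bt, x
        pad, kh = self.pad, self.kernel

        def bwd(g):
            _accum(wt, _conv2d_grad_w(xt.data, g, kh, kh, pad))
            if self.b is not None:
                _accum(bt, g.sum(axis=(0, 2, 3)))
            # dx: full correlation of grad with spatially flipped, transposed W
            w_flip = self.W[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)  # (C,O,kh,kw)
            _accum(xt, _conv2d_raw(g, w_flip, pad=kh - 1 - pad))

        return Tensor(y, parents=parents, bwd=bwd)

    def parameters(self):
        yield self, "W"
        if self.b is not None:
            yield self, "b"


class BatchNorm2d:
    """Per-channel batch normalization with running statistics for eval mode."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(channels)
        self.beta = np.zeros(channels)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps
        self.gt: Tensor | None = None
        self.bt: Tensor | None = None

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        self.gt, self.bt = Tensor(self.gamma), Tensor(self.beta)
        if training:
            mu = x.data.mean(axis=(0, 2, 3))
            var = x.data.var(axis=(0, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mu, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        x_hat = (x.data - mu[None, :, None, None]) * inv_std[None, :, None, None]
        y = self.gamma[None, :, None, None] * x_hat + self.beta[None, :, None, None]
        gt, bt, xt = self.gt, self.bt, x
        m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]

        def bwd(g):
            _accum(gt, (g * x_hat).sum(axis=(0, 2, 3)))
            _accum(bt, g.sum(axis=(0, 2, 3)))
            gs = self.gamma[None, :, None, None] * inv_std[None, :, None, None]
            if training:
                gm = g.mean(axis=(0, 2, 3), keepdims=False)
                gxm = (g * x_hat).mean(axis=(0, 2, 3))
                dx = gs * (g - gm[None, :, None, None] - x_hat * gxm[None, :, None, None])
            else:
                dx = gs * g
            _accum(xt, dx)

        return Tensor(y, parents=(x, self.gt, self.bt), bwd=bwd)

    def parameters(self):
        yield self, "gamma"
        yield self, "beta"


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def bwd(g):
        _accum(x, g * mask)

    return Tensor(x.data * mask, parents=(x,), bwd=bwd)


def add(a: Tensor, b: Tensor) -> Tensor:
    def bwd(g):
        _accum(a, g)
        _accum(b, g)

    return Tensor(a.data + b.data, parents=(a, b), bwd=bwd)


def concat(a: Tensor, b: Tensor) -> Tensor:
    ca = a.data.shape[1]

    def bwd(g):
        _accum(a, g[:, :ca])
        _accum(b, g[:, ca:])

    return Tensor(np.concatenate([a.data, b.data], axis=1), parents=(a, b), bwd=bwd)


def max_pool2x2(x: Tensor) -> tuple[Tensor, np.ndarray]:
    """2x2 stride-2 max pooling; returns (pooled, argmax indices in 0..3).

    The indices identify, per output pixel, which corner of its 2x2 window
    held the maximum; they drive SegNet-style unpooling in the decoder.
    """
    n, c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError(f"spatial size ({h}, {w}) not divisible by 2 for pooling")
    win = x.data.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
        n, c, h // 2, w // 2, 4
    )
    idx = win.argmax(axis=-1)
    y = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]

    def bwd(g):
        gw = np.zeros((n, c, h // 2, w // 2, 4))
        np.put_along_axis(gw, idx[..., None], g[..., None], axis=-1)
        gx = gw.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w)
        _accum(x, gx)

    return Tensor(y, parents=(x,), bwd=bwd), idx


def max_unpool2x2(x: Tensor, idx: np.ndarray) -> Tensor:
    """Place each value at the position its paired pooling chose; zeros elsewhere."""
    n, c, h, w = x.data.shape
    if idx.shape != (n, c, h, w):
        raise ValueError(f"unpool indices shape {idx.shape} does not match input {(n, c, h, w)}")
    out = np.zeros((n, c, h, w, 4))
    np.put_along_axis(out, idx[..., None], x.data[..., None], axis=-1)
    y = out.reshape(n, c, h, w, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, 2 * h, 2 * w)

    def bwd(g):
        gw = g.reshape(n, c, h, 2, w, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w, 4)
        gx = np.take_along_axis(gw, idx[..., None], axis=-1)[..., 0]
        _accum(x, gx)

    return Tensor(y, parents=(x,), bwd=bwd)


def upsample_nearest2x2(x: Tensor) -> Tensor:
    """Double resolution by replicating each pixel over a 2x2 block."""
    n, c, h, w = x.data.shape
    y = np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3)

    def bwd(g):
        gx = g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5))
        _accum(x, gx)

    return Tensor(y, parents=(x,), bwd=bwd)


class ConvTranspose2x2:
    """Transposed convolution, kernel 2x2 stride 2 (resolution doubling)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.cin, self.cout = cin, cout
        std = np.sqrt(2.0 / (cin * 4))
        self.W = rng.normal(0.0, std, size=(cout, cin, 2, 2))
        self.Wt: Tensor | None = None

    def __call__(self, x: Tensor) -> Tensor:
        n, c, h, w = x.data.shape
        if c != self.cin:
            raise ValueError(f"expected {self.cin} input channels, got {c}")
        self.Wt = Tensor(self.W)
        # y[n,o,2i+di,2j+dj] = sum_c W[o,c,di,dj] x[n,c,i,j]
        blocks = np.einsum("ocuv,nchw->nohwuv", self.W, x.data)
        y = blocks.transpose(0, 1, 2, 4, 3, 5).reshape(n, self.cout, 2 * h, 2 * w)
        wt, xt = self.Wt, x

        def bwd(g):
            gb = g.reshape(n, self.cout, h, 2, w, 2).transpose(0, 1, 2, 4, 3, 5)
            _accum(wt, np.einsum("nohwuv,nchw->ocuv", gb, xt.data))
            _accum(xt, np.einsum("nohwuv,ocuv->nchw", gb, self.W))

        return Tensor(y, parents=(x, self.Wt), bwd=bwd)

    def parameters(self):
        yield self, "W"


def softmax(scores: np.ndarray, axis: int = 1) -> np.ndarray:
    z = scores - scores.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def weighted_cross_entropy(scores: Tensor, target: np.ndarray, class_weights: np.ndarray) -> Tensor:
    """Class-weighted pixelwise cross-entropy, averaged over pixels.

    ``scores``: (N, C, H, W) unnormalized logits; ``target``: (N, H, W) int
    labels; ``class_weights``: length-C vector.  Each pixel contributes
    ``w[y] * (-log p[y])`` and the sum is divided by the pixel count.
    """
    n, c, h, w = scores.data.shape
    if target.shape != (n, h, w):
        raise ValueError(f"target shape {target.shape} does not match scores {(n, h, w)}")
    p = softmax(scores.data, axis=1)
    npix = n * h * w
    onehot = np.zeros_like(p)
    ni, hi, wi = np.indices((n, h, w))
    onehot[ni, target, hi, wi] = 1.0
    wpix = class_weights[target]  # (N,H,W)
    logp = np.log(np.clip(p, 1e-12, None))
    loss = -(wpix * logp[ni, target, hi, wi]).sum() / npix

    def bwd(g):
        _accum(scores, g * wpix[:, None] * (p - onehot) / npix)

    return Tensor(loss, parents=(scores,), bwd=bwd)


class SGD:
    """Stochastic gradient descent with classical momentum."""

    def __init__(self, param_sources, momentum: float = 0.9):
        # param_sources: iterable of layer objects exposing .parameters()
        self.entries = [entry for layer in param_sources for entry in layer.parameters()]
        self.momentum = momentum
        self.velocity = [np.zeros_like(getattr(layer, name)) for layer, name in self.entries]

    def _grad(self, layer, name):
        tensor = {"W": "Wt", "b": "bt", "gamma": "gt", "beta": "bt"}[name]
        t = getattr(layer, tensor)
        return None if t is None else t.grad

    def step(self, lr: float) -> None:
        for v, (layer, name) in zip(self.velocity, self.entries):
            g = self._grad(layer, name)
            if g is None:
                continue
            v *= self.momentum
            v -= lr * g
            getattr(layer, name).__iadd__(v)

    def zero_velocity(self) -> None:
        for v in self.velocity:
            v[...] = 0.0
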