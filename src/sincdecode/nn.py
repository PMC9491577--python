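"""Neural-network building blocks on the autodiff core.

Contains the layer types the decoding networks are assembled from: dense
layers, batch normalization, dropout, the temporal/spatial/separable
convolutions of the classifier, 2-D convolutions and transposed
convolutions for the image generator and discriminator, pooling, and the
fused softmax / cross-entropy heads.  Convolutions are implemented with
sliding-window views and einsum; their input gradients scatter-add per
kernel tap, which keeps memory proportional to the activations.
"""

from __future__ import annotations

import copy
from typing import Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .autodiff import Tensor

# ---------------------------------------------------------------------------
# module / parameter plumbing
# ---------------------------------------------------------------------------


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float64), requires_grad=True)


class Module:
    """Base class with recursive parameter discovery and train/eval mode."""

    def __init__(self):
        self.training = True

    def modules(self) -> Iterable["Module"]:
        yield self
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        for m in self.modules():
            for v in m.__dict__.values():
                if isinstance(v, Parameter):
                    params.append(v)
                elif isinstance(v, (list, tuple)):
                    params.extend(p for p in v if isinstance(p, Parameter))
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            m.training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def state_dict(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_dict(self, state: Sequence[np.ndarray]) -> None:
        params = self.parameters()
        if len(params) != len(state):
            raise ValueError(f"state has {len(state)} arrays, model has "
                             f"{len(params)} parameters")
        for p, arr in zip(params, state):
            p.data = np.array(arr, dtype=np.float64)

    # buffers (running stats) travel with deepcopy when checkpointing
    def clone_state(self):
        return copy.deepcopy([(p.data.copy()) for p in self.parameters()]), \
            copy.deepcopy(self._buffers())

    def _buffers(self):
        bufs = []
        for m in self.modules():
            if isinstance(m, BatchNorm):
                bufs.append((m.running_mean.copy(), m.running_var.copy()))
        return bufs

    def _load_buffers(self, bufs) -> None:
        bns = [m for m in self.modules() if isinstance(m, BatchNorm)]
        for m, (rm, rv) in zip(bns, bufs):
            m.running_mean = rm.copy()
            m.running_var = rv.copy()

    def load_clone(self, state) -> None:
        params, bufs = state
        self.load_state_dict(params)
        self._load_buffers(bufs)


# ---------------------------------------------------------------------------
# basic layers
# ---------------------------------------------------------------------------


class Dense(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 bias: bool = True):
        super().__init__()
        scale = np.sqrt(2.0 / n_in)  # He init; hidden units are relu/elu
        self.weight = Parameter(rng.normal(0.0, scale, size=(n_in, n_out)))
        self.bias = Parameter(np.zeros(n_out)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


class BatchNorm(Module):
    """Normalize per feature over batch (and any trailing spatial axes).

    ``axes`` are the reduction axes; the feature axis is whatever remains.
    Evaluation mode uses exponential running statistics.
    """

    def __init__(self, n_features: int, axes: tuple[int, ...],
                 momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.axes = axes
        self.momentum = momentum
        self.eps = eps
        self.gamma = Parameter(np.ones(n_features))
        self.beta = Parameter(np.zeros(n_features))
        self.running_mean = np.zeros(n_features)
        self.running_var = np.ones(n_features)
        self._feature_axis: int | None = None

    def _param_shape(self, ndim: int) -> tuple[int, ...]:
        feat_axes = [ax for ax in range(ndim) if ax not in
                     {a % ndim for a in self.axes}]
        if len(feat_axes) != 1:
            raise ValueError("BatchNorm expects exactly one feature axis")
        self._feature_axis = feat_axes[0]
        shape = [1] * ndim
        shape[feat_axes[0]] = -1
        return tuple(shape)

    def __call__(self, x: Tensor) -> Tensor:
        shape = self._param_shape(x.ndim)
        gamma = self.gamma.reshape(shape)
        beta = self.beta.reshape(shape)
        if self.training:
            mu = x.mean(axis=self.axes, keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=self.axes, keepdims=True)
            y = xc * ((var + self.eps) ** -0.5) * gamma + beta
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean
                                 + m * mu.data.reshape(-1))
            self.running_var = ((1 - m) * self.running_var
                                + m * var.data.reshape(-1))
            return y
        rm = self.running_mean.reshape(shape)
        rv = self.running_var.reshape(shape)
        return (x - rm) * ((rv + self.eps) ** -0.5) * gamma + beta


class Dropout(Module):
    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        mask = (self.rng.random(x.shape) < keep) / keep
        return x * mask


# ---------------------------------------------------------------------------
# convolution primitives
# ---------------------------------------------------------------------------


def _same_pad(k: int) -> tuple[int, int]:
    # Keras-style asymmetric padding for even kernels
    left = (k - 1) // 2
    return left, k - 1 - left


def conv1d_bank(x: Tensor, kernels: Tensor) -> Tensor:
    """Temporal filter bank: (B, C, T) ⊛ (F, K) → (B, F, C, T), same padding.

    Every kernel is correlated with every channel independently — the first
    stage of the classifier, where each band-pass filter produces one
    filtered copy of all electrodes.
    """
    B, C, T = x.shape
    F, K = kernels.shape
    pl, pr = _same_pad(K)
    xp = np.pad(x.data, ((0, 0), (0, 0), (pl, pr)))
    patches = sliding_window_view(xp, K, axis=2)  # (B, C, T, K)
    out = np.einsum("bctk,fk->bfct", patches, kernels.data, optimize=True)

    def bwd(g):
        if kernels.requires_grad:
            gk = np.einsum("bfct,bctk->fk", g, patches, optimize=True)
            kernels._accumulate(gk)
        if x.requires_grad:
            dxp = np.zeros_like(xp)
            for j in range(K):
                contrib = np.einsum("bfct,f->bct", g, kernels.data[:, j],
                                    optimize=True)
                dxp[:, :, j:j + T] += contrib
            x._accumulate(dxp[:, :, pl:pl + T])

    return Tensor.make(out, (x, kernels), bwd)


def spatial_collapse(x: Tensor, weights: Tensor) -> Tensor:
    """Depthwise spatial filtering: (B, F, C, T) × (F, M, C) → (B, F·M, T).

    For each band-pass map, project the C electrodes through M learned
    spatial patterns (depthwise convolution with kernel (C, 1), depth
    multiplier M).
    """
    B, F, C, T = x.shape
    F2, M, C2 = weights.shape
    if (F2, C2) != (F, C):
        raise ValueError(f"weights shape {weights.shape} does not match "
                         f"input (F={F}, C={C})")
    out = np.einsum("bfct,fmc->bfmt", x.data, weights.data, optimize=True)
    out = out.reshape(B, F * M, T)

    def bwd(g):
        gr = g.reshape(B, F, M, T)
        if weights.requires_grad:
            gw = np.einsum("bfmt,bfct->fmc", gr, x.data, optimize=True)
            weights._accumulate(gw)
        if x.requires_grad:
            gx = np.einsum("bfmt,fmc->bfct", gr, weights.data, optimize=True)
            x._accumulate(gx)

    return Tensor.make(out, (x, weights), bwd)


def depthwise_time_conv(x: Tensor, kernels: Tensor) -> Tensor:
    """Per-map temporal convolution: (B, M, T) ⊛ (M, K) → (B, M, T), same pad."""
    B, M, T = x.shape
    M2, K = kernels.shape
    if M2 != M:
        raise ValueError(f"kernel count {M2} != map count {M}")
    pl, pr = _same_pad(K)
    xp = np.pad(x.data, ((0, 0), (0, 0), (pl, pr)))
    patches = sliding_window_view(xp, K, axis=2)  # (B, M, T, K)
    out = np.einsum("bmtk,mk->bmt", patches, kernels.data, optimize=True)

    def bwd(g):
        if kernels.requires_grad:
            gk = np.einsum("bmt,bmtk->mk", g, patches, optimize=True)
            kernels._accumulate(gk)
        if x.requires_grad:
            dxp = np.zeros_like(xp)
            for j in range(K):
                dxp[:, :, j:j + T] += g * kernels.data[:, j][None, :, None]
            x._accumulate(dxp[:, :, pl:pl + T])

    return Tensor.make(out, (x, kernels), bwd)


def avg_pool_time(x: Tensor, size: int) -> Tensor:
    """Non-overlapping average pooling over the last axis (floor division)."""
    T = x.shape[-1]
    n = T // size
    trimmed = x[..., : n * size]
    return trimmed.reshape(*x.shape[:-1], n, size).mean(axis=-1)


def conv2d(x: Tensor, w: Tensor) -> Tensor:
    """2-D convolution, stride 1, same padding: (B,C,H,W) ⊛ (F,C,kh,kw)."""
    B, C, H, W = x.shape
    F, C2, kh, kw = w.shape
    if C2 != C:
        raise ValueError(f"channel mismatch: input {C}, kernel {C2}")
    pt, pb = _same_pad(kh)
    pl, pr = _same_pad(kw)
    xp = np.pad(x.data, ((0, 0), (0, 0), (pt, pb), (pl, pr)))
    patches = sliding_window_view(xp, (kh, kw), axis=(2, 3))  # (B,C,H,W,kh,kw)
    out = np.einsum("bchwij,fcij->bfhw", patches, w.data, optimize=True)

    def bwd(g):
        if w.requires_grad:
            gw = np.einsum("bfhw,bchwij->fcij", g, patches, optimize=True)
            w._accumulate(gw)
        if x.requires_grad:
            dxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    contrib = np.einsum("bfhw,fc->bchw", g, w.data[:, :, i, j],
                                        optimize=True)
                    dxp[:, :, i:i + H, j:j + W] += contrib
            x._accumulate(dxp[:, :, pt:pt + H, pl:pl + W])

    return Tensor.make(out, (x, w), bwd)


def conv_transpose2d(x: Tensor, w: Tensor, stride: int,
                     padding: str) -> Tensor:
    """Transposed 2-D convolution: (B,C,h,w) × (C,F,k,k) → (B,F,H,W).

    ``padding='valid'``: H = (h-1)·stride + k.  ``padding='same'``:
    H = h·stride (the full output is cropped by (k-stride)//2 on the
    top/left and the remainder on the bottom/right).
    """
    B, C, h, wdt = x.shape
    C2, F, k, k2 = w.shape
    if C2 != C or k != k2:
        raise ValueError(f"kernel shape {w.shape} incompatible with input")
    full_h = (h - 1) * stride + k
    full_w = (wdt - 1) * stride + k
    if padding == "valid":
        crop_t = crop_l = 0
        H, W = full_h, full_w
    elif padding == "same":
        if k < stride:
            raise ValueError("same padding requires kernel >= stride")
        crop_t = crop_l = (k - stride) // 2
        H, W = h * stride, wdt * stride
    else:
        raise ValueError(f"unknown padding {padding!r}")

    full = np.zeros((B, F, full_h, full_w))
    for a in range(k):
        for b in range(k):
            contrib = np.einsum("bchw,cf->bfhw", x.data, w.data[:, :, a, b],
                                optimize=True)
            full[:, :, a:a + (h - 1) * stride + 1:stride,
                 b:b + (wdt - 1) * stride + 1:stride] += contrib
    out = full[:, :, crop_t:crop_t + H, crop_l:crop_l + W]

    def bwd(g):
        gfull = np.zeros((B, F, full_h, full_w))
        gfull[:, :, crop_t:crop_t + H, crop_l:crop_l + W] = g
        for a in range(k):
            for b in range(k):
                gslice = gfull[:, :, a:a + (h - 1) * stride + 1:stride,
                               b:b + (wdt - 1) * stride + 1:stride]
                if w.requires_grad:
                    gw = np.einsum("bchw,bfhw->cf", x.data, gslice,
                                   optimize=True)
                    _acc_kernel(w, gw, a, b)
                if x.requires_grad:
                    gx = np.einsum("bfhw,cf->bchw", gslice, w.data[:, :, a, b],
                                   optimize=True)
                    x._accumulate(gx)

    return Tensor.make(out.copy(), (x, w), bwd)


def _acc_kernel(w: Tensor, gw: np.ndarray, a: int, b: int) -> None:
    if w.grad is None:
        w.grad = np.zeros_like(w.data)
    w.grad[:, :, a, b] += gw


def max_pool2d(x: Tensor, size: int = 2) -> Tensor:
    """Non-overlapping max pooling (floor division on odd sizes)."""
    B, C, H, W = x.shape
    nh, nw = H // size, W // size
    t = x[:, :, : nh * size, : nw * size]
    t = t.reshape(B, C, nh, size, nw, size)
    return t.max(axis=5).max(axis=3)


# ---------------------------------------------------------------------------
# heads and losses
# ---------------------------------------------------------------------------


def log_softmax(x: Tensor) -> Tensor:
    """Numerically stable log-softmax over the last axis."""
    m = x.data.max(axis=-1, keepdims=True)
    z = x.data - m
    lse = np.log(np.exp(z).sum(axis=-1, keepdims=True))
    out = z - lse
    probs = np.exp(out)

    def bwd(g):
        x._accumulate(g - probs * g.sum(axis=-1, keepdims=True))

    return Tensor.make(out, (x,), bwd)


def softmax(x: Tensor) -> Tensor:
    return log_softmax(x).exp()


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean softmax cross-entropy with integer labels."""
    labels = np.asarray(labels)
    ls = log_softmax(logits)
    picked = ls[np.arange(len(labels)), labels]
    return -picked.mean()


def binary_cross_entropy(p: Tensor, target: float, eps: float = 1e-12) -> Tensor:
    """Mean BCE of probabilities ``p`` against a constant 0/1 target."""
    if target == 1.0:
        return -((p + eps).log()).mean()
    if target == 0.0:
        return -((1.0 - p + eps).log()).mean()
    raise ValueError("target must be 0 or 1")


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------


class Adam:
    def __init__(self, params: Sequence[Parameter], lr: float = 5e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
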