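"""Minimal NumPy neural-network core used by the segmentation models.

Implements exactly the pieces the residual U-Nets need — 2D convolution,
instance normalization, LeakyReLU, factor-2 bilinear upsampling, channel
concatenation and residual addition — each as a layer object with an explicit
``forward``/``backward`` pair, plus the soft-Dice + focal segmentation loss
and the two optimizers used during training (Muon for convolution kernels,
AdamW for normalization affine parameters and biases).

Everything runs in float32 on the CPU.  Convolutions use im2col with
``numpy.lib.stride_tricks.sliding_window_view`` so forward and backward are
plain matrix products; the col2im scatter in the backward pass is done with
nine strided slice-adds (one per kernel tap), which never overlap for a fixed
tap, so no ``np.add.at`` is required.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Param",
    "Conv2d",
    "InstanceNorm2d",
    "LeakyReLU",
    "BilinearUp2",
    "dice_focal_loss",
    "Muon",
    "AdamW",
    "cosine_to_constant_lr",
]


class Param:
    """A trainable array with its gradient accumulator.

    ``kind`` routes the parameter to an optimizer: ``"conv"`` kernels go to
    Muon, everything else (normalization affine parameters, biases) to AdamW.
    """

    def __init__(self, value: np.ndarray, kind: str, name: str = "") -> None:
        self.value = np.ascontiguousarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)
        self.kind = kind
        self.name = name

    @property
    def size(self) -> int:
        return self.value.size

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    std = math.sqrt(2.0 / max(fan_in, 1))
    return rng.normal(0.0, std, size=shape).astype(np.float32)


class Conv2d:
    """2D convolution, NCHW layout.

    3x3 convolutions use same-padding; the 2x2 stride-2 downsampling
    convolution uses no padding (even input sizes are guaranteed by the
    U-Net's input padding).  Bias is omitted whenever the convolution feeds a
    normalization layer.
    """

    def __init__(self, cin: int, cout: int, k: int, stride: int = 1,
                 bias: bool = False, rng: np.random.Generator | None = None,
                 name: str = "conv") -> None:
        rng = rng or np.random.default_rng(0)
        self.cin, self.cout, self.k, self.stride = cin, cout, k, stride
        self.pad = (k - 1) // 2 if stride == 1 else 0
        self.weight = Param(_he_init(rng, (cout, cin, k, k), cin * k * k),
                            "conv", name + ".weight")
        self.bias = Param(np.zeros(cout, np.float32), "bias", name + ".bias") if bias else None
        self._cache = None

    def params(self):
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        k, s, p = self.k, self.stride, self.pad
        if p:
            x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        hp, wp = x.shape[2], x.shape[3]
        ho, wo = (hp - k) // s + 1, (wp - k) // s + 1
        win = sliding_window_view(x, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * k * k)
        wm = self.weight.value.reshape(self.cout, c * k * k)
        y = cols @ wm.T
        if self.bias is not None:
            y += self.bias.value
        self._cache = (cols, x.shape, (n, ho, wo))
        return np.ascontiguousarray(
            y.reshape(n, ho, wo, self.cout).transpose(0, 3, 1, 2))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, xshape, (n, ho, wo) = self._cache
        k, s, p, c = self.k, self.stride, self.pad, self.cin
        dyc = dy.transpose(0, 2, 3, 1).reshape(n * ho * wo, self.cout)
        wm = self.weight.value.reshape(self.cout, c * k * k)
        self.weight.grad += (dyc.T @ cols).reshape(self.weight.value.shape)
        if self.bias is not None:
            self.bias.grad += dyc.sum(axis=0)
        dcols = (dyc @ wm).reshape(n, ho, wo, c, k, k)
        dxp = np.zeros(xshape, np.float32)
        for ki in range(k):
            for kj in range(k):
                dxp[:, :, ki:ki + s * ho:s, kj:kj + s * wo:s] += \
                    dcols[:, :, :, :, ki, kj].transpose(0, 3, 1, 2)
        if p:
            dxp = dxp[:, :, p:-p, p:-p]
        return dxp


class InstanceNorm2d:
    """Per-sample, per-channel normalization over the spatial axes."""

    def __init__(self, c: int, eps: float = 1e-5, name: str = "norm") -> None:
        self.eps = eps
        self.gamma = Param(np.ones(c, np.float32), "affine", name + ".gamma")
        self.beta = Param(np.zeros(c, np.float32), "affine", name + ".beta")
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=(2, 3), keepdims=True)
        var = x.var(axis=(2, 3), keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xh = (x - mu) * inv
        self._cache = (xh, inv)
        return self.gamma.value[None, :, None, None] * xh + \
            self.beta.value[None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xh, inv = self._cache
        self.gamma.grad += (dy * xh).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        dxh = dy * self.gamma.value[None, :, None, None]
        m = xh.shape[2] * xh.shape[3]
        return inv * (dxh - dxh.mean(axis=(2, 3), keepdims=True)
                      - xh * (dxh * xh).mean(axis=(2, 3), keepdims=True))


class LeakyReLU:
    def __init__(self, slope: float = 0.01) -> None:
        self.slope = slope
        self._mask = None

    def params(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x >= 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, self.slope * dy)


class BilinearUp2:
    """Factor-2 bilinear upsampling (half-pixel centers, edges clamped).

    Output pixel centers fall at input coordinates (i - 0.5) / 2, so even
    outputs mix (0.25, 0.75) and odd outputs (0.75, 0.25) of neighbouring
    input rows/columns; the transpose of the same stencil is the backward.
    """

    def __init__(self) -> None:
        self._in_shape = None

    def params(self):
        return []

    @staticmethod
    def _up1d(x: np.ndarray, axis: int) -> np.ndarray:
        xm = np.moveaxis(x, axis, -1)
        lo = np.concatenate([xm[..., :1], xm[..., :-1]], axis=-1)   # x[i-1]
        hi = np.concatenate([xm[..., 1:], xm[..., -1:]], axis=-1)   # x[i+1]
        even = 0.25 * lo + 0.75 * xm
        odd = 0.75 * xm + 0.25 * hi
        out = np.empty(xm.shape[:-1] + (2 * xm.shape[-1],), np.float32)
        out[..., 0::2] = even
        out[..., 1::2] = odd
        return np.moveaxis(out, -1, axis)

    @staticmethod
    def _down1d(dy: np.ndarray, axis: int) -> np.ndarray:
        g = np.moveaxis(dy, axis, -1)
        even, odd = g[..., 0::2], g[..., 1::2]
        # transpose of _up1d: even[i] sends 0.25 to i-1 (clamped) and 0.75 to i;
        # odd[i] sends 0.75 to i and 0.25 to i+1 (clamped).
        dx = 0.75 * even + 0.75 * odd
        dx[..., 0] += 0.25 * even[..., 0]
        dx[..., :-1] += 0.25 * even[..., 1:]
        dx[..., -1] += 0.25 * odd[..., -1]
        dx[..., 1:] += 0.25 * odd[..., :-1]
        return np.moveaxis(dx, -1, axis)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._in_shape = x.shape
        return self._up1d(self._up1d(x, 2), 3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return self._down1d(self._down1d(dy, 3), 2)


# ---------------------------------------------------------------------------
# Loss
# ---------------------------------------------------------------------------

def softmax(z: np.ndarray, axis: int = 1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def dice_focal_loss(logits: np.ndarray, target: np.ndarray,
                    focal_gamma: float = 2.0,
                    class_weights: np.ndarray | None = None,
                    eps: float = 1.0):
    """Sum of soft Dice loss and focal loss for dense multi-class targets.

    Parameters
    ----------
    logits : (N, C, H, W) raw scores.
    target : (N, H, W) integer class mask.
    focal_gamma : focusing exponent; 0 recovers plain cross-entropy.
    class_weights : optional per-class weights applied to the focal term.
    eps : Dice smoothing constant.

    Returns
    -------
    loss : float, ``dice + focal``.
    dlogits : gradient of the loss with respect to ``logits``.
    parts : dict with the two terms separately.
    """
    if target.size == 0:
        raise ValueError("empty target")
    n, c, h, w = logits.shape
    p = softmax(logits.astype(np.float64), axis=1)
    onehot = np.zeros_like(p)
    idx0, idx2, idx3 = np.ogrid[:n, :h, :w]
    onehot[idx0, target, idx2, idx3] = 1.0

    # --- soft Dice: 1 - mean_c (2 sum p t + eps) / (sum p + sum t + eps)
    inter = (p * onehot).sum(axis=(0, 2, 3))
    psum = p.sum(axis=(0, 2, 3))
    tsum = onehot.sum(axis=(0, 2, 3))
    num = 2.0 * inter + eps
    den = psum + tsum + eps
    dice_loss = 1.0 - float(np.mean(num / den))
    # d(dice_loss)/dp_c[i] = -(1/C) * (2 t - num/den) / den
    ddice_dp = -(1.0 / c) * (2.0 * onehot - (num / den)[None, :, None, None]) \
        / den[None, :, None, None]

    # --- focal: mean_i  w_t (1 - p_t)^gamma (-log p_t)
    pt = np.clip(p[idx0, target, idx2, idx3], 1e-12, 1.0)
    wt = (class_weights[target] if class_weights is not None
          else np.ones_like(pt))
    npix = n * h * w
    focal = float(np.mean(wt * (1.0 - pt) ** focal_gamma * (-np.log(pt))))
    # dL/dp_t per pixel (scalar g), then softmax jacobian: dz_j = g pt (d_jt - p_j)
    g = wt * (focal_gamma * (1.0 - pt) ** (focal_gamma - 1.0) * np.log(pt)
              - (1.0 - pt) ** focal_gamma / pt) / npix

    # chain both terms through softmax: dz = p * (dp - sum_c dp_c p_c)
    dfocal_dp = np.zeros_like(p)
    dfocal_dp[idx0, target, idx2, idx3] = g
    dp = ddice_dp + dfocal_dp
    dz = p * (dp - (dp * p).sum(axis=1, keepdims=True))
    loss = dice_loss + focal
    return loss, dz.astype(np.float32), {"dice": dice_loss, "focal": focal}


# ---------------------------------------------------------------------------
# Optimizers and schedule
# ---------------------------------------------------------------------------

def newton_schulz_orthogonalize(g: np.ndarray, steps: int = 5) -> np.ndarray:
    """Approximately map a matrix to the nearest (semi-)orthogonal matrix.

    Quintic Newton-Schulz iteration with the coefficients commonly used for
    the Muon optimizer; operates on the Frobenius-normalized input.
    """
    a, b, c = 3.4445, -4.7750, 2.0315
    x = g.astype(np.float32)
    x = x / (np.linalg.norm(x) + 1e-7)
    transposed = x.shape[0] > x.shape[1]
    if transposed:
        x = x.T
    for _ in range(steps):
        s = x @ x.T
        x = a * x + (b * s + c * (s @ s)) @ x
    return x.T if transposed else x


class Muon:
    """Orthogonalized-momentum updates for convolution kernels.

    Kernels are reshaped to (out_channels, in_channels * k * k); the momentum
    buffer is orthogonalized by Newton-Schulz before the step, scaled by
    sqrt(max(1, rows/cols)) to keep update RMS comparable across shapes.
    """

    def __init__(self, params, lr: float, momentum: float = 0.95,
                 nesterov: bool = True) -> None:
        self.params = [p for p in params if p.kind == "conv"]
        self.lr = lr
        self.momentum = momentum
        self.nesterov = nesterov
        self._buf = [np.zeros_like(p.value) for p in self.params]

    def step(self) -> None:
        for p, buf in zip(self.params, self._buf):
            g = p.grad
            buf *= self.momentum
            buf += g
            use = g + self.momentum * buf if self.nesterov else buf
            mat = use.reshape(use.shape[0], -1)
            o = newton_schulz_orthogonalize(mat)
            scale = math.sqrt(max(1.0, mat.shape[0] / mat.shape[1]))
            p.value -= (self.lr * scale) * o.reshape(p.value.shape)


class AdamW:
    def __init__(self, params, lr: float, betas=(0.9, 0.999),
                 weight_decay: float = 0.001, eps: float = 1e-8) -> None:
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.wd = weight_decay
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in self.params]
        self._v = [np.zeros_like(p.value) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.b1, self.b2
        for p, m, v in zip(self.params, self._m, self._v):
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mh = m / (1 - b1 ** self.t)
            vh = v / (1 - b2 ** self.t)
            p.value -= self.lr * (mh / (np.sqrt(vh) + self.eps)
                                  + self.wd * p.value)


def cosine_to_constant_lr(batch: int, lr_init: float, lr_final: float,
                          schedule_batches: int) -> float:
    """Cosine decay from ``lr_init`` to ``lr_final``, then constant."""
    if batch >= schedule_batches:
        return lr_final
    frac = batch / schedule_batches
    return lr_final + 0.5 * (lr_init - lr_final) * (1 + math.cos(math.pi * frac))
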