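"""Residual U-Nets for paper-ECG segmentation, and their training loop.

Two networks are defined:

* the main 4-class network (background, grid, signal, text) with encoder
  widths (32, 64, 128, 256, 320, 320, 320, 320), and
* a lightweight 13-class lead-text network (background + the 12 standard
  leads) with widths (32, 64, 128, 256, 256) that reads the single-channel
  text-probability plane.

Architecture recipe (fixed; the default main configuration has 22,554,340
trainable parameters, i.e. 22.6 M at one decimal):

* stem: 3x3 conv (no bias) + InstanceNorm + LeakyReLU to the first width;
* one residual encoder block per width: two (3x3 conv, InstanceNorm,
  LeakyReLU) stages with an identity shortcut over the pair;
* a 2x2 stride-2 convolution + InstanceNorm + LeakyReLU between widths;
* decoder per level: bilinear x2 upsample, 1x1 conv + InstanceNorm +
  LeakyReLU down to the skip width, concatenation with the skip, then two
  (3x3 conv, InstanceNorm, LeakyReLU) stages with a 1x1 projection shortcut
  over the pair;
* final 3x3 convolution (with bias) to the output classes.

Convolutions that feed a normalization carry no bias.  Training follows the
full-scale recipe: soft Dice + focal loss, Muon on convolution kernels and
AdamW on normalization affine parameters, cosine-to-constant learning rate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .nn import (AdamW, BilinearUp2, Conv2d, InstanceNorm2d, LeakyReLU, Muon,
                 cosine_to_constant_lr, dice_focal_loss, softmax)

__all__ = [
    "UNetConfig", "TrainConfig", "UNet", "build_main_unet", "build_text_unet",
    "train", "segment", "save_checkpoint", "load_checkpoint",
    "TrainingDivergence", "MAIN_WIDTHS", "TEXT_WIDTHS", "CLASS_NAMES",
    "LEAD_CLASS_NAMES",
]

MAIN_WIDTHS = (32, 64, 128, 256, 320, 320, 320, 320)
TEXT_WIDTHS = (32, 64, 128, 256, 256)

#: fixed class order of the main network's output planes
CLASS_NAMES = ("background", "grid", "signal", "text")
#: fixed class order of the text network (background first, then leads)
LEAD_CLASS_NAMES = ("background", "I", "II", "III", "aVR", "aVL", "aVF",
                    "V1", "V2", "V3", "V4", "V5", "V6")


class TrainingDivergence(RuntimeError):
    """Raised when the loss becomes non-finite during training."""


@dataclass(frozen=True)
class UNetConfig:
    encoder_widths: tuple = MAIN_WIDTHS
    in_channels: int = 3
    out_channels: int = 4
    negative_slope: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if not self.encoder_widths or any(w <= 0 for w in self.encoder_widths):
            raise ValueError("encoder widths must be non-empty and positive")
        if self.out_channels < 2:
            raise ValueError("out_channels must be >= 2")


@dataclass
class TrainConfig:
    batch_size: int = 12
    patch_px: int = 1024
    lr_init: float = 0.0037
    lr_final: float = 0.00037
    schedule_batches: int = 20_000
    weight_decay: float = 0.001
    muon_momentum: float = 0.95
    adamw_betas: tuple = (0.9, 0.999)
    epochs: int = 45
    seed: int = 0
    focal_gamma: float = 2.0
    use_muon: bool = True           # False -> pure AdamW fallback

    def __post_init__(self):
        if self.lr_final > self.lr_init:
            raise ValueError("lr_final must be <= lr_init")
        for name in ("batch_size", "patch_px", "lr_init", "lr_final",
                     "schedule_batches", "epochs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


class _EncoderBlock:
    """Two conv-norm-act stages with an identity residual shortcut."""

    def __init__(self, w, slope, rng, name):
        self.conv1 = Conv2d(w, w, 3, rng=rng, name=name + ".conv1")
        self.norm1 = InstanceNorm2d(w, name=name + ".norm1")
        self.act1 = LeakyReLU(slope)
        self.conv2 = Conv2d(w, w, 3, rng=rng, name=name + ".conv2")
        self.norm2 = InstanceNorm2d(w, name=name + ".norm2")
        self.act2 = LeakyReLU(slope)

    def params(self):
        return (self.conv1.params() + self.norm1.params()
                + self.conv2.params() + self.norm2.params())

    def forward(self, x):
        h = self.act1.forward(self.norm1.forward(self.conv1.forward(x)))
        h = self.norm2.forward(self.conv2.forward(h))
        return self.act2.forward(h + x)

    def backward(self, dy):
        d = self.act2.backward(dy)
        db = self.norm2.backward(d)
        db = self.conv2.backward(db)
        db = self.act1.backward(db)
        db = self.norm1.backward(db)
        db = self.conv1.backward(db)
        return db + d


class _Down:
    def __init__(self, cin, cout, slope, rng, name):
        self.conv = Conv2d(cin, cout, 2, stride=2, rng=rng, name=name + ".conv")
        self.norm = InstanceNorm2d(cout, name=name + ".norm")
        self.act = LeakyReLU(slope)

    def params(self):
        return self.conv.params() + self.norm.params()

    def forward(self, x):
        return self.act.forward(self.norm.forward(self.conv.forward(x)))

    def backward(self, dy):
        return self.conv.backward(self.norm.backward(self.act.backward(dy)))


class _DecoderBlock:
    """Upsample, reduce, concat skip, two conv stages + projection shortcut."""

    def __init__(self, cdeep, w, slope, rng, name):
        self.up = BilinearUp2()
        self.pre = Conv2d(cdeep, w, 1, rng=rng, name=name + ".pre")
        self.pre_norm = InstanceNorm2d(w, name=name + ".pre_norm")
        self.pre_act = LeakyReLU(slope)
        self.conv1 = Conv2d(2 * w, w, 3, rng=rng, name=name + ".conv1")
        self.norm1 = InstanceNorm2d(w, name=name + ".norm1")
        self.act1 = LeakyReLU(slope)
        self.conv2 = Conv2d(w, w, 3, rng=rng, name=name + ".conv2")
        self.norm2 = InstanceNorm2d(w, name=name + ".norm2")
        self.proj = Conv2d(2 * w, w, 1, rng=rng, name=name + ".proj")
        self.act2 = LeakyReLU(slope)
        self.w = w

    def params(self):
        return (self.pre.params() + self.pre_norm.params()
                + self.conv1.params() + self.norm1.params()
                + self.conv2.params() + self.norm2.params()
                + self.proj.params())

    def forward(self, deep, skip):
        u = self.pre_act.forward(self.pre_norm.forward(
            self.pre.forward(self.up.forward(deep))))
        cat = np.concatenate([u, skip], axis=1)
        h = self.act1.forward(self.norm1.forward(self.conv1.forward(cat)))
        h = self.norm2.forward(self.conv2.forward(h))
        return self.act2.forward(h + self.proj.forward(cat))

    def backward(self, dy):
        d = self.act2.backward(dy)
        dcat = self.proj.backward(d)
        db = self.norm2.backward(d)
        db = self.conv2.backward(db)
        db = self.act1.backward(db)
        db = self.norm1.backward(db)
        dcat = dcat + self.conv1.backward(db)
        du, dskip = dcat[:, :self.w], dcat[:, self.w:]
        du = self.pre.backward(self.pre_norm.backward(self.pre_act.backward(du)))
        ddeep = self.up.backward(du)
        return ddeep, dskip


class UNet:
    """Residual U-Net assembled from the fixed recipe above."""

    def __init__(self, config: UNetConfig) -> None:
        self.config = config
        w = config.encoder_widths
        slope = config.negative_slope
        rng = np.random.default_rng(config.seed)
        self.stem_conv = Conv2d(config.in_channels, w[0], 3, rng=rng, name="stem")
        self.stem_norm = InstanceNorm2d(w[0], name="stem.norm")
        self.stem_act = LeakyReLU(slope)
        self.enc = [_EncoderBlock(w[i], slope, rng, f"enc{i}")
                    for i in range(len(w))]
        self.down = [_Down(w[i], w[i + 1], slope, rng, f"down{i}")
                     for i in range(len(w) - 1)]
        self.dec = [_DecoderBlock(w[i + 1], w[i], slope, rng, f"dec{i}")
                    for i in range(len(w) - 1)]
        self.head = Conv2d(w[0], config.out_channels, 3, bias=True, rng=rng,
                           name="head")
        self._skips = None

    # -- bookkeeping ---------------------------------------------------
    def params(self):
        ps = self.stem_conv.params() + self.stem_norm.params()
        for b in self.enc:
            ps += b.params()
        for d in self.down:
            ps += d.params()
        for d in self.dec:
            ps += d.params()
        ps += self.head.params()
        return ps

    def num_parameters(self) -> int:
        """Total trainable parameter count."""
        return sum(p.size for p in self.params())

    @property
    def depth(self) -> int:
        return len(self.config.encoder_widths)

    @property
    def stride(self) -> int:
        """Input sizes must be divisible by this (2^(levels-1))."""
        return 2 ** (self.depth - 1)

    def zero_grad(self):
        for p in self.params():
            p.zero_grad()

    # -- forward / backward --------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        """x: (N, C, H, W) float32, H and W divisible by ``self.stride``."""
        if x.shape[2] % self.stride or x.shape[3] % self.stride:
            raise ValueError(
                f"spatial size {x.shape[2:]} not divisible by {self.stride}")
        h = self.stem_act.forward(self.stem_norm.forward(
            self.stem_conv.forward(x)))
        skips = []
        for i, blk in enumerate(self.enc):
            h = blk.forward(h)
            if i < len(self.down):
                skips.append(h)
                h = self.down[i].forward(h)
        self._skips = skips
        for i in reversed(range(len(self.dec))):
            h = self.dec[i].forward(h, skips[i])
        return self.head.forward(h)

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        d = self.head.backward(dlogits)
        dskips = [None] * len(self.dec)
        for i in range(len(self.dec)):
            d, ds = self.dec[i].backward(d)
            dskips[i] = ds
        for i in reversed(range(len(self.enc))):
            if i < len(self.down):
                d = self.down[i].backward(d)
                d = d + dskips[i]
            d = self.enc[i].backward(d)
        d = self.stem_conv.backward(self.stem_norm.backward(
            self.stem_act.backward(d)))
        return d


def build_main_unet(config: UNetConfig | None = None) -> UNet:
    """The 4-class background/grid/signal/text segmentation network."""
    return UNet(config or UNetConfig())


def build_text_unet(config: UNetConfig | None = None) -> UNet:
    """The lightweight 13-class lead-name network (1-channel input)."""
    if config is None:
        config = UNetConfig(encoder_widths=TEXT_WIDTHS, in_channels=1,
                            out_channels=13)
    if config.in_channels != 1 or config.out_channels != 13:
        raise ValueError("text net takes 1 input channel and 13 classes")
    return UNet(config)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def train(model: UNet, sample_stream: Iterable, config: TrainConfig):
    """Optimize ``model`` on a stream of (image, mask) batches.

    ``sample_stream`` yields ``(images, masks)`` with images (N, C, H, W)
    float32 in [0, 1] and masks (N, H, W) integer class labels.  Convolution
    kernels are updated with Muon (orthogonalized momentum), normalization
    affine parameters and biases with AdamW; the learning rate follows a
    cosine decay from ``lr_init`` to ``lr_final`` over ``schedule_batches``
    batches and is constant afterwards.

    Returns the list of per-batch losses (the loss log).
    """
    params = model.params()
    conv_params = [p for p in params if p.kind == "conv"]
    other_params = [p for p in params if p.kind != "conv"]
    if config.use_muon:
        muon = Muon(conv_params, lr=config.lr_init,
                    momentum=config.muon_momentum)
        adamw = AdamW(other_params, lr=config.lr_init,
                      betas=config.adamw_betas,
                      weight_decay=config.weight_decay)
    else:
        muon = None
        adamw = AdamW(params, lr=config.lr_init, betas=config.adamw_betas,
                      weight_decay=config.weight_decay)

    loss_log = []
    for batch_idx, (images, masks) in enumerate(sample_stream):
        lr = cosine_to_constant_lr(batch_idx, config.lr_init, config.lr_final,
                                   config.schedule_batches)
        model.zero_grad()
        logits = model.forward(np.ascontiguousarray(images, np.float32))
        loss, dz, _ = dice_focal_loss(logits, masks,
                                      focal_gamma=config.focal_gamma)
        if not np.isfinite(loss):
            raise TrainingDivergence(
                f"non-finite loss {loss!r} at batch {batch_idx}")
        model.backward(dz)
        if muon is not None:
            muon.lr = lr
            adamw.lr = lr
            muon.step()
            adamw.step()
        else:
            adamw.lr = lr
            adamw.step()
        loss_log.append(float(loss))
    return loss_log


# ---------------------------------------------------------------------------
# Inference
# ---------------------------------------------------------------------------

def _as_nchw(image: np.ndarray, in_channels: int) -> np.ndarray:
    img = np.asarray(image)
    if img.dtype == np.uint8:
        img = img.astype(np.float32) / 255.0
    img = img.astype(np.float32)
    if img.ndim == 2:
        img = img[:, :, None]
    if img.shape[2] != in_channels:
        if in_channels == 1:
            img = img.mean(axis=2, keepdims=True)
        elif in_channels == 3 and img.shape[2] == 1:
            img = np.repeat(img, 3, axis=2)
        else:
            raise ValueError(f"image has {img.shape[2]} channels, "
                             f"model wants {in_channels}")
    return img.transpose(2, 0, 1)[None]


def _forward_probs(model: UNet, x: np.ndarray) -> np.ndarray:
    """Pad to the model stride, forward, softmax, crop back. x: (1,C,H,W)."""
    s = model.stride
    h, w = x.shape[2], x.shape[3]
    ph = (-h) % s
    pw = (-w) % s
    if ph or pw:
        x = np.pad(x, ((0, 0), (0, 0), (0, ph), (0, pw)), mode="reflect")
    logits = model.forward(x)
    return softmax(logits, axis=1)[0, :, :h, :w]


def segment(model: UNet, image: np.ndarray, tile: int = 1024,
            overlap: int = 128) -> np.ndarray:
    """Per-pixel class probabilities for an image of any size.

    Images whose long side exceeds ``tile`` are processed in overlapping
    tiles blended with a cosine ramp, so tiled and whole-image inference
    agree closely away from tile borders.  Returns (C, H, W) probabilities
    that sum to one per pixel.
    """
    x = _as_nchw(image, model.config.in_channels)
    h, w = x.shape[2], x.shape[3]
    if max(h, w) <= tile:
        return _forward_probs(model, x)

    step = tile - overlap
    out = np.zeros((model.config.out_channels, h, w), np.float64)
    weight = np.zeros((h, w), np.float64)

    def ramp(n):
        r = np.ones(n)
        k = min(overlap, n)
        t = 0.5 * (1 - np.cos(np.pi * (np.arange(k) + 0.5) / k))
        r[:k] = t
        r[n - k:] = t[::-1]
        return r

    ys = list(range(0, max(h - tile, 0) + 1, step)) or [0]
    if ys[-1] + tile < h:
        ys.append(h - tile)
    xs = list(range(0, max(w - tile, 0) + 1, step)) or [0]
    if xs[-1] + tile < w:
        xs.append(w - tile)
    for y0 in ys:
        for x0 in xs:
            y1, x1 = min(y0 + tile, h), min(x0 + tile, w)
            probs = _forward_probs(model, x[:, :, y0:y1, x0:x1])
            wy = ramp(y1 - y0)
            wx = ramp(x1 - x0)
            wmat = wy[:, None] * wx[None, :]
            out[:, y0:y1, x0:x1] += probs * wmat
            weight[y0:y1, x0:x1] += wmat
    out /= np.maximum(weight, 1e-12)
    return (out / out.sum(axis=0, keepdims=True)).astype(np.float32)


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: UNet, path) -> None:
    """Single-file checkpoint: weights (npz) with the config embedded."""
    arrays = {f"p{i}": p.value for i, p in enumerate(model.params())}
    cfg = asdict(model.config)
    cfg["encoder_widths"] = list(cfg["encoder_widths"])
    arrays["config_json"] = np.frombuffer(
        json.dumps(cfg).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path) -> UNet:
    with np.load(path) as data:
        cfg = json.loads(bytes(data["config_json"]).decode())
        cfg["encoder_widths"] = tuple(cfg["encoder_widths"])
        model = UNet(UNetConfig(**cfg))
        for i, p in enumerate(model.params()):
            arr = data[f"p{i}"]
            if arr.shape != p.value.shape:
                raise ValueError("checkpoint does not match architecture")
            p.value[...] = arr
    return model
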