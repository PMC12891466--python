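"""Synthetic paper-ECG generator with pixel-level ground truth.

Produces the training and test material for every downstream stage: a
parametric multi-lead ECG simulator (sum of five Gaussian waves per beat —
P, Q, R, S, T — with beat-to-beat jitter, baseline wander and noise), a
paper renderer that draws the standard 1 mm / 5 mm grid, the lead traces and
lead-name text at a configurable dpi, and a perspective/background
augmenter.  Every rendered sample carries exact class masks (background,
grid, signal, text), a 13-class lead-text mask, the ground-truth signals,
the applied homography and the true pixels-per-mm calibration.

Limb leads satisfy III = II - I (and the augmented-lead identities) exactly,
which downstream consistency checks rely on.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
from PIL import Image, ImageDraw, ImageFont
from scipy import ndimage
from skimage.draw import line as skline
from skimage.transform import ProjectiveTransform, warp

from .layout import (DEFAULT_LAYOUT, STANDARD_LEADS, LayoutTemplate,
                     builtin_templates, get_template)

__all__ = [
    "MultiLeadSignal", "RenderConfig", "RenderedSample", "PanelGeometry",
    "simulate_ecg", "render_paper", "apply_perspective", "make_training_crop",
]

MM_PER_INCH = 25.4

# class mask labels
BACKGROUND, GRID, SIGNAL, TEXT = 0, 1, 2, 3


@dataclass
class MultiLeadSignal:
    """Per-lead voltage series in millivolts at a common sample rate."""
    lead_names: list
    samples: np.ndarray        # (n_leads, n) float
    rate: float                # Hz

    def __post_init__(self):
        self.samples = np.atleast_2d(np.asarray(self.samples, float))
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if len(self.lead_names) != self.samples.shape[0]:
            raise ValueError("lead_names/samples mismatch")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("voltages must be finite")

    @property
    def duration_s(self) -> float:
        return self.samples.shape[1] / self.rate

    def lead(self, name: str) -> np.ndarray:
        return self.samples[self.lead_names.index(name)]


@dataclass
class RenderConfig:
    """Rendering and augmentation knobs for one paper render."""
    speed_mm_per_s: float = 25.0
    gain_mm_per_mV: float = 10.0
    dpi: float = 150.0
    layout_name: str = DEFAULT_LAYOUT
    line_width_px: int | None = None        # None -> dpi-scaled default
    line_color: tuple = (25, 25, 35)
    grid_color: tuple = (245, 170, 170)
    grid_major_color: tuple = (235, 120, 120)
    paper_color: tuple = (252, 250, 246)
    background_style: str = "white"
    text_font_scale: float = 1.0
    margin_mm: float = 10.0
    row_height_mm: float = 30.0
    calibration_pulse: bool = False
    thermal_fade: float = 0.0               # 0..1 brightness-field strength
    seed: int = 0

    def __post_init__(self):
        if self.speed_mm_per_s <= 0 or self.gain_mm_per_mV <= 0:
            raise ValueError("speed and gain must be positive")
        if self.dpi <= 0:
            raise ValueError("dpi must be positive")

    @property
    def px_per_mm(self) -> float:
        return self.dpi / MM_PER_INCH


@dataclass
class PanelGeometry:
    """Pixel-space geometry of one rendered lead segment."""
    lead: str
    x0: int
    x1: int
    baseline_row: float
    window: tuple              # (t0, t1) seconds
    band: tuple                # (y0, y1) pixel rows of the band
    is_rhythm: bool


@dataclass
class RenderedSample:
    image: np.ndarray           # (H, W, 3) uint8
    class_mask: np.ndarray      # (H, W) uint8 in {0..3}
    lead_text_mask: np.ndarray  # (H, W) uint8, 0=bg, 1..12 standard leads
    truth: MultiLeadSignal
    homography: np.ndarray      # 3x3, original paper coords -> image coords
    calibration_truth: tuple    # (px_per_mm_x, px_per_mm_y)
    config: RenderConfig
    panels: list                # list of PanelGeometry (original paper frame)


# ---------------------------------------------------------------------------
# Waveform simulation
# ---------------------------------------------------------------------------

# (center s relative to R, width s, amplitude mV) for P, Q, R, S, T
_BASE_WAVES = ((-0.17, 0.025, 0.12), (-0.042, 0.010, -0.12),
               (0.0, 0.013, 1.10), (0.036, 0.013, -0.25),
               (0.30, 0.060, 0.35))

_DEFAULT_MORPHOLOGY = {
    "heart_rate_bpm": 70.0,
    "rr_jitter": 0.03,           # s.d. of RR as a fraction of the mean
    "amp_scale_range": (0.55, 1.3),   # per-wave scale range, chest leads
    "lead_jitter_range": (0.82, 1.18),  # independent per-limb-lead variation
    "qrs_axis_deg": (42.0, 52.0),     # frontal-plane QRS axis range
    "baseline_wander_mv": 0.08,
    "noise_mv": 0.008,
}


def simulate_ecg(n_leads=12, duration_s: float = 10.0, rate: float = 1000.0,
                 morphology_params: dict | None = None,
                 seed: int = 0) -> MultiLeadSignal:
    """Quasi-periodic P-QRS-T waveforms as a sum of Gaussians per beat.

    ``n_leads`` may be an integer (the first n standard leads) or an
    explicit list of lead names.  Leads I and II are frontal-plane
    projections of per-wave dipole axes (P, QRS and T axes drawn from
    physiologic ranges) with independent per-lead amplitude jitter; the
    remaining limb leads are derived so that III = II - I,
    aVR = -(I + II)/2, aVL = I - II/2 and aVF = II - I/2 hold exactly.
    Chest leads get independent per-wave scales.  Deterministic per seed.
    """
    if duration_s <= 0 or rate <= 0:
        raise ValueError("duration and rate must be positive")
    names = (list(STANDARD_LEADS[:n_leads]) if isinstance(n_leads, int)
             else list(n_leads))
    for nm in names:
        if nm not in STANDARD_LEADS:
            raise ValueError(f"unknown lead {nm!r}")
    p = dict(_DEFAULT_MORPHOLOGY, **(morphology_params or {}))
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * rate))
    t = np.arange(n) / rate

    # beat centers with jittered RR intervals
    rr = 60.0 / p["heart_rate_bpm"]
    centers = []
    c = rr * rng.uniform(0.3, 0.9)
    while c < duration_s + rr:
        centers.append(c)
        c += rr * max(0.5, 1.0 + p["rr_jitter"] * rng.normal())
    centers = np.array(centers)

    def synth_channel(wave_scales):
        y = np.zeros(n)
        for (c0, w, a), s in zip(_BASE_WAVES, wave_scales):
            for bc in centers:
                mu = bc + c0
                lo = max(0, int((mu - 5 * w) * rate))
                hi = min(n, int((mu + 5 * w) * rate) + 1)
                if lo < hi:
                    y[lo:hi] += a * s * np.exp(
                        -0.5 * ((t[lo:hi] - mu) / w) ** 2)
        return y

    def rand_scales(base=1.0):
        lo, hi = p["amp_scale_range"]
        return base * rng.uniform(lo, hi, size=5)

    def degrade(y):
        """Baseline wander + noise on an independent (source) channel."""
        out = y.copy()
        if p["baseline_wander_mv"] > 0:
            amp = p["baseline_wander_mv"] * rng.uniform(0.3, 1.0)
            f = rng.uniform(0.15, 0.4)
            ph = rng.uniform(0, 2 * np.pi)
            out += amp * np.sin(2 * np.pi * f * t + ph)
        if p["noise_mv"] > 0:
            out += p["noise_mv"] * rng.normal(size=out.shape)
        return out

    # noise is applied to the source channels (I, II, V1-V6) before the
    # derived limb leads are formed, so III = II - I holds exactly
    channels = {}
    need_limb = any(l in names for l in ("I", "II", "III", "aVR", "aVL", "aVF"))
    if need_limb:
        # per-wave frontal axes: QRS axis shared by Q, R, S; P and T near it
        qlo, qhi = p["qrs_axis_deg"]
        qrs_axis = rng.uniform(qlo, qhi)
        axes_deg = np.array([
            rng.uniform(42, 58),             # P
            qrs_axis, qrs_axis, qrs_axis,    # Q, R, S
            qrs_axis - rng.uniform(5, 25),   # T
        ])
        axes = np.radians(axes_deg)
        jlo, jhi = p["lead_jitter_range"]
        proj_i = np.cos(axes) * rng.uniform(jlo, jhi, size=5)
        proj_ii = np.cos(axes - math.radians(60)) \
            * rng.uniform(jlo, jhi, size=5)
        lead_i = degrade(synth_channel(proj_i))
        lead_ii = degrade(synth_channel(proj_ii))
        channels["I"], channels["II"] = lead_i, lead_ii
        channels["III"] = lead_ii - lead_i
        channels["aVR"] = -(lead_i + lead_ii) / 2.0
        channels["aVL"] = lead_i - lead_ii / 2.0
        channels["aVF"] = lead_ii - lead_i / 2.0
    for v in ("V1", "V2", "V3", "V4", "V5", "V6"):
        if v in names:
            channels[v] = degrade(synth_channel(rand_scales()))

    sig = np.stack([channels[nm] for nm in names])
    return MultiLeadSignal(names, sig, rate)


# ---------------------------------------------------------------------------
# Paper rendering
# ---------------------------------------------------------------------------

def _draw_polyline_mask(mask: np.ndarray, rows: np.ndarray, cols: np.ndarray,
                        width_px: int) -> None:
    """Rasterize a polyline (with thickness) into a boolean mask."""
    h, w = mask.shape
    stroke = np.zeros_like(mask)
    r = np.clip(np.round(rows).astype(int), 0, h - 1)
    c = np.clip(np.round(cols).astype(int), 0, w - 1)
    for i in range(len(r) - 1):
        rr, cc = skline(r[i], c[i], r[i + 1], c[i + 1])
        stroke[rr, cc] = True
    if width_px > 1:
        stroke = ndimage.binary_dilation(
            stroke, structure=ndimage.generate_binary_structure(2, 2),
            iterations=(width_px - 1) // 2 + (width_px - 1) % 2)
        # disk-ish footprint: one 8-connected pass per extra pixel of radius
    mask |= stroke


def _default_font(px: int):
    try:
        return ImageFont.load_default(size=max(8, px))
    except TypeError:                      # very old Pillow: fixed-size font
        return ImageFont.load_default()


def _render_text(label: str, px: int):
    """Render a label, return a boolean glyph mask (alpha > 0.5)."""
    font = _default_font(px)
    probe = Image.new("L", (8 * px + 32, 3 * px + 16), 0)
    d = ImageDraw.Draw(probe)
    d.text((4, 4), label, fill=255, font=font)
    arr = np.asarray(probe) > 127
    ys, xs = np.nonzero(arr)
    if len(ys) == 0:
        return np.zeros((1, 1), bool)
    return arr[ys.min():ys.max() + 1, xs.min():xs.max() + 1]


def render_paper(signal: MultiLeadSignal, config: RenderConfig
                 ) -> RenderedSample:
    """Draw a gridded paper ECG with exact class and lead-text masks.

    Minor gridlines fall every 1 mm and major lines every 5 mm at the
    dpi-determined pixel spacing; each lead segment is drawn at the
    configured speed/gain scaling with its name printed near the panel's
    top left.  ``calibration_truth`` is dpi/25.4 pixels per mm on both axes.
    """
    template = get_template(config.layout_name)
    if signal.duration_s < template.duration_s - 1e-9:
        raise ValueError(
            f"signal covers {signal.duration_s:.2f}s but layout "
            f"{template.name!r} needs {template.duration_s:.2f}s")
    ppm = config.px_per_mm
    margin = config.margin_mm * ppm
    seg_s = template.duration_s / template.cols
    width_mm = (template.duration_s * config.speed_mm_per_s
                + 2 * config.margin_mm)
    height_mm = template.total_rows * config.row_height_mm + 2 * config.margin_mm
    W = int(round(width_mm * ppm))
    H = int(round(height_mm * ppm))

    rng = np.random.default_rng(config.seed)
    image = np.empty((H, W, 3), np.uint8)
    image[:] = config.paper_color
    class_mask = np.zeros((H, W), np.uint8)
    lead_text_mask = np.zeros((H, W), np.uint8)

    # --- grid: minor every 1 mm, major every 5 mm, anchored at the origin
    minor_w = max(1, int(round(ppm / 8)))
    major_w = max(minor_w, int(round(ppm / 5)))
    grid = np.zeros((H, W), np.uint8)        # 0 none, 1 minor, 2 major
    for k in range(int(width_mm) + 1):
        x = int(round(k * ppm))
        if x >= W:
            break
        lw = major_w if k % 5 == 0 else minor_w
        val = 2 if k % 5 == 0 else 1
        grid[:, max(0, x - lw // 2):x + (lw + 1) // 2] = np.maximum(
            grid[:, max(0, x - lw // 2):x + (lw + 1) // 2], val)
    for k in range(int(height_mm) + 1):
        y = int(round(k * ppm))
        if y >= H:
            break
        lw = major_w if k % 5 == 0 else minor_w
        val = 2 if k % 5 == 0 else 1
        grid[max(0, y - lw // 2):y + (lw + 1) // 2, :] = np.maximum(
            grid[max(0, y - lw // 2):y + (lw + 1) // 2, :], val)
    image[grid == 1] = config.grid_color
    image[grid == 2] = config.grid_major_color
    class_mask[grid > 0] = GRID

    # --- lead traces
    lw = (config.line_width_px if config.line_width_px is not None
          else max(1, int(round(ppm / 5))))
    band_h = config.row_height_mm * ppm
    sig_mask = np.zeros((H, W), bool)
    panels = []
    for p in template.panels():
        x0n, y0n, x1n, y1n = p.box
        y_band0 = margin + y0n * (H - 2 * margin)
        y_band1 = margin + y1n * (H - 2 * margin)
        baseline = 0.5 * (y_band0 + y_band1)
        t0, t1 = p.window
        i0 = int(round(t0 * signal.rate))
        i1 = int(round(t1 * signal.rate))
        v = signal.lead(p.lead)[i0:i1]
        tt = np.arange(len(v)) / signal.rate
        cols = margin + (t0 + tt) * config.speed_mm_per_s * ppm
        rows = baseline - v * config.gain_mm_per_mV * ppm
        # stop short of the panel edge so adjacent lead segments in a row
        # stay disjoint (like a printer lifting the pen between panels)
        x_end = margin + t1 * config.speed_mm_per_s * ppm
        keep = cols <= x_end - (lw / 2 + 1.7)
        _draw_polyline_mask(sig_mask, rows[keep], cols[keep], lw)
        panels.append(PanelGeometry(
            p.lead, int(round(cols[0])), int(round(cols[-1])),
            baseline, p.window, (y_band0, y_band1), p.is_rhythm))

    # --- optional 1 mV calibration pulse at the left of each band row
    if config.calibration_pulse:
        pulse_h = config.gain_mm_per_mV * ppm        # 1 mV
        for r in range(template.total_rows):
            yb = margin + (r + 0.65) / template.total_rows * (H - 2 * margin)
            xa = 0.2 * margin
            seg = [(yb, xa), (yb, xa + 1 * ppm),
                   (yb - pulse_h, xa + 1 * ppm), (yb - pulse_h, xa + 6 * ppm),
                   (yb, xa + 6 * ppm), (yb, xa + 7 * ppm)]
            rows = np.array([s[0] for s in seg])
            cols = np.array([s[1] for s in seg])
            _draw_polyline_mask(sig_mask, rows, cols, lw)

    image[sig_mask] = config.line_color
    class_mask[sig_mask] = SIGNAL

    # --- lead-name text
    text_px = max(6, int(round(2.8 * ppm * config.text_font_scale)))
    pos = template.marker_positions()
    for lead, (xn, yn) in pos.items():
        glyph = _render_text(lead, text_px)
        gy = int(round(margin + yn * (H - 2 * margin))) - glyph.shape[0]
        gx = int(round(margin + xn * (W - 2 * margin)))
        gy = np.clip(gy, 0, H - glyph.shape[0])
        gx = np.clip(gx, 0, W - glyph.shape[1])
        sl = (slice(gy, gy + glyph.shape[0]), slice(gx, gx + glyph.shape[1]))
        image[sl][glyph] = config.line_color
        class_mask[sl][glyph] = TEXT
        lead_text_mask[sl][glyph] = STANDARD_LEADS.index(lead) + 1

    # --- optional thermal-paper fading (brightness field)
    if config.thermal_fade > 0:
        yy, xx = np.mgrid[0:H, 0:W]
        f = (np.sin(2 * np.pi * (xx / W * rng.uniform(0.5, 2) +
                                 rng.uniform(0, 1)))
             * np.sin(2 * np.pi * (yy / H * rng.uniform(0.5, 2)
                                   + rng.uniform(0, 1))))
        fade = 1.0 - config.thermal_fade * 0.25 * (f + 1)
        image = np.clip(image * fade[:, :, None], 0, 255).astype(np.uint8)

    return RenderedSample(image, class_mask, lead_text_mask, signal,
                          np.eye(3), (ppm, ppm), config, panels)


# ---------------------------------------------------------------------------
# Perspective augmentation
# ---------------------------------------------------------------------------

def _estimate_projective(src: np.ndarray, dst: np.ndarray):
    """Fit a projective transform src -> dst across skimage API versions."""
    if hasattr(ProjectiveTransform, "from_estimate"):
        tf = ProjectiveTransform.from_estimate(src, dst)
        return tf if tf else None
    tf = ProjectiveTransform()                     # pragma: no cover
    return tf if tf.estimate(src, dst) else None


def _background(style: str, shape, rng) -> np.ndarray:
    h, w = shape
    if style == "white":
        return np.full((h, w, 3), 255, np.uint8)
    if style == "gradient":
        g = np.linspace(rng.uniform(40, 90), rng.uniform(150, 210), w)
        base = np.tile(g[None, :, None], (h, 1, 3))
        tint = rng.uniform(0.8, 1.0, size=3)
        return np.clip(base * tint, 0, 255).astype(np.uint8)
    if style == "noise":
        base = rng.uniform(60, 180)
        img = base + 25 * rng.standard_normal((h, w, 3))
        return np.clip(img, 0, 255).astype(np.uint8)
    if style == "table":
        yy, xx = np.mgrid[0:h, 0:w]
        planks = 90 + 50 * np.sin(2 * np.pi * xx / rng.uniform(60, 200)
                                  + 0.3 * np.sin(yy / 37.0))
        img = np.stack([planks * 1.0, planks * 0.72, planks * 0.45], axis=-1)
        img += 10 * rng.standard_normal((h, w, 3))
        return np.clip(img, 0, 255).astype(np.uint8)
    raise ValueError(f"unknown background style {style!r}")


def apply_perspective(sample: RenderedSample, max_tilt_deg: float = 12.0,
                      background_style: str = "noise",
                      seed: int = 0) -> RenderedSample:
    """Warp a render by a random homography and composite a background.

    The image and all masks are warped with the same transform, which is
    recorded in the output (original paper coordinates -> warped image
    coordinates).  ``max_tilt_deg = 0`` keeps the identity homography.
    """
    if max_tilt_deg < 0:
        raise ValueError("max_tilt_deg must be >= 0")
    rng = np.random.default_rng(seed)
    h, w = sample.class_mask.shape
    if max_tilt_deg == 0:
        return replace(sample)

    corners = np.array([[0, 0], [w, 0], [w, h], [0, h]], float)
    for _ in range(32):
        ang = math.radians(rng.uniform(-max_tilt_deg, max_tilt_deg))
        c, s = math.cos(ang), math.sin(ang)
        rot = np.array([[c, -s], [s, c]])
        center = corners.mean(axis=0)
        jitter_amp = math.tan(math.radians(max_tilt_deg)) * 0.25 * min(h, w)
        dst = (corners - center) @ rot.T + center \
            + rng.uniform(-jitter_amp, jitter_amp, size=(4, 2))
        pad = 0.04 * min(h, w)
        dst -= dst.min(axis=0) - pad
        tf = _estimate_projective(corners, dst)
        if tf is not None and np.isfinite(tf.params).all() \
                and abs(np.linalg.det(tf.params)) > 1e-9:
            break
    else:                                   # pragma: no cover
        raise RuntimeError("could not sample an invertible homography")

    out_w = int(math.ceil(dst[:, 0].max() + pad))
    out_h = int(math.ceil(dst[:, 1].max() + pad))
    inv = tf.inverse
    img_w = warp(sample.image.astype(np.float32), inv,
                 output_shape=(out_h, out_w), order=1, cval=0.0)
    alpha = warp(np.ones((h, w), np.float32), inv,
                 output_shape=(out_h, out_w), order=1, cval=0.0)
    bg = _background(background_style, (out_h, out_w), rng).astype(np.float32)
    composited = img_w * alpha[:, :, None] + bg * (1 - alpha[:, :, None])
    cm = warp(sample.class_mask, inv, output_shape=(out_h, out_w), order=0,
              cval=0, preserve_range=True).astype(np.uint8)
    lt = warp(sample.lead_text_mask, inv, output_shape=(out_h, out_w),
              order=0, cval=0, preserve_range=True).astype(np.uint8)
    return RenderedSample(
        np.clip(composited, 0, 255).astype(np.uint8), cm, lt, sample.truth,
        tf.params @ sample.homography, sample.calibration_truth,
        sample.config, sample.panels)


def make_training_crop(sample: RenderedSample, size_px: int, seed: int = 0):
    """An aligned random (image, class-mask) crop of ``size_px`` square.

    Images smaller than ``size_px`` are zero-padded (background label), so
    the sampler is total.  Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    img, mask = sample.image, sample.class_mask
    h, w = mask.shape
    ph, pw = max(0, size_px - h), max(0, size_px - w)
    if ph or pw:
        img = np.pad(img, ((0, ph), (0, pw), (0, 0)))
        mask = np.pad(mask, ((0, ph), (0, pw)))
        h, w = mask.shape
    y = int(rng.integers(0, h - size_px + 1))
    x = int(rng.integers(0, w - size_px + 1))
    return (img[y:y + size_px, x:x + size_px].copy(),
            mask[y:y + size_px, x:x + size_px].copy())
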