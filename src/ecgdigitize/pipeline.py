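"""End-to-end orchestration: image in, calibrated multi-lead record out.

Stages run in the order segmentation -> perspective correction -> grid
calibration -> layout identification -> trace extraction, with graceful
degradation at every step: a failed dewarp falls back to the unwarped
frame, a failed grid calibration to a configured default spacing, a failed
layout identification to the default template, and unresolvable samples
become NaN.  No input image aborts the pipeline; every fallback is recorded
in the returned debug information.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from . import dewarp as _dewarp
from . import gridscale as _gridscale
from . import layout as _layout
from . import segnet as _segnet
from . import trace as _trace

logger = logging.getLogger("ecgdigitize")

__all__ = ["PipelineConfig", "digitize", "train_demo_models",
           "training_batches"]


@dataclass
class PipelineConfig:
    main_model: object = None          # UNet or checkpoint path
    text_model: object = None          # UNet, checkpoint path, or None
    layout_candidates: list | None = None   # templates or YAML path
    speed_mm_per_s: float = 25.0
    gain_mm_per_mV: float = 10.0
    target_rate: float = 1000.0
    default_layout: str = _layout.DEFAULT_LAYOUT
    fallback_px_per_mm: float = 10.0
    min_finite_fraction: float = 0.01   # below: no traceable ECG on the page
    skip_dewarp: bool = False
    debug_dir: str | None = None
    dewarp_config: _dewarp.DewarpConfig = field(
        default_factory=_dewarp.DewarpConfig)
    grid_config: _gridscale.GridSearchConfig = field(
        default_factory=_gridscale.GridSearchConfig)
    trace_config: _trace.TraceConfig = field(default_factory=_trace.TraceConfig)

    def __post_init__(self):
        if self.target_rate <= 0:
            raise ValueError("target_rate must be positive")


def _load_model(model):
    if model is None:
        return None
    if isinstance(model, (str, Path)):
        if not Path(model).exists():
            raise FileNotFoundError(f"model checkpoint not found: {model}")
        return _segnet.load_checkpoint(model)
    return model


def _load_image(image):
    if isinstance(image, (str, Path)):
        try:
            return np.asarray(Image.open(image).convert("RGB"))
        except Exception as exc:
            raise IOError(f"cannot read image {image}: {exc}") from exc
    return np.asarray(image)


def digitize(image, config: PipelineConfig):
    """Digitize one paper-ECG image.

    Returns ``(record, debug)`` where ``record`` is an
    :class:`~ecgdigitize.trace.ECGRecord` (NaN where nothing could be
    traced) and ``debug`` is a JSON-serializable per-stage status dict.
    """
    debug = {"stages": {}, "warnings": []}
    t_start = time.time()
    img = _load_image(image)
    main_model = _load_model(config.main_model)
    if main_model is None:
        raise ValueError("a main segmentation model is required")
    text_model = _load_model(config.text_model)

    # --- 1. segmentation
    t0 = time.time()
    probs = _segnet.segment(main_model, img)
    debug["stages"]["segment"] = {
        "seconds": round(time.time() - t0, 2),
        "class_mass": [float(p.sum()) for p in probs]}

    # --- 2. perspective correction and cropping
    t0 = time.time()
    dewarped = None
    if not config.skip_dewarp:
        try:
            fams = _dewarp.find_line_families(probs[1], config.dewarp_config)
            dewarped = _dewarp.rectify(img, probs, fams[:2], fams[2],
                                       config.dewarp_config)
            debug["stages"]["dewarp"] = {
                "seconds": round(time.time() - t0, 2), "status": "ok",
                "crop_box": list(dewarped.crop_box)}
        except _dewarp.DewarpFailure as exc:
            debug["warnings"].append(f"dewarp failed ({exc}); "
                                     "falling back to the unwarped frame")
            logger.warning("dewarp failure: %s", exc)
    if dewarped is None:
        dewarped = _dewarp.DewarpedSample(img, probs, np.eye(3),
                                          (0, 0) + probs.shape[1:],
                                          fallback=True)
        debug["stages"].setdefault("dewarp", {})["status"] = "fallback"
    rect_img, rect_maps = dewarped.image, dewarped.maps

    # --- 3. grid size extraction
    t0 = time.time()
    try:
        calibration = _gridscale.estimate_calibration(
            rect_maps[1], config.speed_mm_per_s, config.gain_mm_per_mV,
            config.grid_config)
        debug["stages"]["gridscale"] = {
            "seconds": round(time.time() - t0, 2), "status": "ok",
            "d_px_x": calibration.d_px_x, "d_px_y": calibration.d_px_y}
    except (_gridscale.CalibrationFailure, ValueError) as exc:
        calibration = _gridscale.Calibration(
            config.fallback_px_per_mm, config.fallback_px_per_mm,
            config.speed_mm_per_s, config.gain_mm_per_mV)
        debug["warnings"].append(f"grid calibration failed ({exc}); "
                                 f"using {config.fallback_px_per_mm} px/mm")
        debug["stages"]["gridscale"] = {"status": "fallback"}

    # --- 4. layout identification
    t0 = time.time()
    candidates = config.layout_candidates
    if isinstance(candidates, (str, Path)):
        candidates = _layout.load_layout_config(candidates)
    candidates = candidates or _layout.builtin_templates()
    match = None
    if text_model is not None:
        try:
            markers = _layout.detect_markers(rect_maps[3], text_model)
            match = _layout.match_layout(markers, candidates)
            if match.fallback:
                match = None
        except Exception as exc:      # degraded, never fatal
            debug["warnings"].append(f"layout identification failed ({exc})")
    if match is None:
        template = _layout.get_template(config.default_layout, candidates)
        debug["warnings"].append(
            f"layout fallback to default template {template.name!r}")
        debug["stages"]["layout"] = {"status": "fallback",
                                     "template": template.name}
    else:
        template = match.template
        debug["stages"]["layout"] = {
            "seconds": round(time.time() - t0, 2), "status": "ok",
            "template": template.name, "cost": match.cost,
            "missing": list(match.missing)}

    # --- 5. segmentation-to-trace conversion
    t0 = time.time()
    traces = _trace.extract_lead_traces(rect_maps[2], template, calibration,
                                        config.trace_config)
    record = _trace.assemble_record(traces, template, calibration,
                                    config.target_rate,
                                    metadata={
                                        "layout": template.name,
                                        "speed_mm_per_s": config.speed_mm_per_s,
                                        "gain_mm_per_mV": config.gain_mm_per_mV,
                                        "warnings": debug["warnings"]})
    finite_frac = float(np.mean(np.isfinite(record.samples)))
    no_grid = (dewarped.fallback
               and debug["stages"]["gridscale"].get("status") == "fallback")
    if no_grid or 0 < finite_frac < config.min_finite_fraction:
        # no gridline structure anywhere, or almost nothing traced:
        # the page carries no measurable ECG, so every sample is NaN
        record.samples[...] = np.nan
        finite_frac = 0.0
        debug["warnings"].append("no traceable ECG found; "
                                 "all samples set to NaN")
    debug["stages"]["trace"] = {"seconds": round(time.time() - t0, 2),
                                "nan_fraction": 1.0 - finite_frac}
    debug["seconds_total"] = round(time.time() - t_start, 2)

    if config.debug_dir:
        _write_debug_bundle(config.debug_dir, img, probs, rect_img,
                            rect_maps, record, debug)
    return record, debug


def _write_debug_bundle(debug_dir, img, probs, rect_img, rect_maps,
                        record, debug) -> None:
    """Per-stage images and status JSON (segmentation overlay, dewarped
    frame, trace plot) for localizing which stage degraded."""
    out = Path(debug_dir)
    out.mkdir(parents=True, exist_ok=True)
    Image.fromarray(np.asarray(img).astype(np.uint8)).save(out / "input.png")
    palette = np.array([[0, 0, 0], [255, 120, 120], [40, 40, 220],
                        [40, 200, 40]], np.uint8)
    overlay = palette[probs.argmax(0)]
    Image.fromarray(overlay).save(out / "segmentation.png")
    Image.fromarray(np.asarray(rect_img).astype(np.uint8)).save(
        out / "dewarped.png")
    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        n = len(record.lead_names)
        fig, axes = plt.subplots(n, 1, figsize=(10, 1.2 * n), sharex=True)
        t = np.arange(record.samples.shape[1]) / record.rate
        for ax, lead, row in zip(np.atleast_1d(axes), record.lead_names,
                                 record.samples):
            ax.plot(t, row, lw=0.6)
            ax.set_ylabel(lead, rotation=0, ha="right")
        fig.tight_layout()
        fig.savefig(out / "traces.png", dpi=100)
        plt.close(fig)
    except Exception:                      # plotting is best-effort
        pass
    with open(out / "status.json", "w") as fh:
        json.dump(debug, fh, indent=2, default=str)


# ---------------------------------------------------------------------------
# Desk-scale training helpers
# ---------------------------------------------------------------------------

def training_batches(n_batches: int, batch_size: int = 4, crop_px: int = 96,
                     dpi: float = 100.0, n_renders: int = 4, seed: int = 0,
                     target: str = "main", warp_fraction: float = 0.0):
    """Generator of synthetic (image, mask) training batches.

    ``target="main"``: RGB crops with the 4-class mask.  ``target="text"``:
    single-channel text-probability crops with the 13-class lead-name mask.
    A fraction of the source renders can be perspective-warped.
    """
    from .synthgen import (RenderConfig, apply_perspective,
                           make_training_crop, render_paper, simulate_ecg)
    rng = np.random.default_rng(seed)
    renders = []
    for i in range(n_renders):
        s = int(rng.integers(2 ** 31))
        sig = simulate_ecg(12, 10.0, 500.0, seed=s)
        rs = render_paper(sig, RenderConfig(dpi=dpi, seed=s))
        if rng.uniform() < warp_fraction:
            rs = apply_perspective(rs, max_tilt_deg=8.0, seed=s)
        renders.append(rs)
    for _ in range(n_batches):
        imgs, masks = [], []
        for _b in range(batch_size):
            rs = renders[int(rng.integers(len(renders)))]
            crop_seed = int(rng.integers(2 ** 31))
            if target == "main":
                img, m = make_training_crop(rs, crop_px, seed=crop_seed)
                imgs.append(img.astype(np.float32).transpose(2, 0, 1) / 255.0)
                masks.append(m.astype(np.int64))
            else:
                text_plane = (rs.class_mask == 3).astype(np.float32)
                lead_mask = rs.lead_text_mask
                h, w = text_plane.shape
                rr = np.random.default_rng(crop_seed)
                y = int(rr.integers(0, max(1, h - crop_px + 1)))
                x = int(rr.integers(0, max(1, w - crop_px + 1)))
                tp = text_plane[y:y + crop_px, x:x + crop_px]
                lm = lead_mask[y:y + crop_px, x:x + crop_px]
                if tp.shape != (crop_px, crop_px):
                    tp = np.pad(tp, ((0, crop_px - tp.shape[0]),
                                     (0, crop_px - tp.shape[1])))
                    lm = np.pad(lm, ((0, crop_px - lm.shape[0]),
                                     (0, crop_px - lm.shape[1])))
                imgs.append(tp[None])
                masks.append(lm.astype(np.int64))
        yield np.stack(imgs), np.stack(masks)


def train_demo_models(seed: int = 0, steps: int = 300, widths=(8, 16, 32),
                      text_steps: int = 0, dpi: float = 100.0):
    """Train small CPU-scale models on synthetic data.

    These are reduced-width stand-ins for the full-scale recipe (which
    uses the default widths for days of GPU time); the optimizer, loss and
    schedule are identical.  Returns ``(main_model, text_model_or_None)``.
    """
    from .segnet import TrainConfig, UNet, UNetConfig, train
    main = UNet(UNetConfig(encoder_widths=tuple(widths), seed=seed))
    cfg = TrainConfig(batch_size=4, patch_px=96, schedule_batches=max(steps, 1),
                      seed=seed)
    train(main, training_batches(steps, seed=seed, dpi=dpi), cfg)
    text = None
    if text_steps > 0:
        text = UNet(UNetConfig(encoder_widths=tuple(widths), in_channels=1,
                               out_channels=13, seed=seed + 1))
        train(text, training_batches(text_steps, seed=seed + 1, dpi=dpi,
                                     target="text"), cfg)
    return main, text
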