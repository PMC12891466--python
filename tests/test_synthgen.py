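"""Tests for the waveform simulator and paper renderer."""

import numpy as np
import pytest
from scipy.signal import find_peaks

from ecgdigitize.layout import builtin_templates
from ecgdigitize.synthgen import (RenderConfig, apply_perspective,
                                  make_training_crop, render_paper,
                                  simulate_ecg)


def test_sample_count_and_determinism():
    a = simulate_ecg(3, 10.0, 1000.0, seed=4)
    assert a.samples.shape == (3, 10_000)
    b = simulate_ecg(3, 10.0, 1000.0, seed=4)
    assert np.array_equal(a.samples, b.samples)
    c = simulate_ecg(3, 10.0, 1000.0, seed=5)
    assert not np.array_equal(a.samples, c.samples)


def test_beat_count_at_60_bpm():
    sig = simulate_ecg(["II"], 10.0, 500.0,
                       {"heart_rate_bpm": 60.0, "baseline_wander_mv": 0.0,
                        "noise_mv": 0.0}, seed=3)
    y = sig.lead("II")
    peaks, _ = find_peaks(y, height=0.6 * y.max(), distance=int(0.4 * 500))
    assert 9 <= len(peaks) <= 11


def test_limb_lead_identities_exact():
    sig = simulate_ecg(12, 5.0, 500.0, seed=9)
    i, ii = sig.lead("I"), sig.lead("II")
    assert np.array_equal(sig.lead("III"), ii - i)
    assert np.allclose(sig.lead("aVR"), -(i + ii) / 2)
    assert np.allclose(sig.lead("aVL"), i - ii / 2)
    assert np.allclose(sig.lead("aVF"), ii - i / 2)


def test_invalid_arguments_rejected():
    with pytest.raises(ValueError):
        simulate_ecg(3, -1.0, 500.0)
    with pytest.raises(ValueError):
        simulate_ecg(3, 10.0, 0.0)
    with pytest.raises(ValueError):
        RenderConfig(speed_mm_per_s=-25)
    with pytest.raises(ValueError):
        RenderConfig(dpi=0)


def test_calibration_truth_at_254_dpi():
    sig = simulate_ecg(12, 10.0, 250.0, seed=0)
    sample = render_paper(sig, RenderConfig(dpi=254, seed=0))
    assert sample.calibration_truth == pytest.approx((10.0, 10.0))


def test_flat_signal_renders_13_horizontal_segments():
    """The 3x4 + rhythm layout shows 12 grid segments plus a full-width
    rhythm strip; a flat signal makes each a horizontal stroke."""
    from ecgdigitize.synthgen import MultiLeadSignal
    from scipy import ndimage
    names = list(builtin_templates()[0].leads)
    sig = MultiLeadSignal(names + [], np.zeros((12, 5000)), 500.0)
    sample = render_paper(sig, RenderConfig(dpi=100, seed=1))
    lbl, n = ndimage.label(sample.class_mask == 2,
                           structure=np.ones((3, 3), int))
    segs = 0
    for k in range(1, n + 1):
        rows, cols = np.nonzero(lbl == k)
        if np.ptp(rows) <= 4 and np.ptp(cols) > 20:
            segs += 1
    assert segs == 13


def test_calibration_pulse_height():
    """A 1 mV pulse at 10 mm/mV and 254 dpi spans 100 +- 1 pixels."""
    sig = simulate_ecg(12, 10.0, 250.0, seed=2)
    cfg = RenderConfig(dpi=254, calibration_pulse=True, line_width_px=1,
                       seed=0)
    sample = render_paper(sig, cfg)
    margin_px = int(0.9 * cfg.margin_mm * cfg.px_per_mm)
    strip = sample.class_mask[:, :margin_px] == 2
    rows = np.nonzero(strip.any(axis=1))[0]
    spans, start, prev = [], rows[0], rows[0]
    for r in rows[1:]:
        if r - prev > 5:
            spans.append(prev - start)
            start = r
        prev = r
    spans.append(prev - start)
    assert all(abs(s - 100) <= 1 for s in spans)


def test_signal_mask_pixels_have_line_color():
    sig = simulate_ecg(12, 10.0, 250.0, seed=5)
    cfg = RenderConfig(dpi=100, seed=5)
    sample = render_paper(sig, cfg)
    sel = sample.class_mask == 2
    assert sel.any()
    assert np.all(sample.image[sel] == np.array(cfg.line_color, np.uint8))


def test_short_signal_rejected():
    sig = simulate_ecg(12, 4.0, 500.0, seed=0)
    with pytest.raises(ValueError):
        render_paper(sig, RenderConfig(seed=0))
    with pytest.raises(KeyError):
        render_paper(simulate_ecg(12, 10.0, 500.0, seed=0),
                     RenderConfig(layout_name="nope", seed=0))


def test_perspective_identity_at_zero_tilt(clean_render_100dpi):
    warped = apply_perspective(clean_render_100dpi, max_tilt_deg=0.0, seed=1)
    assert np.array_equal(warped.image, clean_render_100dpi.image)
    assert np.allclose(warped.homography, np.eye(3))


def test_perspective_masks_consistent_and_invertible(clean_render_100dpi):
    from skimage.transform import ProjectiveTransform, warp
    sample = clean_render_100dpi
    warped = apply_perspective(sample, max_tilt_deg=10.0,
                               background_style="gradient", seed=4)
    h = warped.homography
    assert abs(np.linalg.det(h)) > 1e-9
    # corners of the paper map exactly through the recorded homography
    hh, ww = sample.class_mask.shape
    corners = np.array([[0, 0, 1], [ww, 0, 1], [ww, hh, 1], [0, hh, 1]],
                       float)
    mapped = corners @ h.T
    mapped = mapped[:, :2] / mapped[:, 2:3]
    oh, ow = warped.class_mask.shape
    assert np.all(mapped[:, 0] >= -1) and np.all(mapped[:, 0] <= ow + 1)
    assert np.all(mapped[:, 1] >= -1) and np.all(mapped[:, 1] <= oh + 1)
    # warping the mask back recovers the original away from borders
    tf = ProjectiveTransform(matrix=h)
    back = warp(warped.class_mask, tf, output_shape=sample.class_mask.shape,
                order=0, preserve_range=True).astype(np.uint8)
    inner = (slice(8, -8), slice(8, -8))
    agree = np.mean(back[inner] == sample.class_mask[inner])
    assert agree > 0.95   # thin 1 px gridlines alias under round-trip warps


def test_training_crop_shapes_and_commutation(clean_render_100dpi):
    sample = clean_render_100dpi
    img, mask = make_training_crop(sample, 256, seed=3)
    assert img.shape == (256, 256, 3) and mask.shape == (256, 256)
    img2, mask2 = make_training_crop(sample, 256, seed=3)
    assert np.array_equal(img, img2) and np.array_equal(mask, mask2)
    # identity crop when the requested size equals the image
    h, w = sample.class_mask.shape
    size = min(h, w)
    imgc, maskc = make_training_crop(sample, size, seed=0)
    assert imgc.shape[:2] == (size, size)
    # crops larger than the render are padded with background
    imgp, maskp = make_training_crop(sample, max(h, w) + 64, seed=0)
    assert imgp.shape[:2] == (max(h, w) + 64,) * 2
    assert maskp[-1, -1] == 0


def test_layout_registry_contents():
    names = {t.name for t in builtin_templates()}
    assert names == {"3x4+rhythm", "3x4", "6x2", "12x1"}
    for t in builtin_templates():
        leads = t.leads
        assert len(set(leads)) == len(leads)
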