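"""Tests for the shifted-SNR evaluation metrics."""

import math

import numpy as np
import pytest

from ecgdigitize.metrics import (SNR_INF, align, correlation, evaluate_pair,
                                 evaluate_record, rmse, snr)
from ecgdigitize.trace import ECGRecord


def _ecg_like(n=2000, seed=0):
    rng = np.random.default_rng(seed)
    t = np.arange(n) / 1000.0
    y = np.zeros(n)
    for c in np.arange(0.3, t[-1], 0.8):
        y += 1.1 * np.exp(-0.5 * ((t - c) / 0.012) ** 2)
        y += 0.3 * np.exp(-0.5 * ((t - c - 0.25) / 0.05) ** 2)
    return y + 0.01 * rng.normal(size=n)


def _smooth_walk(n=2000, seed=0):
    """Aperiodic smooth series: unambiguous time alignment."""
    from scipy.ndimage import gaussian_filter1d
    rng = np.random.default_rng(seed)
    return gaussian_filter1d(np.cumsum(rng.normal(size=n)), 20)


def test_exact_delayed_copy_recovered():
    y = _smooth_walk()
    y_hat = np.roll(y, 40)
    y_hat[:40] = 0.0
    s, a, b = align(y, y_hat, max_shift_ms=100)
    assert s == 40
    r = snr(a, b)
    assert r == SNR_INF or r > 60


def test_shift_saturates_at_the_bound():
    y = _smooth_walk()
    y_hat = np.roll(y, 150)
    y_hat[:150] = 0.0
    s, _, _ = align(y, y_hat, max_shift_ms=100)
    assert s == 100


def test_shift_search_equals_exhaustive_enumeration():
    rng = np.random.default_rng(3)
    for trial in range(20):
        y = _ecg_like(800, seed=trial)
        true_shift = int(rng.integers(-80, 81))
        y_hat = np.roll(y, true_shift) + 0.05 * rng.normal(size=len(y))
        s, _, _ = align(y, y_hat, max_shift_ms=100)

        def ratio(shift):
            if shift >= 0:
                a = y[:len(y) - shift or None]
                b = y_hat[shift:]
            else:
                a, b = y[-shift:], y_hat[:shift]
            n = min(len(a), len(b))
            a = a[:n] - a[:n].mean()
            b = b[:n] - b[:n].mean()
            d = a - b
            return np.sum(a * a) / max(np.sum(d * d), 1e-300)

        brute = max(range(-100, 101), key=ratio)
        assert s == brute


def test_zero_reconstruction_scores_exactly_zero_db():
    y = _ecg_like()
    r = evaluate_pair(y, np.zeros_like(y), "II")
    assert r.snr_db == 0.0


def test_snr_reference_values():
    rng = np.random.default_rng(1)
    y = rng.normal(size=1000)
    y -= y.mean()
    assert snr(y, y) == SNR_INF
    assert snr(y, 0.9 * y) == pytest.approx(20.0, abs=1e-9)
    with pytest.warns(UserWarning):
        assert math.isnan(snr(np.zeros(10), np.ones(10)))


def test_snr_invariant_to_constant_offsets():
    y = _ecg_like()
    y_hat = y + 0.05 * np.random.default_rng(2).normal(size=len(y))
    r0 = evaluate_pair(y, y_hat)
    r1 = evaluate_pair(y + 0.7, y_hat - 1.3)
    assert r1.snr_db == pytest.approx(r0.snr_db, abs=1e-9)


def test_snr_decreases_with_noise():
    y = _ecg_like()
    rng = np.random.default_rng(4)
    noise = rng.normal(size=len(y))
    snrs = [evaluate_pair(y, y + a * noise).snr_db
            for a in (0.01, 0.03, 0.1, 0.3)]
    assert all(s1 > s2 for s1, s2 in zip(snrs, snrs[1:]))


def test_rmse_and_correlation_examples():
    y = np.array([0.0, 1.0, 0.0, -1.0])
    assert rmse(y, np.zeros(4)) == pytest.approx(math.sqrt(0.5) * 1000,
                                                 abs=0.1)
    assert rmse(y, y) == 0.0
    assert correlation(y, y) == pytest.approx(1.0)
    assert correlation(y, -y) == pytest.approx(-1.0)
    with pytest.warns(UserWarning):
        assert math.isnan(correlation(y, np.zeros(4)))


def test_rmse_snr_identity():
    """RMSE^2 = (signal power / N) * 10^(-SNR/10) on centered pairs."""
    rng = np.random.default_rng(5)
    y = _ecg_like(1500, seed=9)
    y_hat = y + 0.08 * rng.normal(size=len(y))
    s, a, b = align(y, y_hat)
    r_db = snr(a, b)
    r_uv = rmse(a, b)
    predicted = math.sqrt(np.sum(a * a) / len(a) * 10 ** (-r_db / 10)) * 1000
    assert r_uv == pytest.approx(predicted, rel=1e-9)


def test_evaluate_record_aggregation():
    y = _ecg_like()
    truth = ECGRecord(["I", "II", "III"], np.stack([y, 2 * y, 0.5 * y]),
                      1000.0)
    rng = np.random.default_rng(6)
    rec = ECGRecord(["I", "II", "III"],
                    truth.samples + 0.05 * rng.normal(
                        size=truth.samples.shape), 1000.0)
    results, summary = evaluate_record(truth, rec)
    assert len(results) == 3
    finite = [r.snr_db for r in results if math.isfinite(r.snr_db)]
    assert summary["snr_db_mean"] == pytest.approx(np.mean(finite))
    assert summary["rmse_uV_mean"] == pytest.approx(
        np.mean([r.rmse_uV for r in results]))
    # identical records: every lead hits the sentinel, RMSE is zero
    res2, summ2 = evaluate_record(truth, truth)
    assert summ2["snr_inf_count"] == 3
    assert summ2["rmse_uV_mean"] == 0.0
    with pytest.raises(ValueError):
        evaluate_record(truth, ECGRecord(["V1"], np.zeros((1, 100)), 1000.0))


def test_nan_strict_mode_excludes_missing_samples():
    y = _ecg_like()
    y_hat = y.copy()
    y_hat[100:300] = np.nan
    strict = evaluate_pair(y, y_hat, nan_mode="strict")
    zeroed = evaluate_pair(y, y_hat, nan_mode="zero")
    assert strict.snr_db == SNR_INF or strict.snr_db > 60
    assert zeroed.snr_db < strict.snr_db
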