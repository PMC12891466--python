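"""Evaluation metrics: shifted SNR, RMSE and correlation.

The signal-to-noise ratio of a reconstruction ``y_hat`` against the ground
truth ``y`` is

    SNR = 10 log10( sum_t y[t]^2 / sum_t (y[t] - y_hat[t])^2 )

computed after alignment: both series are zero-centered (there is no fixed
baseline on paper), and an integer-sample horizontal shift of at most
100 ms is chosen to maximize the SNR (time translation carries no clinical
meaning).  NaN samples in the reconstruction are scored as zero on the
centered scale by default — setting a lead to zeros scores exactly 0 dB —
with a strict mode that excludes them instead.  RMSE is reported in
microvolts and correlation is Pearson's r on the overlap.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "MetricResult", "align", "snr", "rmse", "correlation",
    "evaluate_pair", "evaluate_record", "SNR_INF",
]

#: sentinel for a perfect reconstruction (zero noise power)
SNR_INF = math.inf


@dataclass
class MetricResult:
    lead: str
    snr_db: float
    rmse_uV: float
    correlation: float
    applied_shift_ms: float
    nan_fraction: float


def _center(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, float)
    m = np.nanmean(y)
    return y - (m if np.isfinite(m) else 0.0)


def _noise_power(y: np.ndarray, y_hat: np.ndarray) -> float:
    d = y - y_hat
    return float(np.sum(d * d))


def align(y: np.ndarray, y_hat: np.ndarray, max_shift_ms: float = 100.0,
          rate: float = 1000.0, nan_mode: str = "zero"):
    """Vertical (zero-centering) and bounded horizontal alignment.

    Both series are mean-centered; NaNs in ``y_hat`` are then replaced by 0
    (``nan_mode="zero"``) or left out of the overlap (``nan_mode="strict"``).
    The integer-sample shift s in [-max, max] maximizing the SNR of
    ``y_hat`` delayed by s against ``y`` is found by exhaustive search.

    Returns ``(shift_samples, yc, yhc)`` where the two series are the
    centered, shifted, equal-length overlap.
    """
    y = np.asarray(y, float)
    y_hat = np.asarray(y_hat, float)
    max_shift = int(round(max_shift_ms * rate / 1000.0))

    best = None
    for s in range(-max_shift, max_shift + 1):
        # positive s: the reconstruction lags the truth by s samples
        if s >= 0:
            a = y[:len(y) - s if s else len(y)]
            b = y_hat[s:]
        else:
            a, b = y[-s:], y_hat[:s]
        n = min(len(a), len(b))
        if n == 0:
            continue
        a, b = a[:n], b[:n]
        if nan_mode == "strict":
            ok = np.isfinite(b)
            a, b = a[ok], b[ok]
            if len(a) == 0:
                continue
        # zero-center on the compared overlap; NaNs score as (centered) zero
        a = a - a.mean()
        b = b - np.nanmean(b) if np.any(np.isfinite(b)) else b
        b = np.where(np.isfinite(b), b, 0.0)
        npow = _noise_power(a, b)
        spow = float(np.sum(a * a))
        key = (spow / npow) if npow > 0 else math.inf
        if best is None or key > best[0]:
            best = (key, s, a, b)
    if best is None:
        raise ValueError("series do not overlap for any candidate shift")
    _, s, a, b = best
    return s, a, b


def snr(y: np.ndarray, y_hat: np.ndarray) -> float:
    """10 log10 of signal power over residual power, on aligned inputs.

    Returns the +inf sentinel when the residual is exactly zero, and NaN
    (with a warning) when the reference has no power.
    """
    y = np.asarray(y, float)
    y_hat = np.asarray(y_hat, float)
    spow = float(np.sum(y * y))
    npow = _noise_power(y, y_hat)
    if spow == 0.0:
        warnings.warn("zero signal power; SNR undefined")
        return math.nan
    if npow == 0.0:
        return SNR_INF
    return 10.0 * math.log10(spow / npow)


def rmse(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Root mean squared difference, in microvolts (inputs in mV)."""
    d = np.asarray(y, float) - np.asarray(y_hat, float)
    return float(np.sqrt(np.mean(d * d)) * 1000.0)


def correlation(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Pearson correlation on the overlap; NaN for constant series."""
    y = np.asarray(y, float)
    y_hat = np.asarray(y_hat, float)
    sy = y.std()
    sh = y_hat.std()
    if sy == 0 or sh == 0:
        warnings.warn("constant series; correlation undefined")
        return math.nan
    return float(np.corrcoef(y, y_hat)[0, 1])


def evaluate_pair(y: np.ndarray, y_hat: np.ndarray, lead: str = "",
                  max_shift_ms: float = 100.0, rate: float = 1000.0,
                  nan_mode: str = "zero") -> MetricResult:
    """Align then score one lead."""
    nan_frac = float(np.mean(~np.isfinite(np.asarray(y_hat, float))))
    s, a, b = align(y, y_hat, max_shift_ms, rate, nan_mode)
    return MetricResult(lead, snr(a, b), rmse(a, b), correlation(a, b),
                        1000.0 * s / rate, nan_frac)


def evaluate_record(truth, rec, max_shift_ms: float = 100.0,
                    nan_mode: str = "zero"):
    """Per-lead metrics for two records plus mean/s.d. aggregates.

    Leads present in both records are scored; infinite SNR sentinels are
    excluded from the aggregate mean and counted separately.

    Returns ``(results, summary)`` with ``summary`` a dict of means and
    standard deviations in the usual reporting style.
    """
    if truth.rate != rec.rate:
        raise ValueError("records must share a sample rate")
    shared = [l for l in truth.lead_names if l in rec.lead_names]
    if not shared:
        raise ValueError("no shared leads to evaluate")
    results = [evaluate_pair(truth.lead(l), rec.lead(l), l, max_shift_ms,
                             truth.rate, nan_mode) for l in shared]
    snrs = np.array([r.snr_db for r in results])
    finite = snrs[np.isfinite(snrs)]
    summary = {
        "snr_db_mean": float(np.mean(finite)) if len(finite) else math.nan,
        "snr_db_sd": float(np.std(finite)) if len(finite) else math.nan,
        "snr_inf_count": int(np.sum(np.isinf(snrs))),
        "rmse_uV_mean": float(np.mean([r.rmse_uV for r in results])),
        "rmse_uV_sd": float(np.std([r.rmse_uV for r in results])),
        "correlation_mean": float(np.nanmean([r.correlation
                                              for r in results])),
        "correlation_sd": float(np.nanstd([r.correlation for r in results])),
        "nan_fraction": float(np.mean([r.nan_fraction for r in results])),
    }
    return results, summary
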