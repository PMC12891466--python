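"""Grid-spacing estimation and pixel-to-physical calibration.

ECG paper carries minor gridlines every 1 mm and major lines every 5 mm.
After dewarping, the spacing ``d`` (pixels per mm) is estimated per axis:
the grid probability map is collapsed to a 1D profile (column sums for the
horizontal axis, row sums for the vertical), the profile's discrete
autocorrelation R_xx[m] = sum_n x[n] x[n+m] is computed over valid indices,
and a comb template — Gaussian bumps at multiples of d, amplified at
multiples of 5d — is matched to the trend-removed autocorrelation by
normalized correlation over an adaptive grid search in d.  Together with
the paper constants (mm/s, mm/mV) the estimate converts pixel coordinates
to seconds and millivolts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "AxisProfile", "AutocorrProfile", "GridEstimate", "Calibration",
    "GridSearchConfig", "CalibrationFailure", "axis_profile",
    "autocorrelation", "estimate_spacing", "to_physical",
    "estimate_calibration",
]


class CalibrationFailure(RuntimeError):
    """No periodic grid structure found; caller may fall back to a default."""


@dataclass
class AxisProfile:
    values: np.ndarray
    axis: str                    # "horizontal" | "vertical"


@dataclass
class AutocorrProfile:
    lags: np.ndarray             # 0..m_max
    values: np.ndarray
    axis: str = ""


@dataclass
class GridEstimate:
    d_px: float                  # minor-grid spacing, fractional pixels
    score: float                 # normalized template correlation
    axis: str


@dataclass
class Calibration:
    """Pixel spacing of the 1 mm grid plus the printing constants."""
    d_px_x: float
    d_px_y: float
    speed_mm_per_s: float = 25.0
    gain_mm_per_mV: float = 10.0

    def __post_init__(self):
        for name in ("d_px_x", "d_px_y", "speed_mm_per_s", "gain_mm_per_mV"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def seconds_per_px(self) -> float:
        return 1.0 / (self.d_px_x * self.speed_mm_per_s)

    @property
    def mV_per_px(self) -> float:
        return 1.0 / (self.d_px_y * self.gain_mm_per_mV)

    @property
    def px_per_second(self) -> float:
        return self.d_px_x * self.speed_mm_per_s

    @property
    def px_per_mV(self) -> float:
        return self.d_px_y * self.gain_mm_per_mV


@dataclass
class GridSearchConfig:
    d_min: float = 3.0
    d_max: float = 80.0
    coarse_step: float = 0.25
    refine_rounds: int = 4
    refine_shrink: float = 0.2
    min_step: float = 0.01
    sigma_frac: float = 1.0 / 12.0     # template bump sigma = d * sigma_frac
    major_weight: float = 3.0          # bump weight at multiples of 5d
    minor_weight: float = 1.0
    score_periods: float = 10.0        # lag window = this many minor periods
    trend_window_frac: float = 1.5     # moving-average window = frac * d
    min_score: float = 0.2             # below -> calibration failure


def axis_profile(grid_map: np.ndarray, axis: str) -> AxisProfile:
    """Collapse the 2D grid map to 1D.

    ``horizontal``: sum over rows for each column (vertical gridlines appear
    as peaks, giving the x spacing); ``vertical``: sum over columns for each
    row.
    """
    gm = np.asarray(grid_map, float)
    if axis == "horizontal":
        return AxisProfile(gm.sum(axis=0), axis)
    if axis == "vertical":
        return AxisProfile(gm.sum(axis=1), axis)
    raise ValueError("axis must be 'horizontal' or 'vertical'")


def autocorrelation(profile: AxisProfile, m_max: int) -> AutocorrProfile:
    """Exact discrete autocorrelation over valid indices (no wrap-around)."""
    x = np.asarray(profile.values, float)
    n = len(x)
    if m_max >= n:
        raise ValueError("m_max must be < profile length")
    full = np.correlate(x, x, mode="full")[n - 1:]
    return AutocorrProfile(np.arange(m_max + 1), full[:m_max + 1])


def _comb_template(lags: np.ndarray, d: float,
                   config: GridSearchConfig) -> np.ndarray:
    """Gaussian bumps at multiples of d, amplified at multiples of 5d."""
    sigma = max(d * config.sigma_frac, 0.5)
    r = np.mod(lags, d)
    dist = np.minimum(r, d - r)
    t = config.minor_weight * np.exp(-0.5 * (dist / sigma) ** 2)
    r5 = np.mod(lags, 5.0 * d)
    dist5 = np.minimum(r5, 5.0 * d - r5)
    t += (config.major_weight - config.minor_weight) * \
        np.exp(-0.5 * (dist5 / sigma) ** 2)
    return t


def _detrend(values: np.ndarray, window: int) -> np.ndarray:
    window = max(3, int(window) | 1)
    pad = window // 2
    padded = np.pad(values, pad, mode="reflect")
    kernel = np.ones(window) / window
    baseline = np.convolve(padded, kernel, mode="valid")
    return values - baseline


def _score(auto: AutocorrProfile, d: float,
           config: GridSearchConfig) -> float:
    """Normalized correlation of the comb template with the autocorrelation.

    The lag window is proportional to the candidate d (``score_periods``
    minor periods, skipping the zero-lag peak): long enough to cover the
    5d major-line structure, short enough that the score varies smoothly in
    d and the adaptive grid search cannot step over the peak.
    """
    m_lo = int(math.ceil(d * 0.5))        # skip the zero-lag peak region
    m_hi = min(len(auto.lags) - 1,
               int(math.ceil((config.score_periods + 0.5) * d)))
    lags = auto.lags[m_lo:m_hi + 1]
    if len(lags) < 8:
        return -np.inf
    vals = _detrend(auto.values[:m_hi + 1],
                    config.trend_window_frac * d)[m_lo:]
    tmpl = _comb_template(lags.astype(float), d, config)
    tmpl = tmpl - tmpl.mean()
    vs = vals - vals.mean()
    denom = np.linalg.norm(tmpl) * np.linalg.norm(vs)
    if denom <= 0:
        return -np.inf
    return float(tmpl @ vs / denom)


def estimate_spacing(auto: AutocorrProfile,
                     d_range: tuple | None = None,
                     config: GridSearchConfig | None = None) -> GridEstimate:
    """Adaptive grid search for the minor-grid spacing d.

    Scores each candidate d by the normalized correlation between the comb
    template and the trend-removed autocorrelation; a coarse sweep over
    ``d_range`` is followed by shrinking refinement rounds until the step
    is below 0.01 px.  Invariant to a constant scaling of the profile.
    """
    config = config or GridSearchConfig()
    d_lo, d_hi = d_range if d_range is not None else (config.d_min,
                                                      config.d_max)
    m_max = int(auto.lags[-1])
    d_hi = min(d_hi, m_max / 6.0)    # need at least one major period
    if d_hi <= d_lo:
        raise ValueError("d range collapsed; autocorrelation too short")
    step = config.coarse_step
    cands = np.arange(d_lo, d_hi + 1e-9, step)
    scores = np.array([_score(auto, d, config) for d in cands])
    best = float(cands[int(np.argmax(scores))])
    best_score = float(np.max(scores))
    for _ in range(config.refine_rounds):
        step *= config.refine_shrink
        if step < config.min_step:
            break
        cands = np.arange(max(d_lo, best - 5 * step),
                          min(d_hi, best + 5 * step) + 1e-9, step)
        scores = np.array([_score(auto, d, config) for d in cands])
        if scores.max() > best_score:
            best = float(cands[int(np.argmax(scores))])
            best_score = float(scores.max())
    axis = getattr(auto, "axis", "")
    if not np.isfinite(best_score) or best_score < config.min_score:
        raise CalibrationFailure(
            f"no periodic grid structure (score {best_score:.3f})")
    return GridEstimate(best, best_score, axis)


def to_physical(est_x: GridEstimate, est_y: GridEstimate,
                speed_mm_per_s: float = 25.0,
                gain_mm_per_mV: float = 10.0) -> Calibration:
    """Combine the per-axis spacing estimates with the paper constants."""
    return Calibration(est_x.d_px, est_y.d_px, speed_mm_per_s, gain_mm_per_mV)


def estimate_calibration(grid_map: np.ndarray,
                         speed_mm_per_s: float = 25.0,
                         gain_mm_per_mV: float = 10.0,
                         config: GridSearchConfig | None = None
                         ) -> Calibration:
    """Convenience wrapper: profile, autocorrelate and match both axes."""
    config = config or GridSearchConfig()
    ests = {}
    for axis in ("horizontal", "vertical"):
        prof = axis_profile(grid_map, axis)
        m_max = min(len(prof.values) - 1,
                    max(int(25 * config.d_max), len(prof.values) // 2))
        auto = autocorrelation(prof, m_max)
        auto.axis = axis
        ests[axis] = estimate_spacing(auto, config=config)
    return to_physical(ests["horizontal"], ests["vertical"],
                       speed_mm_per_s, gain_mm_per_mV)
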