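"""Perspective correction from the grid probability map.

A paper ECG photographed at an angle shows two pencils of nearly parallel
gridlines.  In the Hough angle-radius domain (y sin(theta) + x cos(theta) =
rho) each pencil collapses onto a straight line, so finding the perspective
reduces to finding two straight lines in the accumulator.  That search is
done in a second dual domain — the angle-angle domain — where the value at
(theta_i, theta_j) is the variance of accumulator samples along the segment
from (theta_i, rho_min) to (theta_j, rho_max): a pencil becomes a single
bright point.  The two most prominent maxima (about 90 degrees apart) give
the two line families, from which the vanishing points and the rectifying
homography follow.  The rectified image is cropped to the signal-class mass
with a margin.

Coordinate convention: origin at the top-left pixel center, x = column,
y = row, angles measured from the +x axis; rho may be negative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.measure import block_reduce
from skimage.transform import warp

__all__ = [
    "DewarpConfig", "HoughAccumulator", "AngleAngleMap", "LineFamily",
    "DewarpedSample", "DewarpFailure", "hough_transform",
    "angle_angle_transform", "find_line_families", "rectify",
]


class DewarpFailure(RuntimeError):
    """Grid structure could not be identified; caller should fall back."""


@dataclass
class DewarpConfig:
    coarse_step_deg: float = 0.5
    fine_step_deg: float = 0.02
    fine_half_deg: float = 2.0
    rho_resolution: float = 1.0
    sep_tol_deg: float = 15.0        # tolerance on the ~90 deg separation
    prominence: float = 4.0          # peak value vs map median, in MADs
    second_peak_ratio: float = 0.02  # min value of peak 2 relative to peak 1
    max_spread_deg: float = 30.0     # search band on |theta_i - theta_j|
    pool_long_side: int = 2048
    crop_margin_units: float = 2.0   # major-grid units (5 mm each)
    signal_threshold: float = 0.5


@dataclass
class HoughAccumulator:
    theta_axis: np.ndarray      # radians, ascending
    rho_axis: np.ndarray        # pixels, ascending
    votes: np.ndarray           # (n_theta, n_rho)


@dataclass
class AngleAngleMap:
    theta_axis: np.ndarray
    values: np.ndarray          # (n_theta, n_theta), variance along lines


@dataclass
class LineFamily:
    theta_at_rho_min: float
    theta_at_rho_max: float
    rho_min: float
    rho_max: float

    @property
    def mean_theta(self) -> float:
        return 0.5 * (self.theta_at_rho_min + self.theta_at_rho_max)

    def vanishing_point(self) -> np.ndarray:
        """Homogeneous intersection of the family's two extreme lines."""
        t0, t1 = self.theta_at_rho_min, self.theta_at_rho_max
        l0 = np.array([math.cos(t0), math.sin(t0), -self.rho_min])
        l1 = np.array([math.cos(t1), math.sin(t1), -self.rho_max])
        return np.cross(l0, l1)


@dataclass
class DewarpedSample:
    image: np.ndarray
    maps: np.ndarray            # (C, H, W) probability maps, same transform
    homography: np.ndarray      # input pixel coords -> output pixel coords
    crop_box: tuple             # (y0, x0, y1, x1) in the pre-crop frame
    fallback: bool = False


# ---------------------------------------------------------------------------
# Transforms
# ---------------------------------------------------------------------------

def hough_transform(grid_map: np.ndarray, theta_axis: np.ndarray,
                    rho_resolution: float = 1.0) -> HoughAccumulator:
    """Probability-weighted Hough transform of a grid map.

    Every pixel votes its probability into the (theta, rho = x cos(theta) +
    y sin(theta)) bin for every theta on the axis; the transform is linear
    in the map.
    """
    gm = np.asarray(grid_map, np.float32)
    h, w = gm.shape
    ys, xs = np.nonzero(gm > 0)
    vals = gm[ys, xs].astype(np.float64)
    diag = math.hypot(h, w)
    n_rho = max(2, int(math.ceil(2 * diag / rho_resolution)) + 1)
    rho_axis = -diag + rho_resolution * np.arange(n_rho)
    votes = np.zeros((len(theta_axis), n_rho))
    if len(ys):
        x = xs.astype(np.float64)
        y = ys.astype(np.float64)
        for i, th in enumerate(theta_axis):
            rho = x * math.cos(th) + y * math.sin(th)
            idx = np.round((rho + diag) / rho_resolution).astype(np.int64)
            np.clip(idx, 0, n_rho - 1, out=idx)
            votes[i] = np.bincount(idx, weights=vals, minlength=n_rho)
    return HoughAccumulator(np.asarray(theta_axis, float), rho_axis, votes)


def angle_angle_transform(acc: HoughAccumulator, chunk: int = 32,
                          band_deg: float | None = None) -> AngleAngleMap:
    """Variance along straight lines across the accumulator.

    The value at (theta_i, theta_j) is the variance of bilinear samples of
    the accumulator along the segment from (theta_i, rho_min) to
    (theta_j, rho_max), one sample per rho bin.  ``band_deg`` optionally
    restricts the search to |theta_i - theta_j| <= band_deg (entries outside
    the band are set to -inf); a pencil of near-parallel gridlines always
    lies inside a narrow band.
    """
    n_t, n_rho = acc.votes.shape
    if n_rho < 2:
        raise ValueError("accumulator needs at least 2 rho bins")
    if band_deg is None:
        half = n_t
    else:
        step = float(np.mean(np.diff(acc.theta_axis))) if n_t > 1 else 1.0
        half = max(1, int(math.ceil(math.radians(band_deg) / step)))
    votes = np.ascontiguousarray(acc.votes, np.float64)
    out = _aa_variance(votes, half)
    if band_deg is None:
        out[~np.isfinite(out)] = 0.0
    return AngleAngleMap(acc.theta_axis, out)


def _aa_variance_numpy(votes: np.ndarray, half: int) -> np.ndarray:
    n_t, n_rho = votes.shape
    t = np.linspace(0.0, 1.0, n_rho)
    rho_idx = t * (n_rho - 1)
    out = np.full((n_t, n_t), -np.inf)
    chunk = max(1, int(4e6 // (2 * half * n_rho + 1)))
    for i0 in range(0, n_t, chunk):
        i1 = min(i0 + chunk, n_t)
        j0 = max(0, i0 - half)
        j1 = min(n_t, i1 + half)
        ii = np.arange(i0, i1, dtype=np.float64)
        jj = np.arange(j0, j1, dtype=np.float64)
        # theta index along the segment: i + (j - i) * t
        ti = ii[:, None, None] + (jj[None, :, None]
                                  - ii[:, None, None]) * t[None, None, :]
        ri = np.broadcast_to(rho_idx, ti.shape)
        samples = ndimage.map_coordinates(
            votes, [ti.ravel(), ri.ravel()], order=1, mode="nearest")
        samples = samples.reshape(ti.shape)
        var = samples.var(axis=-1)
        off = np.abs(jj[None, :] - ii[:, None]) > half
        var[off] = -np.inf
        out[i0:i1, j0:j1] = var
    return out


try:                                           # numba accelerates the O(n^3)
    from numba import njit                     # sampling loop when available

    @njit(fastmath=True)
    def _aa_variance_jit(votes, half):         # pragma: no cover - jitted
        n_t, n_rho = votes.shape
        out = np.full((n_t, n_t), -np.inf)
        inv = 1.0 / (n_rho - 1)
        for i in range(n_t):
            j0 = max(0, i - half)
            j1 = min(n_t, i + half + 1)
            for j in range(j0, j1):
                s = 0.0
                s2 = 0.0
                step = (j - i) * inv
                pos = float(i)
                for r in range(n_rho):
                    i0 = int(pos)
                    if i0 >= n_t - 1:
                        v = votes[n_t - 1, r]
                    else:
                        f = pos - i0
                        v = (1.0 - f) * votes[i0, r] + f * votes[i0 + 1, r]
                    s += v
                    s2 += v * v
                    pos += step
                mean = s / n_rho
                out[i, j] = max(0.0, s2 / n_rho - mean * mean)
        return out

    @njit(fastmath=True)
    def _aa_best_jit(votes, ii, jj):           # pragma: no cover - jitted
        n_t, n_rho = votes.shape
        inv = 1.0 / (n_rho - 1)
        best_v = -np.inf
        bi, bj = ii[0], jj[0]
        for a in range(len(ii)):
            i = ii[a]
            for b in range(len(jj)):
                j = jj[b]
                s = 0.0
                s2 = 0.0
                step = (j - i) * inv
                pos = float(i)
                for r in range(n_rho):
                    i0 = int(pos)
                    if i0 >= n_t - 1:
                        v = votes[n_t - 1, r]
                    else:
                        f = pos - i0
                        v = (1.0 - f) * votes[i0, r] + f * votes[i0 + 1, r]
                    s += v
                    s2 += v * v
                    pos += step
                mean = s / n_rho
                var = s2 / n_rho - mean * mean
                if var > best_v:
                    best_v = var
                    bi, bj = i, j
        return bi, bj

    def _aa_variance(votes, half):
        return _aa_variance_jit(votes, half)

    def _aa_best_in_window(votes, ii, jj):
        return _aa_best_jit(votes, ii, jj)
except Exception:                              # pragma: no cover
    _aa_variance = _aa_variance_numpy

    def _aa_best_in_window(votes, ii, jj):
        n_t = votes.shape[0]
        half = n_t
        out = _aa_variance_numpy(votes, half)
        sub = out[np.ix_(ii, jj)]
        a, b = np.unravel_index(np.argmax(sub), sub.shape)
        return ii[a], jj[b]


# ---------------------------------------------------------------------------
# Family search
# ---------------------------------------------------------------------------

def _find_two_peaks(aa: AngleAngleMap, config: DewarpConfig):
    """The two most prominent maxima separated by roughly 90 degrees."""
    v = aa.values
    finite = v[np.isfinite(v)]
    med = np.median(finite)
    mad = np.median(np.abs(finite - med)) + 1e-12
    i1, j1 = np.unravel_index(np.argmax(v), v.shape)
    if v[i1, j1] <= med + config.prominence * mad:
        raise DewarpFailure("no prominent gridline family")
    th = np.degrees(aa.theta_axis)
    # the second family sits ~90 deg away on both axes
    ok_i = np.abs(np.abs(th - th[i1]) - 90.0) <= config.sep_tol_deg
    ok_j = np.abs(np.abs(th - th[j1]) - 90.0) <= config.sep_tol_deg
    masked = np.where(ok_i[:, None] & ok_j[None, :], v, -np.inf)
    i2, j2 = np.unravel_index(np.argmax(masked), v.shape)
    if not np.isfinite(masked[i2, j2]) or \
            masked[i2, j2] < config.second_peak_ratio * v[i1, j1]:
        raise DewarpFailure("no second gridline family near 90 degrees")
    return (i1, j1), (i2, j2)


def _refine_family(grid_map, ti, tj, config: DewarpConfig) -> LineFamily:
    """Fine search: +-fine_half_deg windows around the coarse (ti, tj)."""
    step = math.radians(config.fine_step_deg)
    half = math.radians(config.fine_half_deg)
    lo = min(ti, tj) - half
    hi = max(ti, tj) + half
    axis = np.arange(lo, hi + 1e-12, step)
    acc = hough_transform(grid_map, axis, config.rho_resolution)
    iwin = np.abs(axis - ti) <= half + 1e-12
    jwin = np.abs(axis - tj) <= half + 1e-12
    best = _aa_best_in_window(
        np.ascontiguousarray(acc.votes, np.float64),
        np.nonzero(iwin)[0].astype(np.int64),
        np.nonzero(jwin)[0].astype(np.int64))
    i, j = int(best[0]), int(best[1])
    return LineFamily(float(axis[i]), float(axis[j]),
                      float(acc.rho_axis[0]), float(acc.rho_axis[-1]))


def find_line_families(grid_map: np.ndarray,
                       config: DewarpConfig | None = None):
    """Locate the two gridline families (coarse-to-fine).

    Runs a coarse Hough over [-pi/4, 3pi/4], takes the angle-angle map's two
    most prominent ~90-degree-separated maxima, then re-runs the Hough at
    fine resolution around each candidate.  Returns ``(family_a, family_b,
    pool_factor)``; raises :class:`DewarpFailure` when no grid is found.
    """
    config = config or DewarpConfig()
    gm = np.asarray(grid_map, np.float32)
    if not np.any(gm > 0):
        raise DewarpFailure("empty grid map")
    factor = max(1, int(math.ceil(max(gm.shape) / config.pool_long_side)))
    if factor > 1:
        gm = block_reduce(gm, (factor, factor), np.max)
    step = math.radians(config.coarse_step_deg)
    axis = np.arange(-math.pi / 4, 3 * math.pi / 4, step)
    acc = hough_transform(gm, axis, config.rho_resolution)
    aa = angle_angle_transform(acc, band_deg=config.max_spread_deg)
    (i1, j1), (i2, j2) = _find_two_peaks(aa, config)
    fam1 = _refine_family(gm, axis[i1], axis[j1], config)
    fam2 = _refine_family(gm, axis[i2], axis[j2], config)
    return fam1, fam2, factor


# ---------------------------------------------------------------------------
# Rectification
# ---------------------------------------------------------------------------

def _scale_vp(vp: np.ndarray, factor: int) -> np.ndarray:
    """Vanishing point from pooled coordinates to full resolution."""
    return np.array([vp[0] * factor, vp[1] * factor, vp[2]])


def rectification_homography(families, shape, pool_factor: int = 1
                             ) -> np.ndarray:
    """Homography sending both families' vanishing points to infinity.

    The family with mean angle nearest 0 holds the vertical gridlines
    (x = const) and is aligned with the image y axis; the other with the x
    axis.  The affine residual is fixed by unit scaling at the image center
    and by requiring no flip.
    """
    h, w = shape
    fams = sorted(families, key=lambda f: abs(math.sin(f.mean_theta)))
    f_vert, f_horz = fams[0], fams[1]
    vp_v = _scale_vp(f_vert.vanishing_point(), pool_factor)
    vp_h = _scale_vp(f_horz.vanishing_point(), pool_factor)
    linf = np.cross(vp_v, vp_h)
    if np.linalg.norm(linf[:2]) < 1e-15 and abs(linf[2]) < 1e-15:
        raise DewarpFailure("degenerate vanishing-point configuration")
    center = np.array([w / 2.0, h / 2.0, 1.0])
    denom = linf @ center
    if abs(denom) < 1e-12:
        raise DewarpFailure("image center on the line at infinity")
    hp = np.eye(3)
    hp[2] = linf / denom
    # directions of the two families after the projective part
    d_v = hp @ vp_v        # ideal point: direction of vertical gridlines
    d_h = hp @ vp_h
    dv = d_v[:2] / (np.linalg.norm(d_v[:2]) + 1e-15)
    dh = d_h[:2] / (np.linalg.norm(d_h[:2]) + 1e-15)
    # map dh -> +-x, dv -> +-y; signs chosen to avoid flips (positive
    # diagonal of the Jacobian at the image center)
    a = np.linalg.inv(np.column_stack([dh, dv]))
    hmat = np.eye(3)
    hmat[:2, :2] = a
    hmat = hmat @ hp
    jac = _jacobian(hmat, center[:2])
    if jac[0, 0] < 0:
        hmat = np.diag([-1.0, 1.0, 1.0]) @ hmat
        jac = _jacobian(hmat, center[:2])
    if jac[1, 1] < 0:
        hmat = np.diag([1.0, -1.0, 1.0]) @ hmat
        jac = _jacobian(hmat, center[:2])
    # unit scale per axis at the center
    sx = 1.0 / (np.linalg.norm(jac[:, 0]) + 1e-15)
    sy = 1.0 / (np.linalg.norm(jac[:, 1]) + 1e-15)
    return np.diag([sx, sy, 1.0]) @ hmat


def _jacobian(hmat: np.ndarray, p: np.ndarray, eps: float = 1.0) -> np.ndarray:
    def apply(q):
        v = hmat @ np.array([q[0], q[1], 1.0])
        return v[:2] / v[2]
    p0 = apply(p)
    return np.column_stack([(apply(p + [eps, 0]) - p0) / eps,
                            (apply(p + [0, eps]) - p0) / eps])


def _apply_h(hmat, pts):
    pts = np.atleast_2d(pts)
    q = np.column_stack([pts, np.ones(len(pts))]) @ hmat.T
    return q[:, :2] / q[:, 2:3]


def rectify(image: np.ndarray, maps: np.ndarray, families,
            pool_factor: int = 1, config: DewarpConfig | None = None,
            grid_spacing_px: float | None = None) -> DewarpedSample:
    """Resample image and maps so gridlines are axis-aligned, then crop.

    ``maps`` is (C, H, W) with the class order of the main network
    (background, grid, signal, text).  The crop covers the bounding box of
    signal probability above threshold, dilated by 2 major-grid units
    (estimated from ``grid_spacing_px`` when given, else 2% of the long
    side), bounded by the rectified extent.
    """
    config = config or DewarpConfig()
    h, w = image.shape[:2]
    hmat = rectification_homography(families, (h, w), pool_factor)
    corners = np.array([[0, 0], [w - 1, 0], [w - 1, h - 1], [0, h - 1]], float)
    tc = _apply_h(hmat, corners)
    shift = tc.min(axis=0)
    span = tc.max(axis=0) - shift
    if not np.all(np.isfinite(span)) or span.max() > 4 * max(h, w):
        raise DewarpFailure("rectification blows up the image")
    t_final = np.array([[1, 0, -shift[0]], [0, 1, -shift[1]], [0, 0, 1.0]]) @ hmat
    out_w, out_h = int(math.ceil(span[0])) + 1, int(math.ceil(span[1])) + 1
    hinv = np.linalg.inv(t_final)

    def do_warp(arr, order):
        return warp(arr.astype(np.float32), _InvMap(hinv),
                    output_shape=(out_h, out_w), order=order, cval=0.0,
                    preserve_range=True)

    img_r = do_warp(image, 1)
    maps_r = np.stack([do_warp(m, 1) for m in maps])

    sig = maps_r[2] if maps_r.shape[0] > 2 else maps_r[-1]
    mask = sig > config.signal_threshold
    if mask.any():
        ys, xs = np.nonzero(mask)
        if grid_spacing_px is not None:
            margin = config.crop_margin_units * 5.0 * grid_spacing_px
        else:
            margin = 0.02 * max(out_h, out_w)
        m = int(round(margin))
        y0, y1 = max(0, ys.min() - m), min(out_h, ys.max() + m + 1)
        x0, x1 = max(0, xs.min() - m), min(out_w, xs.max() + m + 1)
    else:
        y0, x0, y1, x1 = 0, 0, out_h, out_w
    crop_t = np.array([[1, 0, -x0], [0, 1, -y0], [0, 0, 1.0]]) @ t_final
    img_c = img_r[y0:y1, x0:x1]
    if image.dtype == np.uint8:
        img_c = np.clip(img_c, 0, 255).astype(np.uint8)
    return DewarpedSample(img_c, maps_r[:, y0:y1, x0:x1].astype(np.float32),
                          crop_t, (y0, x0, y1, x1))


class _InvMap:
    """Callable inverse map for skimage.warp (output coords -> input)."""

    def __init__(self, hinv):
        self.hinv = hinv

    def __call__(self, coords):
        return _apply_h(self.hinv, coords)
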