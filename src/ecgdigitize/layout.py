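"""Lead layouts: templates, marker detection, and best-match selection.

A printed 12-lead ECG arranges its leads in one of a few conventional grids
(3x4, 3x4 with a rhythm strip, 6x2, 12x1, ...).  This module holds the
layout templates (user-extensible through a YAML config), locates lead-name
markers from the 13-class text segmentation, and selects the minimum-cost
candidate layout: detected markers are paired with template markers by lead
identity, a per-axis scale + translation is fitted by least squares, and the
candidate cost is

    cost = (1/|G|) * (lambda * |M_miss| + sum ||p' - g||)

with ``lambda = 0.5`` (half the normalized image width) charged for every
template lead that was not detected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "STANDARD_LEADS", "LayoutTemplate", "LayoutPanel", "Marker", "MarkerSet",
    "LayoutMatch", "builtin_templates", "load_layout_config",
    "save_layout_config", "generate_layout", "markers_from_probs",
    "detect_markers", "match_layout", "DEFAULT_LAYOUT",
]

STANDARD_LEADS = ("I", "II", "III", "aVR", "aVL", "aVF",
                  "V1", "V2", "V3", "V4", "V5", "V6")

DEFAULT_LAYOUT = "3x4+rhythm"


@dataclass(frozen=True)
class LayoutPanel:
    """One lead's region of the paper, in normalized [0,1]^2 coordinates."""
    lead: str
    box: tuple          # (x0, y0, x1, y1), normalized
    window: tuple       # (t0, t1) seconds of the recording shown
    is_rhythm: bool = False


@dataclass(frozen=True)
class LayoutTemplate:
    """A candidate lead arrangement.

    ``lead_grid`` is row-major: ``lead_grid[i][j]`` is the lead in row i,
    column j.  ``rhythm`` lists leads printed as full-width strips below the
    grid.  Columns split the total duration evenly; rhythm strips span it
    entirely.
    """
    name: str
    lead_grid: tuple            # tuple of tuples of lead names
    rhythm: tuple = ()
    duration_s: float = 10.0

    def __post_init__(self):
        leads = [l for row in self.lead_grid for l in row]
        if len(set(leads)) != len(leads):
            raise ValueError("duplicate lead in layout grid")
        for l in leads + list(self.rhythm):
            if l not in STANDARD_LEADS:
                raise ValueError(f"unknown lead {l!r}")

    @property
    def rows(self) -> int:
        return len(self.lead_grid)

    @property
    def cols(self) -> int:
        return len(self.lead_grid[0])

    @property
    def total_rows(self) -> int:
        return self.rows + len(self.rhythm)

    @property
    def leads(self) -> tuple:
        return tuple(l for row in self.lead_grid for l in row)

    def panels(self) -> list:
        """All panels (grid leads then rhythm strips), normalized boxes."""
        out = []
        R, C, T = self.total_rows, self.cols, self.duration_s
        for i, row in enumerate(self.lead_grid):
            for j, lead in enumerate(row):
                out.append(LayoutPanel(
                    lead=lead,
                    box=(j / C, i / R, (j + 1) / C, (i + 1) / R),
                    window=(j * T / C, (j + 1) * T / C)))
        for r, lead in enumerate(self.rhythm):
            i = self.rows + r
            out.append(LayoutPanel(lead=lead, box=(0.0, i / R, 1.0, (i + 1) / R),
                                   window=(0.0, T), is_rhythm=True))
        return out

    def marker_positions(self) -> dict:
        """Nominal label-anchor position per marker in [0,1]^2.

        Labels sit near the top-left of each panel.  A lead that appears
        both in the grid and as a rhythm strip keeps its grid marker (one
        marker per lead identity).
        """
        pos = {}
        for p in self.panels():
            if p.lead in pos:
                continue
            x0, y0, x1, y1 = p.box
            pos[p.lead] = (x0 + 0.06 * (x1 - x0) if not p.is_rhythm
                           else x0 + 0.015,
                           y0 + 0.28 * (y1 - y0))
        return pos


def builtin_templates() -> list:
    """The four layouts shipped by default (3x4+rhythm first: the default)."""
    col_3x4 = (("I", "aVR", "V1", "V4"),
               ("II", "aVL", "V2", "V5"),
               ("III", "aVF", "V3", "V6"))
    col_6x2 = (("I", "V1"), ("II", "V2"), ("III", "V3"),
               ("aVR", "V4"), ("aVL", "V5"), ("aVF", "V6"))
    col_12x1 = tuple((l,) for l in STANDARD_LEADS)
    return [
        LayoutTemplate("3x4+rhythm", col_3x4, rhythm=("II",)),
        LayoutTemplate("3x4", col_3x4),
        LayoutTemplate("6x2", col_6x2),
        LayoutTemplate("12x1", col_12x1),
    ]


def get_template(name: str, candidates=None) -> LayoutTemplate:
    for t in candidates or builtin_templates():
        if t.name == name:
            return t
    raise KeyError(f"unknown layout template {name!r}")


def load_layout_config(path) -> list:
    """Read candidate layouts from a YAML file.

    Each entry: ``name``, ``lead_grid`` (list of rows), optional ``rhythm``
    and ``duration_s``.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    out = []
    for entry in raw["layouts"]:
        out.append(LayoutTemplate(
            name=entry["name"],
            lead_grid=tuple(tuple(r) for r in entry["lead_grid"]),
            rhythm=tuple(entry.get("rhythm", ())),
            duration_s=float(entry.get("duration_s", 10.0))))
    return out


def save_layout_config(templates, path) -> None:
    data = {"layouts": [
        {"name": t.name, "lead_grid": [list(r) for r in t.lead_grid],
         "rhythm": list(t.rhythm), "duration_s": t.duration_s}
        for t in templates]}
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Markers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Marker:
    lead: str
    x: float            # pixels
    y: float
    mass: float


@dataclass
class MarkerSet:
    markers: list
    width: int
    height: int

    def normalized(self) -> dict:
        return {m.lead: (m.x / self.width, m.y / self.height)
                for m in self.markers}


def markers_from_probs(probs13: np.ndarray, min_mass: float = 3.0,
                       lead_names=STANDARD_LEADS) -> MarkerSet:
    """Weighted centroid of each lead class's probability mass.

    ``probs13``: (13, H, W) with class 0 = background and classes 1..12 in
    the standard lead order.  Classes with total mass below ``min_mass``
    (in probability-pixels) are dropped.  When a lead's mass splits into
    several blobs, the largest blob wins (one marker per lead identity).
    """
    from scipy import ndimage
    _, h, w = probs13.shape
    markers = []
    for k, lead in enumerate(lead_names, start=1):
        plane = probs13[k]
        hard = plane > 0.5
        if hard.any():
            lbl, n = ndimage.label(hard)
            if n > 1:
                masses = ndimage.sum_labels(plane, lbl, index=np.arange(1, n + 1))
                keep = int(np.argmax(masses)) + 1
                plane = np.where(lbl == keep, plane, 0.0)
        mass = float(plane.sum())
        if mass < min_mass:
            continue
        ys, xs = np.nonzero(plane > 0)
        vals = plane[ys, xs]
        markers.append(Marker(lead, float((xs * vals).sum() / mass),
                              float((ys * vals).sum() / mass), mass))
    return MarkerSet(markers, width=w, height=h)


def detect_markers(text_prob_map: np.ndarray, text_model,
                   min_mass: float = 3.0) -> MarkerSet:
    """Run the 13-class text net on the dewarped text plane, then centroid.

    ``text_prob_map``: (H, W) single-channel probability of the text class
    from the main segmentation network, in the dewarped frame.
    """
    from .segnet import segment
    probs = segment(text_model, text_prob_map.astype(np.float32))
    return markers_from_probs(probs, min_mass=min_mass)


# ---------------------------------------------------------------------------
# Matching (layout selection)
# ---------------------------------------------------------------------------

@dataclass
class LayoutMatch:
    template: LayoutTemplate
    cost: float
    matched: dict          # lead -> (transformed detected pos, template pos)
    missing: tuple         # template leads with no detection
    scale: tuple
    translate: tuple
    fallback: bool = False


def generate_layout(template: LayoutTemplate) -> dict:
    """Template marker coordinates G: lead -> (x, y) in [0,1]^2."""
    return template.marker_positions()


def _fit_similarity(p: np.ndarray, g: np.ndarray):
    """Least squares for s*p + t ~= g with one shared scale, per-axis shift.

    A single scale keeps the vertical pitch relative to the horizontal pitch
    discriminative: layouts differing only in row count (3x4 versus 3x4 with
    a rhythm strip) are not absorbed by the fit.  Scale falls back to 1 when
    under-determined.
    """
    pc = p - p.mean(axis=0)
    gc = g - g.mean(axis=0)
    denom = float(np.sum(pc * pc))
    s = float(np.sum(pc * gc)) / denom if len(p) >= 2 and denom > 1e-12 \
        else 1.0
    t = g.mean(axis=0) - s * p.mean(axis=0)
    return s, (float(t[0]), float(t[1]))


def match_layout(markers: MarkerSet, candidates=None,
                 lam: float = 0.5) -> LayoutMatch:
    """Select the minimum-cost layout for a detected marker set.

    Detected markers are normalized by image size, paired with template
    markers by lead identity, registered by per-axis scale + translation,
    and scored by the mean distance plus ``lam`` per missing lead.  Ties
    keep the earlier candidate.  If nothing matches for any candidate, the
    first candidate is returned as a flagged fallback.
    """
    candidates = list(candidates or builtin_templates())
    if not candidates:
        raise ValueError("no candidate layouts")
    det = markers.normalized()
    best = None
    for template in candidates:
        g = generate_layout(template)
        shared = [l for l in g if l in det]
        missing = tuple(l for l in g if l not in det)
        if not shared:
            continue
        p = np.array([det[l] for l in shared])
        gm = np.array([g[l] for l in shared])
        s, (tx, ty) = _fit_similarity(p, gm)
        sx = sy = s
        pt = np.column_stack([sx * p[:, 0] + tx, sy * p[:, 1] + ty])
        dist = np.linalg.norm(pt - gm, axis=1).sum()
        cost = (lam * len(missing) + dist) / len(g)
        if best is None or cost < best.cost:
            best = LayoutMatch(template, float(cost),
                               {l: (tuple(pt[i]), tuple(gm[i]))
                                for i, l in enumerate(shared)},
                               missing, (sx, sy), (tx, ty))
    if best is None:
        t = candidates[0]
        best = LayoutMatch(t, float("inf"), {}, tuple(generate_layout(t)),
                           (1.0, 1.0), (0.0, 0.0), fallback=True)
    return best
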