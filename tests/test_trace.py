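"""Tests for component extraction, snipping, chaining and record assembly."""

import itertools

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from ecgdigitize.gridscale import Calibration
from ecgdigitize.layout import get_template
from ecgdigitize.trace import (ECGRecord, LeadChain, TraceComponent,
                               TraceConfig, _assignment_cost, assemble_record,
                               chain_to_trace, extract_components,
                               merge_components, snip_component, write_csv,
                               write_wfdb)


def flood_fill_count(mask):
    """Recursive-free 8-connected flood fill oracle."""
    mask = mask.copy()
    h, w = mask.shape
    count = 0
    for sy in range(h):
        for sx in range(w):
            if not mask[sy, sx]:
                continue
            count += 1
            stack = [(sy, sx)]
            mask[sy, sx] = False
            while stack:
                y, x = stack.pop()
                for dy in (-1, 0, 1):
                    for dx in (-1, 0, 1):
                        ny, nx = y + dy, x + dx
                        if 0 <= ny < h and 0 <= nx < w and mask[ny, nx]:
                            mask[ny, nx] = False
                            stack.append((ny, nx))
    return count


def test_component_extents_and_endpoints():
    m = np.zeros((40, 100), np.float32)
    m[10, 5:30] = 1.0
    m[25, 40:90] = 1.0
    comps = extract_components(m, 0.5, 5)
    assert [(c.c_min, c.c_max) for c in comps] == [(5, 29), (40, 89)]
    # a diagonal stroke has its endpoints at the stroke ends
    d = np.zeros((50, 50), np.float32)
    for k in range(30):
        d[10 + k, 10 + k] = 1.0
    (comp,) = extract_components(d, 0.5, 5)
    assert comp.left_endpoint == (10.0, 10.0)
    assert comp.right_endpoint == (39.0, 39.0)


def test_component_count_matches_flood_fill_oracle():
    rng = np.random.default_rng(0)
    for _ in range(5):
        m = (rng.uniform(size=(64, 64)) < 0.25).astype(np.float32)
        comps = extract_components(m, 0.5, min_mass=1)
        assert len(comps) == flood_fill_count(m > 0.5)


def test_snip_separates_bridged_strokes():
    m = np.zeros((30, 60), np.float32)
    m[8, 5:55] = 1.0
    m[20, 5:55] = 1.0
    m[8:21, 30] = 1.0
    (comp,) = extract_components(m, 0.5, 5)
    parts = snip_component(comp, m)
    assert len(parts) == 2
    # locality: no pixels outside the original component appear
    orig = set(zip(comp.rows.tolist(), comp.cols.tolist()))
    for p in parts:
        assert set(zip(p.rows.tolist(), p.cols.tolist())) <= orig


def test_snip_solid_rectangle_flagged_unchanged():
    m = np.zeros((20, 30), np.float32)
    m[5:15, 5:25] = 1.0
    (comp,) = extract_components(m, 0.5, 5)
    (out,) = snip_component(comp, m)
    assert out.flag == "no-split"
    assert out.mass == comp.mass


def test_collinear_strokes_chain_in_order():
    m = np.zeros((20, 100), np.float32)
    m[10, 0:20] = 1.0
    m[10, 30:60] = 1.0
    m[11, 70:99] = 1.0
    comps = extract_components(m, 0.5, 5)
    chains, noise = merge_components(comps, panel_span=(0, 100))
    assert len(chains) == 1 and not noise
    assert [c.c_min for c in chains[0].components] == [0, 30, 70]


def test_distant_speck_self_matches_and_is_dropped():
    m = np.zeros((40, 100), np.float32)
    m[30, 0:20] = 1.0
    m[30, 30:60] = 1.0
    m[31, 70:99] = 1.0
    m[2, 45:58] = 1.0          # speck far above the lead band
    comps = extract_components(m, 0.5, 5)
    chains, noise = merge_components(comps, panel_span=(0, 100))
    assert len(chains) == 1 and len(chains[0].components) == 3
    assert len(noise) == 1 and int(noise[0].rows[0]) == 2


def test_assignment_equals_exhaustive_permutation_minimum():
    """The JV solution cost equals brute force over all permutations for
    up to 7 components, across 30 seeded random fixtures."""
    rng = np.random.default_rng(7)
    for _ in range(30):
        n = int(rng.integers(2, 8))
        comps = []
        for _k in range(n):
            c0 = int(rng.integers(0, 80))
            c1 = c0 + int(rng.integers(3, 20))
            row = int(rng.integers(0, 40))
            cols = np.arange(c0, c1 + 1)
            comps.append(TraceComponent(np.full(len(cols), row), cols))
        cost = _assignment_cost(comps, TraceConfig(), (0, 110))
        rows, cols = linear_sum_assignment(cost)
        best = cost[rows, cols].sum()
        brute = min(sum(cost[i, p[i]] for i in range(n))
                    for p in itertools.permutations(range(n)))
        assert best == pytest.approx(brute, rel=1e-12)


def test_chain_to_trace_constant_missing_and_units():
    m = np.zeros((40, 60), np.float32)
    m[20, 5:55] = 1.0
    m[20, 30] = 0.0            # one missing column inside the stroke
    comps = extract_components(m, 0.5, 5)
    cal = Calibration(10.0, 10.0, 25.0, 10.0)
    chain = LeadChain(comps)
    tr = chain_to_trace(chain, m, cal, (5, 55), (0.0, 0.2), "I")
    assert np.isnan(tr.values_mV[30 - 5])
    finite = tr.values_mV[np.isfinite(tr.values_mV)]
    assert np.allclose(finite, 0.0, atol=1e-12)   # constant, baseline removed
    assert np.count_nonzero(np.isnan(tr.values_mV)) == 1


def test_chain_to_trace_recovers_ramp_slope():
    """A rendered straight ramp of known mV/s slope round-trips within 2%."""
    cal = Calibration(10.0, 10.0, 25.0, 10.0)   # 250 px/s, 100 px/mV
    slope_mv_per_s = 0.5
    w = 500
    m = np.zeros((300, w), np.float32)
    for c in range(w):
        t = c / cal.px_per_second
        row = int(round(200 - slope_mv_per_s * t * cal.px_per_mV))
        m[row, c] = 1.0
    comps = extract_components(m, 0.5, 5)
    tr = chain_to_trace(LeadChain(comps), m, cal, (0, w), (0.0, 2.0), "II")
    fit = np.polyfit(tr.t[np.isfinite(tr.values_mV)],
                     tr.values_mV[np.isfinite(tr.values_mV)], 1)
    assert fit[0] == pytest.approx(slope_mv_per_s, rel=0.02)


def test_assemble_record_resampling_and_nan_preservation():
    cal = Calibration(10.0, 10.0, 25.0, 10.0)   # 250 px/s
    template = get_template("12x1")
    t = np.arange(2500) / 250.0
    vals = np.sin(2 * np.pi * 0.7 * t)
    vals[500:700] = np.nan
    traces = []
    from ecgdigitize.trace import LeadTrace
    for lead in template.leads:
        traces.append(LeadTrace(lead, t, vals.copy()))
    # native-rate resampling is the identity within float tolerance
    rec250 = assemble_record(traces, template, cal, 250.0)
    got = rec250.lead("I")
    ok = np.isfinite(vals)
    assert np.allclose(got[ok], vals[ok], atol=1e-9)
    # doubling the rate doubles the length and preserves the NaN fraction
    rec1k = assemble_record(traces, template, cal, 500.0)
    assert rec1k.samples.shape[1] == 2 * rec250.samples.shape[1]
    f250 = np.mean(np.isnan(rec250.lead("I")))
    f1k = np.mean(np.isnan(rec1k.lead("I")))
    assert abs(f250 - f1k) < 0.01
    with pytest.raises(ValueError):
        assemble_record(traces, template, cal, -5)


def test_wfdb_and_csv_writers(tmp_path):
    rec = ECGRecord(["I", "II"],
                    np.array([[0.0, 0.5, np.nan, -0.25],
                              [1.0, np.nan, 0.125, 0.0]]), 500.0)
    prefix = tmp_path / "rec"
    write_wfdb(rec, prefix)
    header = (tmp_path / "rec.hea").read_text().splitlines()
    assert header[0].split() == ["rec", "2", "500", "4"]
    data = np.fromfile(tmp_path / "rec.dat", dtype="<i2").reshape(-1, 2)
    assert data[0, 0] == 0 and data[1, 0] == 500
    assert data[2, 0] == -32768              # NaN sentinel
    assert data[2, 1] == 125
    write_csv(rec, tmp_path / "rec.csv")
    import pandas as pd
    df = pd.read_csv(tmp_path / "rec.csv")
    assert list(df.columns) == ["time_s", "I", "II"]
    assert np.isnan(df["I"][2])
    assert df["II"][2] == pytest.approx(0.125)
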