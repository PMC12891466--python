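"""Tests for lead-marker detection and layout matching."""

import numpy as np
import pytest

from ecgdigitize.layout import (STANDARD_LEADS, LayoutTemplate, Marker,
                                MarkerSet, builtin_templates, generate_layout,
                                get_template, load_layout_config,
                                markers_from_probs, match_layout,
                                save_layout_config)


def markers_for(template, width=1000, height=800, jitter=0.0, rng=None,
                drop=()):
    g = generate_layout(template)
    markers = []
    for lead, (x, y) in g.items():
        if lead in drop:
            continue
        dx = rng.normal(0, jitter) if rng is not None and jitter else 0.0
        dy = rng.normal(0, jitter) if rng is not None and jitter else 0.0
        markers.append(Marker(lead, (x + dx) * width, (y + dy) * height,
                              mass=20.0))
    return MarkerSet(markers, width, height)


def test_generate_layout_structure():
    t12 = get_template("12x1")
    g = generate_layout(t12)
    assert len(g) == 12
    xs = {round(x, 6) for x, _ in g.values()}
    assert len(xs) == 1                      # one shared column
    ys = sorted(y for _, y in g.values())
    diffs = np.diff(ys)
    assert np.allclose(diffs, diffs[0], atol=1e-9)   # equally spaced

    t34 = get_template("3x4")
    g34 = generate_layout(t34)
    assert len(g34) == 12
    assert len({round(x, 6) for x, _ in g34.values()}) == 4
    assert len({round(y, 6) for _, y in g34.values()}) == 3
    # the rhythm variant still has one marker per lead identity
    assert len(generate_layout(get_template("3x4+rhythm"))) == 12


def test_perfect_markers_select_true_template_with_zero_cost():
    for template in builtin_templates():
        ms = markers_for(template)
        match = match_layout(ms, builtin_templates())
        assert match.template.name == template.name
        assert match.cost == pytest.approx(0.0, abs=1e-9)


def test_one_missing_marker_costs_lambda_over_g():
    template = get_template("3x4")
    ms = markers_for(template, drop=("V3",))
    match = match_layout(ms, [template])
    assert match.missing == ("V3",)
    assert match.cost == pytest.approx(0.5 / 12, abs=1e-9)


def test_costs_match_direct_reevaluation():
    """The reported cost equals a from-scratch evaluation of the printed
    formula on the matched pairs."""
    rng = np.random.default_rng(0)
    for trial in range(20):
        template = builtin_templates()[trial % 4]
        drop = tuple(rng.choice(list(template.leads),
                                size=rng.integers(0, 3), replace=False))
        ms = markers_for(template, jitter=0.004, rng=rng, drop=drop)
        match = match_layout(ms, builtin_templates())
        g = generate_layout(match.template)
        det = ms.normalized()
        shared = [l for l in g if l in det]
        p = np.array([det[l] for l in shared])
        gm = np.array([g[l] for l in shared])
        sx, sy = match.scale
        tx, ty = match.translate
        pt = np.column_stack([sx * p[:, 0] + tx, sy * p[:, 1] + ty])
        cost = (0.5 * (len(g) - len(shared))
                + np.linalg.norm(pt - gm, axis=1).sum()) / len(g)
        assert match.cost == pytest.approx(cost, rel=1e-9)


def test_cost_invariant_to_scale_and_translation():
    template = get_template("6x2")
    base = markers_for(template)
    match0 = match_layout(base, [template])
    moved = MarkerSet([Marker(m.lead, 0.6 * m.x + 100, 0.6 * m.y + 50,
                              m.mass) for m in base.markers],
                      base.width, base.height)
    match1 = match_layout(moved, [template])
    assert match1.cost == pytest.approx(match0.cost, abs=1e-6)


def test_deleting_a_marker_never_decreases_true_template_cost():
    rng = np.random.default_rng(1)
    template = get_template("3x4+rhythm")
    full = markers_for(template, jitter=0.003, rng=rng)
    c_full = match_layout(full, [template]).cost
    for lead in ("I", "V2", "aVF"):
        dropped = MarkerSet([m for m in full.markers if m.lead != lead],
                            full.width, full.height)
        assert match_layout(dropped, [template]).cost >= c_full - 1e-12


def test_empty_marker_set_falls_back():
    ms = MarkerSet([], 100, 100)
    match = match_layout(ms, builtin_templates())
    assert match.fallback
    assert match.template.name == "3x4+rhythm"


def test_markers_from_probs_zero_map_and_dedup():
    probs = np.zeros((13, 60, 80), np.float32)
    assert markers_from_probs(probs).markers == []
    # two blobs for lead I: the larger wins
    probs[1, 10:14, 10:16] = 0.9
    probs[1, 40:42, 60:62] = 0.9
    ms = markers_from_probs(probs)
    assert len(ms.markers) == 1
    m = ms.markers[0]
    assert m.lead == "I" and abs(m.x - 12.5) < 1 and abs(m.y - 11.5) < 1


def test_markers_recovered_from_rendered_text_mask(clean_render_100dpi):
    """One-hot truth masks yield 12 markers, each near its label box."""
    sample = clean_render_100dpi
    lt = sample.lead_text_mask
    probs = np.stack([(lt == k).astype(np.float32) for k in range(13)])
    ms = markers_from_probs(probs)
    found = {m.lead for m in ms.markers}
    assert found == set(STANDARD_LEADS)
    text_h = 2.8 * sample.config.px_per_mm
    for m in ms.markers:
        ys, xs = np.nonzero(lt == STANDARD_LEADS.index(m.lead) + 1)
        assert abs(m.y - ys.mean()) < text_h
        assert abs(m.x - xs.mean()) < 3 * text_h


def test_layout_config_yaml_round_trip(tmp_path):
    path = tmp_path / "layouts.yaml"
    save_layout_config(builtin_templates(), path)
    loaded = load_layout_config(path)
    assert [t.name for t in loaded] == [t.name for t in builtin_templates()]
    assert loaded[0].rhythm == ("II",)
    with pytest.raises(ValueError):
        LayoutTemplate("bad", (("I", "I"),))
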