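"""Unit tests for the NumPy neural-network core: gradients, loss, optimizers."""

import math

import numpy as np
import pytest

from ecgdigitize.nn import (AdamW, Muon, cosine_to_constant_lr,
                            dice_focal_loss, newton_schulz_orthogonalize,
                            softmax)
from ecgdigitize.segnet import UNet, UNetConfig


def _tiny_net():
    return UNet(UNetConfig(encoder_widths=(4, 6, 8), in_channels=3,
                           out_channels=4, seed=1))


def test_backprop_matches_finite_differences():
    """Analytic gradients through the whole net agree with central
    differences for randomly sampled parameters and inputs."""
    rng = np.random.default_rng(0)
    model = _tiny_net()
    x = rng.normal(size=(2, 3, 8, 8)).astype(np.float32)
    target = rng.integers(0, 4, size=(2, 8, 8))

    def loss_of():
        logits = model.forward(x)
        return dice_focal_loss(logits, target)

    model.zero_grad()
    _, dz, _ = loss_of()
    dx = model.backward(dz)

    params = model.params()
    picked = [params[i] for i in rng.choice(len(params), size=6,
                                            replace=False)]
    eps = 1e-3
    for p in picked:
        idx = tuple(rng.integers(0, s) for s in p.value.shape)
        old = p.value[idx]
        p.value[idx] = old + eps
        l1, _, _ = loss_of()
        p.value[idx] = old - eps
        l2, _, _ = loss_of()
        p.value[idx] = old
        fd = (l1 - l2) / (2 * eps)
        assert abs(fd - p.grad[idx]) < 0.1 * max(abs(fd), 1e-3) + 1e-4, p.name

    idx = (0, 1, 3, 4)
    old = x[idx]
    x[idx] = old + eps
    l1, _, _ = loss_of()
    x[idx] = old - eps
    l2, _, _ = loss_of()
    fd = (l1 - l2) / (2 * eps)
    assert abs(fd - dx[idx]) < 0.1 * max(abs(fd), 1e-3) + 1e-4


def test_loss_perfect_prediction_near_zero():
    rng = np.random.default_rng(1)
    target = rng.integers(0, 4, size=(1, 6, 6))
    logits = np.full((1, 4, 6, 6), -50.0, np.float32)
    for c in range(4):
        logits[0, c][target[0] == c] = 50.0
    loss, _, parts = dice_focal_loss(logits, target)
    assert parts["focal"] < 1e-6
    assert parts["dice"] < 0.05        # limited only by the smoothing term


def test_focal_gamma_zero_is_cross_entropy():
    rng = np.random.default_rng(2)
    logits = rng.normal(size=(1, 4, 5, 5)).astype(np.float32)
    target = rng.integers(0, 4, size=(1, 5, 5))
    _, _, parts = dice_focal_loss(logits, target, focal_gamma=0.0)
    p = softmax(logits.astype(np.float64), axis=1)
    i0, i2, i3 = np.ogrid[:1, :5, :5]
    ce = float(np.mean(-np.log(p[i0, target, i2, i3])))
    assert parts["focal"] == pytest.approx(ce, rel=1e-9)


def test_focal_uniform_prediction_closed_form():
    """Uniform 4-class prediction: focal term = (3/4)^gamma * ln 4 per
    pixel, independent of the target."""
    gamma = 2.0
    logits = np.zeros((1, 4, 6, 6), np.float32)
    target = np.random.default_rng(3).integers(0, 4, size=(1, 6, 6))
    _, _, parts = dice_focal_loss(logits, target, focal_gamma=gamma)
    expected = (0.75 ** gamma) * math.log(4.0)
    assert parts["focal"] == pytest.approx(expected, rel=1e-6)


def test_empty_target_rejected():
    with pytest.raises(ValueError):
        dice_focal_loss(np.zeros((1, 4, 0, 0), np.float32),
                        np.zeros((1, 0, 0), int))


def test_newton_schulz_orthogonalizes():
    rng = np.random.default_rng(4)
    g = rng.normal(size=(12, 20)).astype(np.float32)
    o = newton_schulz_orthogonalize(g)
    gram = o @ o.T
    assert np.allclose(gram, np.eye(12), atol=0.35)
    # sign structure preserved: positive alignment with the input
    assert float(np.sum(o * g)) > 0


def test_cosine_schedule_endpoints_and_tail():
    assert cosine_to_constant_lr(0, 0.0037, 0.00037, 20_000) == \
        pytest.approx(0.0037)
    assert cosine_to_constant_lr(20_000, 0.0037, 0.00037, 20_000) == \
        pytest.approx(0.00037)
    assert cosine_to_constant_lr(50_000, 0.0037, 0.00037, 20_000) == \
        pytest.approx(0.00037)
    mid = cosine_to_constant_lr(10_000, 0.0037, 0.00037, 20_000)
    assert 0.00037 < mid < 0.0037


def test_optimizers_reduce_a_quadratic():
    rng = np.random.default_rng(5)
    from ecgdigitize.nn import Param
    w = Param(rng.normal(size=(4, 3, 3, 3)).astype(np.float32), "conv")
    b = Param(rng.normal(size=4).astype(np.float32), "affine")
    n0w, n0b = np.linalg.norm(w.value), np.linalg.norm(b.value)
    muon = Muon([w], lr=0.04)
    adamw = AdamW([b], lr=0.05, weight_decay=0.0)
    for _ in range(250):
        w.grad = w.value.copy()
        b.grad = b.value.copy()
        muon.step()
        adamw.step()
    assert np.linalg.norm(w.value) < 0.2 * n0w
    assert np.linalg.norm(b.value) < 0.2 * n0b
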