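"""The two forward passes, the three losses, and their contracts."""

import numpy as np
import pytest
from scipy import integrate

from collabnet.config import CNConfig
from collabnet.model import (
    CNModel,
    binary_cross_entropy,
    f_forward,
    f_loss,
    g_forward,
    g_loss,
    load_checkpoint,
    pretrain_loss,
    save_checkpoint,
)
from collabnet.nn import Adam
from collabnet.training import _f_step, _g_step


def make_model(seed=0, zero_head=False, **cfg) -> CNModel:
    config = CNConfig(**cfg)
    model = CNModel(2, config, np.random.default_rng(seed))
    model.fit_scaling(np.random.default_rng(1).normal(size=(50, 2)),
                      np.random.default_rng(2).normal(size=50))
    if zero_head:
        # Zero final-layer weights and biases of both networks.
        for net in (model.g_net, model.f_net):
            net.params[-2][:] = 0.0
            net.params[-1][:] = 0.0
    return model


def test_untrained_zero_head_g_outputs_half():
    model = make_model(zero_head=True)
    x = np.array([[0.3, -1.2], [5.0, 2.0]])
    np.testing.assert_allclose(g_forward(model, [0.0, 3.7], x), 0.5)


def test_untrained_zero_head_f_is_constant():
    model = make_model(zero_head=True)
    x = np.random.default_rng(3).normal(size=(6, 2))
    out = f_forward(model, np.linspace(0.1, 0.9, 6), x)
    np.testing.assert_allclose(out, out[0])


def test_g_forward_strictly_inside_unit_interval():
    model = make_model(seed=5)
    rng = np.random.default_rng(6)
    p = g_forward(model, rng.normal(size=100) * 50, rng.normal(size=(100, 2)) * 50)
    assert np.all(p > 0.0) and np.all(p < 1.0)


def test_g_forward_rejects_non_finite():
    model = make_model()
    with pytest.raises(ValueError):
        g_forward(model, np.nan, [[0.0, 0.0]])
    with pytest.raises(ValueError):
        g_forward(model, 0.0, [[np.inf, 0.0]])


def test_f_forward_rejects_out_of_domain_q():
    model = make_model()
    for q in (0.0, 1.0, -0.2, 1.3):
        with pytest.raises(ValueError):
            f_forward(model, q, [[0.0, 0.0]])


@pytest.mark.parametrize(
    "b,a,expected",
    [(1, 0.5, 0.6931), (1, 0.9, 0.1054), (0, 0.2, 0.2231), (0, 0.5, 0.6931)],
)
def test_binary_cross_entropy_values(b, a, expected):
    assert binary_cross_entropy(b, a) == pytest.approx(expected, abs=1e-4)


def test_loss_functions_reject_empty_batches():
    model = make_model()
    empty = np.empty((0, 2))
    with pytest.raises(ValueError):
        g_loss(model, empty, np.empty(0), np.empty(0))
    with pytest.raises(ValueError):
        f_loss(model, empty, np.empty(0))
    with pytest.raises(ValueError):
        pretrain_loss(model, empty, np.empty(0), np.empty(0))


def test_f_loss_on_degenerate_model_matches_squared_gap():
    # Zero-head model: g outputs 0.5 everywhere, so the f-loss reduces to
    # (q - 0.5)^2 exactly.
    model = make_model(zero_head=True)
    x = np.zeros((1, 2))
    assert float(f_loss(model, x, [0.3])) == pytest.approx(0.04, abs=1e-12)
    assert float(f_loss(model, x, [0.5])) == pytest.approx(0.0, abs=1e-12)


def test_f_loss_uniform_q_expectation_one_twelfth():
    # E[(q - 1/2)^2] = 1/12 for q ~ Uniform(0,1) when the composition is
    # constant at 1/2.
    model = make_model(zero_head=True)
    rng = np.random.default_rng(7)
    q = rng.uniform(size=100_000)
    x = np.zeros((q.size, 2))
    assert float(f_loss(model, x, q)) == pytest.approx(1 / 12, abs=2e-3)


def test_pretrain_loss_indicator_cases():
    # Zero-head model gives g = 0.5; with y=2, z=3 the indicator is 1 and the
    # pretrain loss is -log(1/2).
    model = make_model(zero_head=True)
    x = np.zeros((1, 2))
    val = float(pretrain_loss(model, x, [2.0], [3.0]))
    assert val == pytest.approx(0.6931, abs=1e-4)


def test_calibrated_g_loss_constant_half():
    """At a calibrated composition the expected g-loss is the mean binary
    entropy of a uniform percentile: int_0^1 -[q ln q + (1-q) ln(1-q)] dq = 1/2.
    """
    exact, _ = integrate.quad(
        lambda q: -(q * np.log(q) + (1 - q) * np.log(1 - q)), 0, 1
    )
    assert exact == pytest.approx(0.5, abs=1e-10)
    rng = np.random.default_rng(8)
    q = rng.uniform(size=100_000)
    mc = binary_cross_entropy((rng.uniform(size=q.size) < q), q).mean()
    assert mc == pytest.approx(0.5, abs=0.01)


def test_fixed_affine_scale_matches_logit_second_moment():
    from collabnet.nn import LOGIT_SECOND_MOMENT_SCALE

    assert LOGIT_SECOND_MOMENT_SCALE**2 == pytest.approx(np.pi**2 / 3, rel=1e-12)
    # Reproduces the printed 3.29 to three significant figures.
    assert round(LOGIT_SECOND_MOMENT_SCALE**2, 2) == 3.29


@pytest.mark.parametrize("a", [0.1, 0.5, 0.9])
def test_cross_entropy_minimized_at_matching_probability(a):
    b = np.linspace(1e-4, 1 - 1e-4, 20_001)
    losses = -(a * np.log(b) + (1 - a) * np.log(1 - b))
    assert b[np.argmin(losses)] == pytest.approx(a, abs=1e-3)


def test_gradient_isolation_between_steps():
    """An f-step must change only f's parameters and a g-step only g's."""
    model = make_model(seed=11)
    rng = np.random.default_rng(12)
    x = rng.normal(size=(16, 2))
    x_std = model.standardize_x(x)
    g_before = [p.copy() for p in model.g_net.params]
    f_before = [p.copy() for p in model.f_net.params]

    _f_step(model, x_std, rng.uniform(size=16), Adam(model.f_net.params))
    assert all(np.array_equal(a, b) for a, b in zip(model.g_net.params, g_before))
    assert any(not np.array_equal(a, b) for a, b in zip(model.f_net.params, f_before))

    f_mid = [p.copy() for p in model.f_net.params]
    _g_step(model, x_std, rng.normal(size=16), rng.normal(size=16),
            Adam(model.g_net.params))
    assert all(np.array_equal(a, b) for a, b in zip(model.f_net.params, f_mid))
    assert any(not np.array_equal(a, b) for a, b in zip(model.g_net.params, g_before))


def test_checkpoint_round_trip(tmp_path):
    model = make_model(seed=13)
    model.norm.running_mean, model.norm.running_var = 0.3, 2.1
    model.norm.fitted = True
    path = tmp_path / "model.ckpt"
    save_checkpoint(model, str(path))
    loaded = load_checkpoint(str(path))
    rng = np.random.default_rng(14)
    x = rng.normal(size=(5, 2))
    z = rng.normal(size=5)
    np.testing.assert_array_equal(g_forward(model, z, x), g_forward(loaded, z, x))
    np.testing.assert_array_equal(
        f_forward(model, 0.3, x), f_forward(loaded, 0.3, x)
    )
    assert loaded.config == model.config
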