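"""Distributional queries: rectification, quantiles, intervals, bins."""

import numpy as np
import pytest
from scipy import stats

from collabnet.config import CNConfig
from collabnet.inference import (
    ConditionalDistribution,
    IntervalEstimate,
    cdf_curve,
    cdf_curves,
    predict_quantiles,
    rectify_cdf,
)
from collabnet.model import CNModel


def normal_curve(grid_span=8.0, n=2001):
    grid = np.linspace(-grid_span, grid_span, n)
    return ConditionalDistribution(grid=grid, cdf=stats.norm.cdf(grid))


def test_rectify_running_maximum_example():
    np.testing.assert_allclose(
        rectify_cdf(np.array([0.1, 0.3, 0.25, 0.6])), [0.1, 0.3, 0.3, 0.6]
    )


def test_rectify_clips_endpoints():
    out = rectify_cdf(np.array([-0.2, 0.5, 1.4]), prob_floor=1e-6)
    assert out[0] == pytest.approx(1e-6)
    assert out[-1] == pytest.approx(1 - 1e-6)


def test_rectified_identity_on_monotone_input():
    raw = stats.norm.cdf(np.linspace(-4, 4, 100))
    np.testing.assert_allclose(rectify_cdf(raw, 1e-9), raw, atol=1e-6)


class TestNormalOracleCurve:
    def test_median_and_upper_quantile(self):
        dist = normal_curve()
        assert dist.quantile(0.5) == pytest.approx(0.0, abs=1e-2)
        assert dist.quantile(0.95) == pytest.approx(1.6449, abs=1e-2)

    def test_round_trip(self):
        dist = normal_curve()
        for q in (0.1, 0.35, 0.5, 0.72, 0.9):
            assert dist.cdf_at(dist.quantile(q)) == pytest.approx(q, abs=1e-3)

    def test_central_interval_width(self):
        iv = normal_curve().interval(0.9)
        assert iv.width == pytest.approx(2 * 1.6449, abs=2e-2)
        assert iv.lower == pytest.approx(-iv.upper, abs=2e-2)

    def test_interval_nesting(self):
        dist = normal_curve()
        small, big = dist.interval(0.3), dist.interval(0.9)
        assert big.lower <= small.lower <= small.upper <= big.upper
        assert dist.interval(0.02).width < 0.1

    def test_bin_probabilities_at_unit_edges(self):
        probs = normal_curve().bin_probabilities(np.array([-1.0, 1.0]))
        np.testing.assert_allclose(probs, [0.1587, 0.6827, 0.1587], atol=1e-3)

    def test_quantile_domain_errors(self):
        dist = normal_curve()
        for q in (0.0, 1.0, -1.0):
            with pytest.raises(ValueError):
                dist.quantile(q)


def test_uniform_oracle_decile_bins():
    grid = np.linspace(-0.2, 1.2, 2001)
    dist = ConditionalDistribution(grid=grid, cdf=np.clip(grid, 0, 1))
    probs = dist.bin_probabilities(np.linspace(0.1, 0.9, 9))
    np.testing.assert_allclose(probs, 0.1, atol=1e-3)


def test_bin_probabilities_sum_to_one_and_floor():
    grid = np.linspace(0, 1, 50)
    dist = ConditionalDistribution(grid=grid, cdf=np.linspace(0, 1, 50))
    probs = dist.bin_probabilities(np.array([0.0001, 0.0002, 0.5]),
                                   prob_floor=1e-6)
    assert probs.sum() == pytest.approx(1.0, abs=1e-9)
    assert np.all(probs >= 1e-6 / 2)


def test_unsorted_bin_edges_rejected():
    dist = normal_curve()
    with pytest.raises(ValueError):
        dist.bin_probabilities(np.array([1.0, -1.0]))


def test_interval_estimate_validates_order():
    with pytest.raises(ValueError):
        IntervalEstimate(lower=1.0, upper=0.0, nominal_level=0.5)


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
def test_rectified_curves_monotone_for_random_networks(seed):
    """Monotonicity must hold by construction for arbitrary parameters."""
    cfg = CNConfig(grid_size=257)
    model = CNModel(2, cfg, np.random.default_rng(seed))
    rng = np.random.default_rng(100 + seed)
    model.fit_scaling(rng.normal(size=(30, 2)), rng.normal(size=30))
    _, cdf = cdf_curves(model, rng.normal(size=(8, 2)))
    assert np.all(np.diff(cdf, axis=1) >= 0)
    assert cdf.min() >= cfg.prob_floor and cdf.max() <= 1 - cfg.prob_floor


def test_route_g_and_route_f_medians_agree_after_training(sine_cn, sine_bench):
    """g- and f-route medians agree on >= 90% of test points once the
    composition is learned.

    The attainable agreement is limited by f's inversion error, roughly
    sqrt(f-loss)/density — a few hundredths here — which exceeds the grid
    resolution; the tolerance is the larger of two grid spacings and 5% of
    the outcome spread.
    """
    X = sine_bench.test.features
    med_g = predict_quantiles(sine_cn, X, [0.5], route="g")[:, 0]
    med_f = predict_quantiles(sine_cn, X, [0.5], route="f")[:, 0]
    grid = np.linspace(sine_cn.y_min - sine_cn.explorer_margin,
                       sine_cn.y_max + sine_cn.explorer_margin,
                       sine_cn.config.grid_size)
    spacing = grid[1] - grid[0]
    tol = max(2 * spacing, 0.075 * sine_bench.train.outcomes.std())
    assert np.mean(np.abs(med_g - med_f) <= tol) >= 0.9


def test_quantiles_nondecreasing_in_level_after_training(sine_cn, sine_bench):
    X = sine_bench.test.features[:50]
    qs = np.linspace(0.05, 0.95, 10)
    Qg = predict_quantiles(sine_cn, X, qs, route="g")
    assert np.all(np.diff(Qg, axis=1) >= -1e-9)
    Qf = predict_quantiles(sine_cn, X, qs, route="f")
    # f's monotonicity is empirical, not architectural: allow rare slack.
    assert np.mean(np.diff(Qf, axis=1) >= -1e-6) > 0.95


def test_trained_weibull_model_rejects_negative_outcomes(weibull_cn, weibull_bench):
    """Outcome mass below zero is (nearly) absent for the Weibull fit."""
    X = weibull_bench.test.features[:100]
    dist0 = cdf_curve(weibull_cn, X[0])
    assert dist0.cdf_at(0.0) < 0.05
    _, cdf = cdf_curves(weibull_cn, X)
    grid = np.linspace(weibull_cn.y_min - weibull_cn.explorer_margin,
                       weibull_cn.y_max + weibull_cn.explorer_margin,
                       weibull_cn.config.grid_size)
    at_zero = np.array([np.interp(0.0, grid, row) for row in cdf])
    assert at_zero.mean() < 0.05
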