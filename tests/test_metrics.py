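"""Calibration, coverage, binned log-likelihood, MAE and sharpness."""

import numpy as np
import pytest

from collabnet.metrics import (
    DEFAULT_CALIBRATION_LEVELS,
    BinningScheme,
    calibration_error,
    cdf_values_to_bin_probs,
    coverage_at_90,
    gof,
    mae,
    sharpness_curve,
)


def test_default_levels_are_eight_equally_spaced():
    lv = DEFAULT_CALIBRATION_LEVELS
    assert lv.size == 8
    assert lv[0] == pytest.approx(0.02) and lv[-1] == pytest.approx(0.98)
    np.testing.assert_allclose(np.diff(lv), np.diff(lv)[0])


def test_calibration_zero_when_empirically_exact():
    rng = np.random.default_rng(0)
    y = rng.uniform(size=1000)
    intervals = {}
    for c in DEFAULT_CALIBRATION_LEVELS:
        lo = np.full(y.size, (1 - c) / 2)
        hi = np.full(y.size, (1 + c) / 2)
        # Replace outcomes: coverage of U(0,1) by these bands is exactly c in
        # expectation; to make it exact, use the quantile structure directly.
        intervals[c] = (lo, hi)
    exact_y = np.linspace(0.0005, 0.9995, 1000)
    err = calibration_error(intervals, exact_y)
    assert err == pytest.approx(0.0, abs=0.11)


def test_calibration_single_level_example():
    # 85 of 100 outcomes covered at nominal 0.9 -> 5%.
    y = np.arange(100, dtype=float)
    lo = np.zeros(100)
    hi = np.where(np.arange(100) < 85, 200.0, -1.0)
    assert calibration_error({0.9: (lo, hi)}, y) == pytest.approx(5.0)


def test_calibration_mismatched_lengths_rejected():
    with pytest.raises(ValueError):
        calibration_error({0.5: (np.zeros(3), np.ones(3))}, np.zeros(4))


def test_coverage_at_90_counts_closed_endpoints():
    y = np.array([0.0, 1.0, 2.0, 5.0, -1.0, 0.5, 0.5, 3.0, 1.5, 0.1])
    lo = np.full(10, 0.0)
    hi = np.full(10, 2.0)
    # 7 of 10 fall in [0, 2]; the endpoint values 0.0 and 2.0 count as covered
    assert coverage_at_90(lo, hi, y) == pytest.approx(70.0)
    assert coverage_at_90(np.ones(10) * 10, np.ones(10) * 11, y) == 0.0


class TestBinningScheme:
    def test_edges_anchored_at_5th_95th_percentiles(self):
        y = np.linspace(0.0, 100.0, 10001)
        scheme = BinningScheme.from_outcomes(y)
        assert scheme.edges[0] == pytest.approx(5.0, abs=0.05)
        assert scheme.edges[-1] == pytest.approx(95.0, abs=0.05)
        np.testing.assert_allclose(np.diff(scheme.edges),
                                   np.diff(scheme.edges)[0])
        assert scheme.n_bins == 10

    def test_rejects_bad_edges(self):
        with pytest.raises(ValueError):
            BinningScheme(edges=np.arange(5))
        with pytest.raises(ValueError):
            BinningScheme(edges=np.zeros(9))

    def test_assignment_right_closed(self):
        scheme = BinningScheme(edges=np.arange(1.0, 10.0))
        assert scheme.assign(np.array([0.5]))[0] == 0
        assert scheme.assign(np.array([1.0]))[0] == 0
        assert scheme.assign(np.array([1.5]))[0] == 1
        assert scheme.assign(np.array([100.0]))[0] == 9


def test_gof_trivial_cases():
    scheme = BinningScheme(edges=np.arange(1.0, 10.0))
    y = np.array([0.5, 3.5, 8.0])
    certain = np.zeros((3, 10))
    certain[np.arange(3), scheme.assign(y)] = 1.0
    assert gof(certain, y, scheme) == pytest.approx(0.0)
    uniform = np.full((3, 10), 0.1)
    assert gof(uniform, y, scheme) == pytest.approx(-2.3026, abs=1e-4)


def test_gof_decreases_when_mass_moves_to_wrong_bins():
    scheme = BinningScheme(edges=np.arange(1.0, 10.0))
    rng = np.random.default_rng(1)
    y = rng.uniform(0, 10, 50)
    probs = np.full((50, 10), 0.02)
    probs[np.arange(50), scheme.assign(y)] = 0.82
    base = gof(probs, y, scheme)
    worse = probs.copy()
    realized = scheme.assign(y)
    worse[np.arange(50), realized] -= 0.3
    worse[np.arange(50), (realized + 1) % 10] += 0.3
    assert gof(worse, y, scheme) < base


def test_gof_requires_positive_realized_probability():
    scheme = BinningScheme(edges=np.arange(1.0, 10.0))
    probs = np.zeros((1, 10))
    probs[0, 1] = 1.0
    with pytest.raises(ValueError):
        gof(probs, np.array([0.0]), scheme)  # realized bin 0 has mass 0


def test_cdf_values_to_bin_probs_floors_and_renormalizes():
    F = np.array([[0.0, 0.0, 0.5, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0]])
    probs = cdf_values_to_bin_probs(F, prob_floor=1e-6)
    assert probs.shape == (1, 10)
    assert probs.sum() == pytest.approx(1.0, abs=1e-12)
    assert probs.min() >= 1e-6 / 2


def test_mae_examples():
    assert mae([1.0, 2.0], [1.0, 2.0]) == 0.0
    assert mae(np.arange(5) + 0.5, np.arange(5)) == pytest.approx(0.5)
    with pytest.raises(ValueError):
        mae([], [])
    with pytest.raises(ValueError):
        mae([1.0], [1.0, 2.0])


def test_metrics_invariant_to_sample_ordering():
    rng = np.random.default_rng(2)
    y = rng.normal(size=200)
    lo, hi = y - rng.uniform(0.5, 1.5, 200), y + rng.uniform(0.2, 2.0, 200)
    perm = rng.permutation(200)
    assert coverage_at_90(lo, hi, y) == coverage_at_90(lo[perm], hi[perm], y[perm])
    scheme = BinningScheme.from_outcomes(y)
    probs = rng.dirichlet(np.ones(10), size=200)
    assert gof(probs, y, scheme) == pytest.approx(gof(probs[perm], y[perm], scheme))
    assert mae(lo, y) == pytest.approx(mae(lo[perm], y[perm]))


def test_sharpness_curve_shapes_and_monotone_widths():
    rng = np.random.default_rng(3)
    y = rng.normal(size=500)

    def interval_fn(c):
        from scipy import stats
        half = stats.norm.ppf((1 + c) / 2)
        return np.full(500, -half), np.full(500, half)

    curve = sharpness_curve(interval_fn, y, [0.3, 0.6, 0.9])
    cov, widths = zip(*curve)
    assert list(cov) == sorted(cov)
    assert list(widths) == sorted(widths)
    # Nominal 0.9 on a standard normal: width 2 * 1.6449.
    assert widths[-1] == pytest.approx(3.290, abs=1e-3)
    assert cov[-1] == pytest.approx(0.9, abs=0.05)


def test_sharpness_degenerate_point_mass_predictor():
    y = np.zeros(10)
    curve = sharpness_curve(lambda c: (y, y), y, [0.2, 0.8])
    assert all(w == 0.0 for _, w in curve)
    assert all(c == 1.0 for c, _ in curve)  # point mass sits on the outcome
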