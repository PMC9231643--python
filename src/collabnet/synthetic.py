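"""Synthetic benchmarks with closed-form ground-truth conditional
distributions.

Three generators are provided, each returning a :class:`LabeledDataset`
whose ``oracle`` attribute exposes the exact conditional CDF, quantile
function and median of the generating process (the theoretically optimal —
"TH" — reference against which fitted models are judged):

* a heteroskedastic Gaussian: ``y ~ N(mu, sigma^2)`` with ``mu ~ N(0, 4)``
  (variance 4) and ``sigma ~ Uniform(0.5, 2.5)``, covariates ``[mu, sigma]``;
* a Weibull with per-sample scale ``lambda ~ Uniform(0.5, 2)`` and shape
  ``k ~ Uniform(1, 5)``, covariates ``[lambda, k]`` — an asymmetric,
  nonnegative, survival-style outcome;
* a 1-d sine study: equally spaced ``x`` on [-0.5, 0.5] with
  ``y | x ~ N(sin(4 pi x), (0.5 + 0.3 sin(4 pi x))^2)`` — two full periods
  of a trigonometric mean with sympathetic heteroskedastic noise.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from scipy import stats

from .data import LabeledDataset

__all__ = [
    "GroundTruthOracle",
    "GaussianHetOracle",
    "WeibullOracle",
    "SineOracle",
    "gen_gaussian_het",
    "gen_weibull",
    "gen_sine_1d",
    "oracle_metrics",
]


class GroundTruthOracle:
    """Closed-form conditional distribution of a synthetic generator.

    All methods are vectorized over rows of ``x`` (shape ``(n, p)``);
    ``z``/``q``/``t`` may be scalars or length-n arrays.
    """

    def cdf(self, z, x) -> np.ndarray:
        raise NotImplementedError

    def quantile(self, q, x) -> np.ndarray:
        raise NotImplementedError

    def median(self, x) -> np.ndarray:
        return self.quantile(0.5, x)

    def survival_beyond(self, t, x) -> np.ndarray:
        return 1.0 - self.cdf(t, x)

    def central_interval(self, level, x):
        """Exact equal-tail interval ``[q_{(1-c)/2}, q_{(1+c)/2}]``."""
        lo = (1.0 - level) / 2.0
        return self.quantile(lo, x), self.quantile(1.0 - lo, x)


class GaussianHetOracle(GroundTruthOracle):
    """Normal(mu, sigma^2) family with ``x = [mu, sigma]``."""

    def _params(self, x):
        x = np.atleast_2d(np.asarray(x, dtype=float))
        return x[:, 0], x[:, 1]

    def cdf(self, z, x):
        mu, sigma = self._params(x)
        return stats.norm.cdf(z, loc=mu, scale=sigma)

    def quantile(self, q, x):
        mu, sigma = self._params(x)
        return stats.norm.ppf(q, loc=mu, scale=sigma)


class WeibullOracle(GroundTruthOracle):
    """Weibull family, CDF ``1 - exp(-(z/lambda)^k)``, ``x = [lambda, k]``."""

    def _params(self, x):
        x = np.atleast_2d(np.asarray(x, dtype=float))
        return x[:, 0], x[:, 1]

    def cdf(self, z, x):
        lam, k = self._params(x)
        z = np.asarray(z, dtype=float)
        out = np.zeros(np.broadcast_shapes(z.shape, lam.shape))
        zb = np.broadcast_to(z, out.shape)
        lamb = np.broadcast_to(lam, out.shape)
        kb = np.broadcast_to(k, out.shape)
        pos = zb > 0
        out[pos] = -np.expm1(-((zb[pos] / lamb[pos]) ** kb[pos]))
        return out

    def quantile(self, q, x):
        lam, k = self._params(x)
        q = np.asarray(q, dtype=float)
        return lam * (-np.log1p(-q)) ** (1.0 / k)


class SineOracle(GroundTruthOracle):
    """Normal with mean ``sin(4 pi x)`` and sd ``0.5 + 0.3 sin(4 pi x)``."""

    @staticmethod
    def mean_sd(x):
        x = np.atleast_2d(np.asarray(x, dtype=float))[:, 0]
        s = np.sin(4.0 * np.pi * x)
        return s, 0.5 + 0.3 * s

    def cdf(self, z, x):
        mean, sd = self.mean_sd(x)
        return stats.norm.cdf(z, loc=mean, scale=sd)

    def quantile(self, q, x):
        mean, sd = self.mean_sd(x)
        return stats.norm.ppf(q, loc=mean, scale=sd)


def gen_gaussian_het(n: int, seed: int) -> LabeledDataset:
    """Heteroskedastic Gaussian benchmark (location and scale both vary)."""
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = np.random.default_rng(seed)
    mu = rng.normal(0.0, 2.0, size=n)  # N(0, 4): variance 4
    sigma = rng.uniform(0.5, 2.5, size=n)
    y = rng.normal(mu, sigma)
    return LabeledDataset(
        features=np.column_stack([mu, sigma]),
        outcomes=y,
        true_median=mu.copy(),
        oracle=GaussianHetOracle(),
        feature_names=["mu", "sigma"],
    )


def gen_weibull(n: int, seed: int) -> LabeledDataset:
    """Weibull benchmark (scale and shape both vary; nonnegative outcomes)."""
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = np.random.default_rng(seed)
    lam = rng.uniform(0.5, 2.0, size=n)
    k = rng.uniform(1.0, 5.0, size=n)
    y = lam * rng.weibull(k, size=n)
    return LabeledDataset(
        features=np.column_stack([lam, k]),
        outcomes=y,
        true_median=lam * np.log(2.0) ** (1.0 / k),
        oracle=WeibullOracle(),
        feature_names=["lambda", "k"],
    )


def gen_sine_1d(n: int, seed: int = 0) -> LabeledDataset:
    """1-d sine study on a deterministic, equally spaced covariate grid."""
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = np.random.default_rng(seed)
    x = np.linspace(-0.5, 0.5, n)
    mean = np.sin(4.0 * np.pi * x)
    sd = 0.5 + 0.3 * mean
    y = rng.normal(mean, sd)
    return LabeledDataset(
        features=x[:, None],
        outcomes=y,
        true_median=mean,
        oracle=SineOracle(),
        feature_names=["x"],
    )


def oracle_metrics(
    oracle: GroundTruthOracle,
    features: np.ndarray,
    outcomes: np.ndarray,
    scheme=None,
    levels: Optional[np.ndarray] = None,
):
    """Evaluate the ground-truth (TH) reference through the metrics module.

    Intervals come from the exact conditional quantiles and bin
    probabilities from the exact CDF; MAE is omitted because the true
    medians are themselves the MAE reference.
    """
    from . import metrics as M

    outcomes = np.asarray(outcomes, dtype=float).ravel()
    if scheme is None:
        scheme = M.BinningScheme.from_outcomes(outcomes)
    if levels is None:
        levels = M.DEFAULT_CALIBRATION_LEVELS
    intervals = {c: oracle.central_interval(c, features) for c in levels}
    cal = M.calibration_error(intervals, outcomes)
    lo90, hi90 = oracle.central_interval(0.9, features)
    cov90 = M.coverage_at_90(lo90, hi90, outcomes)
    cdf_at = np.stack(
        [oracle.cdf(np.full(outcomes.shape, a), features) for a in scheme.edges],
        axis=1,
    )
    probs = M.cdf_values_to_bin_probs(cdf_at)
    gof_val = M.gof(probs, outcomes, scheme)
    curve = M.sharpness_curve(
        lambda c: oracle.central_interval(c, features), outcomes
    )
    return M.MetricsReport(
        cal=cal, coverage90=cov90, gof=gof_val, mae=float("nan"),
        sharpness_curve=curve,
    )
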