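"""Distributional queries on a trained model.

The g-network gives, for a fixed query point x, a raw CDF estimate at any
outcome value z.  For interval and quantile queries the curve is
materialized on a dense outcome grid spanning the explorer range
``[y_min - K, y_max + K]``, repaired to be non-decreasing by a running
maximum (the raw network output is not architecturally monotone), and
clipped away from {0,1}.  Quantiles are then read off by linear
interpolation, which is exact up to grid resolution and monotone by
construction.

Two routes are exposed, mirroring the two networks:

* route ``"g"`` (preferred): invert the rectified CDF curve from g;
* route ``"f"``: evaluate the quantile network directly; its CDF is
  obtained by inverting f on a dense percentile grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np

from .metrics import BinningScheme, cdf_values_to_bin_probs
from .model import CNModel, f_forward

__all__ = [
    "ConditionalDistribution",
    "IntervalEstimate",
    "rectify_cdf",
    "cdf_curve",
    "cdf_curves",
    "quantile",
    "predict_quantiles",
    "central_interval",
    "predict_intervals",
    "bin_probabilities",
    "predict_bin_probs",
]

# Percentile range the f-route is queried on; outcome distributions are
# treated as bounded within these quantiles.
F_ROUTE_Q_GRID = np.linspace(0.001, 0.999, 999)


def rectify_cdf(raw: np.ndarray, prob_floor: float = 1e-6) -> np.ndarray:
    """Monotone repair by running maximum along the last axis, then clip to
    ``[prob_floor, 1 - prob_floor]``."""
    rect = np.maximum.accumulate(np.asarray(raw, dtype=float), axis=-1)
    return np.clip(rect, prob_floor, 1.0 - prob_floor)


@dataclass
class IntervalEstimate:
    lower: float
    upper: float
    nominal_level: float

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValueError("interval lower bound exceeds upper bound")

    @property
    def width(self) -> float:
        return self.upper - self.lower


@dataclass
class ConditionalDistribution:
    """A per-query monotone CDF on an ascending outcome grid."""

    grid: np.ndarray
    cdf: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float).ravel()
        self.cdf = np.asarray(self.cdf, dtype=float).ravel()
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        if np.any(np.diff(self.cdf) < 0) or self.cdf.min() < 0 or self.cdf.max() > 1:
            raise ValueError("cdf must be non-decreasing within [0,1]")

    def quantile(self, q: float) -> float:
        if not 0.0 < q < 1.0:
            raise ValueError("q must lie strictly in (0,1)")
        return float(_grid_quantile(self.grid, self.cdf[None, :], np.array([q]))[0, 0])

    def median(self) -> float:
        return self.quantile(0.5)

    def interval(self, level: float) -> IntervalEstimate:
        if not 0.0 < level < 1.0:
            raise ValueError("level must lie strictly in (0,1)")
        lo = (1.0 - level) / 2.0
        return IntervalEstimate(self.quantile(lo), self.quantile(1.0 - lo), level)

    def cdf_at(self, z: float) -> float:
        return float(np.interp(z, self.grid, self.cdf))

    def bin_probabilities(self, bin_edges: np.ndarray, prob_floor: float = 1e-6
                          ) -> np.ndarray:
        edges = np.asarray(bin_edges, dtype=float).ravel()
        if np.any(np.diff(edges) <= 0):
            raise ValueError("bin edges must be strictly ascending")
        F = np.interp(edges, self.grid, self.cdf)[None, :]
        return cdf_values_to_bin_probs(F, prob_floor)[0]


def _grid_quantile(grid: np.ndarray, cdf: np.ndarray, qs: np.ndarray) -> np.ndarray:
    """Vectorized inverse of monotone curves: leftmost crossing with linear
    interpolation.  ``cdf`` has shape (n, grid); returns (n, len(qs))."""
    n, m = cdf.shape
    out = np.empty((n, qs.size))
    for j, q in enumerate(qs):
        # First index where cdf >= q.
        idx = np.argmax(cdf >= q, axis=1)
        below = cdf[np.arange(n), np.maximum(idx - 1, 0)]
        above = cdf[np.arange(n), idx]
        frac = np.where(above > below, (q - below) / np.where(above > below, above - below, 1.0), 0.0)
        frac = np.clip(frac, 0.0, 1.0)
        lo_z = grid[np.maximum(idx - 1, 0)]
        hi_z = grid[idx]
        val = lo_z + frac * (hi_z - lo_z)
        # q below the whole curve -> left grid end; above -> right end.
        val = np.where(cdf[:, 0] >= q, grid[0], val)
        val = np.where(cdf[:, -1] < q, grid[-1], val)
        out[:, j] = val
    return out


def _outcome_grid(model: CNModel) -> np.ndarray:
    k = model.explorer_margin
    return np.linspace(model.y_min - k, model.y_max + k, model.config.grid_size)


def cdf_curves(model: CNModel, X: np.ndarray, route: str = "g"
               ) -> Tuple[np.ndarray, np.ndarray]:
    """Rectified CDF curves for every row of ``X``.

    Returns ``(grid, cdf)`` with ``cdf`` of shape ``(n, grid_size)``.
    Route ``"f"`` builds the curve by evaluating the quantile network on a
    dense percentile grid and inverting.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    grid = _outcome_grid(model)
    floor = model.config.prob_floor
    if route == "g":
        x_std = model.standardize_x(X)
        zz = np.tile(grid, n)
        xx = np.repeat(x_std, grid.size, axis=0)
        p, _, _ = model.g_forward_full(zz, xx, train=False)
        return grid, rectify_cdf(p.reshape(n, grid.size), floor)
    if route == "f":
        qs = F_ROUTE_Q_GRID
        qq = np.tile(qs, n)
        xx = np.repeat(model.standardize_x(X), qs.size, axis=0)
        z, _ = model.f_forward_full(qq, xx)
        z = np.maximum.accumulate(z.reshape(n, qs.size), axis=-1)
        cdf = np.empty((n, grid.size))
        for i in range(n):
            cdf[i] = np.interp(grid, z[i], qs, left=qs[0], right=qs[-1])
        return grid, rectify_cdf(cdf, floor)
    raise ValueError("route must be 'g' or 'f'")


def cdf_curve(model: CNModel, x: np.ndarray, route: str = "g") -> ConditionalDistribution:
    """CDF curve for a single query point."""
    grid, cdf = cdf_curves(model, np.atleast_2d(x), route)
    return ConditionalDistribution(grid=grid, cdf=cdf[0])


def predict_quantiles(model: CNModel, X: np.ndarray, qs: Sequence[float],
                      route: str = "g") -> np.ndarray:
    """Per-row conditional quantiles at levels ``qs``; shape (n, len(qs))."""
    qs = np.asarray(qs, dtype=float).ravel()
    if np.any((qs <= 0) | (qs >= 1)):
        raise ValueError("quantile levels must lie strictly in (0,1)")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if route == "f":
        out = np.empty((X.shape[0], qs.size))
        for j, q in enumerate(qs):
            out[:, j] = f_forward(model, q, X)
        return out
    grid, cdf = cdf_curves(model, X, route="g")
    return _grid_quantile(grid, cdf, qs)


def quantile(model: CNModel, x: np.ndarray, q: float, route: str = "g") -> float:
    """Conditional quantile at a single level for a single query point."""
    return float(predict_quantiles(model, np.atleast_2d(x), [q], route)[0, 0])


def predict_intervals(model: CNModel, X: np.ndarray, level: float,
                      route: str = "g") -> Tuple[np.ndarray, np.ndarray]:
    """Equal-tail central intervals at nominal coverage ``level``."""
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie strictly in (0,1)")
    lo = (1.0 - level) / 2.0
    q = predict_quantiles(model, X, [lo, 1.0 - lo], route)
    return q[:, 0], q[:, 1]


def central_interval(model: CNModel, x: np.ndarray, level: float,
                     route: str = "g") -> IntervalEstimate:
    lo, hi = predict_intervals(model, np.atleast_2d(x), level, route)
    return IntervalEstimate(float(lo[0]), float(hi[0]), level)


def predict_bin_probs(model: CNModel, X: np.ndarray, scheme: BinningScheme,
                      route: str = "g") -> np.ndarray:
    """Per-row probabilities of the 10 gof bins (floored, renormalized)."""
    grid, cdf = cdf_curves(model, X, route)
    F = np.empty((cdf.shape[0], scheme.edges.size))
    for i in range(cdf.shape[0]):
        F[i] = np.interp(scheme.edges, grid, cdf[i])
    return cdf_values_to_bin_probs(F, model.config.prob_floor)


def bin_probabilities(model: CNModel, x: np.ndarray, bin_edges: np.ndarray,
                      route: str = "g") -> np.ndarray:
    """Bin probabilities for one query point over arbitrary ascending edges."""
    return cdf_curve(model, x, route).bin_probabilities(
        bin_edges, model.config.prob_floor
    )
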