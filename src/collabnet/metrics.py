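"""Evaluation criteria for conditional-distribution estimates.

Four metrics are implemented:

* **calibration error** — the mean absolute gap between nominal central
  interval levels and their empirical coverage, over 8 equally spaced
  levels from 0.02 to 0.98, reported in percent;
* **90% coverage** — the empirical coverage of nominal 90% equal-tail
  intervals, in percent;
* **gof** — a discretized predictive log-likelihood: the mean natural-log
  probability assigned to the bin containing each realized outcome, using
  10 bins anchored at the 5th/95th empirical outcome percentiles with
  equally spaced interior edges;
* **MAE** — mean absolute error of the predicted conditional medians
  against a reference (the true medians on synthetic benchmarks).

A sharpness curve (empirical coverage vs. median interval width across
nominal levels) complements the scalar metrics: at matched coverage, a
lower curve means sharper — more informative — intervals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_CALIBRATION_LEVELS",
    "DEFAULT_SHARPNESS_LEVELS",
    "DEFAULT_PROB_FLOOR",
    "BinningScheme",
    "MetricsReport",
    "calibration_error",
    "coverage_at_90",
    "gof",
    "mae",
    "sharpness_curve",
    "cdf_values_to_bin_probs",
]

# 8 equally spaced nominal levels with endpoints 0.02 and 0.98.
DEFAULT_CALIBRATION_LEVELS = 0.02 + 0.96 * np.arange(8) / 7.0
DEFAULT_SHARPNESS_LEVELS = np.linspace(0.05, 0.95, 19)
DEFAULT_PROB_FLOOR = 1e-6


@dataclass
class BinningScheme:
    """10-bin outcome discretization for the gof metric.

    ``edges`` holds the 9 interior boundaries a_1 < ... < a_9; the outer
    bins extend to -inf and +inf.  a_1 and a_9 are the 5th and 95th
    empirical percentiles of the anchoring outcomes, interior edges equally
    spaced between them.
    """

    edges: np.ndarray

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float).ravel()
        if self.edges.size != 9 or np.any(np.diff(self.edges) <= 0):
            raise ValueError("need 9 strictly ascending bin edges")

    @property
    def n_bins(self) -> int:
        return self.edges.size + 1

    @classmethod
    def from_outcomes(cls, outcomes: np.ndarray) -> "BinningScheme":
        y = np.asarray(outcomes, dtype=float).ravel()
        a1, a9 = np.percentile(y, [5.0, 95.0])
        return cls(edges=np.linspace(a1, a9, 9))

    def assign(self, outcomes: np.ndarray) -> np.ndarray:
        """Bin index (0..9) of each outcome; right-closed interior edges."""
        return np.searchsorted(self.edges, np.asarray(outcomes, dtype=float),
                               side="left")


@dataclass
class MetricsReport:
    """The four scalar criteria plus the coverage-vs-width sharpness curve."""

    cal: float
    coverage90: float
    gof: float
    mae: float
    sharpness_curve: List[Tuple[float, float]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "cal_percent": self.cal,
            "coverage90_percent": self.coverage90,
            "gof": self.gof,
            "mae": self.mae,
            "sharpness_curve": [
                {"empirical_coverage": c, "median_width": w}
                for c, w in self.sharpness_curve
            ],
        }

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def to_csv_row(self, **labels) -> pd.DataFrame:
        row = dict(labels)
        row.update(
            cal_percent=self.cal,
            coverage90_percent=self.coverage90,
            gof=self.gof,
            mae=self.mae,
        )
        return pd.DataFrame([row])

    def sharpness_frame(self, **labels) -> pd.DataFrame:
        df = pd.DataFrame(
            self.sharpness_curve, columns=["empirical_coverage", "median_width"]
        )
        for k, v in labels.items():
            df.insert(0, k, v)
        return df


def _coverage(lower: np.ndarray, upper: np.ndarray, outcomes: np.ndarray) -> float:
    lower = np.asarray(lower, dtype=float).ravel()
    upper = np.asarray(upper, dtype=float).ravel()
    y = np.asarray(outcomes, dtype=float).ravel()
    if not (lower.size == upper.size == y.size):
        raise ValueError("interval bounds and outcomes must have equal length")
    # Endpoints count as covered (closed intervals).
    return float(np.mean((y >= lower) & (y <= upper)))


def calibration_error(
    intervals: Dict[float, Tuple[np.ndarray, np.ndarray]],
    outcomes: np.ndarray,
    weights: Optional[Dict[float, float]] = None,
) -> float:
    """Weighted mean absolute nominal-vs-empirical coverage gap, in percent.

    ``intervals`` maps each nominal level q_j to its per-sample (lower,
    upper) bounds.  Unit weights by default.
    """
    if not intervals:
        raise ValueError("need at least one nominal level")
    total = 0.0
    for level, (lo, hi) in intervals.items():
        w = 1.0 if weights is None else float(weights[level])
        total += w * abs(level - _coverage(lo, hi, outcomes))
    return 100.0 * total / len(intervals)


def coverage_at_90(lower, upper, outcomes) -> float:
    """Empirical coverage (percent) of nominal 90% intervals."""
    return 100.0 * _coverage(lower, upper, outcomes)


def cdf_values_to_bin_probs(
    cdf_at_edges: np.ndarray, prob_floor: float = DEFAULT_PROB_FLOOR
) -> np.ndarray:
    """Convert per-sample CDF values at the 9 edges into 10 bin
    probabilities, floored at ``prob_floor`` and renormalized to sum to 1.
    """
    F = np.atleast_2d(np.asarray(cdf_at_edges, dtype=float))
    ones = np.ones((F.shape[0], 1))
    probs = np.diff(np.hstack([np.zeros_like(ones), F, ones]), axis=1)
    probs = np.maximum(probs, prob_floor)
    return probs / probs.sum(axis=1, keepdims=True)


def gof(bin_probs: np.ndarray, outcomes: np.ndarray, scheme: BinningScheme) -> float:
    """Mean natural-log probability of each outcome's realized bin."""
    probs = np.atleast_2d(np.asarray(bin_probs, dtype=float))
    y = np.asarray(outcomes, dtype=float).ravel()
    if probs.shape[0] != y.size or probs.shape[1] != scheme.n_bins:
        raise ValueError("bin_probs shape must be (n_samples, n_bins)")
    realized = probs[np.arange(y.size), scheme.assign(y)]
    if np.any(realized <= 0.0):
        raise ValueError("zero probability in a realized bin; apply a prob floor")
    return float(np.log(realized).mean())


def mae(predicted_medians: np.ndarray, reference: np.ndarray) -> float:
    """Mean absolute deviation of median predictions from a reference."""
    pred = np.asarray(predicted_medians, dtype=float).ravel()
    ref = np.asarray(reference, dtype=float).ravel()
    if pred.size == 0 or pred.size != ref.size:
        raise ValueError("predictions and reference must be nonempty, equal length")
    return float(np.mean(np.abs(pred - ref)))


def sharpness_curve(
    interval_fn: Callable[[float], Tuple[np.ndarray, np.ndarray]],
    outcomes: np.ndarray,
    nominal_levels: Sequence[float] = DEFAULT_SHARPNESS_LEVELS,
) -> List[Tuple[float, float]]:
    """(empirical coverage, median interval width) per nominal level.

    ``interval_fn(level)`` must return per-sample (lower, upper) bounds.
    Points are sorted by empirical coverage.
    """
    pts = []
    for level in nominal_levels:
        if not 0.0 < level < 1.0:
            raise ValueError("nominal levels must lie in (0,1)")
        lo, hi = interval_fn(float(level))
        pts.append(
            (_coverage(lo, hi, outcomes), float(np.median(np.asarray(hi) - np.asarray(lo))))
        )
    return sorted(pts)
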