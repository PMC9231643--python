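"""Benchmark experiments: variant-vs-ground-truth tables and sample-size
sweeps on the synthetic generators.

A benchmark run draws a fresh dataset and a fresh 7:3 train/test split per
replication (replication r uses seed ``seed + r`` throughout), trains the
requested variants, and reports the four evaluation metrics per variant as
mean ± sample sd over replications.

Variants
--------
``TH``     exact metrics of the true conditional distribution (no training);
``CN-g``   full joint training, uncertainty read from the g-network;
``CN-f``   the same trained model, uncertainty read from the f-network;
``g-only`` g trained alone against explorer comparison points;
``U-g``    g trained against a fixed uniform comparison distribution;
``T-g``    g trained with f pinned to the true quantile function (an
           infeasible-in-practice upper reference).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .config import CNConfig
from .data import LabeledDataset, train_test_split
from .inference import cdf_curves, _grid_quantile
from .metrics import (
    DEFAULT_CALIBRATION_LEVELS,
    DEFAULT_SHARPNESS_LEVELS,
    BinningScheme,
    MetricsReport,
    calibration_error,
    cdf_values_to_bin_probs,
    coverage_at_90,
    gof,
    mae,
    sharpness_curve,
)
from .model import CNModel
from .synthetic import gen_gaussian_het, gen_sine_1d, gen_weibull, oracle_metrics
from .training import TrainingMode, joint_train

__all__ = [
    "BENCHMARKS",
    "VARIANTS",
    "ExperimentSpec",
    "evaluate_model",
    "train_variant",
    "run_benchmark",
    "run_sample_size_sweep",
    "summarize",
]

BENCHMARKS = {
    "gaussian_het": gen_gaussian_het,
    "weibull": gen_weibull,
    "sine_1d": gen_sine_1d,
}

VARIANTS = ("TH", "CN-g", "CN-f", "g-only", "U-g", "T-g")

# The 1-d sine study pins its fixed-uniform comparison distribution to a
# range generously covering the outcome support.
SINE_UNIFORM_BOUNDS = (-2.5, 3.5)


@dataclass
class ExperimentSpec:
    """Declarative description of one benchmark experiment."""

    benchmark: str = "gaussian_het"
    variants: Sequence[str] = ("TH", "CN-g")
    replications: int = 10
    n: int = 1000
    test_fraction: float = 0.3
    scale_factor: float = 1.0
    seed: int = 0
    config: CNConfig = field(default_factory=CNConfig)

    def __post_init__(self) -> None:
        if self.benchmark not in BENCHMARKS:
            raise ValueError(f"unknown benchmark {self.benchmark!r}")
        unknown = set(self.variants) - set(VARIANTS)
        if unknown:
            raise ValueError(f"unknown variants: {sorted(unknown)}")
        if not self.variants:
            raise ValueError("variants must be non-empty")
        if self.replications < 1:
            raise ValueError("replications must be >= 1")

    @classmethod
    def from_yaml(cls, path: str) -> "ExperimentSpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        config = CNConfig.from_dict(raw.pop("config", {}) or {})
        return cls(config=config, **raw)

    def scaled_config(self, seed: int) -> CNConfig:
        cfg = self.config.replace(seed=seed)
        if self.scale_factor < 1.0:
            cfg = cfg.scaled(self.scale_factor)
        return cfg


def evaluate_model(
    model: CNModel,
    test: LabeledDataset,
    scheme: BinningScheme,
    route: str = "g",
    levels: np.ndarray = DEFAULT_CALIBRATION_LEVELS,
) -> MetricsReport:
    """All four metrics plus the sharpness curve from one CDF-curve pass."""
    grid, cdf = cdf_curves(model, test.features, route=route)
    all_levels = np.unique(
        np.concatenate([levels, DEFAULT_SHARPNESS_LEVELS, [0.9]])
    )
    tail = np.concatenate([(1 - all_levels) / 2, (1 + all_levels) / 2, [0.5]])
    qs = np.unique(tail)
    Z = _grid_quantile(grid, cdf, qs)
    col = {q: j for j, q in enumerate(qs)}

    def interval(c: float) -> Tuple[np.ndarray, np.ndarray]:
        return Z[:, col[(1 - c) / 2]], Z[:, col[(1 + c) / 2]]

    cal = calibration_error({c: interval(c) for c in levels}, test.outcomes)
    cov90 = coverage_at_90(*interval(0.9), test.outcomes)
    F = np.stack([np.interp(scheme.edges, grid, row) for row in cdf])
    gof_val = gof(cdf_values_to_bin_probs(F, model.config.prob_floor),
                  test.outcomes, scheme)
    reference = test.true_median if test.true_median is not None else test.outcomes
    mae_val = mae(Z[:, col[0.5]], reference)
    curve = sharpness_curve(interval, test.outcomes, DEFAULT_SHARPNESS_LEVELS)
    return MetricsReport(cal=cal, coverage90=cov90, gof=gof_val, mae=mae_val,
                         sharpness_curve=curve)


def _training_mode(variant: str, benchmark: str) -> TrainingMode:
    if variant in ("CN-g", "CN-f"):
        return TrainingMode("joint")
    if variant == "g-only":
        return TrainingMode("g_only")
    if variant == "U-g":
        bounds = SINE_UNIFORM_BOUNDS if benchmark == "sine_1d" else None
        return TrainingMode("fixed_f_uniform", uniform_bounds=bounds)
    if variant == "T-g":
        return TrainingMode("fixed_f_oracle")
    raise ValueError(f"variant {variant!r} requires no training mode")


def train_variant(
    variant: str, train: LabeledDataset, config: CNConfig, benchmark: str
) -> CNModel:
    return joint_train(train, config, _training_mode(variant, benchmark))


def run_benchmark(spec: ExperimentSpec) -> pd.DataFrame:
    """Per-variant, per-replication metrics table (tidy, one row each)."""
    gen = BENCHMARKS[spec.benchmark]
    rows = []
    for rep in range(spec.replications):
        rep_seed = spec.seed + rep
        try:
            dataset = gen(spec.n, seed=rep_seed)
            split_rng = np.random.default_rng(
                np.random.SeedSequence([rep_seed, 7])
            )
            train, test = train_test_split(dataset, split_rng, spec.test_fraction)
            scheme = BinningScheme.from_outcomes(dataset.outcomes)
            cfg = spec.scaled_config(rep_seed)
            trained: Dict[str, CNModel] = {}
            for variant in spec.variants:
                if variant == "TH":
                    report = oracle_metrics(
                        dataset.oracle, test.features, test.outcomes, scheme
                    )
                else:
                    key = "joint" if variant in ("CN-g", "CN-f") else variant
                    if key not in trained:
                        trained[key] = train_variant(
                            variant, train, cfg, spec.benchmark
                        )
                    route = "f" if variant == "CN-f" else "g"
                    report = evaluate_model(trained[key], test, scheme, route)
                rows.append(
                    dict(variant=variant, replication=rep, seed=rep_seed,
                         **{k: v for k, v in report.to_dict().items()
                            if k != "sharpness_curve"})
                )
        except Exception as err:  # pragma: no cover - diagnostic path
            raise RuntimeError(
                f"replication {rep} (seed {rep_seed}) failed: {err}"
            ) from err
    return pd.DataFrame(rows)


def summarize(results: pd.DataFrame) -> pd.DataFrame:
    """Mean ± sample sd (ddof=1) per variant over replications."""
    metrics = ["cal_percent", "gof", "coverage90_percent", "mae"]
    out = results.groupby("variant")[metrics].agg(["mean", "std"])
    out.columns = [f"{m}_{s}" for m, s in out.columns]
    return out.reset_index()


def run_sample_size_sweep(
    benchmark: str,
    variants: Sequence[str],
    n_grid: Sequence[int],
    reps: int,
    seed: int,
    config: Optional[CNConfig] = None,
    test_fraction: float = 0.3,
) -> pd.DataFrame:
    """Held-out gof per variant across training-set sizes.

    Larger samples should move every consistent variant's gof toward the
    TH reference from below; variants with a better space-searching f get
    there at smaller n.
    """
    if list(n_grid) != sorted(n_grid):
        raise ValueError("n_grid must be ascending")
    config = config or CNConfig()
    gen = BENCHMARKS[benchmark]
    rows = []
    for n in n_grid:
        for rep in range(reps):
            rep_seed = seed + rep
            dataset = gen(n, seed=rep_seed)
            split_rng = np.random.default_rng(np.random.SeedSequence([rep_seed, 7]))
            train, test = train_test_split(dataset, split_rng, test_fraction)
            scheme = BinningScheme.from_outcomes(dataset.outcomes)
            trained: Dict[str, CNModel] = {}
            for variant in variants:
                if variant == "TH":
                    report = oracle_metrics(
                        dataset.oracle, test.features, test.outcomes, scheme
                    )
                else:
                    key = "joint" if variant in ("CN-g", "CN-f") else variant
                    if key not in trained:
                        trained[key] = train_variant(
                            variant, train, config.replace(seed=rep_seed), benchmark
                        )
                    route = "f" if variant == "CN-f" else "g"
                    report = evaluate_model(trained[key], test, scheme, route)
                rows.append(dict(variant=variant, n=n, replication=rep,
                                 gof=report.gof))
    return pd.DataFrame(rows)
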