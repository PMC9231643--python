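"""Model and training configuration."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import yaml

__all__ = ["CNConfig"]


@dataclass
class CNConfig:
    """Hyper-parameters of the collaborating-networks model and its training.

    Attributes
    ----------
    g_hidden_sizes, f_hidden_sizes
        Hidden-layer widths of the CDF network g (two hidden layers by
        default) and of the quantile network f (three by default).
    activation
        Hidden-layer nonlinearity; one of ``elu``, ``tanh``, ``relu``.
    pretrain_iters, joint_iters
        Number of pre-training iterations for g (uniform space-searching
        comparison points) and of alternating joint f/g iterations.
    batch_size
        Mini-batch size for both phases.
    explorer_margin
        Margin K (outcome units) extending the explorer distribution
        U(min(y) - K, max(y) + K) beyond the observed outcome range.
        ``None`` selects half the observed outcome range.
    quantile_dist
        Distribution of the percentile draws q: ``"uniform"`` for
        Uniform(0,1) or ``"beta"`` with :attr:`quantile_beta` parameters
        (tail-weighted sampling hook).
    learning_rate_g, learning_rate_f
        Adam step sizes for the two networks.
    grid_size
        Number of outcome-grid points used when a CDF curve is materialized
        for quantile/interval queries.
    prob_floor
        Minimum probability assigned to any bin when computing binned
        log-likelihoods; protects against -inf from a confident but
        slightly misplaced CDF.
    ema_decay
        Decay of the exponential moving average kept over both networks'
        parameters during the joint phase; evaluation uses the averaged
        parameters, which smooths out the wander of constant-step
        stochastic updates.  0 disables averaging.
    explorer_mix
        Fraction of each joint-phase g-batch whose comparison points are
        drawn from the explorer distribution instead of from f.  Keeps the
        comparison distribution supported on the whole outcome range even
        if f momentarily concentrates, so g never forgets the CDF away
        from f's support.  The moment constraint is still computed on the
        f-derived subset only.  0 disables mixing.
    seed
        Root seed; data splitting, batching, percentile/explorer draws and
        weight initialization all derive independent streams from it.
    """

    g_hidden_sizes: List[int] = field(default_factory=lambda: [64, 64])
    f_hidden_sizes: List[int] = field(default_factory=lambda: [64, 64, 64])
    activation: str = "elu"
    pretrain_iters: int = 20_000
    joint_iters: int = 20_000
    batch_size: int = 128
    explorer_margin: Optional[float] = None
    quantile_dist: str = "uniform"
    quantile_beta: Tuple[float, float] = (0.5, 0.5)
    learning_rate_g: float = 5e-4
    learning_rate_f: float = 5e-4
    grid_size: int = 1024
    prob_floor: float = 1e-6
    standardize_features: bool = True
    ema_decay: float = 0.999
    explorer_mix: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("pretrain_iters", "joint_iters", "batch_size", "grid_size"):
            if int(getattr(self, name)) <= 0:
                raise ValueError(f"{name} must be positive")
        if not all(int(h) > 0 for h in self.g_hidden_sizes + self.f_hidden_sizes):
            raise ValueError("hidden sizes must be positive")
        if not 0.0 < self.prob_floor <= 1e-3:
            raise ValueError("prob_floor must lie in (0, 1e-3]")
        if self.explorer_margin is not None and self.explorer_margin < 0:
            raise ValueError("explorer_margin must be nonnegative")
        if self.quantile_dist not in ("uniform", "beta"):
            raise ValueError("quantile_dist must be 'uniform' or 'beta'")
        if self.learning_rate_g <= 0 or self.learning_rate_f <= 0:
            raise ValueError("learning rates must be positive")
        if not 0.0 <= self.ema_decay < 1.0:
            raise ValueError("ema_decay must lie in [0, 1)")
        if not 0.0 <= self.explorer_mix < 1.0:
            raise ValueError("explorer_mix must lie in [0, 1)")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CNConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if "quantile_beta" in d:
            d["quantile_beta"] = tuple(d["quantile_beta"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str) -> "CNConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str) -> None:
        d = self.to_dict()
        d["quantile_beta"] = list(d["quantile_beta"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    def replace(self, **kw) -> "CNConfig":
        return dataclasses.replace(self, **kw)

    def scaled(self, factor: float) -> "CNConfig":
        """Return a copy with iteration counts multiplied by ``factor``."""
        if not 0 < factor <= 1:
            raise ValueError("scale factor must be in (0, 1]")
        return self.replace(
            pretrain_iters=max(1, int(round(self.pretrain_iters * factor))),
            joint_iters=max(1, int(round(self.joint_iters * factor))),
        )
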