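"""The two collaborating function approximators and their losses.

The model pairs two networks trained against one another:

* ``g(z, x)`` estimates the conditional CDF ``P(Y < z | X = x)``.  Its raw
  logit passes through a fixed-affine moment normalization (zero shift,
  scale ``sqrt(pi^2/3)``) before the sigmoid, pinning the first two moments
  of the logits to those of ``logit(q)`` for ``q ~ Uniform(0,1)`` — the
  distribution the composed output ``g(f(q,x),x)`` attains at the optimum.
* ``f(q, x)`` estimates the conditional quantile function (inverse CDF).

Each network has its own loss.  The g-loss is a binary cross-entropy
between the event indicator ``1(y < z)`` and ``g(z, x)``, where the
comparison point ``z`` comes from f (or from a fixed explorer distribution
during pre-training).  The f-loss is the squared gap ``(q - g(f(q,x),x))^2``
and vanishes exactly when the composition is the identity on the batch —
the fixed point at which both networks describe the same conditional
distribution.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .config import CNConfig
from .nn import MLP, MomentNorm

__all__ = [
    "CNModel",
    "LossValue",
    "g_forward",
    "f_forward",
    "g_loss",
    "f_loss",
    "pretrain_loss",
    "binary_cross_entropy",
    "save_checkpoint",
    "load_checkpoint",
]

CHECKPOINT_FORMAT_VERSION = 1

# Clamp for pre-sigmoid logits before any log; keeps g's output strictly
# inside (0,1) and every cross-entropy term finite.
LOGIT_CLAMP = 15.0


@dataclass
class LossValue:
    """Scalar loss in nats (cross-entropies) or squared probability units."""

    value: float

    def __float__(self) -> float:
        return float(self.value)


class CNModel:
    """Parameters and state of the paired CDF / quantile networks.

    Besides the two MLPs and the logit moment-normalization state, the model
    records the observed outcome range (``y_min``/``y_max``, which anchors
    the explorer distribution and the inference grid) and the input
    standardization computed on the training split.
    """

    def __init__(self, n_features: int, config: CNConfig, rng: np.random.Generator):
        self.config = config
        self.n_features = int(n_features)
        rng_g, rng_f = rng.spawn(2)
        self.g_net = MLP(
            [n_features + 1, *config.g_hidden_sizes, 1], rng_g, config.activation
        )
        self.f_net = MLP(
            [n_features + 1, *config.f_hidden_sizes, 1], rng_f, config.activation
        )
        self.norm = MomentNorm()
        # Outcome-range metadata; set by fit_scaling().
        self.y_min = 0.0
        self.y_max = 1.0
        self.y_center = 0.0
        self.y_scale = 1.0
        self.x_mean = np.zeros(n_features)
        self.x_std = np.ones(n_features)
        self.fitted = False
        # Per-iteration loss traces, filled by the training loops.
        self.history: dict = {"pretrain": [], "g": [], "f": []}

    # ------------------------------------------------------------------ #
    def fit_scaling(self, features: np.ndarray, outcomes: np.ndarray) -> None:
        """Record outcome range and feature standardization from training data."""
        y = np.asarray(outcomes, dtype=float)
        self.y_min = float(y.min())
        self.y_max = float(y.max())
        self.y_center = float(y.mean())
        # Degenerate (constant) outcomes fall back to unit scale.
        std = float(y.std())
        self.y_scale = std if std > 0 else 1.0
        if self.config.standardize_features:
            x = np.asarray(features, dtype=float)
            self.x_mean = x.mean(axis=0)
            self.x_std = np.maximum(x.std(axis=0), 1e-12)
        self.fitted = True

    @property
    def explorer_margin(self) -> float:
        k = self.config.explorer_margin
        if k is None:
            k = 0.5 * (self.y_max - self.y_min)
            if k == 0.0:  # constant outcomes still need a searchable range
                k = self.y_scale
        return float(k)

    def standardize_x(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        return (x - self.x_mean) / self.x_std

    def standardize_z(self, z: np.ndarray) -> np.ndarray:
        return (np.asarray(z, dtype=float) - self.y_center) / self.y_scale

    # Internal forwards (return caches for backprop) ------------------- #
    def g_forward_full(self, z: np.ndarray, x_std: np.ndarray, train: bool,
                       stats_mask: Optional[np.ndarray] = None,
                       update_running: bool = False):
        inp = np.column_stack([self.standardize_z(z), x_std])
        logits, mlp_cache = self.g_net.forward(inp)
        s, norm_cache = self.norm.forward(
            logits.ravel(), train, stats_mask, update_running
        )
        s = np.clip(s, -LOGIT_CLAMP, LOGIT_CLAMP)
        p = 1.0 / (1.0 + np.exp(-s))
        return p, s, (mlp_cache, norm_cache)

    def f_forward_full(self, q: np.ndarray, x_std: np.ndarray):
        inp = np.column_stack([np.asarray(q, dtype=float), x_std])
        out, cache = self.f_net.forward(inp)
        # f's head is expressed in standardized outcome units; map back.
        return self.y_center + self.y_scale * out.ravel(), cache


# ---------------------------------------------------------------------- #
# Public forward passes


def g_forward(model: CNModel, z, x, train: bool = False) -> np.ndarray:
    """Estimated conditional CDF ``P(Y < z | X = x)``; strictly in (0,1).

    ``z`` may be a scalar or an array broadcastable against the rows of
    ``x``.  In evaluation mode (default) the normalization uses the running
    moments, so the output is deterministic given the parameters.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    z = np.broadcast_to(np.asarray(z, dtype=float).ravel(), (x.shape[0],))
    if not (np.isfinite(z).all() and np.isfinite(x).all()):
        raise ValueError("g_forward requires finite inputs")
    p, _, _ = model.g_forward_full(z, model.standardize_x(x), train)
    return p


def f_forward(model: CNModel, q, x) -> np.ndarray:
    """Estimated conditional quantile ``y`` with ``P(Y < y | X = x) = q``."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    q = np.broadcast_to(np.asarray(q, dtype=float).ravel(), (x.shape[0],))
    if not np.isfinite(x).all():
        raise ValueError("f_forward requires finite inputs")
    if np.any((q <= 0.0) | (q >= 1.0)):
        raise ValueError("quantile level q must lie strictly in (0,1)")
    y, _ = model.f_forward_full(q, model.standardize_x(x))
    return y


# ---------------------------------------------------------------------- #
# Losses (values; the gradient steps live in collabnet.training)


def binary_cross_entropy(indicator: np.ndarray, prob: np.ndarray) -> np.ndarray:
    """Elementwise ``-b log a - (1-b) log(1-a)`` with probabilities clamped
    away from {0,1}."""
    eps = 1.0 / (1.0 + math.exp(LOGIT_CLAMP))
    a = np.clip(np.asarray(prob, dtype=float), eps, 1.0 - eps)
    b = np.asarray(indicator, dtype=float)
    return -(b * np.log(a) + (1.0 - b) * np.log1p(-a))


def g_loss(
    model: CNModel,
    features: np.ndarray,
    outcomes: np.ndarray,
    q_samples: np.ndarray,
    stop_f_gradient: bool = True,
    train: bool = False,
) -> LossValue:
    """Mean cross-entropy of ``1(y < f(q,x))`` against ``g(f(q,x), x)``.

    One percentile draw per sample; f provides the comparison points.  This
    evaluates the loss only — during training the g-step never propagates
    gradients into f (``stop_f_gradient`` records that contract).
    """
    features = np.atleast_2d(features)
    if features.shape[0] == 0:
        raise ValueError("empty batch")
    z = f_forward(model, q_samples, features)
    return pretrain_loss(model, features, outcomes, z, train=train)


def f_loss(
    model: CNModel,
    features: np.ndarray,
    q_samples: np.ndarray,
    freeze_g: bool = True,
    train: bool = False,
) -> LossValue:
    """Mean of ``(q - g(f(q,x),x))^2``; zero iff the composition is the
    identity on the batch."""
    features = np.atleast_2d(features)
    if features.shape[0] == 0:
        raise ValueError("empty batch")
    q = np.asarray(q_samples, dtype=float).ravel()
    z = f_forward(model, q, features)
    p = g_forward(model, z, features, train=train)
    return LossValue(float(np.mean((q - p) ** 2)))


def pretrain_loss(
    model: CNModel,
    features: np.ndarray,
    outcomes: np.ndarray,
    z_samples: np.ndarray,
    train: bool = False,
) -> LossValue:
    """g-loss with externally supplied comparison points (explorer draws)."""
    features = np.atleast_2d(features)
    if features.shape[0] == 0:
        raise ValueError("empty batch")
    y = np.asarray(outcomes, dtype=float).ravel()
    z = np.asarray(z_samples, dtype=float).ravel()
    p = g_forward(model, z, features, train=train)
    return LossValue(float(binary_cross_entropy((y < z), p).mean()))


# ---------------------------------------------------------------------- #
# Checkpointing


def save_checkpoint(model: CNModel, path: str) -> None:
    """Serialize the full model (both networks, normalization state, outcome
    range, config) to a single versioned JSON file."""
    payload = {
        "format_version": CHECKPOINT_FORMAT_VERSION,
        "config": model.config.to_dict(),
        "n_features": model.n_features,
        "g_params": [p.tolist() for p in model.g_net.params],
        "f_params": [p.tolist() for p in model.f_net.params],
        "norm_state": model.norm.state_dict(),
        "y_min": model.y_min,
        "y_max": model.y_max,
        "y_center": model.y_center,
        "y_scale": model.y_scale,
        "x_mean": model.x_mean.tolist(),
        "x_std": model.x_std.tolist(),
        "fitted": model.fitted,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_checkpoint(path: str) -> CNModel:
    with open(path) as fh:
        payload = json.load(fh)
    version = payload.get("format_version")
    if version != CHECKPOINT_FORMAT_VERSION:
        raise ValueError(f"unsupported checkpoint format version: {version}")
    config = CNConfig.from_dict(payload["config"])
    model = CNModel(payload["n_features"], config, np.random.default_rng(0))
    model.g_net.params = [np.asarray(p, dtype=float) for p in payload["g_params"]]
    model.f_net.params = [np.asarray(p, dtype=float) for p in payload["f_params"]]
    model.norm.load_state_dict(payload["norm_state"])
    model.y_min = float(payload["y_min"])
    model.y_max = float(payload["y_max"])
    model.y_center = float(payload["y_center"])
    model.y_scale = float(payload["y_scale"])
    model.x_mean = np.asarray(payload["x_mean"], dtype=float)
    model.x_std = np.asarray(payload["x_std"], dtype=float)
    model.fitted = bool(payload["fitted"])
    return model
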