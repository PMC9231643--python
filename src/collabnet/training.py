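"""Training loops for the collaborating networks.

The full procedure has two phases:

1. **Pre-training of g.**  Before f exists in any useful form, g is trained
   alone with comparison points drawn from a broad "space-searching"
   explorer distribution ``U(min(y) - K, max(y) + K)``, exposing g to the
   whole relevant outcome range.  This stabilizes g so that f, whose loss is
   routed entirely through g, never faces a collapsed (overconfident)
   partner.
2. **Joint learning.**  Each iteration samples a mini-batch and per-sample
   percentiles ``q ~ p(q)``, takes one gradient step on the f-loss
   ``(q - g(f(q,x),x))^2`` (gradient flows *through* g into f; g's
   parameters are untouched), then one step on the g-loss with comparison
   points ``z = f(q,x)`` treated as constants (no gradient into f).

Fixed-f variants replace the f-derived comparison points during the joint
phase: ``g_only`` keeps the explorer distribution (pre-training continued),
``fixed_f_uniform`` uses a prescribed uniform, and ``fixed_f_oracle`` uses
the ground-truth quantile function of a synthetic benchmark (an infeasible
but informative upper reference).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .config import CNConfig
from .data import LabeledDataset
from .model import CNModel
from .nn import Adam

__all__ = [
    "TrainingMode",
    "sample_explorer",
    "pretrain_g",
    "joint_train",
    "refresh_norm_stats",
    "training_log_frame",
]

_MODES = ("joint", "g_only", "fixed_f_uniform", "fixed_f_oracle")


@dataclass
class TrainingMode:
    """Which comparison-point source drives the g-updates.

    ``uniform_bounds`` applies to ``fixed_f_uniform`` only; ``None`` falls
    back to the explorer range.
    """

    mode: str = "joint"
    uniform_bounds: Optional[Tuple[float, float]] = None

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}")


def sample_explorer(
    y_min: float, y_max: float, K: float, count: int, rng: np.random.Generator
) -> np.ndarray:
    """I.i.d. draws from the space-searching distribution U(y_min-K, y_max+K)."""
    if K < 0:
        raise ValueError("explorer margin K must be nonnegative")
    if y_min > y_max:
        raise ValueError("y_min must not exceed y_max")
    if count < 1:
        raise ValueError("count must be >= 1")
    return rng.uniform(y_min - K, y_max + K, size=count)


def _draw_q(rng: np.random.Generator, n: int, config: CNConfig) -> np.ndarray:
    if config.quantile_dist == "beta":
        a, b = config.quantile_beta
        q = rng.beta(a, b, size=n)
        return np.clip(q, 1e-6, 1.0 - 1e-6)
    return rng.uniform(0.0, 1.0, size=n)


def _init_model(dataset: LabeledDataset, config: CNConfig) -> CNModel:
    rng_init = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    model = CNModel(dataset.p, config, rng_init)
    model.fit_scaling(dataset.features, dataset.outcomes)
    return model


def _check_finite(loss: float, phase: str, iteration: int) -> None:
    if not np.isfinite(loss):
        raise RuntimeError(
            f"non-finite {phase} loss at iteration {iteration}; "
            "check data scaling and learning rates"
        )


def _g_step(model: CNModel, xb_std, yb, zb, adam: Adam, stats_mask=None) -> float:
    """One cross-entropy gradient step on g; returns the batch loss (nats)."""
    if stats_mask is not None and stats_mask.sum() < 2:
        stats_mask = None
    p, s, (mlp_cache, norm_cache) = model.g_forward_full(
        zb, xb_std, train=True, stats_mask=stats_mask
    )
    b = (yb < zb).astype(float)
    ce = np.logaddexp(0.0, s) - b * s
    # The recorded trace is the loss on the f-derived part of the batch
    # (the quantity that plateaus at the binary-entropy constant 0.5 once
    # the composition is calibrated); explorer admixture still contributes
    # to the gradient.
    loss = float(np.mean(ce if stats_mask is None else ce[stats_mask]))
    ds = (p - b) / b.size
    dlogits = model.norm.backward(norm_cache, ds)
    _, grads = model.g_net.backward(mlp_cache, dlogits[:, None])
    adam.step(model.g_net.params, grads)
    return loss

def _f_step(model: CNModel, xb_std, qb, adam: Adam) -> float:
    """One squared-gap step on f; the gradient passes through g but g's
    parameters stay frozen.

    g is evaluated with its evaluation-mode (data-anchored) normalization
    statistics, so f inverts the same curve that inference queries.  Batch
    statistics would leave f's location unidentified: they recenter
    whatever distribution f emits, letting f drift off the outcome support
    while the composition still looks perfect.
    """
    z, f_cache = model.f_forward_full(qb, xb_std)
    p, _, (g_cache, norm_cache) = model.g_forward_full(z, xb_std, train=False)
    resid = p - qb
    loss = float(np.mean(resid**2))
    ds = (2.0 / qb.size) * resid * p * (1.0 - p)
    dlogits = model.norm.backward(norm_cache, ds)
    dinp, _ = model.g_net.backward(g_cache, dlogits[:, None])
    # g's first input column is the standardized comparison point, which is
    # exactly f's raw head output, so the chain rule needs no rescaling.
    _, grads = model.f_net.backward(f_cache, dinp[:, 0][:, None])
    adam.step(model.f_net.params, grads)
    return loss


# Percentile grid for the quantile-quantile anchoring of the logit
# normalization; spans the levels the calibration metrics interrogate.
_ANCHOR_PERCENTILES = np.linspace(0.05, 0.95, 19)


def refresh_norm_stats(model: CNModel, dataset: LabeledDataset) -> None:
    """Re-anchor the evaluation statistics of the logit normalization.

    The moment constraint pins g's normalized logits to the distribution of
    ``logit(q)``, ``q ~ Uniform(0,1)``.  During joint training it is applied
    per batch on comparison points drawn from f — a distribution that moves
    with f itself — and a uniform logit offset is invisible to those
    batch-standardized gradients.  The pair (f, g) can therefore satisfy
    ``g(f(q,x),x) = q`` exactly while both drift from the truth by a common
    monotone-affine transform in logit space.  The observed data supply the
    missing anchor: at the fixed point ``g(Y, X)`` is uniform on (0,1), so
    the raw logits evaluated at the observed ``(y_i, x_i)`` must, after
    standardization, be distributed as ``logit(Uniform)``.  This routine
    sets the evaluation mean and variance by an affine quantile-quantile
    fit: empirical logit quantiles at 19 levels (0.05 … 0.95) are
    least-squares matched to the corresponding ``logit(Uniform)`` quantiles.
    Fitting the whole quantile span — rather than, say, the first two raw
    moments, which the logit distribution's heavy tails would dominate —
    calibrates the curve across all the levels the interval metrics use.
    """
    inp = np.column_stack(
        [model.standardize_z(dataset.outcomes), model.standardize_x(dataset.features)]
    )
    logits = model.g_net(inp).ravel()
    emp = np.quantile(logits, _ANCHOR_PERCENTILES)
    theo = np.log(_ANCHOR_PERCENTILES / (1.0 - _ANCHOR_PERCENTILES)) / model.norm.scale
    slope = float(np.cov(emp, theo)[0, 1] / np.var(theo))
    intercept = float(emp.mean() - slope * theo.mean())
    model.norm.running_mean = intercept
    model.norm.running_var = float(max(slope**2 - model.norm.eps, model.norm.eps))
    model.norm.fitted = True


def _batches(rng: np.random.Generator, n: int, batch_size: int, iters: int):
    for _ in range(iters):
        yield rng.integers(0, n, size=min(batch_size, n))


def pretrain_g(
    dataset: LabeledDataset,
    config: CNConfig,
    model: Optional[CNModel] = None,
    iters: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    adam: Optional[Adam] = None,
) -> CNModel:
    """Train g alone against explorer comparison points (f untouched).

    The loss trace is recorded in ``model.history["pretrain"]``; it
    typically plateaus well before the full iteration budget.
    """
    if model is None:
        model = _init_model(dataset, config)
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    if adam is None:
        adam = Adam(model.g_net.params, lr=config.learning_rate_g)
    iters = config.pretrain_iters if iters is None else iters
    x_std = model.standardize_x(dataset.features)
    y = dataset.outcomes
    k = model.explorer_margin
    for it, idx in enumerate(_batches(rng, dataset.n, config.batch_size, iters)):
        zb = sample_explorer(model.y_min, model.y_max, k, idx.size, rng)
        loss = _g_step(model, x_std[idx], y[idx], zb, adam)
        model.history["pretrain"].append(loss)
        if it % 200 == 0:
            _check_finite(loss, "pre-training", it)
    refresh_norm_stats(model, dataset)
    return model


def joint_train(
    dataset: LabeledDataset,
    config: CNConfig,
    mode: TrainingMode = TrainingMode(),
) -> CNModel:
    """Full training: pre-train g, then run the joint (or fixed-f) phase.

    Per-iteration losses are recorded in ``model.history``; in joint mode
    the g-loss trace settles near 0.5 once f has learned the inverse, since
    a calibrated composition reduces each term to the binary entropy of a
    uniform percentile draw.
    """
    if mode.mode == "fixed_f_oracle" and dataset.oracle is None:
        raise ValueError("fixed_f_oracle requires a dataset with an oracle")
    model = _init_model(dataset, config)
    rng_pre = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    rng_joint = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    adam_g = Adam(model.g_net.params, lr=config.learning_rate_g)
    adam_f = Adam(model.f_net.params, lr=config.learning_rate_f)
    pretrain_g(dataset, config, model=model, rng=rng_pre, adam=adam_g)

    x_std = model.standardize_x(dataset.features)
    y = dataset.outcomes
    k = model.explorer_margin
    if mode.mode == "fixed_f_uniform":
        lo, hi = mode.uniform_bounds or (model.y_min - k, model.y_max + k)
    decay = config.ema_decay
    ema_g = [p.copy() for p in model.g_net.params] if decay > 0 else None
    ema_f = [p.copy() for p in model.f_net.params] if decay > 0 else None
    for it, idx in enumerate(
        _batches(rng_joint, dataset.n, config.batch_size, config.joint_iters)
    ):
        xb, xb_raw, yb = x_std[idx], dataset.features[idx], y[idx]
        stats_mask = None
        if mode.mode == "joint":
            qb = _draw_q(rng_joint, idx.size, config)
            floss = _f_step(model, xb, qb, adam_f)
            model.history["f"].append(floss)
            # Fresh percentiles for the g-step; f's output is a constant here.
            qb = _draw_q(rng_joint, idx.size, config)
            zb, _ = model.f_forward_full(qb, xb)
            if config.explorer_mix > 0:
                # Keep part of the comparison batch on the full outcome
                # range; the moment statistics stay on the f-derived part.
                explore = rng_joint.random(idx.size) < config.explorer_mix
                if explore.any():
                    zb = zb.copy()
                    zb[explore] = sample_explorer(
                        model.y_min, model.y_max, k, int(explore.sum()), rng_joint
                    )
                    stats_mask = ~explore
        elif mode.mode == "g_only":
            zb = sample_explorer(model.y_min, model.y_max, k, idx.size, rng_joint)
        elif mode.mode == "fixed_f_uniform":
            zb = rng_joint.uniform(lo, hi, size=idx.size)
        else:  # fixed_f_oracle
            qb = _draw_q(rng_joint, idx.size, config)
            zb = np.asarray(dataset.oracle.quantile(qb, xb_raw), dtype=float)
        gloss = _g_step(model, xb, yb, zb, adam_g, stats_mask)
        model.history["g"].append(gloss)
        if it % 200 == 0:
            _check_finite(gloss, "joint", it)
            # Keep the evaluation statistics anchored to the data while the
            # joint phase reshapes g; the f-step inverts this curve.
            refresh_norm_stats(model, dataset)
        if decay > 0:
            for e, p in zip(ema_g, model.g_net.params):
                e *= decay
                e += (1.0 - decay) * p
            for e, p in zip(ema_f, model.f_net.params):
                e *= decay
                e += (1.0 - decay) * p
    if decay > 0:
        # Evaluate with the averaged parameters; the averaging window damps
        # the wander of constant-step stochastic updates around the optimum.
        model.g_net.params = ema_g
        model.f_net.params = ema_f
    refresh_norm_stats(model, dataset)
    return model


def training_log_frame(model: CNModel) -> pd.DataFrame:
    """Structured training log (phase, iteration, loss) for CSV export."""
    rows = []
    for phase in ("pretrain", "f", "g"):
        for it, loss in enumerate(model.history.get(phase, [])):
            rows.append({"phase": phase, "iteration": it, "loss": loss})
    return pd.DataFrame(rows, columns=["phase", "iteration", "loss"])
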