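"""Minimal feed-forward network machinery used by the collaborating networks.

The two function approximators in this package are small multilayer
perceptrons (a few thousand parameters each), trained with explicit
forward/backward passes written against numpy.  Keeping the numerics
in-package has one important payoff for this method: the f-step needs the
gradient of the g-network's output with respect to its *input* (the outcome
value produced by f), including the coupling introduced by the
batch-statistics moment normalization, and writing the backward pass by hand
makes that dependency explicit and testable.

Everything here is deterministic given a :class:`numpy.random.Generator`.
"""

from __future__ import annotations

import math
from typing import List, Sequence, Tuple

import numpy as np

__all__ = ["MLP", "Adam", "MomentNorm", "LOGIT_SECOND_MOMENT_SCALE"]

# sqrt(E[(logit q)^2]) for q ~ Uniform(0,1); E[(logit q)^2] = pi^2 / 3.
LOGIT_SECOND_MOMENT_SCALE: float = math.sqrt(math.pi**2 / 3.0)


def _elu(x: np.ndarray) -> np.ndarray:
    return np.where(x > 0.0, x, np.expm1(np.minimum(x, 0.0)))


def _elu_grad(x: np.ndarray, out: np.ndarray) -> np.ndarray:
    # For ELU with alpha=1, d/dx = 1 for x>0 else elu(x)+1.
    return np.where(x > 0.0, 1.0, out + 1.0)


def _tanh(x: np.ndarray) -> np.ndarray:
    return np.tanh(x)


def _tanh_grad(x: np.ndarray, out: np.ndarray) -> np.ndarray:
    return 1.0 - out**2


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def _relu_grad(x: np.ndarray, out: np.ndarray) -> np.ndarray:
    return (x > 0.0).astype(x.dtype)


_ACTIVATIONS = {
    "elu": (_elu, _elu_grad),
    "tanh": (_tanh, _tanh_grad),
    "relu": (_relu, _relu_grad),
}


class MLP:
    """Fully connected network with linear output.

    Parameters are stored as a flat list ``[W0, b0, W1, b1, ...]`` so that
    optimizers can treat them uniformly.  ``backward`` returns both the
    parameter gradients and the gradient with respect to the input batch.
    """

    def __init__(
        self,
        layer_sizes: Sequence[int],
        rng: np.random.Generator,
        activation: str = "elu",
    ) -> None:
        if len(layer_sizes) < 2:
            raise ValueError("need at least an input and an output size")
        if activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {activation!r}")
        self.activation = activation
        self.layer_sizes = list(layer_sizes)
        self.params: List[np.ndarray] = []
        for fan_in, fan_out in zip(layer_sizes[:-1], layer_sizes[1:]):
            # Glorot-uniform keeps pre-activations O(1) at init.
            limit = math.sqrt(6.0 / (fan_in + fan_out))
            self.params.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
            self.params.append(np.zeros(fan_out))

    @property
    def n_layers(self) -> int:
        return len(self.layer_sizes) - 1

    def forward(self, x: np.ndarray) -> Tuple[np.ndarray, list]:
        """Return ``(output, cache)``; cache feeds :meth:`backward`."""
        act, _ = _ACTIVATIONS[self.activation]
        h = np.asarray(x, dtype=float)
        cache = []
        for i in range(self.n_layers):
            w, b = self.params[2 * i], self.params[2 * i + 1]
            pre = h @ w + b
            if i < self.n_layers - 1:
                out = act(pre)
            else:
                out = pre
            cache.append((h, pre, out))
            h = out
        return h, cache

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)[0]

    def backward(
        self, cache: list, dout: np.ndarray
    ) -> Tuple[np.ndarray, List[np.ndarray]]:
        """Backpropagate ``dout`` (dL/doutput); return ``(dx, grads)``."""
        _, act_grad = _ACTIVATIONS[self.activation]
        grads: List[np.ndarray] = [np.empty(0)] * len(self.params)
        delta = np.asarray(dout, dtype=float)
        for i in range(self.n_layers - 1, -1, -1):
            h, pre, out = cache[i]
            if i < self.n_layers - 1:
                delta = delta * act_grad(pre, out)
            w = self.params[2 * i]
            grads[2 * i] = h.T @ delta
            grads[2 * i + 1] = delta.sum(axis=0)
            delta = delta @ w.T
        return delta, grads


class MomentNorm:
    """Fixed-affine moment normalization of the pre-sigmoid logits.

    In training mode the incoming batch of logits is standardized to mean 0
    and unit variance using the *batch* statistics, then rescaled by the
    constant ``sqrt(pi^2/3) ~ 1.814`` (so the second moment matches that of
    logit(q) for q ~ Uniform(0,1)) with zero shift.  Running moments are
    tracked with exponential momentum and used verbatim in evaluation mode.
    Unlike ordinary batch normalization there is nothing learnable here: the
    affine part is pinned to the moments the calibrated model must attain.
    """

    def __init__(self, momentum: float = 0.1, eps: float = 1e-5) -> None:
        self.scale = LOGIT_SECOND_MOMENT_SCALE
        self.momentum = momentum
        self.eps = eps
        self.running_mean = 0.0
        self.running_var = 1.0
        self.fitted = False

    def forward(
        self,
        logits: np.ndarray,
        train: bool,
        stats_mask: "np.ndarray | None" = None,
        update_running: bool = True,
    ) -> Tuple[np.ndarray, tuple]:
        """Normalize a batch of logits.

        ``stats_mask`` (train mode only) restricts the batch statistics to a
        subset of the batch — the moment constraint is defined on the
        composed outputs ``g(f(q,x),x)``, so when a batch mixes f-derived
        and explorer comparison points, only the f-derived subset defines
        the standardization; the remaining elements are normalized with the
        same statistics.
        """
        l = np.asarray(logits, dtype=float)
        if train:
            sel = l if stats_mask is None else l[stats_mask]
            if sel.size < 2:
                raise ValueError("moment normalization needs >= 2 stats samples in train mode")
            mean = float(sel.mean())
            var = float(sel.var())
            inv_std = 1.0 / math.sqrt(var + self.eps)
            xhat = (l - mean) * inv_std
            if update_running:
                self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
                self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
                self.fitted = True
            return self.scale * xhat, (True, xhat, inv_std, stats_mask, sel.size)
        inv_std = 1.0 / math.sqrt(self.running_var + self.eps)
        xhat = (l - self.running_mean) * inv_std
        return self.scale * xhat, (False, None, inv_std, None, l.size)

    def backward(self, cache: tuple, dout: np.ndarray) -> np.ndarray:
        train, xhat, inv_std, stats_mask, m = cache
        dxhat = self.scale * np.asarray(dout, dtype=float)
        if not train:
            return dxhat * inv_std
        if stats_mask is None:
            # Standard batch-norm input gradient (statistics couple samples).
            return (inv_std / m) * (
                m * dxhat - dxhat.sum() - xhat * float((dxhat * xhat).sum())
            )
        # Statistics come from a subset: every output depends on the subset's
        # mean/var, so their gradient terms land only on subset elements.
        dl = dxhat * inv_std
        dmean = -inv_std * dxhat.sum()
        dvar_term = -(inv_std / m) * float((dxhat * xhat).sum())
        dl = dl.copy()
        dl[stats_mask] += (dmean / m) + xhat[stats_mask] * dvar_term
        return dl

    def state_dict(self) -> dict:
        return {
            "running_mean": self.running_mean,
            "running_var": self.running_var,
            "fitted": self.fitted,
            "momentum": self.momentum,
            "eps": self.eps,
        }

    def load_state_dict(self, state: dict) -> None:
        self.running_mean = float(state["running_mean"])
        self.running_var = float(state["running_var"])
        self.fitted = bool(state["fitted"])
        self.momentum = float(state.get("momentum", self.momentum))
        self.eps = float(state.get("eps", self.eps))


class Adam:
    """Adam optimizer over a flat list of parameter arrays."""

    def __init__(
        self,
        params: List[np.ndarray],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]

    def step(self, params: List[np.ndarray], grads: List[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
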