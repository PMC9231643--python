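# Methods

## The estimation problem

Given tabular regression data `(x_i, y_i)` with continuous outcome `Y` and
covariates `X`, the package estimates the full conditional distribution
`P(Y < z | X = x)` — not just a point prediction — so that prediction
intervals at any nominal level can be produced, and so that their nominal
coverage matches the frequency with which they actually contain new
outcomes (calibration) while staying as narrow as the data allow
(sharpness).

## Model

Two multilayer perceptrons are trained with distinct, mutually referential
losses:

* `g_γ(z, x)` — the **CDF network** — outputs `σ(s(z, x))`, an estimate of
  `P(Y < z | X = x)`;
* `f_θ(q, x)` — the **quantile network** — estimates the inverse,
  `y_(q,x)` with `P(Y < y_(q,x) | X = x) = q`.

At the ideal solution the two are exact inverses: `g(f(q,x), x) = q` for
every percentile `q ∈ (0,1)`.  This identity drives both losses:

* **g-loss** (cross-entropy): with per-sample percentiles `q_i ~ p(q)`
  (Uniform(0,1) by default) and comparison points `z_i = f(q_i, x_i)`
  treated as constants,

      ℓ_g = mean_i [ −1(y_i < z_i) log g(z_i, x_i) − 1(y_i ≥ z_i) log(1 − g(z_i, x_i)) ].

  For fixed `(z, x)` the population minimizer of this loss in `g` is the
  true conditional CDF; this holds for *any* comparison-point distribution
  with full support, so f only has to be a serviceable space-searcher, not
  an optimal one.

* **f-loss** (squared composition gap):

      ℓ_f = mean_i (q_i − g(f(q_i, x_i), x_i))²,

  zero exactly when the composition is the identity on the batch.  The
  gradient flows *through* g into f; g's parameters are frozen during this
  step, and no gradient flows into f during the g-step.

An optimal f makes the g-updates sample-efficient: comparison points drawn
as `f(q, x)` with uniform `q` concentrate where the conditional density
lives, in contrast to blind uniform search.

### Moment normalization of the logits

At the optimum the composed output `g(f(q,x),x)` is distributed as
`q ~ Uniform(0,1)`, so its logits are distributed as `logit(q)` — mean 0,
second moment `E[(logit q)²] = π²/3 ≈ 3.29`.  The pre-sigmoid logit of g is
therefore passed through a normalization layer with a *fixed* affine part:
the batch of logits is standardized and rescaled by `√(π²/3)` with zero
shift.  This pins the predicted coverage distribution to the one an
optimally trained model must produce, regularizing training.  A visible
consequence is that the joint-phase g-loss settles near
`∫₀¹ −[q ln q + (1−q) ln(1−q)] dq = 0.5`, the mean binary entropy of a
uniform percentile.

### Training algorithm

1. **Pre-training of g** (default 20 000 iterations, batch 128): comparison
   points are drawn from the explorer distribution
   `U(min(y) − K, max(y) + K)` with margin `K = 0.5 (max(y) − min(y))` by
   default, exposing g to the whole relevant outcome range before f exists
   in any useful form.  This keeps g from ever becoming the collapsed,
   overconfident partner that would starve f of gradient signal.
2. **Joint phase** (default 20 000 iterations): per iteration, sample a
   mini-batch and percentiles, take one Adam step on the f-loss, redraw
   percentiles, and take one Adam step on the g-loss with comparison points
   from f.

Both networks use ELU activations and Adam with learning rate 1e-3 (g: two
hidden layers of 64; f: three of 64).  All randomness — weight
initialization, batching, percentile and explorer draws, train/test
splits — derives from a single root seed through independent
`SeedSequence` streams, so a seed plus a configuration reproduces training
exactly.

### Stabilizers

Three additional stabilizers address failure modes we observed in the
plain alternating scheme; all are on by default and exposed in
`CNConfig`:

* **Explorer admixture in the joint g-step** (`explorer_mix = 0.25`).  If
  every comparison point comes from f, g's training distribution moves with
  f: when f momentarily concentrates, g forgets the CDF away from f's
  support (on the 1-d sine study this collapsed the joint fit entirely
  while g-only training was unaffected).  A 25% fraction of each joint
  g-batch keeps comparison points on the full explorer range.  The theory
  is indifferent to the admixture — any full-support comparison
  distribution leaves g's population optimum unchanged — and the moment
  statistics are still computed on the f-derived subset only, since the
  moment constraint is a statement about composed outputs.
* **Data-anchored evaluation statistics.**  The batch standardization
  annihilates the gradient of a uniform logit shift, so the pair (f, g)
  can drift along a monotone-affine gauge direction in logit space: the
  composition stays perfect while both networks are biased against the
  truth (we observed probability-integral-transform means of 0.57 instead
  of 0.50).  The data pin this gauge down: at the fixed point
  `g(Y, X) ~ Uniform(0,1)`, so the raw logits at the observed `(y_i, x_i)`
  must be distributed as `logit(Uniform)` after standardization — median
  0, interquartile range `2 ln 3`.  The evaluation mean/variance of the
  normalization layer are therefore set by matching the median and IQR of
  those logits (quantile matching rather than raw moments, because the
  logit distribution's heavy tails dominate a sample second moment).
  Re-anchoring runs every 200 joint iterations and at the end of each
  phase; the f-step inverts g under these evaluation statistics — i.e. f
  learns the inverse of the same curve that inference queries — which
  removes the corresponding gauge freedom in f.
* **Parameter averaging** (`ema_decay = 0.999`).  Constant-step stochastic
  updates wander around the optimum instead of settling on it; evaluation
  uses an exponential moving average of both networks' joint-phase
  parameters, which damps that wander at no cost to the training dynamics.

### Training variants

* `joint` — the full scheme above (read out through g: "CN-g", or through
  f: "CN-f").
* `g_only` — the joint phase keeps drawing comparison points from the
  explorer distribution; literally pre-training continued, with f unused.
* `fixed_f_uniform` ("U-g") — comparison points from a prescribed uniform
  (the 1-d sine study uses U(−2.5, 3.5)).
* `fixed_f_oracle` ("T-g") — comparison points are true conditional
  quantiles at uniform percentiles; infeasible in practice but the best
  possible space-searcher, an upper reference for the joint scheme.

## Inference

g is not architecturally monotone in `z`, so the raw CDF curve on a
1024-point grid spanning `[min(y) − K, max(y) + K]` is repaired by a
running maximum — order-preserving, exact whenever the raw curve is
already monotone — and clipped to `[prob_floor, 1 − prob_floor]`
(`prob_floor = 1e-6`).  Quantiles are leftmost crossings with linear
interpolation; the nominal-`c` central interval is
`[quantile((1−c)/2), quantile((1+c)/2)]` (equal tail mass); bin
probabilities are CDF differences floored at `prob_floor` and
renormalized.  The f-route inverts f evaluated on the percentile grid
0.001…0.999; outcome distributions are treated as bounded within those
quantiles.

## Evaluation metrics

* **Calibration error** — mean absolute gap between nominal and empirical
  coverage of central intervals over 8 equally spaced levels from 0.02 to
  0.98, in percent (unit weights; endpoints of an interval count as
  covered).
* **90% coverage** — empirical coverage of the nominal 90% interval, in
  percent.
* **gof** — mean natural-log probability of the realized outcome's bin
  under a 10-bin discretization anchored at the 5th/95th percentiles of
  the full experiment's outcomes (fixed per experiment, identical across
  methods); a discretized predictive log-likelihood, maximized in
  expectation by the true conditional distribution.
* **MAE** — mean absolute error of conditional medians; on synthetic
  benchmarks the reference is the known true median, so MAE measures
  distributional recovery rather than irreducible noise.
* **Sharpness curve** — (empirical coverage, median interval width) pairs
  over a nominal-level grid; at matched coverage, lower is sharper.

## Synthetic benchmarks

* **Heteroskedastic Gaussian** — `μ ~ N(0, 4)` (variance 4),
  `σ ~ U(0.5, 2.5)`, `y ~ N(μ, σ²)`, covariates `[μ, σ]`.  The optimal
  90% interval width is `2 × 1.6449 σ`, so heteroskedasticity recovery is
  directly visible in the interval widths.
* **Weibull** — scale `λ ~ U(0.5, 2)`, shape `k ~ U(1, 5)`,
  `y ~ Weibull(λ, k)` (CDF `1 − exp(−(z/λ)^k)`), covariates `[λ, k]`.
  Asymmetric, nonnegative, survival-style outcomes; true median
  `λ (ln 2)^{1/k}`.
* **1-d sine** — `x` equally spaced on [−0.5, 0.5],
  `y | x ~ N(sin 4πx, (0.5 + 0.3 sin 4πx)²)`: two periods of a
  high-frequency mean with sympathetic heteroskedastic noise.

Each generator carries a closed-form oracle (CDF, quantile, median,
survival) used for the "TH" reference rows, for MAE references, and for
probability-integral-transform checks of the generator itself.  What the
generators deliberately do *not* emulate: covariates that are informative
but not sufficient for the conditional law (here the covariates *are* the
distribution parameters), feature noise, missingness, and heavy-tailed or
multimodal conditional families.  Passing tests on these benchmarks
demonstrates distributional recovery when the conditional family is
learnable from the features, not robustness to misspecified or incomplete
features.

The benchmark protocol draws 1 000 samples, splits 7:3, and repeats with
independent generation and splits (replication `r` uses seed `seed + r`);
tables report mean ± sample sd (ddof = 1).

## Problem sizes used in the shipped checks

The test suite and the acceptance script run a scaled-down protocol —
10 000 + 10 000 iterations, 1–3 replications — which we found on these
benchmarks to match the full protocol's accuracy at n ≤ 1 000 training
samples (constant-step training at n_train = 700 begins to overfit mildly
beyond ~10k joint iterations, and parameter averaging makes the shorter
runs stable).  The ground-truth reference rows always use 10 replications;
they involve no training.

## Numerical choices

* Logits are clamped at ±15 before any sigmoid/log, so probabilities stay
  strictly inside (0,1) and cross-entropies finite.
* The normalization layer guards zero batch variance with ε = 1e-5.
* Feature standardization (training-split mean/sd) is on by default;
  outcomes are standardized internally for network conditioning only —
  all reported quantities are in outcome units.  Constant outcomes fall
  back to unit scale and a unit explorer margin.
* Quantile inversion returns the leftmost grid crossing on ties; queries
  below/above the whole curve return the grid ends.
* Percentile draws from the optional Beta(a, b) hook are clipped to
  [1e-6, 1 − 1e-6].

## Known limitations

* The f-route is weaker in the distribution tails (few tail samples and a
  uniform percentile generator); the g-route is the recommended read-out.
* Monotonicity of f in `q` is empirical, not architectural; the g-route
  is monotone by construction after rectification.
* The grid inversion bounds queries to the explorer range; quantiles
  beyond `[prob_floor, 1 − prob_floor]` of that range saturate.
* Single-output regression only; no early stopping, learning-rate
  schedules, or hyperparameter search.
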