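# Methods

## The model being fitted

The drift-diffusion model (DDM) describes a two-alternative decision as a
one-dimensional accumulation process: a decision variable starts at
`w * a`, drifts at rate `v` under unit-variance Wiener noise, and the
trial ends when it first crosses the upper bound `a` (choice `c = 1`) or
the lower bound `0` (`c = 0`). The observed reaction time is the
first-passage time plus a non-decision latency `tau`, so every simulated
`rt` exceeds `tau`. A second variant lets both bounds collapse linearly
toward the midline at rate `|gamma|` (`gamma <= 0`), which truncates slow
decisions; this variant has no tractable likelihood.

Parameters carry these units and default uniform priors:

| parameter | meaning | unit | prior |
|---|---|---|---|
| `v` | drift rate | evidence/s | U(-2, 2) |
| `a` | boundary separation | evidence | U(0.5, 2) |
| `w` | relative start point | — | U(0.3, 0.7) |
| `tau` | non-decision time | s | U(0.2, 1.8) |
| `gamma` | bound collapse slope | evidence/s | U(-1, 0) |

## Simulator

Trajectories are integrated by Euler–Maruyama with `dt = 1e-4` s
(configurable) and a decision-time cap of 10 s beyond `tau`. Between
grid points the path is treated as a Brownian bridge and absorbed with
the exact crossing probability `exp(-2 d0 d1 / dt)` (`d0, d1` the
distances to the bound at the step's ends — a form that is exact for
linear bounds too). This removes the `O(sqrt(dt))` boundary-overshoot
bias of the naive scheme, which is otherwise clearly detectable by a
1e5-sample KS test against the analytic first-passage density; with the
correction those tests pass across the prior. A non-absorbed trajectory is
re-simulated on a fresh noise stream up to three times and then raises —
silent censoring would bias the trained likelihood. Each trial consumes
its own counter-derived RNG stream, so results are independent of how
trials are batched and a shorter run is a prefix of a longer one with the
same seed.

The collapsing-bound geometry is symmetric: upper bound `a + gamma*t`,
lower bound `-gamma*t`, meeting at `a/2`; a still-undecided trajectory at
the pinch time is forced to the nearer bound and flagged. The noise
coefficient is fixed to 1 (the standard DDM identifiability convention).

## Analytic likelihood

For the constant-bound DDM the joint density of `(c, rt)` is the Wiener
first-passage-time (WFPT) distribution, computed from the classical
series expansions with automatic switching between the small-time and
large-time forms; the number of terms is chosen per evaluation point to
meet a truncation tolerance of `1e-7` on the density (capped at 64
terms). Everything is evaluated in log-space with the dominant
exponential factored out, so log-densities remain finite down to
`rt - tau ~ 1e-3` s. `rt <= tau` yields `-inf` rather than an exception.
The upper-bound density uses the reflection `(v, w) -> (-v, 1-w)`.
`choice_probability` integrates the density by adaptive quadrature (with
the domain split near zero, where the density can spike when `w`
approaches a bound); the closed-form absorption probability of drifted
Brownian motion serves as an independent cross-check in the tests.

## Mixed neural likelihood estimator

The single-trial likelihood factorizes as
`q(rt, c | theta) = q(c | theta) * q(rt | c, theta)`:

- **Choice model** — a small feed-forward network (2 x 32 hidden units,
  ReLU) maps z-scored `theta` to a Bernoulli logit. Trained by the mean
  negative Bernoulli log-likelihood.
- **Reaction-time flow** — a conditional normalizing flow over
  `y = (log rt - m) / s` (`m, s` fixed from the training set), with a
  standard normal base. The conditioning network (2 x 64 hidden units,
  ReLU; inputs z-scored `theta` and the choice encoded as ±1) emits the
  parameters of (i) a conditional affine layer (shift and log-scale,
  clipped to ±5) and (ii) two monotone rational-quadratic spline
  transforms with 16 bins on `[-5, 5]` and identity tails. The affine
  layer removes the strongly `theta`-dependent location/scale of
  `log rt` (dominated by `tau`), so the splines only shape a
  standardized residual — without it the fit plateaus well short of the
  accuracy needed for posterior work. The support of the learned density
  is `rt > 0`, deliberately not `rt > tau`.

The training proposal need not be the prior — any distribution covering
its support is valid — and by default the workflows here use the prior
box padded by 10% of each side's width (`PriorSpec.expand(0.1)`, clipped
at hard physical limits such as `tau > 0`). Conditional density
estimates are biased near the boundary of the conditioning
distribution; padding moves the prior's edges into the interior, which
measurably improves the estimator exactly where prior-sampled
evaluation parameters land.

Both components are trained separately on the same `(theta, x)` pairs
(one simulation per proposal draw) with Adam (lr 5e-4, halved after 5
stagnant validation epochs), minibatches of 128, a 90/10
train/validation split, gradient-norm clipping at 5, and early stopping
after 25 epochs without validation improvement; the best-validation
weights are restored. Parameters are z-scored under the proposal
(uniform prior moments, not data moments, so the scaling is exact and
deterministic).

The flow's training loss is importance-weighted by the inverse predicted
choice probability (capped at 25), which balances the two
choice-conditionals per parameter region: without this, parameter
regions where one choice is rare contribute almost nothing to that
conditional's fit, and the emulator's minority-choice reaction-time
distributions are visibly wrong. Weighted conditional maximum likelihood
remains consistent for the conditional density because the weights
depend only on the conditioning variables `(theta, c)`.

The networks and the rational-quadratic splines are implemented on a
small reverse-mode automatic-differentiation core (`mnle.nn.autograd`)
written for this package; its gradients are validated against finite
differences in the test suite, and the spline code has an exact
quadratic-solve inverse used for sampling. Density evaluation and
sampling bypass the tape through a NumPy fast path that exploits the
MCMC access pattern: for a batch of `n` trials times `m` parameters the
conditioning network runs on only the `2m` distinct `(theta, c)`
contexts.

## Posterior sampling

The posterior over `theta` given an i.i.d. trial table multiplies
single-trial likelihoods with the prior. Sampling operates in an
unconstrained space via an affine-then-logit map of the prior box with
exact log-Jacobian (round-trip identity and Jacobian correctness are
property-tested). Chains start from sequential importance resampling
(prior proposals weighted by likelihood; default 1e4 proposals) and
advance by axis-wise slice sampling with stepping out (unit initial
width, at most 20 expansions split randomly between the sides). All
chains step in lock-step so each potential evaluation is one batched
(trials x chains) likelihood call. Defaults: 10 chains, 500 burn-in
sweeps, thinning 10, 1000 pooled draws; every comparison between the
analytic and learned backends uses identical MCMC settings. Ensembles
pool equal draw counts from several independently initialized
estimators, tagged by member.

## Diagnostics

- **Likelihood metrics** — Huber loss (delta = 1, the conventional
  default) and MSE between estimated and analytic likelihoods and
  log-likelihoods; each observation is one simulated trial, compared
  across fresh prior draws. Likelihoods are floored at `1e-7` before the
  log-scale metrics so prior draws with `tau > rt` (zero analytic
  likelihood) contribute bounded errors.
- **C2ST** — 5-fold cross-validated accuracy of a scikit-learn MLP
  classifier (two hidden layers of 10 x dimension units) on z-scored,
  label-balanced samples; 0.5 means indistinguishable. The classifier is
  configurable; only held-out accuracy is contracted.
- **SBC** — ranks of prior-drawn ground truths under their inferred
  posteriors; uniformity is tested per dimension by a KS test of the
  randomized PIT `(rank + U(0,1)) / (L + 1)`, which is exactly uniform
  under calibration for any number of posterior draws `L`.
- **Posterior metrics** — per-dimension and dimension-averaged
  |mean difference| / reference std, |variance difference| / reference
  variance, MSE of the posterior mean against ground truth, and C2ST
  against reference draws.
- **Predictive checks** — choice fractions and rt quantiles of observed
  vs prior-predictive vs posterior-predictive trials simulated from
  resampled parameter draws.

## What the synthetic data does and does not emulate

All training and evaluation data come from the package's own DDM
simulators, matching the generative assumptions of the estimator
exactly: i.i.d. trials, no inter-trial variability in drift or start
point, no stimulus dependence, exact uniform priors. Passing tests
therefore demonstrate that the estimator and inference machinery recover
the data-generating process when the model class is correct; they say
nothing about robustness to model misspecification, contaminant
responses, or lapses that real reaction-time data contain. The Euler
discretization at `dt = 1e-4` is shared between training data and test
oracles, so its (small) first-passage bias cancels in emulator
comparisons but is present relative to the exact analytic density at the
level noted above.

## Problem sizes used by the tests and the acceptance script

Training uses the standard budget of 1e5 simulations (one per proposal
draw) for both DDM variants and 1e4 for the reduced-budget emulator
check. Posterior comparisons use 100-trial observations and lean MCMC
settings shared by both backends (8 chains, 100 burn-in sweeps, 800
pooled draws; for SBC: 3 chains, 120 burn-in, 250 draws, 50 calibration
runs per configuration; the acceptance script reports 10 observations
and 30 SBC runs). These sizes keep the full pipeline on one CPU core at
a practical runtime while leaving the statistical thresholds of each
check unchanged.

## Known limitations

- The learned likelihood's support is `rt > 0` while the true model's is
  `rt > tau`. Near observations that pin `tau` very tightly (small
  boundary separations produce reaction-time distributions with a sharp
  left edge just above `tau`), the learned and analytic posteriors can
  have `tau` marginals that are each only ~0.002 s wide but offset by a
  few of those widths. A classifier two-sample test then separates the
  two posteriors almost perfectly for such observations even though
  posterior means, variances, parameter recovery and calibration all
  agree; the dimension-averaged C2ST reported by the acceptance script
  reflects this. Matching the analytic posterior at that resolution
  would require per-trial density accuracy far beyond what a
  1e5-simulation budget supports.
- Binary choices only; generalizing the discrete head to more categories
  is straightforward but not exercised here.
- No weight sharing between the two components, and no embedding of
  stimulus covariates; both are extension hooks.
- The collapsing-bound geometry (symmetric linear collapse acting on
  each bound) is one of several reasonable parametrizations; results for
  that variant are specific to it.
- Slice sampling is effective for these 4-5 dimensional posteriors but
  is not gradient-based; much higher-dimensional models would want HMC
  or variational alternatives.
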