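# mnle-ddm

Simulation-based Bayesian inference for drift-diffusion models of
decision-making, via **mixed neural likelihood estimation (MNLE)**.

## The problem

The drift-diffusion model (DDM) explains two-alternative decisions as
noisy evidence accumulation: a decision variable starts at a fraction
`w` of the boundary separation `a`, drifts at rate `v`, and the first
bound it hits determines the choice `c ∈ {0, 1}`; the reaction time is
the first-passage time plus a non-decision latency `τ`. Fitting such
models in a Bayesian way requires the per-trial likelihood
`L(c, rt | θ)`, which is tractable only for the simplest variant —
already a mild extension such as linearly collapsing bounds (slope `γ`)
has no usable closed form.

MNLE sidesteps this: it learns the likelihood from simulations. The
mixed (discrete × continuous) single-trial likelihood is factorized as

    q(rt, c | θ) = q_ψc(c | θ) · q_ψrt(rt | c, θ)

where `q_ψc` is a Bernoulli network predicting the choice probability
and `q_ψrt` is a conditional normalizing flow (monotone
rational-quadratic splines over `log rt` with a context-conditioned
affine layer) — both trained by maximum likelihood on `(θ, x)` pairs,
one simulated trial per prior draw. The learned likelihood is exactly
normalized, can be sampled (a trial *emulator*), and plugs into MCMC:

    p(θ | X) ∝ p(θ) · Π_i q(rt_i, c_i | θ)

so one trained estimator serves any number of trials without
retraining. Posteriors are drawn by axis-wise slice sampling in an
unconstrained reparametrization, with chains initialized by sequential
importance resampling. For the simple DDM the analytic Wiener
first-passage-time likelihood is included, both as a reference backend
and as the verification oracle.

## Worked example

```python
from mnle import (PriorSpec, DDMParams, generate_training_set,
                  MixedNeuralLikelihood, infer_posterior, MCMCConfig,
                  simulate_ddm)

prior = PriorSpec.default_ddm()          # v, a, w, tau boxes
proposal = prior.expand(0.1)             # pad the training proposal 10%
theta, trials = generate_training_set(proposal, 100_000, seed=3)
model = MixedNeuralLikelihood(theta, trials, proposal)
estimator = model.fit(seed=0)            # ~3 min on one CPU
print(estimator.summary())

truth = DDMParams(v=1.0, a=1.5, w=0.5, tau=0.3)
observation = simulate_ddm(truth, n_trials=100, seed=5)
posterior = infer_posterior("mnle", estimator, prior, observation,
                            MCMCConfig(n_chains=4, burn_in=200, thin=1,
                                       n_samples=1000), seed=2)
print(posterior.summary())
```

Output for this seed:

```
Mixed neural likelihood estimator
==================================
parameter dimensions: 4 (v, a, w, tau)
trained: True
choice net hidden: (32, 32)
flow: 2 spline transforms, 16 bins, tail bound 5.0
choice: best val loss 0.4632 at epoch 23 (44 epochs run)
rt flow: best val loss -0.2653 at epoch 44 (65 epochs run)

Posterior samples
=================
1000 draws, 4 chains
   param      mean        sd      2.5%       50%     97.5%
       v    0.5451    0.1869    0.1740    0.5432    0.9193
       a    1.3156    0.0577    1.2059    1.3134    1.4381
       w    0.5527    0.0352    0.4755    0.5545    0.6158
     tau    0.3083    0.0119    0.2828    0.3090    0.3294
```

Each row is one DDM parameter; the generating values were v=1.0, a=1.5,
w=0.5, τ=0.3. Drift is the least constrained at 100 trials and
non-decision time the most; the apparent undershoot in `v` and `a` is a
property of this particular observation, not of the learned likelihood —
rerunning the same call with `backend="analytic"` (the exact
first-passage likelihood) gives an almost identical posterior
(v 0.598 ± 0.195, a 1.350 ± 0.066, w 0.546 ± 0.036, τ 0.309 ± 0.013).

The same workflow is available from the shell:

```bash
mnle simulate --model ddm --n 100000 --seed 3 --out-prefix train
mnle train --params-csv train_params.csv --trials-csv train_trials.csv \
           --prior-json train_prior.json --out estimator.npz
mnle infer --observation-csv obs.csv --checkpoint estimator.npz --out post.csv
mnle diagnose --config diagnostics.yaml --out-dir reports/
```

## Diagnostics

`mnle.diagnostics` implements the full evaluation battery: Huber/MSE
accuracy of the learned likelihood against the analytic one, classifier
two-sample tests (C2ST) between posterior sample sets, simulation-based
calibration (SBC) rank uniformity, normalized posterior mean/variance
discrepancies, parameter-recovery error, and posterior-predictive
checks.

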