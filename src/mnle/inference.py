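"""Posterior sampling with slice-sampling MCMC.

The posterior over DDM parameters given an i.i.d. trial table X is

    p(theta | X)  ∝  prod_i q(rt_i, c_i | theta) * p(theta),

where ``q`` is either the analytic first-passage likelihood (reference,
simple DDM only) or a trained mixed neural likelihood estimator.  Sampling
operates in an unconstrained space obtained by an affine-then-logit map of
the prior box onto R^d; the potential includes the log-Jacobian of the
inverse map.  Chains are initialized by sequential importance resampling
from the prior and advanced with axis-wise slice sampling with stepping
out.  All chains are updated in lock-step so the likelihood backend sees
batched (trials x parameters) evaluations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .estimator import MixedLikelihoodEstimator
from .simulators import PriorSpec
from .wfpt import wfpt_log_density_batch

__all__ = [
    "ParameterTransform",
    "PosteriorSamples",
    "MCMCConfig",
    "joint_potential",
    "init_chains_sis",
    "slice_sample",
    "infer_posterior",
    "ensemble_posterior",
]


class ParameterTransform:
    """Invertible map between the prior box and R^d (affine then logit)."""

    def __init__(self, prior: PriorSpec):
        self.low = prior.low
        self.high = prior.high
        self.width = prior.high - prior.low

    def to_unconstrained(self, theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(np.asarray(theta, float))
        p = np.clip((theta - self.low) / self.width, 1e-12, 1 - 1e-12)
        return np.log(p) - np.log1p(-p)

    def to_constrained(self, u: np.ndarray) -> np.ndarray:
        u = np.atleast_2d(np.asarray(u, float))
        s = 1.0 / (1.0 + np.exp(-u))
        return self.low + self.width * s

    def log_abs_det_jacobian(self, u: np.ndarray) -> np.ndarray:
        """log |d theta / d u| summed over dimensions, per row."""
        u = np.atleast_2d(np.asarray(u, float))
        # d theta/du = width * sigmoid(u) * (1 - sigmoid(u))
        log_sig = -np.logaddexp(0.0, -u)
        log_1msig = -np.logaddexp(0.0, u)
        return np.sum(np.log(self.width) + log_sig + log_1msig, axis=-1)


@dataclass
class MCMCConfig:
    """Slice-sampling settings shared by all likelihood backends."""

    n_chains: int = 10
    burn_in: int = 500
    thin: int = 10
    n_samples: int = 1000  # pooled retained draws
    slice_width: float = 1.0
    max_step_out: int = 20
    sis_proposals: int = 10_000


@dataclass
class PosteriorSamples:
    """Posterior draws with chain provenance.

    ``draws`` has shape (n_draws, n_params); ``chain`` gives the chain id
    of each pooled draw.
    """

    draws: np.ndarray
    chain: np.ndarray
    param_names: list[str]
    metadata: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return self.draws.shape[0]

    def mean(self) -> np.ndarray:
        return self.draws.mean(axis=0)

    def var(self, ddof: int = 1) -> np.ndarray:
        return self.draws.var(axis=0, ddof=ddof)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.draws, columns=self.param_names)
        df.insert(0, "draw", np.arange(self.n_draws))
        df.insert(0, "chain", self.chain)
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False, float_format="%.17g")
        side = Path(path).with_suffix(".meta.json")
        side.write_text(json.dumps(self.metadata, indent=2, default=str))

    @classmethod
    def from_csv(cls, path: str | Path) -> "PosteriorSamples":
        df = pd.read_csv(path)
        names = [c for c in df.columns if c not in ("chain", "draw")]
        side = Path(path).with_suffix(".meta.json")
        meta = json.loads(side.read_text()) if side.exists() else {}
        return cls(df[names].to_numpy(float), df["chain"].to_numpy(int), names, meta)

    def summary(self) -> str:
        lines = ["Posterior samples", "=" * 17,
                 f"{self.n_draws} draws, {len(np.unique(self.chain))} chains"]
        mu, sd = self.mean(), np.sqrt(self.var())
        q = np.quantile(self.draws, [0.025, 0.5, 0.975], axis=0)
        lines.append(f"{'param':>8} {'mean':>9} {'sd':>9} {'2.5%':>9} "
                     f"{'50%':>9} {'97.5%':>9}")
        for i, name in enumerate(self.param_names):
            lines.append(f"{name:>8} {mu[i]:9.4f} {sd[i]:9.4f} {q[0, i]:9.4f} "
                         f"{q[1, i]:9.4f} {q[2, i]:9.4f}")
        return "\n".join(lines)


def joint_potential(
    loglik_backend: str,
    estimator: MixedLikelihoodEstimator | None,
    prior: PriorSpec,
    trials: pd.DataFrame,
) -> Callable[[np.ndarray], np.ndarray]:
    """Unnormalized log-posterior over unconstrained parameters.

    Returns a callable that accepts a (m, d) batch of unconstrained points
    and returns a length-m array of log-densities: the summed per-trial
    log-likelihood plus log-prior plus the transform's log-Jacobian;
    ``-inf`` outside the prior support.
    """
    if len(trials) == 0:
        raise ValueError("trial table must be nonempty")
    if loglik_backend not in ("analytic", "mnle"):
        raise ValueError(f"unknown likelihood backend {loglik_backend!r}")
    if loglik_backend == "mnle":
        if estimator is None or not estimator.trained:
            raise RuntimeError("mnle backend requires a trained estimator")
    transform = ParameterTransform(prior)
    rts = trials["rt"].to_numpy(float)
    choices = trials["choice"].to_numpy(float)

    def potential(u: np.ndarray) -> np.ndarray:
        u = np.atleast_2d(np.asarray(u, float))
        theta = transform.to_constrained(u)
        logp = prior.log_prob(theta) + transform.log_abs_det_jacobian(u)
        finite = np.isfinite(logp)
        if np.any(finite):
            if loglik_backend == "analytic":
                ll = wfpt_log_density_batch(rts, choices, theta[finite])
            else:
                z = estimator.choice_model.logits(theta[finite])[:, 0]
                lp_c = choices[:, None] * z[None, :] \
                    - np.logaddexp(0.0, z)[None, :]
                ll = lp_c + estimator.rt_flow.log_prob_grid(rts, choices,
                                                            theta[finite])
            logp[finite] += ll.sum(axis=0)
        return logp

    potential.transform = transform  # type: ignore[attr-defined]
    return potential


def init_chains_sis(
    potential: Callable[[np.ndarray], np.ndarray],
    prior: PriorSpec,
    n_chains: int,
    n_proposals: int,
    seed: int,
    transform: ParameterTransform | None = None,
) -> np.ndarray:
    """Sequential-importance-resampling chain initialization.

    Draws ``n_proposals`` prior points, weights them by the likelihood
    (potential minus the prior-plus-Jacobian part, which is the prior's
    own density in unconstrained space) and resamples ``n_chains`` starts.
    """
    if n_proposals < n_chains:
        raise ValueError("n_proposals must be >= n_chains")
    rng = np.random.default_rng(seed)
    transform = transform or getattr(potential, "transform", None) or ParameterTransform(prior)
    theta = prior.sample(n_proposals, rng)
    u = transform.to_unconstrained(theta)
    logpost = potential(u)
    # proposal density in u-space = prior(theta) * |dtheta/du|^{-1}... the
    # potential already contains prior + Jacobian, so the importance weight
    # reduces to the likelihood factor:
    logw = logpost - (prior.log_prob(theta) + transform.log_abs_det_jacobian(u))
    ok = np.isfinite(logw)
    if not np.any(ok):
        raise RuntimeError(
            "all SIS proposal weights are zero or non-finite; "
            "increase n_proposals or check the observation"
        )
    logw = logw - np.max(logw[ok])
    w = np.where(ok, np.exp(logw), 0.0)
    w = w / w.sum()
    idx = rng.choice(n_proposals, size=n_chains, replace=True, p=w)
    starts = u[idx]
    if not np.all(np.isfinite(potential(starts))):
        raise RuntimeError("SIS produced a start with non-finite potential")
    return starts


def slice_sample(
    potential: Callable[[np.ndarray], np.ndarray],
    starts: np.ndarray,
    n_samples: int,
    burn_in: int,
    thin: int = 1,
    seed: int = 0,
    slice_width: float = 1.0,
    max_step_out: int = 20,
    param_names: Sequence[str] | None = None,
    transform: ParameterTransform | None = None,
) -> PosteriorSamples:
    """Axis-wise slice sampling with stepping out, chains in lock-step.

    ``n_samples`` is the total number of pooled draws across chains (each
    chain contributes ``ceil(n_samples / n_chains)``).  The returned draws
    are in the constrained (model) space when ``transform`` is given,
    otherwise in the sampling space.
    """
    starts = np.atleast_2d(np.asarray(starts, float))
    n_chains, d = starts.shape
    logp = potential(starts)
    if not np.all(np.isfinite(logp)):
        raise ValueError("all chain starts must have finite potential")
    rng = np.random.default_rng(seed)
    per_chain = int(np.ceil(n_samples / n_chains))
    n_sweeps = burn_in + per_chain * thin
    x = starts.copy()
    kept = np.empty((per_chain, n_chains, d))
    k = 0

    for sweep in range(n_sweeps):
        for dim in range(d):
            x0 = x[:, dim].copy()
            logy = logp + np.log(rng.uniform(size=n_chains))
            # stepping out
            u0 = rng.uniform(size=n_chains)
            left = x0 - slice_width * u0
            right = left + slice_width
            jmax = rng.integers(0, max_step_out + 1, size=n_chains)
            kmax = max_step_out - jmax

            def eval_at(vals: np.ndarray, active: np.ndarray) -> np.ndarray:
                out = np.full(n_chains, -np.inf)
                if np.any(active):
                    pts = x[active].copy()
                    pts[:, dim] = vals[active]
                    out[active] = potential(pts)
                return out

            active = eval_at(left, np.ones(n_chains, bool)) > logy
            steps = np.zeros(n_chains)
            while np.any(active & (steps < jmax)):
                go = active & (steps < jmax)
                left[go] -= slice_width
                steps[go] += 1
                active = go & (eval_at(left, go) > logy)
            active = eval_at(right, np.ones(n_chains, bool)) > logy
            steps = np.zeros(n_chains)
            while np.any(active & (steps < kmax)):
                go = active & (steps < kmax)
                right[go] += slice_width
                steps[go] += 1
                active = go & (eval_at(right, go) > logy)

            # shrinkage
            pending = np.ones(n_chains, bool)
            newx = x0.copy()
            newlogp = logp.copy()
            guard = 0
            while np.any(pending):
                guard += 1
                if guard > 1000:
                    raise RuntimeError(
                        f"slice shrinkage failed to terminate at state {x[pending][0]}"
                    )
                prop = np.where(pending,
                                left + rng.uniform(size=n_chains) * (right - left),
                                newx)
                lp_prop = eval_at(prop, pending)
                accept = pending & (lp_prop > logy)
                newx[accept] = prop[accept]
                newlogp[accept] = lp_prop[accept]
                pending = pending & ~accept
                shrink_left = pending & (prop < x0)
                left[shrink_left] = prop[shrink_left]
                shrink_right = pending & ~(prop < x0)
                right[shrink_right] = prop[shrink_right]
            x[:, dim] = newx
            logp = newlogp
        if sweep >= burn_in and (sweep - burn_in) % thin == 0 and k < per_chain:
            kept[k] = x
            k += 1

    draws_u = kept[:k].reshape(-1, d)
    chain_ids = np.tile(np.arange(n_chains), k)
    draws = transform.to_constrained(draws_u) if transform is not None else draws_u
    # trim to exactly n_samples pooled draws
    if draws.shape[0] > n_samples:
        sel = rng.permutation(draws.shape[0])[:n_samples]
        draws, chain_ids = draws[sel], chain_ids[sel]
    names = list(param_names) if param_names is not None else \
        [f"p{i}" for i in range(d)]
    return PosteriorSamples(draws, chain_ids, names,
                            metadata={"seed": seed, "burn_in": burn_in,
                                      "thin": thin, "n_chains": n_chains})


def infer_posterior(
    backend: str,
    estimator: MixedLikelihoodEstimator | None,
    prior: PriorSpec,
    trials: pd.DataFrame,
    config: MCMCConfig | None = None,
    seed: int = 0,
) -> PosteriorSamples:
    """End-to-end posterior sampling for one observation."""
    config = config or MCMCConfig()
    pot = joint_potential(backend, estimator, prior, trials)
    seeds = np.random.SeedSequence((seed, 17)).generate_state(2)
    starts = init_chains_sis(pot, prior, config.n_chains, config.sis_proposals,
                             int(seeds[0] >> 1))
    samples = slice_sample(
        pot, starts, config.n_samples, config.burn_in, config.thin,
        seed=int(seeds[1] >> 1), slice_width=config.slice_width,
        max_step_out=config.max_step_out, param_names=prior.names,
        transform=pot.transform,
    )
    samples.metadata.update({"backend": backend, "n_trials": int(len(trials))})
    return samples


def ensemble_posterior(
    estimators: Sequence[MixedLikelihoodEstimator],
    prior: PriorSpec,
    trials: pd.DataFrame,
    config: MCMCConfig | None = None,
    seed: int = 0,
) -> PosteriorSamples:
    """Pool equal numbers of posterior draws from several MNLE members.

    Mitigates estimator-initialization variance: each member contributes
    ``n_samples`` draws from its own MCMC run and the pooled set is an
    equally weighted mixture, tagged by member index.
    """
    if len(estimators) < 2:
        raise ValueError("ensemble requires at least two trained estimators")
    config = config or MCMCConfig()
    pooled, chains, members = [], [], []
    for i, est in enumerate(estimators):
        try:
            ps = infer_posterior("mnle", est, prior, trials, config,
                                 seed=int(np.random.SeedSequence((seed, i)).generate_state(1)[0] >> 1))
        except Exception as err:
            raise RuntimeError(f"ensemble member {i} failed: {err}") from err
        pooled.append(ps.draws)
        chains.append(ps.chain + i * config.n_chains)
        members.append(np.full(ps.n_draws, i))
    out = PosteriorSamples(np.vstack(pooled), np.concatenate(chains),
                           list(prior.names),
                           metadata={"ensemble_size": len(estimators), "seed": seed})
    out.metadata["member"] = np.concatenate(members).tolist()
    return out
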