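"""Mixed neural likelihood estimation (MNLE).

The likelihood of a decision-making trial ``x = (c, rt)`` given model
parameters ``theta`` factorizes into a discrete and a continuous part,

    q(rt, c | theta) = q(c | theta) * q(rt | c, theta),

and each factor is learned separately from simulated ``(theta, x)`` pairs:
a feed-forward Bernoulli network predicts the choice probability
``rho(theta)``, and a conditional neural spline flow models the density of
``log rt`` given ``(theta, c)`` with a standard normal base distribution.
Both components are trained by maximum likelihood on the same training
set.  The trained pair is a normalized density in ``rt > 0`` for every
conditioning value, can be evaluated in large (trials x parameters)
batches for MCMC, and can be sampled to emulate the simulator.

The module follows a model/results layout: :class:`MixedNeuralLikelihood`
holds the training data and configuration, and its :meth:`fit` returns a
:class:`MixedLikelihoodEstimator` carrying the trained networks.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .nn.autograd import Tensor, softplus
from .nn.layers import MLP
from .nn.spline import (
    make_spline_params,
    rq_spline_forward,
    rq_spline_forward_numpy,
    rq_spline_inverse,
    spline_params_numpy,
)
from .nn.train import TrainConfig, TrainResult, fit_mle
from .simulators import PriorSpec

__all__ = [
    "ArchitectureConfig",
    "ChoiceModel",
    "RTFlow",
    "MixedNeuralLikelihood",
    "MixedLikelihoodEstimator",
    "train_choice_model",
    "train_rt_flow",
    "mnle_log_prob",
    "mnle_sample",
]


@dataclass(frozen=True)
class ArchitectureConfig:
    """Architecture descriptor for both estimator components.

    The networks are deliberately small: the conditioning space is only
    4-5 dimensional, and small networks keep MCMC evaluation fast.
    """

    choice_hidden: tuple[int, ...] = (32, 32)
    flow_hidden: tuple[int, ...] = (64, 64)
    n_transforms: int = 2
    n_bins: int = 16
    tail_bound: float = 5.0  # on standardized log rt
    activation: str = "relu"
    fourier_features: int = 0  # sin/cos harmonics appended to the context

    def to_dict(self) -> dict:
        d = asdict(self)
        d["choice_hidden"] = list(self.choice_hidden)
        d["flow_hidden"] = list(self.flow_hidden)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ArchitectureConfig":
        return cls(
            choice_hidden=tuple(d["choice_hidden"]),
            flow_hidden=tuple(d["flow_hidden"]),
            n_transforms=int(d["n_transforms"]),
            n_bins=int(d["n_bins"]),
            tail_bound=float(d["tail_bound"]),
            activation=d.get("activation", "relu"),
            fourier_features=int(d.get("fourier_features", 0)),
        )


class _Standardizer:
    """Affine z-scoring of conditioning parameters under the proposal."""

    def __init__(self, mean: np.ndarray, std: np.ndarray):
        self.mean = np.asarray(mean, float)
        self.std = np.asarray(std, float)

    @classmethod
    def from_prior(cls, prior: PriorSpec) -> "_Standardizer":
        return cls(prior.mean, prior.std)

    def __call__(self, theta: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(theta) - self.mean) / self.std


def _fourier_expand(x: np.ndarray, n_harmonics: int) -> np.ndarray:
    """Append sin/cos harmonics of each input column.

    A positional encoding of the (z-scored) conditioning variables; it
    lets a small network express fine-grained dependence on a
    low-dimensional context.
    """
    if n_harmonics <= 0:
        return x
    feats = [x]
    for k in range(1, n_harmonics + 1):
        feats.append(np.sin(k * x))
        feats.append(np.cos(k * x))
    return np.concatenate(feats, axis=1)


class ChoiceModel:
    """Bernoulli choice-probability network rho(theta) = P(c = 1 | theta)."""

    def __init__(self, n_params: int, arch: ArchitectureConfig,
                 standardizer: _Standardizer, seed: int = 0):
        self.n_params = n_params
        self.arch = arch
        self.standardizer = standardizer
        in_dim = n_params * (1 + 2 * arch.fourier_features)
        self.net = MLP(in_dim, arch.choice_hidden, 1,
                       np.random.default_rng(seed), activation=arch.activation)
        self.train_result: TrainResult | None = None

    def _features(self, theta: np.ndarray) -> np.ndarray:
        return _fourier_expand(self.standardizer(theta),
                               self.arch.fourier_features)

    def logits(self, theta: np.ndarray) -> np.ndarray:
        return self.net.forward_numpy(self._features(theta))

    def prob(self, theta: np.ndarray) -> np.ndarray:
        """rho(theta), kept strictly inside (0, 1) by the sigmoid output."""
        z = self.logits(theta)[:, 0]
        return 1.0 / (1.0 + np.exp(-z))

    def log_prob(self, choices: np.ndarray, theta: np.ndarray) -> np.ndarray:
        z = self.logits(theta)[:, 0]
        c = np.asarray(choices, float)
        # log Bernoulli(c; sigmoid(z)) = c*z - softplus(z)
        return c * z - np.logaddexp(0.0, z)

    def fit(self, theta: np.ndarray, choices: np.ndarray,
            config: TrainConfig) -> TrainResult:
        theta = np.atleast_2d(theta)
        c = np.asarray(choices, float).reshape(-1, 1)
        if len(np.unique(c)) < 1 or len(c) != len(theta):
            raise ValueError("choices and parameters must be aligned and nonempty")
        ctx = self._features(theta)

        def loss_fn(idx: np.ndarray) -> Tensor:
            z = self.net(ctx[idx])
            cb = c[idx]
            # mean negative Bernoulli log-likelihood: softplus(z) - c*z
            return (softplus(z) - Tensor(cb) * z).mean()

        self.train_result = fit_mle(
            loss_fn, self.net.parameters, self.net.state_dict,
            self.net.load_state_dict, len(theta), config,
        )
        return self.train_result


class RTFlow:
    """Conditional spline flow over log reaction time, conditioned on (theta, c).

    The reaction time is mapped to ``y = (log rt - m) / s`` with ``m, s``
    fixed from the training data, then through ``n_transforms`` monotone
    rational-quadratic splines whose knots are produced by a conditioning
    network; the base distribution is standard normal.  The density over
    ``rt`` includes the Jacobians of both the affine map and ``log``.
    """

    def __init__(self, n_params: int, arch: ArchitectureConfig,
                 standardizer: _Standardizer, seed: int = 0):
        self.n_params = n_params
        self.arch = arch
        self.standardizer = standardizer
        # head layout: [shift, log_scale] of the conditional affine layer,
        # then 3K-1 spline parameters per transform
        per_transform = 3 * arch.n_bins - 1
        in_dim = n_params * (1 + 2 * arch.fourier_features) + 1
        self.net = MLP(in_dim, arch.flow_hidden,
                       2 + arch.n_transforms * per_transform,
                       np.random.default_rng(seed), activation=arch.activation)
        self.log_rt_mean = 0.0
        self.log_rt_std = 1.0
        self.train_result: TrainResult | None = None

    # -- internal --------------------------------------------------------
    def _context(self, theta: np.ndarray, choices: np.ndarray) -> np.ndarray:
        ctx = _fourier_expand(self.standardizer(theta),
                              self.arch.fourier_features)
        c = np.asarray(choices, float).reshape(-1, 1)
        return np.concatenate([ctx, 2.0 * c - 1.0], axis=1)

    def _forward(self, y: np.ndarray, context: np.ndarray):
        """Transform standardized log-rt to base space; returns Tensors.

        The first layer is a context-conditioned affine map that removes
        the conditional location and scale of log rt, so the splines only
        have to shape a standardized residual.
        """
        raw = self.net(context)
        K = self.arch.n_bins
        per = 3 * K - 1
        h = Tensor(y) if not isinstance(y, Tensor) else y
        shift = raw[:, 0]
        log_scale = raw[:, 1].clip(-5.0, 5.0)
        inv_scale = (-log_scale).exp()
        h = (h - shift) * inv_scale
        total_ld = -log_scale
        for t in range(self.arch.n_transforms):
            params_t = raw[:, 2 + t * per:2 + (t + 1) * per]
            xk, yk, d = make_spline_params(params_t, K, self.arch.tail_bound)
            h, ld = rq_spline_forward(h, xk, yk, d, self.arch.tail_bound)
            total_ld = total_ld + ld
        return h, total_ld

    def _nll(self, y: np.ndarray, context: np.ndarray,
             weights: np.ndarray | None = None) -> Tensor:
        z, ld = self._forward(y, context)
        per_sample = (z * z) * 0.5 - ld
        if weights is None:
            return per_sample.mean() + 0.5 * np.log(2 * np.pi)
        w = weights / weights.sum()
        return (per_sample * w).sum() + 0.5 * np.log(2 * np.pi)

    # -- public ----------------------------------------------------------
    def log_prob(self, rts: np.ndarray, choices: np.ndarray,
                 theta: np.ndarray) -> np.ndarray:
        """Log-density of rt given (theta, c); ``-inf`` for rt <= 0."""
        rts = np.asarray(rts, float)
        out = np.full(rts.shape, -np.inf)
        ok = rts > 0
        if not np.any(ok):
            return out
        theta = np.atleast_2d(np.asarray(theta, float))
        if theta.shape[0] == 1 and rts.shape[0] > 1:
            theta = np.repeat(theta, rts.shape[0], axis=0)
        logrt = np.log(rts[ok])
        y = (logrt - self.log_rt_mean) / self.log_rt_std
        ctx = self._context(theta[ok], np.asarray(choices)[ok])
        raw = self.net.forward_numpy(ctx)
        K = self.arch.n_bins
        per = 3 * K - 1
        shift = raw[:, 0]
        log_scale = np.clip(raw[:, 1], -5.0, 5.0)
        z = (y - shift) * np.exp(-log_scale)
        total_ld = -log_scale.copy()
        for t in range(self.arch.n_transforms):
            knots = spline_params_numpy(raw[:, 2 + t * per:2 + (t + 1) * per],
                                        K, self.arch.tail_bound)
            z, ld = rq_spline_forward_numpy(z, *knots, self.arch.tail_bound)
            total_ld += ld
        logq_y = -0.5 * z**2 - 0.5 * np.log(2 * np.pi) + total_ld
        # y = (log rt - m)/s  =>  log q(rt) = log q(y) - log s - log rt
        out[ok] = logq_y - np.log(self.log_rt_std) - logrt
        return out

    def log_prob_grid(self, rts: np.ndarray, choices: np.ndarray,
                      theta: np.ndarray) -> np.ndarray:
        """Log-density for every (trial, parameter) pair, shape (n, m).

        The conditioning network is evaluated only on the ``2 m`` distinct
        (theta, c) contexts and its spline parameters are then indexed per
        pair, which makes the MCMC access pattern (many trials x many
        parameters) cheap.
        """
        rts = np.asarray(rts, float)
        choices = np.asarray(choices, float)
        theta = np.atleast_2d(np.asarray(theta, float))
        n, m = rts.shape[0], theta.shape[0]
        out = np.full((n, m), -np.inf)
        ok = rts > 0
        if not np.any(ok):
            return out
        # contexts: for each parameter, both choice values (order c=0, c=1)
        feats = _fourier_expand(self.standardizer(theta),
                                self.arch.fourier_features)
        ctx = np.concatenate([
            np.repeat(feats, 2, axis=0),
            np.tile(np.array([[-1.0], [1.0]]), (m, 1)),
        ], axis=1)
        raw = self.net.forward_numpy(ctx)  # (2m, n_out)
        K = self.arch.n_bins
        per = 3 * K - 1
        y = (np.log(rts[ok]) - self.log_rt_mean) / self.log_rt_std
        # row of the context table for pair (trial i, parameter j)
        rows = (2 * np.arange(m)[None, :] + choices[ok, None].astype(int)).ravel()
        shift = raw[:, 0]
        log_scale = np.clip(raw[:, 1], -5.0, 5.0)
        z = (np.tile(y[:, None], (1, m)).ravel() - shift[rows]) \
            * np.exp(-log_scale[rows])
        total_ld = -log_scale[rows]
        for t in range(self.arch.n_transforms):
            xk, yk, d = spline_params_numpy(raw[:, 2 + t * per:2 + (t + 1) * per],
                                            K, self.arch.tail_bound)
            z, ld = rq_spline_forward_numpy(z, xk[rows], yk[rows], d[rows],
                                            self.arch.tail_bound)
            total_ld += ld
        logq_y = -0.5 * z**2 - 0.5 * np.log(2 * np.pi) + total_ld
        vals = logq_y.reshape(-1, m) - np.log(self.log_rt_std) \
            - np.log(rts[ok])[:, None]
        out[ok] = vals
        return out

    def sample(self, theta: np.ndarray, choices: np.ndarray,
               rng: np.random.Generator) -> np.ndarray:
        """Draw rt ~ q(rt | theta, c) by inverting the transforms."""
        ctx = self._context(theta, choices)
        n = ctx.shape[0]
        z = rng.standard_normal(n)
        raw = self.net.forward_numpy(ctx)
        K = self.arch.n_bins
        per = 3 * K - 1
        for t in reversed(range(self.arch.n_transforms)):
            xk, yk, d = spline_params_numpy(raw[:, 2 + t * per:2 + (t + 1) * per],
                                            K, self.arch.tail_bound)
            z = rq_spline_inverse(z, xk, yk, d, self.arch.tail_bound)
        z = z * np.exp(np.clip(raw[:, 1], -5.0, 5.0)) + raw[:, 0]
        logrt = z * self.log_rt_std + self.log_rt_mean
        return np.exp(logrt)

    def fit(self, theta: np.ndarray, trials: pd.DataFrame,
            config: TrainConfig,
            sample_weights: np.ndarray | None = None) -> TrainResult:
        """Weighted maximum-likelihood fit of the conditional flow.

        ``sample_weights`` (optional) rebalance the conditioning
        distribution — e.g. inverse predicted choice probabilities, so
        that the rarer choice's conditional density at each parameter
        region is learned as well as the dominant one.
        """
        theta = np.atleast_2d(theta)
        rts = trials["rt"].to_numpy(float)
        choices = trials["choice"].to_numpy(float)
        if np.any(rts <= 0):
            raise ValueError("reaction times must be positive")
        logrt = np.log(rts)
        self.log_rt_mean = float(np.mean(logrt))
        self.log_rt_std = float(np.std(logrt) + 1e-12)
        y = (logrt - self.log_rt_mean) / self.log_rt_std
        ctx = self._context(theta, choices)
        w = None if sample_weights is None else np.asarray(sample_weights, float)

        def loss_fn(idx: np.ndarray) -> Tensor:
            return self._nll(y[idx], ctx[idx],
                             None if w is None else w[idx])

        def get_state():
            return {"net": self.net.state_dict(),
                    "m": self.log_rt_mean, "s": self.log_rt_std}

        def set_state(state):
            self.net.load_state_dict(state["net"])
            self.log_rt_mean = state["m"]
            self.log_rt_std = state["s"]

        self.train_result = fit_mle(loss_fn, self.net.parameters, get_state,
                                    set_state, len(theta), config)
        return self.train_result


class MixedLikelihoodEstimator:
    """Results object: the trained (choice model, rt flow) pair.

    Exposes the joint log-density (Eq. above), emulator sampling, and
    checkpoint (de)serialization.  Construct via
    :meth:`MixedNeuralLikelihood.fit` or :meth:`load`.
    """

    def __init__(self, choice_model: ChoiceModel, rt_flow: RTFlow,
                 prior: PriorSpec, trained: bool = False,
                 metadata: dict | None = None):
        self.choice_model = choice_model
        self.rt_flow = rt_flow
        self.prior = prior
        self.trained = trained
        self.metadata = metadata or {}

    # -- density ---------------------------------------------------------
    def log_prob(self, trials: pd.DataFrame, theta: np.ndarray,
                 require_trained: bool = True) -> np.ndarray:
        """Joint log-density matrix of shape (n_trials, n_parameters).

        Evaluates ``log q(c|theta) + log q(rt|c,theta)`` for every
        (trial, parameter) pair in one batched pass — the MCMC access
        pattern.  Entries with ``rt <= 0`` are ``-inf``.
        """
        if require_trained and not self.trained:
            raise RuntimeError("estimator has not been trained; call fit() first")
        theta = np.atleast_2d(np.asarray(theta, float))
        rts = np.asarray(trials["rt"], float)
        choices = np.asarray(trials["choice"], float)
        # Bernoulli part: logits per parameter, outer with the trial choices
        z = self.choice_model.logits(theta)[:, 0]  # (m,)
        lp_c = choices[:, None] * z[None, :] - np.logaddexp(0.0, z)[None, :]
        lp_rt = self.rt_flow.log_prob_grid(rts, choices, theta)
        return lp_c + lp_rt

    def sample(self, params, n: int, seed: int = 0) -> pd.DataFrame:
        """Emulate ``n`` trials at a single parameter vector."""
        if not self.trained:
            raise RuntimeError("estimator has not been trained; call fit() first")
        theta = params.to_array() if hasattr(params, "to_array") else np.asarray(params, float)
        theta = np.atleast_2d(theta)[:, : self.choice_model.n_params]
        rng = np.random.default_rng(seed)
        rho = self.choice_model.prob(theta)[0]
        choices = (rng.uniform(size=n) < rho).astype(float)
        theta_rep = np.repeat(theta, n, axis=0)
        rts = self.rt_flow.sample(theta_rep, choices, rng)
        return pd.DataFrame({"trial": np.arange(n), "choice": choices.astype(int),
                             "rt": rts})

    # -- reporting -------------------------------------------------------
    def summary(self) -> str:
        lines = ["Mixed neural likelihood estimator", "=" * 34]
        lines.append(f"parameter dimensions: {self.choice_model.n_params} "
                     f"({', '.join(self.prior.names)})")
        lines.append(f"trained: {self.trained}")
        arch = self.rt_flow.arch
        lines.append(f"choice net hidden: {arch.choice_hidden}")
        lines.append(f"flow: {arch.n_transforms} spline transforms, "
                     f"{arch.n_bins} bins, tail bound {arch.tail_bound}")
        for name, comp in (("choice", self.choice_model), ("rt flow", self.rt_flow)):
            tr = comp.train_result
            if tr is not None:
                lines.append(
                    f"{name}: best val loss {tr.best_val_loss:.4f} "
                    f"at epoch {tr.best_epoch} ({len(tr.val_losses)} epochs run)"
                )
        if self.metadata:
            lines.append(f"metadata: {json.dumps(self.metadata, sort_keys=True)}")
        return "\n".join(lines)

    # -- persistence -----------------------------------------------------
    def save(self, path) -> None:
        """Single-archive checkpoint: weights + descriptors + prior."""
        meta = {
            "arch": self.rt_flow.arch.to_dict(),
            "prior": {k: [lo, hi] for k, lo, hi in
                      zip(self.prior.names, self.prior.low, self.prior.high)},
            "trained": self.trained,
            "log_rt_mean": self.rt_flow.log_rt_mean,
            "log_rt_std": self.rt_flow.log_rt_std,
            "metadata": self.metadata,
        }
        arrays = {f"choice_{k}": v for k, v in self.choice_model.net.state_dict().items()}
        arrays.update({f"flow_{k}": v for k, v in self.rt_flow.net.state_dict().items()})
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **arrays)

    @classmethod
    def load(cls, path) -> "MixedLikelihoodEstimator":
        with np.load(path) as archive:
            meta = json.loads(bytes(archive["__meta__"]).decode())
            arch = ArchitectureConfig.from_dict(meta["arch"])
            prior = PriorSpec({k: tuple(v) for k, v in meta["prior"].items()})
            std = _Standardizer.from_prior(prior)
            choice = ChoiceModel(prior.ndim, arch, std)
            flow = RTFlow(prior.ndim, arch, std)
            try:
                choice.net.load_state_dict(
                    {k[7:]: archive[k] for k in archive.files if k.startswith("choice_")})
                flow.net.load_state_dict(
                    {k[5:]: archive[k] for k in archive.files if k.startswith("flow_")})
            except (ValueError, KeyError) as err:
                raise ValueError(f"checkpoint does not match its architecture "
                                 f"descriptor: {err}") from err
            flow.log_rt_mean = meta["log_rt_mean"]
            flow.log_rt_std = meta["log_rt_std"]
            return cls(choice, flow, prior, trained=meta["trained"],
                       metadata=meta.get("metadata", {}))


class MixedNeuralLikelihood:
    """Model object: training set + configuration for an MNLE fit.

    Parameters
    ----------
    theta : (N, d) array
        Parameter vectors drawn from the proposal (typically the prior).
    trials : DataFrame with columns ``choice, rt``
        One simulated trial per parameter vector, index-aligned.
    prior : PriorSpec
        The proposal; also used to standardize the conditioning inputs.
    arch, train_config : optional
        Architecture and optimization settings.
    """

    def __init__(self, theta: np.ndarray, trials: pd.DataFrame,
                 prior: PriorSpec, arch: ArchitectureConfig | None = None,
                 train_config: TrainConfig | None = None,
                 balance_choices: bool = True):
        theta = np.atleast_2d(np.asarray(theta, float))
        if len(theta) != len(trials):
            raise ValueError("theta and trials must be index-aligned")
        self.theta = theta
        self.trials = trials.reset_index(drop=True)
        self.prior = prior
        self.arch = arch or ArchitectureConfig()
        self.train_config = train_config or TrainConfig()
        self.balance_choices = balance_choices

    def build(self, seed: int = 0) -> MixedLikelihoodEstimator:
        """Construct an untrained estimator (random initialization)."""
        std = _Standardizer.from_prior(self.prior)
        seeds = np.random.SeedSequence(seed).generate_state(2)
        choice = ChoiceModel(self.prior.ndim, self.arch, std, seed=int(seeds[0] >> 1))
        flow = RTFlow(self.prior.ndim, self.arch, std, seed=int(seeds[1] >> 1))
        # give the untrained flow sensible input scaling so its density is proper
        logrt = np.log(self.trials["rt"].to_numpy(float))
        flow.log_rt_mean = float(np.mean(logrt))
        flow.log_rt_std = float(np.std(logrt) + 1e-12)
        return MixedLikelihoodEstimator(choice, flow, self.prior, trained=False)

    def fit(self, seed: int = 0, verbose: bool = False) -> MixedLikelihoodEstimator:
        """Train both components by maximum likelihood on the training set."""
        est = self.build(seed)
        seeds = np.random.SeedSequence((seed, 1)).generate_state(2)
        cfg_c = TrainConfig(**{**asdict(self.train_config), "seed": int(seeds[0] >> 1)})
        cfg_f = TrainConfig(**{**asdict(self.train_config), "seed": int(seeds[1] >> 1)})
        choices = self.trials["choice"].to_numpy(float)
        rc = est.choice_model.fit(self.theta, choices, cfg_c)
        if verbose:  # pragma: no cover
            print(f"choice model: best val loss {rc.best_val_loss:.4f} "
                  f"(epoch {rc.best_epoch})")
        weights = None
        if self.balance_choices:
            # equalize the two choice-conditionals per parameter region:
            # weight each trial by the inverse predicted choice probability
            rho = est.choice_model.prob(self.theta)
            q = np.where(choices == 1, rho, 1.0 - rho)
            weights = 1.0 / np.clip(q, 1.0 / 25.0, 1.0)
        rf = est.rt_flow.fit(self.theta, self.trials, cfg_f,
                             sample_weights=weights)
        if verbose:  # pragma: no cover
            print(f"rt flow: best val loss {rf.best_val_loss:.4f} "
                  f"(epoch {rf.best_epoch})")
        est.trained = True
        est.metadata = {
            "n_train": int(len(self.theta)),
            "seed": int(seed),
            "choice_val_loss": float(rc.best_val_loss),
            "flow_val_loss": float(rf.best_val_loss),
        }
        return est


# ---------------------------------------------------------------------------
# Operation-style wrappers
# ---------------------------------------------------------------------------

def train_choice_model(theta: np.ndarray, choices: np.ndarray, prior: PriorSpec,
                       arch: ArchitectureConfig | None = None,
                       config: TrainConfig | None = None,
                       seed: int = 0) -> ChoiceModel:
    """Train only the Bernoulli choice component."""
    arch = arch or ArchitectureConfig()
    config = config or TrainConfig()
    model = ChoiceModel(np.atleast_2d(theta).shape[1], arch,
                        _Standardizer.from_prior(prior), seed=seed)
    model.fit(theta, choices, config)
    return model


def train_rt_flow(theta: np.ndarray, trials: pd.DataFrame, prior: PriorSpec,
                  arch: ArchitectureConfig | None = None,
                  config: TrainConfig | None = None,
                  seed: int = 0) -> RTFlow:
    """Train only the conditional reaction-time flow."""
    arch = arch or ArchitectureConfig()
    config = config or TrainConfig()
    flow = RTFlow(np.atleast_2d(theta).shape[1], arch,
                  _Standardizer.from_prior(prior), seed=seed)
    flow.fit(theta, trials, config)
    return flow


def mnle_log_prob(est: MixedLikelihoodEstimator, trials: pd.DataFrame,
                  theta: np.ndarray) -> np.ndarray:
    """Batched joint log-density, shape (n_trials, n_parameters)."""
    return est.log_prob(trials, theta)


def mnle_sample(est: MixedLikelihoodEstimator, params, n: int,
                seed: int = 0) -> pd.DataFrame:
    """Emulate trials from the trained estimator."""
    return est.sample(params, n, seed=seed)
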