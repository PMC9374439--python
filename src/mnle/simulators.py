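"""Drift-diffusion model simulators and uniform priors.

The drift-diffusion model (DDM) describes two-alternative decisions as a
noisy accumulation process: a decision variable ``X`` starts at a fraction
``w`` of the boundary separation ``a``, drifts with rate ``v`` under unit
Wiener noise, and a response is triggered when ``X`` first crosses either
the upper bound (choice 1) or the lower bound at zero (choice 0).  The
observed reaction time is the first-passage time plus a non-decision time
``tau``.  A variant with linearly collapsing bounds adds a slope parameter
``gamma <= 0``; both bounds approach the midline ``a / 2`` at rate
``|gamma|`` so that long trials are increasingly truncated.

Trajectories are integrated with the Euler--Maruyama scheme, with a
Brownian-bridge correction for boundary crossings between grid points
(removing the leading discretization bias of first-passage sampling).
Each trial draws its noise from its own counter-derived stream so that
results do not depend on how trials are batched.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from numba import njit

__all__ = [
    "DDMParams",
    "PriorSpec",
    "sample_prior",
    "simulate_ddm",
    "simulate_collapsing_ddm",
    "generate_training_set",
    "trials_to_csv",
    "trials_from_csv",
]

DEFAULT_DT = 1e-4
DEFAULT_MAX_T = 10.0  # decision-time cap beyond tau, seconds
_MAX_RESIM = 3

#: Default uniform prior bounds for the simple DDM.
DEFAULT_BOUNDS = {
    "v": (-2.0, 2.0),
    "a": (0.5, 2.0),
    "w": (0.3, 0.7),
    "tau": (0.2, 1.8),
}

#: Extra bound for the collapse slope of the collapsing-bound DDM.
COLLAPSE_BOUND = {"gamma": (-1.0, 0.0)}


@dataclass(frozen=True)
class DDMParams:
    """Parameter vector of the drift-diffusion model.

    Parameters
    ----------
    v : float
        Drift rate (evidence units per second).
    a : float
        Boundary separation (evidence units), ``a > 0``.
    w : float
        Relative starting point, ``0 < w < 1`` (fraction of ``a``).
    tau : float
        Non-decision time in seconds, ``tau > 0``.
    gamma : float, optional
        Slope of the linearly collapsing bounds, ``gamma <= 0``.  ``None``
        selects the constant-bound model.
    """

    v: float
    a: float
    w: float
    tau: float
    gamma: float | None = None

    def __post_init__(self) -> None:
        if not self.a > 0:
            raise ValueError(f"boundary separation must be positive, got a={self.a}")
        if not 0 < self.w < 1:
            raise ValueError(f"starting point must lie strictly in (0, 1), got w={self.w}")
        if not self.tau > 0:
            raise ValueError(f"non-decision time must be positive, got tau={self.tau}")
        if self.gamma is not None and self.gamma > 0:
            raise ValueError(f"collapse slope must be <= 0, got gamma={self.gamma}")

    def to_array(self) -> np.ndarray:
        vals = [self.v, self.a, self.w, self.tau]
        if self.gamma is not None:
            vals.append(self.gamma)
        return np.asarray(vals, dtype=float)

    @classmethod
    def from_array(cls, arr: Sequence[float]) -> "DDMParams":
        arr = np.asarray(arr, dtype=float)
        if arr.shape[-1] == 4:
            return cls(*arr[:4])
        if arr.shape[-1] == 5:
            return cls(arr[0], arr[1], arr[2], arr[3], arr[4])
        raise ValueError(f"expected 4 or 5 parameters, got shape {arr.shape}")


class PriorSpec:
    """Independent uniform priors, one box per parameter dimension."""

    def __init__(self, bounds: dict[str, tuple[float, float]] | None = None):
        if bounds is None:
            bounds = dict(DEFAULT_BOUNDS)
        self.names = list(bounds.keys())
        self.low = np.array([bounds[k][0] for k in self.names], dtype=float)
        self.high = np.array([bounds[k][1] for k in self.names], dtype=float)
        if np.any(self.low >= self.high):
            bad = [k for k, lo, hi in zip(self.names, self.low, self.high) if lo >= hi]
            raise ValueError(f"lower bound must be < upper bound for {bad}")

    @classmethod
    def default_ddm(cls) -> "PriorSpec":
        return cls(dict(DEFAULT_BOUNDS))

    @classmethod
    def default_collapsing_ddm(cls) -> "PriorSpec":
        return cls({**DEFAULT_BOUNDS, **COLLAPSE_BOUND})

    @property
    def ndim(self) -> int:
        return len(self.names)

    def expand(self, fraction: float) -> "PriorSpec":
        """A wider box, padded by ``fraction`` of each side's width.

        Useful as a training proposal: any distribution containing the
        prior's support is admissible, and padding moves the prior's
        edges into the interior of the training distribution, where
        conditional density estimates are less biased.  Bounds with hard
        physical limits (``a``, ``w``, ``tau`` positive; ``w < 1``;
        ``gamma <= 0``) are clipped accordingly.
        """
        hard = {"a": (1e-6, np.inf), "w": (1e-3, 1 - 1e-3),
                "tau": (1e-3, np.inf), "gamma": (-np.inf, 0.0)}
        bounds = {}
        for name, lo, hi in zip(self.names, self.low, self.high):
            pad = fraction * (hi - lo)
            h = hard.get(name, (-np.inf, np.inf))
            bounds[name] = (max(lo - pad, h[0]), min(hi + pad, h[1]))
        return PriorSpec(bounds)

    @property
    def mean(self) -> np.ndarray:
        return 0.5 * (self.low + self.high)

    @property
    def std(self) -> np.ndarray:
        return (self.high - self.low) / np.sqrt(12.0)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.uniform(self.low, self.high, size=(n, self.ndim))

    def log_prob(self, theta: np.ndarray) -> np.ndarray:
        """Log-density of the box prior, ``-inf`` outside the support."""
        theta = np.atleast_2d(np.asarray(theta, dtype=float))
        inside = np.all((theta >= self.low) & (theta <= self.high), axis=-1)
        logp = np.full(theta.shape[0], -np.inf)
        logp[inside] = -np.sum(np.log(self.high - self.low))
        return logp

    def contains(self, theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(np.asarray(theta, dtype=float))
        return np.all((theta >= self.low) & (theta <= self.high), axis=-1)

    def to_json(self, path: str | Path) -> None:
        payload = {k: [lo, hi] for k, lo, hi in zip(self.names, self.low, self.high)}
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "PriorSpec":
        payload = json.loads(Path(path).read_text())
        return cls({k: tuple(v) for k, v in payload.items()})

    def __repr__(self) -> str:  # pragma: no cover
        body = ", ".join(
            f"{k}~U({lo:g},{hi:g})" for k, lo, hi in zip(self.names, self.low, self.high)
        )
        return f"PriorSpec({body})"


def sample_prior(spec: PriorSpec, n: int, seed: int) -> np.ndarray:
    """Draw ``n`` parameter vectors from the uniform prior box."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    return spec.sample(n, rng)


def _trial_seeds(seed: int, n_trials: int, n_attempts: int = _MAX_RESIM + 1) -> np.ndarray:
    """Counter-based per-trial (and per-resimulation-attempt) seeds."""
    ss = np.random.SeedSequence(seed)
    states = ss.generate_state(n_trials * n_attempts, dtype=np.uint32)
    return states.reshape(n_trials, n_attempts)


@njit(cache=True)
def _simulate_const(v, a, w, tau, dt, max_t, seeds, choices, rts, flags):
    """Constant-bound first-passage trials, one RNG stream per attempt.

    Between grid points the trajectory is treated as a Brownian bridge
    and absorbed with the exact crossing probability ``exp(-2 d0 d1 /
    dt)`` (``d0, d1`` the start/end distances to the bound), which
    removes the O(sqrt(dt)) boundary-overshoot bias of the naive Euler
    scheme.  ``flags`` records -1 if no attempt absorbed by ``max_t``.
    """
    sqrt_dt = np.sqrt(dt)
    near = 9.0 * dt  # exponent < -18: crossing probability negligible
    chunk = 1024
    n = seeds.shape[0]
    n_attempts = seeds.shape[1]
    for i in range(n):
        ai = a[i]
        vdt = v[i] * dt
        x0 = w[i] * ai
        done = False
        for attempt in range(n_attempts):
            np.random.seed(seeds[i, attempt])
            x = x0
            t = 0.0
            buf = np.empty(chunk)
            j = chunk
            while t < max_t:
                x_old = x
                if j == chunk:
                    buf = np.random.standard_normal(chunk)
                    j = 0
                x += vdt + sqrt_dt * buf[j]
                j += 1
                t += dt
                if x >= ai or x <= 0.0:
                    choices[i] = 1.0 if x >= ai else 0.0
                    rts[i] = tau[i] + t
                    done = True
                    break
                p_up = 0.0
                p_lo = 0.0
                if (ai - x_old) * (ai - x) < near:
                    p_up = np.exp(-2.0 * (ai - x_old) * (ai - x) / dt)
                if x_old * x < near:
                    p_lo = np.exp(-2.0 * x_old * x / dt)
                if p_up > 0.0 or p_lo > 0.0:
                    u = np.random.random()
                    if u < p_up + p_lo:
                        choices[i] = 1.0 if u < p_up else 0.0
                        rts[i] = tau[i] + t
                        done = True
                        break
            if done:
                break
        if not done:
            flags[i] = -1


@njit(cache=True)
def _simulate_collapse(v, a, w, tau, gamma, dt, max_t, seeds, choices, rts,
                       flags):
    """Linearly collapsing bounds; bridge-corrected like the constant case.

    The bridge crossing formula with start/end bound distances is exact
    for a linear boundary.  ``flags`` records 1 for a pinch-forced
    decision, -1 if no attempt absorbed.
    """
    sqrt_dt = np.sqrt(dt)
    near = 9.0 * dt
    chunk = 1024
    n = seeds.shape[0]
    n_attempts = seeds.shape[1]
    for i in range(n):
        ai = a[i]
        gi = gamma[i]
        vdt = v[i] * dt
        x0 = w[i] * ai
        done = False
        for attempt in range(n_attempts):
            np.random.seed(seeds[i, attempt])
            x = x0
            t = 0.0
            buf = np.empty(chunk)
            j = chunk
            while t < max_t:
                x_old = x
                up_old = ai + gi * t
                lo_old = -gi * t
                if j == chunk:
                    buf = np.random.standard_normal(chunk)
                    j = 0
                x += vdt + sqrt_dt * buf[j]
                j += 1
                t += dt
                up = ai + gi * t
                lo = -gi * t
                if up - lo <= dt * 1e-6:
                    # bounds pinched: force the decision at the pinch point
                    choices[i] = 1.0 if x >= 0.5 * ai else 0.0
                    rts[i] = tau[i] + t
                    flags[i] = 1
                    done = True
                    break
                if x >= up or x <= lo:
                    choices[i] = 1.0 if x >= up else 0.0
                    rts[i] = tau[i] + t
                    done = True
                    break
                p_up = 0.0
                p_lo = 0.0
                if (up_old - x_old) * (up - x) < near:
                    p_up = np.exp(-2.0 * (up_old - x_old) * (up - x) / dt)
                if (x_old - lo_old) * (x - lo) < near:
                    p_lo = np.exp(-2.0 * (x_old - lo_old) * (x - lo) / dt)
                if p_up > 0.0 or p_lo > 0.0:
                    u = np.random.random()
                    if u < p_up + p_lo:
                        choices[i] = 1.0 if u < p_up else 0.0
                        rts[i] = tau[i] + t
                        done = True
                        break
            if done:
                break
        if not done:
            flags[i] = -1


def _run_sim(theta: np.ndarray, n_trials: int, dt: float, max_t: float, seed: int) -> pd.DataFrame:
    """Dispatch a (possibly per-trial) parameter array to the numba core."""
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    if theta.shape[0] == 1:
        theta = np.repeat(theta, n_trials, axis=0)
    if theta.shape[0] != n_trials:
        raise ValueError("theta must be a single vector or one row per trial")
    v, a, w, tau = theta[:, 0], theta[:, 1], theta[:, 2], theta[:, 3]
    gamma = theta[:, 4] if theta.shape[1] == 5 else np.zeros(n_trials)
    seeds = _trial_seeds(seed, n_trials)
    choices = np.empty(n_trials)
    rts = np.empty(n_trials)
    flags = np.zeros(n_trials, dtype=np.int64)
    if np.all(gamma == 0.0):
        _simulate_const(v, a, w, tau, dt, max_t, seeds, choices, rts, flags)
    else:
        _simulate_collapse(v, a, w, tau, gamma, dt, max_t, seeds, choices,
                           rts, flags)
    if np.any(flags == -1):
        bad = int(np.sum(flags == -1))
        raise RuntimeError(
            f"{bad} trials were not absorbed within max_t={max_t}s after "
            f"{_MAX_RESIM + 1} attempts; increase max_t"
        )
    return pd.DataFrame(
        {"trial": np.arange(n_trials), "choice": choices.astype(int), "rt": rts}
    )


def simulate_ddm(
    params: DDMParams | np.ndarray,
    n_trials: int,
    dt: float = DEFAULT_DT,
    max_t: float = DEFAULT_MAX_T,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate the constant-bound DDM.

    Returns a trial table with columns ``trial, choice, rt``; reaction times
    are strictly greater than ``tau``.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if dt <= 0:
        raise ValueError("dt must be positive")
    theta = params.to_array() if isinstance(params, DDMParams) else np.asarray(params, float)
    theta2 = np.atleast_2d(theta)
    if theta2.shape[1] == 5 and np.any(theta2[:, 4] != 0.0):
        raise ValueError("simulate_ddm requires gamma absent or zero; use simulate_collapsing_ddm")
    return _run_sim(theta2[:, :4], n_trials, dt, max_t, seed)


def simulate_collapsing_ddm(
    params: DDMParams | np.ndarray,
    n_trials: int,
    dt: float = DEFAULT_DT,
    max_t: float = DEFAULT_MAX_T,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate the DDM with symmetric linearly collapsing bounds.

    The upper bound is ``a + gamma * t`` and the lower bound ``-gamma * t``
    (decision time ``t``, slope ``gamma <= 0``), so both bounds meet at
    ``a / 2``; a trajectory still undecided at the pinch time is forced to
    the nearer bound.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    theta = params.to_array() if isinstance(params, DDMParams) else np.asarray(params, float)
    theta2 = np.atleast_2d(theta)
    if theta2.shape[1] != 5:
        raise ValueError("collapsing-bound simulation requires 5 parameters (v, a, w, tau, gamma)")
    if np.any(theta2[:, 4] > 0):
        raise ValueError("gamma must be <= 0")
    return _run_sim(theta2, n_trials, dt, max_t, seed)


def generate_training_set(
    spec: PriorSpec,
    n: int,
    simulator: str = "ddm",
    dt: float = DEFAULT_DT,
    max_t: float = DEFAULT_MAX_T,
    seed: int = 0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Sample ``n`` parameters from the prior and simulate one trial each.

    Parameters and trials are index-aligned: row ``i`` of the returned
    parameter matrix generated row ``i`` of the trial table.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if simulator not in ("ddm", "ddm-collapse"):
        raise ValueError(f"unknown simulator {simulator!r}")
    rng = np.random.default_rng(np.random.SeedSequence(seed).generate_state(1)[0] >> 1)
    theta = spec.sample(n, rng)
    sim_seed = int(np.random.SeedSequence(seed).generate_state(2)[1] >> 1)
    if simulator == "ddm":
        if spec.ndim != 4:
            raise ValueError("simple DDM requires a 4-dimensional prior")
        trials = _run_sim(theta, n, dt, max_t, sim_seed)
    else:
        if spec.ndim != 5:
            raise ValueError("collapsing-bound DDM requires a 5-dimensional prior")
        trials = _run_sim(theta, n, dt, max_t, sim_seed)
    return theta, trials


def trials_to_csv(trials: pd.DataFrame, path: str | Path) -> None:
    trials.to_csv(path, index=False, float_format="%.17g")


def trials_from_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    expected = {"trial", "choice", "rt"}
    if not expected.issubset(df.columns):
        raise ValueError(f"trial CSV must have columns {sorted(expected)}")
    return df
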