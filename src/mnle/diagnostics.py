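"""Evaluation procedures: likelihood accuracy, posterior accuracy,
classifier two-sample tests, simulation-based calibration and posterior
predictive checks.

These diagnostics quantify two distinct questions.  First, how close is
the learned likelihood surface to the analytic one (Huber / mean-squared
error on likelihoods and log-likelihoods over prior-sampled parameters)?
Second, how good are the posteriors it induces: distance to reference
posterior samples (normalized mean and variance differences, C2ST),
recovery of ground-truth parameters, calibration of posterior
uncertainties (SBC rank uniformity), and predictive adequacy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier

from .estimator import MixedLikelihoodEstimator
from .simulators import DDMParams, PriorSpec, simulate_ddm
from .wfpt import wfpt_log_density_batch

__all__ = [
    "DiagnosticsReport",
    "likelihood_accuracy",
    "c2st",
    "sbc",
    "sbc_ecdf_data",
    "posterior_metrics",
    "predictive_check",
]

#: Floor applied to likelihood values before taking logs in the accuracy
#: metrics, so that parameter draws with zero analytic likelihood (rt out
#: of support) contribute a finite, bounded error.
LIKELIHOOD_FLOOR = 1e-7


def _huber(x: np.ndarray, y: np.ndarray, delta: float) -> float:
    r = np.abs(x - y)
    quad = 0.5 * r**2
    lin = delta * (r - 0.5 * delta)
    return float(np.mean(np.where(r <= delta, quad, lin)))


def likelihood_accuracy(
    est: MixedLikelihoodEstimator,
    prior: PriorSpec,
    n_obs: int = 100,
    n_params_per_obs: int = 1000,
    huber_delta: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Huber loss and MSE of estimated vs analytic (log-)likelihoods.

    For each of ``n_obs`` observations (one trial simulated at a prior
    draw), both likelihoods are evaluated at ``n_params_per_obs`` fresh
    prior draws and compared; one row per observation.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_obs):
        theta_true = prior.sample(1, rng)[0]
        obs = simulate_ddm(DDMParams(*theta_true), 1,
                           seed=int(rng.integers(2**31)))
        theta_test = prior.sample(n_params_per_obs, rng)
        la = wfpt_log_density_batch(obs["rt"].to_numpy(),
                                    obs["choice"].to_numpy(), theta_test)[0]
        lq = est.log_prob(obs, theta_test, require_trained=False)[0]
        floor = np.log(LIKELIHOOD_FLOOR)
        la_f, lq_f = np.maximum(la, floor), np.maximum(lq, floor)
        La, Lq = np.exp(la_f), np.exp(lq_f)
        rows.append({
            "obs": i,
            "huber_likelihood": _huber(La, Lq, huber_delta),
            "mse_likelihood": float(np.mean((La - Lq) ** 2)),
            "huber_log_likelihood": _huber(la_f, lq_f, huber_delta),
            "mse_log_likelihood": float(np.mean((la_f - lq_f) ** 2)),
        })
    return pd.DataFrame(rows)


def c2st(
    samples_a: np.ndarray,
    samples_b: np.ndarray,
    folds: int = 5,
    seed: int = 0,
    classifier: Callable[..., object] | None = None,
) -> float:
    """Classifier two-sample test score in [~0.5, 1].

    Cross-validated held-out accuracy of a feed-forward classifier on
    z-scored, label-balanced samples; 0.5 means the two sample sets are
    indistinguishable.
    """
    a = np.atleast_2d(np.asarray(samples_a, float))
    b = np.atleast_2d(np.asarray(samples_b, float))
    if a.shape[1] != b.shape[1]:
        raise ValueError(f"dimension mismatch: {a.shape[1]} vs {b.shape[1]}")
    if min(len(a), len(b)) < 100:
        raise ValueError("c2st requires at least 100 draws per sample set")
    rng = np.random.default_rng(seed)
    n = min(len(a), len(b))
    a = a[rng.permutation(len(a))[:n]]
    b = b[rng.permutation(len(b))[:n]]
    X = np.vstack([a, b])
    y = np.concatenate([np.zeros(n), np.ones(n)])
    mu, sd = X.mean(axis=0), X.std(axis=0) + 1e-12
    X = (X - mu) / sd
    d = X.shape[1]
    scores = []
    skf = StratifiedKFold(n_splits=folds, shuffle=True,
                          random_state=int(rng.integers(2**31)))
    for train, test in skf.split(X, y):
        if classifier is None:
            clf = MLPClassifier(hidden_layer_sizes=(10 * d, 10 * d),
                                max_iter=300, early_stopping=True,
                                n_iter_no_change=20,
                                random_state=int(rng.integers(2**31)))
        else:
            clf = classifier(random_state=int(rng.integers(2**31)))
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clf.fit(X[train], y[train])
        scores.append(clf.score(X[test], y[test]))
    return float(np.mean(scores))


def sbc(
    prior: PriorSpec,
    simulate_fn: Callable[[np.ndarray, int], pd.DataFrame],
    posterior_fn: Callable[[pd.DataFrame, int], np.ndarray],
    n_runs: int = 100,
    n_posterior_draws: int = 1000,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulation-based calibration.

    For each run: draw ``theta*`` from the prior, simulate an observation
    with ``simulate_fn(theta*, seed)``, call ``posterior_fn(observation,
    seed)`` for posterior draws, and record the rank of each ground-truth
    coordinate among the draws.  Under a calibrated posterior the ranks
    are uniform on {0, ..., L}; uniformity is assessed per dimension by a
    KS test of the randomized PIT values.

    Returns ``(ranks, uniformity)``: long-format ranks
    (``run, param, rank``) and a per-parameter KS table.
    """
    if n_runs < 20:
        raise ValueError("sbc needs at least 20 runs")
    rng = np.random.default_rng(seed)
    records = []
    n_failed = 0
    for run in range(n_runs):
        theta_star = prior.sample(1, rng)[0]
        obs = simulate_fn(theta_star, int(rng.integers(2**31)))
        try:
            draws = posterior_fn(obs, int(rng.integers(2**31)))
        except Exception:  # posterior failure: skip and count
            n_failed += 1
            continue
        draws = np.atleast_2d(draws)
        if draws.shape[0] > n_posterior_draws:
            sel = rng.permutation(draws.shape[0])[:n_posterior_draws]
            draws = draws[sel]
        L = draws.shape[0]
        for j, name in enumerate(prior.names):
            rank = int(np.sum(draws[:, j] < theta_star[j]))
            records.append({"run": run, "param": name, "rank": rank, "L": L})
    ranks = pd.DataFrame(records)
    uni_rows = []
    for name in prior.names:
        sub = ranks[ranks["param"] == name]
        # randomized PIT: uniform on [0,1] under uniform discrete ranks
        u = (sub["rank"].to_numpy() + rng.uniform(size=len(sub))) / (sub["L"].to_numpy() + 1)
        ks = stats.kstest(u, "uniform")
        uni_rows.append({"param": name, "ks_stat": float(ks.statistic),
                         "ks_pvalue": float(ks.pvalue), "n_runs": len(sub),
                         "n_failed": n_failed})
    return ranks, pd.DataFrame(uni_rows)


def sbc_ecdf_data(ranks: pd.DataFrame) -> pd.DataFrame:
    """Empirical CDF of normalized ranks per parameter (plot data)."""
    rows = []
    for name, sub in ranks.groupby("param"):
        r = np.sort(sub["rank"].to_numpy() / sub["L"].to_numpy())
        ecdf = np.arange(1, len(r) + 1) / len(r)
        rows.append(pd.DataFrame({"param": name, "rank_frac": r, "ecdf": ecdf}))
    return pd.concat(rows, ignore_index=True)


def posterior_metrics(
    samples: np.ndarray,
    reference_samples: np.ndarray,
    true_params: np.ndarray | None = None,
    seed: int = 0,
    compute_c2st: bool = True,
) -> dict:
    """Distance of a posterior-sample set from a reference set.

    Per-dimension and dimension-averaged: |mean difference| / reference
    std, |variance difference| / reference variance, MSE of the posterior
    mean against the ground truth, and the C2ST score.
    """
    s = np.atleast_2d(np.asarray(samples, float))
    r = np.atleast_2d(np.asarray(reference_samples, float))
    if s.shape[1] != r.shape[1]:
        raise ValueError("sample sets must have the same dimensionality")
    ref_std = r.std(axis=0, ddof=1)
    ref_var = r.var(axis=0, ddof=1)
    if np.any(ref_var == 0):
        raise ValueError("reference posterior has zero variance")
    mean_diff = np.abs(s.mean(axis=0) - r.mean(axis=0)) / ref_std
    var_diff = np.abs(s.var(axis=0, ddof=1) - ref_var) / ref_var
    out = {
        "mean_diff_per_dim": mean_diff.tolist(),
        "var_diff_per_dim": var_diff.tolist(),
        "mean_diff": float(mean_diff.mean()),
        "var_diff": float(var_diff.mean()),
    }
    if true_params is not None:
        true_params = np.asarray(true_params, float)
        se = (s.mean(axis=0) - true_params) ** 2
        out["mse_to_truth_per_dim"] = se.tolist()
        out["mse_to_truth"] = float(se.mean())
    if compute_c2st:
        out["c2st"] = c2st(s, r, seed=seed)
    return out


def predictive_check(
    posterior_samples,
    simulator: Callable[[np.ndarray, int, int], pd.DataFrame],
    observed: pd.DataFrame,
    n_sims: int = 1000,
    seed: int = 0,
    prior: PriorSpec | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Posterior-predictive (and optionally prior-predictive) check.

    Resamples ``n_sims`` parameter vectors from the posterior, simulates
    one trial from each, and compares choice fractions and reaction-time
    quantiles with the observed trial table.  Returns ``(summary,
    predictive_trials)``; the trials table carries a ``source`` column
    suitable for overlay histograms.
    """
    rng = np.random.default_rng(seed)
    draws = posterior_samples.draws if hasattr(posterior_samples, "draws") \
        else np.atleast_2d(posterior_samples)
    idx = rng.integers(0, draws.shape[0], size=n_sims)
    theta_rep = draws[idx]
    post_pred = simulator(theta_rep, n_sims, int(rng.integers(2**31)))
    post_pred = post_pred.assign(source="posterior_predictive")
    tables = [observed.assign(source="observed"), post_pred]
    if prior is not None:
        theta_prior = prior.sample(n_sims, rng)
        prior_pred = simulator(theta_prior, n_sims, int(rng.integers(2**31)))
        tables.append(prior_pred.assign(source="prior_predictive"))
    trials = pd.concat(tables, ignore_index=True)

    qs = [0.05, 0.25, 0.5, 0.75, 0.95]
    rows = []
    for source, sub in trials.groupby("source"):
        row = {"source": source, "n": len(sub),
               "choice_fraction": float(sub["choice"].mean()),
               "rt_iqr": float(sub["rt"].quantile(0.75) - sub["rt"].quantile(0.25))}
        for q in qs:
            row[f"rt_q{int(q * 100):02d}"] = float(sub["rt"].quantile(q))
        rows.append(row)
    return pd.DataFrame(rows), trials


@dataclass
class DiagnosticsReport:
    """Container for the full set of evaluation outputs."""

    likelihood_metrics: pd.DataFrame | None = None
    posterior_metrics: list[dict] = field(default_factory=list)
    c2st_scores: list[float] = field(default_factory=list)
    sbc_ranks: pd.DataFrame | None = None
    sbc_uniformity: pd.DataFrame | None = None
    extra: dict = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {"posterior_metrics": self.posterior_metrics,
                   "c2st_scores": self.c2st_scores, "extra": self.extra}
        if self.likelihood_metrics is not None:
            payload["likelihood_metrics_mean"] = {
                k: float(self.likelihood_metrics[k].mean())
                for k in self.likelihood_metrics.columns if k != "obs"
            }
        if self.sbc_uniformity is not None:
            payload["sbc_uniformity"] = self.sbc_uniformity.to_dict("records")
        return json.dumps(payload, indent=2)

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        (directory / "report.json").write_text(self.to_json())
        if self.likelihood_metrics is not None:
            self.likelihood_metrics.to_csv(directory / "likelihood_metrics.csv",
                                           index=False)
        if self.sbc_ranks is not None:
            self.sbc_ranks[["run", "param", "rank"]].to_csv(
                directory / "sbc_ranks.csv", index=False)
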