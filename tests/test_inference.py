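"""Posterior machinery: transform correctness, potential composition,
SIS initialization, slice-sampler statistical correctness, ensembles."""

import numpy as np
import pandas as pd
import pytest

from mnle.diagnostics import c2st
from mnle.inference import (
    MCMCConfig,
    ParameterTransform,
    PosteriorSamples,
    ensemble_posterior,
    infer_posterior,
    init_chains_sis,
    joint_potential,
    slice_sample,
)
from mnle.simulators import DDMParams, PriorSpec, sample_prior, simulate_ddm
from mnle.wfpt import analytic_loglik_dataset


class TestParameterTransform:
    def test_round_trip(self, prior):
        tf = ParameterTransform(prior)
        theta = sample_prior(prior, 200, seed=40)
        back = tf.to_constrained(tf.to_unconstrained(theta))
        np.testing.assert_allclose(back, theta, atol=1e-10)

    def test_jacobian_matches_numeric(self, prior):
        tf = ParameterTransform(prior)
        u = np.random.default_rng(41).normal(size=(20, 4))
        eps = 1e-6
        analytic = tf.log_abs_det_jacobian(u)
        numeric = np.zeros(20)
        for d in range(4):
            up = u.copy(); up[:, d] += eps
            dn = u.copy(); dn[:, d] -= eps
            deriv = (tf.to_constrained(up)[:, d] - tf.to_constrained(dn)[:, d]) / (2 * eps)
            numeric += np.log(deriv)
        np.testing.assert_allclose(analytic, numeric, atol=1e-6)

    def test_inverse_always_in_box(self, prior):
        tf = ParameterTransform(prior)
        u = np.random.default_rng(42).normal(scale=50, size=(500, 4))
        theta = tf.to_constrained(u)
        assert np.all(theta >= prior.low) and np.all(theta <= prior.high)


class TestJointPotential:
    def test_support_of_potential(self, prior):
        true = DDMParams(0.5, 1.0, 0.5, 0.3)
        trials = simulate_ddm(true, 5, seed=43)
        pot = joint_potential("analytic", None, prior, trials)
        tf = pot.transform
        # the box prior vanishes outside its support
        assert prior.log_prob(np.array([[3.0, 1.0, 0.5, 0.4]]))[0] == -np.inf
        # finite at the generating parameters ...
        assert np.isfinite(pot(tf.to_unconstrained(true.to_array()[None]))[0])
        # ... and -inf when the non-decision time exceeds an observed rt
        bad = np.array([0.5, 1.0, 0.5, trials["rt"].min() + 0.05])
        assert pot(tf.to_unconstrained(bad[None]))[0] == -np.inf

    def test_single_trial_decomposition(self, prior):
        trials = simulate_ddm(DDMParams(0.5, 1.0, 0.5, 0.3), 1, seed=44)
        pot = joint_potential("analytic", None, prior, trials)
        tf = pot.transform
        theta = sample_prior(prior, 1, seed=44)
        u = tf.to_unconstrained(theta)
        expected = (analytic_loglik_dataset(trials, theta[0])
                    + prior.log_prob(theta)[0]
                    + tf.log_abs_det_jacobian(u)[0])
        assert pot(u)[0] == pytest.approx(expected, rel=1e-12)

    def test_many_trials_match_loop(self, prior):
        trials = simulate_ddm(DDMParams(0.5, 1.2, 0.45, 0.3), 100, seed=45)
        pot = joint_potential("analytic", None, prior, trials)
        tf = pot.transform
        theta = sample_prior(prior, 4, seed=45)
        u = tf.to_unconstrained(theta)
        vals = pot(u)
        for j in range(4):
            loop_ll = sum(
                analytic_loglik_dataset(trials.iloc[[i]], theta[j])
                for i in range(100)
            )
            expected = loop_ll + prior.log_prob(theta[j:j + 1])[0] \
                + tf.log_abs_det_jacobian(u[j:j + 1])[0]
            assert vals[j] == pytest.approx(expected, rel=1e-10)

    def test_mnle_backend_requires_trained_estimator(self, prior, tiny_training):
        from mnle.estimator import MixedNeuralLikelihood
        theta, trials = tiny_training
        untrained = MixedNeuralLikelihood(theta, trials, prior).build(0)
        with pytest.raises(RuntimeError, match="trained"):
            joint_potential("mnle", untrained, prior, trials.iloc[:5])

    def test_empty_trials_rejected(self, prior):
        with pytest.raises(ValueError, match="nonempty"):
            joint_potential("analytic", None, prior,
                            pd.DataFrame({"choice": [], "rt": []}))


class TestSISInit:
    def test_flat_potential_recovers_prior(self, prior):
        tf = ParameterTransform(prior)

        def pot(u):
            theta = tf.to_constrained(u)
            return prior.log_prob(theta) + tf.log_abs_det_jacobian(u)

        pot.transform = tf
        starts = init_chains_sis(pot, prior, n_chains=2000, n_proposals=20_000,
                                 seed=46)
        theta = tf.to_constrained(starts)
        from scipy import stats
        for d in range(4):
            u01 = (theta[:, d] - prior.low[d]) / (prior.high[d] - prior.low[d])
            assert stats.kstest(u01, "uniform").pvalue > 0.01

    def test_peaked_potential_concentrates_starts(self, prior):
        tf = ParameterTransform(prior)
        center = tf.to_unconstrained(prior.mean[None])[0]

        def pot(u):
            u = np.atleast_2d(u)
            return -0.5 * np.sum(((u - center) / 0.3) ** 2, axis=-1)

        pot.transform = tf
        starts = init_chains_sis(pot, prior, n_chains=50, n_proposals=20_000,
                                 seed=47)
        # all starts inside the 99.9% radius of the peak (chi2_4 quantile)
        from scipy import stats
        r2 = np.sum(((starts - center) / 0.3) ** 2, axis=-1)
        assert np.all(r2 < stats.chi2(df=4).ppf(0.999))

    def test_insufficient_proposals_rejected(self, prior):
        pot = lambda u: np.zeros(np.atleast_2d(u).shape[0])
        with pytest.raises(ValueError, match="n_proposals"):
            init_chains_sis(pot, prior, n_chains=10, n_proposals=5, seed=48)


class TestSliceSampler:
    def test_standard_normal_moments(self):
        pot = lambda u: -0.5 * np.sum(np.atleast_2d(u) ** 2, axis=-1)
        ps = slice_sample(pot, np.zeros((4, 2)), 10_000, burn_in=100, seed=49)
        assert np.all(np.abs(ps.mean()) < 0.05)
        assert np.all(np.abs(ps.var() - 1.0) < 0.1)

    def test_conjugate_gaussian_posterior(self):
        # prior N(0, 1), likelihood x_i ~ N(theta, sigma=0.5), 20 obs
        rng = np.random.default_rng(50)
        x = rng.normal(0.7, 0.5, size=20)
        sig2, s02 = 0.25, 1.0
        post_var = 1.0 / (1 / s02 + len(x) / sig2)
        post_mean = post_var * (x.sum() / sig2)

        def pot(u):
            u = np.atleast_2d(u)
            lp = -0.5 * u[:, 0] ** 2 / s02
            ll = -0.5 * np.sum((x[None, :] - u[:, :1]) ** 2, axis=-1) / sig2
            return lp + ll

        ps = slice_sample(pot, np.zeros((4, 1)), 6000, burn_in=150, seed=51)
        mc_se = np.sqrt(post_var / ps.n_draws)
        assert abs(ps.mean()[0] - post_mean) < 5 * mc_se
        assert abs(ps.var()[0] - post_var) < 0.15 * post_var

    def test_draws_respect_support(self, prior):
        """Sampling through the transform never leaves the prior box."""
        trials = simulate_ddm(DDMParams(0.8, 1.2, 0.5, 0.3), 20, seed=52)
        ps = infer_posterior("analytic", None, prior, trials,
                             MCMCConfig(n_chains=3, burn_in=50, thin=1,
                                        n_samples=300, sis_proposals=500),
                             seed=53)
        assert np.all(ps.draws >= prior.low) and np.all(ps.draws <= prior.high)
        assert ps.draws.shape == (300, 4)

    def test_nonfinite_start_rejected(self):
        pot = lambda u: np.full(np.atleast_2d(u).shape[0], -np.inf)
        with pytest.raises(ValueError, match="finite"):
            slice_sample(pot, np.zeros((2, 2)), 10, burn_in=0, seed=54)


class TestPosteriorSamples:
    def test_csv_round_trip(self, tmp_path):
        draws = np.random.default_rng(55).normal(size=(50, 3))
        ps = PosteriorSamples(draws, np.repeat([0, 1], 25), ["v", "a", "w"],
                              metadata={"seed": 1})
        path = tmp_path / "post.csv"
        ps.to_csv(path)
        back = PosteriorSamples.from_csv(path)
        np.testing.assert_allclose(back.draws, draws)
        assert back.param_names == ["v", "a", "w"]
        assert back.metadata["seed"] == 1


class TestEnsemble:
    def test_identical_members_equal_single(self, tiny_estimator, prior):
        trials = simulate_ddm(DDMParams(0.5, 1.2, 0.5, 0.3), 50, seed=56)
        cfg = MCMCConfig(n_chains=3, burn_in=80, thin=1, n_samples=300,
                         sis_proposals=1000)
        pooled = ensemble_posterior([tiny_estimator, tiny_estimator], prior,
                                    trials, cfg, seed=57)
        member = np.asarray(pooled.metadata["member"])
        counts = np.bincount(member)
        assert counts[0] == counts[1]  # equal pooling by construction
        single = infer_posterior("mnle", tiny_estimator, prior, trials, cfg,
                                 seed=58)
        score = c2st(pooled.draws[member == 0], single.draws, seed=59)
        assert score < 0.58  # same distribution up to MCMC noise

    def test_requires_two_members(self, tiny_estimator, prior):
        trials = simulate_ddm(DDMParams(0.5, 1.2, 0.5, 0.3), 10, seed=60)
        with pytest.raises(ValueError, match="at least two"):
            ensemble_posterior([tiny_estimator], prior, trials)
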