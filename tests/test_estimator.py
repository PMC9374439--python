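"""Mixed likelihood estimator: component learning on known generative
rules, joint-density normalization, batching, sampling and persistence."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate

from mnle.estimator import (
    ArchitectureConfig,
    MixedLikelihoodEstimator,
    MixedNeuralLikelihood,
    mnle_log_prob,
    mnle_sample,
    train_choice_model,
    train_rt_flow,
)
from mnle.nn.train import TrainConfig
from mnle.simulators import DDMParams, PriorSpec, sample_prior, simulate_ddm

QUICK = TrainConfig(max_epochs=25, patience=6)


class TestChoiceModel:
    def test_degenerate_labels_learned(self, prior):
        theta = sample_prior(prior, 2000, seed=20)
        model = train_choice_model(
            theta, np.ones(2000), prior,
            config=TrainConfig(max_epochs=80, patience=80, lr=5e-3), seed=0)
        probe = sample_prior(prior, 200, seed=21)
        assert np.all(model.prob(probe) >= 0.99)

    def test_logistic_rule_recovered(self, prior):
        rng = np.random.default_rng(22)
        theta = sample_prior(prior, 20_000, seed=22)
        rho_true = 1.0 / (1.0 + np.exp(-theta[:, 0]))  # depends on drift only
        c = (rng.uniform(size=len(theta)) < rho_true).astype(float)
        model = train_choice_model(theta, c, prior,
                                   config=TrainConfig(max_epochs=60, patience=10),
                                   seed=1)
        probe = sample_prior(prior, 500, seed=23)
        pred = model.prob(probe)
        target = 1.0 / (1.0 + np.exp(-probe[:, 0]))
        assert np.mean(np.abs(pred - target)) < 0.03

    def test_symmetric_data_gives_half(self, prior):
        p = DDMParams(v=0.0, a=1.2, w=0.5, tau=0.4)
        trials = simulate_ddm(p, 4000, seed=24)
        theta = np.tile(p.to_array(), (4000, 1))
        model = train_choice_model(theta, trials["choice"].to_numpy(float),
                                   prior, config=QUICK, seed=2)
        assert abs(model.prob(p.to_array()[None])[0] - 0.5) < 0.03


class TestRTFlow:
    def test_known_shifted_exponential_density(self, prior):
        # rt = 0.3 + Exp(1), independent of parameters and choice
        rng = np.random.default_rng(25)
        n = 12_000
        theta = sample_prior(prior, n, seed=25)
        rts = 0.3 + rng.exponential(1.0, size=n)
        trials = pd.DataFrame({"choice": rng.integers(0, 2, n), "rt": rts})
        flow = train_rt_flow(theta, trials, prior,
                             config=TrainConfig(max_epochs=40, patience=8), seed=3)
        grid = np.linspace(0.35, 4.0, 60)
        probe = prior.mean
        est_pdf = np.exp(flow.log_prob(grid, np.ones(60),
                                       np.tile(probe, (60, 1))))
        true_pdf = np.exp(-(grid - 0.3))
        assert np.mean(np.abs(est_pdf - true_pdf)) < 0.05

    def test_normalization_any_conditioning(self, tiny_estimator, prior):
        flow = tiny_estimator.rt_flow
        for theta in sample_prior(prior, 3, seed=26):
            for c in (0.0, 1.0):
                pdf = lambda rt: np.exp(flow.log_prob(
                    np.array([rt]), np.array([c]), theta[None])).item()
                val, _ = integrate.quad(pdf, 1e-6, 60.0, limit=200)
                assert val == pytest.approx(1.0, abs=1e-2)

    def test_training_determinism(self, prior):
        theta = sample_prior(prior, 1500, seed=27)
        p = DDMParams(0.5, 1.2, 0.5, 0.3)
        trials = simulate_ddm(p, 1500, seed=27)
        cfg = TrainConfig(max_epochs=5, patience=3)
        f1 = train_rt_flow(theta, trials, prior, config=cfg, seed=4)
        f2 = train_rt_flow(theta, trials, prior, config=cfg, seed=4)
        assert f1.train_result.val_losses == f2.train_result.val_losses

    def test_nonpositive_rt_rejected_for_training(self, prior):
        theta = sample_prior(prior, 10, seed=28)
        trials = pd.DataFrame({"choice": np.zeros(10), "rt": np.linspace(-1, 1, 10)})
        with pytest.raises(ValueError, match="positive"):
            train_rt_flow(theta, trials, prior, config=QUICK)


class TestJointEstimator:
    def test_joint_normalization(self, tiny_estimator, prior):
        for theta in sample_prior(prior, 3, seed=29):
            total = 0.0
            for c in (0, 1):
                pdf = lambda rt: np.exp(tiny_estimator.log_prob(
                    pd.DataFrame({"choice": [c], "rt": [rt]}), theta[None])).item()
                val, _ = integrate.quad(pdf, 1e-6, 60.0, limit=200)
                total += val
            assert total == pytest.approx(1.0, abs=1e-2)

    def test_batched_equals_elementwise(self, tiny_estimator, prior):
        trials = simulate_ddm(DDMParams(0.5, 1.0, 0.5, 0.3), 20, seed=30)
        theta = sample_prior(prior, 5, seed=30)
        grid = mnle_log_prob(tiny_estimator, trials, theta)
        assert grid.shape == (20, 5)
        for i in range(0, 20, 7):
            for j in range(5):
                single = tiny_estimator.log_prob(trials.iloc[[i]], theta[j:j + 1])
                assert grid[i, j] == pytest.approx(single.item(), rel=1e-12)

    def test_nonpositive_rt_gives_minus_inf(self, tiny_estimator, prior):
        trials = pd.DataFrame({"choice": [1, 0], "rt": [-0.5, 0.8]})
        out = tiny_estimator.log_prob(trials, sample_prior(prior, 2, seed=31))
        assert np.all(out[0] == -np.inf)
        assert np.all(np.isfinite(out[1]))

    def test_untrained_estimator_raises(self, prior, tiny_training):
        theta, trials = tiny_training
        est = MixedNeuralLikelihood(theta, trials, prior).build(seed=0)
        with pytest.raises(RuntimeError, match="train"):
            est.log_prob(trials.iloc[:2], theta[:2])
        with pytest.raises(RuntimeError, match="train"):
            est.sample(theta[0], 5)

    def test_choice_conditioning_matters_for_asymmetric_start(self, tiny_estimator):
        """With w != 0.5 the reaction-time densities differ by choice."""
        theta = np.array([0.0, 1.5, 0.65, 0.4])
        grid = np.linspace(0.45, 4.0, 200)
        d0 = np.exp(tiny_estimator.rt_flow.log_prob(
            grid, np.zeros(200), np.tile(theta, (200, 1))))
        d1 = np.exp(tiny_estimator.rt_flow.log_prob(
            grid, np.ones(200), np.tile(theta, (200, 1))))
        tv = 0.5 * np.trapezoid(np.abs(d0 - d1), grid)
        assert tv > 0.05


class TestSampling:
    def test_choice_fraction_matches_rho(self, tiny_estimator, prior):
        theta = sample_prior(prior, 1, seed=32)[0]
        rho = tiny_estimator.choice_model.prob(theta[None])[0]
        emu = mnle_sample(tiny_estimator, theta, 4000, seed=33)
        se = np.sqrt(rho * (1 - rho) / 4000)
        assert abs(emu["choice"].mean() - rho) < 3 * se
        assert np.all(emu["rt"] > 0)

    def test_sampling_deterministic(self, tiny_estimator, prior):
        theta = sample_prior(prior, 1, seed=34)[0]
        a = mnle_sample(tiny_estimator, theta, 100, seed=35)
        b = mnle_sample(tiny_estimator, theta, 100, seed=35)
        pd.testing.assert_frame_equal(a, b)


class TestPersistence:
    def test_checkpoint_round_trip(self, tiny_estimator, prior, tmp_path):
        path = tmp_path / "est.npz"
        tiny_estimator.save(path)
        back = MixedLikelihoodEstimator.load(path)
        trials = simulate_ddm(DDMParams(0.5, 1.0, 0.5, 0.3), 10, seed=36)
        theta = sample_prior(prior, 3, seed=36)
        np.testing.assert_allclose(back.log_prob(trials, theta),
                                   tiny_estimator.log_prob(trials, theta))
        assert back.trained

    def test_descriptor_mismatch_fails_loudly(self, tiny_estimator, tmp_path):
        path = tmp_path / "est.npz"
        tiny_estimator.save(path)
        import json
        with np.load(path) as archive:
            data = {k: archive[k] for k in archive.files}
        meta = json.loads(bytes(data["__meta__"]).decode())
        meta["arch"]["flow_hidden"] = [8, 8]  # wrong descriptor
        data["__meta__"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
        np.savez(path, **data)
        with pytest.raises(ValueError, match="descriptor"):
            MixedLikelihoodEstimator.load(path)

    def test_misaligned_training_data_rejected(self, prior, tiny_training):
        theta, trials = tiny_training
        with pytest.raises(ValueError, match="aligned"):
            MixedNeuralLikelihood(theta[:-5], trials, prior)
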