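"""Shared fixtures.

Expensive session-scoped fixtures (trained estimators, posterior pairs)
are shared between the unit tests and the acceptance suite so that the
whole run stays within a practical CPU budget; problem sizes are chosen
accordingly and documented in the package's methods note.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mnle.estimator import ArchitectureConfig, MixedNeuralLikelihood
from mnle.nn.train import TrainConfig
from mnle.simulators import PriorSpec, generate_training_set


@pytest.fixture(scope="session")
def prior() -> PriorSpec:
    return PriorSpec.default_ddm()


@pytest.fixture(scope="session")
def collapse_prior() -> PriorSpec:
    return PriorSpec.default_collapsing_ddm()


@pytest.fixture(scope="session")
def tiny_training(prior):
    """Small aligned (theta, trials) training set for fast unit tests."""
    return generate_training_set(prior, 4000, seed=101)


@pytest.fixture(scope="session")
def tiny_estimator(prior, tiny_training):
    """Quickly trained estimator; coarse but usable for contract tests."""
    theta, trials = tiny_training
    model = MixedNeuralLikelihood(
        theta, trials, prior,
        train_config=TrainConfig(max_epochs=30, patience=8, seed=0),
    )
    return model.fit(seed=7)


@pytest.fixture(scope="session")
def full_estimator(prior):
    """Estimator trained at the standard 1e5-simulation budget.

    The training proposal is the prior box padded by 10% per side, which
    keeps the prior's edges in the interior of the training distribution.
    """
    proposal = prior.expand(0.1)
    theta, trials = generate_training_set(proposal, 100_000, seed=3)
    model = MixedNeuralLikelihood(theta, trials, proposal)
    est = model.fit(seed=0)
    est._training_set = (theta, trials)  # reused by acceptance tests
    return est
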