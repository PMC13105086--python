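import numpy as np
import pytest

from deephtl import (
    LearnerConfig,
    SimulationConfig,
    cross_fit,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def fast_mlp() -> LearnerConfig:
    """Small, quickly trainable network ensemble for test runs."""
    return LearnerConfig(
        hidden_layer_sizes=(16,),
        solver="lbfgs",
        max_epochs=100,
        n_members=3,
        n_folds=3,
    )


@pytest.fixture(scope="session")
def fast_ridge() -> LearnerConfig:
    """Linear base learner; near-instant fits for plumbing tests."""
    return LearnerConfig(base_learner="ridge", n_members=3, n_folds=3)


@pytest.fixture(scope="session")
def small_null_dataset():
    """Homogeneous-null simulated study used across estimation tests."""
    return simulate_dataset(
        SimulationConfig(n=400, p=5, sigma=1.0, tau_scenario="zero", seed=101)
    )


@pytest.fixture(scope="session")
def small_null_nuisances(small_null_dataset, fast_ridge):
    return cross_fit(small_null_dataset, targets=("e", "mu"),
                     config=fast_ridge, seed=7)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
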