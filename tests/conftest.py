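import numpy as np
import pytest

from kneegp import ExperimentConfig, GaitSimConfig, generate_dataset, run_experiment


@pytest.fixture(scope="session")
def default_dataset():
    """The default synthetic gait dataset: 4 speeds x 5 cycles, seed 0."""
    return generate_dataset(GaitSimConfig(seed=0))


@pytest.fixture(scope="session")
def default_report(default_dataset):
    """Full three-scenario evaluation on the default dataset (computed once
    per session; this is the expensive end-to-end run)."""
    return run_experiment(default_dataset, ExperimentConfig(seed=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
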