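import numpy as np
import pytest

from aidkit import SimConfig
from aidkit.workflows import RunConfig, run_depletion_experiment


@pytest.fixture(scope="session")
def config():
    return SimConfig()


@pytest.fixture(scope="session")
def quiet_config():
    """Noise-free configuration for closed-form comparisons."""
    return SimConfig(noise_cv=0.0)


@pytest.fixture(scope="session")
def saturating_cohort():
    """20 baseline-normalized cells under 0.5 mM instant-delivery auxin."""
    return run_depletion_experiment(RunConfig(seed=1234), 0.5, seed=1234)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
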