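import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")

from copdreadmit import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    """A 300-patient synthetic cohort shared across fast tests."""
    return simulate_cohort(SimulationConfig(n_patients=300, seed=7))


@pytest.fixture(scope="session")
def trained_run():
    """One full pipeline run on a small cohort, shared across tests."""
    from copdreadmit import RunConfig, run_all
    return run_all(RunConfig(seed=11, n_patients=400))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
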