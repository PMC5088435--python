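import numpy as np
import pytest

from dynaprof.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """12 synthetic patients with rounds already assigned by the generator."""
    cohort, _ = simulate_cohort(SimulationConfig(n_patients=12, seed=11))
    return cohort


@pytest.fixture(scope="session")
def medium_cohort():
    """27-patient cohort at the default study conditions."""
    cohort, truth = simulate_cohort(SimulationConfig(n_patients=27, seed=5))
    return cohort, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
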