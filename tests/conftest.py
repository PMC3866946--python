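import numpy as np
import pytest

from endoscore.simulate import SimulationConfig, generate


@pytest.fixture(scope="session")
def small_cohort():
    """A 400-patient simulated cohort shared across tests."""
    return generate(SimulationConfig(n_patients=400, seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(20260903)
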