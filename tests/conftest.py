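import numpy as np
import pytest
from hypothesis import settings

from fcreg import SimulationScenario, build_basis, generate_dataset

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_dataset():
    """A small generated dataset shared by fitting tests."""
    scenario = SimulationScenario(n_subjects=40, m_range=(15, 25), n_test=10)
    return generate_dataset(scenario, np.random.SeedSequence(2024))


@pytest.fixture(scope="session")
def unit_basis():
    """Cubic basis with 6 interior knots on [0, 1] (c = 10)."""
    return build_basis(np.linspace(0.0, 1.0, 101), n_interior=6, order=4)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
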