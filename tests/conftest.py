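import numpy as np
import pytest
from hypothesis import settings

from cetsakit import GridSpec, SyntheticSpec, TemperatureGradient

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def gradient() -> TemperatureGradient:
    return TemperatureGradient.tmt10()


@pytest.fixture
def small_spec() -> SyntheticSpec:
    """A fast, fully-featured synthetic design for unit tests."""
    return SyntheticSpec(n_proteins=30, n_replicates=3, target_fraction=0.2,
                         noise_cv=0.05, seed=11)


@pytest.fixture(scope="session")
def coarse_grid() -> GridSpec:
    """A reduced grid for tests that exercise fitting logic, not resolution."""
    return GridSpec(midpoint_range=(40.0, 70.0), midpoint_step=1.0,
                    slope_range=(0.5, 6.0), n_slopes=8,
                    plateau_range=(0.0, 0.4), plateau_step=0.1)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
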