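import numpy as np
import pytest

from mitgan.forward import build_sensitivity
from mitgan.geometry import build_coil_array, build_grid


@pytest.fixture(scope="session")
def full_grid():
    """The standard 67x67 / 3409-pixel imaging grid."""
    return build_grid(67, 0.1)


@pytest.fixture(scope="session")
def coils():
    return build_coil_array()


@pytest.fixture(scope="session")
def full_model(full_grid, coils):
    return build_sensitivity(full_grid, coils)


@pytest.fixture(scope="session")
def small_grid():
    """A coarse grid for fast dataset/training tests."""
    return build_grid(21, 0.1)


@pytest.fixture(scope="session")
def small_model(small_grid, coils):
    return build_sensitivity(small_grid, coils)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
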