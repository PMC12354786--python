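import numpy as np
import pytest

from wallmech.fivebeam import FiveBeamParams, simulate_cyclic, simulate_monotonic
from wallmech.synthetic import GeneratorProfile

LAMBDA_GRID = np.linspace(1.0, 1.5, 251)
CYCLIC_PEAKS = [1.1, 1.2, 1.3, 1.4, 1.5]


@pytest.fixture(scope="session")
def default_params():
    return FiveBeamParams()


@pytest.fixture(scope="session")
def fivebeam_monotonic(default_params):
    """Default five-beam monotonic response, shared across the suite."""
    curve, states = simulate_monotonic(default_params, LAMBDA_GRID)
    return curve, states


@pytest.fixture(scope="session")
def fivebeam_cyclic(default_params):
    """Default five-beam incremental cyclic response."""
    return simulate_cyclic(default_params, CYCLIC_PEAKS)


@pytest.fixture()
def noise_free_profile():
    return GeneratorProfile(noise_sd_force=0.0, noise_sd_stretch=0.0, seed=1)
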