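import numpy as np
import pytest

from transgrad import SimulationConfig, make_parcellation, simulate_smooth_map


@pytest.fixture(scope="session")
def meta68():
    """Default 68-region (34 per hemisphere) synthetic parcellation."""
    return make_parcellation(SimulationConfig())


@pytest.fixture(scope="session")
def meta20():
    """Small 20-region parcellation for cheap model tests."""
    return make_parcellation(SimulationConfig(n_regions_per_hemisphere=10))


@pytest.fixture()
def smooth_map68(meta68):
    return simulate_smooth_map(meta68, 0.6, seed=12345)
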