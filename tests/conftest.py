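import numpy as np
import pytest

from effconn.rate import RateModelParams


@pytest.fixture(scope="session")
def osc_params():
    """Single delayed-inhibition unit in a robust oscillatory regime."""
    return RateModelParams(n_areas=1, i0=1.0, k_local=20.0, d_local=1.0,
                           d_cross=0.5, dt=0.01, duration=200.0)


@pytest.fixture(scope="session")
def two_area_weak():
    """Two-area motif in the symmetry-broken out-of-phase regime."""
    return RateModelParams(n_areas=2, i0=1.0, k_local=20.0, k_cross=0.1,
                           d_local=1.0, d_cross=0.5, dt=0.01, duration=600.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
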