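import numpy as np
import pytest

from mexmri import NoiseModel, RAT_SCHEDULE, make_phantom, simulate_series


@pytest.fixture
def homogeneous_series():
    """Noiseless 24x24 single-slice series with known uniform truth."""
    phantom = make_phantom(
        "homogeneous", (24, 24, 1), seed=0, F=0.08, T1=1500.0, tau=20.0
    )
    return simulate_series(phantom, RAT_SCHEDULE, NoiseModel()), phantom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
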