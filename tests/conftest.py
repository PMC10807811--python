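import numpy as np
import pytest

from nvtension import (
    MonteCarloConfig,
    PolymerParams,
    default_calibration,
    default_physics,
)


@pytest.fixture(scope="session")
def physics():
    """Sensor constants calibrated to the default 391/795 us anchors."""
    return default_physics()


@pytest.fixture(scope="session")
def calibration():
    """Default analytic height -> T1 calibration table (0.3-6 nm)."""
    return default_calibration()


@pytest.fixture(scope="session")
def mc_config():
    return MonteCarloConfig()


@pytest.fixture(scope="session")
def polymer():
    return PolymerParams()


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)
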