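import numpy as np
import pytest

from wntgrad.models import ChannelGeometry, ErfcFitResult, FlowParams, ResponseModel


@pytest.fixture
def geometry():
    return ChannelGeometry()


@pytest.fixture
def small_geometry():
    """Short channel (4 grooves) to keep image-based tests fast."""
    return ChannelGeometry(length_um=2000.0, n_grooves=4)


@pytest.fixture
def flow(geometry):
    return FlowParams.from_flow_rate(2.0, geometry)


@pytest.fixture
def device_fit():
    """Reference profile used across tests: (c_max, c_min, alpha, beta)."""
    return ErfcFitResult(c_max=1.0, c_min=0.0, alpha_um=450.0, beta_um=120.0)


@pytest.fixture
def response():
    return ResponseModel()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
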