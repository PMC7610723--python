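import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from minsted import EPSFModel, LocalizerParams, PhotonScene  # noqa: E402


@pytest.fixture
def model():
    """775 nm STED beam through a 1.4 NA objective (d0 ~ 276.8 nm)."""
    return EPSFModel(lambda_sted=775.0, numerical_aperture=1.4)


@pytest.fixture
def params():
    """Standard homing-in schedule: alpha=0.15, gamma=0.97, R/d=0.5, d_min=40."""
    return LocalizerParams()


@pytest.fixture
def scene():
    """Single emitter at the origin, SBR 20, 60 nm starting offset."""
    return PhotonScene(r_FL=(0.0, 0.0), sbr=20.0, sigma0=60.0, seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
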