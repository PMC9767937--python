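import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import scotomap as sm

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def hrf():
    return sm.HRFSpec()


@pytest.fixture(scope="session")
def movie():
    """Default drifting-bar run (136 frames, 101 px raster)."""
    return sm.make_lcr_movie()


@pytest.fixture(scope="session")
def small_movie():
    """Coarse-raster run for fast forward-model and cohort tests."""
    return sm.make_lcr_movie(shape=(41, 41))


@pytest.fixture(scope="session")
def ff_aperture(movie):
    return sm.effective_aperture(movie, "FF")


@pytest.fixture(scope="session")
def small_aperture(small_movie):
    return sm.effective_aperture(small_movie, "FF")


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
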