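import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ocutilt import CameraModel

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def camera() -> CameraModel:
    """The default 720p pinhole camera used throughout."""
    return CameraModel()


@pytest.fixture(scope="session")
def small_camera() -> CameraModel:
    """A quarter-size camera for render-heavy Monte-Carlo tests."""
    return CameraModel(image_width=640, image_height=360, focal_length=500.0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
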