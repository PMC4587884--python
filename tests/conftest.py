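import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from paradigmflow import QuarticLandscape, critical_points
from paradigmflow.dynamics import DynamicsParams

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def landscape() -> QuarticLandscape:
    """The default double-hill landscape."""
    return QuarticLandscape()


@pytest.fixture(scope="session")
def cp(landscape):
    return critical_points(landscape)


@pytest.fixture()
def params() -> DynamicsParams:
    return DynamicsParams()


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
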