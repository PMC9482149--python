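import pytest
from hypothesis import settings

import conchvision as cv

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cfg() -> cv.ViewingConfig:
    """Default viewing geometry: 50 mm distance, 0.25 mm pixels, 256x256."""
    return cv.ViewingConfig()


@pytest.fixture(scope="session")
def display() -> cv.DisplayModel:
    return cv.DisplayModel(gamma=1.0)


@pytest.fixture(scope="session")
def linear_profile() -> cv.ExpansionProfile:
    """The fast 5 s linear expansion of the resolution experiment."""
    return cv.ExpansionProfile(shape="linear", duration_s=5.0, alpha_max_deg=83.0)


@pytest.fixture(scope="session")
def exp_profile() -> cv.ExpansionProfile:
    """The slow 10 s exponential expansion of the contrast experiment."""
    return cv.ExpansionProfile(
        shape="exponential", duration_s=10.0, alpha_max_deg=83.0, alpha_start_deg=0.1
    )
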