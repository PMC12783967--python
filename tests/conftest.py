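import dataclasses

import pytest
from hypothesis import HealthCheck, settings

import rodnoise as rn

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def wt():
    return rn.get_preset("WT", "PM3")


@pytest.fixture(scope="session")
def ko():
    return rn.get_preset("GARP2KO", "PM3")


@pytest.fixture(scope="session")
def ko_pm9():
    """Preset carrying the two-component ROS length mixture."""
    return rn.get_preset("GARP2KO", "PM9")


@pytest.fixture(scope="session")
def quiet_config():
    """Noise-free flash acquisition settings."""
    return dataclasses.replace(rn.SimulationConfig(), flash_noise_sd=0.0)


@pytest.fixture(scope="session")
def short_dark_config():
    """Shorter dark epochs for Monte-Carlo loops."""
    return dataclasses.replace(
        rn.SimulationConfig(), dark_duration=20.0, saturated_duration=15.0
    )
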