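import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20221128)


@pytest.fixture
def montage29():
    from eegfc import default_montage
    return default_montage()


@pytest.fixture
def tiny_recording(rng):
    """0.5 min of 4-channel white noise at 500 Hz."""
    from eegfc import Recording
    return Recording(labels=("A", "B", "C", "D"), sampling_rate=500.0,
                     data=rng.standard_normal((4, 15_000)), stage=1)
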