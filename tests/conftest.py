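import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def sensor_array():
    from rcfdose.moem_sensor import dosimoems_v1

    return dosimoems_v1()


@pytest.fixture(scope="session")
def quiet_array(sensor_array):
    """The default array with all stochastic read noise switched off."""
    import dataclasses

    return dataclasses.replace(sensor_array, glitch_sigma=0.0)


@pytest.fixture
def uniform_odmap():
    from rcfdose.film_model import ODMap

    def make(netod: float, size_mm: float = 30.0, pitch: float = 0.25):
        n = int(round(size_mm / pitch))
        return ODMap(np.full((n, n), netod), pitch)

    return make
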