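import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from legsearch import LegGeometry, default_config


@pytest.fixture(scope="session")
def geom():
    return LegGeometry(13.0, 12.0)


@pytest.fixture()
def config():
    return default_config()


@pytest.fixture(scope="session")
def equal_geom():
    return LegGeometry(10.0, 10.0)


@pytest.fixture(scope="session")
def sine_trace():
    """1 Hz sine sampled at 2 ms for 10 s: t_ms, x arrays."""
    t = np.arange(0.0, 10_000.0, 2.0)
    return t, 10.0 + 15.0 * np.sin(2 * np.pi * t / 1000.0)
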