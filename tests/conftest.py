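import datetime as dt

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from gaitbelt.gait_speed import GaitSpeedMeasurement

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20190107)


@pytest.fixture
def make_measurement():
    """Factory for bout-level measurements with sensible defaults."""

    def factory(timestamp=dt.datetime(2019, 1, 7, 10, 0), speed=1.2,
                duration=60.0, pid="p1", n_steps=100):
        return GaitSpeedMeasurement(
            participant_id=pid, timestamp=timestamp, speed=speed,
            duration=duration, n_steps=n_steps,
        )

    return factory
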