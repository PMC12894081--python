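import numpy as np
import pytest

from mmscoord import (AngleSeries, CourseSpec, Segment, build_course,
                      canonical_face_model, default_camera, simulate_drive)


@pytest.fixture(scope="session")
def face_model():
    return canonical_face_model()


@pytest.fixture(scope="session")
def camera():
    return default_camera()


@pytest.fixture(scope="session")
def long_slalom():
    """A 100 m slalom stretch: ~100 s of periodic steering at 1 m/s."""
    return CourseSpec("long_slalom", (Segment("slalom", 100.0),))


@pytest.fixture(scope="session")
def slalom_drive(long_slalom):
    return simulate_drive(long_slalom, speed=1.0, rate=10.0)


def sine_series(period_s: float, duration_s: float, rate: float,
                phase_s: float = 0.0, amp: float = 20.0,
                channel: str = "steering") -> AngleSeries:
    t = np.arange(int(round(duration_s * rate))) / rate
    return AngleSeries(t, amp * np.sin(2 * np.pi * (t + phase_s) / period_s),
                       rate, channel)
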