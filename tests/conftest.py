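import numpy as np
import pytest

from pupildeconv import PupilRecording


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_recording(diameter, rate_hz=60.0, confidence=None, gaze=None, t0=0.0):
    """Recording on a uniform grid from a diameter array."""
    diameter = np.asarray(diameter, dtype=float)
    n = diameter.size
    time = t0 + np.arange(n) / rate_hz
    conf = np.ones(n) if confidence is None else np.asarray(confidence, float)
    gx = np.zeros(n) if gaze is None else np.asarray(gaze[0], float)
    gy = np.zeros(n) if gaze is None else np.asarray(gaze[1], float)
    return PupilRecording(time=time, diameter=diameter, gaze_x=gx, gaze_y=gy,
                         confidence=conf, rate_hz=rate_hz)


@pytest.fixture
def flat_recording():
    return make_recording(np.full(600, 3.0))
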