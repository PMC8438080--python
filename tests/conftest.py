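import numpy as np
import pytest

from observa.containers import GazeRecording
from observa.synthetic import SimProfile, gen_display_spec


@pytest.fixture(scope="session")
def display():
    return gen_display_spec(condition="efficient")


@pytest.fixture(scope="session")
def display_small():
    """Quarter-resolution display for cheap pixel-level tests."""
    return gen_display_spec(resolution=(480, 300), condition="efficient")


@pytest.fixture(scope="session")
def adult_profile():
    return SimProfile.adult_like()


@pytest.fixture(scope="session")
def child_profile():
    return SimProfile.child_like()


def make_recording(t, x, y, pupil=None, valid=None, condition="efficient",
                   participant="p0", trial=0):
    t = np.asarray(t, float)
    n = t.size
    return GazeRecording(
        participant_id=participant, trial_id=trial, condition=condition,
        t=t, x=np.asarray(x, float), y=np.asarray(y, float),
        pupil=np.full(n, 4.0) if pupil is None else np.asarray(pupil, float),
        valid=np.ones(n, bool) if valid is None else np.asarray(valid, bool),
    )


@pytest.fixture
def recording_factory():
    return make_recording
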