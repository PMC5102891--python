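import numpy as np
import pytest

from lamsync import RecordingSession, SynthConfig, generate_recording


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_session(rng):
    """2-channel, 1 kHz, 1 s session with integer-µV samples (so EDF
    round-trips are exact)."""
    sig = np.round(rng.normal(0.0, 40.0, (2, 1000)))
    return RecordingSession(signal=sig, sample_rate=1000.0,
                            group="control", isoflurane_pct=1.0,
                            animal_id="m1", session_id="s1")


@pytest.fixture
def bs_recording():
    """One minute of 16-channel burst/suppression with ground truth."""
    cfg = SynthConfig(state_schedule=(("burst_suppression", 60.0),))
    return generate_recording(cfg, seed=7)
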