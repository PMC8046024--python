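import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import speechdpoae as sd

settings.register_profile(
    "deterministic",
    derandomize=True,
    database=None,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def male_kit():
    """20-s male-voice synthetic speech with pitch, w0, eliciting pair, template."""
    spec = sd.SpeechLikeSpec(duration_s=20.0, seed=3)
    speech, track = sd.synth_speechlike(spec)
    w0 = sd.extract_fundamental(speech, track)
    return {
        "spec": spec,
        "speech": speech,
        "track": track,
        "w0": w0,
        "w9": sd.harmonic(w0, 9),
        "w11": sd.harmonic(w0, 11),
        "t7": sd.distortion_template(9, 11, w0, "lower"),
    }


@pytest.fixture(scope="session")
def tone_w0():
    """A 150-Hz tone wrapped as a fundamental waveform (bin-centered, 1 s)."""
    fs = 44100.0
    t = np.arange(int(fs)) / fs
    return sd.FundamentalWaveform(
        samples=0.7 * np.cos(2 * np.pi * 150.0 * t),
        rate_hz=fs,
        passband_hz=(145.0, 155.0),
    )
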