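import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import beatsync as bs

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def stim120():
    """Full-length study stimulus: 128 beats at 120 BPM."""
    return bs.generate_beat_onsets(120.0, 128)


@pytest.fixture(scope="session")
def short_stim():
    """Short stimulus for fast unit tests: 40 beats at 120 BPM (20 s)."""
    return bs.generate_beat_onsets(120.0, 40)


@pytest.fixture(scope="session")
def locked_trial(stim120):
    """Perfectly phase-locked single-marker trial (zero phase noise, no startup)."""
    params = bs.BounceParams(
        mean_lag_rad=0.0, phase_noise_sd=0.0, startup_s=0.0,
        noise_mm=0.5, n_markers=1, seed=42,
    )
    return bs.simulate_bounce_trial(params, stim120)


@pytest.fixture(scope="session")
def full_body_trial(short_stim):
    """Default 28-marker trial on a short stimulus."""
    params = bs.BounceParams(seed=7)
    return bs.simulate_bounce_trial(params, short_stim)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
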