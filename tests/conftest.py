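import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import scgkit as sk

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def rest_session():
    """A 300 s resting session (HR 76 bpm, RR 20 brpm) with mild noise."""
    cfg = sk.SimulationConfig(
        duration_s=300.0, heart_rate_bpm=76.0, resp_rate_brpm=20.0, seed=42
    )
    trace, truth = sk.simulate_chest_acceleration(cfg)
    return cfg, trace, truth


@pytest.fixture(scope="session")
def clean_60bpm_session():
    """Noiseless, jitter-free 60 s session at exactly 60 bpm / 12 brpm."""
    cfg = sk.SimulationConfig(
        duration_s=60.0,
        heart_rate_bpm=60.0,
        resp_rate_brpm=12.0,
        rate_jitter_frac=0.0,
        noise_sd=0.0,
        seed=1,
    )
    trace, truth = sk.simulate_chest_acceleration(cfg)
    return cfg, trace, truth


def make_rate_series(rates, kind="heartbeat", valid=None, hop=10.0):
    rates = np.asarray(rates, dtype=float)
    centers = 30.0 + hop * np.arange(rates.size)
    if valid is None:
        valid = np.ones(rates.size, dtype=bool)
    return sk.RateSeries(centers, rates, valid, window_length_s=60.0, kind=kind)
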