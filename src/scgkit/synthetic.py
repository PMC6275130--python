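"""Synthetic chest-acceleration (SCG) generator with known ground truth.

The chest-wall acceleration measured by a sternum accelerometer is modelled
as an additive superposition

    a_T(t) = a_L(t) + a_H(t) + noise

where ``a_L`` is a slow, large-amplitude respiratory oscillation (a sinusoid
at the breathing frequency, optionally with a few harmonics) and ``a_H`` is
a fast, small-amplitude cardiac component (a train of Gaussian-windowed
cosine wavelets, one per heartbeat).  The generator records every beat and
breath time so downstream rate estimators can be scored against truth.

Amplitude ordering follows physiology: the respiratory acceleration is
larger and slower than the cardiac one (default ratio 10:1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import AccelerationTrace, InvalidConfigError

__all__ = ["SimulationConfig", "GroundTruth", "simulate_chest_acceleration"]

#: High-pass/low-pass split frequency the simulator must respect so that
#: cardiac energy lands in the high band and respiratory energy in the low
#: band (matches the band-separation default cutoff).
DEFAULT_BAND_SPLIT_HZ = 0.5


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated recording session.

    Defaults reproduce a resting adult measured at 50 samples/s for 600 s:
    heart rate 76 beats/min, respiration 20 breaths/min, respiratory
    amplitude 10x the cardiac amplitude, 2% cycle-to-cycle period jitter
    and additive white Gaussian sensor noise at 20% of the cardiac
    amplitude.
    """

    duration_s: float = 600.0
    sampling_rate_hz: float = 50.0
    heart_rate_bpm: float = 76.0
    resp_rate_brpm: float = 20.0
    cardiac_amplitude: float = 0.1
    resp_amplitude: float = 1.0
    cardiac_wavelet_freq_hz: float = 15.0
    cardiac_wavelet_width_s: float = 0.08
    rate_jitter_frac: float = 0.02
    noise_sd: float = 0.02
    resp_harmonics: int = 1
    seed: int = 0

    def validate(self, band_split_hz: float = DEFAULT_BAND_SPLIT_HZ) -> None:
        """Raise :class:`InvalidConfigError` on any violated constraint."""
        if not (self.duration_s > 0):
            raise InvalidConfigError(f"duration_s must be > 0, got {self.duration_s}")
        if not (self.sampling_rate_hz > 0):
            raise InvalidConfigError(
                f"sampling_rate_hz must be > 0, got {self.sampling_rate_hz}"
            )
        if not (30.0 <= self.heart_rate_bpm <= 220.0):
            raise InvalidConfigError(
                f"heart_rate_bpm must lie in [30, 220], got {self.heart_rate_bpm}"
            )
        if not (2.0 <= self.resp_rate_brpm <= 60.0):
            raise InvalidConfigError(
                f"resp_rate_brpm must lie in [2, 60], got {self.resp_rate_brpm}"
            )
        if self.cardiac_amplitude < 0 or self.resp_amplitude < 0:
            raise InvalidConfigError("amplitudes must be >= 0")
        if not (0.0 <= self.rate_jitter_frac <= 0.5):
            raise InvalidConfigError(
                f"rate_jitter_frac must lie in [0, 0.5], got {self.rate_jitter_frac}"
            )
        if self.noise_sd < 0:
            raise InvalidConfigError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if not (1 <= int(self.resp_harmonics) <= 3):
            raise InvalidConfigError("resp_harmonics must be 1, 2 or 3")
        # Band-overlap constraints: the two components must be separable by
        # the downstream split frequency.
        if not (self.cardiac_wavelet_freq_hz > band_split_hz):
            raise InvalidConfigError(
                "cardiac_wavelet_freq_hz "
                f"({self.cardiac_wavelet_freq_hz} Hz) must exceed the band "
                f"split frequency ({band_split_hz} Hz)"
            )
        top_resp_hz = int(self.resp_harmonics) * self.resp_rate_brpm / 60.0
        if top_resp_hz > band_split_hz:
            raise InvalidConfigError(
                f"respiratory frequency content ({top_resp_hz:.3f} Hz) must "
                f"not exceed the band split frequency ({band_split_hz} Hz)"
            )
        if self.cardiac_wavelet_freq_hz >= self.sampling_rate_hz / 2:
            raise InvalidConfigError(
                "cardiac_wavelet_freq_hz must be below Nyquist "
                f"({self.sampling_rate_hz / 2} Hz)"
            )
        if not (self.cardiac_wavelet_width_s > 0):
            raise InvalidConfigError("cardiac_wavelet_width_s must be > 0")


@dataclass(frozen=True)
class GroundTruth:
    """Event bookkeeping of a simulated session for recovery tests."""

    beat_times_s: np.ndarray
    breath_times_s: np.ndarray
    true_hr_bpm: float
    true_rr_brpm: float

    def __post_init__(self) -> None:
        for name in ("beat_times_s", "breath_times_s"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.size and np.any(np.diff(arr) <= 0):
                raise InvalidConfigError(f"{name} must be strictly increasing")
            object.__setattr__(self, name, arr)


def _event_schedule(
    rng: np.random.Generator,
    period_s: float,
    jitter_frac: float,
    duration_s: float,
) -> np.ndarray:
    """Event times with inter-event periods ``period * (1 + u)``,
    u ~ Uniform(-jitter_frac, +jitter_frac); first event half a (jittered)
    period after t=0, so a duration of k periods holds exactly k events."""
    times = []
    t = 0.5 * period_s * (
        1.0 + (rng.uniform(-jitter_frac, jitter_frac) if jitter_frac else 0.0)
    )
    while t < duration_s:
        times.append(t)
        step = period_s
        if jitter_frac:
            step *= 1.0 + rng.uniform(-jitter_frac, jitter_frac)
        t += step
    return np.asarray(times)


def simulate_chest_acceleration(
    config: SimulationConfig,
    band_split_hz: float = DEFAULT_BAND_SPLIT_HZ,
) -> tuple[AccelerationTrace, GroundTruth]:
    """Simulate one chest-acceleration session.

    The trace is the sum of a respiratory sinusoid (plus optional decaying
    harmonics), a cardiac train of Gaussian-windowed cosine wavelets centred
    at the recorded beat times, and white Gaussian noise.  Identical config
    (including seed) gives bit-identical output: the single seeded generator
    draws the beat jitter first and the noise second, independently of the
    amplitudes, so zeroing an amplitude never changes the event schedule.

    Returns
    -------
    (AccelerationTrace, GroundTruth)
    """
    config.validate(band_split_hz)
    rng = np.random.default_rng(config.seed)

    n = int(round(config.duration_s * config.sampling_rate_hz))
    t = np.arange(n) / config.sampling_rate_hz

    # Cardiac schedule (drawn unconditionally: keeps superposition exact).
    beat_period = 60.0 / config.heart_rate_bpm
    beat_times = _event_schedule(
        rng, beat_period, config.rate_jitter_frac, config.duration_s
    )

    # Respiratory component: sinusoid (harmonic k scaled by 1/k^2); breath
    # "events" are the maxima of the fundamental.
    f_resp = config.resp_rate_brpm / 60.0
    resp = np.zeros(n)
    for k in range(1, int(config.resp_harmonics) + 1):
        resp += np.sin(2.0 * np.pi * k * f_resp * t) / k**2
    resp *= config.resp_amplitude
    breath_times = np.arange(0.25 / f_resp, config.duration_s, 1.0 / f_resp)

    # Cardiac component: Gaussian envelope * cosine, maximum exactly at the
    # beat time so peak detection can be scored against the schedule.
    cardiac = np.zeros(n)
    sigma = config.cardiac_wavelet_width_s
    half_support = 4.0 * sigma
    fs = config.sampling_rate_hz
    for tk in beat_times:
        i0 = max(0, int(np.ceil((tk - half_support) * fs)))
        i1 = min(n, int(np.floor((tk + half_support) * fs)) + 1)
        tt = t[i0:i1] - tk
        cardiac[i0:i1] += np.exp(-0.5 * (tt / sigma) ** 2) * np.cos(
            2.0 * np.pi * config.cardiac_wavelet_freq_hz * tt
        )
    cardiac *= config.cardiac_amplitude

    noise = rng.normal(0.0, config.noise_sd, n) if config.noise_sd > 0 else 0.0

    trace = AccelerationTrace(
        samples=resp + cardiac + noise, sampling_rate_hz=config.sampling_rate_hz
    )
    truth = GroundTruth(
        beat_times_s=beat_times,
        breath_times_s=breath_times,
        true_hr_bpm=config.heart_rate_bpm,
        true_rr_brpm=config.resp_rate_brpm,
    )
    return trace, truth
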