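"""Shared containers and error types for the chest-acceleration toolkit.

Everything downstream (filtering, rate estimation, health scoring) passes
uniformly sampled single-axis acceleration around as an
:class:`AccelerationTrace`.  Amplitudes are unit-agnostic ("accel units"):
the processing chain is scale-invariant, so no g vs m/s² commitment is made.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ScgError",
    "InvalidConfigError",
    "InvalidTraceError",
    "InvalidInputError",
    "InsufficientDataError",
    "NoValidDataError",
    "FilterDesignError",
    "PipelineStageError",
    "AccelerationTrace",
    "HEART_RATE_BOUNDS_BPM",
    "RESP_RATE_BOUNDS_BRPM",
]

# Physiological validity ceilings/floors used for rate sanity flags and
# detector refractory defaults (220 bpm ceiling -> 0.27 s, 60 brpm -> 1 s).
HEART_RATE_BOUNDS_BPM = (30.0, 220.0)
RESP_RATE_BOUNDS_BRPM = (2.0, 60.0)


class ScgError(Exception):
    """Base class for all toolkit errors."""


class InvalidConfigError(ScgError, ValueError):
    """A configuration value violates its documented constraint."""


class InvalidTraceError(ScgError, ValueError):
    """An acceleration trace is malformed (NaN/Inf, bad sampling rate)."""


class InvalidInputError(ScgError, ValueError):
    """Mismatched or malformed operation inputs."""


class InsufficientDataError(ScgError, ValueError):
    """Too few samples/windows/pairs for the requested statistic."""


class NoValidDataError(ScgError, ValueError):
    """Every window of a rate series is flagged invalid."""


class FilterDesignError(ScgError, ValueError):
    """Filter specification cannot be realized (e.g. cutoff >= Nyquist)."""


class PipelineStageError(ScgError, RuntimeError):
    """Wraps a stage failure inside the end-to-end pipeline.

    Carries the stage name so callers (and the CLI) can attribute the
    failure without parsing messages.
    """

    def __init__(self, stage: str, original: Exception):
        self.stage = stage
        self.original = original
        super().__init__(f"stage '{stage}': {original}")


@dataclass(frozen=True)
class AccelerationTrace:
    """Uniformly sampled single-axis chest acceleration.

    Parameters
    ----------
    samples
        Acceleration values (unit-agnostic), one per sample.
    sampling_rate_hz
        Sampling frequency in Hz; must be positive.
    start_time_s
        Time of the first sample, seconds.
    """

    samples: np.ndarray
    sampling_rate_hz: float
    start_time_s: float = 0.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples, dtype=float)
        if arr.ndim != 1:
            raise InvalidTraceError(
                f"trace must be 1-D, got shape {arr.shape}"
            )
        if not np.all(np.isfinite(arr)):
            bad = int(np.flatnonzero(~np.isfinite(arr))[0])
            raise InvalidTraceError(
                f"trace contains non-finite sample at index {bad}"
            )
        if not (self.sampling_rate_hz > 0):
            raise InvalidTraceError(
                f"sampling_rate_hz must be > 0, got {self.sampling_rate_hz}"
            )
        object.__setattr__(self, "samples", arr)

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        """Duration covered by the samples (n / fs)."""
        return self.n_samples / self.sampling_rate_hz

    def times(self) -> np.ndarray:
        """Sample timestamps in seconds."""
        return self.start_time_s + np.arange(self.n_samples) / self.sampling_rate_hz
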