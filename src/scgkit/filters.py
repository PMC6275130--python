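"""Butterworth band separation of chest acceleration.

The raw trace a_T is split into a cardiac component a_H (high-pass) and a
respiratory component a_L (low-pass) with second-order Butterworth filters
sharing a 0.5 Hz cutoff by default.  At 50 Hz sampling, 0.5 Hz corresponds
to the normalised value 0.01 under the sampling-rate convention (0.02 under
the Nyquist convention scipy uses); filters are always designed from the
physical cutoff in Hz, and both conventions are exposed read-only through
:func:`normalized_cutoff`.

Offline processing defaults to forward-backward (zero-phase) filtering,
which squares the magnitude response and preserves peak timing — rate
estimation depends on that.  A single-pass causal mode is available for
streaming parity; its group delay is not compensated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .core import (
    AccelerationTrace,
    FilterDesignError,
    InsufficientDataError,
    InvalidTraceError,
)

__all__ = [
    "FilterSpec",
    "BandSeparatedSignal",
    "normalized_cutoff",
    "design_butterworth",
    "separate_bands",
]

#: Seconds flagged as filter settling transient at each end of the record.
EDGE_TRANSIENT_S = 5.0


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth design parameters for the band split.

    ``cutoff_hz`` applies to both the high-pass and the low-pass unless
    ``lowpass_cutoff_hz`` overrides the latter.
    """

    order: int = 2
    cutoff_hz: float = 0.5
    mode: str = "zero_phase_offline"  # or "causal_streaming"
    normalization_convention: str = "sampling_rate"  # or "nyquist"
    lowpass_cutoff_hz: float | None = None

    def __post_init__(self) -> None:
        if not (isinstance(self.order, (int, np.integer)) and self.order >= 1):
            raise FilterDesignError(f"order must be a positive integer, got {self.order}")
        if not (self.cutoff_hz > 0):
            raise FilterDesignError(f"cutoff_hz must be > 0, got {self.cutoff_hz}")
        if self.mode not in ("zero_phase_offline", "causal_streaming"):
            raise FilterDesignError(f"unknown mode {self.mode!r}")
        if self.normalization_convention not in ("sampling_rate", "nyquist"):
            raise FilterDesignError(
                f"unknown normalization convention {self.normalization_convention!r}"
            )
        if self.lowpass_cutoff_hz is not None and not (self.lowpass_cutoff_hz > 0):
            raise FilterDesignError("lowpass_cutoff_hz must be > 0")

    @property
    def effective_lowpass_cutoff_hz(self) -> float:
        return self.cutoff_hz if self.lowpass_cutoff_hz is None else self.lowpass_cutoff_hz


@dataclass(frozen=True)
class BandSeparatedSignal:
    """Cardiac (a_H) and respiratory (a_L) components of one trace."""

    cardiac: AccelerationTrace
    respiratory: AccelerationTrace
    filter_spec: FilterSpec
    #: samples within this many seconds of either end sit inside the filter
    #: settling transient; downstream windows treat them as unreliable.
    edge_transient_s: float = EDGE_TRANSIENT_S

    def __post_init__(self) -> None:
        if self.cardiac.n_samples != self.respiratory.n_samples:
            raise InvalidTraceError("component lengths differ")
        if self.cardiac.sampling_rate_hz != self.respiratory.sampling_rate_hz:
            raise InvalidTraceError("component sampling rates differ")


def normalized_cutoff(
    cutoff_hz: float, sampling_rate_hz: float, convention: str = "sampling_rate"
) -> float:
    """Cutoff as a dimensionless fraction of a reference frequency.

    ``sampling_rate`` divides by fs (0.5 Hz at 50 Hz -> 0.01); ``nyquist``
    divides by fs/2 (-> 0.02), the convention digital-filter routines use.
    """
    if convention not in ("sampling_rate", "nyquist"):
        raise FilterDesignError(f"unknown normalization convention {convention!r}")
    if not (0 < cutoff_hz < sampling_rate_hz / 2):
        raise FilterDesignError(
            f"cutoff {cutoff_hz} Hz must lie in (0, Nyquist={sampling_rate_hz / 2} Hz)"
        )
    ref = sampling_rate_hz if convention == "sampling_rate" else sampling_rate_hz / 2
    return cutoff_hz / ref


def design_butterworth(
    spec: FilterSpec, kind: str, sampling_rate_hz: float
) -> tuple[np.ndarray, np.ndarray]:
    """Digital Butterworth coefficients (b, a) for ``kind`` in
    {"lowpass", "highpass"} at the spec's physical cutoff.

    Raises :class:`FilterDesignError` if the design is unstable or the
    cutoff is not below Nyquist.
    """
    if kind not in ("lowpass", "highpass"):
        raise FilterDesignError(f"kind must be 'lowpass' or 'highpass', got {kind!r}")
    cutoff = spec.effective_lowpass_cutoff_hz if kind == "lowpass" else spec.cutoff_hz
    # validates 0 < cutoff < Nyquist
    wn = normalized_cutoff(cutoff, sampling_rate_hz, "nyquist")
    b, a = sps.butter(spec.order, wn, btype=kind)
    poles = np.roots(a)
    if np.any(np.abs(poles) >= 1.0 + 1e-12):
        raise FilterDesignError(
            f"unstable {kind} design (order {spec.order}, cutoff {cutoff} Hz "
            f"at fs {sampling_rate_hz} Hz)"
        )
    return b, a


def _apply(b: np.ndarray, a: np.ndarray, x: np.ndarray, mode: str) -> np.ndarray:
    if mode == "zero_phase_offline":
        return sps.filtfilt(b, a, x)
    return sps.lfilter(b, a, x)


def separate_bands(trace: AccelerationTrace, spec: FilterSpec | None = None) -> BandSeparatedSignal:
    """Split a trace into cardiac (high-pass) and respiratory (low-pass)
    components.

    In ``zero_phase_offline`` mode each filter runs forward and backward
    (zero phase lag, squared magnitude); ``causal_streaming`` applies a
    single causal pass.  The first and last :data:`EDGE_TRANSIENT_S` seconds
    are flagged, not removed.
    """
    if spec is None:
        spec = FilterSpec()
    x = trace.samples  # AccelerationTrace guarantees finite values
    if x.size < 10 * spec.order:
        raise InsufficientDataError(
            f"trace has {x.size} samples; need at least {10 * spec.order} "
            f"for an order-{spec.order} filter"
        )
    b_hi, a_hi = design_butterworth(spec, "highpass", trace.sampling_rate_hz)
    b_lo, a_lo = design_butterworth(spec, "lowpass", trace.sampling_rate_hz)
    cardiac = _apply(b_hi, a_hi, x, spec.mode)
    respiratory = _apply(b_lo, a_lo, x, spec.mode)
    mk = lambda y: AccelerationTrace(  # noqa: E731
        samples=y,
        sampling_rate_hz=trace.sampling_rate_hz,
        start_time_s=trace.start_time_s,
    )
    return BandSeparatedSignal(
        cardiac=mk(cardiac), respiratory=mk(respiratory), filter_spec=spec
    )
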