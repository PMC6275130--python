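"""Beat/breath peak detection and windowed rate estimation.

Peaks are local maxima that exceed ``threshold_k`` times a rolling (5 s)
standard deviation of the component and are separated by a physiological
refractory period (0.27 s for heartbeats = 220 bpm ceiling, 1.0 s for
breaths = 60 brpm ceiling).  Rates are computed per sliding window as
60 / median(inter-peak interval): a single missed or spurious peak corrupts
one interval but barely moves the median, which is why median-interval
estimation is preferred over peak counting.

Windows with fewer than two peaks, rates outside physiological bounds
(30-220 bpm, 2-60 brpm) or overlap with the filter settling transient are
carried with ``valid=False`` — never silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .core import (
    AccelerationTrace,
    HEART_RATE_BOUNDS_BPM,
    RESP_RATE_BOUNDS_BRPM,
    InvalidConfigError,
    NoValidDataError,
)

__all__ = [
    "PeakList",
    "RateSeries",
    "SessionSummary",
    "detect_peaks",
    "rate_from_peaks",
    "session_summary",
]

#: Per-kind detector defaults: (threshold_k, refractory_s).
#: The cardiac component is a sparse wavelet train, so its peaks stand well
#: above 1.5 rolling SDs; the respiratory component is a smooth oscillation
#: whose peak-to-SD ratio is only sqrt(2), so its threshold factor is lower.
DETECTOR_DEFAULTS: dict[str, tuple[float, float]] = {
    "heartbeat": (1.5, 0.27),
    "respiration": (0.5, 1.0),
}

ROLLING_STD_WINDOW_S = 5.0

#: zero-phase high-pass cutoff applied to the cardiac band before beat
#: detection; sits between the respiratory leak (<= 0.5 Hz) and the beat
#: wavelet energy (~15 Hz)
CARDIAC_CONDITIONING_HZ = 2.0
RATE_BOUNDS = {"heartbeat": HEART_RATE_BOUNDS_BPM, "respiration": RESP_RATE_BOUNDS_BRPM}


@dataclass(frozen=True)
class PeakList:
    """Detected event times/amplitudes plus the detector settings used."""

    peak_times_s: np.ndarray
    peak_amplitudes: np.ndarray
    kind: str
    threshold_k: float
    refractory_s: float

    def __post_init__(self) -> None:
        t = np.asarray(self.peak_times_s, dtype=float)
        a = np.asarray(self.peak_amplitudes, dtype=float)
        if t.size != a.size:
            raise InvalidConfigError("peak times and amplitudes differ in length")
        if t.size > 1 and np.any(np.diff(t) < self.refractory_s - 1e-9):
            raise InvalidConfigError("peaks closer than the refractory period")
        object.__setattr__(self, "peak_times_s", t)
        object.__setattr__(self, "peak_amplitudes", a)

    @property
    def n_peaks(self) -> int:
        return self.peak_times_s.size


@dataclass(frozen=True)
class RateSeries:
    """Per-window rate estimates in events/min with validity flags."""

    window_centers_s: np.ndarray
    rates: np.ndarray
    valid: np.ndarray
    window_length_s: float
    kind: str

    def __post_init__(self) -> None:
        for name, dtype in (("window_centers_s", float), ("rates", float), ("valid", bool)):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=dtype))
        if not (self.window_centers_s.size == self.rates.size == self.valid.size):
            raise InvalidConfigError("rate-series arrays differ in length")

    @property
    def valid_rates(self) -> np.ndarray:
        return self.rates[self.valid]

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())


@dataclass(frozen=True)
class SessionSummary:
    median: float
    mean: float
    n_valid: int
    n_invalid: int
    kind: str


def _check_kind(kind: str) -> None:
    if kind not in DETECTOR_DEFAULTS:
        raise InvalidConfigError(
            f"kind must be 'heartbeat' or 'respiration', got {kind!r}"
        )


def detect_peaks(
    component: AccelerationTrace,
    kind: str,
    threshold_k: float | None = None,
    refractory_s: float | None = None,
    amplitude_frac: float = 0.6,
) -> PeakList:
    """Detect beat/breath events in a band-separated component.

    Local maxima must exceed ``threshold_k`` x the rolling (5 s, centred)
    standard deviation at their location and be separated by at least
    ``refractory_s``; when peaks conflict the taller one wins.  On a flat
    plateau the earliest sample wins.  A flat or empty component yields an
    empty list, not an error.

    The cardiac band is first conditioned with a zero-phase second-order
    2 Hz high-pass: the 0.5 Hz band split leaves a residual of the much
    larger respiratory wave under the beat wavelets, and beat heights are
    only meaningful once that baseline is removed (beat wavelet energy sits
    far above 2 Hz, the leak far below).  The respiratory band *is* the
    slow signal, so it is detected as-is.

    A second pass drops surviving peaks whose height falls below
    ``amplitude_frac`` x the median detected height: beats (or breaths) of
    one physiological source share an amplitude scale, so isolated
    low-grade maxima are noise rather than events.  Set
    ``amplitude_frac=0`` to disable.
    """
    _check_kind(kind)
    k_def, refr_def = DETECTOR_DEFAULTS[kind]
    k = k_def if threshold_k is None else float(threshold_k)
    refractory = refr_def if refractory_s is None else float(refractory_s)
    if k < 0 or refractory <= 0:
        raise InvalidConfigError("threshold_k must be >= 0 and refractory_s > 0")

    x = component.samples
    fs = component.sampling_rate_hz
    if x.size < 3:
        return PeakList(np.empty(0), np.empty(0), kind, k, refractory)

    if kind == "heartbeat" and CARDIAC_CONDITIONING_HZ < fs / 2:
        b, a = sps.butter(2, CARDIAC_CONDITIONING_HZ / (fs / 2), "highpass")
        x = sps.filtfilt(b, a, x)

    distance = max(1, int(round(refractory * fs)))
    idx, props = sps.find_peaks(x, distance=distance, plateau_size=(1, None))
    # earliest-sample tie rule on plateaus
    idx = props.get("left_edges", idx)
    if idx.size > 1:
        # plateau left-shifting can re-violate the refractory spacing;
        # greedy left-to-right pass restores it
        kept = [idx[0]]
        for j in idx[1:]:
            if j - kept[-1] >= distance:
                kept.append(j)
        idx = np.asarray(kept)

    win = max(2, int(round(ROLLING_STD_WINDOW_S * fs)))
    rolling_sd = (
        pd.Series(x).rolling(win, center=True, min_periods=1).std(ddof=0).to_numpy()
    )
    keep = x[idx] > k * rolling_sd[idx]
    idx = idx[keep]

    if amplitude_frac > 0 and idx.size:
        median_height = np.median(x[idx])
        idx = idx[x[idx] > amplitude_frac * median_height]

    times = component.start_time_s + idx / fs
    return PeakList(times, x[idx], kind, k, refractory)


def rate_from_peaks(
    peaks: PeakList,
    window_length_s: float = 60.0,
    hop_s: float = 10.0,
    duration_s: float | None = None,
    start_time_s: float = 0.0,
    edge_exclusion_s: float = 0.0,
) -> RateSeries:
    """Windowed rate series: per window, 60 / median(inter-peak interval).

    Windows slide by ``hop_s`` over ``[start_time_s, start_time_s +
    duration_s]`` (duration defaults to the span of the peaks).  A window is
    flagged invalid when it holds fewer than two peaks, when its rate falls
    outside the physiological bounds for its kind, or when it overlaps the
    ``edge_exclusion_s`` settling margin at either end of the record.
    """
    if window_length_s <= 0 or hop_s <= 0:
        raise InvalidConfigError("window_length_s and hop_s must be > 0")
    t = peaks.peak_times_s
    if duration_s is None:
        duration_s = float(t[-1] - start_time_s) if t.size else 0.0
    end = start_time_s + duration_s
    if duration_s >= window_length_s:
        centers = np.arange(
            start_time_s + window_length_s / 2.0, end - window_length_s / 2.0 + 1e-9, hop_s
        )
    else:  # record shorter than a window: one window covering it all
        centers = np.array([start_time_s + duration_s / 2.0])

    lo_bound, hi_bound = RATE_BOUNDS[peaks.kind]
    rates = np.zeros(centers.size)
    valid = np.zeros(centers.size, dtype=bool)
    half = window_length_s / 2.0
    for i, c in enumerate(centers):
        in_win = t[(t >= c - half) & (t <= c + half)]
        if in_win.size < 2:
            continue
        rate = 60.0 / float(np.median(np.diff(in_win)))
        rates[i] = rate
        in_bounds = lo_bound <= rate <= hi_bound
        clear_of_edges = edge_exclusion_s <= 0 or (
            c - half >= start_time_s + edge_exclusion_s - 1e-9
            and c + half <= end - edge_exclusion_s + 1e-9
        )
        valid[i] = in_bounds and clear_of_edges
    return RateSeries(centers, rates, valid, window_length_s, peaks.kind)


def session_summary(series: RateSeries) -> SessionSummary:
    """Median and mean rate over valid windows (invalid count reported)."""
    good = series.valid_rates
    if good.size == 0:
        raise NoValidDataError(
            f"no valid {series.kind} windows out of {series.rates.size}"
        )
    return SessionSummary(
        median=float(np.median(good)),
        mean=float(np.mean(good)),
        n_valid=int(good.size),
        n_invalid=int(series.rates.size - good.size),
        kind=series.kind,
    )
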