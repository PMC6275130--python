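"""Distribution-shape healthy measure and three-class screening.

A session's rate distribution is reduced to two numbers: its *length* L
(span of observed rates) and *height* h (count in the tallest 1-unit
histogram bin).  The healthy measure is the ratio L / h — a wide, flat rate
distribution (disordered cardiorespiratory control) scores high, a narrow,
peaked one (stable rates) scores low.  The printed reference computation is
L = 17, h = 10 -> measure 1.7 for a healthy heartbeat distribution.

Two conventions for (L, h) are provided, because "length and height of a
normal-distribution plot" admits either reading:

* ``histogram`` (default): L = max - min of the valid rates, h = modal bin
  count of a histogram with the given bin width;
* ``normal_fit``: L = 2 z sigma of a fitted normal (z configurable,
  default 2), h = expected modal-bin count n * (Phi(w/2s) - Phi(-w/2s)).

The convention used is recorded in the result so reports are unambiguous.

Sessions are placed into three classes — healthy, entering an emergency
condition, dangerous — by comparing the measure against two increasing
borders.  The defaults are midpoints between the per-class measures
reported for single subjects (heartbeat 1.7 / 5.56 / 9.88 -> borders 3.63
and 7.72; respiration 1.54 / 1.9 / 2.3 -> borders 1.72 and 2.10); they are
screening defaults, not clinically validated thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats

from .core import InsufficientDataError, InvalidConfigError
from .rates import RateSeries

__all__ = [
    "DistributionShape",
    "HealthyMeasure",
    "HealthClass",
    "DEFAULT_BORDERS",
    "estimate_distribution_shape",
    "healthy_measure",
    "classify",
]

#: (lower, upper) healthy-measure borders per signal kind; midpoints of the
#: reported per-class measures.  Fully overridable in :func:`classify`.
DEFAULT_BORDERS: dict[str, tuple[float, float]] = {
    "heartbeat": (3.63, 7.72),
    "respiration": (1.72, 2.10),
}

MIN_VALID_WINDOWS = 10


@dataclass(frozen=True)
class DistributionShape:
    """Length L and height h of a rate distribution."""

    length_L: float
    height_h: float
    bin_width: float
    n_samples: int
    kind: str
    degenerate: bool = False
    method: str = "histogram"

    def __post_init__(self) -> None:
        if self.length_L < 0:
            raise InvalidConfigError("length_L must be >= 0")
        if self.n_samples >= 1 and not (1 <= self.height_h <= self.n_samples):
            raise InvalidConfigError(
                f"height_h must lie in [1, n_samples], got {self.height_h}"
            )


@dataclass(frozen=True)
class HealthyMeasure:
    """Dimensionless distribution-shape ratio L / h."""

    value: float
    kind: str


@dataclass(frozen=True)
class HealthClass:
    label: str  # healthy | emergency | dangerous
    borders: tuple[float, float]
    measure: HealthyMeasure


def estimate_distribution_shape(
    series: RateSeries,
    bin_width: float = 1.0,
    method: str = "histogram",
    z: float = 2.0,
) -> DistributionShape:
    """Length/height of the valid-rate distribution of ``series``.

    Requires at least 10 valid windows.  An all-equal series is returned
    with ``length_L = 0`` and the ``degenerate`` flag set rather than
    raising.  Histogram bins are anchored at integer multiples of
    ``bin_width`` so the height does not depend on the data minimum.
    """
    if bin_width <= 0:
        raise InvalidConfigError(f"bin_width must be > 0, got {bin_width}")
    if method not in ("histogram", "normal_fit"):
        raise InvalidConfigError(f"unknown shape method {method!r}")
    rates = series.valid_rates
    n = rates.size
    if n < MIN_VALID_WINDOWS:
        raise InsufficientDataError(
            f"need >= {MIN_VALID_WINDOWS} valid windows, got {n}"
        )

    lo, hi = float(np.min(rates)), float(np.max(rates))
    degenerate = hi == lo
    if method == "histogram" or degenerate:
        length = hi - lo
        first = np.floor(lo / bin_width)
        last = np.floor(hi / bin_width)
        edges = np.arange(first, last + 2) * bin_width
        counts, _ = np.histogram(rates, bins=edges)
        height = int(counts.max())
    else:
        mu, sigma = float(np.mean(rates)), float(np.std(rates, ddof=1))
        length = 2.0 * z * sigma
        height = float(
            n * (sstats.norm.cdf(bin_width / 2, 0, sigma) - sstats.norm.cdf(-bin_width / 2, 0, sigma))
        )
        height = max(height, 1.0)
    return DistributionShape(
        length_L=float(length),
        height_h=height,
        bin_width=float(bin_width),
        n_samples=int(n),
        kind=series.kind,
        degenerate=bool(degenerate),
        method=method,
    )


def healthy_measure(shape: DistributionShape) -> HealthyMeasure:
    """Healthy measure = length_L / height_h (larger = more disordered)."""
    if shape.height_h <= 0:
        raise InvalidConfigError(
            "degenerate distribution: height_h must be >= 1 to form the ratio"
        )
    return HealthyMeasure(value=shape.length_L / shape.height_h, kind=shape.kind)


def classify(
    measure: HealthyMeasure, borders: tuple[float, float] | None = None
) -> HealthClass:
    """Three-class decision by comparing the measure to two borders.

    measure < lower -> healthy; lower <= measure < upper -> emergency;
    measure >= upper -> dangerous.  A value exactly on a border belongs to
    the more severe class.
    """
    if borders is None:
        borders = DEFAULT_BORDERS[measure.kind]
    lower, upper = borders
    if not (lower < upper):
        raise InvalidConfigError(
            f"borders must be strictly increasing, got ({lower}, {upper})"
        )
    if measure.value < lower:
        label = "healthy"
    elif measure.value < upper:
        label = "emergency"
    else:
        label = "dangerous"
    return HealthClass(label=label, borders=(float(lower), float(upper)), measure=measure)
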