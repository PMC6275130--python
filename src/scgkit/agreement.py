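"""Bland-Altman agreement between an estimated and a reference rate series.

Differences are taken as ``test - reference``.  The statistics follow
standard Bland-Altman practice: mean error (bias), sample standard
deviation of the differences (n-1 divisor), 95% limits of agreement
mean ± 1.96 SD, plus the RMSE of the differences.  By construction

    loa_upper - loa_lower = 2 * 1.96 * sd_error
    rmse^2 = mean_error^2 + sd_error^2 * (n-1)/n

hold exactly, which the test suite asserts on arbitrary inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import InsufficientDataError, InvalidInputError
from .rates import RateSeries

__all__ = [
    "PairedRates",
    "AgreementStats",
    "bland_altman",
    "pair_rate_series",
    "agreement_table",
    "bland_altman_plot",
]

Z_95 = 1.96  # normal quantile used for 95% limits of agreement


@dataclass(frozen=True)
class PairedRates:
    """Aligned reference/test rate pairs in events/min."""

    reference: np.ndarray
    test: np.ndarray

    def __post_init__(self) -> None:
        ref = np.asarray(self.reference, dtype=float)
        tst = np.asarray(self.test, dtype=float)
        if ref.shape != tst.shape or ref.ndim != 1:
            raise InvalidInputError(
                f"reference and test must be 1-D of equal length, got "
                f"{ref.shape} vs {tst.shape}"
            )
        object.__setattr__(self, "reference", ref)
        object.__setattr__(self, "test", tst)

    @property
    def n_pairs(self) -> int:
        return self.reference.size


@dataclass(frozen=True)
class AgreementStats:
    mean_error: float
    sd_error: float
    loa_lower: float
    loa_upper: float
    rmse: float
    n_pairs: int
    #: per-pair Bland-Altman coordinates for plotting
    pair_means: np.ndarray
    pair_diffs: np.ndarray


def bland_altman(pairs: PairedRates) -> AgreementStats:
    """Agreement statistics for ``test - reference`` differences."""
    n = pairs.n_pairs
    if n < 2:
        raise InsufficientDataError(f"need >= 2 pairs for dispersion, got {n}")
    d = pairs.test - pairs.reference
    mean = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return AgreementStats(
        mean_error=mean,
        sd_error=sd,
        loa_lower=mean - Z_95 * sd,
        loa_upper=mean + Z_95 * sd,
        rmse=float(np.sqrt(np.mean(d**2))),
        n_pairs=n,
        pair_means=(pairs.test + pairs.reference) / 2.0,
        pair_diffs=d,
    )


def pair_rate_series(
    test: RateSeries,
    reference_centers_s: np.ndarray,
    reference_rates: np.ndarray,
    max_offset_s: float | None = None,
) -> tuple[PairedRates, int]:
    """Pair valid test windows with the nearest reference window centre.

    A pair is kept when the centre offset is at most ``max_offset_s``
    (default: half the test series' median hop).  Returns the pairs and the
    count of valid test windows left unmatched.
    """
    ref_c = np.asarray(reference_centers_s, dtype=float)
    ref_r = np.asarray(reference_rates, dtype=float)
    if ref_c.shape != ref_r.shape or ref_c.ndim != 1:
        raise InvalidInputError("reference centers/rates must be 1-D of equal length")
    if ref_c.size == 0:
        return PairedRates(np.empty(0), np.empty(0)), int(test.n_valid)
    if max_offset_s is None:
        hops = np.diff(test.window_centers_s)
        max_offset_s = float(np.median(hops)) / 2.0 if hops.size else np.inf

    order = np.argsort(ref_c)
    ref_c, ref_r = ref_c[order], ref_r[order]
    t_c = test.window_centers_s[test.valid]
    t_r = test.rates[test.valid]
    j = np.clip(np.searchsorted(ref_c, t_c), 1, ref_c.size - 1) if ref_c.size > 1 else np.zeros(t_c.size, dtype=int)
    if ref_c.size > 1:
        pick_left = np.abs(t_c - ref_c[j - 1]) <= np.abs(ref_c[j] - t_c)
        j = np.where(pick_left, j - 1, j)
    matched = np.abs(t_c - ref_c[j]) <= max_offset_s + 1e-9
    pairs = PairedRates(reference=ref_r[j][matched], test=t_r[matched])
    return pairs, int((~matched).sum())


def agreement_table(
    stats_hr: AgreementStats, stats_rr: AgreementStats
) -> dict[str, object]:
    """Two-column error table (heartbeat, respiration) with RMSE/SD rows.

    Returns a dict with a machine-readable ``columns`` block and a
    preformatted ``text`` rendering.
    """
    cols = {
        "heartbeat": {"rmse": stats_hr.rmse, "sd": stats_hr.sd_error,
                      "mean_error": stats_hr.mean_error, "n_pairs": stats_hr.n_pairs},
        "respiration": {"rmse": stats_rr.rmse, "sd": stats_rr.sd_error,
                        "mean_error": stats_rr.mean_error, "n_pairs": stats_rr.n_pairs},
    }
    lines = [
        f"{'':<12}{'heartbeat':>12}{'respiration':>14}",
        f"{'RMSE':<12}{stats_hr.rmse:>12.3f}{stats_rr.rmse:>14.3f}",
        f"{'SD':<12}{stats_hr.sd_error:>12.3f}{stats_rr.sd_error:>14.3f}",
        f"{'mean error':<12}{stats_hr.mean_error:>12.3f}{stats_rr.mean_error:>14.3f}",
    ]
    return {"columns": cols, "text": "\n".join(lines)}


def bland_altman_plot(stats: AgreementStats, path: str, title: str = "") -> None:
    """Scatter of pair differences vs means with bias and LoA lines."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(stats.pair_means, stats.pair_diffs, s=12, alpha=0.7)
    ax.axhline(stats.mean_error, color="0.6", linestyle="--", label="mean error")
    for y in (stats.loa_lower, stats.loa_upper):
        ax.axhline(y, color="0.3", linestyle="--")
    ax.set_xlabel("mean of methods (events/min)")
    ax.set_ylabel("difference, test − reference (events/min)")
    if title:
        ax.set_title(title)
    ax.legend(loc="best")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
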