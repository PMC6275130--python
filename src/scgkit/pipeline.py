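"""CSV/JSON readers and writers, configuration, and the end-to-end pipeline.

A session report is one JSON-serialisable dict containing the resolved
configuration and one block per processing stage:

    band_separation -> peak_detection -> rate_estimation -> session_summary
    -> distribution_shape -> healthy_measure -> classification
    (+ agreement when a reference series is supplied)

Reports are deterministic: the same trace and configuration yield a
byte-identical JSON rendering (no timestamps are embedded).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .agreement import bland_altman, pair_rate_series
from .core import (
    AccelerationTrace,
    InvalidConfigError,
    InvalidTraceError,
    PipelineStageError,
)
from .filters import FilterSpec, separate_bands
from .health import DEFAULT_BORDERS, classify, estimate_distribution_shape, healthy_measure
from .rates import DETECTOR_DEFAULTS, detect_peaks, rate_from_peaks, session_summary

__all__ = [
    "PipelineConfig",
    "REPORT_SCHEMA_VERSION",
    "read_trace_csv",
    "write_trace_csv",
    "read_rate_series_csv",
    "write_rate_series_csv",
    "run_pipeline",
    "report_json",
]

REPORT_SCHEMA_VERSION = 1

#: allowed relative deviation of each sampling period from the median
TIME_JITTER_TOL = 0.01


@dataclass(frozen=True)
class PipelineConfig:
    """Resolved settings of one end-to-end run (fully serialisable)."""

    filter_order: int = 2
    cutoff_hz: float = 0.5
    filter_mode: str = "zero_phase_offline"
    threshold_k_heartbeat: float = DETECTOR_DEFAULTS["heartbeat"][0]
    threshold_k_respiration: float = DETECTOR_DEFAULTS["respiration"][0]
    refractory_heartbeat_s: float = DETECTOR_DEFAULTS["heartbeat"][1]
    refractory_respiration_s: float = DETECTOR_DEFAULTS["respiration"][1]
    window_length_s: float = 60.0
    hop_s: float = 10.0
    edge_exclusion_s: float = 5.0
    bin_width: float = 1.0
    shape_method: str = "histogram"
    borders_heartbeat: tuple[float, float] = DEFAULT_BORDERS["heartbeat"]
    borders_respiration: tuple[float, float] = DEFAULT_BORDERS["respiration"]
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["borders_heartbeat"] = list(self.borders_heartbeat)
        d["borders_respiration"] = list(self.borders_respiration)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key in ("borders_heartbeat", "borders_respiration"):
            if key in d:
                d[key] = tuple(d[key])
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise InvalidConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise InvalidConfigError(f"config file {path} must hold a mapping")
        return cls.from_dict(data)


def read_trace_csv(path: str | Path) -> AccelerationTrace:
    """Read a ``time_s,accel`` CSV and infer the sampling rate.

    The time column must be strictly increasing and uniform to within 1% of
    the median period; violations are reported with the offending line
    number (header = line 1).
    """
    df = pd.read_csv(path)
    missing = {"time_s", "accel"} - set(df.columns)
    if missing:
        raise InvalidTraceError(f"{path}: missing column(s) {sorted(missing)}")
    t = df["time_s"].to_numpy(dtype=float)
    x = df["accel"].to_numpy(dtype=float)
    if t.size < 2:
        raise InvalidTraceError(f"{path}: need at least 2 rows to infer a sampling rate")
    dt = np.diff(t)
    bad = np.flatnonzero(dt <= 0)
    if bad.size:
        raise InvalidTraceError(
            f"{path}: time not strictly increasing at line {bad[0] + 3}"
        )
    period = float(np.median(dt))
    off = np.flatnonzero(np.abs(dt - period) > TIME_JITTER_TOL * period)
    if off.size:
        raise InvalidTraceError(
            f"{path}: irregular sampling at line {off[0] + 3} "
            f"(period {dt[off[0]]:.6g}s vs median {period:.6g}s)"
        )
    return AccelerationTrace(
        samples=x, sampling_rate_hz=1.0 / period, start_time_s=float(t[0])
    )


def write_trace_csv(trace: AccelerationTrace, path: str | Path) -> None:
    pd.DataFrame({"time_s": trace.times(), "accel": trace.samples}).to_csv(
        path, index=False, float_format="%.9g"
    )


def write_rate_series_csv(series, path: str | Path) -> None:
    pd.DataFrame(
        {
            "window_center_s": series.window_centers_s,
            "rate": series.rates,
            "valid": series.valid.astype(int),
        }
    ).to_csv(path, index=False, float_format="%.9g")


def read_rate_series_csv(path: str | Path, kind: str, window_length_s: float = 60.0):
    """Read a ``window_center_s,rate,valid`` CSV into a :class:`RateSeries`."""
    from .rates import RateSeries

    df = pd.read_csv(path)
    missing = {"window_center_s", "rate", "valid"} - set(df.columns)
    if missing:
        raise InvalidTraceError(f"{path}: missing column(s) {sorted(missing)}")
    return RateSeries(
        window_centers_s=df["window_center_s"].to_numpy(dtype=float),
        rates=df["rate"].to_numpy(dtype=float),
        valid=df["valid"].to_numpy(dtype=bool),
        window_length_s=window_length_s,
        kind=kind,
    )


def _stage(name: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except PipelineStageError:
        raise
    except Exception as exc:  # attribute every failure to its stage
        raise PipelineStageError(name, exc) from exc


def run_pipeline(
    trace: AccelerationTrace,
    config: PipelineConfig | None = None,
    reference_heartbeat=None,
    reference_respiration=None,
) -> dict:
    """Run the full chain on one trace and return the session report dict.

    ``reference_heartbeat`` / ``reference_respiration`` are optional
    ``RateSeries`` playing the gold-standard role; when given, a
    Bland-Altman agreement block is appended.
    """
    cfg = config or PipelineConfig()
    spec = FilterSpec(order=cfg.filter_order, cutoff_hz=cfg.cutoff_hz, mode=cfg.filter_mode)

    bands = _stage("band_separation", separate_bands, trace, spec)

    peaks = {}
    components = {"heartbeat": bands.cardiac, "respiration": bands.respiratory}
    thresholds = {
        "heartbeat": (cfg.threshold_k_heartbeat, cfg.refractory_heartbeat_s),
        "respiration": (cfg.threshold_k_respiration, cfg.refractory_respiration_s),
    }
    for kind, comp in components.items():
        k, refr = thresholds[kind]
        peaks[kind] = _stage("peak_detection", detect_peaks, comp, kind, k, refr)

    series = {}
    for kind in components:
        series[kind] = _stage(
            "rate_estimation",
            rate_from_peaks,
            peaks[kind],
            cfg.window_length_s,
            cfg.hop_s,
            duration_s=trace.duration_s,
            start_time_s=trace.start_time_s,
            edge_exclusion_s=cfg.edge_exclusion_s,
        )

    summaries = {k: _stage("session_summary", session_summary, s) for k, s in series.items()}
    shapes = {
        k: _stage(
            "distribution_shape",
            estimate_distribution_shape,
            s,
            cfg.bin_width,
            cfg.shape_method,
        )
        for k, s in series.items()
    }
    measures = {k: _stage("healthy_measure", healthy_measure, sh) for k, sh in shapes.items()}
    borders = {"heartbeat": cfg.borders_heartbeat, "respiration": cfg.borders_respiration}
    classes = {
        k: _stage("classification", classify, m, borders[k]) for k, m in measures.items()
    }

    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "config": cfg.to_dict(),
        "stages": {
            "band_separation": {
                "filter_order": spec.order,
                "cutoff_hz": spec.cutoff_hz,
                "mode": spec.mode,
                "n_samples": trace.n_samples,
                "sampling_rate_hz": trace.sampling_rate_hz,
                "edge_transient_s": bands.edge_transient_s,
            },
            "peak_detection": {
                k: {
                    "n_peaks": p.n_peaks,
                    "threshold_k": p.threshold_k,
                    "refractory_s": p.refractory_s,
                }
                for k, p in peaks.items()
            },
            "rate_estimation": {
                k: {
                    "window_length_s": s.window_length_s,
                    "window_centers_s": s.window_centers_s.tolist(),
                    "rates": np.round(s.rates, 6).tolist(),
                    "valid": s.valid.astype(int).tolist(),
                }
                for k, s in series.items()
            },
            "session_summary": {
                k: {
                    "median": round(sm.median, 6),
                    "mean": round(sm.mean, 6),
                    "n_valid": sm.n_valid,
                    "n_invalid": sm.n_invalid,
                }
                for k, sm in summaries.items()
            },
            "distribution_shape": {
                k: {
                    "length_L": round(sh.length_L, 6),
                    "height_h": sh.height_h,
                    "bin_width": sh.bin_width,
                    "n_samples": sh.n_samples,
                    "degenerate": sh.degenerate,
                    "method": sh.method,
                }
                for k, sh in shapes.items()
            },
            "healthy_measure": {
                k: {"value": round(m.value, 6)} for k, m in measures.items()
            },
            "classification": {
                k: {"label": c.label, "borders": list(c.borders)}
                for k, c in classes.items()
            },
        },
    }

    references = {
        "heartbeat": reference_heartbeat,
        "respiration": reference_respiration,
    }
    if any(r is not None for r in references.values()):
        agree_block = {}
        for kind, ref in references.items():
            if ref is None:
                continue
            pairs, unmatched = _stage(
                "agreement", pair_rate_series, series[kind], ref.window_centers_s, ref.rates
            )
            stats = _stage("agreement", bland_altman, pairs)
            agree_block[kind] = {
                "mean_error": round(stats.mean_error, 6),
                "sd_error": round(stats.sd_error, 6),
                "loa_lower": round(stats.loa_lower, 6),
                "loa_upper": round(stats.loa_upper, 6),
                "rmse": round(stats.rmse, 6),
                "n_pairs": stats.n_pairs,
                "n_unmatched": unmatched,
            }
        report["stages"]["agreement"] = agree_block
    return report


def report_json(report: dict) -> str:
    """Canonical (byte-stable) JSON rendering of a session report."""
    return json.dumps(report, sort_keys=True, indent=2) + "\n"
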