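"""Peak detection and windowed rate estimation."""

import numpy as np
import pytest

import scgkit as sk
from scgkit.rates import PeakList, detect_peaks, rate_from_peaks, session_summary

from conftest import make_rate_series


def peaks_at(times, kind="heartbeat"):
    times = np.asarray(times, dtype=float)
    return PeakList(times, np.ones_like(times), kind, 1.5, 0.27)


class TestDetectPeaks:
    def test_flat_component_yields_no_peaks(self):
        flat = sk.AccelerationTrace(np.zeros(5000), 50.0)
        assert detect_peaks(flat, "heartbeat").n_peaks == 0

    def test_impulse_train_spacing_is_exact(self):
        x = np.zeros(3000)
        x[::50] = 1.0
        pk = detect_peaks(sk.AccelerationTrace(x, 50.0), "heartbeat")
        np.testing.assert_allclose(np.diff(pk.peak_times_s), 1.0, atol=1e-12)

    def test_recovers_simulated_beats_within_40ms(self, clean_60bpm_session):
        _, trace, truth = clean_60bpm_session
        bands = sk.separate_bands(trace)
        pk = detect_peaks(bands.cardiac, "heartbeat")
        assert abs(pk.n_peaks - truth.beat_times_s.size) <= 1
        n = min(pk.n_peaks, truth.beat_times_s.size)
        dev = np.abs(pk.peak_times_s[:n] - truth.beat_times_s[:n])
        assert np.max(dev) <= 0.040

    def test_plateau_peak_takes_earliest_sample(self):
        x = np.zeros(600)
        x[100:104] = 1.0  # 4-sample plateau
        pk = detect_peaks(sk.AccelerationTrace(x, 50.0), "respiration")
        assert pk.peak_times_s[0] == pytest.approx(100 / 50.0)

    def test_refractory_period_enforced(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=5000)
        for kind in ("heartbeat", "respiration"):
            pk = detect_peaks(sk.AccelerationTrace(x, 50.0), kind)
            if pk.n_peaks > 1:
                assert np.min(np.diff(pk.peak_times_s)) >= pk.refractory_s - 1e-9

    def test_bad_kind_rejected(self):
        with pytest.raises(sk.InvalidConfigError):
            detect_peaks(sk.AccelerationTrace(np.zeros(100), 50.0), "pulse")


class TestRateFromPeaks:
    def test_uniform_train_gives_60_events_per_min(self):
        series = rate_from_peaks(peaks_at(np.arange(60.0)), 60.0, 10.0)
        assert np.all(series.rates[series.valid] == pytest.approx(60.0))

    def test_median_interval_is_robust_to_one_dropped_peak(self):
        # intervals {1, 1, 2}: median 1.0 -> 60 events/min
        series = rate_from_peaks(peaks_at([0.0, 1.0, 2.0, 4.0]), 60.0, 10.0)
        assert series.rates[0] == pytest.approx(60.0)

    def test_windows_with_fewer_than_two_peaks_flagged_invalid(self):
        series = rate_from_peaks(peaks_at([30.0]), 60.0, 10.0, duration_s=60.0)
        assert not series.valid.any()

    def test_out_of_bound_rates_carried_with_invalid_flag(self):
        # peaks every 0.27 s -> 222 events/min, above the heartbeat ceiling
        series = rate_from_peaks(
            peaks_at(np.arange(0, 60, 0.27)), 60.0, 10.0, duration_s=60.0
        )
        assert series.rates.size > 0
        assert np.all(series.rates > 220)
        assert not series.valid.any()

    def test_edge_exclusion_invalidates_transient_windows(self):
        series = rate_from_peaks(
            peaks_at(np.arange(300.0)), 60.0, 10.0, duration_s=300.0, edge_exclusion_s=5.0
        )
        inner = (series.window_centers_s >= 35.0) & (series.window_centers_s <= 265.0)
        assert series.valid[inner].all()
        assert not series.valid[~inner].any()

    def test_non_positive_window_rejected(self):
        with pytest.raises(sk.InvalidConfigError):
            rate_from_peaks(peaks_at([0.0, 1.0]), 0.0, 10.0)
        with pytest.raises(sk.InvalidConfigError):
            rate_from_peaks(peaks_at([0.0, 1.0]), 60.0, -1.0)


class TestSessionSummary:
    def test_constant_series(self):
        summary = session_summary(make_rate_series([20.0] * 12, kind="respiration"))
        assert summary.median == summary.mean == 20.0

    def test_median_and_mean_hand_computed(self):
        summary = session_summary(make_rate_series([10.0, 20.0, 30.0]))
        assert summary.median == 20.0
        assert summary.mean == 20.0

    def test_invalid_windows_excluded_and_counted(self):
        valid = np.array([True, True, False, True])
        summary = session_summary(make_rate_series([60, 62, 500, 64], valid=valid))
        assert summary.n_valid == 3
        assert summary.n_invalid == 1
        assert summary.median == 62.0

    def test_all_invalid_raises(self):
        series = make_rate_series([60.0, 61.0], valid=np.zeros(2, dtype=bool))
        with pytest.raises(sk.NoValidDataError):
            session_summary(series)


def _session_median(hr, rr, noise_sd, seed, duration=300.0):
    cfg = sk.SimulationConfig(
        duration_s=duration,
        heart_rate_bpm=hr,
        resp_rate_brpm=rr,
        rate_jitter_frac=0.0,
        noise_sd=noise_sd,
        seed=seed,
    )
    trace, _ = sk.simulate_chest_acceleration(cfg)
    bands = sk.separate_bands(trace)
    out = {}
    for kind, comp in (("heartbeat", bands.cardiac), ("respiration", bands.respiratory)):
        pk = detect_peaks(comp, kind)
        series = rate_from_peaks(
            pk, 60.0, 10.0, duration_s=duration, edge_exclusion_s=5.0
        )
        out[kind] = session_summary(series).median
    return out


class TestParameterRecovery:
    def test_rest_scenario_rates_recovered(self, rest_session):
        """Resting session (76 bpm, 20 brpm) recovered within ±2/±1."""
        cfg, trace, truth = rest_session
        report = sk.run_pipeline(trace)
        ss = report["stages"]["session_summary"]
        assert ss["heartbeat"]["median"] == pytest.approx(76.0, abs=2.0)
        assert ss["respiration"]["median"] == pytest.approx(20.0, abs=1.0)

    @pytest.mark.parametrize("hr", [50.0, 150.0])
    @pytest.mark.parametrize("rr", [5.0, 30.0])
    def test_noiseless_grid_corners_recovered(self, hr, rr):
        med = _session_median(hr, rr, 0.0, seed=3)
        assert med["heartbeat"] == pytest.approx(hr, abs=2.0)
        assert med["respiration"] == pytest.approx(rr, abs=1.0)

    def test_noise_robustness_at_low_heart_rate(self):
        med = _session_median(50.0, 12.0, 0.02, seed=7)  # noise = 0.2 x cardiac amp
        assert med["heartbeat"] == pytest.approx(50.0, abs=5.0)

    def test_recovered_rate_monotone_in_true_rate(self):
        hrs = [50.0, 76.0, 100.0, 150.0]
        meds = [_session_median(hr, 12.0, 0.0, seed=3)["heartbeat"] for hr in hrs]
        assert all(a < b for a, b in zip(meds, meds[1:]))

    def test_breath_hold_protocol_recovers_5_brpm(self):
        """Breath hold then deep slow breathing at 5 brpm true rate."""
        hold_cfg = sk.SimulationConfig(
            duration_s=60.0, resp_amplitude=0.0, resp_rate_brpm=5.0, seed=21
        )
        breathe_cfg = sk.SimulationConfig(duration_s=540.0, resp_rate_brpm=5.0, seed=22)
        hold, _ = sk.simulate_chest_acceleration(hold_cfg)
        breathe, _ = sk.simulate_chest_acceleration(breathe_cfg)
        trace = sk.AccelerationTrace(
            np.concatenate([hold.samples, breathe.samples]), 50.0
        )
        bands = sk.separate_bands(trace)
        pk = detect_peaks(bands.respiratory, "respiration")
        series = rate_from_peaks(pk, 60.0, 10.0, duration_s=600.0, edge_exclusion_s=5.0)
        assert session_summary(series).median == pytest.approx(5.0, abs=1.0)
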