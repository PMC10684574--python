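"""Detector and feature-extraction behavior on known waveforms."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import spherocal as sc
from spherocal import simulate as sim
from spherocal.peaks import (
    DetectorParams, TraceError, estimate_baseline, trigger_level,
)

from conftest import make_triangle


class TestBaseline:
    def test_constant_trace(self):
        tr = sc.Trace(np.full(200, 100.0), 1.67)
        baseline, noise = estimate_baseline(tr)
        assert baseline == pytest.approx(100.0, abs=1e-9)
        assert noise == pytest.approx(0.0, abs=1e-9)

    def test_noisy_flat_trace_recovers_level_and_noise(self):
        for seed in range(100):
            rng = np.random.default_rng(seed)
            tr = sc.Trace(100.0 + rng.normal(0, 2, 1000), 1.67)
            baseline, noise = estimate_baseline(tr)
            assert abs(baseline - 100.0) < 1.0
            assert abs(noise - 2.0) < 0.3

    def test_trigger_is_ten_percent_above_baseline(self):
        assert trigger_level(100.0) == pytest.approx(110.0)


class TestDetect:
    def test_flat_trace_has_no_peaks(self):
        tr = sc.Trace(np.full(100, 50.0), 1.0)
        assert sc.detect_peaks(tr) == []

    def test_trace_shorter_than_window_rejected(self):
        with pytest.raises(TraceError, match="search vector"):
            sc.detect_peaks(sc.Trace(np.arange(5, dtype=float) + 1, 1.0))

    def test_clean_train_count_recovered(self, clean_train):
        peaks = sc.detect_peaks(clean_train.trace)
        assert len(peaks) == clean_train.truth.n_events

    def test_clean_train_apex_times_within_one_frame(self, clean_train):
        peaks = sc.detect_peaks(clean_train.trace)
        det = np.array([p.apex_time_s for p in peaks])
        err = np.abs(det - clean_train.truth.apex_times_s)
        assert err.max() <= 1.0 / clean_train.trace.frame_rate_hz

    def test_detection_is_deterministic(self, clean_train):
        a = sc.detect_peaks(clean_train.trace)
        b = sc.detect_peaks(clean_train.trace)
        assert a == b

    def test_monotone_load(self):
        """Detected count never decreases with generator event rate."""
        counts = []
        for rate in [1.0, 2.0, 3.0, 4.0]:
            cfg = sc.SimConfig(event_rate_per_min=rate, event_jitter_cv=0.1,
                               noise_sd=0.0, decay_tau_s=3.0, seed=21)
            counts.append(len(sc.detect_peaks(sim.simulate_well_trace(cfg).trace)))
        assert counts == sorted(counts)


class TestMeasure:
    def test_triangle_geometry(self):
        """CTD50 = W/2, CTD90 = 0.9W, rise = decay = W/2, slope = 2A/W."""
        tr = make_triangle(baseline=100.0, amplitude=10000.0, base_width=8.0)
        peaks = sc.detect_peaks(tr)
        assert len(peaks) == 1
        p = peaks[0]
        assert p.amplitude == pytest.approx(10000.0, rel=1e-6)
        assert p.ctd50_s == pytest.approx(4.0, rel=0.02)
        assert p.ctd90_s == pytest.approx(7.2, rel=0.02)
        assert p.rise_time_s == pytest.approx(4.0, rel=0.03)
        assert p.decay_time_s == pytest.approx(4.0, rel=0.03)
        assert p.rise_slope == pytest.approx(2500.0, rel=0.02)
        assert p.decay_slope == pytest.approx(-2500.0, rel=0.02)

    def test_kernel_widths_match_dense_analytic_evaluation(self):
        """Measured CTDs agree with brute force on the closed-form kernel."""
        rise, decay = 1.0, 4.0
        fs = 16.7  # dense sampling keeps interpolation error tiny
        t = np.arange(int(60 * fs)) / fs
        amp = 1000.0
        kern = amp * sim.transient_kernel(t - 10.0, rise, decay)
        tr = sc.Trace(1000.0 + kern, fs)
        p = sc.detect_peaks(tr)[0]

        # oracle: 1000x-resolution evaluation of the analytic kernel
        td = np.arange(0, 60, 1e-3)
        kd = sim.transient_kernel(td - 10.0, rise, decay)
        for level, measured in [(0.5, p.ctd50_s), (0.1, p.ctd90_s)]:
            above = td[kd >= level]
            assert measured == pytest.approx(above[-1] - above[0], abs=2.0 / fs)

    def test_ead_hump_counted(self):
        cfg = sc.SimConfig(event_rate_per_min=2.0, event_jitter_cv=0.0,
                           noise_sd=0.0, amplitude_cv=0.0, ead_prob=1.0, seed=5)
        out = sim.simulate_well_trace(cfg)
        peaks = sc.detect_peaks(out.trace)
        assert sum(p.n_ead for p in peaks) == out.truth.n_ead == len(peaks)

    def test_no_ead_without_humps(self, clean_train):
        assert sum(p.n_ead for p in sc.detect_peaks(clean_train.trace)) == 0

    def test_degenerate_window_discarded(self):
        tr = sc.Trace(np.linspace(100, 200, 50), 1.0)
        assert sc.measure_peak(tr, 100.0, start=10, apex=10, end=20) is None


class TestInvariances:
    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(scale=st.floats(min_value=0.5, max_value=50.0))
    def test_scale_equivariance(self, scale):
        """Scaling a trace scales amplitudes/slopes, preserves timing."""
        cfg = sc.SimConfig(event_rate_per_min=2.0, event_jitter_cv=0.2,
                           noise_sd=0.0, decay_tau_s=3.0, seed=7)
        tr = sim.simulate_well_trace(cfg).trace
        base = sc.extract_features(tr, sc.detect_peaks(tr))
        scaled_tr = sc.Trace(tr.values * scale, tr.frame_rate_hz, id=tr.id)
        scaled = sc.extract_features(scaled_tr, sc.detect_peaks(scaled_tr))

        assert scaled.peak_count == base.peak_count
        assert scaled.mean_peak_amplitude == pytest.approx(
            base.mean_peak_amplitude * scale, rel=1e-9)
        assert scaled.rise_slope == pytest.approx(base.rise_slope * scale, rel=1e-9)
        assert scaled.decay_slope == pytest.approx(base.decay_slope * scale, rel=1e-9)
        assert scaled.peak_spacing == pytest.approx(base.peak_spacing, rel=1e-12)
        assert scaled.ctd50 == pytest.approx(base.ctd50, rel=1e-9)
        assert scaled.ctd90 == pytest.approx(base.ctd90, rel=1e-9)
        assert scaled.mean_peak_rise_time == pytest.approx(
            base.mean_peak_rise_time, rel=1e-12)

    def test_time_reversal_swaps_rise_and_decay(self, clean_train):
        tr = clean_train.trace
        fwd = sc.extract_features(tr, sc.detect_peaks(tr))
        rev_tr = sc.Trace(tr.values[::-1].copy(), tr.frame_rate_hz, id=tr.id)
        rev = sc.extract_features(rev_tr, sc.detect_peaks(rev_tr))

        assert rev.peak_count == fwd.peak_count
        assert rev.mean_peak_amplitude == pytest.approx(fwd.mean_peak_amplitude, rel=1e-6)
        assert rev.ctd50 == pytest.approx(fwd.ctd50, rel=0.02)
        assert rev.mean_peak_rise_time == pytest.approx(fwd.mean_peak_decay_time, rel=0.02)
        assert rev.mean_peak_decay_time == pytest.approx(fwd.mean_peak_rise_time, rel=0.02)


class TestFeatures:
    def test_regular_train_spacing_and_rate(self, regular_train):
        tr = regular_train.trace
        f = sc.extract_features(tr, sc.detect_peaks(tr))
        assert f.peak_spacing == pytest.approx(12.0, abs=0.01)
        assert f.peak_spacing_sd == pytest.approx(0.0, abs=0.01)
        assert f.mean_peak_rate == pytest.approx(5.0, rel=0.02)
        assert f.peak_count == regular_train.truth.n_events

    def test_zero_peaks_yields_missing_fields(self):
        tr = sc.Trace(np.full(100, 50.0), 1.0)
        f = sc.extract_features(tr, [])
        assert f.peak_count == 0
        for name in sc.FEATURE_NAMES:
            if name != "peak_count":
                assert math.isnan(getattr(f, name)), name

    def test_single_peak_has_missing_sds(self):
        tr = make_triangle()
        f = sc.extract_features(tr, sc.detect_peaks(tr))
        assert f.peak_count == 1
        assert math.isnan(f.peak_amplitude_sd)
        assert math.isnan(f.peak_spacing)
        assert math.isnan(f.peak_spacing_sd)
        assert not math.isnan(f.mean_peak_amplitude)

    def test_feature_catalogue_is_complete(self):
        """Seven mean/SD pairs + count + CTD50 + CTD90 + EAD count."""
        assert len(sc.FEATURE_NAMES) == 18
        assert sum(n.endswith("_sd") for n in sc.FEATURE_NAMES) == 7
        tr = make_triangle()
        assert set(sc.analyze_trace(tr).to_dict()) == set(sc.FEATURE_NAMES)

    def test_ctd50_never_exceeds_ctd90(self, clean_train):
        for p in sc.detect_peaks(clean_train.trace):
            assert p.ctd50_s <= p.ctd90_s
            assert p.rise_slope > 0
            assert p.decay_slope < 0

    def test_detector_params_validation(self):
        with pytest.raises(ValueError):
            DetectorParams(search_vector_length=10)
        with pytest.raises(ValueError):
            DetectorParams(trigger_fraction=0.0)
        with pytest.raises(ValueError):
            DetectorParams(dynamic_threshold_k=-1.0)
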