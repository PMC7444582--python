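"""Smoothing, peak detection vs brute-force oracle, and pulse metrics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import signal as sps

from spermacal import (
    AnalysisParams,
    smooth,
    find_peaks,
    compute_metrics,
    derivative_variance,
    normalize_trace,
    simulate_field,
    load_preset,
)
from spermacal.trace_pipeline import CalciumTrace
from spermacal.transit_annotation import EventRecord
from oracles import brute_force_peaks


def make_trace(F_norm, entry=0, valve_close=None, dt=1.0):
    n = len(F_norm)
    ev = EventRecord(entry_start=entry, valve_close=valve_close,
                     valve_open=valve_close, observation_end=n - 1)
    return CalciumTrace(
        t=np.arange(n) * dt, F_raw=np.asarray(F_norm) * 100.0, F0=100.0,
        F_norm=np.asarray(F_norm, dtype=float), events=ev, dt=dt,
    )


class TestSmooth:
    def test_constant_trace_unchanged(self):
        assert np.array_equal(smooth(np.full(10, 3.0), 5), np.full(10, 3.0))

    def test_unit_impulse_spreads_to_window(self):
        x = np.zeros(9)
        x[4] = 1.0
        out = smooth(x, 5)
        expected = np.zeros(9)
        expected[2:7] = 0.2
        assert np.allclose(out, expected)

    def test_edges_truncate_to_available_samples(self):
        out = smooth(np.array([1.0, 2, 3, 4, 5]), 5)
        assert out[0] == pytest.approx(2.0)   # mean(1,2,3)
        assert out[1] == pytest.approx(2.5)   # mean(1,2,3,4)
        assert out[2] == pytest.approx(3.0)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            smooth(np.zeros(10), 4)


class TestFindPeaks:
    def test_constant_trace_has_no_peaks(self):
        assert find_peaks(np.full(20, 1.0)) == []

    def test_symmetric_triangle_geometry(self):
        x = np.concatenate([np.linspace(0, 1, 11), np.linspace(1, 0, 11)[1:]])
        peaks = find_peaks(x, AnalysisParams(min_prominence=0.1, min_width=5))
        assert len(peaks) == 1
        p = peaks[0]
        assert p.index == 10
        assert p.prominence == pytest.approx(1.0)
        assert p.width == pytest.approx(10.0)  # crossings at height 0.5

    def test_plateau_counts_once_at_left_middle(self):
        x = np.array([0, 0, 5, 5, 5, 5, 0, 0], dtype=float)
        peaks = find_peaks(x, AnalysisParams(min_prominence=0.1, min_width=1))
        assert [p.index for p in peaks] == [3]

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError, match="3 samples"):
            find_peaks(np.array([1.0, 2.0]))

    @pytest.mark.parametrize("quantize", [False, True])
    def test_matches_brute_force_oracle_on_random_traces(self, quantize):
        params = AnalysisParams(min_prominence=0.1, min_width=5)
        for seed in range(100):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(20, 201))
            x = np.cumsum(rng.normal(0, 0.1, n))
            x = smooth(x, 5)
            if quantize:  # coarse quantization creates plateaus
                x = np.round(x, 1)
            got = find_peaks(x, params)
            want = brute_force_peaks(x, params.min_prominence, params.min_width)
            assert [p.index for p in got] == [w[0] for w in want]
            for p, w in zip(got, want):
                assert p.prominence == pytest.approx(w[2], abs=1e-9)
                assert p.width == pytest.approx(w[3], abs=1e-9)

    def test_matches_scipy_on_generic_traces(self):
        # independent cross-check against scipy's prominence/width machinery
        params = AnalysisParams(min_prominence=0.1, min_width=5)
        for seed in range(30):
            rng = np.random.default_rng(1000 + seed)
            x = smooth(np.cumsum(rng.normal(0, 0.1, 150)), 5)
            got = find_peaks(x, params)
            idx, props = sps.find_peaks(x, prominence=0.1, width=5, rel_height=0.5)
            assert [p.index for p in got] == list(idx)
            assert np.allclose([p.prominence for p in got], props["prominences"])
            assert np.allclose([p.width for p in got], props["widths"])

    @settings(max_examples=50, deadline=None)
    @given(offset=st.floats(-100, 100), seed=st.integers(0, 10_000))
    def test_offset_invariance(self, offset, seed):
        rng = np.random.default_rng(seed)
        x = smooth(np.cumsum(rng.normal(0, 0.1, 80)), 5)
        a = find_peaks(x)
        b = find_peaks(x + offset)
        assert [p.index for p in a] == [p.index for p in b]
        for pa, pb in zip(a, b):
            assert pa.prominence == pytest.approx(pb.prominence, abs=1e-9)

    @settings(max_examples=50, deadline=None)
    @given(scale=st.floats(0.5, 20), seed=st.integers(0, 10_000))
    def test_scale_covariance_of_prominence(self, scale, seed):
        rng = np.random.default_rng(seed)
        x = smooth(np.cumsum(rng.normal(0, 0.1, 80)), 5)
        # disable thresholds so the peak sets are identical by construction
        params = AnalysisParams(min_prominence=0.0, min_width=1)
        a = find_peaks(x, params)
        b = find_peaks(x * scale, params)
        assert [p.index for p in a] == [p.index for p in b]
        for pa, pb in zip(a, b):
            assert pb.prominence == pytest.approx(pa.prominence * scale, rel=1e-9)


class TestDerivativeVariance:
    def test_linear_ramp_and_constant_are_zero(self):
        assert derivative_variance(np.linspace(0, 5, 50)) == pytest.approx(0.0)
        assert derivative_variance(np.full(10, 2.0)) == pytest.approx(0.0)

    def test_hand_computed_example(self):
        assert derivative_variance(np.array([0.0, 2.0, 1.0])) == pytest.approx(4.5)


class TestComputeMetrics:
    def test_flat_trace_has_no_peaks_and_null_times(self):
        m = compute_metrics(make_trace(np.ones(100), entry=10))
        assert m.n_peaks == 0
        assert m.peaks_per_second == 0.0
        assert m.t_half_max is None and m.t_max is None
        assert m.deriv_variance == 0.0

    def test_simulated_pulses_are_counted_against_ground_truth(self):
        preset = load_preset("kin2_kd")
        preset.noise_sd = 0.0
        fld, truth = simulate_field(preset, duration=600, seed=0)
        raw = fld.values.mean(axis=1)
        trace = normalize_trace(raw, entry_frame=30)
        trace.events = truth.events
        m = compute_metrics(trace)
        assert m.n_peaks == truth.pulse_count == 19
        # trapped embryo: denominator runs to the recording end
        assert m.peaks_per_second == pytest.approx(19 / 569.0)

    def test_ramp_with_terminal_peak_times(self):
        # F/F0 ramps 1 -> 3 linearly over 100 s from entry, then drops
        entry = 30
        x = np.ones(200)
        x[entry:entry + 101] = np.linspace(1, 3, 101)
        x[entry + 101:] = 1.0
        trace = make_trace(x, entry=entry)
        m = compute_metrics(trace, AnalysisParams(smooth_window=1))
        assert m.t_max == pytest.approx(100.0)
        # first crossing of half of the peak value 3.0 -> 1.5 at 25 s
        assert m.t_half_max == pytest.approx(25.0)

    def test_missing_entry_annotation_is_an_error(self):
        trace = make_trace(np.ones(50))
        trace.events = EventRecord(entry_start=None, observation_end=49)
        trace.events.entry_start = None
        with pytest.raises(ValueError, match="entry"):
            compute_metrics(trace)

    def test_transit_bounded_counting_uses_valve_close(self):
        preset = load_preset("kin2_kd")
        preset.noise_sd = 0.0
        fld, truth = simulate_field(preset, duration=600, seed=0)
        trace = normalize_trace(fld.values.mean(axis=1), entry_frame=30)
        trace.events = EventRecord(entry_start=30, valve_open=250, valve_close=300,
                                   observation_end=599)
        m = compute_metrics(trace)
        # only pulses with onset before the valve closes are counted
        assert m.n_peaks == sum(t <= 300 for t in truth.pulse_onsets)
        assert m.peaks_per_second == pytest.approx(m.n_peaks / 270.0)


def test_flat_preset_is_flatter_than_pulsing_preset_at_equal_noise():
    flat = load_preset("gsa1_kd")
    pulsing = load_preset("kin2_kd")
    assert flat.noise_sd == pulsing.noise_sd
    for seed in range(25):
        f_flat, _ = simulate_field(flat, duration=600, seed=seed)
        f_puls, _ = simulate_field(pulsing, duration=600, seed=10_000 + seed)
        v_flat = derivative_variance(
            normalize_trace(f_flat.values.mean(axis=1), 30).F_norm)
        v_puls = derivative_variance(
            normalize_trace(f_puls.values.mean(axis=1), 30).F_norm)
        assert v_flat < v_puls
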