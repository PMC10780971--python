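"""Extrema detection (gates + refractory) and SBP/DBP aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import bedpress as bp


def brute_force_extrema(x, sys_gate=(100.0, 150.0), dia_gate=(60.0, 100.0)):
    """Independent scan: sample i is a maximum when it rises into i and
    does not rise after i (plateaus resolve to their first sample)."""
    maxima, minima = [], []
    for i in range(1, len(x) - 1):
        if x[i] > x[i - 1] and x[i + 1] <= x[i]:
            if sys_gate[0] <= x[i] <= sys_gate[1]:
                maxima.append(i)
        if x[i] < x[i - 1] and x[i + 1] >= x[i]:
            if dia_gate[0] <= x[i] <= dia_gate[1]:
                minima.append(i)
    return maxima, minima


def _random_bp_like(rng, n):
    """Smooth random signal spanning the amplitude gates."""
    raw = rng.standard_normal(n)
    kernel = np.hanning(21)
    smooth = np.convolve(raw, kernel / kernel.sum(), mode="same")
    smooth = (smooth - smooth.min()) / (np.ptp(smooth) + 1e-12)
    return 55.0 + 100.0 * smooth  # spans ~[55, 155]: gates actually bite


class TestDetectEvents:
    def test_sine_in_gates_detected_with_refractory(self):
        t = np.arange(500) / 100.0
        x = 100.0 + 20.0 * np.sin(2 * np.pi * 1.2 * t)
        events = bp.detect_events(x, fs=100.0)
        sys_e = [e for e in events if e.kind == "systolic"]
        dia_e = [e for e in events if e.kind == "diastolic"]
        assert len(sys_e) == 6
        assert len(dia_e) == 6
        assert all(abs(e.amplitude - 120.0) < 0.1 for e in sys_e)
        assert all(abs(e.amplitude - 80.0) < 0.1 for e in dia_e)

    def test_constant_waveform_has_no_events(self):
        assert bp.detect_events(np.full(300, 110.0)) == []

    def test_amplitude_gate_rejects_out_of_range_peaks(self):
        t = np.arange(500) / 100.0
        x = 120.0 + 45.0 * np.sin(2 * np.pi * 1.0 * t)  # peaks 165, troughs 75
        events = bp.detect_events(x, fs=100.0)
        assert [e for e in events if e.kind == "systolic"] == []
        dia = [e for e in events if e.kind == "diastolic"]
        assert dia and all(abs(e.amplitude - 75.0) < 0.1 for e in dia)

    def test_too_short_waveform_rejected(self):
        with pytest.raises(ValueError):
            bp.detect_events(np.array([100.0, 101.0]))

    def test_refractory_keeps_the_more_extreme_peak(self):
        x = np.full(200, 105.0)
        x[40] = 120.0   # lower peak
        x[60] = 130.0   # higher peak, 20 samples away
        x[150] = 125.0  # far enough to stand alone
        events = [e for e in bp.detect_events(x) if e.kind == "systolic"]
        idx = [e.sample_index for e in events]
        assert 60 in idx and 150 in idx and 40 not in idx

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(seed=st.integers(min_value=0, max_value=10_000),
           n=st.integers(min_value=50, max_value=2000))
    def test_pre_refractory_detection_matches_brute_force(self, seed, n):
        """Oracle equivalence on random smooth signals: the vectorized
        zero-crossing detector (refractory disabled) equals an exhaustive
        local-extrema scan with the same amplitude gates."""
        rng = np.random.default_rng(seed)
        x = _random_bp_like(rng, n)
        events = bp.detect_events(x, refractory=0)
        got_max = [e.sample_index for e in events if e.kind == "systolic"]
        got_min = [e.sample_index for e in events if e.kind == "diastolic"]
        want_max, want_min = brute_force_extrema(x)
        assert got_max == want_max
        assert got_min == want_min

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(seed=st.integers(min_value=0, max_value=10_000))
    def test_refractory_separation_invariant(self, seed):
        """No two retained same-kind events are closer than 50 samples."""
        rng = np.random.default_rng(seed)
        x = _random_bp_like(rng, 1500)
        events = bp.detect_events(x, fs=100.0)
        for kind in ("systolic", "diastolic"):
            idx = [e.sample_index for e in events if e.kind == kind]
            assert all(b - a >= 50 for a, b in zip(idx, idx[1:]))


class TestWindowEstimates:
    def _ev(self, t, amp, kind):
        return bp.BPEvent(sample_index=int(t * 100), time=t, amplitude=amp,
                          kind=kind)

    def test_single_window_mean(self):
        events = [self._ev(t, 120.0, "systolic")
                  for t in np.linspace(0.2, 4.5, 6)]
        wins = bp.window_estimates(events, waveform_duration=5.0)
        assert len(wins) == 1
        assert wins[0].sbp == pytest.approx(120.0)
        assert wins[0].dbp is None

    def test_half_open_window_boundaries(self):
        events = [self._ev(1.0, 110.0, "systolic"),
                  self._ev(6.0, 130.0, "systolic")]
        wins = bp.window_estimates(events, waveform_duration=10.0)
        assert len(wins) == 2
        assert wins[0].sbp == pytest.approx(110.0)
        assert wins[1].sbp == pytest.approx(130.0)

    def test_final_partial_window_included(self):
        events = [self._ev(11.0, 115.0, "systolic")]
        wins = bp.window_estimates(events, waveform_duration=12.0)
        assert len(wins) == 3
        assert wins[2].sbp == pytest.approx(115.0)

    def test_absent_values_are_none_not_zero(self):
        wins = bp.window_estimates([], waveform_duration=10.0)
        assert all(w.sbp is None and w.dbp is None for w in wins)

    def test_adding_event_pulls_mean_toward_it(self):
        base = [self._ev(1.0, 110.0, "systolic")]
        more = base + [self._ev(2.0, 130.0, "systolic")]
        w0 = bp.window_estimates(base, 5.0)[0].sbp
        w1 = bp.window_estimates(more, 5.0)[0].sbp
        assert w0 < w1 <= 130.0


class TestRecordingEstimate:
    def _win(self, sbp, dbp):
        return bp.WindowEstimate(window_start=0.0, sbp=sbp, dbp=dbp,
                                 n_sys_events=int(sbp is not None),
                                 n_dia_events=int(dbp is not None))

    def test_mean_across_windows(self):
        est = bp.recording_estimate([self._win(118.0, 78.0),
                                     self._win(122.0, 82.0)])
        assert est.sbp_mean == pytest.approx(120.0)
        assert est.dbp_mean == pytest.approx(80.0)

    def test_absent_windows_skipped(self):
        est = bp.recording_estimate([self._win(120.0, 80.0),
                                     self._win(None, 80.0),
                                     self._win(126.0, 80.0)])
        assert est.sbp_mean == pytest.approx(123.0)
        assert est.n_windows_sbp == 2

    def test_no_usable_windows_raises(self):
        with pytest.raises(ValueError):
            bp.recording_estimate([self._win(None, None)])

    def test_reference_waveform_recovers_simulated_level(self,
                                                         noiseless_params):
        """End to end on the simulator's reference waveform: the recording
        SBP estimate lands within 1 mmHg of the configured systolic level."""
        rec = bp.simulate_participant(noiseless_params, duration=60.0,
                                      fs=100.0)
        events = bp.detect_events(rec.bp, fs=100.0)
        wins = bp.window_estimates(events, rec.duration)
        est = bp.recording_estimate(wins)
        assert abs(est.sbp_mean - noiseless_params.sbp_level) < 1.0
        assert abs(est.dbp_mean - noiseless_params.dbp_level) < 1.0
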