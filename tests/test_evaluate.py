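"""Waveform metrics and Bland–Altman agreement, checked against closed
forms and a brute-force recomputation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import bedpress as bp
from bedpress.evaluate import loa_width


class TestWaveformMetrics:
    def setup_method(self):
        rng = np.random.default_rng(0)
        self.ref = 100.0 + 10.0 * rng.standard_normal(500)

    def test_identity_reconstruction(self):
        m = bp.waveform_metrics(self.ref, self.ref.copy())
        assert (m.mse, m.mae, m.r2) == (0.0, 0.0, 1.0)

    def test_unit_offset(self):
        m = bp.waveform_metrics(self.ref, self.ref + 1.0)
        assert m.mse == pytest.approx(1.0)
        assert m.mae == pytest.approx(1.0)

    def test_mean_predictor_has_zero_r2(self):
        m = bp.waveform_metrics(self.ref,
                                np.full_like(self.ref, self.ref.mean()))
        assert m.r2 == pytest.approx(0.0, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            bp.waveform_metrics(self.ref, self.ref[:-1])

    def test_constant_reference_rejected(self):
        with pytest.raises(ValueError):
            bp.waveform_metrics(np.full(100, 120.0), np.zeros(100))


class TestBlandAltman:
    def test_identity_gives_zero_bias_and_loa(self):
        x = np.array([118.0, 121.0, 125.0])
        res = bp.bland_altman(x, x.copy())
        assert (res.bias, res.loa_lower, res.loa_upper) == (0.0, 0.0, 0.0)

    def test_constant_offset(self):
        x = np.array([110.0, 120.0, 130.0])
        res = bp.bland_altman(x + 2.0, x)
        assert res.bias == pytest.approx(2.0)
        assert res.sd_diff == pytest.approx(0.0)
        assert res.loa_lower == pytest.approx(2.0)
        assert res.loa_upper == pytest.approx(2.0)

    def test_hand_computed_symmetric_differences(self):
        # d = {-1, 0, 1}: bias 0, sample SD 1, LoA = +/-1.96
        ref = np.array([100.0, 100.0, 100.0])
        est = np.array([99.0, 100.0, 101.0])
        res = bp.bland_altman(est, ref)
        assert res.bias == pytest.approx(0.0)
        assert res.sd_diff == pytest.approx(1.0)
        assert res.loa_upper == pytest.approx(1.96)
        assert res.loa_lower == pytest.approx(-1.96)

    def test_single_pair_rejected(self):
        with pytest.raises(ValueError):
            bp.bland_altman(np.array([1.0]), np.array([2.0]))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(seed=st.integers(min_value=0, max_value=9999),
           n=st.integers(min_value=2, max_value=60))
    def test_matches_brute_force_recomputation(self, seed, n):
        rng = np.random.default_rng(seed)
        est = rng.uniform(90, 150, size=n)
        ref = rng.uniform(90, 150, size=n)
        res = bp.bland_altman(est, ref)
        d = [e - r for e, r in zip(est, ref)]
        mean_d = sum(d) / n
        sd = (sum((x - mean_d) ** 2 for x in d) / (n - 1)) ** 0.5
        assert res.bias == pytest.approx(mean_d, rel=1e-12, abs=1e-12)
        assert res.sd_diff == pytest.approx(sd, rel=1e-10, abs=1e-12)
        assert res.loa_upper == pytest.approx(mean_d + 1.96 * sd, rel=1e-10)
        assert res.loa_lower == pytest.approx(mean_d - 1.96 * sd, rel=1e-10)
        assert res.loa_lower <= res.bias <= res.loa_upper
        assert loa_width(res) == pytest.approx(2 * 1.96 * sd, rel=1e-10)


class TestLoaWidth:
    def test_reported_dbp_window_interval(self):
        res = bp.AgreementResult(bias=2.15, loa_lower=-13.09,
                                 loa_upper=17.39, sd_diff=7.78, n=100)
        assert loa_width(res) == pytest.approx(30.48)

    def test_reported_sbp_window_interval(self):
        res = bp.AgreementResult(bias=-2.31, loa_lower=-21.96,
                                 loa_upper=17.34, sd_diff=10.03, n=100)
        assert loa_width(res) == pytest.approx(39.30)

    def test_degenerate_interval(self):
        res = bp.AgreementResult(bias=1.0, loa_lower=1.0, loa_upper=1.0,
                                 sd_diff=0.0, n=5)
        assert loa_width(res) == 0.0


class TestEvaluateCohort:
    def test_identity_reconstruction_gives_perfect_agreement(self):
        """Substituting the reference waveform for the reconstruction must
        yield zero bias, zero-width LoA and R^2 = 1 end to end."""
        recs = bp.simulate_cohort(3, master_seed=21, duration=30.0)
        recons = [bp.ReconstructedWaveform(values=r.bp[50:], start_index=50,
                                           fs=r.fs,
                                           participant_id=r.participant_id)
                  for r in recs]
        report = bp.evaluate_cohort(None, None, recs,
                                    reconstructions=recons)
        for entry in report["per_recording_waveform_metrics"]:
            assert entry["r2"] == pytest.approx(1.0)
            assert entry["mse"] == pytest.approx(0.0, abs=1e-18)
        for key in ("window_sbp", "window_dbp", "recording_sbp",
                    "recording_dbp"):
            agg = report["agreement"][key]
            assert agg["bias"] == pytest.approx(0.0, abs=1e-12)
            assert agg["loa_width"] == pytest.approx(0.0, abs=1e-12)
        assert report["recordings_without_events"] == []

    def test_recording_level_n_equals_cohort_size(self):
        recs = bp.simulate_cohort(3, master_seed=22, duration=30.0)
        recons = [bp.ReconstructedWaveform(values=r.bp[50:], start_index=50,
                                           fs=r.fs,
                                           participant_id=r.participant_id)
                  for r in recs]
        report = bp.evaluate_cohort(None, None, recs,
                                    reconstructions=recons)
        assert report["agreement"]["recording_sbp"]["n"] == 3
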