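"""ΔF/F quantification: trace normalization, peaks, drug effects,
percentile curves."""

import numpy as np
import pandas as pd
import pytest

import feargen as fg
from feargen._exceptions import ValidationError

from conftest import make_trial

FULL_MASK = np.ones((4, 4), dtype=bool)


class TestComputeDff:
    def test_constant_fluorescence_gives_zero(self):
        trial = make_trial(np.zeros(1000), baseline=200.0)
        trace = fg.compute_dff(trial, FULL_MASK)
        np.testing.assert_array_equal(trace.dff, np.zeros(1000))

    def test_step_from_100_to_125_peaks_at_quarter(self):
        v = np.zeros(1000)
        v[225:575] = 0.25  # odor frames at F=125 over baseline 100
        trial = make_trial(v, baseline=100.0)
        trace = fg.compute_dff(trial, FULL_MASK)
        peak, _ = fg.peak_response(trace)
        assert peak == pytest.approx(0.25)

    def test_scale_invariance(self, rng):
        v = rng.uniform(0, 0.5, 1000)
        a = fg.compute_dff(make_trial(v, baseline=100.0), FULL_MASK)
        b = fg.compute_dff(make_trial(v, baseline=300.0), FULL_MASK)
        np.testing.assert_allclose(a.dff, b.dff, atol=1e-12)

    def test_additive_offset_changes_dff(self):
        v = np.zeros(1000)
        v[300] = 0.2
        base = fg.compute_dff(make_trial(v, baseline=100.0), FULL_MASK)
        trial = make_trial(v, baseline=100.0)
        shifted = fg.ImagingTrial(frames=trial.frames + 50.0, odor="MV", phase="pre")
        off = fg.compute_dff(shifted, FULL_MASK)
        assert not np.allclose(base.dff, off.dff)

    def test_empty_mask_and_bad_baseline_raise(self):
        trial = make_trial(np.zeros(1000))
        with pytest.raises(ValidationError):
            fg.compute_dff(trial, np.zeros((4, 4), dtype=bool))
        dark = fg.ImagingTrial(frames=np.zeros((1000, 4, 4)), odor="MV", phase="pre")
        with pytest.raises(ValidationError):
            fg.compute_dff(dark, FULL_MASK)

    def test_generator_amplitude_recovered_exactly(self, session_noisefree):
        sess = session_noisefree
        trial = next(t for t in sess.trials
                     if not t.mock and t.phase == "pre" and t.odor == "MV").render()
        roi = sorted(sess.tuning.responders("MV"))[0]
        trace = fg.compute_dff(trial, sess.roi_masks[roi], roi=roi)
        peak, _ = fg.peak_response(trace)
        assert peak == pytest.approx(
            sess.truth.expected_peak_dff["MV"][roi], rel=1e-9)


class TestPeakResponse:
    def test_window_max_not_global_max(self):
        v = np.zeros(1000)
        v[100] = 5.0  # pre-odor artifact outside the search window
        v[400] = 0.3
        trace = fg.compute_dff(make_trial(v), FULL_MASK)
        peak, lat = fg.peak_response(trace)
        assert peak == pytest.approx(0.3)
        assert lat == pytest.approx((400 - 225) / 50.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_scan(self, seed):
        rng = np.random.default_rng(seed)
        v = rng.normal(0, 0.1, 1000)
        trace = fg.compute_dff(make_trial(np.clip(v, -0.5, None)), FULL_MASK)
        peak, lat = fg.peak_response(trace)
        lo, hi = 225, 575 + 25
        brute = max(trace.dff[lo:hi])
        assert peak == pytest.approx(brute)
        brute_frame = lo + min(i for i in range(hi - lo)
                               if trace.dff[lo + i] == brute)
        assert lat == pytest.approx((brute_frame - 225) / 50.0)

    def test_empty_window_raises(self):
        trace = fg.compute_dff(make_trial(np.zeros(1000)), FULL_MASK)
        with pytest.raises(ValidationError):
            fg.peak_response(trace, window=(300, 300))


class TestTemporalProfile:
    def test_constant_trace_gives_constant_bins(self):
        v = np.zeros(1000)
        v[225:] = 0.4
        trace = fg.compute_dff(make_trial(v), FULL_MASK)
        np.testing.assert_allclose(fg.temporal_profile(trace), [0.4] * 4)

    def test_impulse_at_three_seconds_localized(self):
        v = np.zeros(1000)
        v[225 + 150] = 0.7  # 3 s after onset
        trace = fg.compute_dff(make_trial(v), FULL_MASK)
        prof = fg.temporal_profile(trace)
        assert prof[1] == pytest.approx(0.7)
        assert prof[0] == prof[2] == prof[3] == 0.0

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_brute_force_interval_max(self, seed):
        rng = np.random.default_rng(100 + seed)
        v = np.clip(rng.normal(0, 0.2, 1000), -0.5, None)
        trace = fg.compute_dff(make_trial(v), FULL_MASK)
        prof = fg.temporal_profile(trace)
        for i in range(4):
            lo = 225 + i * 100
            assert prof[i] == pytest.approx(max(trace.dff[lo:lo + 100]))

    def test_short_trace_raises(self):
        trace = fg.RoiTrace(roi=0, dff=np.zeros(300), frame_rate=50.0,
                            odor_onset=225, odor_offset=575)
        with pytest.raises(ValidationError):
            fg.temporal_profile(trace)


class TestDrugEffect:
    @staticmethod
    def _resp(phase, peaks, mock=False):
        return fg.RoiResponse(roi=1, odor="MV", phase=phase, peaks=list(peaks),
                              latencies_s=[1.0] * len(peaks), mock=mock)

    def test_arithmetic(self):
        eff = fg.drug_effect(self._resp("pre", [0.20]), self._resp("post", [0.25]))
        assert eff.percent_change == pytest.approx(25.0)

    def test_identity_is_zero(self):
        eff = fg.drug_effect(self._resp("pre", [0.2, 0.3]),
                             self._resp("post", [0.3, 0.2]))
        assert eff.percent_change == pytest.approx(0.0)

    def test_mock_and_nonpositive_pre_raise(self):
        with pytest.raises(ValidationError):
            fg.drug_effect(self._resp("pre", [0.2], mock=True),
                           self._resp("post", [0.25]))
        with pytest.raises(ValidationError):
            fg.drug_effect(self._resp("pre", [0.0]), self._resp("post", [0.25]))

    def test_mock_rows_refused_in_table(self, session_noisefree):
        sess = session_noisefree
        trials = [t.render() for t in sess.trials[:16]]
        peaks = fg.summarize_trials(trials, sess.roi_masks,
                                    sess.rois_by_odor(), include_mock=True)
        with pytest.raises(ValidationError):
            fg.drug_effect_table(peaks)


class TestCumulativePercentile:
    def test_small_list_ecdf(self):
        df = fg.cumulative_percentile([10, 20, 30])
        assert df.loc[df["value"] == 20, "percentile"].iloc[0] == pytest.approx(2 / 3)

    def test_identical_values_form_step(self):
        df = fg.cumulative_percentile([5.0] * 4)
        assert (df["percentile"] == 1.0).all()

    def test_matches_sorting_oracle(self, rng):
        v = rng.normal(size=200)
        df = fg.cumulative_percentile(v)
        sv = np.sort(v)
        np.testing.assert_array_equal(df["value"].to_numpy(), sv)
        expected = [(sv <= x).mean() for x in sv]
        np.testing.assert_allclose(df["percentile"], expected)

    def test_monotone_and_empty_raises(self, rng):
        df = fg.cumulative_percentile(rng.normal(size=50))
        assert (np.diff(df["percentile"]) >= 0).all()
        with pytest.raises(ValidationError):
            fg.cumulative_percentile([])


class TestBehaviorPhysiologyPairs:
    @staticmethod
    def _tables():
        eff = pd.DataFrame({
            "mouse": np.repeat(["m1", "m2", "m3"], 3),
            "odor": ["MV", "BA", "HEX"] * 3,
            "drug_effect_pct": np.arange(9, dtype=float),
        })
        imm = eff.rename(columns={"drug_effect_pct": "immobility_pct"}).copy()
        return eff, imm

    def test_fully_matched_gives_nine_rows(self):
        eff, imm = self._tables()
        assert len(fg.behavior_physiology_pairs(eff, imm)) == 9

    def test_missing_key_error_names_it(self):
        eff, imm = self._tables()
        with pytest.raises(ValidationError, match="m2/HEX"):
            fg.behavior_physiology_pairs(
                eff[~((eff.mouse == "m2") & (eff.odor == "HEX"))], imm)

    def test_negative_coupling_sign_recovered(self, rng):
        mice = [f"m{i}" for i in range(14)]
        rows_e, rows_i = [], []
        for m in mice:
            for o in ("MV", "BA", "HEX"):
                eff = rng.uniform(0, 40)
                rows_e.append({"mouse": m, "odor": o, "drug_effect_pct": eff})
                rows_i.append({"mouse": m, "odor": o,
                               "immobility_pct": 60 - eff + rng.normal(0, 5)})
        pairs = fg.behavior_physiology_pairs(pd.DataFrame(rows_e),
                                             pd.DataFrame(rows_i))
        res = fg.pearson_corr(pairs["drug_effect_pct"], pairs["immobility_pct"])
        assert res.r < 0
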