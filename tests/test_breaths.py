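"""Breath segmentation, calm selection and tidal-volume calibration."""

import numpy as np
import pandas as pd
import pytest

import pneumotrace as pt
from pneumotrace.breaths import SegmentationConfig
from conftest import match_onsets


class TestDetectBreaths:
    def test_pure_sinusoid(self):
        # 2 Hz sinusoid for 60 s: 120 breaths, Ti ~ Te ~ 0.25 s
        fs = 200.0
        t = np.arange(int(60 * fs)) / fs
        rec = pt.TraceRecording({"breath": np.sin(2 * np.pi * 2 * t)}, fs)
        br = pt.detect_breaths(rec)
        assert abs(len(br) - 120) <= 1
        assert br["ti_s"].median() == pytest.approx(0.25, abs=0.02)
        assert br["te_s"].median() == pytest.approx(0.25, abs=0.02)

    def test_onsets_match_ground_truth_exactly_on_clean_trace(self):
        p = pt.BreathModelParams(rate_mean=150, rate_cv=0.08, amp_cv=0.1,
                                 noise_sd=0)
        rec, gt = pt.generate_breathing_trace(p, 60.0, 100.0, seed=11)
        br = pt.detect_breaths(rec)
        tp = match_onsets(br["onset_s"], gt.breath_onsets, 1.0 / 100.0)
        assert tp == len(gt.breath_onsets) == len(br)

    def test_moderate_noise_full_recovery(self):
        p = pt.adult_breath_defaults(noise_sd=0.05, sigh_rate=1, apnea_rate=1)
        rec, gt = pt.generate_breathing_trace(p, 60.0, 100.0, seed=12)
        br = pt.detect_breaths(rec)
        tp = match_onsets(br["onset_s"], gt.breath_onsets, 1.0 / 100.0)
        assert tp == len(gt.breath_onsets) == len(br)

    def test_all_zeros_warns_and_returns_empty(self):
        rec = pt.TraceRecording({"breath": np.zeros(1000)}, 100.0)
        with pytest.warns(UserWarning):
            br = pt.detect_breaths(rec)
        assert len(br) == 0

    def test_missing_channel_raises(self):
        rec = pt.TraceRecording({"other": np.random.default_rng(0).normal(size=500)},
                                100.0)
        with pytest.raises(KeyError):
            pt.detect_breaths(rec)

    def test_gain_invariance(self):
        p = pt.adult_breath_defaults(noise_sd=0.05)
        rec, _ = pt.generate_breathing_trace(p, 30.0, 100.0, seed=13)
        br1 = pt.detect_breaths(rec)
        rec.channels["breath"] = rec.channels["breath"] * 137.0
        br2 = pt.detect_breaths(rec)
        assert len(br1) == len(br2)
        assert np.abs(br1["onset_s"].to_numpy()
                      - br2["onset_s"].to_numpy()).max() <= 1.0 / 100.0

    def test_ti_te_tile_gapfree_span(self):
        p = pt.BreathModelParams(rate_mean=150, rate_cv=0.05, noise_sd=0)
        rec, gt = pt.generate_breathing_trace(p, 30.0, 200.0, seed=14)
        br = pt.detect_breaths(rec)
        # over a contiguous run, sum of TT equals span within 1 sample/breath
        span = br["onset_s"].iloc[-1] - br["onset_s"].iloc[0]
        tt_sum = br["tt_s"].iloc[:-1].sum()
        assert abs(tt_sum - span) <= len(br) / 200.0

    def test_breath_invariants(self, adult_breaths):
        br = adult_breaths
        assert (br["onset_s"] < br["insp_end_s"]).all()
        assert (br["insp_end_s"] < br["offset_s"]).all()
        assert (br["ti_s"] > 0).all() and (br["te_s"] > 0).all()
        tt_err = (br["tt_s"] - (br["offset_s"] - br["onset_s"])).abs()
        assert tt_err.max() < 1e-9
        ok = br["ibi_s"].notna()
        assert (br.loc[ok, "ibi_s"] >= br.loc[ok, "tt_s"] - 1.0 / 100.0).all()


class TestCalmSelection:
    def test_metronomic_all_calm(self):
        from conftest import metronome_breaths
        br = pt.select_calm_breaths(metronome_breaths(60))
        assert br["calm"].all()

    def test_outlier_breath_flagged(self):
        from conftest import metronome_breaths
        br = metronome_breaths(60)
        br.loc[30, "tt_s"] *= 5.0
        out = pt.select_calm_breaths(br)
        assert not out.loc[30, "calm"]
        assert out.drop(index=30)["calm"].all()

    def test_infinite_factors_disable_filtering(self):
        from conftest import metronome_breaths
        br = metronome_breaths(60)
        br.loc[10, "tt_s"] *= 7.0
        br.loc[20, "amp"] *= 9.0
        cfg = SegmentationConfig(calm_factor=np.inf, artifact_factor=np.inf)
        out = pt.select_calm_breaths(br, cfg)
        assert out["calm"].all()

    def test_fewer_breaths_than_window_uses_session_medians(self):
        from conftest import metronome_breaths
        br = metronome_breaths(5)
        out = pt.select_calm_breaths(br, SegmentationConfig(calm_window=21))
        assert out["calm"].all()

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            pt.select_calm_breaths(pd.DataFrame(columns=["tt_s", "amp", "calm"]))

    def test_movement_artifact_span_excluded(self):
        p = pt.BreathModelParams(rate_mean=150, noise_sd=0.02)
        rec, _ = pt.generate_breathing_trace(p, 60.0, 100.0, seed=15)
        # inject a large movement artifact in the middle
        x = rec.channels["breath"]
        x[3000:3200] += np.random.default_rng(0).normal(0, 15.0, 200)
        br = pt.detect_breaths(rec)
        out = pt.select_calm_breaths(br, rec=rec)
        inside = out[(out["onset_s"] > 30.0) & (out["onset_s"] < 32.0)]
        assert not inside["calm"].any()


class TestHeartbeats:
    def test_constant_hr_recovered_within_1_bpm(self):
        p = pt.neonate_breath_defaults(noise_sd=0.02)
        rec, _ = pt.generate_breathing_trace(p, 120.0, 200.0, seed=16)
        # dedicated cardiac channel, as recorded in neonatal sessions
        t = np.arange(rec.n_samples) / 200.0
        rec.channels["cardiac"] = (0.5 * np.sin(2 * np.pi * 450 / 60 * t)
                                   + np.random.default_rng(1).normal(0, 0.02,
                                                                     rec.n_samples))
        beats = pt.detect_heartbeats(rec)
        assert beats.mean_hr(10, 110) == pytest.approx(450.0, abs=1.0)

    def test_zero_cardiac_amplitude_yields_empty_series(self):
        rec = pt.TraceRecording({"cardiac": np.zeros(2000)}, 200.0)
        with pytest.warns(UserWarning):
            beats = pt.detect_heartbeats(rec)
        assert len(beats.beat_times) == 0
        assert np.isnan(beats.hr).all()

    def test_rate_ordering(self):
        rates = []
        for hr in (300.0, 500.0):
            t = np.arange(int(60 * 200)) / 200.0
            sig = 0.5 * np.sin(2 * np.pi * hr / 60 * t) \
                + np.random.default_rng(2).normal(0, 0.02, len(t))
            rec = pt.TraceRecording({"cardiac": sig}, 200.0)
            rates.append(pt.detect_heartbeats(rec).mean_hr())
        assert rates[0] < rates[1]
        assert rates[0] == pytest.approx(300, abs=3)
        assert rates[1] == pytest.approx(500, abs=5)

    def test_gap_marks_hr_undefined(self):
        t = np.arange(int(60 * 200)) / 200.0
        sig = 0.5 * np.sin(2 * np.pi * 7.5 * t)
        sig[int(20 * 200):int(35 * 200)] = 0.0     # 15 s silence
        sig += np.random.default_rng(3).normal(0, 0.01, len(t))
        rec = pt.TraceRecording({"cardiac": sig}, 200.0)
        beats = pt.detect_heartbeats(rec)
        mid = (beats.hr_times > 25) & (beats.hr_times < 30)
        assert np.isnan(beats.hr[mid]).all()


def _oracle_drorbaugh_fenn(tb_c, tc_c, pb):
    """Independent implementation of the barometric correction."""
    def ph2o(tc):
        # Antoine equation, mmHg
        return 10 ** (8.07131 - 1730.63 / (233.426 + tc))
    tb = tb_c + 273.15
    tc = tc_c + 273.15
    num = tb * (pb - ph2o(tc_c))
    return num / (num - tc * (pb - ph2o(tb_c)))


class TestTidalVolume:
    def test_identity_calibration(self):
        from conftest import metronome_breaths
        br = metronome_breaths(30, amp=2.0)
        out = pt.calibrate_tidal_volume(br, calibration=(0.02, 2.0),
                                        correction=False)
        assert np.allclose(out["vt_ml"], 0.02)

    def test_correction_matches_independent_oracle(self):
        c = pt.drorbaugh_fenn_factor(37.0, 30.0, 760.0)
        assert c == pytest.approx(_oracle_drorbaugh_fenn(37.0, 30.0, 760.0),
                                  abs=1e-6)

    def test_constant_body_temp_when_pre_equals_post(self):
        from conftest import metronome_breaths
        br = metronome_breaths(30)
        meta = pt.AnimalMeta(id="x", temp_pre=36.5, temp_post=36.5)
        out = pt.calibrate_tidal_volume(br, (0.02, 1.0), animal=meta,
                                        chamber_temp_c=30.0)
        assert out["vt_ml"].nunique() == 1

    def test_missing_calibration_flags_uncalibrated(self):
        from conftest import metronome_breaths
        out = pt.calibrate_tidal_volume(metronome_breaths(10), None)
        assert not out["vt_calibrated"].any()
        assert np.allclose(out["vt_ml"], out["amp"])

    def test_nonpositive_deflection_rejected(self):
        from conftest import metronome_breaths
        with pytest.raises(ValueError):
            pt.calibrate_tidal_volume(metronome_breaths(10), (0.02, 0.0))
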