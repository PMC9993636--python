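"""Landmark detection, CIVD confirmation, phase segmentation, full pipeline."""

import math

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

from civdwave.detect import (
    CIVDCall,
    DetectConfig,
    detect_civd,
    find_flow_landmarks,
    moving_average,
    segment_phases,
    summarize_subject,
)
from civdwave.sigproc import NAMED_BANDS, Recording
from civdwave.synth import SignalParams, simulate_cohort, simulate_recording


def _flat_recording(flow, temp=None, rate=5.0, imm=600.0):
    n = len(flow)
    if temp is None:
        temp = np.full(n, 30.0)
    return Recording("T", rate, imm, np.asarray(flow, float), np.asarray(temp, float))


class TestFindFlowLandmarks:
    def test_monotone_decline_min_at_end_onset_missing(self):
        rate = 5.0
        n = int(2400 * rate)
        flow = np.concatenate([np.full(3000, 100.0),
                               np.linspace(100, 40, n - 3000)])
        t_min, t_on, t_max = find_flow_landmarks(flow, rate, 600.0)
        assert t_min == pytest.approx((n - 3000 - 1) / rate)
        assert math.isnan(t_on) and math.isnan(t_max)

    def test_two_equal_minima_earlier_wins(self):
        rate = 1.0
        flow = np.full(3000, 100.0)
        flow[:600] = 110.0  # baseline above
        flow[1000] = flow[2000] = 10.0
        t_min, *_ = find_flow_landmarks(flow, rate, 600.0, DetectConfig(
            window_s=1, slope_halfwin_s=2, sustain_s=5))
        assert t_min == pytest.approx(1000 - 600)

    def test_short_window_rejected(self):
        with pytest.raises(ValueError, match="sustain"):
            find_flow_landmarks(np.ones(100), 5.0, 15.0)

    def test_planted_landmarks_within_one_sample(self, noiseless_params):
        rec, truth = simulate_recording(noiseless_params, True, seed=5)
        sm = moving_average(rec.flow, rec.rate_hz)
        t_min, t_on, t_max = find_flow_landmarks(sm, rec.rate_hz,
                                                 rec.immersion_start_s)
        tol = 1.0 / rec.rate_hz + 1e-9
        assert abs(t_min - truth["t_minflow_s"]) <= tol
        assert abs(t_on - truth["t_onset_s"]) <= tol
        assert abs(t_max - truth["t_maxflow_s"]) <= tol


class TestDetectCIVD:
    def test_constant_temperature_never_civd(self, noiseless_params):
        rec, _ = simulate_recording(noiseless_params, True, seed=1)
        rec2 = Recording(rec.subject_id, rec.rate_hz, rec.immersion_start_s,
                         rec.flow, np.full_like(rec.temp, 30.0))
        call = detect_civd(rec2)
        assert not call.present
        assert "constant" in call.diagnostic

    def test_flow_rebound_without_temp_rise_is_not_civd(self, noiseless_params):
        # the generator's non-CIVD subjects rebound in flow but keep cooling
        rec, _ = simulate_recording(noiseless_params, False, seed=2)
        call = detect_civd(rec)
        assert not call.present
        assert not math.isnan(call.t_onset_sbf_s)  # flow landmark still there

    def test_temperature_rise_before_flow_minimum_does_not_count(self):
        rate = 1.0
        imm = 600
        n = 3000
        # flow: fall to a min at 1800 then sustained rebound
        flow = np.concatenate([
            np.full(imm, 100.0),
            np.linspace(100, 20, 1200),
            np.linspace(20, 90, n - imm - 1200),
        ])
        # temperature: rises early (during constriction), then falls forever
        temp = np.concatenate([
            np.full(imm, 30.0),
            np.linspace(30, 32, 300),
            np.linspace(32, 10, n - imm - 300),
        ])
        call = detect_civd(_flat_recording(flow, temp, rate, imm))
        assert not call.present

    def test_invariant_to_affine_rescaling_of_flow(self, noiseless_params):
        rec, _ = simulate_recording(noiseless_params, True, seed=3)
        scaled = Recording(rec.subject_id, rec.rate_hz, rec.immersion_start_s,
                           3.5 * rec.flow + 42.0, rec.temp)
        c1, c2 = detect_civd(rec), detect_civd(scaled)
        assert c1.present == c2.present
        assert c1.t_minflow_s == c2.t_minflow_s
        assert c1.t_onset_sbf_s == c2.t_onset_sbf_s

    def test_ordering_invariant_enforced(self):
        with pytest.raises(ValueError, match="ordering"):
            CIVDCall(True, 500.0, 400.0, 800.0, 600.0, 900.0, 11.0, 14.0)


class TestSegmentPhases:
    def test_full_landmarks_contiguous_cover(self):
        call = CIVDCall(True, 700.0, 1000.0, 1300.0, 1050.0, 1400.0, 10.5, 13.0)
        seg = segment_phases(call, 600.0, 2400.0)
        assert seg.baseline == (0.0, 600.0)
        assert seg.phase1 == (600.0, 1300.0)
        assert seg.phase2 == (1300.0, 1600.0)
        assert seg.phase3 == (1600.0, 1900.0)

    def test_missing_onset_caps_phase2_and_drops_phase3(self):
        call = CIVDCall(False, 700.0, float("nan"), float("nan"),
                        float("nan"), float("nan"), 12.9, 16.6)
        seg = segment_phases(call, 600.0, 2400.0)
        assert seg.phase2 == (1300.0, 1900.0)  # capped at 600 s
        assert seg.phase3 is None

    def test_noncivd_subjects_still_get_three_phases(self, small_phenotypes):
        non = small_phenotypes.loc[~small_phenotypes["civd_present"]]
        assert len(non) > 0
        for band in NAMED_BANDS:
            assert non[f"{band}_phase2"].notna().all()
            assert non[f"{band}_phase3"].notna().all()


class TestSummarizeSubject:
    def test_recovers_achieved_profile(self, small_cohort):
        recs, truth = small_cohort
        rec = recs[0]
        ph = summarize_subject(rec)
        ach = truth.achieved_ratios[rec.subject_id]
        cols = list(NAMED_BANDS)
        rel = (ph.amplitudes[cols] / ach[cols] - 1.0).abs()
        assert float(rel.max().max()) < 0.05

    def test_default_profile_within_ten_percent_of_planted(self, noiseless_params):
        rec, truth = simulate_recording(noiseless_params, True, seed=7)
        ph = summarize_subject(rec)
        cols = list(NAMED_BANDS)
        rel = (ph.amplitudes[cols] / truth["target_ratios"][cols] - 1.0).abs()
        assert float(rel.max().max()) < 0.10

    def test_cohort_table_shape_and_flags(self, small_cohort, small_phenotypes):
        _, truth = small_cohort
        assert len(small_phenotypes) == 10
        assert (small_phenotypes["civd_present"].to_numpy()
                == truth.table["civd_present"].to_numpy()).all()

    def test_deterministic(self, small_cohort):
        recs, _ = small_cohort
        a = summarize_subject(recs[0]).amplitudes
        b = summarize_subject(recs[0]).amplitudes
        pd.testing.assert_frame_equal(a, b)

    def test_200hz_generation_path(self):
        p = SignalParams(rate_hz=200.0, noise_sd=0.0, temp_noise_sd=0.0)
        rec, truth = simulate_recording(p, True, seed=1)
        assert rec.rate_hz == 200.0
        ph = summarize_subject(rec)  # downsamples to 5 Hz internally
        assert ph.civd_present
        assert abs(ph.t_minflow_s - truth["t_minflow_s"]) <= 1.0  # block-center shift

    def test_sensitivity_degrades_monotonically_with_noise(self):
        sens = []
        for noise in (0.5, 8.0, 40.0):
            params = SignalParams(noise_sd=noise)
            recs, truth = simulate_cohort(12, prevalence=1.0, params=params, seed=21)
            calls = [detect_civd(r).present for r in recs]
            sens.append(np.mean(calls))
        assert sens[0] >= sens[1] >= sens[2]
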