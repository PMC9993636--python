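"""Synthetic generator: determinism, planted structure, genotype sampling."""

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace
from scipy import stats as st

from civdwave.assoc import hwe_exact
from civdwave.synth import (
    EffectSpec,
    GenotypeSimSpec,
    SignalParams,
    plant_interaction_effects,
    simulate_cohort,
    simulate_genotypes,
    simulate_recording,
)


class TestSimulateRecording:
    def test_seeded_determinism(self, noiseless_params):
        p = SignalParams()
        r1, _ = simulate_recording(p, True, seed=1)
        r2, _ = simulate_recording(p, True, seed=1)
        r3, _ = simulate_recording(p, True, seed=2)
        assert np.array_equal(r1.flow, r2.flow)
        assert np.array_equal(r1.temp, r2.temp)
        assert not np.array_equal(r1.flow, r3.flow)

    def test_noiseless_envelope_minimum_at_planted_time(self):
        # with the oscillation bank silenced the raw flow attains its planted
        # minimum exactly
        p = SignalParams(noise_sd=0.0, temp_noise_sd=0.0, osc_scale=0.0,
                         t_minflow_s=702.0)
        rec, truth = simulate_recording(p, True, seed=0)
        i_imm = int(rec.immersion_start_s * rec.rate_hz)
        t_min = np.argmin(rec.flow[i_imm:]) / rec.rate_hz
        assert abs(t_min - truth["t_minflow_s"]) <= 1.0 / rec.rate_hz + 1e-9

    def test_no_rebound_temperature_monotone(self):
        p = SignalParams(noise_sd=0.0, temp_noise_sd=0.0, rebound_gain=0.0,
                         t_onset_s=None)
        rec, _ = simulate_recording(p, False, seed=0)
        i_imm = int(rec.immersion_start_s * rec.rate_hz)
        assert (np.diff(rec.temp[i_imm:]) <= 1e-9).all()

    def test_inconsistent_landmarks_rejected(self):
        p = SignalParams(t_minflow_s=900.0, t_onset_s=800.0)
        with pytest.raises(ValueError, match="t_minflow_s < t_onset_s"):
            simulate_recording(p, True, seed=0)

    def test_drop_fraction_bounds(self):
        with pytest.raises(ValueError, match="constriction_drop"):
            simulate_recording(replace(SignalParams(), constriction_drop=1.5), True)

    def test_truth_records_achieved_profile(self, noiseless_params):
        _, truth = simulate_recording(noiseless_params, True, seed=4)
        ach = truth["achieved_ratios"]
        assert set(ach.columns) >= {"eno_independent", "eno_dependent", "neurogenic"}
        assert (ach.fillna(0) >= 0).all().all()


class TestSimulateCohort:
    def test_non_civd_count_exact(self, small_cohort):
        _, truth = small_cohort
        assert (~truth.table["civd_present"]).sum() == round(10 * 0.3)

    def test_prevalence_one(self):
        _, truth = simulate_cohort(5, prevalence=1.0, seed=0)
        assert truth.table["civd_present"].all()

    def test_empty_cohort_warns(self):
        with pytest.warns(UserWarning):
            recs, truth = simulate_cohort(0)
        assert recs == []

    def test_study_scale_counts(self):
        # 94 subjects at the study prevalence -> exactly 10 non-responders
        n, prev = 94, 84 / 94
        assert round(n * (1 - prev)) == 10


class TestSimulateGenotypes:
    def test_allele_frequency_concentration(self):
        g = simulate_genotypes(
            GenotypeSimSpec(n_subjects=10000, n_variants=5, maf_range=(0.5, 0.5), seed=1)
        )
        assert ((g.allele_freq() > 0.49) & (g.allele_freq() < 0.51)).all()

    def test_hwe_p_calibrated_under_null(self):
        """Under Hardy-Weinberg sampling the exact-test p-values are valid:
        sub-uniform in every tail (the conditional exact test is discrete and
        conservative, so a KS test against the uniform rejects by design;
        tail calibration is the meaningful null property)."""
        g = simulate_genotypes(
            GenotypeSimSpec(n_subjects=100, n_variants=2000, maf_range=(0.3, 0.3), seed=2)
        )
        pvals = np.array([hwe_exact(*g.genotype_counts(j)) for j in range(g.n_variants)])
        for alpha in (0.001, 0.01, 0.05):
            # allow 3 binomial sds of slack above the nominal level
            slack = 3 * np.sqrt(alpha * (1 - alpha) / g.n_variants)
            assert (pvals < alpha).mean() <= alpha + slack

    def test_no_missingness_full_call_rate(self):
        g = simulate_genotypes(GenotypeSimSpec(50, 20, missing_rate=0.0, seed=0))
        assert (g.call_rate() == 1.0).all()

    def test_missing_rate_applied(self):
        g = simulate_genotypes(GenotypeSimSpec(500, 20, missing_rate=0.1, seed=0))
        assert 0.05 < np.isnan(g.dosage).mean() < 0.15

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            GenotypeSimSpec(10, 5, maf_range=(0.0, 0.5)).validate()
        with pytest.raises(ValueError):
            GenotypeSimSpec(0, 5).validate()


class TestPlantInteraction:
    def _phen(self, g, rng):
        civd = np.ones(g.n_subjects)
        civd[: g.n_subjects // 4] = 0
        return pd.DataFrame(
            {
                "subject_id": g.subjects,
                "civd_present": civd.astype(bool),
                "eno_independent_phase2": 0.6 + 0 * civd,
                "neurogenic_phase2": 0.1 + 0 * civd,
            }
        )

    def test_zero_beta_is_identity(self, genotypes_200x50, rng):
        phen = self._phen(genotypes_200x50, rng)
        out = plant_interaction_effects(
            phen, genotypes_200x50, [EffectSpec(0, "additive", 0.0, "eno_independent")]
        )
        pd.testing.assert_frame_equal(out, phen)

    def test_dominant_shift_by_construction(self, genotypes_200x50, rng):
        phen = self._phen(genotypes_200x50, rng)
        out = plant_interaction_effects(
            phen, genotypes_200x50, [EffectSpec(0, "dominant", -0.2, "eno_independent")]
        )
        non = ~phen["civd_present"].to_numpy()
        carrier = genotypes_200x50.dosage[:, 0] > 0
        grp_carrier = out.loc[non & carrier, "eno_independent_phase2"]
        grp_ref = out.loc[non & ~carrier, "eno_independent_phase2"]
        assert grp_ref.mean() - grp_carrier.mean() == pytest.approx(0.2)
        # responders untouched
        civd_rows = phen["civd_present"].to_numpy()
        assert np.allclose(out.loc[civd_rows, "eno_independent_phase2"],
                           phen.loc[civd_rows, "eno_independent_phase2"])

    def test_unknown_band_rejected(self, genotypes_200x50, rng):
        phen = self._phen(genotypes_200x50, rng)
        with pytest.raises(ValueError, match="unknown band"):
            plant_interaction_effects(
                phen, genotypes_200x50, [EffectSpec(0, "additive", 0.1, "cardiac")]
            )

    def test_amplitudes_clipped_at_zero(self, genotypes_200x50, rng):
        phen = self._phen(genotypes_200x50, rng)
        out = plant_interaction_effects(
            phen, genotypes_200x50, [EffectSpec(0, "additive", -5.0, "neurogenic")]
        )
        assert (out["neurogenic_phase2"] >= 0).all()
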