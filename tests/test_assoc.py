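"""QC, association scans, GEE, Dunnett and LD against independent oracles."""

import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st
import statsmodels.api as sm

from civdwave.assoc import (
    anova_interaction_gwas,
    dunnett_vs_baseline,
    fisher_allelic,
    gee_repeated,
    hwe_exact,
    ld_pairwise,
    logistic_gwas,
    maxT_permutation,
    pca_genotypes,
    select_candidates,
    variant_qc,
)
from civdwave.genotypes import GenotypeMatrix
from civdwave.synth import GenotypeSimSpec, simulate_genotypes


def _gm(dosage, ids=None):
    dosage = np.asarray(dosage, dtype=float)
    n_sub, n_var = dosage.shape
    ids = ids or [f"v{j}" for j in range(n_var)]
    return GenotypeMatrix(
        subjects=[f"s{i}" for i in range(n_sub)],
        variants=pd.DataFrame(
            {"id": ids, "chrom": "1", "pos": np.arange(1, n_var + 1) * 10,
             "ref": "A", "alt": "G"}
        ),
        dosage=dosage,
    )


class TestHWEExact:
    def test_monomorphic_is_one(self):
        assert hwe_exact(25, 0, 0) == 1.0
        assert hwe_exact(0, 0, 25) == 1.0

    def test_small_table_enumeration(self):
        # (1,4,0): rare-allele count 6 of 12; het counts {0,2,4,6} share the
        # conditional distribution; value frozen from direct enumeration
        p = hwe_exact(1, 4, 0)
        assert p == pytest.approx(0.42857142857142855, abs=1e-12)

    def test_homozygote_label_symmetry(self):
        for nAA, nAa, naa in [(3, 5, 9), (0, 7, 2), (10, 1, 4)]:
            assert hwe_exact(nAA, nAa, naa) == pytest.approx(
                hwe_exact(naa, nAa, nAA), abs=1e-12
            )

    def test_rejects_negative(self):
        with pytest.raises(ValueError):
            hwe_exact(-1, 2, 3)


class TestVariantQC:
    def test_constructed_failures_labeled(self):
        n = 100
        rng = np.random.default_rng(1)
        cols = []
        # two call-rate failures, two HWE failures, two MAF failures
        low_cr = rng.binomial(2, 0.3, n).astype(float)
        low_cr[:5] = np.nan
        cols += [low_cr, low_cr.copy()]
        hwe_bad = np.array([1.0] * n)  # all hets: extreme HWE violation
        cols += [hwe_bad, hwe_bad.copy()]
        rare = np.zeros(n)             # monomorphic -> MAF 0
        cols += [rare, rare.copy()]
        g = _gm(np.column_stack(cols))
        rep, gq = variant_qc(g)
        assert gq.n_variants == 0
        reasons = rep.table["reasons"].tolist()
        assert "call_rate" in reasons[0] and "call_rate" in reasons[1]
        assert "hwe" in reasons[2] and "hwe" in reasons[3]
        assert "maf" in reasons[4] and "maf" in reasons[5]

    def test_single_het_among_94_passes_maf_floor(self):
        dosage = np.zeros((94, 1))
        dosage[0, 0] = 1.0  # MAF 1/188 ~ 0.00532 >= 0.005
        rep, gq = variant_qc(_gm(dosage), hwe_alpha=1e-4)
        assert rep.table.loc[0, "maf"] == pytest.approx(1 / 188)
        assert rep.table.loc[0, "pass"]

    def test_null_simulation_few_hwe_failures(self):
        g = simulate_genotypes(
            GenotypeSimSpec(200, 2000, maf_range=(0.3, 0.3), seed=9)
        )
        rep, _ = variant_qc(g)
        hwe_failures = rep.table["reasons"].str.contains("hwe").sum()
        # expected <= alpha * n = 0.2 under the (conservative) exact null
        assert hwe_failures <= 4


class TestFisherAllelic:
    def test_enumeration_example(self):
        # cases 1 subject 2 alt alleles, controls 1 subject 0: table
        # [[2,0],[0,2]] -> p = 1/3 by hypergeometric enumeration
        g = _gm(np.array([[2.0], [0.0]]))
        res = fisher_allelic(g, np.array([1.0, 0.0]))
        assert res.loc[0, "p"] == pytest.approx(1 / 3)

    def test_identical_counts_p_one(self):
        g = _gm(np.array([[1.0], [1.0], [1.0], [1.0]]))
        res = fisher_allelic(g, np.array([1.0, 1.0, 0.0, 0.0]))
        assert res.loc[0, "p"] == 1.0

    def test_case_control_swap_invariance(self, genotypes_200x50):
        y = (np.arange(200) % 2).astype(float)
        p1 = fisher_allelic(genotypes_200x50, y)["p"]
        p2 = fisher_allelic(genotypes_200x50, 1 - y)["p"]
        assert np.allclose(p1, p2)


class TestMaxT:
    def test_single_variant_adjusted_matches_unadjusted(self):
        g = simulate_genotypes(GenotypeSimSpec(60, 1, maf_range=(0.3, 0.4), seed=5))
        y = np.zeros(60)
        y[:30] = 1
        res = maxT_permutation(g, y, n_perm=2000, seed=1)
        # with one variant max(T) is the statistic itself: the adjusted p is
        # the empirical permutation p of that variant (within MC error of
        # the exact p)
        assert res.loc[0, "p"] == pytest.approx(res.loc[0, "p_unadjusted"], abs=0.05)

    def test_adjusted_dominates_unadjusted(self, genotypes_200x50):
        y = (np.arange(200) < 100).astype(float)
        res = maxT_permutation(genotypes_200x50, y, n_perm=200, seed=2)
        assert (res["p"] >= res["p_unadjusted"] - 1e-12).all()

    def test_min_permutations_enforced(self, genotypes_200x50):
        with pytest.raises(ValueError):
            maxT_permutation(genotypes_200x50, np.ones(200), n_perm=10)

    def test_missing_data_path_agrees(self):
        g = simulate_genotypes(
            GenotypeSimSpec(80, 10, maf_range=(0.2, 0.5), missing_rate=0.05, seed=3)
        )
        y = (np.arange(80) % 2).astype(float)
        res = maxT_permutation(g, y, n_perm=150, seed=4)
        assert ((res["p"] > 0) & (res["p"] <= 1)).all()


class TestLogistic:
    def test_null_p_uniform(self):
        g = simulate_genotypes(GenotypeSimSpec(300, 400, maf_range=(0.2, 0.5), seed=7))
        rng = np.random.default_rng(7)
        y = (rng.random(300) < 0.5).astype(float)
        res = logistic_gwas(g, y)
        p = res["p"].dropna()
        assert st.kstest(p, "uniform").pvalue > 0.01

    def test_matches_newton_raphson_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            n = int(rng.integers(40, 100))
            x = rng.binomial(2, 0.4, n).astype(float)
            logit = -0.3 + 0.4 * x
            y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(float)
            if y.sum() in (0, n) or np.ptp(x) == 0:
                continue
            res = logistic_gwas(_gm(x[:, None]), y)
            if math.isnan(res.loc[0, "beta"]):
                continue
            # independent oracle: damped Newton-Raphson on the score equations
            X = np.column_stack([np.ones(n), x])
            beta = np.zeros(2)
            for _ in range(60):
                mu = 1 / (1 + np.exp(-X @ beta))
                w = mu * (1 - mu)
                h = X.T @ (w[:, None] * X)
                step = np.linalg.solve(h, X.T @ (y - mu))
                beta = beta + step
                if np.abs(step).max() < 1e-12:
                    break
            assert res.loc[0, "beta"] == pytest.approx(beta[1], abs=1e-6)

    def test_monomorphic_flagged_missing(self):
        g = _gm(np.ones((40, 1)) * 2)
        y = (np.arange(40) % 2).astype(float)
        res = logistic_gwas(g, y)
        assert math.isnan(res.loc[0, "p"])

    def test_requires_both_classes(self, genotypes_200x50):
        with pytest.raises(ValueError):
            logistic_gwas(genotypes_200x50, np.ones(200))


class TestAnovaInteraction:
    def test_constant_response_f_zero_p_one(self):
        rng = np.random.default_rng(0)
        g = _gm(rng.integers(0, 3, (60, 1)).astype(float))
        civd = (rng.random(60) < 0.5).astype(float)
        res = anova_interaction_gwas(g, civd, np.full(60, 0.5))
        assert res.loc[0, "stat"] == 0.0
        assert res.loc[0, "p"] == 1.0

    def test_matches_statsmodels_model_comparison(self):
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(3)
        for _ in range(10):
            n = 80
            gdos = rng.integers(0, 3, n).astype(float)
            civd = (rng.random(n) < 0.7).astype(float)
            y = rng.normal(0.5, 0.2, n)
            if np.ptp(gdos[civd == 0]) == 0 or np.ptp(gdos[civd == 1]) == 0:
                continue
            res = anova_interaction_gwas(_gm(gdos[:, None]), civd, y)
            df = pd.DataFrame({"y": y, "c": civd, "g": gdos})
            m_f = smf.ols("y ~ c + g + c:g", df).fit()
            m_r = smf.ols("y ~ c + g", df).fit()
            f = sm.stats.anova_lm(m_r, m_f).iloc[1]["F"]
            assert res.loc[0, "stat"] == pytest.approx(f, abs=1e-8)

    def test_allele_flip_invariance_additive(self, genotypes_200x50):
        rng = np.random.default_rng(5)
        civd = (rng.random(200) < 0.85).astype(float)
        y = rng.normal(0.5, 0.1, 200)
        res1 = anova_interaction_gwas(genotypes_200x50, civd, y, "additive")
        flipped = GenotypeMatrix(
            genotypes_200x50.subjects,
            genotypes_200x50.variants,
            2 - genotypes_200x50.dosage,
        )
        res2 = anova_interaction_gwas(flipped, civd, y, "additive")
        assert np.allclose(res1["stat"], res2["stat"], rtol=1e-9)

    def test_empty_cell_flagged_missing(self):
        # all non-responders are reference homozygotes: no interaction df
        gdos = np.array([0.0] * 10 + [1.0] * 10)
        civd = np.array([0.0] * 10 + [1.0] * 10)
        y = np.random.default_rng(0).normal(size=20)
        res = anova_interaction_gwas(_gm(gdos[:, None]), civd, y)
        assert math.isnan(res.loc[0, "stat"])

    def test_planted_interaction_detected(self):
        rng = np.random.default_rng(8)
        n = 200
        gdos = rng.binomial(2, 0.3, n).astype(float)
        civd = (rng.random(n) < 0.5).astype(float)
        y = rng.normal(0.5, 0.1, n) + 0.3 * gdos * civd
        ps = []
        for _ in range(20):
            y_i = rng.normal(0.5, 0.1, n) + 0.3 * gdos * civd
            res = anova_interaction_gwas(_gm(gdos[:, None]), civd, y_i)
            ps.append(res.loc[0, "p"])
        assert np.median(ps) < 1e-4


class TestSelectCandidates:
    def _res(self, pmap):
        return pd.DataFrame({"id": list(pmap), "p": list(pmap.values())})

    def test_study_pair_selected(self):
        # a variant at genome-wide significance in one band and borderline
        # in the other qualifies
        eno = self._res({"v1": 7.02e-7})
        neuro = self._res({"v1": 1.89e-8})
        assert select_candidates(eno, neuro).ids == ["v1"]

    def test_borderline_clause_binds(self):
        eno = self._res({"v1": 2e-5})
        neuro = self._res({"v1": 1e-9})
        assert select_candidates(eno, neuro).ids == []

    def test_both_subthreshold_not_selected(self):
        eno = self._res({"v1": 6e-8})
        neuro = self._res({"v1": 6e-8})
        assert select_candidates(eno, neuro).ids == []


class TestPCA:
    def test_separates_two_populations(self):
        rng = np.random.default_rng(12)
        n_each, n_var = 100, 300
        # allele-frequency divergence ~ Fst 0.05 around a 0.3 ancestral freq
        p_anc = rng.uniform(0.2, 0.5, n_var)
        sd = np.sqrt(0.05 * p_anc * (1 - p_anc))
        p1 = np.clip(p_anc + rng.normal(0, sd), 0.02, 0.98)
        p2 = np.clip(p_anc + rng.normal(0, sd), 0.02, 0.98)
        d1 = rng.binomial(2, p1, (n_each, n_var)).astype(float)
        d2 = rng.binomial(2, p2, (n_each, n_var)).astype(float)
        g = _gm(np.vstack([d1, d2]))
        res = pca_genotypes(g, 2)
        labels = np.array([0] * n_each + [1] * n_each)
        r = np.corrcoef(res.scores[:, 0], labels)[0, 1]
        assert abs(r) > 0.9

    def test_scores_centered_and_orthogonal(self, genotypes_200x50):
        res = pca_genotypes(genotypes_200x50, 3)
        assert np.abs(res.scores.mean(axis=0)).max() < 1e-8
        gram = res.scores.T @ res.scores
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-6 * np.abs(np.diag(gram)).max()
        assert (np.diff(res.eigenvalues) <= 1e-12).all()


class TestGEE:
    def test_one_occasion_equals_ols(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(40)],
                "occasion": 0,
                "y": rng.normal(size=40),
                "x": rng.normal(size=40),
            }
        )
        fit = gee_repeated(df, "y", exog_cols=["x"])
        ols = sm.OLS(df["y"], sm.add_constant(df[["x"]].astype(float))).fit()
        assert np.allclose(fit.params.values, ols.params.values, atol=1e-12)

    def test_rho_near_zero_for_independent_errors(self):
        rng = np.random.default_rng(2)
        n = 500
        rows = []
        for i in range(n):
            for k in range(4):
                rows.append({"subject_id": f"s{i}", "occasion": k,
                             "y": rng.normal(), "x": float(i % 2)})
        fit = gee_repeated(pd.DataFrame(rows), "y", exog_cols=["x"])
        assert abs(fit.rho) < 0.1


class TestDunnett:
    def test_single_contrast_reduces_to_paired_t(self):
        rng = np.random.default_rng(3)
        amp = pd.DataFrame({"baseline": rng.normal(0, 1, 40),
                            "phase1": rng.normal(0.4, 1, 40)})
        res = dunnett_vs_baseline(amp, n_mc=200000, seed=1)
        assert res.loc[0, "p_adjusted"] == pytest.approx(res.loc[0, "p_raw"], abs=0.01)

    def test_adjusted_dominates_raw(self):
        rng = np.random.default_rng(4)
        amp = pd.DataFrame({
            "baseline": rng.normal(0, 1, 30),
            "phase1": rng.normal(0.2, 1, 30),
            "phase2": rng.normal(0.5, 1, 30),
            "phase3": rng.normal(0.1, 1, 30),
        })
        res = dunnett_vs_baseline(amp, n_mc=50000, seed=2)
        assert (res["p_adjusted"] >= res["p_raw"] - 0.01).all()

    def test_familywise_error_calibrated(self):
        rng = np.random.default_rng(5)
        n_rep, alpha = 500, 0.05
        fw = 0
        for r in range(n_rep):
            amp = pd.DataFrame(rng.normal(0, 1, (15, 4)),
                               columns=["baseline", "phase1", "phase2", "phase3"])
            res = dunnett_vs_baseline(amp, n_mc=2000, seed=r)
            fw += (res["p_adjusted"] < alpha).any()
        # binomial 99% upper bound around 0.05 at 500 replicates
        assert fw / n_rep <= 0.05 + 2.576 * np.sqrt(0.05 * 0.95 / n_rep)

    def test_too_few_subjects_rejected(self):
        amp = pd.DataFrame({"baseline": [1.0, 2.0], "phase1": [1.0, 2.0]})
        with pytest.raises(ValueError):
            dunnett_vs_baseline(amp)


class TestLD:
    def test_duplicate_column_perfect_ld(self, genotypes_200x50):
        d = genotypes_200x50.dosage.copy()
        d[:, 1] = d[:, 0]
        g = GenotypeMatrix(genotypes_200x50.subjects, genotypes_200x50.variants, d)
        dp, r2 = ld_pairwise(g, 0, 1)
        assert dp == pytest.approx(1.0, abs=1e-9)
        assert r2 == pytest.approx(1.0, abs=1e-9)

    def test_allele_flip_perfect_ld(self, genotypes_200x50):
        d = genotypes_200x50.dosage.copy()
        d[:, 1] = 2 - d[:, 0]
        g = GenotypeMatrix(genotypes_200x50.subjects, genotypes_200x50.variants, d)
        dp, r2 = ld_pairwise(g, 0, 1)
        assert dp == pytest.approx(1.0, abs=1e-9)
        assert r2 == pytest.approx(1.0, abs=1e-9)

    def test_monomorphic_flagged(self):
        d = np.column_stack([np.ones(50) * 2, np.random.default_rng(0).binomial(2, 0.3, 50)])
        dp, r2 = ld_pairwise(_gm(d), 0, 1)
        assert math.isnan(dp) and math.isnan(r2)

    def test_lookup_by_id(self, genotypes_200x50):
        vid0 = genotypes_200x50.variants["id"].iloc[0]
        vid1 = genotypes_200x50.variants["id"].iloc[1]
        dp, r2 = ld_pairwise(genotypes_200x50, vid0, vid1)
        assert 0 <= r2 <= 1
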