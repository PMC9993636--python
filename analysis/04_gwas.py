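#!/usr/bin/env python
"""Association scans on the simulated cohort.

Plants the CIVD-by-genotype interaction on the first variant's phase-2
amplitudes, runs QC, PCA, the logistic and Fisher+max(T) scans of the
binary CIVD trait, the two-way-ANOVA interaction scan of both band
amplitudes (additive and dominant codings), and applies the
cross-phenotype candidate rule at genome-wide/borderline thresholds.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from civdwave import io  # noqa: E402
from civdwave.assoc import (  # noqa: E402
    anova_interaction_gwas,
    logistic_gwas,
    maxT_permutation,
    pca_genotypes,
    select_candidates,
    variant_qc,
)
from civdwave.evaluation import PLANT_BETA_ENO, PLANT_BETA_NEURO  # noqa: E402
from civdwave.synth import EffectSpec, plant_interaction_effects  # noqa: E402

ROOT = Path(__file__).resolve().parents[1] / "results"
SEED = 20240904


def main():
    phen = pd.read_csv(ROOT / "phenotypes.tsv", sep="\t", na_values=io.NA)
    g = io.read_vcf(ROOT / "cohort" / "genotypes.vcf")
    phen = phen.set_index("subject_id").loc[g.subjects].reset_index()

    # plant the interaction on the detected phenotypes (variant 0)
    phen = plant_interaction_effects(
        phen, g,
        [EffectSpec(0, "additive", PLANT_BETA_ENO, "eno_independent"),
         EffectSpec(0, "additive", PLANT_BETA_NEURO, "neurogenic")],
    )
    planted_id = g.variants["id"].iloc[0]

    rep, gq = variant_qc(g)
    rep.table.to_csv(ROOT / "qc_report.tsv", sep="\t", index=False)
    print(f"QC: {gq.n_variants}/{g.n_variants} variants pass "
          f"(fail reasons: {rep.table.loc[~rep.table['pass'], 'reasons'].value_counts().to_dict()})")

    pca = pca_genotypes(gq, 2)
    pd.DataFrame(pca.scores, columns=["PC1", "PC2"], index=gq.subjects).to_csv(
        ROOT / "pca_scores.tsv", sep="\t")
    print(f"PCA: leading eigenvalues {np.round(pca.eigenvalues, 2)}")

    civd = phen["civd_present"].astype(bool).astype(float).to_numpy()
    logi = logistic_gwas(gq, civd)
    logi.to_csv(ROOT / "gwas_logistic_civd.tsv", sep="\t", index=False, na_rep=io.NA)
    print(f"logistic CIVD scan: min p = {logi['p'].min():.3g}")

    fish = maxT_permutation(gq, civd, n_perm=1000, seed=SEED)
    fish.to_csv(ROOT / "gwas_fisher_maxt_civd.tsv", sep="\t", index=False, na_rep=io.NA)
    print(f"Fisher + max(T) (1000 permutations): min adjusted p = {fish['p'].min():.3g}")

    frames = []
    for coding in ("additive", "dominant"):
        for band in ("eno_independent", "neurogenic"):
            res = anova_interaction_gwas(
                gq, civd, phen[f"{band}_phase2"].to_numpy(), coding)
            res.insert(0, "trait", band)
            frames.append(res)
    anova = pd.concat(frames, ignore_index=True)
    anova.to_csv(ROOT / "gwas_anova_interaction.tsv", sep="\t", index=False,
                 na_rep=io.NA)

    for coding in ("additive", "dominant"):
        sub = anova[anova["model"] == coding]
        eno = sub[sub.trait == "eno_independent"]
        neu = sub[sub.trait == "neurogenic"]
        # the 94-subject cohort cannot reach 5e-8; report candidates at the
        # relaxed thresholds used throughout the recovery experiments
        cand = select_candidates(eno, neu, gw=1e-5, borderline=1e-3)
        row = sub[sub["id"] == planted_id]
        pe = row[row.trait == "eno_independent"]["p"].iloc[0]
        pn = row[row.trait == "neurogenic"]["p"].iloc[0]
        print(f"{coding}: planted variant {planted_id} p_eno={pe:.2g} "
              f"p_neuro={pn:.2g}; candidates at relaxed thresholds: {cand.ids}")
        if coding == "additive":
            cand.table.to_csv(ROOT / "candidates.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
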