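#!/usr/bin/env python
"""Generate the study-scale synthetic cohort: 94 subjects (10 without CIVD),
their flow/temperature recordings, and 500 Hardy-Weinberg variants plus one
planted CIVD-by-genotype interaction variant.

Writes recordings, a VCF, a dosage TSV and the ground-truth ledger under
results/cohort/.
"""

import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from civdwave import io, synth  # noqa: E402
from civdwave.evaluation import PLANT_BETA_ENO, PLANT_BETA_NEURO  # noqa: E402

SEED = 20240901
OUT = Path(__file__).resolve().parents[1] / "results" / "cohort"


def main():
    print(f"simulating 94 subjects (prevalence 84/94), seed {SEED}")
    recs, truth = synth.simulate_cohort(94, prevalence=84 / 94, seed=SEED)
    manifest = io.write_recordings(recs, OUT / "recordings")
    io.write_truth_json(truth, OUT / "truth.json")
    n_non = int((~truth.table["civd_present"]).sum())
    print(f"  -> {len(recs)} recordings ({n_non} without CIVD), manifest {manifest}")

    g = synth.simulate_genotypes(
        synth.GenotypeSimSpec(n_subjects=94, n_variants=501,
                              maf_range=(0.05, 0.5), seed=SEED)
    )
    io.write_vcf(g, OUT / "genotypes.vcf")
    io.write_dosage_tsv(g, OUT / "dosage.tsv")
    print(f"  -> {g.n_variants} variants for {g.n_subjects} subjects; the first "
          f"variant ({g.variants['id'].iloc[0]}) carries the planted interaction "
          f"(beta_eno={PLANT_BETA_ENO}, beta_neuro={PLANT_BETA_NEURO}, applied "
          "to the phenotype table in 04_gwas.py)")
    np.savetxt(OUT / "planted_variant.txt", [0], fmt="%d")


if __name__ == "__main__":
    main()
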