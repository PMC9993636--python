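"""Subjects x variants dosage container shared by the simulator, I/O and GWAS."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class GenotypeMatrix:
    """Biallelic genotypes as alt-allele dosages; NaN marks missing calls.

    ``variants`` has columns id, chrom, pos (1-based), ref, alt.
    """

    subjects: list[str]
    variants: pd.DataFrame
    dosage: np.ndarray  # (n_subjects, n_variants), values in {0,1,2,NaN}

    def __post_init__(self):
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.subjects), len(self.variants)):
            raise ValueError("dosage dimensions inconsistent with subjects/variants")
        if (self.variants["pos"] <= 0).any():
            raise ValueError("positions must be 1-based positive")
        if self.variants["id"].duplicated().any():
            raise ValueError("duplicate variant ids")

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def call_rate(self) -> np.ndarray:
        return 1.0 - np.isnan(self.dosage).mean(axis=0)

    def allele_freq(self) -> np.ndarray:
        """Alt-allele frequency per variant over non-missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosage, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def genotype_counts(self, j: int) -> tuple[int, int, int]:
        """(n_ref_hom, n_het, n_alt_hom) for variant j, missing excluded."""
        col = self.dosage[:, j]
        col = col[~np.isnan(col)]
        return int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum())

    def subset_variants(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        return GenotypeMatrix(
            subjects=list(self.subjects),
            variants=self.variants.loc[keep].reset_index(drop=True),
            dosage=self.dosage[:, keep],
        )
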