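"""Variant-level quality control: call rate, Hardy-Weinberg, MAF."""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..genotypes import GenotypeMatrix


def hwe_exact(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact Hardy-Weinberg test (Wigginton-style, two-sided).

    Conditional on the observed allele counts, sums the probabilities of
    all heterozygote counts whose conditional probability does not exceed
    the observed one.  Monomorphic sites return 1.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("empty genotype table")
    n_rare = 2 * min(n_AA, n_aa) + n_Aa
    if n_rare == 0:
        return 1.0
    # heterozygote counts share the parity of the rare-allele count
    het_probs = {}
    mid = n_rare * (2 * n - n_rare) // (2 * n)
    if mid % 2 != n_rare % 2:
        mid += 1
    het_probs[mid] = 1.0
    # recurse downward:  P(h-2)/P(h) = h(h-1) / (4 * hom_r(h+?) ...)
    h = mid
    hom_r = (n_rare - mid) // 2
    hom_c = n - mid - hom_r
    cur = 1.0
    hr, hc = hom_r, hom_c
    while h > 1:
        nxt = cur * h * (h - 1) / (4.0 * (hr + 1) * (hc + 1))
        het_probs[h - 2] = nxt
        cur = nxt
        h -= 2
        hr += 1
        hc += 1
    h, hr, hc = mid, hom_r, hom_c
    cur = 1.0
    while h + 2 <= n_rare:
        nxt = cur * 4.0 * hr * hc / ((h + 2) * (h + 1))
        het_probs[h + 2] = nxt
        cur = nxt
        h += 2
        hr -= 1
        hc -= 1
    total = sum(het_probs.values())
    obs = het_probs[n_Aa] / total
    p = sum(v for v in het_probs.values() if v / total <= obs * (1 + 1e-12)) / total
    return min(1.0, p)


@dataclass
class VariantQCReport:
    table: pd.DataFrame  # id, call_rate, maf, hwe_p, pass, reasons

    def n_pass(self) -> int:
        return int(self.table["pass"].sum())


def variant_qc(
    g: GenotypeMatrix,
    call_rate_min: float = 0.97,
    hwe_alpha: float = 1e-4,
    maf_min: float = 0.005,
) -> tuple[VariantQCReport, GenotypeMatrix]:
    """Drop variants failing call-rate, HWE or MAF thresholds.

    The default thresholds are the array-data profile (call rate >= 0.97,
    HWE p >= 1e-4, MAF >= 0.005); for imputed dosages a 1% MAF floor is the
    conventional choice (pass ``maf_min=0.01``).
    """
    call_rate = g.call_rate()
    maf = g.maf()
    hwe_p = np.empty(g.n_variants)
    for j in range(g.n_variants):
        n0, n1, n2 = g.genotype_counts(j)
        hwe_p[j] = hwe_exact(n0, n1, n2) if (n0 + n1 + n2) else 1.0
    reasons = []
    for j in range(g.n_variants):
        r = []
        if call_rate[j] < call_rate_min:
            r.append("call_rate")
        if hwe_p[j] < hwe_alpha:
            r.append("hwe")
        if not (maf[j] >= maf_min):  # NaN-frequency variants also fail
            r.append("maf")
        reasons.append(",".join(r))
    table = pd.DataFrame(
        {
            "id": g.variants["id"],
            "call_rate": call_rate,
            "maf": maf,
            "hwe_p": hwe_p,
            "pass": [r == "" for r in reasons],
            "reasons": reasons,
        }
    )
    keep = table["pass"].to_numpy()
    if not keep.any():
        warnings.warn("all variants failed QC")
    return VariantQCReport(table=table), g.subset_variants(keep)
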