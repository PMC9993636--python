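"""Pairwise linkage disequilibrium from unphased genotypes (EM haplotypes)."""

from __future__ import annotations

import numpy as np

from ..genotypes import GenotypeMatrix


def _em_haplotypes(g1: np.ndarray, g2: np.ndarray, tol=1e-10, max_iter=200):
    """EM estimate of the four haplotype frequencies (AB, Ab, aB, ab).

    A/a are ref/alt at locus 1 (dosage counts alt), likewise B/b; the only
    ambiguous genotype class is the double heterozygote.
    """
    keep = ~np.isnan(g1) & ~np.isnan(g2)
    g1, g2 = g1[keep].astype(int), g2[keep].astype(int)
    n = g1.size
    if n == 0 or np.ptp(g1) == 0 or np.ptp(g2) == 0:
        return None
    # genotype-class counts
    counts = np.zeros((3, 3))
    for a, b in zip(g1, g2):
        counts[a, b] += 1
    n_hap = 2.0 * n
    p1, p2 = g1.mean() / 2.0, g2.mean() / 2.0
    # init at linkage equilibrium; h = (f_AB, f_Ab, f_aB, f_ab), A=ref
    q1, q2 = 1 - p1, 1 - p2
    h = np.array([q1 * q2, q1 * p2, p1 * q2, p1 * p2])
    # unambiguous haplotype contributions
    base = np.zeros(4)
    for a in range(3):
        for b in range(3):
            c = counts[a, b]
            if c == 0 or (a == 1 and b == 1):
                continue
            # locus1 contributes (2-a) ref and a alt alleles, paired freely
            base[0] += c * (2 - a) * (2 - b) / 2.0
            base[1] += c * (2 - a) * b / 2.0
            base[2] += c * a * (2 - b) / 2.0
            base[3] += c * a * b / 2.0
    n_dh = counts[1, 1]
    for _ in range(max_iter):
        # double hets are AB/ab (cis) or Ab/aB (trans)
        cis = h[0] * h[3]
        trans = h[1] * h[2]
        tot = cis + trans
        w = 0.5 if tot == 0 else cis / tot
        new = base + n_dh * np.array([w, 1 - w, 1 - w, w])
        new /= n_hap
        if np.abs(new - h).max() < tol:
            h = new
            break
        h = new
    return h


def ld_pairwise(g: GenotypeMatrix, v1, v2) -> tuple[float, float]:
    """(D', r^2) between two variants, by id or column index."""
    def col(v):
        if isinstance(v, (int, np.integer)):
            return g.dosage[:, v]
        j = g.variants.index[g.variants["id"] == v]
        if len(j) != 1:
            raise KeyError(f"variant {v!r} not found")
        return g.dosage[:, j[0]]

    h = _em_haplotypes(col(v1), col(v2))
    if h is None:
        return float("nan"), float("nan")
    f_ab = h[3]                      # alt-alt haplotype
    p1 = h[2] + h[3]                 # alt freq locus 1
    p2 = h[1] + h[3]
    d = f_ab - p1 * p2
    denom = p1 * (1 - p1) * p2 * (1 - p2)
    if denom <= 0:
        return float("nan"), float("nan")
    r2 = d * d / denom
    if d >= 0:
        dmax = min(p1 * (1 - p2), (1 - p1) * p2)
    else:
        dmax = min(p1 * p2, (1 - p1) * (1 - p2))
    dprime = abs(d) / dmax if dmax > 0 else float("nan")
    return float(min(dprime, 1.0)), float(min(r2, 1.0))
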