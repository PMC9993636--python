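"""Genotype PCA for population-stratification covariates."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ..genotypes import GenotypeMatrix


@dataclass
class PCAResult:
    scores: np.ndarray       # (n_subjects, k), columns orthogonal
    eigenvalues: np.ndarray  # non-increasing
    loadings: np.ndarray | None = None


def pca_genotypes(g: GenotypeMatrix, k: int = 2) -> PCAResult:
    """Leading principal components of the standardized dosage matrix.

    Missing dosages are mean-imputed per variant; columns are centered at
    2*p_hat and scaled by sqrt(2*p_hat*(1-p_hat)) (the usual unit-variance
    scaling under Hardy-Weinberg).  Zero-variance variants are excluded.
    """
    if g.n_subjects < k + 1:
        raise ValueError("need at least k+1 subjects")
    x = g.dosage.copy()
    p = g.allele_freq()
    ok = np.isfinite(p) & (p > 0) & (p < 1)
    if not ok.all():
        warnings.warn(f"excluding {int((~ok).sum())} zero-variance variants from PCA")
    x = x[:, ok]
    p = p[ok]
    mean = 2.0 * p
    sd = np.sqrt(2.0 * p * (1.0 - p))
    inds = np.where(np.isnan(x))
    x[inds] = np.take(mean, inds[1])
    z = (x - mean) / sd
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    scores = u[:, :k] * s[:k]
    eig = (s**2) / max(1, g.n_subjects - 1)
    return PCAResult(scores=scores, eigenvalues=eig[:k], loadings=vt[:k].T)
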