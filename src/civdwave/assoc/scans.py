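"""Single-variant association scans and the cross-phenotype candidate rule.

Three scans mirror the CIVD study design: logistic regression and Fisher's
exact allelic test for binary traits (CIVD presence and the high/low band
categories), with family-wise error controlled by max(T) permutation, and
a two-way-ANOVA interaction scan in which the phase-2 band amplitude is
regressed on CIVD response, genotype and their interaction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm

from ..genotypes import GenotypeMatrix


def _code(dosage: np.ndarray, coding: str) -> np.ndarray:
    if coding == "additive":
        return dosage.astype(float)
    if coding == "dominant":
        out = (dosage > 0).astype(float)
        out[np.isnan(dosage)] = np.nan
        return out
    raise ValueError(f"unknown coding {coding!r}")


def logistic_gwas(
    g: GenotypeMatrix,
    trait: np.ndarray,
    coding: str = "additive",
    covariates: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-variant maximum-likelihood logistic fit of a binary trait.

    Non-convergent or separated fits are reported as NaN rather than as
    fabricated statistics; monomorphic variants likewise.
    """
    y = np.asarray(trait, dtype=float)
    if set(np.unique(y[~np.isnan(y)])) - {0.0, 1.0}:
        raise ValueError("trait must be binary 0/1")
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("both trait classes must be present")
    rows = []
    coded_all = _code(g.dosage, coding)
    for j in range(g.n_variants):
        x = coded_all[:, j]
        keep = ~np.isnan(x) & ~np.isnan(y)
        xj, yj = x[keep], y[keep]
        beta = se = zstat = pval = np.nan
        if np.ptp(xj) > 0 and 0 < yj.sum() < len(yj):
            cols = [np.ones_like(xj), xj]
            if covariates is not None:
                cols.extend(np.asarray(covariates)[keep].T)
            design = np.column_stack(cols)
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    fit = sm.Logit(yj, design).fit(disp=0, maxiter=100)
                if fit.mle_retvals.get("converged", False) and np.isfinite(fit.bse[1]) \
                        and fit.bse[1] < 1e3:
                    beta, se = fit.params[1], fit.bse[1]
                    zstat = beta / se
                    pval = 2 * st.norm.sf(abs(zstat))
            except Exception:
                pass
        rows.append(
            {
                "id": g.variants["id"].iloc[j],
                "chrom": g.variants["chrom"].iloc[j],
                "pos": g.variants["pos"].iloc[j],
                "model": coding,
                "test": "logistic",
                "beta": beta,
                "stat": zstat,
                "p": pval,
                "n_used": int(keep.sum()),
            }
        )
    return pd.DataFrame(rows)


def _allele_table(dosage_col: np.ndarray, trait: np.ndarray):
    keep = ~np.isnan(dosage_col) & ~np.isnan(trait)
    d, y = dosage_col[keep], trait[keep]
    case_alt = d[y == 1].sum()
    case_ref = 2 * (y == 1).sum() - case_alt
    ctrl_alt = d[y == 0].sum()
    ctrl_ref = 2 * (y == 0).sum() - ctrl_alt
    return np.array([[case_alt, case_ref], [ctrl_alt, ctrl_ref]], dtype=int), int(keep.sum())


def fisher_allelic(g: GenotypeMatrix, trait: np.ndarray) -> pd.DataFrame:
    """Two-sided Fisher's exact test on 2x2 allele-count tables."""
    y = np.asarray(trait, dtype=float)
    rows = []
    for j in range(g.n_variants):
        tab, n_used = _allele_table(g.dosage[:, j], y)
        if tab.sum(axis=0).min() == 0 or tab.sum(axis=1).min() == 0:
            odds, p = np.nan, 1.0
        else:
            odds, p = st.fisher_exact(tab, alternative="two-sided")
        rows.append(
            {
                "id": g.variants["id"].iloc[j],
                "chrom": g.variants["chrom"].iloc[j],
                "pos": g.variants["pos"].iloc[j],
                "model": "additive",
                "test": "fisher",
                "stat": odds,
                "p": p,
                "n_used": n_used,
            }
        )
    return pd.DataFrame(rows)


def _fisher_p_lookup(alt_total: int, n_case: int, n_subj: int) -> np.ndarray:
    """Two-sided Fisher p for every possible case alt-allele count.

    With complete genotypes, a label permutation fixes both table margins,
    so the per-variant p is a function of the case alt-count alone.
    """
    n_alleles = 2 * n_subj
    n_case_al = 2 * n_case
    lo = max(0, alt_total - (n_alleles - n_case_al))
    hi = min(alt_total, n_case_al)
    support = np.arange(lo, hi + 1)
    pmf = st.hypergeom.pmf(support, n_alleles, alt_total, n_case_al)
    out = np.ones(alt_total + 1)
    for a, pa in zip(support, pmf):
        out[a] = pmf[pmf <= pa * (1 + 1e-12)].sum()
    return np.minimum(out, 1.0)


def maxT_permutation(
    g: GenotypeMatrix,
    trait: np.ndarray,
    test: str = "fisher",
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Family-wise adjusted empirical p by max(T) label permutation.

    The statistic is -log10 of the per-variant p; the adjusted p for
    variant i is (1 + #{permutations whose best statistic across all
    variants >= observed_i}) / (n_perm + 1), which can never be zero at
    finite permutation counts.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if test != "fisher":
        raise ValueError("max(T) permutation is implemented for the fisher test")
    y = np.asarray(trait, dtype=float)
    rng = np.random.default_rng(seed)
    obs = fisher_allelic(g, y)
    obs_stat = -np.log10(np.clip(obs["p"].to_numpy(), 1e-300, None))

    complete = not np.isnan(g.dosage).any()
    if complete:
        d = g.dosage
        n_case = int(y.sum())
        alt_tot = d.sum(axis=0).astype(int)
        lookups = [_fisher_p_lookup(a, n_case, g.n_subjects) for a in alt_tot]
        max_stats = np.empty(n_perm)
        labels = np.zeros(g.n_subjects)
        for b in range(n_perm):
            perm = rng.permutation(g.n_subjects)[:n_case]
            labels[:] = 0.0
            labels[perm] = 1.0
            case_alt = (labels @ d).astype(int)
            pvals = np.array([lookups[j][case_alt[j]] for j in range(g.n_variants)])
            max_stats[b] = (-np.log10(np.clip(pvals, 1e-300, None))).max()
    else:  # missing genotypes: permute and re-run the exact test per variant
        max_stats = np.empty(n_perm)
        for b in range(n_perm):
            yp = rng.permutation(y)
            pv = fisher_allelic(g, yp)["p"].to_numpy()
            max_stats[b] = (-np.log10(np.clip(pv, 1e-300, None))).max()

    adj = np.array(
        [(1 + (max_stats >= s - 1e-12).sum()) / (n_perm + 1) for s in obs_stat]
    )
    out = obs.copy()
    out["p_unadjusted"] = out["p"]
    out["p"] = adj
    out["test"] = "fisher_maxT"
    return out


def anova_interaction_gwas(
    g: GenotypeMatrix,
    civd_flag: np.ndarray,
    amplitude: np.ndarray,
    coding: str = "additive",
) -> pd.DataFrame:
    """Interaction F-test: does the genotype effect on the phase-2 band
    amplitude differ between CIVD responders and non-responders?

    Per variant, the full least-squares model (civd + genotype +
    civd:genotype) is compared with the additive model (civd + genotype);
    the F statistic for the highest-order term is invariant to the
    sums-of-squares type.  Designs with an empty civd-by-genotype cell are
    reported as NaN.
    """
    civd = np.asarray(civd_flag, dtype=float)
    amp = np.asarray(amplitude, dtype=float)
    coded_all = _code(g.dosage, coding)
    rows = []
    for j in range(g.n_variants):
        x = coded_all[:, j]
        keep = ~np.isnan(x) & ~np.isnan(amp) & ~np.isnan(civd)
        xj, yj, cj = x[keep], amp[keep], civd[keep]
        fstat = pval = np.nan
        df1 = df2 = 0
        # the interaction needs genotype variation within both civd groups
        ok = (
            keep.sum() > 4
            and len(np.unique(cj)) == 2
            and np.ptp(xj[cj == 0]) > 0
            and np.ptp(xj[cj == 1]) > 0
        )
        if ok:
            x_full = np.column_stack([np.ones_like(xj), cj, xj, cj * xj])
            x_red = x_full[:, :3]
            rss_f, rank_f = _rss(x_full, yj)
            rss_r, rank_r = _rss(x_red, yj)
            df1 = rank_f - rank_r
            df2 = int(keep.sum()) - rank_f
            if df1 > 0 and df2 > 0:
                if rss_f <= 1e-12 * max(1.0, rss_r):
                    # degenerate: a constant (or perfectly fitted) response
                    fstat = np.inf if rss_r - rss_f > 1e-12 else 0.0
                    pval = 0.0 if fstat == np.inf else 1.0
                else:
                    fstat = ((rss_r - rss_f) / df1) / (rss_f / df2)
                    fstat = max(fstat, 0.0)
                    pval = float(st.f.sf(fstat, df1, df2))
        rows.append(
            {
                "id": g.variants["id"].iloc[j],
                "chrom": g.variants["chrom"].iloc[j],
                "pos": g.variants["pos"].iloc[j],
                "model": coding,
                "test": "anova_interaction",
                "stat": fstat,
                "df1": df1,
                "df2": df2,
                "p": pval,
                "n_used": int(keep.sum()),
            }
        )
    return pd.DataFrame(rows)


def _rss(x: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    beta, res, rank, _ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    return float(resid @ resid), int(rank)


@dataclass
class CandidateSet:
    table: pd.DataFrame  # id, p_eno, p_neuro, genomewide_trait

    @property
    def ids(self) -> list[str]:
        return list(self.table["id"])


def select_candidates(
    results_eno: pd.DataFrame,
    results_neuro: pd.DataFrame,
    gw: float = 5e-8,
    borderline: float = 1e-5,
) -> CandidateSet:
    """Cross-phenotype rule: genome-wide in one band amplitude and at least
    borderline in the other."""
    a = results_eno.set_index("id")["p"]
    b = results_neuro.set_index("id")["p"]
    common = a.index.intersection(b.index)
    a, b = a.loc[common], b.loc[common]
    sel_eno = (a < gw) & (b < borderline)
    sel_neuro = (b < gw) & (a < borderline)
    chosen = sel_eno | sel_neuro
    table = pd.DataFrame(
        {
            "id": common[chosen],
            "p_eno": a[chosen].to_numpy(),
            "p_neuro": b[chosen].to_numpy(),
            "genomewide_trait": np.where(
                sel_eno[chosen], "eno_independent", "neurogenic"
            ),
        }
    ).reset_index(drop=True)
    return CandidateSet(table=table)
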