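"""Generalized estimating equations for the repeated phase measurements.

Each subject contributes one band-amplitude value per phase (baseline,
phase 1-3); the within-subject correlation of these repeated measurements
is modeled with a first-order autoregressive working structure, a Gaussian
family with identity link, and robust (sandwich) standard errors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm


@dataclass
class GEEFit:
    params: pd.Series
    robust_se: pd.Series
    p: pd.Series
    rho: float           # AR(1) working-correlation parameter
    n_clusters: int
    n_obs: int
    converged: bool


def gee_repeated(
    long_table: pd.DataFrame,
    response: str,
    subject_col: str = "subject_id",
    time_col: str = "occasion",
    exog_cols: list[str] | None = None,
    corstr: str = "ar1",
) -> GEEFit:
    """Fit a Gaussian identity-link GEE on a long-format repeated table.

    ``time_col`` must give the within-subject measurement order (the wave),
    e.g. 0..3 for baseline, phase1, phase2, phase3.  ``exog_cols`` name the
    regressors (a constant is always added); robust sandwich covariance is
    reported.  With one occasion per subject the estimating equations
    collapse to ordinary least squares.
    """
    df = long_table.dropna(subset=[response] + list(exog_cols or []))
    if exog_cols:
        exog = sm.add_constant(df[list(exog_cols)].astype(float), has_constant="add")
    else:
        exog = pd.DataFrame({"const": np.ones(len(df))}, index=df.index)
    if corstr == "ar1":
        cov = sm.cov_struct.Autoregressive(grid=True)
    elif corstr == "exchangeable":
        cov = sm.cov_struct.Exchangeable()
    elif corstr == "independence":
        cov = sm.cov_struct.Independence()
    else:
        raise ValueError(f"unknown corstr {corstr!r}")
    model = sm.GEE(
        df[response].astype(float),
        exog,
        groups=df[subject_col].to_numpy(),
        time=df[time_col].astype(int).to_numpy(),
        family=sm.families.Gaussian(),
        cov_struct=cov,
    )
    res = model.fit(maxiter=100)
    rho = float(np.atleast_1d(cov.dep_params)[0]) if corstr == "ar1" else float("nan")
    return GEEFit(
        params=res.params,
        robust_se=res.bse,
        p=res.pvalues,
        rho=rho,
        n_clusters=int(df[subject_col].nunique()),
        n_obs=len(df),
        converged=bool(getattr(res, "converged", True)),
    )


def phases_long_table(
    phenotypes: pd.DataFrame, band: str, phases=("baseline", "phase1", "phase2", "phase3")
) -> pd.DataFrame:
    """Reshape the per-subject phenotype table to subject x occasion rows."""
    rows = []
    for _, r in phenotypes.iterrows():
        for k, ph in enumerate(phases):
            rows.append(
                {
                    "subject_id": r["subject_id"],
                    "occasion": k,
                    "phase": ph,
                    "amplitude": r.get(f"{band}_{ph}", np.nan),
                }
            )
    return pd.DataFrame(rows)
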