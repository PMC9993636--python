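"""Paired many-to-one comparisons of phase amplitudes against baseline.

Within-subject differences (phase k minus baseline) give one paired t
statistic per phase; the familywise adjustment simulates the joint null of
the correlated max-|t| statistic (Dunnett-style many-to-one contrasts) by
Monte Carlo, which is exact up to simulation error for the multivariate-t
reference the quadrature formulation would use.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def dunnett_vs_baseline(
    amplitudes: pd.DataFrame,
    baseline_col: str = "baseline",
    n_mc: int = 20000,
    seed: int = 0,
) -> pd.DataFrame:
    """Adjusted p per phase for subject-paired comparisons vs baseline.

    ``amplitudes`` is wide: one row per subject, one column per phase
    including the baseline column.  Rows with any missing value are
    dropped.  Returns raw paired-t p values and max-|t|-adjusted p values.
    """
    df = amplitudes.dropna()
    phases = [c for c in df.columns if c != baseline_col]
    if not phases:
        raise ValueError("need at least one non-baseline phase")
    n = len(df)
    if n < 3:
        raise ValueError("need at least 3 complete subjects")
    diffs = df[phases].to_numpy() - df[[baseline_col]].to_numpy()
    mean = diffs.mean(axis=0)
    se = diffs.std(axis=0, ddof=1) / np.sqrt(n)
    tstats = mean / se
    dfree = n - 1

    # correlation of the difference vectors across subjects
    corr = np.corrcoef(diffs, rowvar=False)
    corr = np.atleast_2d(corr)
    # Monte-Carlo max-|t| null: correlated normals over a shared chi scale
    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(corr + 1e-10 * np.eye(len(phases)))
    z = rng.standard_normal((n_mc, len(phases))) @ chol.T
    scale = np.sqrt(rng.chisquare(dfree, size=n_mc) / dfree)
    max_abs_t = np.abs(z / scale[:, None]).max(axis=1)

    from scipy import stats as st

    raw = 2 * st.t.sf(np.abs(tstats), dfree)
    adj = np.array(
        [(1 + (max_abs_t >= abs(t)).sum()) / (n_mc + 1) for t in tstats]
    )
    return pd.DataFrame(
        {
            "phase": phases,
            "mean_diff": mean,
            "t": tstats,
            "df": dfree,
            "p_raw": raw,
            "p_adjusted": np.minimum(1.0, adj),
            "n": n,
        }
    )
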