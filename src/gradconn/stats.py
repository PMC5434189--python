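"""Between-group tests: Mann-Whitney U (normal approximation) and ANCOVA.

The behavioral and extracted-connectivity group comparisons use the
nonparametric Mann-Whitney U test with a tie-corrected, continuity-corrected
normal approximation (appropriate for the unequal 48/18 group sizes), and an
ANCOVA that tests a binary group factor while controlling for continuous
covariates (age, PTSD severity, depression, lifetime mild TBIs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm
import statsmodels.api as sm

__all__ = ["MannWhitneyResult", "AncovaResult", "mann_whitney_z", "ancova_group_F"]


@dataclass(frozen=True)
class MannWhitneyResult:
    u: float
    z: float
    p: float
    degenerate_variance: bool = False


@dataclass(frozen=True)
class AncovaResult:
    """Partial F for the group factor plus a per-covariate F table."""

    f_group: float
    df: tuple[int, int]
    p: float
    covariate_table: pd.DataFrame


def mann_whitney_z(x, y) -> MannWhitneyResult:
    """Mann-Whitney U with tie-corrected, continuity-corrected normal z.

    U counts pairs where x exceeds y, with 0.5 credit per tie.  The z
    statistic is (U - nm/2 -/+ 0.5) / sigma with the tie-corrected variance;
    swapping the samples negates z.  If every value is tied across both
    samples the variance is zero and z = 0 is returned with a flag.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n, m = len(x), len(y)
    if n < 1 or m < 1:
        raise ValueError("both samples must be non-empty")
    diff = x[:, None] - y[None, :]
    u = float(np.sum(diff > 0) + 0.5 * np.sum(diff == 0))

    combined = np.concatenate([x, y])
    _, counts = np.unique(combined, return_counts=True)
    nm = n + m
    tie_term = np.sum(counts**3 - counts) / (nm * (nm - 1)) if nm > 1 else 0.0
    var = n * m / 12.0 * ((nm + 1) - tie_term)
    if var <= 0:
        return MannWhitneyResult(u=u, z=0.0, p=1.0, degenerate_variance=True)

    centered = u - n * m / 2.0
    cc = 0.5 * np.sign(centered)  # continuity correction toward the null
    z = float((centered - cc) / np.sqrt(var))
    p = float(2.0 * norm.sf(abs(z)))
    return MannWhitneyResult(u=u, z=z, p=min(p, 1.0))


def ancova_group_F(dv, group, covariates: pd.DataFrame | None = None) -> AncovaResult:
    """Partial F for a binary group factor controlling for continuous covariates.

    Fits dv ~ intercept + group + covariates by OLS on complete cases and
    compares against the model without the group column (type-III style; with
    a single factor the partial F is unambiguous).  Covariate rows with
    missing values drop the subject.  Without covariates the F equals the
    squared pooled two-sample t.
    """
    dv = np.asarray(dv, float)
    group = np.asarray(group, float)
    if covariates is not None:
        covariates = pd.DataFrame(covariates)
        keep = ~(np.isnan(dv) | covariates.isna().any(axis=1).to_numpy())
    else:
        keep = ~np.isnan(dv)
    dv, group = dv[keep], group[keep]
    if len(np.unique(group)) < 2:
        raise ValueError("group column is constant after dropping incomplete cases")

    cov = covariates.loc[keep].to_numpy(float) if covariates is not None else np.empty((len(dv), 0))
    X_full = np.column_stack([np.ones_like(dv), group, cov])
    if np.linalg.matrix_rank(X_full) < X_full.shape[1]:
        raise ValueError("design matrix is rank deficient (covariate collinear with group?)")

    full = sm.OLS(dv, X_full).fit()
    names = ["group"] + (list(covariates.columns) if covariates is not None else [])
    rows = []
    f_group = p_group = None
    for j, name in enumerate(names, start=1):
        reduced = sm.OLS(dv, np.delete(X_full, j, axis=1)).fit()
        f, p, _ = full.compare_f_test(reduced)
        rows.append({"term": name, "F": float(f), "p": float(p)})
        if name == "group":
            f_group, p_group = float(f), float(p)
    df = (1, int(full.df_resid))
    table = pd.DataFrame(rows)
    return AncovaResult(f_group=f_group, df=df, p=p_group,
                        covariate_table=table[table["term"] != "group"].reset_index(drop=True))
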