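"""Nuisance regression and seed-based functional connectivity.

Per-subject time series (voxel or parcel) are residualized against the six
motion parameters plus CSF, white-matter and global-signal regressors; the
mean seed (amygdala) time series is then correlated with every other location
and the Pearson r values are Fisher z-transformed for group analysis.  Group
difference maps use a pooled-variance two-sample t per location, or the
signed square root of the partial F for the group factor when covariates are
supplied (ANCOVA-style adjustment).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "NUISANCE_COLUMNS",
    "TimeSeriesBundle",
    "FCMap",
    "GroupDiffMap",
    "nuisance_residualize",
    "seed_connectivity",
    "fisher_z",
    "group_difference_map",
]

NUISANCE_COLUMNS = ["mot1", "mot2", "mot3", "mot4", "mot5", "mot6", "csf", "wm", "global"]

_R_CLIP = 1.0 - 1e-7


@dataclass
class TimeSeriesBundle:
    """T x V data matrix with its T x 9 nuisance table and location labels."""

    data: np.ndarray
    nuisance: np.ndarray
    tr_s: float = 2.0
    labels: list | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, float)
        self.nuisance = np.asarray(self.nuisance, float)
        if self.data.shape[0] != self.nuisance.shape[0]:
            raise ValueError("data and nuisance must share the time dimension")
        if not (np.isfinite(self.data).all() and np.isfinite(self.nuisance).all()):
            raise ValueError("non-finite values in time series or nuisance table")


@dataclass
class FCMap:
    """Seed connectivity map: Pearson r and its Fisher z per location.

    Seed locations themselves and zero-variance series are reported as
    missing (NaN) rather than as r = 1.
    """

    seed_id: str
    r: np.ndarray
    z: np.ndarray
    missing: np.ndarray

    @property
    def n_missing(self) -> int:
        return int(self.missing.sum())


@dataclass
class GroupDiffMap:
    """Per-location group contrast on Fisher z (positive = group1 > group0)."""

    stat: np.ndarray
    df: int
    p: np.ndarray
    nominal_p: float | None = None

    def threshold_value(self, nominal_p: float) -> float:
        """Two-sided t critical value at the given per-location p."""
        return float(stats.t.ppf(1.0 - nominal_p / 2.0, self.df))


def nuisance_residualize(bundle: TimeSeriesBundle) -> np.ndarray:
    """Least-squares residual of every data column against [1 | nuisance].

    Residuals are orthogonal to all regressors; the operation is idempotent.
    Raises on a rank-deficient design, naming the redundant columns.
    """
    T = bundle.data.shape[0]
    X = np.column_stack([np.ones(T), bundle.nuisance])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # locate columns that add no rank beyond their predecessors
        bad = []
        for j in range(1, X.shape[1]):
            if np.linalg.matrix_rank(X[:, : j + 1]) == np.linalg.matrix_rank(X[:, :j]):
                bad.append(NUISANCE_COLUMNS[j - 1] if j - 1 < len(NUISANCE_COLUMNS) else str(j - 1))
        raise ValueError(f"nuisance design is rank deficient; collinear columns: {bad}")
    beta, *_ = np.linalg.lstsq(X, bundle.data, rcond=None)
    return bundle.data - X @ beta


def fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    """Variance-stabilizing arctanh transform, clipped at |r| <= 1 - 1e-7."""
    return np.arctanh(np.clip(r, -_R_CLIP, _R_CLIP))


def seed_connectivity(residuals: np.ndarray, seed: np.ndarray | list | int,
                      seed_id: str = "seed") -> FCMap:
    """Correlate the unweighted mean seed series with every other location.

    ``seed`` is an index or index set into the columns of ``residuals``.
    """
    residuals = np.asarray(residuals, float)
    T, V = residuals.shape
    if T < 3:
        raise ValueError("need at least 3 time points")
    seed_idx = np.atleast_1d(np.asarray(seed, int))
    if seed_idx.size == 0:
        raise ValueError("seed must be non-empty")
    seed_series = residuals[:, seed_idx].mean(axis=1)
    s = seed_series - seed_series.mean()
    s_norm = np.linalg.norm(s)
    if s_norm == 0:
        raise ValueError("seed series has zero variance")

    X = residuals - residuals.mean(axis=0)
    norms = np.linalg.norm(X, axis=0)
    missing = np.zeros(V, bool)
    missing[seed_idx] = True
    missing |= norms == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (s @ X) / (s_norm * norms)
    r[missing] = np.nan
    z = np.full(V, np.nan)
    z[~missing] = fisher_z(r[~missing])
    return FCMap(seed_id=seed_id, r=r, z=z, missing=missing)


def group_difference_map(z_maps: np.ndarray, labels: np.ndarray,
                         covariates: pd.DataFrame | None = None) -> GroupDiffMap:
    """Group contrast of Fisher-z maps at every location.

    Without covariates: pooled-variance two-sample t (df = n - 2).  With
    covariates: signed square root of the partial F for the group factor from
    the per-location linear model [1 | group | covariates] (df = n - p); the
    sign follows the group coefficient, positive when group 1 exceeds group
    0.  Subjects with missing covariates are dropped.
    """
    z_maps = np.asarray(z_maps, float)
    labels = np.asarray(labels, int)
    if z_maps.ndim != 2 or z_maps.shape[0] != len(labels):
        raise ValueError("z_maps must be subjects x locations, aligned with labels")
    if covariates is not None:
        covariates = pd.DataFrame(covariates)
        keep = ~covariates.isna().any(axis=1).to_numpy()
        z_maps, labels, covariates = z_maps[keep], labels[keep], covariates.loc[keep]
    n1, n0 = int((labels == 1).sum()), int((labels == 0).sum())
    if n1 < 2 or n0 < 2:
        raise ValueError("need at least 2 subjects per group")
    n = n0 + n1

    if covariates is None:
        m1 = z_maps[labels == 1].mean(axis=0)
        m0 = z_maps[labels == 0].mean(axis=0)
        s1 = z_maps[labels == 1].var(axis=0, ddof=1)
        s0 = z_maps[labels == 0].var(axis=0, ddof=1)
        sp2 = ((n1 - 1) * s1 + (n0 - 1) * s0) / (n - 2)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (m1 - m0) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n0))
        df = n - 2
    else:
        C = covariates.to_numpy(float)
        X = np.column_stack([np.ones(n), labels.astype(float), C])
        p = X.shape[1]
        if np.linalg.matrix_rank(X) < p:
            raise ValueError("covariate collinear with group indicator")
        xtx_inv = np.linalg.inv(X.T @ X)
        beta = xtx_inv @ X.T @ z_maps
        resid = z_maps - X @ beta
        df = n - p
        s2 = (resid**2).sum(axis=0) / df
        with np.errstate(divide="ignore", invalid="ignore"):
            t = beta[1] / np.sqrt(s2 * xtx_inv[1, 1])
    t = np.where(np.isfinite(t), t, 0.0)
    pvals = 2.0 * stats.t.sf(np.abs(t), df)
    return GroupDiffMap(stat=t, df=df, p=pvals)
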