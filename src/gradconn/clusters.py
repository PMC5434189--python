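"""Cluster-extent inference via ACF smoothness estimation and Monte-Carlo nulls.

Spatial smoothness of residual volumes is summarized by a mixed Gaussian plus
mono-exponential autocorrelation model

    ACF(d) = a * exp(-d^2 / (2 b^2)) + (1 - a) * exp(-d / c)

fitted to the empirical spatial autocorrelation as a function of inter-voxel
distance.  Null Gaussian random fields with that ACF are synthesized by
frequency-domain filtering of white noise; thresholding them two-sidedly at
the nominal per-voxel p and recording the maximum cluster extent yields the
minimum cluster size controlling the familywise error at alpha.  Suprathreshold
clusters of an observed statistic map are extracted by connected-component
labeling (positive and negative exceedances separately).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize, stats

__all__ = [
    "AcfModel",
    "ClusterThreshold",
    "Cluster",
    "estimate_acf",
    "simulate_acf_field",
    "simulate_cluster_threshold",
    "extract_clusters",
    "adjacency_structure",
]

_ADJACENCY = {"face": 1, "face+edge": 2, "face+edge+corner": 3}


def adjacency_structure(adjacency: str) -> np.ndarray:
    """3D binary connectivity structure for the named adjacency rule."""
    try:
        return ndimage.generate_binary_structure(3, _ADJACENCY[adjacency])
    except KeyError:
        raise ValueError(f"unknown adjacency {adjacency!r}; use one of {list(_ADJACENCY)}")


@dataclass
class AcfModel:
    """Mixed Gaussian + mono-exponential spatial autocorrelation model.

    a is the Gaussian mixing fraction, b the Gaussian width (mm), c the
    exponential decay length (mm).  ACF(0) = 1 by construction.
    """

    a: float
    b: float
    c: float
    voxel_size_mm: float = 3.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.a <= 1.0:
            raise ValueError("mixing fraction a must be in [0, 1]")
        if self.b < 0 or self.c < 0:
            raise ValueError("b and c must be nonnegative")

    def acf(self, d) -> np.ndarray:
        d = np.asarray(d, float)
        with np.errstate(divide="ignore", invalid="ignore"):
            g = np.exp(-(d**2) / (2.0 * self.b**2)) if self.b > 0 else (d == 0).astype(float)
            e = np.exp(-d / self.c) if self.c > 0 else (d == 0).astype(float)
        return self.a * g + (1.0 - self.a) * e

    @property
    def fwhm_mm(self) -> float:
        """Equivalent Gaussian-kernel FWHM (mm), floored at one voxel.

        For white noise smoothed with a Gaussian kernel of FWHM f, the ACF is
        Gaussian with half-maximum at d = f / sqrt(2) x sqrt(... ) such that
        f = sqrt(2) * d_half.  The floor reflects the sampling limit: a grid
        cannot resolve smoothness below its voxel size.
        """
        d_half = self._half_max_distance()
        return max(float(np.sqrt(2.0) * d_half), self.voxel_size_mm)

    def _half_max_distance(self) -> float:
        f = lambda d: self.acf(d) - 0.5
        hi = max(self.b, self.c, self.voxel_size_mm) * 2 + 1e-6
        while f(hi) > 0 and hi < 1e4:
            hi *= 2
        if f(hi) > 0:
            return hi
        return float(optimize.brentq(f, 0.0, hi))


@dataclass
class ClusterThreshold:
    """Cluster-correction settings and the simulated minimum extent."""

    nominal_p: float
    alpha: float
    min_cluster_size: int
    n_iter: int
    adjacency: str = "face"

    def __post_init__(self) -> None:
        if not 0 < self.nominal_p < 1:
            raise ValueError("nominal_p must be in (0, 1)")
        if self.min_cluster_size < 1:
            raise ValueError("min_cluster_size must be >= 1")


@dataclass
class Cluster:
    """A suprathreshold connected component of a statistic map."""

    voxels: np.ndarray  # (k, 3) integer coordinates
    size: int
    sign: int
    peak_stat: float
    centroid: tuple[float, float, float]
    mask: np.ndarray = field(repr=False, default=None)


def _empirical_acf(volumes: np.ndarray, mask: np.ndarray,
                   voxel_size_mm: float, max_lag: int) -> tuple[np.ndarray, np.ndarray]:
    """Average lag-wise spatial correlation along the three axes.

    Returns (distance_mm, correlation) for lags 1..max_lag, pooling voxel
    pairs across volumes and axis directions.
    """
    dists, corrs = [], []
    vols = volumes - volumes.mean(axis=(1, 2, 3), keepdims=True)
    for lag in range(1, max_lag + 1):
        num = den1 = den2 = 0.0
        for ax in range(3):
            sl_a = [slice(None)] * 4
            sl_b = [slice(None)] * 4
            sl_a[ax + 1] = slice(0, -lag)
            sl_b[ax + 1] = slice(lag, None)
            ma = [slice(None)] * 3
            mb = [slice(None)] * 3
            ma[ax] = slice(0, -lag)
            mb[ax] = slice(lag, None)
            pair_mask = mask[tuple(ma)] & mask[tuple(mb)]
            if not pair_mask.any():
                continue
            va = vols[tuple(sl_a)][:, pair_mask]
            vb = vols[tuple(sl_b)][:, pair_mask]
            va = va - va.mean()
            vb = vb - vb.mean()
            num += float((va * vb).sum())
            den1 += float((va**2).sum())
            den2 += float((vb**2).sum())
        if den1 > 0 and den2 > 0:
            dists.append(lag * voxel_size_mm)
            corrs.append(num / np.sqrt(den1 * den2))
    return np.asarray(dists), np.asarray(corrs)


def estimate_acf(volumes: np.ndarray, mask: np.ndarray | None = None,
                 voxel_size_mm: float = 3.0, max_lag: int = 8) -> AcfModel:
    """Fit the mixed Gaussian + mono-exponential ACF model to residual volumes.

    ``volumes`` is (T, X, Y, Z) with T >= 2.  The empirical autocorrelation at
    inter-voxel distances up to ``max_lag`` voxels (plus the exact point
    ACF(0) = 1) is fitted by bounded least squares for (a, b, c).  Raises on
    non-convergence, attaching the empirical ACF for inspection.
    """
    volumes = np.asarray(volumes, float)
    if volumes.ndim == 3:
        volumes = volumes[None]
    if volumes.shape[0] < 1:
        raise ValueError("need at least one volume")
    if mask is None:
        mask = np.ones(volumes.shape[1:], bool)
    if not mask.any():
        raise ValueError("mask is empty")

    d, r = _empirical_acf(volumes, mask, voxel_size_mm, max_lag)
    if len(d) == 0:
        raise ValueError("volume too small to measure any spatial lag")
    d_fit = np.concatenate([[0.0], d])
    r_fit = np.concatenate([[1.0], np.clip(r, -0.999, 1.0)])

    def model(dd, a, b, c):
        return AcfModel(a, b, c, voxel_size_mm).acf(dd)

    try:
        popt, _ = optimize.curve_fit(
            model, d_fit, r_fit,
            p0=[0.5, voxel_size_mm, voxel_size_mm],
            bounds=([0.0, 1e-3, 1e-3], [1.0, 100.0, 100.0]),
            maxfev=10000,
        )
    except RuntimeError as exc:  # pragma: no cover - fit pathologies
        err = ValueError(f"ACF model fit failed to converge: {exc}")
        err.empirical_acf = (d, r)
        raise err
    return AcfModel(float(popt[0]), float(popt[1]), float(popt[2]), voxel_size_mm)


def _acf_spectrum(acf: AcfModel, grid_shape: tuple[int, int, int],
                  voxel_size_mm: float) -> np.ndarray:
    """Nonnegative power spectrum whose inverse FFT matches the target ACF."""
    coords = [np.minimum(np.arange(n), n - np.arange(n)) for n in grid_shape]
    dx, dy, dz = np.meshgrid(*coords, indexing="ij")
    dist = np.sqrt(dx**2 + dy**2 + dz**2) * voxel_size_mm
    kernel = acf.acf(dist)
    spec = np.real(np.fft.fftn(kernel))
    return np.clip(spec, 0.0, None)


def simulate_acf_field(acf: AcfModel, grid_shape: tuple[int, int, int],
                       voxel_size_mm: float, rng: np.random.Generator,
                       spectrum: np.ndarray | None = None) -> np.ndarray:
    """One unit-variance Gaussian random field with the target spatial ACF."""
    if spectrum is None:
        spectrum = _acf_spectrum(acf, grid_shape, voxel_size_mm)
    white = rng.standard_normal(grid_shape)
    f = np.fft.fftn(white) * np.sqrt(spectrum)
    field = np.real(np.fft.ifftn(f))
    sd = field.std()
    return field / sd if sd > 0 else field


def _max_cluster_size(exceed_pos: np.ndarray, exceed_neg: np.ndarray,
                      structure: np.ndarray) -> int:
    best = 0
    for ex in (exceed_pos, exceed_neg):
        lab, n = ndimage.label(ex, structure=structure)
        if n:
            best = max(best, int(np.bincount(lab.ravel())[1:].max()))
    return best


def simulate_cluster_threshold(acf: AcfModel, grid_shape: tuple[int, int, int],
                               voxel_size_mm: float, nominal_p: float = 0.01,
                               alpha: float = 0.05, n_iter: int = 1000,
                               seed: int = 0, adjacency: str = "face",
                               mask: np.ndarray | None = None) -> ClusterThreshold:
    """Monte-Carlo minimum cluster extent controlling familywise error.

    Each iteration draws a null field with the target ACF, thresholds it
    two-sidedly at ``nominal_p`` and records the maximum cluster size over
    both signs.  The returned minimum size is the smallest k with
    P(max size >= k) <= alpha.  alpha = 1 gives 1 (every cluster passes).
    """
    if n_iter < 100:
        raise ValueError("n_iter must be >= 100")
    rng = np.random.default_rng(seed)
    structure = adjacency_structure(adjacency)
    spectrum = _acf_spectrum(acf, grid_shape, voxel_size_mm)
    zc = stats.norm.ppf(1.0 - nominal_p / 2.0)
    max_sizes = np.empty(n_iter, int)
    for i in range(n_iter):
        field = simulate_acf_field(acf, grid_shape, voxel_size_mm, rng, spectrum)
        if mask is not None:
            pos = (field > zc) & mask
            neg = (field < -zc) & mask
        else:
            pos = field > zc
            neg = field < -zc
        max_sizes[i] = _max_cluster_size(pos, neg, structure)

    k = 1
    while np.mean(max_sizes >= k) > alpha:
        k += 1
    return ClusterThreshold(nominal_p=nominal_p, alpha=alpha, min_cluster_size=k,
                            n_iter=n_iter, adjacency=adjacency)


def extract_clusters(stat_map: np.ndarray, voxel_threshold: float,
                     min_cluster_size: int = 1, adjacency: str = "face",
                     mask: np.ndarray | None = None) -> list[Cluster]:
    """Suprathreshold connected components, both signs, sorted by size.

    Positive (stat > threshold) and negative (stat < -threshold) exceedances
    are labeled separately under the declared adjacency; components smaller
    than ``min_cluster_size`` are discarded.
    """
    stat_map = np.asarray(stat_map, float)
    structure = adjacency_structure(adjacency)
    in_mask = mask if mask is not None else np.ones(stat_map.shape, bool)
    if not np.isfinite(stat_map[in_mask]).all():
        raise ValueError("statistic map contains non-finite values inside the mask")

    clusters: list[Cluster] = []
    for sign, exceed in ((1, (stat_map > voxel_threshold) & in_mask),
                         (-1, (stat_map < -voxel_threshold) & in_mask)):
        lab, n = ndimage.label(exceed, structure=structure)
        for cid in range(1, n + 1):
            m = lab == cid
            size = int(m.sum())
            if size < min_cluster_size:
                continue
            vox = np.argwhere(m)
            vals = stat_map[m]
            peak = float(vals[np.argmax(np.abs(vals))])
            clusters.append(Cluster(voxels=vox, size=size, sign=sign, peak_stat=peak,
                                    centroid=tuple(vox.mean(axis=0)), mask=m))
    clusters.sort(key=lambda c: -c.size)
    return clusters
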