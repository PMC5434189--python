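"""Synthetic study cohort: roster, planted connectivity, time series and behavior.

The generator emulates a Veteran cohort of 48 controls and 18 subjects
positive for interpersonal early-life trauma (I-ELT+), each with an 8-minute,
TR = 2 s functional run (248 volumes) summarized over a 116-parcel atlas.
Two amygdala connections carry planted group effects on the Fisher-z scale:
an increase to a middle-frontal-gyrus (MFG) parcel and a decrease to a
parahippocampal-gyrus (PHG) parcel in the positive group.  Sustained-attention
behavior (d', RT coefficient of variation) is linearly coupled to the planted
connectivity contrast, and gradCPT button presses are generated from an AR(1)
latent attention state so lapses cluster in time.

Parcel time series are multivariate normal with the subject's target
correlation matrix (via its symmetric square root); voxel grids replicate
parcel series plus spatially smoothed voxel noise.  Everything is
deterministic given (config, seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

from .connectivity import NUISANCE_COLUMNS
from .gradcpt import TRANSITION_MS, PressLog, TrialSequence

__all__ = [
    "GradcptGroupParams",
    "CohortConfig",
    "SubjectTruth",
    "SubjectRecord",
    "make_cohort",
    "simulate_parcel_timeseries",
    "simulate_voxel_grid",
    "simulate_gradcpt_responses",
    "make_block_label_map",
    "roster_frame",
]

# Table-1-style per-group covariate (mean, sd): age, CAPS, DASS-d, mTBI count.
_COVARIATE_MOMENTS = {
    0: {"age": (31.56, 7.88), "caps": (40.15, 24.53), "dass_d": (6.35, 7.90), "mtbi": (1.31, 1.36)},
    1: {"age": (34.22, 7.98), "caps": (50.61, 23.57), "dass_d": (9.53, 7.73), "mtbi": (1.17, 1.38)},
}


@dataclass(frozen=True)
class GradcptGroupParams:
    """Group-level response parameters for the gradCPT simulator."""

    lapse_rate: float  # omission probability on nontarget trials (state-modulated)
    ce_rate: float  # press probability on rare mountain targets
    rt_mean_ms: float
    rt_sd_ms: float
    ar1_coef: float = 0.5  # attention-state persistence per trial


@dataclass(frozen=True)
class CohortConfig:
    """Study-design constants and planted effect sizes.

    Defaults reproduce the emulated study: 18 positive / 48 control subjects,
    248 volumes at TR 2 s, 116 parcels with left/right amygdala seeds, and a
    0.3 Fisher-z connectivity increase (amygdala-MFG) and decrease
    (amygdala-PHG) in the positive group.  ``beta_dprime``/``beta_cv`` couple
    behavior linearly to the planted connectivity contrast
    c = mean_z(seed, MFG) - mean_z(seed, PHG).
    """

    n_pos: int = 18
    n_neg: int = 48
    n_volumes: int = 248
    tr_s: float = 2.0
    n_parcels: int = 116
    seed_parcels: tuple[int, int] = (40, 41)  # left, right amygdala parcel indices
    mfg_parcel: int = 50
    phg_parcel: int = 60
    effect_mfg: float = 0.3  # Fisher-z increase in the positive group
    effect_phg: float = 0.3  # Fisher-z decrease in the positive group
    base_background_r: float = 0.1  # off-diagonal background correlation
    base_seed_target_r: float = 0.2  # amygdala-MFG/PHG baseline correlation
    seed_seed_r: float = 0.4  # homotopic left-right amygdala correlation
    jitter_z: float = 0.04  # subject-level SD of seed-to-parcel Fisher z
    beta_dprime: float = -1.2  # d' units per z-unit of connectivity contrast
    beta_cv: float = 0.057  # CV units per z-unit of contrast
    noise_dprime: float = 0.45  # subject-level residual SD of true d'
    noise_cv: float = 0.02
    nuisance_amp: float = 0.3  # amplitude of added motion/CSF/WM/global signals
    voxel_noise_sd: float = 2.0  # voxel-level noise SD relative to parcel signal SD 1
    gradcpt: dict[int, GradcptGroupParams] = field(default_factory=lambda: {
        0: GradcptGroupParams(lapse_rate=0.011, ce_rate=0.20, rt_mean_ms=752.0, rt_sd_ms=136.0),
        1: GradcptGroupParams(lapse_rate=0.056, ce_rate=0.29, rt_mean_ms=773.0, rt_sd_ms=166.0),
    })
    lapse_state_gain: float = 1.0  # logit-scale modulation of lapses by the AR(1) state
    rt_state_gain: float = 0.25  # log-scale inflation of RT SD by the state
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos + self.n_neg < 6:
            raise ValueError("cohort must contain at least 6 subjects")
        if self.n_pos < 0 or self.n_neg < 0:
            raise ValueError("group sizes must be nonnegative")
        if self.effect_mfg < 0 or self.effect_phg < 0:
            raise ValueError("planted effect magnitudes must be >= 0")
        for name in ("effect_mfg", "effect_phg", "beta_dprime", "beta_cv"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        special = {*self.seed_parcels, self.mfg_parcel, self.phg_parcel}
        if len(special) < 4:
            raise ValueError("seed, MFG and PHG parcels must be distinct")
        if max(special) >= self.n_parcels:
            raise ValueError("parcel indices out of range")


@dataclass
class SubjectTruth:
    """Ground-truth generative parameters for one subject."""

    corr: np.ndarray  # n_parcels x n_parcels target correlation matrix
    contrast: float  # planted connectivity contrast c (Fisher z)
    dprime: float
    cv: float
    p_lapse: float
    p_ce: float
    rt_mean_ms: float
    rt_sd_ms: float
    ar1_coef: float


@dataclass
class SubjectRecord:
    subject_id: str
    group: int
    age: float
    caps: float
    dass_d: float
    mtbi: int
    truth: SubjectTruth

    @property
    def covariates(self) -> dict:
        return {"age": self.age, "caps": self.caps, "dass_d": self.dass_d, "mtbi": self.mtbi}


def _truth_matrix(config: CohortConfig, group: int, rng: np.random.Generator,
                  subject_id: str) -> tuple[np.ndarray, float]:
    """Subject target correlation matrix and the planted contrast it carries.

    Base: compound background correlation; the two amygdala seed rows get
    baseline seed-target values plus the group effect (positive group only)
    plus subject jitter, all on the Fisher-z scale.
    """
    R = config.n_parcels
    corr = np.full((R, R), config.base_background_r)
    np.fill_diagonal(corr, 1.0)
    ls, rs = config.seed_parcels

    others = np.setdiff1d(np.arange(R), np.array(config.seed_parcels))
    contrast_terms = []
    for s in (ls, rs):
        z = np.full(R, np.arctanh(config.base_background_r))
        z[[config.mfg_parcel, config.phg_parcel]] = np.arctanh(config.base_seed_target_r)
        if group == 1:
            z[config.mfg_parcel] += config.effect_mfg
            z[config.phg_parcel] -= config.effect_phg
        z[others] += rng.normal(0.0, config.jitter_z, size=len(others))
        r_row = np.tanh(z)
        corr[s, others] = r_row[others]
        corr[others, s] = r_row[others]
        contrast_terms.append(z[config.mfg_parcel] - z[config.phg_parcel])
    corr[ls, rs] = corr[rs, ls] = config.seed_seed_r

    try:
        np.linalg.cholesky(corr)
    except np.linalg.LinAlgError:
        raise ValueError(
            f"target correlation matrix for subject {subject_id} is not positive definite; "
            "reduce jitter_z or the planted effects"
        )
    return corr, float(np.mean(contrast_terms))


def make_cohort(config: CohortConfig, seed: int | None = None) -> list[SubjectRecord]:
    """Draw the full synthetic roster with ground-truth parameters.

    Exactly ``n_pos`` group-1 and ``n_neg`` group-0 records.  Covariates are
    sampled from per-group normal laws matched to the emulated cohort's
    demographics (no built-in group effect beyond sampled noise).  The true
    behavioral parameters couple to the subject's planted connectivity
    contrast: d' = d'_base(group) + beta_dprime * (c - c_base(group)) + noise,
    and likewise for CV; the omission (lapse) probability is then the
    equal-variance signal-detection inversion of true d' at the group's
    commission-error rate.
    """
    rng = np.random.default_rng(config.rng_seed if seed is None else seed)
    groups = [1] * config.n_pos + [0] * config.n_neg
    records: list[SubjectRecord] = []
    # group-level contrast baselines: zero for controls, planted sum for positives
    c_base = {0: 0.0, 1: config.effect_mfg + config.effect_phg}
    for i, g in enumerate(groups):
        sid = f"sub-{i + 1:03d}"
        mom = _COVARIATE_MOMENTS[g]
        age = rng.normal(*mom["age"])
        caps = max(0.0, rng.normal(*mom["caps"]))
        dass = max(0.0, rng.normal(*mom["dass_d"]))
        mtbi = int(max(0, round(rng.normal(*mom["mtbi"]))))

        corr, contrast = _truth_matrix(config, g, rng, sid)
        gp = config.gradcpt[g]
        d_base = float(norm.ppf(1.0 - gp.ce_rate) - norm.ppf(max(gp.lapse_rate, 1e-4)))
        dprime = d_base + config.beta_dprime * (contrast - c_base[g]) \
            + rng.normal(0.0, config.noise_dprime)
        cv = gp.rt_sd_ms / gp.rt_mean_ms + config.beta_cv * (contrast - c_base[g]) \
            + rng.normal(0.0, config.noise_cv)
        cv = float(np.clip(cv, 0.01, 1.0))
        p_lapse = float(np.clip(norm.cdf(norm.ppf(1.0 - gp.ce_rate) - dprime), 1e-5, 0.5))
        truth = SubjectTruth(
            corr=corr, contrast=contrast, dprime=float(dprime), cv=cv,
            p_lapse=p_lapse, p_ce=gp.ce_rate, rt_mean_ms=gp.rt_mean_ms,
            rt_sd_ms=cv * gp.rt_mean_ms, ar1_coef=gp.ar1_coef,
        )
        records.append(SubjectRecord(subject_id=sid, group=g, age=float(age),
                                     caps=float(caps), dass_d=float(dass), mtbi=mtbi,
                                     truth=truth))
    return records


def roster_frame(records: list[SubjectRecord]) -> pd.DataFrame:
    """Roster TSV layout: subject_id, group, age, caps, dass_d, mtbi."""
    return pd.DataFrame(
        [{"subject_id": r.subject_id, "group": r.group, **r.covariates} for r in records]
    )


def _nuisance_signals(T: int, rng: np.random.Generator) -> np.ndarray:
    """Nine unit-variance nuisance series: 6 slow motion drifts + CSF/WM/global."""
    cols = []
    for _ in range(6):  # motion: random walk (slow drift)
        w = np.cumsum(rng.normal(0.0, 1.0, T))
        cols.append(w)
    for _ in range(3):  # CSF, WM, global: AR(1)
        e = rng.normal(0.0, 1.0, T)
        s = np.empty(T)
        s[0] = e[0]
        for t in range(1, T):
            s[t] = 0.8 * s[t - 1] + e[t]
        cols.append(s)
    M = np.column_stack(cols)
    M -= M.mean(axis=0)
    M /= M.std(axis=0)
    return M


def simulate_parcel_timeseries(subject: SubjectRecord, config: CohortConfig,
                               seed: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Parcel time series (T x R) plus its 9-column nuisance table.

    Rows are zero-mean multivariate normal with the subject's target
    correlation matrix, imposed through the symmetric matrix square root;
    nuisance signals are added with random parcel loadings at amplitude
    ``config.nuisance_amp``.  Empirical correlations of the nuisance-free
    component converge to the target as the number of volumes grows.
    """
    T, R = config.n_volumes, config.n_parcels
    if T < 30:
        warnings.warn(f"n_volumes={T} < 30: correlation estimates will be unstable",
                      stacklevel=2)
    rng = np.random.default_rng(seed)
    vals, vecs = np.linalg.eigh(subject.truth.corr)
    if vals.min() <= 0:
        raise ValueError(f"truth matrix for {subject.subject_id} is not positive definite")
    root = (vecs * np.sqrt(vals)) @ vecs.T
    data = rng.standard_normal((T, R)) @ root

    nuis = _nuisance_signals(T, rng)
    if config.nuisance_amp > 0:
        loadings = rng.normal(0.0, config.nuisance_amp, size=(9, R))
        data = data + nuis @ loadings

    ts = pd.DataFrame(data, columns=[f"parcel{j:03d}" for j in range(R)])
    nuisance = pd.DataFrame(nuis, columns=NUISANCE_COLUMNS)
    return ts, nuisance


def make_block_label_map(grid_shape: tuple[int, int, int], n_parcels: int) -> np.ndarray:
    """Integer label volume tiling the grid into ~equal blocks, ids 1..n_parcels.

    Blocks beyond ``n_parcels`` stay background (0).  Raises when the grid
    has fewer blocks than parcels even at one voxel per block.
    """
    nx, ny, nz = grid_shape
    if nx * ny * nz < n_parcels:
        raise ValueError("grid too small to contain all parcels")
    k = int(np.ceil(n_parcels ** (1.0 / 3.0)))
    divs = []
    for n in grid_shape:
        divs.append(min(n, k))
    while np.prod(divs) < n_parcels:
        j = int(np.argmin([d / n for d, n in zip(divs, grid_shape)]))
        if divs[j] >= grid_shape[j]:
            j = int(np.argmax([n - d for d, n in zip(divs, grid_shape)]))
        divs[j] += 1
    edges = [np.linspace(0, n, d + 1).astype(int) for n, d in zip(grid_shape, divs)]
    labels = np.zeros(grid_shape, int)
    pid = 1
    for ix in range(divs[0]):
        for iy in range(divs[1]):
            for iz in range(divs[2]):
                if pid > n_parcels:
                    return labels
                labels[edges[0][ix]:edges[0][ix + 1],
                       edges[1][iy]:edges[1][iy + 1],
                       edges[2][iz]:edges[2][iz + 1]] = pid
                pid += 1
    if pid <= n_parcels:
        raise ValueError("grid too small to contain all parcels")
    return labels


def simulate_voxel_grid(subject: SubjectRecord, config: CohortConfig,
                        grid_shape: tuple[int, int, int], label_map: np.ndarray,
                        smooth_fwhm_mm: float, seed: int,
                        voxel_size_mm: float = 3.0,
                        parcel_ts: np.ndarray | None = None,
                        ) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """4D voxel volume replicating parcel series plus smoothed voxel noise.

    Every voxel carries its parcel's time series (parcel id v at label-map
    value v+1) plus independent voxel noise that is spatially smoothed with
    the stated Gaussian kernel, so the parcel-mean of the voxel series tracks
    the parcel series.  Returns (volume with shape grid + (T,), label map,
    nuisance table).  Voxels labeled 0 hold pure noise.
    """
    from scipy.ndimage import gaussian_filter

    label_map = np.asarray(label_map, int)
    if label_map.shape != tuple(grid_shape):
        raise ValueError("label_map shape must match grid_shape")
    present = set(np.unique(label_map)) - {0}
    needed = set(range(1, config.n_parcels + 1))
    if not needed <= present:
        missing = sorted(needed - present)
        raise ValueError(f"label map missing parcels {missing[:5]}... (grid too small?)")

    if parcel_ts is None:
        ts, nuis = simulate_parcel_timeseries(subject, config, seed)
        parcel_ts = ts.to_numpy()
    else:
        nuis = pd.DataFrame(np.zeros((parcel_ts.shape[0], 9)), columns=NUISANCE_COLUMNS)
    T = parcel_ts.shape[0]

    rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
    vol = np.zeros(tuple(grid_shape) + (T,))
    # broadcast each parcel's series into its voxels
    flat_labels = label_map.reshape(-1)
    flat = vol.reshape(-1, T)
    in_parcel = flat_labels > 0
    flat[in_parcel] = parcel_ts[:, flat_labels[in_parcel] - 1].T

    if config.voxel_noise_sd > 0:
        sigma_vox = (smooth_fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)))) / voxel_size_mm
        noise = rng.normal(0.0, 1.0, size=tuple(grid_shape) + (T,))
        if sigma_vox > 0:
            noise = gaussian_filter(noise, sigma=(sigma_vox, sigma_vox, sigma_vox, 0))
            noise /= max(noise.std(), 1e-12)
        vol += config.voxel_noise_sd * noise
    return vol, label_map, nuis


def simulate_gradcpt_responses(subject: SubjectRecord, seq: TrialSequence,
                               config: CohortConfig, seed: int) -> PressLog:
    """Generate a button-press stream for one subject on a trial sequence.

    A latent attention state follows a stationary AR(1) process.  On each
    nontarget (city) trial the subject presses with probability
    1 - p_lapse(state), where the lapse probability is modulated on the logit
    scale by the state; on target (mountain) trials a press occurs with the
    commission-error probability.  RTs are normal with the subject's mean and
    a state-inflated SD, truncated to (200, 1560) ms; press times are
    strictly increasing.
    """
    if seq.n_trials < 1:
        raise ValueError("trial sequence is empty")
    t = subject.truth
    rng = np.random.default_rng(seed)
    n = seq.n_trials
    rho = float(np.clip(t.ar1_coef, 0.0, 0.999))
    e = rng.standard_normal(n)
    state = np.empty(n)
    state[0] = e[0]
    innov = np.sqrt(1.0 - rho**2)
    for i in range(1, n):
        state[i] = rho * state[i - 1] + innov * e[i]

    if 0.0 < t.p_lapse < 1.0:
        logit = np.log(t.p_lapse / (1.0 - t.p_lapse)) + config.lapse_state_gain * state
        p_lapse = 1.0 / (1.0 + np.exp(-logit))
    else:
        p_lapse = np.full(n, float(np.clip(t.p_lapse, 0.0, 1.0)))

    u = rng.random(n)
    press = np.where(seq.is_target, u < t.p_ce, u >= p_lapse)

    sd = t.rt_sd_ms * np.exp(config.rt_state_gain * state)
    rt = rng.normal(t.rt_mean_ms, np.maximum(sd, 1e-9))
    lo, hi = 200.0, 1560.0
    bad = (rt <= lo) | (rt >= hi)
    for _ in range(100):
        if not bad.any():
            break
        rt[bad] = rng.normal(t.rt_mean_ms, np.maximum(sd[bad], 1e-9))
        bad = (rt <= lo) | (rt >= hi)
    rt = np.clip(rt, lo + 1e-3, hi - 1e-3)

    times = np.sort(seq.onset_ms[press] + rt[press])
    # enforce strict monotonicity against rare collisions
    for i in range(1, len(times)):
        if times[i] <= times[i - 1]:
            times[i] = times[i - 1] + 1e-6
    return PressLog(press_time_ms=times)


def score_cohort_behavior(records: list[SubjectRecord], config: CohortConfig,
                          n_trials: int = 600, seed: int = 0) -> pd.DataFrame:
    """Simulate and score the gradCPT for every subject; one row per subject."""
    from .gradcpt import assign_presses, build_trial_sequence, summarize_performance

    ss = np.random.SeedSequence([seed, 101])
    child = ss.spawn(len(records) + 1)
    rows = []
    for k, rec in enumerate(records):
        sub_seed = int(child[k].generate_state(1)[0] % (2**31))
        seq = build_trial_sequence(n_trials, 0.1, seed=sub_seed)
        presses = simulate_gradcpt_responses(rec, seq, config, seed=sub_seed + 1)
        summary = summarize_performance(assign_presses(seq, presses))
        rows.append({"subject_id": rec.subject_id, "group": rec.group,
                     **summary.to_dict(),
                     "true_dprime": rec.truth.dprime, "true_cv": rec.truth.cv,
                     "true_contrast": rec.truth.contrast})
    return pd.DataFrame(rows)
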