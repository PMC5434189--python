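"""End-to-end orchestration: simulate -> score -> connectivity -> clusters -> decoding.

A run is driven by a single :class:`RunConfig` (YAML/JSON-loadable) and a
global seed.  Stages write their outputs into the run directory and are
individually re-runnable: each stage regenerates its inputs deterministically
from the recorded config and derived seeds, or reads the persisted outputs of
earlier stages, so a re-run reproduces identical numbers.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import clusters as cl
from . import connectivity as fc
from . import decoding, gradcpt, stats
from .cohort import (CohortConfig, GradcptGroupParams, SubjectRecord, make_cohort,
                     make_block_label_map, roster_frame, score_cohort_behavior,
                     simulate_parcel_timeseries, simulate_voxel_grid)

__all__ = ["RunConfig", "PipelineRun", "run_pipeline", "compute_feature_matrix"]


@dataclass
class RunConfig:
    """All knobs for one pipeline run."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    n_trials: int = 600
    target_rate: float = 0.1
    # voxel-grid / cluster-inference block
    grid_shape: tuple[int, int, int] = (20, 20, 15)
    voxel_size_mm: float = 3.0
    smooth_fwhm_mm: float = 4.0
    nominal_p: float = 0.01
    alpha: float = 0.05
    cluster_n_iter: int = 500
    adjacency: str = "face"
    # decoding block
    n_feature_max: int = 66
    n_perm: int = 1000
    rng_seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "cohort" in d and isinstance(d["cohort"], dict):
            cdict = dict(d["cohort"])
            if "gradcpt" in cdict:
                cdict["gradcpt"] = {int(g): GradcptGroupParams(**p)
                                    for g, p in cdict["gradcpt"].items()}
            for tup in ("seed_parcels",):
                if tup in cdict:
                    cdict[tup] = tuple(cdict[tup])
            d["cohort"] = CohortConfig(**cdict)
        if "grid_shape" in d:
            d["grid_shape"] = tuple(d["grid_shape"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"]["gradcpt"] = {g: dataclasses.asdict(p)
                                  for g, p in self.cohort.gradcpt.items()}
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def _subject_seed(global_seed: int, index: int, stream: int) -> int:
    ss = np.random.SeedSequence([int(global_seed), int(stream), int(index)])
    return int(ss.generate_state(1)[0] % (2**31))


def compute_feature_matrix(records: list[SubjectRecord], config: CohortConfig,
                           seed: int) -> decoding.FeatureMatrix:
    """Seed-to-parcel Fisher-z features: 2 seeds x n_parcels per subject.

    Each subject's parcel series is residualized against its nuisance table;
    the left and right amygdala parcel series are each correlated with every
    parcel.  A seed's own parcel (undefined self-correlation) is recorded as
    a constant 0 so the matrix stays finite; such degenerate features are
    never selected by the training-fold ranking.
    """
    seed_names = ["L_amyg", "R_amyg"]
    names = [f"{s}_parcel{j:03d}" for s in seed_names for j in range(config.n_parcels)]
    rows = []
    for i, rec in enumerate(records):
        ts, nuis = simulate_parcel_timeseries(rec, config, _subject_seed(seed, i, 11))
        resid = fc.nuisance_residualize(fc.TimeSeriesBundle(ts.to_numpy(), nuis.to_numpy(),
                                                            tr_s=config.tr_s))
        feats = []
        for sname, sp in zip(seed_names, config.seed_parcels):
            fmap = fc.seed_connectivity(resid, sp, seed_id=sname)
            z = np.where(np.isfinite(fmap.z), fmap.z, 0.0)
            feats.append(z)
        rows.append(np.concatenate(feats))
    return decoding.FeatureMatrix(values=np.asarray(rows), feature_names=names,
                                  subject_ids=[r.subject_id for r in records])


_BEHAVIOR_MEASURES = [
    ("dprime", "Discrimination ability (d')"),
    ("criterion", "Criterion"),
    ("rt_mean_s", "Reaction time (sec)"),
    ("rt_cv", "Coefficient of variation"),
    ("ce_rate", "Commission error rate"),
    ("oe_rate", "Omission error rate (OE)"),
    ("n_oe_lapses", "Number OE lapses"),
    ("mean_oe_lapse_trials", "Average duration OE lapse (trials)"),
]


class PipelineRun:
    """One configured, seeded pipeline run rooted at ``out_dir``."""

    def __init__(self, config: RunConfig, seed: int | None = None,
                 out_dir: str | Path = "gradconn_run"):
        self.config = config
        self.seed = int(config.rng_seed if seed is None else seed)
        self.out = Path(out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self._records: list[SubjectRecord] | None = None
        self._log: list[dict] = []

    # -- helpers -----------------------------------------------------------
    def _note(self, stage: str, **info) -> None:
        entry = {"stage": stage, "time": time.strftime("%Y-%m-%dT%H:%M:%S"), **info}
        self._log.append(entry)
        with open(self.out / "log.jsonl", "a") as fh:
            fh.write(json.dumps(entry) + "\n")

    @property
    def records(self) -> list[SubjectRecord]:
        if self._records is None:
            self._records = make_cohort(self.config.cohort, seed=self.seed)
        return self._records

    def _labels(self) -> np.ndarray:
        return np.array([r.group for r in self.records])

    # -- stages ------------------------------------------------------------
    def stage_simulate(self) -> Path:
        roster = roster_frame(self.records)
        path = self.out / "roster.tsv"
        roster.to_csv(path, sep="\t", index=False)
        meta = {"config": self.config.to_dict(), "seed": self.seed,
                "config_hash": self.config.digest()}
        (self.out / "run_meta.json").write_text(json.dumps(meta, indent=2, default=str))
        self._note("simulate", n_subjects=len(roster), config_hash=self.config.digest())
        return path

    def stage_score(self) -> pd.DataFrame:
        beh = score_cohort_behavior(self.records, self.config.cohort,
                                    n_trials=self.config.n_trials, seed=self.seed)
        beh.to_csv(self.out / "behavior.tsv", sep="\t", index=False)
        rows = []
        g1 = beh[beh.group == 1]
        g0 = beh[beh.group == 0]
        for col, label in _BEHAVIOR_MEASURES:
            res = stats.mann_whitney_z(g1[col], g0[col])
            rows.append({
                "measure": label,
                "mean_neg": g0[col].mean(), "se_neg": g0[col].sem(),
                "mean_pos": g1[col].mean(), "se_pos": g1[col].sem(),
                "U": res.u, "z": res.z, "p": res.p,
            })
        table = pd.DataFrame(rows)
        table.to_csv(self.out / "behavior_stats.tsv", sep="\t", index=False)
        self._note("score", n_trials=self.config.n_trials)
        return table

    def stage_fc(self) -> dict:
        cfg = self.config
        ccfg = cfg.cohort
        feats = compute_feature_matrix(self.records, ccfg, self.seed)
        fdf = pd.DataFrame(feats.values, columns=feats.feature_names)
        fdf.insert(0, "subject_id", feats.subject_ids)
        fdf.to_csv(self.out / "features.tsv", sep="\t", index=False)

        label_map = make_block_label_map(cfg.grid_shape, ccfg.n_parcels)
        zmaps = {"bilateral": [], "L_amyg": [], "R_amyg": []}
        for i, rec in enumerate(self.records):
            sseed = _subject_seed(self.seed, i, 11)
            ts, nuis = simulate_parcel_timeseries(rec, ccfg, sseed)
            vol, _, _ = simulate_voxel_grid(rec, ccfg, cfg.grid_shape, label_map,
                                            cfg.smooth_fwhm_mm, sseed,
                                            voxel_size_mm=cfg.voxel_size_mm,
                                            parcel_ts=ts.to_numpy())
            vox = vol.reshape(-1, ccfg.n_volumes).T  # T x V
            resid = fc.nuisance_residualize(fc.TimeSeriesBundle(vox, nuis.to_numpy()))
            resid_p = fc.nuisance_residualize(fc.TimeSeriesBundle(ts.to_numpy(),
                                                                  nuis.to_numpy()))
            ls, rs = ccfg.seed_parcels
            for key, seed_series in (
                ("bilateral", resid_p[:, [ls, rs]].mean(axis=1)),
                ("L_amyg", resid_p[:, ls]),
                ("R_amyg", resid_p[:, rs]),
            ):
                s = seed_series - seed_series.mean()
                X = resid - resid.mean(axis=0)
                norms = np.linalg.norm(X, axis=0) * np.linalg.norm(s)
                with np.errstate(divide="ignore", invalid="ignore"):
                    r = (s @ X) / norms
                z = fc.fisher_z(np.where(np.isfinite(r), r, 0.0))
                zmaps[key].append(z.reshape(cfg.grid_shape))
        # smoothness of the maps actually thresholded: group-residual z-maps
        zb = np.asarray(zmaps["bilateral"])
        y = self._labels()
        residmaps = zb.copy()
        for g in (0, 1):
            residmaps[y == g] -= zb[y == g].mean(axis=0)
        acf_model = cl.estimate_acf(residmaps, voxel_size_mm=cfg.voxel_size_mm)

        self._save_nii("label_map.nii", label_map.astype(np.int16))
        for key, maps in zmaps.items():
            # subjects stacked along the 4th axis
            self._save_nii(f"zmaps_{key}.nii", np.moveaxis(np.asarray(maps), 0, -1))
        acf = {"a": acf_model.a, "b": acf_model.b, "c": acf_model.c,
               "voxel_size_mm": acf_model.voxel_size_mm, "fwhm_mm": acf_model.fwhm_mm}
        (self.out / "acf.json").write_text(json.dumps(acf, indent=2))
        self._note("fc", n_features=feats.n_features, acf_fwhm_mm=acf["fwhm_mm"])
        return {"features": feats, "acf": acf_model, "zmaps": zmaps, "label_map": label_map}

    def _save_nii(self, name: str, arr: np.ndarray) -> None:
        affine = np.diag([self.config.voxel_size_mm] * 3 + [1.0])
        nib.save(nib.Nifti1Image(np.asarray(arr), affine), self.out / name)

    def _load_nii(self, name: str) -> np.ndarray:
        return np.asarray(nib.load(self.out / name).dataobj)

    def _load_zmaps(self, key: str) -> np.ndarray:
        return np.moveaxis(self._load_nii(f"zmaps_{key}.nii"), -1, 0)

    def stage_cluster(self) -> list[cl.Cluster]:
        cfg = self.config
        acf_d = json.loads((self.out / "acf.json").read_text())
        acf = cl.AcfModel(acf_d["a"], acf_d["b"], acf_d["c"], acf_d["voxel_size_mm"])
        thr = cl.simulate_cluster_threshold(
            acf, cfg.grid_shape, cfg.voxel_size_mm, nominal_p=cfg.nominal_p,
            alpha=cfg.alpha, n_iter=cfg.cluster_n_iter,
            seed=_subject_seed(self.seed, 0, 23), adjacency=cfg.adjacency)
        zb = self._load_zmaps("bilateral")
        diff = fc.group_difference_map(zb.reshape(len(zb), -1), self._labels())
        stat = diff.stat.reshape(cfg.grid_shape)
        tcrit = diff.threshold_value(cfg.nominal_p)
        found = cl.extract_clusters(stat, tcrit, thr.min_cluster_size, cfg.adjacency)

        rows = []
        cluster_labels = np.zeros(cfg.grid_shape, int)
        for k, c in enumerate(found, start=1):
            cluster_labels[c.mask] = k
            rows.append({"cluster_id": k, "sign": c.sign, "size": c.size,
                         "peak_stat": c.peak_stat,
                         "centroid_vox": ",".join(f"{v:.1f}" for v in c.centroid),
                         "centroid_mm": ",".join(f"{v * cfg.voxel_size_mm:.1f}"
                                                 for v in c.centroid)})
        pd.DataFrame(rows, columns=["cluster_id", "sign", "size", "peak_stat",
                                    "centroid_vox", "centroid_mm"]).to_csv(
            self.out / "cluster_report.tsv", sep="\t", index=False)
        self._save_nii("cluster_labels.nii", cluster_labels.astype(np.int16))
        self._save_nii("group_diff_stat.nii", stat)
        (self.out / "threshold.json").write_text(json.dumps({
            "acf": acf_d, "nominal_p": cfg.nominal_p, "alpha": cfg.alpha,
            "min_cluster_size": thr.min_cluster_size, "n_iter": cfg.cluster_n_iter,
            "adjacency": cfg.adjacency, "df": diff.df, "t_critical": tcrit,
            "seed": self.seed}, indent=2))
        self._note("cluster", n_clusters=len(found), min_cluster_size=thr.min_cluster_size)
        return found

    def _reference_clusters(self) -> list[cl.Cluster]:
        labels = self._load_nii("cluster_labels.nii").astype(int)
        stat = self._load_nii("group_diff_stat.nii")
        refs = []
        for k in np.unique(labels)[1:]:
            m = labels == k
            vox = np.argwhere(m)
            vals = stat[m]
            peak = float(vals[np.argmax(np.abs(vals))])
            refs.append(cl.Cluster(voxels=vox, size=int(m.sum()),
                                   sign=int(np.sign(peak)), peak_stat=peak,
                                   centroid=tuple(vox.mean(axis=0)), mask=m))
        return refs

    def stage_decode_behavior(self) -> dict:
        cfg = self.config
        beh = pd.read_csv(self.out / "behavior.tsv", sep="\t")
        refs = self._reference_clusters()[:2]
        if len(refs) < 2:
            self._note("decode_behavior", skipped="fewer than 2 reference clusters")
            (self.out / "loso_regression.json").write_text(json.dumps(
                {"skipped": "fewer than 2 reference clusters"}))
            return {}
        zb = self._load_zmaps("bilateral")
        zseed = {"L_amyg": self._load_zmaps("L_amyg"), "R_amyg": self._load_zmaps("R_amyg")}
        out = {}
        for measure in ("dprime", "rt_cv"):
            res = decoding.loso_behavior_prediction(
                zb, zseed, self._labels(), beh[measure].to_numpy(), refs,
                nominal_p=cfg.nominal_p, adjacency=cfg.adjacency)
            pd.DataFrame({"subject_id": beh["subject_id"], "observed": res.observed,
                          "predicted": res.predicted}).to_csv(
                self.out / f"loso_{measure}.tsv", sep="\t", index=False)
            sizes = pd.DataFrame(res.fold_cluster_sizes)
            out[measure] = {"r": res.r, "p": res.p,
                            "cluster_size_range": [int(sizes.min().min()),
                                                   int(sizes.max().max())]}
        (self.out / "loso_regression.json").write_text(json.dumps(out, indent=2))
        self._note("decode_behavior", **{m: v["r"] for m, v in out.items()})
        return out

    def stage_classify(self) -> dict:
        cfg = self.config
        fdf = pd.read_csv(self.out / "features.tsv", sep="\t")
        X = fdf.drop(columns="subject_id").to_numpy()
        y = self._labels()
        n_max = min(cfg.n_feature_max, X.shape[1], len(y))
        res = decoding.loso_classify(X, y, range(1, n_max + 1))
        pd.DataFrame({"n_features": res.n_values, "accuracy": res.accuracy,
                      "sensitivity": res.sensitivity,
                      "specificity": res.specificity}).to_csv(
            self.out / "accuracy_curve.tsv", sep="\t", index=False)
        perm = decoding.permutation_test(X, y, res.best_n, n_perm=cfg.n_perm,
                                         seed=_subject_seed(self.seed, 0, 31))
        summary = {"best_n": res.best_n, "confusion": res.confusion,
                   "metrics": res.metrics,
                   "permutation": {"observed_accuracy": perm.observed_accuracy,
                                   "p": perm.p, "n_perm": perm.n_perm}}
        (self.out / "classification.json").write_text(json.dumps(summary, indent=2))
        np.savetxt(self.out / "permutation_null.tsv", perm.null_accuracies,
                   header="null_accuracy", comments="")
        self._note("classify", best_n=res.best_n,
                   accuracy=res.metrics["accuracy"], perm_p=perm.p)
        return summary

    def stage_report(self) -> Path:
        sections = []
        meta = json.loads((self.out / "run_meta.json").read_text())
        sections.append(f"# gradconn run report\n\nconfig hash `{meta['config_hash']}`, "
                        f"seed {meta['seed']}\n")
        bs = pd.read_csv(self.out / "behavior_stats.tsv", sep="\t")
        sections.append("## Behavioral group comparison\n\n" + bs.to_string(index=False))
        cr = pd.read_csv(self.out / "cluster_report.tsv", sep="\t")
        sections.append("## Group-difference clusters\n\n"
                        + (cr.to_string(index=False) if len(cr) else "(none)"))
        lr = json.loads((self.out / "loso_regression.json").read_text())
        sections.append("## LOSO behavior prediction\n\n" + json.dumps(lr, indent=2))
        cls = json.loads((self.out / "classification.json").read_text())
        sections.append("## LOSO classification\n\n" + json.dumps(cls, indent=2))
        path = self.out / "report.md"
        path.write_text("\n\n".join(sections) + "\n")
        self._note("report")
        return path

    def run_all(self) -> dict:
        self.stage_simulate()
        behavior = self.stage_score()
        self.stage_fc()
        found = self.stage_cluster()
        regression = self.stage_decode_behavior()
        classification = self.stage_classify()
        self.stage_report()
        return {"behavior": behavior, "clusters": found,
                "regression": regression, "classification": classification}


def run_pipeline(config: RunConfig, seed: int | None = None,
                 out_dir: str | Path = "gradconn_run") -> dict:
    """Run every stage in order; returns the per-stage summary objects."""
    return PipelineRun(config, seed=seed, out_dir=out_dir).run_all()
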