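"""End-to-end orchestration: simulate → fit → group → rois → mean level →
MVPA, with every stage also runnable standalone on the previous stage's
on-disk outputs.  Running the stages in sequence is byte-identical to the
monolithic pipeline because each stage reads only the files the previous
one wrote.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, glm, group as grp, mvpa as mv, roimean, synth

log = logging.getLogger(__name__)

CONTRASTS = {
    "NAgtNR": {"NA": 1.0, "NR": -1.0},
    "NVgtNR": {"NV": 1.0, "NR": -1.0},
    "NAgtNV": {"NA": 1.0, "NV": -1.0},
    "NVgtNA": {"NV": 1.0, "NA": -1.0},
}


@dataclass
class PipelineConfig:
    """JSON-serializable configuration for the whole analysis."""

    seed: int = 0
    n_subjects: int = 21
    design: dict = field(default_factory=dict)  # AcquisitionDesign overrides
    atlas_grid: tuple[int, int, int] = (20, 24, 20)
    atlas_voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.4375)
    atlas_radius: float = 2.0
    effects: list[dict] = field(default_factory=list)
    noise: dict = field(default_factory=dict)  # NoiseSpec overrides
    between_subject_sd: float = 0.1
    smooth_fwhm_mm: float = 6.0
    highpass_cutoff_s: float = 128.0
    include_cue: bool = True
    use_motion_regressors: bool = True
    voxel_p: float = 0.001
    cluster_alpha: float = 0.05
    n_permutations: int = 500
    connectivity: int = 26
    min_roi_voxels: int = 3
    mvpa_n_folds: int = 8
    mvpa_shift_s: float = 4.0
    mvpa_C: float = 1.0
    mvpa_smoothed: bool = False
    meanlevel_alternative: str = "two-sided"

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        raw = json.loads(Path(path).read_text())
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - names
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=1, sort_keys=True, default=str)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]

    def effect_spec(self) -> synth.EffectSpec:
        amp, psd = {}, {}
        for e in self.effects:
            key = (e["region"], e["condition"])
            if "amplitude" in e:
                amp[key] = float(e["amplitude"])
            if "pattern_sd" in e:
                psd[key] = float(e["pattern_sd"])
        return synth.EffectSpec(amp, psd)

    def build(self):
        design, events = synth.build_design(**self.design)
        atlas = synth.default_atlas(
            tuple(self.atlas_grid), tuple(self.atlas_voxel_size_mm), self.atlas_radius
        )
        return design, events, atlas


def _provenance(cfg: PipelineConfig, stage: str, started: float) -> dict:
    return {
        "stage": stage,
        "config_hash": cfg.config_hash,
        "seed": cfg.seed,
        "package_version": __version__,
        "elapsed_s": round(time.time() - started, 3),
    }


def _write_provenance(cfg: PipelineConfig, stage: str, out: Path, started: float) -> None:
    (out / f"{stage}_provenance.json").write_text(
        json.dumps(_provenance(cfg, stage, started), indent=1, sort_keys=True)
    )


def _load_nii(path: Path):
    import nibabel as nib

    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=float), img.affine


def _save_nii(data: np.ndarray, affine: np.ndarray, path: Path) -> None:
    import nibabel as nib

    nib.save(nib.Nifti1Image(np.asarray(data), affine), str(path))


def stage_simulate(cfg: PipelineConfig, out_dir: str | Path) -> Path:
    started = time.time()
    out = Path(out_dir)
    design, events, atlas = cfg.build()
    cohort = out / "cohort"
    synth.simulate_cohort(
        cfg.n_subjects, design, events, atlas, cfg.effect_spec(),
        synth.NoiseSpec(**cfg.noise), cfg.between_subject_sd, cfg.seed, cohort,
    )
    _write_provenance(cfg, "simulate", cohort, started)
    return cohort


def _subject_dirs(cohort: Path) -> list[Path]:
    manifest = json.loads((cohort / "manifest.json").read_text())
    return [cohort / s["id"] for s in manifest["subjects"]]


def _load_subject_runs(sdir: Path, cfg: PipelineConfig):
    design = synth.AcquisitionDesign(**cfg.design)
    runs, events, motion = [], [], []
    for r in range(1, design.n_runs + 1):
        data, affine = _load_nii(sdir / f"func_run-{r}.nii")
        runs.append(synth.VolumeSeries(data, design.tr_seconds, affine, r - 1))
        # keep_default_na: the condition label "NA" must not parse as NaN
        events.append(
            pd.read_csv(sdir / f"events_run-{r}.tsv", sep="\t", keep_default_na=False)
        )
        mpath = sdir / f"motion_run-{r}.tsv"
        motion.append(pd.read_csv(mpath, sep="\t").to_numpy() if mpath.exists() else None)
    return design, runs, events, motion


def stage_fit(cfg: PipelineConfig, out_dir: str | Path) -> Path:
    """First-level GLM per subject: smooth, fit per run, average contrast
    effects across runs, write one effect NIfTI per subject × contrast."""
    started = time.time()
    out = Path(out_dir)
    cohort = out / "cohort"
    first = out / "firstlevel"
    first.mkdir(parents=True, exist_ok=True)
    voxel_size = tuple(cfg.atlas_voxel_size_mm)
    for sdir in _subject_dirs(cohort):
        design, runs, events, motion = _load_subject_runs(sdir, cfg)
        mask = np.ones(runs[0].data.shape[:3], dtype=bool)
        effects: dict[str, list[np.ndarray]] = {c: [] for c in CONTRASTS}
        for vs, ev, mo in zip(runs, events, motion):
            data = glm.smooth_volume(vs.data, cfg.smooth_fwhm_mm, voxel_size)
            X = glm.build_design_matrix(
                ev, vs.n_volumes, vs.tr_seconds,
                highpass_cutoff_s=cfg.highpass_cutoff_s,
                motion=mo if cfg.use_motion_regressors else None,
                include_cue=cfg.include_cue,
            )
            fit = glm.fit_glm(data, X, mask)
            for cname, weights in CONTRASTS.items():
                cm = glm.compute_contrast(fit, weights, cname)
                effects[cname].append(cm.effect)
        for cname, maps in effects.items():
            _save_nii(np.mean(maps, axis=0), runs[0].affine,
                      first / f"{sdir.name}_{cname}_effect.nii")
    _write_provenance(cfg, "fit", first, started)
    return first


def _subject_effect_maps(first: Path, contrast: str) -> list[np.ndarray]:
    paths = sorted(first.glob(f"sub-*_{contrast}_effect.nii"))
    if not paths:
        raise FileNotFoundError(f"no first-level maps for contrast {contrast!r} in {first}")
    return [_load_nii(p)[0] for p in paths]


def stage_group(cfg: PipelineConfig, out_dir: str | Path) -> Path:
    started = time.time()
    out = Path(out_dir)
    first = out / "firstlevel"
    gdir = out / "group"
    gdir.mkdir(parents=True, exist_ok=True)
    _, affine = _load_nii(next(iter(sorted(first.glob("sub-*_effect.nii")))))
    report_rows = []
    for i, cname in enumerate(CONTRASTS):
        maps = _subject_effect_maps(first, cname)
        gmap = grp.one_sample_group_t(maps)
        gmap.contrast_name = cname
        thr = grp.threshold_with_cluster_fwe(
            maps, cfg.voxel_p, cfg.cluster_alpha, cfg.n_permutations,
            seed=cfg.seed + 7919 * (i + 1), connectivity=cfg.connectivity,
        )
        _save_nii(gmap.t, affine, gdir / f"{cname}_t.nii")
        _save_nii(thr.mask.astype(np.int16), affine, gdir / f"{cname}_mask.nii")
        for j, vox in enumerate(thr.clusters):
            centroid = vox.mean(axis=0)
            report_rows.append({
                "contrast": cname, "cluster": j + 1, "n_voxels": len(vox),
                "centroid_i": round(float(centroid[0]), 3),
                "centroid_j": round(float(centroid[1]), 3),
                "centroid_k": round(float(centroid[2]), 3),
            })
    pd.DataFrame(
        report_rows,
        columns=["contrast", "cluster", "n_voxels", "centroid_i", "centroid_j", "centroid_k"],
    ).to_csv(gdir / "cluster_report.tsv", sep="\t", index=False)
    _write_provenance(cfg, "group", gdir, started)
    return gdir


def stage_rois(cfg: PipelineConfig, out_dir: str | Path) -> Path:
    """Conjunction of the two generation contrasts, split by atlas label."""
    started = time.time()
    out = Path(out_dir)
    gdir = out / "group"
    rdir = out / "rois"
    rdir.mkdir(parents=True, exist_ok=True)
    ma, affine = _load_nii(gdir / "NAgtNR_mask.nii")
    mb, _ = _load_nii(gdir / "NVgtNR_mask.nii")
    conj = grp.conjunction(ma > 0, mb > 0)
    atlas_grid, _ = _load_nii(out / "cohort" / "atlas.nii")
    manifest = json.loads((out / "cohort" / "manifest.json").read_text())
    label_names = {int(k): v for k, v in manifest["label_names"].items()}
    atlas = synth.LabelVolume(
        atlas_grid.astype(int), tuple(cfg.atlas_voxel_size_mm), affine, label_names
    )
    rois = grp.segment_shared_rois(conj, atlas, cfg.min_roi_voxels)
    _save_nii(conj.astype(np.int16), affine, rdir / "conjunction_mask.nii")
    payload = [
        {
            "name": r.name,
            "parent_label": r.parent_label,
            "n_voxels": r.n_voxels,
            "voxels": r.voxels.tolist(),
            "centroid_world": (
                atlas.affine @ np.append(r.voxels.mean(axis=0), 1.0)
            )[:3].tolist(),
        }
        for r in rois
    ]
    (rdir / "rois.json").write_text(json.dumps(payload, indent=1, sort_keys=True))
    _write_provenance(cfg, "rois", rdir, started)
    return rdir


def _load_rois(out: Path) -> list[grp.SharedROI]:
    payload = json.loads((out / "rois" / "rois.json").read_text())
    return [grp.SharedROI(r["name"], np.asarray(r["voxels"]), r["parent_label"])
            for r in payload]


def stage_meanlevel(cfg: PipelineConfig, out_dir: str | Path) -> Path:
    started = time.time()
    out = Path(out_dir)
    mdir = out / "meanlevel"
    mdir.mkdir(parents=True, exist_ok=True)
    rois = _load_rois(out)
    columns = ["roi", "n", "mean_A", "mean_B", "t", "dof", "p_raw", "p_adj", "alternative"]
    rows = []
    if rois:
        maps_a = _subject_effect_maps(out / "firstlevel", "NAgtNR")
        maps_b = _subject_effect_maps(out / "firstlevel", "NVgtNR")
        per_a = {r.name: np.array([roimean.roi_mean_contrast(m, r) for m in maps_a])
                 for r in rois}
        per_b = {r.name: np.array([roimean.roi_mean_contrast(m, r) for m in maps_b])
                 for r in rois}
        for res in roimean.mean_level_table(per_a, per_b, cfg.meanlevel_alternative):
            rows.append({
                "roi": res.roi_name, "n": len(res.per_subject_a),
                "mean_A": round(float(res.per_subject_a.mean()), 6),
                "mean_B": round(float(res.per_subject_b.mean()), 6),
                "t": round(res.t, 6), "dof": res.dof,
                "p_raw": round(res.p_raw, 6), "p_adj": round(res.p_adjusted, 6),
                "alternative": res.alternative,
            })
    df = pd.DataFrame(rows, columns=columns)
    df.to_csv(mdir / "mean_level.tsv", sep="\t", index=False)
    (mdir / "mean_level.json").write_text(df.to_json(orient="records", indent=1))
    _write_provenance(cfg, "meanlevel", mdir, started)
    return mdir


def stage_mvpa(cfg: PipelineConfig, out_dir: str | Path) -> Path:
    started = time.time()
    out = Path(out_dir)
    vdir = out / "mvpa"
    vdir.mkdir(parents=True, exist_ok=True)
    rois = _load_rois(out)
    columns = ["roi", "n", "mean_acc", "se", "t", "dof", "p", "p_bonferroni"]
    rows = []
    if rois:
        voxel_size = tuple(cfg.atlas_voxel_size_mm)
        results = []
        for roi in rois:
            folds_per_subject = []
            for sdir in _subject_dirs(out / "cohort"):
                design, runs, events, _ = _load_subject_runs(sdir, cfg)
                if cfg.mvpa_smoothed:
                    for vs in runs:
                        vs.data = glm.smooth_volume(vs.data, cfg.smooth_fwhm_mm, voxel_size)
                folds_per_subject.append(mv.decode_subject(
                    runs, roi, events, design.tr_seconds, cfg.mvpa_shift_s,
                    n_folds=cfg.mvpa_n_folds, seed=cfg.seed, C=cfg.mvpa_C,
                    subject_id=sdir.name,
                ))
            results.append(mv.group_decode(folds_per_subject, roi.name))
        adj = roimean.bonferroni([r.p for r in results], len(results))
        for res, p_adj in zip(results, adj):
            res.p_adjusted = p_adj
            rows.append({
                "roi": res.roi_name, "n": len(res.per_subject_accuracy),
                "mean_acc": round(res.group_mean, 6), "se": round(res.group_se, 6),
                "t": round(res.t, 6), "dof": res.dof,
                "p": round(res.p, 6), "p_bonferroni": round(p_adj, 6),
            })
    df = pd.DataFrame(rows, columns=columns)
    df.to_csv(vdir / "mvpa.tsv", sep="\t", index=False)
    (vdir / "mvpa.json").write_text(df.to_json(orient="records", indent=1))
    _write_provenance(cfg, "mvpa", vdir, started)
    return vdir


STAGES = {
    "simulate": stage_simulate,
    "fit": stage_fit,
    "group": stage_group,
    "rois": stage_rois,
    "meanlevel": stage_meanlevel,
    "mvpa": stage_mvpa,
}


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path) -> dict[str, Path]:
    """Execute every stage in order; aborts naming the failing stage while
    keeping whatever partial outputs were already written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(cfg.to_json())
    produced: dict[str, Path] = {}
    for name, fn in STAGES.items():
        t0 = time.time()
        try:
            produced[name] = fn(cfg, out)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        log.info("stage %-9s done in %.2f s", name, time.time() - t0)
    return produced
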