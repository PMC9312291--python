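"""Synthetic block-design BOLD cohorts with known ground truth.

Builds the acquisition schedule (TR = 2 s, two runs of twelve task blocks
interleaved with twelve 10-s rest blocks), rasterizes spherical parcels
into a label volume, and simulates 4D volume series whose signal model is

    BOLD = baseline
         + Σ_condition (amplitude + pattern[voxel]) · (boxcar ⊛ HRF)
         + drift + motion leakage + AR(1) noise.

Condition regressors come from :mod:`fmripattern.glm`'s convolution path so
simulation and analysis agree on the hemodynamic model exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import glm

__all__ = [
    "AcquisitionDesign",
    "LabelVolume",
    "EffectSpec",
    "NoiseSpec",
    "VolumeSeries",
    "GroundTruth",
    "BASELINE",
    "DEFAULT_REGIONS",
    "build_design",
    "make_atlas",
    "default_atlas",
    "simulate_subject",
    "simulate_cohort",
]

log = logging.getLogger(__name__)

#: baseline intensity; amplitudes then read as percent signal change
BASELINE = 100.0

DEFAULT_REGIONS = ("LSMA", "RSMA", "LIFG", "LIPL", "CONTROL")


@dataclass(frozen=True)
class AcquisitionDesign:
    """Block-design acquisition timing (defaults mirror the study design)."""

    tr_seconds: float = 2.0
    n_runs: int = 2
    blocks_per_task_per_run: int = 4
    cue_seconds: float = 2.0
    trials_per_block: int = 6
    fixation_seconds: float = 1.0
    stimulus_seconds: float = 1.5
    rest_seconds: float = 10.0
    task_names: tuple[str, ...] = ("NA", "NV", "NR")

    def __post_init__(self) -> None:
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        for name in ("cue_seconds", "fixation_seconds", "stimulus_seconds", "rest_seconds"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def task_block_seconds(self) -> float:
        """Trial epoch length: trials × (fixation + stimulus)."""
        return self.trials_per_block * (self.fixation_seconds + self.stimulus_seconds)

    @property
    def blocks_per_run(self) -> int:
        return self.blocks_per_task_per_run * len(self.task_names)

    @property
    def run_duration_seconds(self) -> float:
        per_block = self.cue_seconds + self.task_block_seconds + self.rest_seconds
        return self.blocks_per_run * per_block

    @property
    def n_volumes_per_run(self) -> int:
        dur = self.run_duration_seconds
        n = dur / self.tr_seconds
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                f"run duration {dur:g} s is not a multiple of TR {self.tr_seconds:g} s "
                f"(cue={self.cue_seconds:g}, trial block={self.task_block_seconds:g}, "
                f"rest={self.rest_seconds:g})"
            )
        return int(round(n))


def _block_order(design: AcquisitionDesign, run: int) -> list[str]:
    """Latin-square rotation of condition tuples, mirrored on odd runs.

    Even runs rotate the task tuple one step per block group; odd runs
    replay the previous even run's order reversed in time (ABBA-style),
    so condition order and temporal position are counterbalanced across
    run pairs and no condition is systematically early or late.
    """
    k = len(design.task_names)
    order: list[str] = []
    for grp in range(design.blocks_per_task_per_run):
        shift = (grp + run // 2) % k
        order.extend(design.task_names[(i + shift) % k] for i in range(k))
    return order[::-1] if run % 2 else order


def build_design(**overrides) -> tuple[AcquisitionDesign, list[pd.DataFrame]]:
    """Default design (unless overridden) plus one event table per run.

    Each run alternates cue → task block → rest.  Event tables are
    BIDS-style frames with columns run_id, onset, duration, trial_type,
    block_id; the cue and its task block share a block_id.
    """
    design = AcquisitionDesign(**overrides)
    n_vol = design.n_volumes_per_run  # validates TR divisibility
    tables = []
    for run in range(design.n_runs):
        rows = []
        t = 0.0
        for block_id, cond in enumerate(_block_order(design, run)):
            if design.cue_seconds > 0:
                rows.append((run, t, design.cue_seconds, "cue", block_id))
            t += design.cue_seconds
            if design.task_block_seconds > 0:
                rows.append((run, t, design.task_block_seconds, cond, block_id))
            t += design.task_block_seconds
            if design.rest_seconds > 0:
                rows.append((run, t, design.rest_seconds, "rest", block_id))
            t += design.rest_seconds
        tables.append(
            pd.DataFrame(rows, columns=["run_id", "onset", "duration", "trial_type", "block_id"])
        )
    return design, tables


@dataclass
class LabelVolume:
    """Integer parcellation on a regular grid; label 0 is background."""

    grid: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    affine: np.ndarray
    label_names: dict[int, str]

    def label_of(self, name: str) -> int:
        for lab, nm in self.label_names.items():
            if nm == name:
                return lab
        raise KeyError(name)

    def region_mask(self, name: str) -> np.ndarray:
        return self.grid == self.label_of(name)

    def region_voxels(self, name: str) -> np.ndarray:
        """k×3 array of 0-based (i, j, k) indices of the named region."""
        return np.argwhere(self.region_mask(name))


def make_atlas(
    grid_shape: tuple[int, int, int],
    voxel_size_mm: tuple[float, float, float],
    region_specs: list[tuple[str, tuple[float, float, float], float]],
) -> LabelVolume:
    """Rasterize non-overlapping spheres (center, radius in voxels) into labels."""
    grid = np.zeros(grid_shape, dtype=np.int16)
    names: dict[int, str] = {}
    idx = np.indices(grid_shape).astype(float)
    for lab, (name, center, radius) in enumerate(region_specs, start=1):
        c = np.asarray(center, dtype=float)
        if np.any(c - radius < -0.5) or np.any(c + radius > np.asarray(grid_shape) - 0.5):
            raise ValueError(f"region {name!r} does not fit inside the grid")
        d2 = sum((idx[a] - c[a]) ** 2 for a in range(3))
        sphere = d2 <= radius * radius + 1e-12
        if np.any(grid[sphere] != 0):
            clash = names[int(grid[sphere][grid[sphere] != 0][0])]
            raise ValueError(f"region {name!r} overlaps region {clash!r}")
        grid[sphere] = lab
        names[lab] = name
    for lab, name in names.items():
        if not np.any(grid == lab):
            raise ValueError(f"region {name!r} rasterized to zero voxels")
    affine = np.diag(list(voxel_size_mm) + [1.0])
    return LabelVolume(grid, tuple(voxel_size_mm), affine, names)


def default_atlas(
    grid_shape: tuple[int, int, int] = (20, 24, 20),
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.4375),
    radius: float = 2.0,
) -> LabelVolume:
    """Five spherical parcels (LSMA, RSMA, LIFG, LIPL, CONTROL) on a small grid."""
    gx, gy, gz = grid_shape
    centers = [
        (gx * 0.30, gy * 0.50, gz * 0.75),
        (gx * 0.70, gy * 0.50, gz * 0.75),
        (gx * 0.20, gy * 0.75, gz * 0.40),
        (gx * 0.25, gy * 0.25, gz * 0.55),
        (gx * 0.75, gy * 0.20, gz * 0.30),
    ]
    specs = [(name, c, radius) for name, c in zip(DEFAULT_REGIONS, centers)]
    return make_atlas(grid_shape, voxel_size_mm, specs)


@dataclass
class EffectSpec:
    """Per-(region, condition) mean amplitudes and zero-mean pattern scales.

    ``amplitude[(region, cond)]`` is the mean percent-signal-change effect;
    ``pattern_sd[(region, cond)]`` scales a fixed zero-mean voxelwise
    pattern drawn from ``pattern_seed[region]`` (defaults derived from the
    simulation seed).
    """

    amplitude: dict[tuple[str, str], float] = field(default_factory=dict)
    pattern_sd: dict[tuple[str, str], float] = field(default_factory=dict)
    pattern_seed: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for v in list(self.amplitude.values()) + list(self.pattern_sd.values()):
            if not np.isfinite(v):
                raise ValueError("effect amplitudes and pattern scales must be finite")

    def regions(self) -> list[str]:
        seen: dict[str, None] = {}
        for region, _ in list(self.amplitude) + list(self.pattern_sd):
            seen.setdefault(region, None)
        return list(seen)


@dataclass(frozen=True)
class NoiseSpec:
    """White + AR(1) + cosine drift + motion-leakage nuisance structure."""

    white_sd: float = 1.0
    ar1_rho: float = 0.3
    drift_amplitude: float = 1.0
    n_drift_components: int = 3
    motion_coupling: float = 0.0
    drift_cutoff_s: float = 128.0

    def __post_init__(self) -> None:
        if not abs(self.ar1_rho) < 1:
            raise ValueError("|ar1_rho| must be < 1")
        for name in ("white_sd", "drift_amplitude", "motion_coupling"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class VolumeSeries:
    """One run of 4D BOLD data (x, y, z, t)."""

    data: np.ndarray
    tr_seconds: float
    affine: np.ndarray
    run_id: int

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]


@dataclass
class GroundTruth:
    """What the simulator actually injected, for recovery oracles."""

    beta_maps: dict[str, np.ndarray]  # condition -> 3D amplitude+pattern map
    pattern_vectors: dict[str, dict[str, np.ndarray]]  # region -> cond -> vector
    amplitudes: dict[str, dict[str, float]]  # region -> cond -> amplitude used
    noise: NoiseSpec
    seed: int
    motion: list[np.ndarray] = field(default_factory=list)  # per run T×6


def _pattern_vector(rng: np.random.Generator, n_voxels: int, sd: float) -> np.ndarray:
    """Zero-mean (exactly) voxelwise pattern with scale ``sd``."""
    if sd == 0 or n_voxels < 2:
        return np.zeros(n_voxels)
    v = rng.normal(0.0, sd, size=n_voxels)
    return v - v.mean()


def _ar1_noise(rng: np.random.Generator, shape: tuple[int, ...], rho: float, sd: float) -> np.ndarray:
    """Stationary AR(1) series along the last axis with marginal sd ``sd``."""
    if sd == 0:
        return np.zeros(shape)
    innov_sd = sd * np.sqrt(1.0 - rho * rho)
    w = rng.normal(0.0, innov_sd, size=shape)
    out = np.empty(shape)
    out[..., 0] = rng.normal(0.0, sd, size=shape[:-1])
    for t in range(1, shape[-1]):
        out[..., t] = rho * out[..., t - 1] + w[..., t]
    return out


def _motion_regressors(rng: np.random.Generator, n_volumes: int) -> np.ndarray:
    """Six standardized random-walk nuisance traces."""
    steps = rng.normal(0.0, 1.0, size=(n_volumes, 6))
    walk = np.cumsum(steps, axis=0)
    walk -= walk.mean(axis=0)
    sd = walk.std(axis=0)
    sd[sd == 0] = 1.0
    return walk / sd


def simulate_subject(
    design: AcquisitionDesign,
    events: list[pd.DataFrame],
    atlas: LabelVolume,
    effect_spec: EffectSpec,
    noise_spec: NoiseSpec,
    seed: int | np.random.SeedSequence,
    hrf: glm.Hrf | None = None,
    subject_amplitudes: dict[tuple[str, str], float] | None = None,
) -> tuple[list[VolumeSeries], GroundTruth]:
    """Simulate one subject's runs; reproducible for a fixed seed.

    ``subject_amplitudes`` (used by :func:`simulate_cohort`) overrides the
    population amplitudes of ``effect_spec`` for this subject only.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    seed_int = int(ss.entropy) if ss.spawn_key == () else hash(ss.spawn_key)
    rng = np.random.default_rng(ss)
    hrf = hrf or glm.Hrf()
    n_vol = design.n_volumes_per_run
    shape = atlas.grid.shape
    amps = dict(effect_spec.amplitude)
    if subject_amplitudes:
        amps.update(subject_amplitudes)

    # fixed per-region patterns (shared across runs and, via pattern_seed,
    # across subjects)
    patterns: dict[str, dict[str, np.ndarray]] = {}
    amplitudes: dict[str, dict[str, float]] = {}
    beta_maps = {c: np.zeros(shape) for c in design.task_names}
    keys = sorted(set(amps) | set(effect_spec.pattern_sd))
    for region in sorted({r for r, _ in keys}):
        try:
            vox = atlas.region_voxels(region)
        except KeyError:
            raise ValueError(f"effect region {region!r} not present in atlas") from None
        base = effect_spec.pattern_seed.get(region)
        patterns[region] = {}
        amplitudes[region] = {}
        for ci, cond in enumerate(design.task_names):
            sd = effect_spec.pattern_sd.get((region, cond), 0.0)
            if base is None:
                prng = np.random.default_rng(ss.spawn(1)[0])
            else:
                prng = np.random.default_rng([base, ci])
            pat = _pattern_vector(prng, len(vox), sd)
            amp = amps.get((region, cond), 0.0)
            patterns[region][cond] = pat
            amplitudes[region][cond] = amp
            beta_maps[cond][tuple(vox.T)] += amp + pat

    drift_basis = glm.dct_basis(n_vol, design.tr_seconds, noise_spec.drift_cutoff_s)
    drift_basis = drift_basis[:, : noise_spec.n_drift_components]

    runs: list[VolumeSeries] = []
    motion_all: list[np.ndarray] = []
    for run, ev in enumerate(events):
        regs = glm.convolved_regressors(ev, design.task_names, n_vol, design.tr_seconds, hrf)
        data = np.full(shape + (n_vol,), BASELINE)
        for cond in design.task_names:
            bmap = beta_maps[cond]
            nz = bmap != 0
            if np.any(nz):
                data[nz] += np.outer(bmap[nz], regs[cond])

        run_rng = np.random.default_rng(ss.spawn(1)[0])
        if noise_spec.drift_amplitude > 0 and drift_basis.shape[1] > 0:
            coef = run_rng.normal(
                0.0, noise_spec.drift_amplitude, size=shape + (drift_basis.shape[1],)
            )
            data += coef @ drift_basis.T
        motion = _motion_regressors(run_rng, n_vol)
        motion_all.append(motion)
        if noise_spec.motion_coupling > 0:
            coupling = run_rng.normal(0.0, noise_spec.motion_coupling, size=shape + (6,))
            data += coupling @ motion.T
        data += _ar1_noise(run_rng, shape + (n_vol,), noise_spec.ar1_rho, noise_spec.white_sd)
        runs.append(VolumeSeries(data, design.tr_seconds, atlas.affine.copy(), run))

    gt = GroundTruth(beta_maps, patterns, amplitudes, noise_spec, seed_int, motion_all)
    return runs, gt


def _json_default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.integer, np.floating)):
        return o.item()
    raise TypeError(type(o))


def simulate_cohort(
    n_subjects: int,
    design: AcquisitionDesign,
    events: list[pd.DataFrame],
    atlas: LabelVolume,
    effect_spec: EffectSpec,
    noise_spec: NoiseSpec,
    between_subject_sd: float,
    seed: int,
    out_dir: str | Path,
) -> dict:
    """Simulate and write a cohort to disk; returns the manifest.

    Layout: ``sub-XX/func_run-Y.nii`` + ``events_run-Y.tsv`` +
    ``motion_run-Y.tsv`` per subject, plus ``atlas.nii``,
    ``ground_truth.json`` and ``manifest.json`` at the root.  Subject
    amplitudes are drawn around the population values with
    ``between_subject_sd``.
    """
    import nibabel as nib

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(seed)
    amp_rng = np.random.default_rng(root.spawn(1)[0])
    subject_seeds = root.spawn(n_subjects)

    # patterns must be shared across subjects: pin per-region pattern seeds
    # derived from the cohort seed unless the caller fixed them already
    regions = sorted({r for r, _ in set(effect_spec.pattern_sd) | set(effect_spec.amplitude)})
    pattern_seed = dict(effect_spec.pattern_seed)
    for i, region in enumerate(regions):
        pattern_seed.setdefault(region, seed * 1000 + i)
    effect_spec = replace(effect_spec, pattern_seed=pattern_seed)

    nib.save(
        nib.Nifti1Image(atlas.grid.astype(np.int16), atlas.affine), str(out / "atlas.nii")
    )
    gt_all: dict[str, dict] = {}
    manifest: dict = {
        "n_subjects": n_subjects,
        "seed": seed,
        "design": asdict(design),
        "noise": asdict(noise_spec),
        "between_subject_sd": between_subject_sd,
        "label_names": {str(k): v for k, v in atlas.label_names.items()},
        "subjects": [],
    }
    for s in range(n_subjects):
        sub = f"sub-{s + 1:02d}"
        sdir = out / sub
        sdir.mkdir(exist_ok=True)
        sub_amps = {
            key: float(amp_rng.normal(val, between_subject_sd))
            for key, val in effect_spec.amplitude.items()
        }
        try:
            runs, gt = simulate_subject(
                design, events, atlas, effect_spec, noise_spec, subject_seeds[s],
                subject_amplitudes=sub_amps,
            )
            files = []
            for run, (vs, ev) in enumerate(zip(runs, events)):
                fn = sdir / f"func_run-{run + 1}.nii"
                nib.save(nib.Nifti1Image(vs.data.astype(np.float32), vs.affine), str(fn))
                ev.to_csv(sdir / f"events_run-{run + 1}.tsv", sep="\t", index=False)
                pd.DataFrame(
                    gt.motion[run], columns=[f"motion_{i + 1}" for i in range(6)]
                ).to_csv(sdir / f"motion_run-{run + 1}.tsv", sep="\t", index=False)
                files.append(fn.name)
        except OSError as exc:
            raise OSError(f"failed writing cohort under {sdir}: {exc}") from exc
        gt_all[sub] = {
            "amplitudes": gt.amplitudes,
            "pattern_vectors": {
                r: {c: v for c, v in d.items()} for r, d in gt.pattern_vectors.items()
            },
            "noise": asdict(noise_spec),
        }
        manifest["subjects"].append({"id": sub, "runs": files})

    (out / "ground_truth.json").write_text(
        json.dumps(gt_all, default=_json_default, indent=1, sort_keys=True)
    )
    payload = json.dumps(manifest, default=_json_default, indent=1, sort_keys=True)
    manifest["checksum"] = hashlib.sha256(payload.encode()).hexdigest()
    (out / "manifest.json").write_text(
        json.dumps(manifest, default=_json_default, indent=1, sort_keys=True)
    )
    return manifest
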