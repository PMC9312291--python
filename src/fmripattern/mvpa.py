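"""Multi-voxel pattern analysis within shared ROIs.

Pipeline: extract the ROI voxels × timepoints matrix, apply the two-step
(temporal then spatial) z-normalization, label each volume as a sample of
its block's condition (after a hemodynamic shift), split at block level
into folds (leave-one-block-pair-out by default) and score a linear
max-margin classifier, then test the per-subject accuracies against
chance at group level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.svm import SVC

__all__ = [
    "RoiMatrix",
    "NormalizedMatrix",
    "SampleSet",
    "MvpaResult",
    "extract_roi_timeseries",
    "normalize_two_step",
    "assemble_samples",
    "crossval_classify",
    "group_accuracy_test",
    "decode_subject",
    "group_decode",
]

log = logging.getLogger(__name__)

DEFAULT_SHIFT_S = 4.0
DEFAULT_FOLDS = 8
CHANCE = 0.5


@dataclass
class RoiMatrix:
    """Raw voxels × timepoints matrix for one ROI (runs concatenated)."""

    values: np.ndarray
    voxel_ids: np.ndarray  # k×3 voxel indices
    timepoints: pd.DataFrame  # columns: run_id, volume

    @property
    def n_voxels(self) -> int:
        return self.values.shape[0]


@dataclass
class NormalizedMatrix:
    """Two-step-normalized matrix: per-timepoint spatial mean 0, sd 1."""

    values: np.ndarray
    voxel_ids: np.ndarray
    timepoints: pd.DataFrame
    stage1_mean: np.ndarray  # per voxel
    stage1_sd: np.ndarray
    stage2_mean: np.ndarray  # per timepoint
    stage2_sd: np.ndarray


@dataclass
class SampleSet:
    """Per-volume feature vectors with condition labels and block groups."""

    features: np.ndarray  # samples × voxels
    labels: np.ndarray  # condition per sample
    groups: np.ndarray  # (run_id, block_id) encoded per sample
    subject_id: str = ""


@dataclass
class MvpaResult:
    """Group summary of per-subject cross-validated accuracies."""

    roi_name: str
    per_subject_accuracy: np.ndarray
    per_fold_accuracies: list[np.ndarray]
    group_mean: float
    group_se: float
    t: float
    dof: int
    p: float
    chance: float = CHANCE
    p_adjusted: float | None = None


def extract_roi_timeseries(vols, roi) -> RoiMatrix:
    """Row per ROI voxel, column per volume, runs in acquisition order."""
    vox = roi.voxels
    if vox.size == 0:
        raise ValueError("empty ROI")
    blocks = []
    tps = []
    for vs in vols:
        data = np.asarray(getattr(vs, "data", vs))
        if np.any(vox >= data.shape[:3]):
            raise ValueError("ROI voxels fall outside the volume grid")
        blocks.append(data[tuple(vox.T)])
        run_id = getattr(vs, "run_id", 0)
        tps.extend((run_id, t) for t in range(data.shape[3]))
    values = np.concatenate(blocks, axis=1).astype(float)
    return RoiMatrix(values, vox, pd.DataFrame(tps, columns=["run_id", "volume"]))


def normalize_two_step(m: RoiMatrix) -> NormalizedMatrix:
    """Temporal z-score per voxel, then spatial z-score per timepoint.

    Constant voxels are dropped with a warning before stage 1 (their
    temporal sd is 0); a zero spatial sd after stage 1 is only possible
    for single-voxel ROIs and is rejected.  Standard deviations use the
    population convention (ddof = 0).
    """
    a = np.asarray(m.values, dtype=float)
    mu_t = a.mean(axis=1)
    sd_t = a.std(axis=1)
    keep = sd_t > 0
    if not keep.all():
        log.warning("normalize_two_step: dropped %d constant voxel(s)",
                    int(np.count_nonzero(~keep)))
    a = a[keep]
    mu_t, sd_t = mu_t[keep], sd_t[keep]
    if a.shape[0] == 0:
        raise ValueError("no voxels left after dropping constant rows")
    z = (a - mu_t[:, None]) / sd_t[:, None]
    mu_s = z.mean(axis=0)
    sd_s = z.std(axis=0)
    if np.any(sd_s == 0):
        raise ValueError("zero spatial variance at some timepoint "
                         "(ROI too small for spatial normalization)")
    b = (z - mu_s[None, :]) / sd_s[None, :]
    return NormalizedMatrix(b, m.voxel_ids[keep], m.timepoints.copy(),
                            mu_t, sd_t, mu_s, sd_s)


def assemble_samples(
    norm: NormalizedMatrix,
    events: list[pd.DataFrame],
    tr: float,
    hemodynamic_shift_s: float = DEFAULT_SHIFT_S,
    conditions: tuple[str, ...] = ("NA", "NV"),
    subject_id: str = "",
) -> SampleSet:
    """Label volumes whose shifted midpoints fall inside condition epochs.

    A volume acquired in run r with index i is a sample of condition c if
    (i + 1/2)·TR − shift lies within a c-block's stimulus epoch.  Rest,
    cue and unlisted conditions are excluded.  Groups encode
    (run, block_id) so folding can respect block structure.
    """
    if hemodynamic_shift_s < 0:
        raise ValueError("hemodynamic_shift_s must be >= 0")
    by_run = {int(ev["run_id"].iloc[0]): ev for ev in events if len(ev)}
    tp = norm.timepoints
    run_ids = tp["run_id"].to_numpy(dtype=int)
    vols = tp["volume"].to_numpy(dtype=float)
    mids = (vols + 0.5) * tr - hemodynamic_shift_s
    cols, labels, groups = [], [], []
    for run_id, ev in by_run.items():
        in_run = run_ids == run_id
        rows = ev[ev["trial_type"].isin(conditions)]
        for onset, duration, cond, block in zip(
            rows["onset"], rows["duration"], rows["trial_type"], rows["block_id"]
        ):
            hit = np.flatnonzero(in_run & (onset <= mids) & (mids < onset + duration))
            cols.extend(hit.tolist())
            labels.extend([cond] * len(hit))
            groups.extend([run_id * 10_000 + int(block)] * len(hit))
    order = np.argsort(np.asarray(cols, dtype=int), kind="stable")
    feats = [norm.values[:, cols[i]] for i in order]
    labels = np.asarray(labels)[order]
    groups = np.asarray(groups)[order]
    for cond in conditions:
        if not np.any(labels == cond):
            raise ValueError(f"no samples labeled for condition {cond!r}")
    counts = {c: int(np.sum(labels == c)) for c in conditions}
    if len(set(counts.values())) > 1:
        log.warning("assemble_samples: unbalanced sample counts %s", counts)
    return SampleSet(np.asarray(feats), labels, groups, subject_id)


def _block_pair_folds(samples: SampleSet, n_folds: int, seed) -> list[np.ndarray]:
    """Leave-one-block-pair-out folds: all samples of a block stay together."""
    conds = sorted(set(samples.labels.tolist()))
    blocks_by_cond = {
        c: sorted(set(samples.groups[samples.labels == c].tolist())) for c in conds
    }
    n_pairs = min(len(b) for b in blocks_by_cond.values())
    if n_folds > n_pairs:
        raise ValueError(
            f"n_folds={n_folds} exceeds the {n_pairs} available block pairs")
    fold_of_pair = np.arange(n_pairs) % n_folds
    rng = np.random.default_rng(seed)
    rng.shuffle(fold_of_pair)  # seed controls fold order only
    fold_groups: list[set] = [set() for _ in range(n_folds)]
    for c in conds:
        for i, block in enumerate(blocks_by_cond[c]):
            if i < n_pairs:
                fold_groups[fold_of_pair[i]].add(block)
            else:
                fold_groups[fold_of_pair[i % n_pairs]].add(block)
    return [np.isin(samples.groups, sorted(g)) for g in fold_groups]


def crossval_classify(
    samples: SampleSet,
    n_folds: int = DEFAULT_FOLDS,
    seed: int = 0,
    C: float = 1.0,
) -> np.ndarray:
    """Block-grouped cross-validated accuracy of a linear max-margin classifier.

    Returns per-fold accuracies.  Every fold's test blocks are excluded
    from its training set (asserted structurally); a training or test fold
    containing a single class is rejected.
    """
    folds = _block_pair_folds(samples, n_folds, seed)
    accs = np.empty(n_folds)
    for k, test in enumerate(folds):
        train = ~test
        assert not np.any(
            np.isin(samples.groups[train], samples.groups[test])
        ), "block leaked between train and test"
        for name, idx in (("training", train), ("test", test)):
            if len(set(samples.labels[idx].tolist())) < 2:
                raise ValueError(f"fold {k} has a single class in its {name} set")
        clf = SVC(kernel="linear", C=C)
        clf.fit(samples.features[train], samples.labels[train])
        accs[k] = float(np.mean(clf.predict(samples.features[test]) == samples.labels[test]))
    return accs


def group_accuracy_test(per_subject_accuracy, chance: float = CHANCE):
    """One-sample t of accuracy − chance, one-sided (greater)."""
    acc = np.asarray(per_subject_accuracy, dtype=float)
    if acc.ndim != 1 or len(acc) < 2:
        raise ValueError("need at least 2 per-subject accuracies")
    if acc.max() == acc.min():
        if np.allclose(acc, chance):
            return 0.0, len(acc) - 1, 0.5
        raise ValueError("zero variance in per-subject accuracies")
    res = sps.ttest_1samp(acc, chance, alternative="greater")
    return float(res.statistic), len(acc) - 1, float(res.pvalue)


def decode_subject(
    vols,
    roi,
    events: list[pd.DataFrame],
    tr: float,
    hemodynamic_shift_s: float = DEFAULT_SHIFT_S,
    conditions: tuple[str, ...] = ("NA", "NV"),
    n_folds: int = DEFAULT_FOLDS,
    seed: int = 0,
    C: float = 1.0,
    subject_id: str = "",
) -> np.ndarray:
    """Full per-subject decoding chain; returns per-fold accuracies."""
    mat = extract_roi_timeseries(vols, roi)
    norm = normalize_two_step(mat)
    samples = assemble_samples(norm, events, tr, hemodynamic_shift_s, conditions, subject_id)
    return crossval_classify(samples, n_folds, seed, C)


def group_decode(per_subject_folds: list[np.ndarray], roi_name: str,
                 chance: float = CHANCE) -> MvpaResult:
    """Aggregate per-subject fold accuracies into the group result."""
    per_subject = np.array([np.mean(f) for f in per_subject_folds])
    t, dof, p = group_accuracy_test(per_subject, chance)
    se = float(per_subject.std(ddof=1) / np.sqrt(len(per_subject)))
    return MvpaResult(roi_name, per_subject, list(per_subject_folds),
                      float(per_subject.mean()), se, t, dof, p, chance)
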