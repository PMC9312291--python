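"""Group inference: one-sample t maps, sign-flip cluster-FWE thresholding,
conjunction masks, and shared-ROI segmentation by atlas label.

Family-wise error over clusters is controlled by a sign-flipping
permutation of the subject effect maps (max cluster extent), which is
exact under exchangeability and replaces parametric random-field
correction.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy import stats as sps

__all__ = [
    "GroupStatMap",
    "ThresholdedMap",
    "SharedROI",
    "one_sample_group_t",
    "threshold_with_cluster_fwe",
    "conjunction",
    "segment_shared_rois",
]

log = logging.getLogger(__name__)

_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass
class GroupStatMap:
    """Voxelwise one-sample t map over subjects (dof = n - 1)."""

    t: np.ndarray
    dof: int
    n_subjects: int
    contrast_name: str = ""


@dataclass
class ThresholdedMap:
    """Binary map of clusters surviving voxel + cluster-FWE thresholds."""

    mask: np.ndarray
    clusters: list[np.ndarray]  # each k×3 voxel indices
    voxel_p_threshold: float
    cluster_alpha: float
    n_permutations: int
    null_max_cluster_sizes: np.ndarray
    t_threshold: float = float("nan")


@dataclass
class SharedROI:
    """Conjunction voxels restricted to one atlas parcel."""

    name: str
    voxels: np.ndarray  # k×3, 0-based (i, j, k)
    parent_label: int

    def __post_init__(self) -> None:
        self.voxels = np.atleast_2d(np.asarray(self.voxels, dtype=int))
        if self.voxels.size == 0:
            raise ValueError(f"ROI {self.name!r} has no voxels")

    @property
    def n_voxels(self) -> int:
        return self.voxels.shape[0]

    def mask(self, shape: tuple[int, int, int]) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        m[tuple(self.voxels.T)] = True
        return m


def _stack(maps) -> np.ndarray:
    arr = np.stack([np.asarray(m, dtype=float) for m in maps])
    if arr.ndim != 4:
        raise ValueError("expected a stack of 3D subject maps")
    return arr


def one_sample_group_t(effect_maps) -> GroupStatMap:
    """Voxelwise t = mean / (sd / sqrt n); zero-variance voxels get t = 0."""
    arr = _stack(effect_maps)
    n = arr.shape[0]
    if n < 2:
        raise ValueError("group t-test needs at least 2 subjects")
    mean = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=1)
    zero = sd == 0
    n_zero = int(np.count_nonzero(zero & np.isfinite(mean)))
    if n_zero:
        log.warning("one_sample_group_t: %d zero-variance voxels set to t=0", n_zero)
    with np.errstate(invalid="ignore"):
        t = np.where(zero, 0.0, mean / np.where(zero, 1.0, sd / np.sqrt(n)))
    return GroupStatMap(t, n - 1, n)


def _sign_matrix(n_subjects: int, n_permutations: int, seed) -> np.ndarray:
    """Sign-flip patterns, identity first; exhaustive when 2^n is small."""
    if 2 ** n_subjects <= n_permutations:
        log.warning(
            "only %d distinct sign flips for %d subjects; enumerating exhaustively",
            2 ** n_subjects, n_subjects,
        )
        return np.array(list(itertools.product((1.0, -1.0), repeat=n_subjects)))
    rng = np.random.default_rng(seed)
    signs = rng.choice((1.0, -1.0), size=(n_permutations, n_subjects))
    signs[0] = 1.0
    return signs


def _max_cluster_size(supra: np.ndarray, structure: np.ndarray) -> int:
    if not supra.any():
        return 0
    labels, n = ndimage.label(supra, structure=structure)
    return int(np.bincount(labels.ravel())[1:].max())


def threshold_with_cluster_fwe(
    subject_maps,
    voxel_p: float = 0.001,
    cluster_alpha: float = 0.05,
    n_permutations: int = 1000,
    seed: int = 0,
    connectivity: int = 26,
    mask: np.ndarray | None = None,
) -> ThresholdedMap:
    """One-sided voxel threshold + permutation FWE over max cluster extent.

    The observed (identity-sign) statistic is included in the null, so the
    smallest attainable cluster p is 1/n_permutations.
    """
    if n_permutations < 100:
        raise ValueError("n_permutations must be >= 100")
    structure = _STRUCTURES[connectivity]
    arr = _stack(subject_maps)
    n, shape = arr.shape[0], arr.shape[1:]
    if mask is not None:
        arr = arr * np.asarray(mask, dtype=bool)
    flat = np.nan_to_num(arr.reshape(n, -1))
    dof = n - 1
    t_crit = float(sps.t.isf(voxel_p, dof))

    signs = _sign_matrix(n, n_permutations, seed)
    n_perm = signs.shape[0]
    ss_ = np.sum(flat * flat, axis=0)  # invariant under sign flips
    null_max = np.zeros(n_perm, dtype=int)
    obs_supra = None
    for p in range(n_perm):
        mean = signs[p] @ flat / n
        var = np.maximum(ss_ - n * mean * mean, 0.0) / (n - 1)
        with np.errstate(invalid="ignore", divide="ignore"):
            t = np.where(var > 0, mean / np.sqrt(var / n), 0.0)
        supra = (t > t_crit).reshape(shape)
        null_max[p] = _max_cluster_size(supra, structure)
        if p == 0:
            obs_supra = supra

    out_mask = np.zeros(shape, dtype=bool)
    clusters: list[np.ndarray] = []
    if obs_supra.any():
        labels, n_cl = ndimage.label(obs_supra, structure=structure)
        for lab in range(1, n_cl + 1):
            vox = np.argwhere(labels == lab)
            p_cluster = float(np.mean(null_max >= len(vox)))
            if p_cluster <= cluster_alpha:
                clusters.append(vox)
                out_mask[labels == lab] = True
    clusters.sort(key=len, reverse=True)
    return ThresholdedMap(
        out_mask, clusters, voxel_p, cluster_alpha, n_perm, null_max, t_crit
    )


def conjunction(a, b) -> np.ndarray:
    """Voxelwise AND of two thresholded masks (intersection conjunction)."""
    ma = np.asarray(getattr(a, "mask", a), dtype=bool)
    mb = np.asarray(getattr(b, "mask", b), dtype=bool)
    if ma.shape != mb.shape:
        raise ValueError(f"grid mismatch: {ma.shape} vs {mb.shape}")
    return ma & mb


def segment_shared_rois(mask: np.ndarray, atlas, min_voxels: int = 1) -> list[SharedROI]:
    """Split a binary mask by atlas label into named shared ROIs.

    Mask voxels on background (label 0) are excluded with a log entry;
    groups smaller than ``min_voxels`` are dropped likewise.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != atlas.grid.shape:
        raise ValueError(f"grid mismatch: mask {mask.shape} vs atlas {atlas.grid.shape}")
    labels = atlas.grid[mask]
    n_bg = int(np.count_nonzero(labels == 0))
    if n_bg:
        log.warning("segment_shared_rois: %d mask voxels on background excluded", n_bg)
    rois: list[SharedROI] = []
    for lab in sorted(set(labels.tolist()) - {0}):
        vox = np.argwhere(mask & (atlas.grid == lab))
        name = f"shared-{atlas.label_names.get(int(lab), str(lab))}"
        if len(vox) < min_voxels:
            log.warning("segment_shared_rois: %s dropped (%d < %d voxels)",
                        name, len(vox), min_voxels)
            continue
        rois.append(SharedROI(name, vox, int(lab)))
    return rois
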