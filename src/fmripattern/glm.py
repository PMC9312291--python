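"""Subject-level general linear model for block-design BOLD time series.

Provides the hemodynamic kernel, boxcar-convolved task regressors,
discrete-cosine drift regressors, spatial smoothing, a two-pass AR(1)
prewhitened least-squares fit, and linear contrasts of the fitted
coefficients.  The regressor-construction code here is also used by the
simulator so that synthesis and analysis share one hemodynamic model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from scipy import stats as sps

__all__ = [
    "Hrf",
    "DesignMatrix",
    "GlmFit",
    "ContrastMap",
    "hrf_evaluate",
    "hrf_kernel",
    "convolved_regressors",
    "dct_basis",
    "n_dct_components",
    "smooth_volume",
    "build_design_matrix",
    "fit_glm",
    "compute_contrast",
]

log = logging.getLogger(__name__)

#: multiply a FWHM by this to obtain the Gaussian sigma
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

TASK_CONDITIONS = ("NA", "NV", "NR")


@dataclass(frozen=True)
class Hrf:
    """Double-gamma hemodynamic response, normalized to unit peak.

    The positive lobe is a gamma density whose mode sits at ``peak_delay``
    and the undershoot a gamma density with mode at ``undershoot_delay``,
    subtracted with weight ``undershoot_ratio``.  ``microtime_bins`` is the
    oversampling factor (bins per TR) used when convolving regressors.
    """

    kind: str = "double-gamma"
    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    undershoot_ratio: float = 1.0 / 6.0
    microtime_bins: int = 16

    def __post_init__(self) -> None:
        if self.kind != "double-gamma":
            raise ValueError(f"unsupported HRF kind {self.kind!r}")
        if self.peak_dispersion <= 0 or self.undershoot_dispersion <= 0:
            raise ValueError("HRF dispersions must be positive")
        if self.microtime_bins < 1:
            raise ValueError("microtime_bins must be >= 1")


def _hrf_raw(hrf: Hrf, t: np.ndarray) -> np.ndarray:
    # shape a = 1 + delay/dispersion places the gamma mode at `delay`
    a1 = 1.0 + hrf.peak_delay / hrf.peak_dispersion
    a2 = 1.0 + hrf.undershoot_delay / hrf.undershoot_dispersion
    pos = sps.gamma.pdf(t, a1, scale=hrf.peak_dispersion)
    neg = sps.gamma.pdf(t, a2, scale=hrf.undershoot_dispersion)
    return pos - hrf.undershoot_ratio * neg


def _hrf_peak_value(hrf: Hrf) -> float:
    grid = np.arange(0.0, 32.0, 0.01)
    return float(_hrf_raw(hrf, grid).max())


def hrf_evaluate(hrf: Hrf, t) -> np.ndarray | float:
    """Evaluate the response at time(s) ``t`` (seconds since event onset).

    Negative times are rejected; the response is exactly 0 at t = 0 and is
    scaled so its maximum over [0, 32] s equals 1.
    """
    arr = np.asarray(t, dtype=float)
    if np.any(arr < 0):
        raise ValueError("HRF is only defined for t >= 0")
    out = _hrf_raw(hrf, arr) / _hrf_peak_value(hrf)
    return float(out) if np.isscalar(t) else out


def hrf_kernel(hrf: Hrf, dt: float, duration_s: float = 32.0) -> np.ndarray:
    """Discrete kernel sampled every ``dt`` seconds, scaled to unit sum.

    Unit sum means a sustained unit boxcar convolved with the kernel
    plateaus at 1, so task amplitudes read directly as percent signal
    change against a baseline of 100.
    """
    t = np.arange(0.0, duration_s, dt)
    k = _hrf_raw(hrf, t)
    s = k.sum()
    if s <= 0:
        raise ValueError("degenerate HRF kernel (non-positive integral)")
    return k / s


def convolved_regressors(
    events,
    conditions,
    n_volumes: int,
    tr: float,
    hrf: Hrf | None = None,
) -> dict[str, np.ndarray]:
    """Boxcar ⊛ HRF regressor per condition, sampled at volume onsets.

    ``events`` is a DataFrame with columns onset, duration, trial_type.
    This is the single convolution path shared by simulation and analysis.
    """
    hrf = hrf or Hrf()
    dt = tr / hrf.microtime_bins
    n_fine = n_volumes * hrf.microtime_bins
    kernel = hrf_kernel(hrf, dt)
    out: dict[str, np.ndarray] = {}
    for cond in conditions:
        rows = events[events["trial_type"] == cond]
        u = np.zeros(n_fine)
        for onset, duration in zip(rows["onset"], rows["duration"]):
            i0 = int(round(onset / dt))
            i1 = int(round((onset + duration) / dt))
            u[i0:min(i1, n_fine)] = 1.0
        x = np.convolve(u, kernel)[:n_fine]
        out[cond] = x[:: hrf.microtime_bins].copy()
    return out


def n_dct_components(n_volumes: int, tr: float, cutoff_s: float) -> int:
    """Number of cosine components with frequency strictly below 1/cutoff."""
    total = n_volumes * tr
    k = int(np.floor(2.0 * total / cutoff_s))
    while k > 0 and k / (2.0 * total) >= 1.0 / cutoff_s:
        k -= 1
    return k


def dct_basis(n_volumes: int, tr: float, cutoff_s: float) -> np.ndarray:
    """Unit-norm DCT-II drift columns below the high-pass cutoff (no constant)."""
    k = n_dct_components(n_volumes, tr, cutoff_s)
    n = np.arange(n_volumes)
    cols = [
        np.sqrt(2.0 / n_volumes) * np.cos(np.pi * j * (2 * n + 1) / (2 * n_volumes))
        for j in range(1, k + 1)
    ]
    return np.column_stack(cols) if cols else np.empty((n_volumes, 0))


@dataclass
class DesignMatrix:
    """T×P design with named, partitioned columns (constant last)."""

    values: np.ndarray
    column_names: list[str]
    partition: dict[str, str]  # column -> {task, cue, drift, motion, constant}
    tr_seconds: float

    def __post_init__(self) -> None:
        if self.values.shape[1] != len(self.column_names):
            raise ValueError("column_names length must match design width")
        if sum(1 for v in self.partition.values() if v == "constant") != 1:
            raise ValueError("design must contain exactly one constant column")

    @property
    def n_volumes(self) -> int:
        return self.values.shape[0]

    def column_index(self, name: str) -> int:
        return self.column_names.index(name)

    def columns_of(self, kind: str) -> list[str]:
        return [c for c in self.column_names if self.partition[c] == kind]


def build_design_matrix(
    events,
    n_volumes: int,
    tr: float,
    hrf: Hrf | None = None,
    highpass_cutoff_s: float = 128.0,
    motion: np.ndarray | None = None,
    conditions: tuple[str, ...] = TASK_CONDITIONS,
    include_cue: bool = True,
) -> DesignMatrix:
    """Task + cue + drift + motion + constant design for one run.

    Rest is the implicit baseline.  A condition listed in ``conditions``
    but absent from the events is an error; pass a shorter tuple to model
    fewer task regressors.
    """
    hrf = hrf or Hrf()
    total = n_volumes * tr
    ends = np.asarray(events["onset"]) + np.asarray(events["duration"])
    if len(ends) and ends.max() > total + 1e-9:
        raise ValueError(
            f"events extend to {ends.max():g} s but the run holds only {total:g} s"
        )
    cols: list[np.ndarray] = []
    names: list[str] = []
    partition: dict[str, str] = {}

    for cond in conditions:
        if not (events["trial_type"] == cond).any():
            raise ValueError(f"condition {cond!r} has zero events")
    task = convolved_regressors(events, conditions, n_volumes, tr, hrf)
    for cond in conditions:
        cols.append(task[cond])
        names.append(cond)
        partition[cond] = "task"

    if include_cue and (events["trial_type"] == "cue").any():
        cue = convolved_regressors(events, ("cue",), n_volumes, tr, hrf)["cue"]
        cols.append(cue)
        names.append("cue")
        partition["cue"] = "cue"

    drift = dct_basis(n_volumes, tr, highpass_cutoff_s)
    for j in range(drift.shape[1]):
        cols.append(drift[:, j])
        name = f"drift_{j + 1}"
        names.append(name)
        partition[name] = "drift"

    if motion is not None:
        motion = np.asarray(motion, dtype=float)
        if motion.shape[0] != n_volumes:
            raise ValueError("motion regressors must have one row per volume")
        for j in range(motion.shape[1]):
            name = f"motion_{j + 1}"
            cols.append(motion[:, j])
            names.append(name)
            partition[name] = "motion"

    cols.append(np.ones(n_volumes))
    names.append("constant")
    partition["constant"] = "constant"

    return DesignMatrix(np.column_stack(cols), names, partition, tr)


def smooth_volume(data: np.ndarray, fwhm_mm, voxel_size_mm) -> np.ndarray:
    """Per-volume Gaussian smoothing with reflective boundaries.

    ``data`` is 3D or 4D (x, y, z[, t]); FWHM and voxel size are per-axis
    in mm.  Reflective boundaries conserve the per-volume mean.
    """
    fwhm = np.broadcast_to(np.asarray(fwhm_mm, dtype=float), (3,))
    vox = np.broadcast_to(np.asarray(voxel_size_mm, dtype=float), (3,))
    if np.any(fwhm < 0):
        raise ValueError("FWHM must be non-negative")
    sigma_vox = fwhm * FWHM_TO_SIGMA / vox
    if np.all(sigma_vox == 0):
        return data.astype(float, copy=True)
    out = np.asarray(data, dtype=float).copy()
    if out.ndim == 3:
        return ndimage.gaussian_filter(out, sigma=sigma_vox, mode="reflect")
    for t in range(out.shape[3]):
        out[..., t] = ndimage.gaussian_filter(out[..., t], sigma=sigma_vox, mode="reflect")
    return out


@dataclass
class GlmFit:
    """AR(1)-prewhitened least-squares fit over the in-mask voxels."""

    beta: np.ndarray  # P × V
    sigma2: np.ndarray  # V
    rho: float
    dof: int
    design: DesignMatrix
    mask: np.ndarray  # 3D bool
    xtx_inv: np.ndarray  # (Xw' Xw)^-1

    def beta_map(self, column: str) -> np.ndarray:
        """Scatter one coefficient back onto the 3D grid (NaN off-mask)."""
        out = np.full(self.mask.shape, np.nan)
        out[self.mask] = self.beta[self.design.column_index(column)]
        return out


def _whiten(rho: float, arr: np.ndarray) -> np.ndarray:
    """Exact AR(1) whitening along axis 0 (first row scaled, rest differenced)."""
    out = np.empty_like(arr, dtype=float)
    out[0] = np.sqrt(1.0 - rho * rho) * arr[0]
    out[1:] = arr[1:] - rho * arr[:-1]
    return out


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        _, r = np.linalg.qr(X)
        bad = [names[j] for j in range(X.shape[1]) if abs(r[j, j]) < 1e-8 * abs(r[0, 0])]
        raise ValueError(f"rank-deficient design; collinear columns: {bad or names}")


def fit_glm(data, X: DesignMatrix, mask: np.ndarray, rho: float | None = None) -> GlmFit:
    """Two-pass GLM: OLS, pooled residual lag-1 autocorrelation, prewhitened refit.

    ``data`` may be a 4D array or anything with a 4D ``.data`` attribute.
    A single rho is pooled over all in-mask voxels; pass ``rho`` explicitly
    to skip estimation (``rho=0`` reproduces plain OLS).
    """
    arr = np.asarray(getattr(data, "data", data), dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    if arr.shape[:3] != mask.shape or arr.shape[3] != X.n_volumes:
        raise ValueError("data, mask and design shapes are inconsistent")
    Y = arr[mask].T  # T × V
    Xv = X.values
    _check_rank(Xv, X.column_names)

    if rho is None:
        pinv = np.linalg.pinv(Xv)
        resid = Y - Xv @ (pinv @ Y)
        num = float(np.sum(resid[1:] * resid[:-1]))
        den = float(np.sum(resid * resid))
        rho = 0.0 if den == 0 else float(np.clip(num / den, -0.99, 0.99))
    elif not abs(rho) < 1:
        raise ValueError("|rho| must be < 1")

    Yw = _whiten(rho, Y)
    Xw = _whiten(rho, Xv)
    _check_rank(Xw, X.column_names)
    beta, _, _, _ = np.linalg.lstsq(Xw, Yw, rcond=None)
    rw = Yw - Xw @ beta
    dof = X.n_volumes - np.linalg.matrix_rank(Xw)
    sigma2 = np.sum(rw * rw, axis=0) / dof
    xtx_inv = np.linalg.inv(Xw.T @ Xw)
    return GlmFit(beta, sigma2, rho, dof, X, mask, xtx_inv)


@dataclass
class ContrastMap:
    """Effect (cβ̂) and t maps for one contrast of a subject-level fit."""

    contrast_vector: np.ndarray
    effect: np.ndarray  # 3D, NaN off-mask
    t: np.ndarray  # 3D, NaN off-mask
    dof: int
    name: str = ""


def compute_contrast(fit: GlmFit, weights: dict[str, float], name: str = "") -> ContrastMap:
    """Weighted coefficient combination with its t statistic.

    ``weights`` maps column names to contrast weights; unnamed columns get
    weight 0.  Voxels with zero standard error get t = 0.
    """
    c = np.zeros(len(fit.design.column_names))
    for col, w in weights.items():
        c[fit.design.column_index(col)] = w
    if not np.any(c):
        raise ValueError("contrast weights are all zero")
    effect = c @ fit.beta
    var = fit.sigma2 * float(c @ fit.xtx_inv @ c)
    se = np.sqrt(np.maximum(var, 0.0))
    t = np.where(se > 0, effect / np.where(se > 0, se, 1.0), 0.0)
    eff3 = np.full(fit.mask.shape, np.nan)
    t3 = np.full(fit.mask.shape, np.nan)
    eff3[fit.mask] = effect
    t3[fit.mask] = t
    return ContrastMap(c, eff3, t3, fit.dof, name or "+".join(
        f"{w:+g}*{k}" for k, w in weights.items()))
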