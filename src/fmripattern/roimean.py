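"""Mean-activation-level comparison within shared ROIs, paired t tests,
Bonferroni adjustment, and the post-scan recall comparison.

Mean levels are computed on contrast effect values (cβ̂), not t values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "PairedTResult",
    "MeanLevelResult",
    "RecallComparison",
    "roi_mean_contrast",
    "paired_t_test",
    "bonferroni",
    "mean_level_table",
    "compare_recall",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PairedTResult:
    t: float
    p: float
    dof: int
    alternative: str = "two-sided"


@dataclass
class MeanLevelResult:
    """Per-ROI paired comparison of two contrasts' mean effects."""

    roi_name: str
    per_subject_a: np.ndarray
    per_subject_b: np.ndarray
    t: float
    p_raw: float
    p_adjusted: float
    m_comparisons: int
    dof: int
    alternative: str = "two-sided"


@dataclass
class RecallComparison:
    """Per-task recall accuracy summary plus the paired test (None when
    the differences are degenerate with both columns constant)."""

    mean_per_task: dict[str, float]
    sd_per_task: dict[str, float]
    test: PairedTResult | None
    degenerate: bool = False


def roi_mean_contrast(contrast_map, roi) -> float:
    """Arithmetic mean of the contrast effect over the ROI voxels."""
    vox = roi.voxels
    if vox.size == 0:
        raise ValueError("empty ROI")
    effect = np.asarray(contrast_map.effect if hasattr(contrast_map, "effect") else contrast_map)
    if np.any(vox >= effect.shape) or np.any(vox < 0):
        raise ValueError("ROI voxels fall outside the map grid")
    vals = effect[tuple(vox.T)]
    if np.any(~np.isfinite(vals)):
        raise ValueError("ROI covers voxels with non-finite contrast values")
    return float(vals.mean())


def paired_t_test(a, b, alternative: str = "two-sided") -> PairedTResult:
    """Paired t on the elementwise differences a - b.

    Identically zero differences return t = 0 (p = 1 two-sided); non-zero
    constant differences are degenerate and rejected.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be 1-D and equal length")
    n = len(a)
    if n < 2:
        raise ValueError("paired t-test needs n >= 2")
    d = a - b
    dof = n - 1
    if d.std(ddof=1) == 0:
        if np.all(d == 0):
            p = 1.0 if alternative == "two-sided" else 0.5
            return PairedTResult(0.0, p, dof, alternative)
        raise ValueError("zero-variance non-zero differences: paired t undefined")
    res = sps.ttest_rel(a, b, alternative=alternative)
    return PairedTResult(float(res.statistic), float(res.pvalue), dof, alternative)


def bonferroni(p_values, m: int | None = None) -> list[float]:
    """Multiply each p by m (default: number of tests) and cap at 1."""
    p = [float(x) for x in p_values]
    if any(not 0.0 <= x <= 1.0 for x in p):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p) if m is None else int(m)
    if m < len(p):
        raise ValueError("m must be at least the number of p-values")
    return [min(1.0, m * x) for x in p]


def mean_level_table(
    per_roi_a: dict[str, np.ndarray],
    per_roi_b: dict[str, np.ndarray],
    alternative: str = "two-sided",
) -> list[MeanLevelResult]:
    """Paired comparison per ROI with Bonferroni over the ROIs tested."""
    names = list(per_roi_a)
    if set(names) != set(per_roi_b):
        raise ValueError("ROI sets differ between the two contrasts")
    m = len(names)
    results = []
    raws = []
    for name in names:
        res = paired_t_test(per_roi_a[name], per_roi_b[name], alternative)
        raws.append(res.p)
        results.append((name, res))
    adj = bonferroni(raws, m)
    return [
        MeanLevelResult(
            name,
            np.asarray(per_roi_a[name], dtype=float),
            np.asarray(per_roi_b[name], dtype=float),
            res.t, res.p, p_adj, m, res.dof, alternative,
        )
        for (name, res), p_adj in zip(results, adj)
    ]


def compare_recall(behavior: pd.DataFrame, tasks: tuple[str, str] = ("NA", "NV")) -> RecallComparison:
    """Per-task mean/sd of recall accuracy plus a paired comparison.

    ``behavior`` is long-format with columns subject, task, accuracy.
    Missing cells are rejected listing the offending subjects.
    """
    required = {"subject", "task", "accuracy"}
    if not required.issubset(behavior.columns):
        raise ValueError(f"behavior table needs columns {sorted(required)}")
    acc = behavior["accuracy"].to_numpy(dtype=float)
    if np.any((acc < 0) | (acc > 1)):
        raise ValueError("accuracies must lie in [0, 1]")
    wide = behavior.pivot_table(index="subject", columns="task", values="accuracy")
    missing = [str(s) for s in wide.index
               if any(t not in wide.columns or pd.isna(wide.loc[s, t]) for t in tasks)]
    if missing:
        raise ValueError(f"missing task cells for subjects: {missing}")
    a = wide[tasks[0]].to_numpy(dtype=float)
    b = wide[tasks[1]].to_numpy(dtype=float)
    means = {t: float(wide[t].mean()) for t in tasks}
    sds = {t: float(wide[t].std(ddof=1)) for t in tasks}
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        log.warning("compare_recall: degenerate (constant) accuracy columns; "
                    "paired test not performed")
        return RecallComparison(means, sds, None, degenerate=True)
    return RecallComparison(means, sds, paired_t_test(a, b))
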