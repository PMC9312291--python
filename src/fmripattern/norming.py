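"""Stimulus norming: action-consistency ratios and threshold/quota-based
stimulus selection from rater data."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

__all__ = [
    "UNANIMOUS",
    "action_consistency",
    "build_norming_table",
    "select_stimuli",
]

#: sentinel for unanimous response sets (second-most-common count is 0);
#: sorts above every finite consistency ratio
UNANIMOUS = math.inf


def action_consistency(counts: dict[str, int]) -> float:
    """Ratio of the most common to the second most common response count.

    Unanimous responses (no second action) return :data:`UNANIMOUS`.
    Invariant to action relabeling and to scaling all counts.
    """
    if not counts:
        raise ValueError("empty response counts")
    vals = sorted((int(v) for v in counts.values()), reverse=True)
    if any(v < 0 for v in vals):
        raise ValueError("response counts must be >= 0")
    n1 = vals[0]
    if n1 == 0:
        raise ValueError("all response counts are zero")
    n2 = vals[1] if len(vals) > 1 else 0
    return UNANIMOUS if n2 == 0 else n1 / n2


def build_norming_table(ratings: pd.DataFrame) -> pd.DataFrame:
    """Summarize per-rater rows into one row per noun.

    ``ratings`` has columns rater, noun, action_response, familiarity
    (0–7).  Returns a frame indexed by noun with columns top_action,
    consistency, familiarity_mean.
    """
    required = {"noun", "action_response", "familiarity"}
    if not required.issubset(ratings.columns):
        raise ValueError(f"ratings need columns {sorted(required)}")
    fam = ratings["familiarity"].to_numpy(dtype=float)
    if np.any((fam < 0) | (fam > 7)):
        raise ValueError("familiarity ratings must lie in [0, 7]")
    rows = []
    for noun, grp in ratings.groupby("noun", sort=True):
        counts = grp["action_response"].value_counts().to_dict()
        rows.append({
            "noun": noun,
            "top_action": grp["action_response"].value_counts().idxmax(),
            "consistency": action_consistency(counts),
            "familiarity_mean": float(grp["familiarity"].mean()),
        })
    return pd.DataFrame(rows).set_index("noun")


def select_stimuli(
    table: pd.DataFrame,
    min_consistency: float,
    min_familiarity: float,
    balance_groups: dict[str, int],
    n_select: int | None = None,
) -> list[str]:
    """Fill per-action quotas with qualifying nouns.

    Nouns passing both thresholds are ranked by (consistency,
    familiarity_mean) descending — deterministic, ties broken by noun name
    — and taken to fill each action's quota.  An unfillable quota is an
    error naming the deficient action group.
    """
    if n_select is not None and n_select != sum(balance_groups.values()):
        raise ValueError("n_select disagrees with the quota totals")
    ok = table[
        (table["consistency"] >= min_consistency)
        & (table["familiarity_mean"] >= min_familiarity)
    ]
    ranked = ok.loc[
        sorted(ok.index, key=lambda n: (-ok.loc[n, "consistency"],
                                        -ok.loc[n, "familiarity_mean"], n))
    ]
    selected: list[str] = []
    for action, quota in balance_groups.items():
        pool = [n for n in ranked.index if ranked.loc[n, "top_action"] == action]
        if len(pool) < quota:
            raise ValueError(
                f"cannot fill quota for action {action!r}: "
                f"{len(pool)} qualifying nouns, {quota} required")
        selected.extend(pool[:quota])
    return selected
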