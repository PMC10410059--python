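"""Per-subject annualized slopes and post-divergence group comparison.

Each subject's rate of change is the ordinary least-squares slope of the
outcome on years since their own first visit ("annualized"), so it is
invariant to adding a constant to all of a subject's observations. Groups are
compared with a two-sample t-test restricted to subjects whose *baseline* EYO
is at or past a supplied threshold (typically the cross-sectional divergence
point); Welch's unequal-variance test is the default, with the pooled-variance
Student test available by flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError

logger = logging.getLogger(__name__)

__all__ = ["subject_slopes", "SlopeComparison", "compare_slopes"]


def subject_slopes(table: pd.DataFrame, outcome: str) -> pd.DataFrame:
    """One row per subject: group, baseline EYO, OLS slope, visit bookkeeping.

    Subjects with fewer than two distinct visit times (or no non-missing
    outcome at >= 2 times) carry no slope and are excluded, logged.
    """
    need = ["subject_id", "group", "visit", "visit_age", "eyo", outcome]
    missing = [c for c in need if c not in table.columns]
    if missing:
        raise InputError(f"table lacks columns {missing}")
    rows, dropped = [], []
    for sid, sub in table.sort_values(["subject_id", "visit"]).groupby(
        "subject_id", sort=True, observed=True
    ):
        sub = sub.dropna(subset=[outcome, "visit_age"])
        if sub.empty:
            dropped.append(sid)
            continue
        t = sub["visit_age"].to_numpy(dtype=float)
        t = t - t[0]
        y = sub[outcome].to_numpy(dtype=float)
        base = sub.iloc[0]
        if len(np.unique(t)) < 2:
            dropped.append(sid)
            continue
        tbar, ybar = t.mean(), y.mean()
        slope = float(np.sum((t - tbar) * (y - ybar)) / np.sum((t - tbar) ** 2))
        rows.append({
            "subject_id": sid,
            "group": str(base["group"]),
            "baseline_eyo": float(base["eyo"]),
            "slope": slope,
            "n_visits": int(len(sub)),
            "followup_years": float(t[-1]),
        })
    if dropped:
        logger.info(
            "%d subject(s) without >= 2 usable visits excluded from slopes "
            "for %s: %s", len(dropped), outcome, ", ".join(map(str, dropped[:10])),
        )
    return pd.DataFrame(
        rows, columns=["subject_id", "group", "baseline_eyo", "slope",
                       "n_visits", "followup_years"],
    )


@dataclass(frozen=True)
class SlopeComparison:
    t: float
    df: float
    pvalue: float
    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    threshold_eyo: float
    groups: tuple[str, str]
    equal_var: bool


def compare_slopes(
    slopes: pd.DataFrame,
    threshold_eyo: float,
    groups: tuple[str, str] = ("TM", "CY"),
    equal_var: bool = False,
) -> SlopeComparison:
    """t-test of annualized slopes between groups, restricted to subjects with
    baseline EYO >= threshold. Welch by default (equal_var=True for pooled)."""
    sel = slopes[slopes["baseline_eyo"] >= threshold_eyo]
    a = sel.loc[sel["group"] == groups[0], "slope"].to_numpy(dtype=float)
    b = sel.loc[sel["group"] == groups[1], "slope"].to_numpy(dtype=float)
    for name, arr in zip(groups, (a, b)):
        if len(arr) < 2:
            raise InputError(
                f"group {name!r} has {len(arr)} subject(s) with baseline EYO >= "
                f"{threshold_eyo}; need >= 2"
            )
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return SlopeComparison(
        t=float(res.statistic), df=float(res.df), pvalue=float(res.pvalue),
        mean_a=float(a.mean()), sd_a=float(a.std(ddof=1)), n_a=len(a),
        mean_b=float(b.mean()), sd_b=float(b.std(ddof=1)), n_b=len(b),
        threshold_eyo=float(threshold_eyo), groups=groups, equal_var=equal_var,
    )
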