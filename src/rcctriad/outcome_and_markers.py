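"""Three-marker immunohistochemistry rule, clinical cross-tabulations and
survival analysis of the assigned groups.

The marker rule assigns tumors from microvessel density (CD34 count per
0.036 mm^2 spot) plus nuclear DEK and MSH6 positivity (> 1% stained tumor
cells): high MVD with DEK+ and MSH6+ -> group A; MSH6-negative (any MVD,
any DEK) -> group B; low MVD with DEK+ and MSH6+ -> group C; every other
profile is unassigned.  Microvessel counts between the low and high cutoffs
(neither > 100 nor < 50) are indeterminate and therefore unassignable.

Survival uses the Kaplan-Meier product-limit estimator and the k-group
log-rank test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

GROUP_LABELS = ("A", "B", "C")
UNASSIGNED = "unassigned"


@dataclass
class IhcThresholds:
    positivity_pct: float = 1.0  # % tumor cells with nuclear staining
    mvd_high_min: int = 100  # microvessels per spot: high iff count > this
    mvd_low_max: int = 50  # low iff count < this
    spot_area_mm2: float = 0.036

    def __post_init__(self) -> None:
        if not 0 <= self.positivity_pct <= 100:
            raise ValueError("positivity_pct must be in [0, 100]")
        if self.mvd_low_max >= self.mvd_high_min:
            raise ValueError("mvd_low_max must be < mvd_high_min")


def call_marker_status(
    mvd_count: float,
    dek_pct: float,
    msh6_pct: float,
    thresholds: IhcThresholds | None = None,
) -> tuple[str, str, str]:
    """(mvd, dek, msh6) status: mvd in {high, low, indeterminate}, stains in
    {pos, neg} with positivity strictly above the percentage cutoff."""
    t = thresholds or IhcThresholds()
    if mvd_count < 0:
        raise ValueError("mvd_count must be >= 0")
    for pct in (dek_pct, msh6_pct):
        if not 0 <= pct <= 100:
            raise ValueError("staining percentages must be in [0, 100]")
    if mvd_count > t.mvd_high_min:
        mvd = "high"
    elif mvd_count < t.mvd_low_max:
        mvd = "low"
    else:
        mvd = "indeterminate"
    dek = "pos" if dek_pct > t.positivity_pct else "neg"
    msh6 = "pos" if msh6_pct > t.positivity_pct else "neg"
    return mvd, dek, msh6


def assign_group_by_markers(status: tuple[str, str, str]) -> str:
    """Map a marker status triple to a group (total function)."""
    mvd, dek, msh6 = status
    if msh6 == "neg":
        return "B"
    if dek == "pos" and msh6 == "pos":
        if mvd == "high":
            return "A"
        if mvd == "low":
            return "C"
    return UNASSIGNED


def assign_cohort(
    clinical: pd.DataFrame, thresholds: IhcThresholds | None = None
) -> pd.Series:
    """Apply the marker rule to every row of a clinical/IHC table."""
    groups = [
        assign_group_by_markers(
            call_marker_status(
                row.mvd_count, row.dek_pct, row.msh6_pct, thresholds
            )
        )
        for row in clinical.itertuples()
    ]
    return pd.Series(groups, index=clinical.index, name="group")


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def classification_table(
    annotation: pd.DataFrame,
    groups: pd.Series,
    fields: tuple[str, ...] = ("subtype", "stage", "grade", "sarcomatoid"),
    decimals: int = 0,
) -> pd.DataFrame:
    """Cross-tabulate annotation levels against assigned groups.

    For each level of each annotation field: per-group counts, row
    percentages (half-away-from-zero rounding by default, one decimal with
    ``decimals=1``) and the row total.
    """
    ann = annotation.loc[groups.index]
    cols = sorted(groups.unique())
    rows = []
    for field_name in fields:
        if field_name not in ann.columns:
            continue
        for level, sub in ann.groupby(field_name, sort=False):
            idx = sub.index
            counts = groups.loc[idx].value_counts()
            total = int(counts.sum())
            row = {"field": field_name, "level": level, "total": total}
            for g in cols:
                c = int(counts.get(g, 0))
                pct = 100.0 * c / total if total else 0.0
                row[f"{g}_n"] = c
                row[f"{g}_pct"] = (
                    _round_half_away(pct) if decimals == 0 else round(pct, decimals)
                )
            rows.append(row)
    return pd.DataFrame(rows)


def kaplan_meier(records: pd.DataFrame) -> pd.DataFrame:
    """Product-limit survival estimate.

    ``records`` needs columns ``time`` (months, > 0) and ``event`` (1 =
    death).  Returns the step function as (time, survival) rows including
    the origin at t=0, S=1.
    """
    if len(records) < 1:
        raise ValueError("need at least one record")
    if (records["time"] <= 0).any():
        raise ValueError("survival times must be positive")
    km = KaplanMeierFitter()
    km.fit(records["time"], records["event"])
    sf = km.survival_function_
    out = sf.reset_index()
    out.columns = ["time", "survival"]
    return out


def logrank_test(records: pd.DataFrame, groups: pd.Series):
    """k-group log-rank test.

    Returns (chi-square statistic, degrees of freedom, p-value); every group
    must contribute at least one record and there must be at least one event
    overall.
    """
    groups = groups.loc[records.index]
    counts = groups.value_counts()
    if len(counts) < 2:
        raise ValueError("need >= 2 groups")
    if (counts < 1).any():
        raise ValueError("every group needs at least one record")
    if records["event"].sum() < 1:
        raise ValueError("need at least one event")
    res = multivariate_logrank_test(
        records["time"], groups.to_numpy(), records["event"]
    )
    df = len(counts) - 1
    return float(res.test_statistic), df, float(res.p_value)


def survival_by_group(
    records: pd.DataFrame, groups: pd.Series
) -> dict[str, pd.DataFrame]:
    """Kaplan-Meier step functions per assigned group (unassigned dropped)."""
    groups = groups.loc[records.index]
    out = {}
    for g in sorted(groups.unique()):
        if g == UNASSIGNED:
            continue
        out[g] = kaplan_meier(records[groups == g])
    return out
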