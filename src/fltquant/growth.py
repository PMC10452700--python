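"""Caliper growth curves, vehicle normalization, and cohort comparison statistics.

Tumor volume is estimated from two perpendicular external caliper lengths L1
and L2 (mm) with the ellipsoid-style formula

    V = (4*pi/3) * (L1/2) * (L2/2) * ((L1 + L2)/4)   [mm^3],

i.e. the third semi-axis is taken as the average of the two measured radii.
Growth is reported as percent change from each subject's own day-0 baseline;
treated arms can additionally be normalized to the vehicle-arm mean. Group
comparisons use the two-tailed Mann-Whitney U test, with optional one-pass
Grubbs (extreme studentized deviate) outlier screening per group-day.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .errors import DegenerateNormalizationError, ValidationError

__all__ = [
    "GrowthRecord",
    "CohortTable",
    "caliper_volume",
    "percent_change",
    "normalize_to_vehicle",
    "mann_whitney",
    "MannWhitneyResult",
    "grubbs_outlier",
    "GrubbsResult",
    "grubbs_critical_value",
    "percent_change_table",
    "growth_report",
    "GrowthReport",
]

logger = logging.getLogger(__name__)


def caliper_volume(L1: float, L2: float) -> float:
    """Ellipsoid-style tumor volume (mm^3) from two perpendicular lengths (mm)."""
    if L1 < 0 or L2 < 0:
        raise ValidationError(f"caliper lengths must be >= 0, got L1={L1}, L2={L2}")
    return (4.0 * math.pi / 3.0) * (L1 / 2.0) * (L2 / 2.0) * ((L1 + L2) / 4.0)


def percent_change(baseline: float, current: float) -> float:
    """100 x (current - baseline) / baseline; negative means regression."""
    if baseline <= 0:
        raise ValidationError(f"baseline must be > 0, got {baseline}")
    return 100.0 * (current - baseline) / baseline


@dataclass(frozen=True)
class GrowthRecord:
    """One caliper measurement: subject, arm, day, the two lengths, derived volume."""

    subject_id: str
    arm: str
    day: int
    L1: float
    L2: float
    weight: Optional[float] = None

    @property
    def volume(self) -> float:
        return caliper_volume(self.L1, self.L2)


@dataclass
class CohortTable:
    """Longitudinal caliper records for a multi-arm study.

    Wraps a DataFrame with columns ``subject_id, arm, day, L1, L2, volume``;
    each subject appears at most once per day and every arm label is declared.
    """

    records: pd.DataFrame
    arms: list[str] = field(default_factory=list)

    REQUIRED = ("subject_id", "arm", "day", "L1", "L2")

    def __post_init__(self) -> None:
        df = self.records
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValidationError(f"records missing columns: {missing}")
        if not self.arms:
            self.arms = list(pd.unique(df["arm"]))
        unknown = set(df["arm"]) - set(self.arms)
        if unknown:
            raise ValidationError(f"records reference undeclared arms: {sorted(unknown)}")
        dup = df.duplicated(subset=["subject_id", "day"])
        if dup.any():
            pair = df.loc[dup, ["subject_id", "day"]].iloc[0]
            raise ValidationError(
                f"subject {pair['subject_id']!r} has multiple records on day {pair['day']}"
            )
        if (df["L1"] < 0).any() or (df["L2"] < 0).any():
            raise ValidationError("caliper lengths must be >= 0")
        vol = np.array([caliper_volume(l1, l2) for l1, l2 in zip(df["L1"], df["L2"])])
        if "volume" in df.columns:
            if not np.allclose(df["volume"].to_numpy(), vol, rtol=1e-9, atol=1e-9):
                raise ValidationError("stored volumes disagree with the caliper formula")
        else:
            df = df.assign(volume=vol)
        self.records = df.reset_index(drop=True)

    @classmethod
    def from_growth_records(cls, records: Sequence[GrowthRecord], arms=None) -> "CohortTable":
        df = pd.DataFrame(
            {
                "subject_id": [r.subject_id for r in records],
                "arm": [r.arm for r in records],
                "day": [r.day for r in records],
                "L1": [r.L1 for r in records],
                "L2": [r.L2 for r in records],
                "volume": [r.volume for r in records],
            }
        )
        return cls(records=df, arms=list(arms) if arms else [])

    @property
    def days(self) -> list[int]:
        return sorted(self.records["day"].unique())


def percent_change_table(cohort: CohortTable, baseline_day: int = 0) -> pd.DataFrame:
    """Per-subject percent change from the subject's own baseline, per day.

    Subjects lacking a baseline measurement are excluded with a logged warning.
    """
    df = cohort.records
    base = df[df["day"] == baseline_day].set_index("subject_id")["volume"]
    missing = sorted(set(df["subject_id"]) - set(base.index))
    if missing:
        logger.warning("excluding subjects with no day-%d baseline: %s", baseline_day, missing)
    out = df[df["subject_id"].isin(base.index)].copy()
    out["pct_change"] = [
        percent_change(base[s], v) for s, v in zip(out["subject_id"], out["volume"])
    ]
    return out[["subject_id", "arm", "day", "volume", "pct_change"]]


def normalize_to_vehicle(
    cohort: CohortTable, vehicle_arm: str, day: int, baseline_day: int = 0
) -> pd.DataFrame:
    """Per-subject percent changes divided by the vehicle-arm mean at ``day``."""
    pct = percent_change_table(cohort, baseline_day=baseline_day)
    at_day = pct[pct["day"] == day]
    vehicle = at_day[at_day["arm"] == vehicle_arm]["pct_change"]
    if vehicle.empty:
        raise ValidationError(f"no {vehicle_arm!r} subjects measured on day {day}")
    vmean = float(vehicle.mean())
    if vmean == 0.0:
        raise DegenerateNormalizationError(
            f"vehicle-arm mean percent change on day {day} is exactly 0"
        )
    out = at_day.copy()
    out["normalized"] = out["pct_change"] / vmean
    return out[["subject_id", "arm", "day", "pct_change", "normalized"]]


class MannWhitneyResult(NamedTuple):
    u_statistic: float
    p_value: float
    method: str  # "exact" | "asymptotic"


def _has_ties(a: np.ndarray, b: np.ndarray) -> bool:
    pooled = np.concatenate([a, b])
    return np.unique(pooled).size < pooled.size


def mann_whitney(
    a: Sequence[float] | np.ndarray, b: Sequence[float] | np.ndarray
) -> MannWhitneyResult:
    """Two-tailed Mann-Whitney U test.

    The p-value is by exact enumeration when min(n1, n2) <= 8 and the pooled
    sample has no ties; otherwise the normal approximation with tie and
    continuity corrections is used. The method is recorded in the result.
    The U statistic reported is U for the first sample.
    """
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups must be non-empty")
    exact_ok = min(a.size, b.size) <= 8 and not _has_ties(a, b)
    method = "exact" if exact_ok else "asymptotic"
    res = scipy.stats.mannwhitneyu(
        a, b, alternative="two-sided", method="exact" if exact_ok else "asymptotic"
    )
    return MannWhitneyResult(
        u_statistic=float(res.statistic), p_value=float(res.pvalue), method=method
    )


def grubbs_critical_value(n: int, alpha: float = 0.05) -> float:
    """Two-sided Grubbs critical value from the Student-t quantile.

    G_crit = ((n-1)/sqrt(n)) * sqrt(t^2 / (n - 2 + t^2)) with t the upper
    alpha/(2n) quantile of Student-t on n-2 degrees of freedom.
    """
    if n < 3:
        raise ValidationError(f"Grubbs test requires n >= 3, got {n}")
    if not 0 < alpha < 1:
        raise ValidationError("alpha must lie in (0, 1)")
    t = scipy.stats.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return (n - 1) / math.sqrt(n) * math.sqrt(t * t / (n - 2 + t * t))


class GrubbsResult(NamedTuple):
    outlier_index: Optional[int]
    g_statistic: float
    critical_value: float


def grubbs_outlier(
    values: Sequence[float] | np.ndarray, alpha: float = 0.05
) -> GrubbsResult:
    """One-pass two-sided Grubbs (extreme studentized deviate) test.

    G = max|x - mean| / sd (sample SD). The single most extreme point is
    flagged iff G exceeds the critical value; the test is not re-applied
    after removal.
    """
    values = np.asarray(values, dtype=np.float64).ravel()
    n = values.size
    if n < 3:
        raise ValidationError(f"Grubbs test requires n >= 3, got {n}")
    sd = float(np.std(values, ddof=1))
    if sd == 0.0:
        raise ValidationError("Grubbs test undefined for zero sample SD")
    deviations = np.abs(values - values.mean())
    idx = int(np.argmax(deviations))
    g = float(deviations[idx] / sd)
    crit = grubbs_critical_value(n, alpha)
    return GrubbsResult(
        outlier_index=idx if g > crit else None, g_statistic=g, critical_value=crit
    )


class GrowthReport(NamedTuple):
    summary: pd.DataFrame      # per (day, arm): mean/sd/n of percent change
    comparisons: pd.DataFrame  # per (day, arm pair): U, p, method
    excluded: pd.DataFrame     # Grubbs-flagged records, if screening enabled


def growth_report(
    cohort: CohortTable,
    baseline_day: int = 0,
    alpha: float = 0.05,
    grubbs: bool = False,
) -> GrowthReport:
    """Per-day arm means +/- SD of percent change and pairwise Mann-Whitney p.

    With ``grubbs=True`` each group-day is screened once by the extreme
    studentized deviate test (two-sided, at ``alpha``) and flagged values are
    excluded from both summaries and comparisons.
    """
    pct = percent_change_table(cohort, baseline_day=baseline_day)
    excluded_rows = []
    if grubbs:
        kept = []
        for (day, arm), grp in pct.groupby(["day", "arm"], sort=True):
            vals = grp["pct_change"].to_numpy()
            if vals.size >= 3 and np.std(vals, ddof=1) > 0:
                res = grubbs_outlier(vals, alpha=alpha)
                if res.outlier_index is not None:
                    out_row = grp.iloc[res.outlier_index]
                    excluded_rows.append(out_row)
                    grp = grp.drop(index=grp.index[res.outlier_index])
                    logger.warning(
                        "Grubbs excluded subject %s (arm %s, day %s, %.1f%%)",
                        out_row["subject_id"], arm, day, out_row["pct_change"],
                    )
            kept.append(grp)
        pct = pd.concat(kept, ignore_index=True)
    summary = (
        pct.groupby(["day", "arm"], sort=True)["pct_change"]
        .agg(mean="mean", sd=lambda x: x.std(ddof=1) if len(x) > 1 else 0.0, n="count")
        .reset_index()
    )
    rows = []
    arms = cohort.arms
    if len(arms) >= 2:
        for day, day_grp in pct.groupby("day", sort=True):
            for i in range(len(arms)):
                for j in range(i + 1, len(arms)):
                    g1 = day_grp[day_grp["arm"] == arms[i]]["pct_change"].to_numpy()
                    g2 = day_grp[day_grp["arm"] == arms[j]]["pct_change"].to_numpy()
                    if g1.size == 0 or g2.size == 0:
                        continue
                    mw = mann_whitney(g1, g2)
                    rows.append(
                        {
                            "day": day,
                            "arm_a": arms[i],
                            "arm_b": arms[j],
                            "u_statistic": mw.u_statistic,
                            "p_value": mw.p_value,
                            "method": mw.method,
                            "significant": mw.p_value < alpha,
                        }
                    )
    comparisons = pd.DataFrame(
        rows, columns=["day", "arm_a", "arm_b", "u_statistic", "p_value", "method", "significant"]
    )
    excluded = (
        pd.DataFrame(excluded_rows).reset_index(drop=True)
        if excluded_rows
        else pd.DataFrame(columns=pct.columns)
    )
    return GrowthReport(summary=summary, comparisons=comparisons, excluded=excluded)
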