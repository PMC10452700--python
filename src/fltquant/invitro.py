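"""Dose-response survival, assay percent changes, and biomarker-viability regression.

Operates on per-well scalar signals (GFP fluorescence for viability,
2-deoxyglucose bioluminescence for glucose uptake, EdU fluorescence for
proliferation); image-to-signal extraction is upstream. Percent survival is
the treated-well mean as a percentage of the control-well mean; percent
change is signed the same way (negative = decrease), so
survival = 100 + change for identical inputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .errors import DegenerateNormalizationError, UnitError, ValidationError
from .growth import mann_whitney

__all__ = [
    "AssayPlate",
    "RegressionResult",
    "CHANNELS",
    "percent_survival",
    "dose_response_table",
    "normalize_to_baseline",
    "assay_percent_change",
    "biomarker_viability_regression",
]

CHANNELS = ("viability_gfp", "glucose_2dg", "proliferation_edu")
CONTROL_LABEL = "control"


@dataclass
class AssayPlate:
    """Per-well assay readouts with condition, dose, timepoint and channel labels.

    Wraps a DataFrame with columns ``condition, dose, dose_unit, timepoint_h,
    channel, signal``. Signals are arbitrary units >= 0. Every channel /
    timepoint combination must include a designated control condition
    (label ``"control"``, case-insensitive).
    """

    wells: pd.DataFrame

    REQUIRED = ("condition", "dose", "dose_unit", "timepoint_h", "channel", "signal")

    def __post_init__(self) -> None:
        df = self.wells
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValidationError(f"wells missing columns: {missing}")
        if (df["signal"] < 0).any():
            raise ValidationError("signals must be >= 0")
        bad = set(df["channel"]) - set(CHANNELS)
        if bad:
            raise ValidationError(f"unknown channels {sorted(bad)}; expected {CHANNELS}")
        for (channel, t), grp in df.groupby(["channel", "timepoint_h"]):
            if not (grp["condition"].str.lower() == CONTROL_LABEL).any():
                raise ValidationError(
                    f"no control condition for channel {channel!r} at {t} h"
                )
        self.wells = df.reset_index(drop=True)

    def signals(self, condition: str, channel: str, timepoint_h: float | None = None) -> np.ndarray:
        df = self.wells
        sel = (df["condition"].str.lower() == condition.lower()) & (df["channel"] == channel)
        if timepoint_h is not None:
            sel &= df["timepoint_h"] == timepoint_h
        return df.loc[sel, "signal"].to_numpy(dtype=np.float64)


class PercentWithSD(NamedTuple):
    percent: float
    sd: float


def _replicate_stats(treated: np.ndarray, control: np.ndarray, op: str) -> PercentWithSD:
    treated = np.asarray(treated, dtype=np.float64).ravel()
    control = np.asarray(control, dtype=np.float64).ravel()
    if treated.size == 0 or control.size == 0:
        raise ValidationError("treated and control signal lists must be non-empty")
    cmean = float(control.mean())
    if cmean <= 0:
        raise DegenerateNormalizationError("control mean signal must be > 0")
    sd = float(np.std(treated, ddof=1)) if treated.size > 1 else 0.0
    if op == "survival":
        value = 100.0 * (float(treated.mean()) / cmean)
    else:
        value = 100.0 * ((float(treated.mean()) - cmean) / cmean)
    return PercentWithSD(percent=value, sd=100.0 * sd / cmean)


def percent_survival(
    treated_signals: Sequence[float] | np.ndarray,
    control_signals: Sequence[float] | np.ndarray,
) -> PercentWithSD:
    """Treated-well mean as a percentage of the control-well mean, +/- SD.

    The SD is the treated-replicate sample SD scaled by the control mean
    (replicate spread expressed on the percent scale).
    """
    return _replicate_stats(np.asarray(treated_signals), np.asarray(control_signals), "survival")


def assay_percent_change(
    treated_signals: Sequence[float] | np.ndarray,
    control_signals: Sequence[float] | np.ndarray,
) -> PercentWithSD:
    """Signed percent change of the treated mean vs control mean (negative = decrease)."""
    return _replicate_stats(np.asarray(treated_signals), np.asarray(control_signals), "change")


def normalize_to_baseline(signal_t: float, signal_baseline: float) -> float:
    """Fold change of a well signal relative to its own baseline signal."""
    if signal_baseline <= 0:
        raise DegenerateNormalizationError(
            f"baseline signal must be > 0, got {signal_baseline}"
        )
    return signal_t / signal_baseline


def dose_response_table(
    plate: AssayPlate,
    agent: str,
    channel: str = "viability_gfp",
    timepoint_h: float | None = None,
) -> pd.DataFrame:
    """Dose-ordered percent-survival rows for one agent, with Mann-Whitney vs control.

    Conditions whose label starts with ``agent`` (case-insensitive) form the
    dose series; all their doses must share one unit. Requires at least two
    dose levels plus the control.
    """
    df = plate.wells
    sel = (df["channel"] == channel)
    if timepoint_h is not None:
        sel &= df["timepoint_h"] == timepoint_h
    sub = df[sel]
    is_control = sub["condition"].str.lower() == CONTROL_LABEL
    control = sub.loc[is_control, "signal"].to_numpy(dtype=np.float64)
    if control.size == 0:
        raise ValidationError(f"missing control wells for channel {channel!r}")
    agent_rows = sub[sub["condition"].str.lower().str.startswith(agent.lower()) & ~is_control]
    if agent_rows.empty:
        raise ValidationError(f"no wells found for agent {agent!r}")
    units = sorted(set(agent_rows["dose_unit"]))
    if len(units) > 1:
        raise UnitError(f"agent {agent!r} mixes dose units {units}")
    doses = sorted(agent_rows["dose"].unique())
    if len(doses) < 2:
        raise ValidationError(f"agent {agent!r} needs >= 2 dose levels, got {len(doses)}")
    rows = []
    for dose in doses:
        treated = agent_rows.loc[agent_rows["dose"] == dose, "signal"].to_numpy(dtype=np.float64)
        surv = percent_survival(treated, control)
        mw = mann_whitney(treated, control)
        rows.append(
            {
                "agent": agent,
                "dose": dose,
                "dose_unit": units[0],
                "percent_survival": surv.percent,
                "sd": surv.sd,
                "n_wells": treated.size,
                "u_statistic": mw.u_statistic,
                "p_value": mw.p_value,
                "method": mw.method,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class RegressionResult:
    """Ordinary least squares fit of endpoint viability on an early biomarker."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValidationError(f"R^2 must lie in [0, 1], got {self.r_squared}")
        if self.n < 3:
            raise ValidationError("regression requires n >= 3")


def biomarker_viability_regression(
    biomarker: Sequence[float] | np.ndarray,
    endpoint_viability: Sequence[float] | np.ndarray,
) -> RegressionResult:
    """OLS of matched per-well endpoint viability on a 48-h biomarker signal.

    R^2 = 1 - SS_res/SS_tot; the two-tailed p-value for the slope comes from
    the t distribution with n-2 degrees of freedom. A constant response
    (zero SS_tot) yields R^2 = 0 with a warning rather than NaN; constant x
    is an error.
    """
    x = np.asarray(biomarker, dtype=np.float64).ravel()
    y = np.asarray(endpoint_viability, dtype=np.float64).ravel()
    if x.size != y.size:
        raise ValidationError(f"unmatched pair counts: {x.size} vs {y.size}")
    n = x.size
    if n < 3:
        raise ValidationError(f"regression requires >= 3 matched pairs, got {n}")
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0.0:
        raise ValidationError("zero variance in the biomarker values")
    sxy = float(np.sum((x - x.mean()) * (y - y.mean())))
    sst = float(np.sum((y - y.mean()) ** 2))
    slope = sxy / sxx
    intercept = float(y.mean()) - slope * float(x.mean())
    if sst == 0.0:
        warnings.warn("constant endpoint values: R^2 reported as 0", stacklevel=2)
        return RegressionResult(slope=slope, intercept=intercept, r_squared=0.0, p_value=1.0, n=n)
    ssr = float(np.sum((y - (intercept + slope * x)) ** 2))
    r2 = max(0.0, min(1.0, 1.0 - ssr / sst))
    if ssr <= 0.0:
        p = 0.0
    else:
        se = np.sqrt(ssr / (n - 2) / sxx)
        t = slope / se
        p = float(2.0 * scipy.stats.t.sf(abs(t), n - 2))
    return RegressionResult(slope=slope, intercept=intercept, r_squared=r2, p_value=p, n=n)
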