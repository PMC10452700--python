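"""Seeded synthetic phantoms and tabular datasets for the full analysis pipeline.

The phantom emulates the salient statistical structure of a heterogeneous
(PDX-like) tumor on FLT-PET: an ellipsoidal tumor whose contiguous central
necrotic core (default 45% of tumor voxels, within the 30-60% range typical
of such models) sits near SUV 0.4, a viable high-uptake rim, and a separate
reference muscle region. Treatment effect is modeled as a multiplicative
suppression of the viable-rim mean only; necrotic tissue is
treatment-invariant. Voxels are independent Gaussian draws per region,
clipped at zero — no spatial autocorrelation or scanner noise texture is
modeled.

Tabular generators produce four-arm caliper growth cohorts (enrollment
volumes in the 125-300 mm^3 window) and 96-well-style assay plates with at
least five replicates per condition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import scipy.stats
from pydantic import BaseModel, Field, model_validator

from .errors import SizingError, ValidationError
from .growth import CohortTable, caliper_volume
from .invitro import AssayPlate
from .quant import PETStudy

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "generate_phantom",
    "generate_longitudinal_study",
    "generate_growth_cohort",
    "generate_plate",
    "analytic_proliferative_fraction",
    "DEFAULT_GROWTH_ARMS",
    "DEFAULT_VIABILITY_CONDITIONS",
    "DEFAULT_EDU_CONDITIONS",
]


class PhantomSpec(BaseModel):
    """Parameters of one synthetic PET study.

    SUV means/SDs are region-level Gaussians. ``suppression`` scales the
    viable-rim mean multiplicatively, modeling treatment-induced loss of
    proliferative uptake. The viable-rim default (SUV 1.2 +/- 0.2) is an
    assumption of this generator, chosen to sit well above a typical muscle
    reference (0.5 +/- 0.05) so the proliferative threshold separates the
    regions; it is not a measured value.
    """

    seed: int = Field(ge=0, lt=2**31)
    grid_shape: Tuple[int, int, int] = (64, 64, 64)
    voxel_size: Tuple[float, float, float] = (0.5, 0.5, 0.5)  # mm
    necrotic_fraction: float = Field(default=0.45, ge=0.0, le=1.0)
    necrotic_suv_mean: float = Field(default=0.4, gt=0.0)
    necrotic_suv_sd: float = Field(default=0.05, ge=0.0)
    viable_suv_mean: float = Field(default=1.2, gt=0.0)
    viable_suv_sd: float = Field(default=0.2, ge=0.0)
    muscle_suv_mean: float = Field(default=0.5, gt=0.0)
    muscle_suv_sd: float = Field(default=0.05, ge=0.0)
    suppression: float = Field(default=1.0, gt=0.0, le=1.0)
    tumor_radii: Optional[Tuple[float, float, float]] = None  # voxels; default 0.22*grid
    muscle_size: int = Field(default=8, ge=2)  # cuboid edge, voxels

    @model_validator(mode="after")
    def _check(self) -> "PhantomSpec":
        if any(n < 8 for n in self.grid_shape):
            raise ValueError("grid_shape axes must each be >= 8 voxels")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size entries must be > 0")
        if self.tumor_radii is not None and any(r <= 0 for r in self.tumor_radii):
            raise ValueError("tumor_radii must be > 0")
        return self

    def resolved_radii(self) -> Tuple[float, float, float]:
        if self.tumor_radii is not None:
            return self.tumor_radii
        return tuple(0.22 * n for n in self.grid_shape)  # type: ignore[return-value]


@dataclass
class GroundTruth:
    """Generator-side truth for one phantom.

    ``true_proliferative_fraction`` is the closed-form expected fraction of
    tumor voxels at/above the nominal threshold (muscle mean + 2 SD), from
    the normal tail probabilities of the two regions.
    """

    necrotic_mask: np.ndarray
    viable_mask: np.ndarray
    true_proliferative_fraction: float


def _normal_tail(threshold: float, mean: float, sd: float) -> float:
    """P(X >= threshold) for X ~ Normal(mean, sd); degenerate sd=0 is a step."""
    if sd == 0.0:
        return 1.0 if mean >= threshold else 0.0
    return float(scipy.stats.norm.sf(threshold, loc=mean, scale=sd))


def analytic_proliferative_fraction(spec: PhantomSpec, sd_multiplier: float = 2.0) -> float:
    """Expected proliferative fraction under the spec's region Gaussians."""
    thr = spec.muscle_suv_mean + sd_multiplier * spec.muscle_suv_sd
    viable_tail = _normal_tail(thr, spec.suppression * spec.viable_suv_mean, spec.viable_suv_sd)
    necrotic_tail = _normal_tail(thr, spec.necrotic_suv_mean, spec.necrotic_suv_sd)
    f = spec.necrotic_fraction
    return (1.0 - f) * viable_tail + f * necrotic_tail


def _phantom_geometry(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Tumor mask, normalized ellipsoidal radius per voxel, and muscle mask."""
    shape = spec.grid_shape
    radii = spec.resolved_radii()
    margin = 1
    # tumor sits toward the high corner, muscle cuboid at the low corner,
    # maximizing their separation on small grids
    center = tuple(n - 1 - margin - r for n, r in zip(shape, radii))
    for n, r, c in zip(shape, radii, center):
        if c - r < margin or c + r > n - 1 - margin:
            raise SizingError(
                f"tumor radii {radii} do not fit grid {shape} with margin {margin}"
            )
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    r2 = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    tumor = r2 <= 1.0
    ms = spec.muscle_size
    lo = 2
    if lo + ms >= min(shape):
        raise SizingError(f"muscle cuboid of edge {ms} does not fit grid {shape}")
    muscle = np.zeros(shape, dtype=bool)
    muscle[lo : lo + ms, lo : lo + ms, lo : lo + ms] = True
    if (tumor & muscle).any():
        raise SizingError(
            f"tumor (radii {radii}) and muscle cuboid overlap on grid {shape}; "
            "enlarge the grid or shrink the tumor"
        )
    return tumor, np.sqrt(r2), muscle


def generate_phantom(spec: PhantomSpec) -> tuple[PETStudy, GroundTruth]:
    """Generate one seeded SUV phantom and its ground truth.

    The necrotic core is the innermost ``necrotic_fraction`` of tumor voxels
    by normalized ellipsoidal radius (a concentric core), so the realized
    core fraction matches the spec up to voxel quantization. Identical seeds
    give bit-identical output.
    """
    tumor, radius, muscle = _phantom_geometry(spec)
    tumor_radius = radius[tumor]
    n_tumor = int(tumor.sum())
    # innermost k voxels by radius; stable argsort keeps the count exact even
    # when the symmetric ellipsoid produces many tied radii
    k = int(round(spec.necrotic_fraction * n_tumor))
    order = np.argsort(tumor_radius, kind="stable")
    tumor_flat = np.flatnonzero(tumor.ravel())
    necrotic = np.zeros(tumor.size, dtype=bool)
    necrotic[tumor_flat[order[:k]]] = True
    necrotic = necrotic.reshape(tumor.shape)
    viable = tumor & ~necrotic

    rng = np.random.default_rng(spec.seed)
    volume = np.zeros(spec.grid_shape, dtype=np.float64)
    volume[viable] = rng.normal(
        spec.suppression * spec.viable_suv_mean, spec.viable_suv_sd, int(viable.sum())
    )
    volume[necrotic] = rng.normal(
        spec.necrotic_suv_mean, spec.necrotic_suv_sd, int(necrotic.sum())
    )
    volume[muscle] = rng.normal(spec.muscle_suv_mean, spec.muscle_suv_sd, int(muscle.sum()))
    np.clip(volume, 0.0, None, out=volume)

    affine = np.diag([*spec.voxel_size, 1.0])
    study = PETStudy(
        suv_volume=volume,
        tumor_mask=tumor,
        muscle_mask=muscle,
        subject_id=f"phantom-{spec.seed}",
        day=0,
        affine=affine,
    )
    truth = GroundTruth(
        necrotic_mask=necrotic,
        viable_mask=viable,
        true_proliferative_fraction=analytic_proliferative_fraction(spec),
    )
    assert not (necrotic & viable).any()
    assert ((necrotic | viable) == tumor).all()
    assert n_tumor == int(necrotic.sum() + viable.sum())
    return study, truth


def _subseed(seed: int, index: int) -> int:
    """Deterministic per-timepoint sub-seed below 2^31."""
    return int(np.random.SeedSequence((seed, index)).generate_state(1)[0] % 2**31)


def generate_longitudinal_study(
    spec: PhantomSpec, timepoints: Sequence[Tuple[int, float]]
) -> list[PETStudy]:
    """One phantom per (day, suppression) timepoint, sharing geometry and seed lineage.

    Geometry (tumor, core, muscle placement) is identical across timepoints;
    voxel noise is redrawn per timepoint from a deterministic sub-seed, and
    the viable mean is scaled by each timepoint's suppression factor.
    """
    if len(timepoints) == 0:
        raise ValidationError("timepoints must be non-empty")
    days = [d for d, _ in timepoints]
    if any(b <= a for a, b in zip(days, days[1:])):
        raise ValidationError(f"days must be strictly increasing, got {days}")
    for _, s in timepoints:
        if not 0.0 < s <= 1.0:
            raise ValidationError(f"suppression must lie in (0, 1], got {s}")
    studies = []
    for i, (day, suppression) in enumerate(timepoints):
        spec_t = spec.model_copy(
            update={"seed": _subseed(spec.seed, i), "suppression": suppression}
        )
        study, _ = generate_phantom(spec_t)
        study.subject_id = f"phantom-{spec.seed}"
        study.day = day
        studies.append(study)
    return studies


#: four-arm defaults: (name, mean % volume change per assessment, SD of that change).
#: Rates are calibrated so six 3-day assessments compound to endpoint percent
#: changes of roughly +117 / +43 / +22 / -32 for vehicle, trastuzumab,
#: niraparib and combination respectively.
DEFAULT_GROWTH_ARMS: list[Tuple[str, float, float]] = [
    ("vehicle", 13.8, 8.0),
    ("trastuzumab", 6.1, 8.0),
    ("niraparib", 3.3, 10.0),
    ("combination", -6.3, 10.0),
]


def generate_growth_cohort(
    seed: int,
    arms: Optional[Sequence[Tuple[str, float, float]]] = None,
    n_per_arm: int = 5,
    n_assessments: int = 6,
    assessment_interval_days: int = 3,
    baseline_range: Tuple[float, float] = (125.0, 300.0),
) -> CohortTable:
    """Seeded four-arm caliper growth cohort with noisy multiplicative trajectories.

    Baseline volumes are uniform over the 125-300 mm^3 enrollment window.
    Each assessment multiplies the previous volume by
    ``1 + Normal(mean_pct, sd)/100`` (floored at 0). Tumors are recorded as
    equal perpendicular lengths, so the stored volume satisfies the caliper
    formula exactly.
    """
    if arms is None:
        arms = DEFAULT_GROWTH_ARMS
    if n_per_arm < 1:
        raise ValidationError("n_per_arm must be >= 1")
    if n_assessments < 1:
        raise ValidationError("n_assessments must be >= 1")
    for name, _, sd in arms:
        if sd < 0:
            raise ValidationError(f"arm {name!r} has negative sd")
    lo, hi = baseline_range
    if not 0 < lo <= hi:
        raise ValidationError(f"invalid baseline range {baseline_range}")
    rng = np.random.default_rng(seed)
    rows = []
    for name, mean_pct, sd in arms:
        for k in range(n_per_arm):
            subject = f"{name}-{k + 1:02d}"
            volume = float(rng.uniform(lo, hi))
            for a in range(n_assessments + 1):
                day = a * assessment_interval_days
                # equal perpendicular lengths: V = (pi/6) L^3
                length = (6.0 * volume / np.pi) ** (1.0 / 3.0)
                rows.append(
                    {
                        "subject_id": subject,
                        "arm": name,
                        "day": day,
                        "L1": length,
                        "L2": length,
                        "volume": caliper_volume(length, length),
                    }
                )
                if a < n_assessments:
                    factor = 1.0 + (mean_pct + sd * float(rng.standard_normal())) / 100.0
                    volume = volume * max(factor, 0.0)
    import pandas as pd

    return CohortTable(records=pd.DataFrame(rows), arms=[name for name, _, _ in arms])


#: plate conditions: (label, dose, dose_unit, mean signal fraction of control, SD fraction).
#: Viability fractions emulate observed survival under 1 ug/mL trastuzumab
#: (60 +/- 4%), 1 uM niraparib, and their combination (42 +/- 10%), with
#: dose-dependent monotone decline for the two monotherapy series.
DEFAULT_VIABILITY_CONDITIONS: list[Tuple[str, float, str, float, float]] = [
    ("control", 0.0, "none", 1.00, 0.05),
    ("trastuzumab", 0.1, "ug/mL", 0.95, 0.05),
    ("trastuzumab", 1.0, "ug/mL", 0.60, 0.0425),
    ("trastuzumab", 10.0, "ug/mL", 0.55, 0.05),
    ("trastuzumab", 100.0, "ug/mL", 0.50, 0.05),
    ("niraparib", 0.1, "uM", 0.98, 0.05),
    ("niraparib", 1.0, "uM", 0.80, 0.05),
    ("niraparib", 10.0, "uM", 0.30, 0.05),
    ("niraparib", 100.0, "uM", 0.20, 0.05),
    ("combination", 1.0, "combo", 0.42, 0.1041),
]

#: EdU (proliferation) fractions at 48 h: decreases of ~67.5% / 22.9% / 79.7%
#: for trastuzumab, niraparib and combination against control.
DEFAULT_EDU_CONDITIONS: list[Tuple[str, float, str, float, float]] = [
    ("control", 0.0, "none", 1.000, 0.05),
    ("trastuzumab", 1.0, "ug/mL", 0.325, 0.0327),
    ("niraparib", 1.0, "uM", 0.771, 0.0489),
    ("combination", 1.0, "combo", 0.203, 0.0148),
]


def generate_plate(
    seed: int,
    conditions: Optional[Sequence[Tuple[str, float, str, float, float]]] = None,
    n_replicates: int = 5,
    channel: str = "viability_gfp",
    timepoint_h: float = 96.0,
    control_signal: float = 1000.0,
) -> AssayPlate:
    """Seeded assay plate: per-well Normal draws around fraction x control signal.

    Each condition is ``(label, dose, dose_unit, mean_signal_fraction,
    sd_fraction)``; signals are clipped at 0. A condition labeled
    ``"control"`` must be present.
    """
    if conditions is None:
        conditions = DEFAULT_VIABILITY_CONDITIONS
    if n_replicates < 1:
        raise ValidationError("n_replicates must be >= 1")
    if not any(label.lower() == "control" for label, *_ in conditions):
        raise ValidationError("conditions must include a 'control' condition")
    for label, _, _, frac, sd in conditions:
        if frac < 0 or sd < 0:
            raise ValidationError(f"condition {label!r} has negative mean fraction or sd")
    rng = np.random.default_rng(seed)
    rows = []
    for label, dose, unit, frac, sd in conditions:
        signals = frac * control_signal + sd * control_signal * rng.standard_normal(n_replicates)
        np.clip(signals, 0.0, None, out=signals)
        for s in signals:
            rows.append(
                {
                    "condition": label,
                    "dose": dose,
                    "dose_unit": unit,
                    "timepoint_h": timepoint_h,
                    "channel": channel,
                    "signal": float(s),
                }
            )
    import pandas as pd

    return AssayPlate(wells=pd.DataFrame(rows))
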