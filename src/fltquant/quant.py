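"""SUV computation, ROI statistics, and muscle-referenced proliferative voxel classification.

The central operation is the proliferative threshold: tumor voxels whose
standardized uptake value (SUV) is at or above the reference-muscle mean plus
two standard deviations are classified proliferative; voxels below it are
treated as necrotic / non-proliferative. The threshold is recomputed per scan
from that scan's own muscle region.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Optional

import numpy as np

from .errors import EmptyROIError, ShapeMismatchError, ValidationError

__all__ = [
    "PETStudy",
    "SUVSummary",
    "ProliferativeClassification",
    "QuantifiedStudy",
    "compute_suv",
    "roi_summary",
    "proliferative_threshold",
    "classify_voxels",
    "quantify_study",
]


def _as_bool_mask(mask: np.ndarray) -> np.ndarray:
    """Coerce any nonzero value to membership; masks are strictly binary."""
    return np.asarray(mask) != 0


@dataclass
class PETStudy:
    """One animal/timepoint: an SUV volume with co-registered tumor and muscle masks.

    ``suv_volume`` is dimensionless (body-weight SUV under the 1 g/mL density
    convention). Masks must share the volume's shape; any nonzero mask value
    counts as membership. ``injected_activity`` (Bq) and ``body_weight`` (g)
    are optional when the volume is already in SUV units.
    """

    suv_volume: np.ndarray
    tumor_mask: np.ndarray
    muscle_mask: np.ndarray
    subject_id: str = ""
    day: int = 0
    injected_activity: Optional[float] = None
    body_weight: Optional[float] = None
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.suv_volume = np.asarray(self.suv_volume, dtype=np.float64)
        self.tumor_mask = _as_bool_mask(self.tumor_mask)
        self.muscle_mask = _as_bool_mask(self.muscle_mask)
        if self.tumor_mask.shape != self.suv_volume.shape:
            raise ShapeMismatchError(
                f"tumor mask shape {self.tumor_mask.shape} != volume shape "
                f"{self.suv_volume.shape}"
            )
        if self.muscle_mask.shape != self.suv_volume.shape:
            raise ShapeMismatchError(
                f"muscle mask shape {self.muscle_mask.shape} != volume shape "
                f"{self.suv_volume.shape}"
            )
        if not self.tumor_mask.any():
            raise EmptyROIError("tumor mask is empty")
        if not self.muscle_mask.any():
            raise EmptyROIError("muscle mask is empty")
        if (self.tumor_mask & self.muscle_mask).any():
            raise ValidationError("tumor and muscle masks overlap")
        if np.any(self.suv_volume < 0):
            raise ValidationError("SUV volume contains negative values")

    def tumor_values(self) -> np.ndarray:
        """SUVs of all tumor voxels, flattened in array order."""
        return self.suv_volume[self.tumor_mask]

    def muscle_values(self) -> np.ndarray:
        return self.suv_volume[self.muscle_mask]


@dataclass(frozen=True)
class SUVSummary:
    """First-order statistics over one ROI (mean, sample SD, max, voxel count)."""

    mean: float
    sd: float
    max: float
    n_voxels: int

    def __post_init__(self) -> None:
        if self.n_voxels < 1:
            raise ValidationError("SUVSummary requires at least one voxel")
        if self.sd < 0:
            raise ValidationError("sd must be non-negative")


@dataclass
class ProliferativeClassification:
    """Per-voxel proliferative/necrotic labels with threshold provenance.

    ``proliferative_mask`` and ``necrotic_mask`` partition the tumor mask;
    ties at the threshold are proliferative (inclusive boundary). When no
    tumor voxel reaches the threshold, ``proliferative_summary`` is ``None``
    and ``is_empty`` is set rather than fabricating statistics.
    """

    threshold: float
    proliferative_mask: np.ndarray
    necrotic_mask: np.ndarray
    proliferative_summary: Optional[SUVSummary]
    proliferative_fraction: float

    @property
    def is_empty(self) -> bool:
        return self.proliferative_summary is None


class QuantifiedStudy(NamedTuple):
    tumor: SUVSummary
    muscle: SUVSummary
    classification: ProliferativeClassification


def compute_suv(
    activity_volume: np.ndarray, injected_activity: float, body_weight: float
) -> np.ndarray:
    """Convert an activity-concentration volume (Bq/mL) to body-weight SUV.

    SUV = concentration x body_weight / injected_activity, assuming tissue
    density of 1 g/mL, so the result is dimensionless. Decay correction is
    assumed to have been applied upstream by the scanner.

    Parameters
    ----------
    activity_volume : array of Bq/mL, all values >= 0
    injected_activity : injected dose in Bq, > 0
    body_weight : animal body weight in g, > 0
    """
    if injected_activity <= 0:
        raise ValidationError(f"injected_activity must be > 0, got {injected_activity}")
    if body_weight <= 0:
        raise ValidationError(f"body_weight must be > 0, got {body_weight}")
    activity_volume = np.asarray(activity_volume, dtype=np.float64)
    if np.any(activity_volume < 0):
        raise ValidationError("activity volume contains negative values")
    return activity_volume * (body_weight / injected_activity)


def roi_summary(study: PETStudy, which: str) -> SUVSummary:
    """Mean / sample SD (n-1) / max / count of SUV over one ROI.

    ``which`` selects ``"tumor"`` or ``"muscle"``. A single-voxel ROI reports
    sd = 0 with a degenerate-ROI warning.
    """
    if which == "tumor":
        values = study.tumor_values()
    elif which == "muscle":
        values = study.muscle_values()
    else:
        raise ValidationError(f"which must be 'tumor' or 'muscle', got {which!r}")
    return summarize_values(values, label=which)


def summarize_values(values: np.ndarray, label: str = "ROI") -> SUVSummary:
    values = np.asarray(values, dtype=np.float64).ravel()
    if values.size == 0:
        raise EmptyROIError(f"{label} mask selects no voxels")
    if values.size == 1:
        warnings.warn(
            f"degenerate {label} ROI with a single voxel: sd reported as 0",
            stacklevel=2,
        )
        sd = 0.0
    else:
        sd = float(np.std(values, ddof=1))
    return SUVSummary(
        mean=float(np.mean(values)),
        sd=sd,
        max=float(np.max(values)),
        n_voxels=int(values.size),
    )


def proliferative_threshold(muscle: SUVSummary, sd_multiplier: float = 2.0) -> float:
    """Muscle-referenced proliferative cutoff: muscle mean + ``sd_multiplier`` x SD.

    Requires at least two muscle voxels — a spread estimated from one voxel is
    meaningless, so the threshold refuses degenerate reference ROIs.
    """
    if muscle.n_voxels < 2:
        raise ValidationError(
            "proliferative threshold requires >= 2 muscle voxels "
            f"(got {muscle.n_voxels}); sd is undefined"
        )
    if sd_multiplier < 0:
        raise ValidationError("sd_multiplier must be >= 0")
    return muscle.mean + sd_multiplier * muscle.sd


def classify_voxels(study: PETStudy, threshold: float) -> ProliferativeClassification:
    """Label each tumor voxel proliferative iff SUV >= threshold (inclusive).

    Voxels below the threshold are labeled necrotic / non-proliferative. The
    two masks partition the tumor mask. The proliferative summary is computed
    over proliferative voxels only.
    """
    if threshold < 0:
        raise ValidationError(f"threshold must be >= 0, got {threshold}")
    proliferative = study.tumor_mask & (study.suv_volume >= threshold)
    necrotic = study.tumor_mask & ~proliferative
    n_tumor = int(study.tumor_mask.sum())
    n_prolif = int(proliferative.sum())
    if n_prolif > 0:
        summary = summarize_values(study.suv_volume[proliferative], label="proliferative")
    else:
        summary = None
    return ProliferativeClassification(
        threshold=float(threshold),
        proliferative_mask=proliferative,
        necrotic_mask=necrotic,
        proliferative_summary=summary,
        proliferative_fraction=n_prolif / n_tumor,
    )


def quantify_study(study: PETStudy, sd_multiplier: float = 2.0) -> QuantifiedStudy:
    """Full per-scan quantification: tumor + muscle statistics and classification.

    Muscle statistics are recomputed per scan (per animal, per timepoint), so
    each scan's threshold reflects its own physiology.
    """
    tumor = roi_summary(study, "tumor")
    muscle = roi_summary(study, "muscle")
    threshold = proliferative_threshold(muscle, sd_multiplier=sd_multiplier)
    classification = classify_voxels(study, threshold)
    return QuantifiedStudy(tumor=tumor, muscle=muscle, classification=classification)
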