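"""Fractional-frequency histograms and Kolmogorov-Smirnov distribution comparison.

A fractional-frequency histogram is the voxel-SUV histogram divided by the
total number of tumor voxels, which normalizes distributions for tumor volume
so that tumors of different sizes are directly comparable. Distribution shifts
between timepoints or cohorts are quantified by the two-sample
Kolmogorov-Smirnov (KS) distance, the supremum absolute difference between
the two empirical CDFs.

KS is computed on the raw voxel samples (exact ECDFs); binning is used for
reporting and plotting only, since binned KS loses information. An optional
binned mode exists for fidelity experiments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .errors import RangeError, ValidationError
from .quant import PETStudy, proliferative_threshold, summarize_values

__all__ = [
    "FractionalHistogram",
    "KSResult",
    "fractional_histogram",
    "default_bin_edges",
    "ks_two_sample",
    "longitudinal_ks",
    "histogram_report",
    "pool_tumor_voxels",
]

#: above this product of sample sizes the exact p-value switches to asymptotic
EXACT_P_MAX_PRODUCT = 10_000


@dataclass(frozen=True)
class FractionalHistogram:
    """Binned voxel-SUV distribution normalized by total tumor voxel count.

    Bins are left-closed / right-open, except the last bin which is closed on
    both sides (so the maximum value is counted). Frequencies sum to 1.
    """

    bin_edges: np.ndarray
    fractional_frequency: np.ndarray
    n_voxels: int
    source_id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "bin_edges", np.asarray(self.bin_edges, dtype=np.float64))
        object.__setattr__(
            self, "fractional_frequency", np.asarray(self.fractional_frequency, dtype=np.float64)
        )
        if self.bin_edges.ndim != 1 or self.bin_edges.size < 2:
            raise ValidationError("bin_edges must be a 1-D array of length >= 2")
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValidationError("bin_edges must be strictly increasing")
        if self.fractional_frequency.size != self.bin_edges.size - 1:
            raise ValidationError("need exactly one frequency per bin")
        if np.any(self.fractional_frequency < 0):
            raise ValidationError("frequencies must be non-negative")
        total = float(self.fractional_frequency.sum())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"frequencies sum to {total}, expected 1 within 1e-9")
        if self.n_voxels < 1:
            raise ValidationError("n_voxels must be >= 1")


@dataclass(frozen=True)
class KSResult:
    """Two-sample KS comparison: D statistic, p-value, sample sizes, p method."""

    distance: float
    p_value: float
    n1: int
    n2: int
    method: str  # "exact" | "asymptotic"

    def __post_init__(self) -> None:
        if not 0.0 <= self.distance <= 1.0:
            raise ValidationError(f"D must lie in [0, 1], got {self.distance}")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValidationError(f"p must lie in [0, 1], got {self.p_value}")


def fractional_histogram(
    suv_values: Sequence[float] | np.ndarray,
    bin_edges: Sequence[float] | np.ndarray,
    source_id: str = "",
) -> FractionalHistogram:
    """Histogram of voxel SUVs with counts divided by the total voxel number.

    Values outside the edges are an error (naming the offending value) rather
    than being silently dropped, which would break the sum-to-one guarantee.
    """
    values = np.asarray(suv_values, dtype=np.float64).ravel()
    edges = np.asarray(bin_edges, dtype=np.float64)
    if values.size == 0:
        raise ValidationError("fractional_histogram requires at least one value")
    if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValidationError("bin_edges must be strictly increasing with >= 2 entries")
    low, high = edges[0], edges[-1]
    if values.min() < low:
        raise RangeError(f"value {values.min()} below the first bin edge {low}")
    if values.max() > high:
        raise RangeError(f"value {values.max()} above the last bin edge {high}")
    counts, _ = np.histogram(values, bins=edges)
    return FractionalHistogram(
        bin_edges=edges,
        fractional_frequency=counts / values.size,
        n_voxels=int(values.size),
        source_id=source_id,
    )


def default_bin_edges(
    values: Sequence[float] | np.ndarray,
    bin_width: float = 0.1,
    upper_quantile: float = 0.999,
) -> np.ndarray:
    """Edges from 0 up to the ``upper_quantile`` of the pooled sample.

    The upper limit is rounded up to a whole number of bins and extended to
    the sample maximum when necessary so no voxel falls outside the edges.
    Default width 0.1 SUV.
    """
    if bin_width <= 0:
        raise ValidationError("bin_width must be > 0")
    values = np.asarray(values, dtype=np.float64).ravel()
    if values.size == 0:
        raise ValidationError("cannot derive bin edges from an empty sample")
    top = max(float(np.quantile(values, upper_quantile)), float(values.max()))
    n_bins = max(1, int(math.ceil(top / bin_width - 1e-12)))
    return np.linspace(0.0, n_bins * bin_width, n_bins + 1)


def _ks_distance(a: np.ndarray, b: np.ndarray) -> float:
    """sup_x |ECDF_a(x) - ECDF_b(x)| evaluated at the pooled sample points."""
    a = np.sort(a)
    b = np.sort(b)
    grid = np.concatenate([a, b])
    cdf_a = np.searchsorted(a, grid, side="right") / a.size
    cdf_b = np.searchsorted(b, grid, side="right") / b.size
    return float(np.abs(cdf_a - cdf_b).max())


def _ks_exact_p(n1: int, n2: int, d: float) -> float:
    """Exact P(D >= d) under H0 by lattice-path counting over orderings.

    All C(n1+n2, n1) interleavings of the two samples are equally likely under
    the null; a path through (i, j) corresponds to having seen i values of the
    first sample and j of the second. D < d iff the path keeps
    |i*n2 - j*n1| < round(d*n1*n2) throughout (the ECDF difference at every
    pooled order statistic is an integer multiple of 1/(n1*n2)). Exact integer
    arithmetic throughout. Assumes continuous data (no cross-sample ties).
    """
    c = int(round(d * n1 * n2))
    if c == 0:
        return 1.0
    # inside[j] = number of admissible paths reaching (i, j)
    inside = np.zeros(n2 + 1, dtype=object)
    inside[0] = 1
    for j in range(1, n2 + 1):
        inside[j] = inside[j - 1] if abs(j * n1) < c else 0
    for i in range(1, n1 + 1):
        prev = inside.copy()
        inside[0] = prev[0] if abs(i * n2) < c else 0
        for j in range(1, n2 + 1):
            if abs(i * n2 - j * n1) < c:
                inside[j] = inside[j - 1] + prev[j]
            else:
                inside[j] = 0
    total = math.comb(n1 + n2, n1)
    return float(1 - inside[n2] / total)


def ks_two_sample(
    a: Sequence[float] | np.ndarray, b: Sequence[float] | np.ndarray
) -> KSResult:
    """Two-sample KS test: D = sup |ECDF_a - ECDF_b| with a p-value.

    The p-value is exact (lattice-path enumeration) when n1*n2 <= 10^4 and
    asymptotic (Kolmogorov distribution at effective n = n1*n2/(n1+n2))
    otherwise; the method used is recorded in the result.
    """
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    if a.size == 0 or b.size == 0:
        raise ValidationError("both samples must be non-empty")
    d = _ks_distance(a, b)
    n1, n2 = int(a.size), int(b.size)
    if n1 * n2 <= EXACT_P_MAX_PRODUCT:
        p = _ks_exact_p(n1, n2, d)
        method = "exact"
    else:
        en = n1 * n2 / (n1 + n2)
        p = float(scipy.stats.kstwobign.sf(math.sqrt(en) * d))
        method = "asymptotic"
    return KSResult(distance=d, p_value=min(max(p, 0.0), 1.0), n1=n1, n2=n2, method=method)


def pool_tumor_voxels(
    studies: Iterable[PETStudy],
    voxels: str = "all",
    sd_multiplier: float = 2.0,
) -> np.ndarray:
    """Pool tumor voxel SUVs across animals within one cohort-timepoint.

    ``voxels="proliferative"`` first applies each scan's own muscle-referenced
    threshold and pools only voxels at or above it.
    """
    if voxels not in ("all", "proliferative"):
        raise ValidationError(f"voxels must be 'all' or 'proliferative', got {voxels!r}")
    pooled = []
    for study in studies:
        values = study.tumor_values()
        if voxels == "proliferative":
            muscle = summarize_values(study.muscle_values(), label="muscle")
            thr = proliferative_threshold(muscle, sd_multiplier=sd_multiplier)
            values = values[values >= thr]
        pooled.append(values)
    if not pooled:
        raise ValidationError("no studies supplied")
    return np.concatenate(pooled)


def longitudinal_ks(
    cohort_studies_day0: Sequence[PETStudy],
    cohort_studies_dayT: Sequence[PETStudy],
    voxels: str = "all",
    sd_multiplier: float = 2.0,
) -> KSResult:
    """KS distance between pooled cohort voxel samples at two timepoints.

    Voxels are pooled across animals within each cohort-timepoint before the
    comparison, yielding one D per cohort pair. The same code path serves
    cohort-vs-control comparisons on a single day.
    """
    if len(cohort_studies_day0) == 0 or len(cohort_studies_dayT) == 0:
        raise ValidationError("both study lists must be non-empty")
    a = pool_tumor_voxels(cohort_studies_day0, voxels=voxels, sd_multiplier=sd_multiplier)
    b = pool_tumor_voxels(cohort_studies_dayT, voxels=voxels, sd_multiplier=sd_multiplier)
    return ks_two_sample(a, b)


def histogram_report(
    histograms: Sequence[FractionalHistogram],
    csv_path: str | Path,
    plot_path: Optional[str | Path] = None,
) -> pd.DataFrame:
    """Aligned table of fractional frequencies per source, plus an overlay plot.

    All histograms must share identical bin edges. Returns the table written
    to ``csv_path``; a bin-center overlay plot is written when ``plot_path``
    is given.
    """
    if len(histograms) == 0:
        raise ValidationError("histogram_report requires at least one histogram")
    edges = histograms[0].bin_edges
    for h in histograms[1:]:
        if h.bin_edges.shape != edges.shape or not np.allclose(h.bin_edges, edges):
            raise ValidationError(
                f"bin edges of {h.source_id!r} do not match {histograms[0].source_id!r}"
            )
    centers = 0.5 * (edges[:-1] + edges[1:])
    table = pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:], "bin_center": centers})
    for i, h in enumerate(histograms):
        name = h.source_id or f"hist_{i}"
        table[name] = h.fractional_frequency
    table.to_csv(csv_path, index=False)
    if plot_path is not None:
        from .plotting import plot_histograms

        plot_histograms(histograms, plot_path)
    return table
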