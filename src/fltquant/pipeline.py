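"""End-to-end orchestration: simulate -> quantify -> histogram/KS -> growth -> in-vitro.

``run_pipeline`` drives the whole analysis from one validated ``RunConfig``
and writes every artifact class (summary CSVs, fractional-frequency
histograms and KS tables, growth report, in-vitro tables, classification
masks, plots) plus a JSON manifest with config echo, seed and version.
Identical config + seed reruns are byte-identical.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Literal, Optional, Tuple

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .errors import FltQuantError
from .heterogeneity import (
    default_bin_edges,
    fractional_histogram,
    histogram_report,
    longitudinal_ks,
    pool_tumor_voxels,
)
from .invitro import biomarker_viability_regression, dose_response_table, percent_survival
from .io import ResultWriter, read_pet_study
from .quant import PETStudy, quantify_study
from .simulate import (
    DEFAULT_EDU_CONDITIONS,
    DEFAULT_VIABILITY_CONDITIONS,
    PhantomSpec,
    generate_growth_cohort,
    generate_longitudinal_study,
    generate_plate,
)
from .growth import growth_report, normalize_to_vehicle
from .plotting import plot_growth_curves

__all__ = ["RunConfig", "PipelineStageError", "run_pipeline"]

logger = logging.getLogger(__name__)


class PipelineStageError(FltQuantError):
    """A pipeline stage failed; the message names the stage and the cause."""


class RunConfig(BaseModel):
    """Validated configuration for a full pipeline run.

    ``threshold_sd_multiplier`` sets the proliferative cutoff at muscle mean
    plus that many SDs (default 2). ``ks_voxels`` selects whether KS uses all
    tumor voxels or only threshold-passing ones. Unknown keys are rejected
    before any computation.
    """

    model_config = ConfigDict(extra="forbid")

    seed: int = Field(ge=0, lt=2**31)
    out_dir: str
    bin_width: float = Field(default=0.1, gt=0.0)
    threshold_sd_multiplier: float = Field(default=2.0, ge=0.0)
    ks_voxels: Literal["all", "proliferative"] = "all"
    alpha: float = Field(default=0.05, gt=0.0, lt=1.0)
    # synthetic-study design (used when no input table is given)
    grid_shape: Tuple[int, int, int] = (32, 32, 32)
    n_per_arm: int = Field(default=4, ge=1)
    timepoint_days: Tuple[int, int] = (0, 10)
    arm_suppressions: dict[str, float] = {
        "vehicle": 1.0,
        "trastuzumab": 0.8,
        "niraparib": 0.8,
        "combination": 0.7,
    }
    vehicle_arm: str = "vehicle"
    input_table: Optional[str] = None  # CSV of pre-existing studies, else simulate
    write_masks: bool = True


def _subseed(*entropy: int) -> int:
    return int(np.random.SeedSequence(entropy).generate_state(1)[0] % 2**31)


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            logger.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raised with stage context
                raise PipelineStageError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %s: done", name)
            return out

        return wrapped

    return deco


@_stage("simulate")
def _simulate_studies(config: RunConfig) -> list[tuple[str, PETStudy]]:
    """(arm, study) pairs for a multi-arm two-timepoint synthetic PET study."""
    day0, dayT = config.timepoint_days
    out = []
    for arm_idx, (arm, suppression) in enumerate(sorted(config.arm_suppressions.items())):
        for k in range(config.n_per_arm):
            spec = PhantomSpec(
                seed=_subseed(config.seed, arm_idx, k), grid_shape=config.grid_shape
            )
            studies = generate_longitudinal_study(
                spec, [(day0, 1.0), (dayT, suppression)]
            )
            for s in studies:
                s.subject_id = f"{arm}-{k + 1:02d}"
                logger.debug("simulated %s arm=%s day=%d", s.subject_id, arm, s.day)
                out.append((arm, s))
    return out


@_stage("load")
def _load_studies(config: RunConfig) -> list[tuple[str, PETStudy]]:
    """Read studies listed in a CSV with columns arm,subject_id,day,suv,tumor_mask,muscle_mask."""
    table = pd.read_csv(config.input_table)
    required = {"arm", "subject_id", "day", "suv", "tumor_mask", "muscle_mask"}
    missing = required - set(table.columns)
    if missing:
        raise FltQuantError(f"input table missing columns: {sorted(missing)}")
    base = Path(config.input_table).parent
    out = []
    for row in table.itertuples():
        study = read_pet_study(
            base / row.suv, base / row.tumor_mask, base / row.muscle_mask,
            subject_id=str(row.subject_id), day=int(row.day),
        )
        out.append((str(row.arm), study))
    return out


@_stage("quantify")
def _quantify(config: RunConfig, studies, writer: ResultWriter) -> pd.DataFrame:
    rows = []
    for arm, study in studies:
        q = quantify_study(study, sd_multiplier=config.threshold_sd_multiplier)
        c = q.classification
        rows.append(
            {
                "subject_id": study.subject_id,
                "arm": arm,
                "day": study.day,
                "tumor_mean_suv": q.tumor.mean,
                "tumor_sd_suv": q.tumor.sd,
                "tumor_max_suv": q.tumor.max,
                "tumor_n_voxels": q.tumor.n_voxels,
                "muscle_mean_suv": q.muscle.mean,
                "muscle_sd_suv": q.muscle.sd,
                "threshold": c.threshold,
                "proliferative_fraction": c.proliferative_fraction,
                "proliferative_mean_suv": (
                    c.proliferative_summary.mean if not c.is_empty else np.nan
                ),
            }
        )
        if config.write_masks:
            writer.add_volume(
                c.proliferative_mask,
                study.affine,
                f"masks/{study.subject_id}_day{study.day}_proliferative",
            )
    df = pd.DataFrame(rows)
    writer.add_table(df, "suv_summary")
    return df


@_stage("heterogeneity")
def _heterogeneity(config: RunConfig, studies, writer: ResultWriter) -> pd.DataFrame:
    by_group: dict[tuple[str, int], list[PETStudy]] = {}
    for arm, study in studies:
        by_group.setdefault((arm, study.day), []).append(study)
    pooled = {
        key: pool_tumor_voxels(
            group, voxels=config.ks_voxels, sd_multiplier=config.threshold_sd_multiplier
        )
        for key, group in by_group.items()
    }
    edges = default_bin_edges(np.concatenate(list(pooled.values())), config.bin_width)
    hists = [
        fractional_histogram(values, edges, source_id=f"{arm}_day{day}")
        for (arm, day), values in sorted(pooled.items())
    ]
    csv_path = writer.out_dir / "fractional_histograms.csv"
    plot_path = writer.out_dir / "fractional_histograms.png"
    histogram_report(hists, csv_path, plot_path)
    writer.add_file(csv_path)
    writer.add_file(plot_path)

    days = sorted({day for _, day in by_group})
    day0, dayT = days[0], days[-1]
    rows = []
    arms = sorted({arm for arm, _ in by_group})
    for arm in arms:
        ks = longitudinal_ks(
            by_group[(arm, day0)], by_group[(arm, dayT)],
            voxels=config.ks_voxels, sd_multiplier=config.threshold_sd_multiplier,
        )
        rows.append(
            {
                "comparison": f"{arm}: day {day0} vs day {dayT}",
                "ks_distance": ks.distance, "p_value": ks.p_value,
                "n1": ks.n1, "n2": ks.n2, "method": ks.method,
            }
        )
    for arm in arms:
        if arm == config.vehicle_arm or (config.vehicle_arm, dayT) not in by_group:
            continue
        ks = longitudinal_ks(
            by_group[(config.vehicle_arm, dayT)], by_group[(arm, dayT)],
            voxels=config.ks_voxels, sd_multiplier=config.threshold_sd_multiplier,
        )
        rows.append(
            {
                "comparison": f"{config.vehicle_arm} vs {arm}: day {dayT}",
                "ks_distance": ks.distance, "p_value": ks.p_value,
                "n1": ks.n1, "n2": ks.n2, "method": ks.method,
            }
        )
    df = pd.DataFrame(rows)
    writer.add_table(df, "ks_comparisons")
    return df


@_stage("growth")
def _growth(config: RunConfig, writer: ResultWriter) -> pd.DataFrame:
    cohort = generate_growth_cohort(_subseed(config.seed, 101))
    report = growth_report(cohort, alpha=config.alpha, grubbs=True)
    writer.add_table(cohort.records, "growth_records")
    writer.add_table(report.summary, "growth_summary")
    writer.add_table(report.comparisons, "growth_comparisons")
    final_day = cohort.days[-1]
    normalized = normalize_to_vehicle(cohort, config.vehicle_arm, final_day)
    writer.add_table(normalized, "growth_vehicle_normalized")
    plot_path = writer.out_dir / "growth_curves.png"
    plot_growth_curves(report.summary, plot_path)
    writer.add_file(plot_path)
    return report.summary


@_stage("invitro")
def _invitro(config: RunConfig, writer: ResultWriter) -> pd.DataFrame:
    viability = generate_plate(
        _subseed(config.seed, 201), DEFAULT_VIABILITY_CONDITIONS,
        channel="viability_gfp", timepoint_h=96.0,
    )
    edu = generate_plate(
        _subseed(config.seed, 202), DEFAULT_EDU_CONDITIONS,
        channel="proliferation_edu", timepoint_h=48.0,
    )
    writer.add_table(viability.wells, "plate_viability")
    writer.add_table(edu.wells, "plate_edu")
    tables = []
    for agent in ("trastuzumab", "niraparib"):
        tables.append(dose_response_table(viability, agent, channel="viability_gfp"))
    dose_df = pd.concat(tables, ignore_index=True)
    writer.add_table(dose_df, "dose_response")

    control_v = viability.signals("control", "viability_gfp")
    rows = []
    for cond in ("trastuzumab", "niraparib", "combination"):
        sel = viability.wells["condition"] == cond
        at_1 = viability.wells[sel & (viability.wells["dose"] == 1.0)]
        surv = percent_survival(at_1["signal"].to_numpy(), control_v)
        rows.append({"condition": cond, "percent_survival": surv.percent, "sd": surv.sd})
    surv_df = pd.DataFrame(rows)
    writer.add_table(surv_df, "percent_survival")

    # matched wells: 48-h proliferation biomarker vs endpoint viability
    conds = [c for c, *_ in DEFAULT_EDU_CONDITIONS]
    biomarker, endpoint = [], []
    for cond in conds:
        b = edu.signals(cond, "proliferation_edu")
        sel = viability.wells["condition"].str.lower() == cond
        v = viability.wells[sel & (viability.wells["dose"].isin([0.0, 1.0]))]
        v = v["signal"].to_numpy()[: b.size]
        n = min(b.size, v.size)
        biomarker.extend(b[:n])
        endpoint.extend(v[:n])
    reg = biomarker_viability_regression(biomarker, endpoint)
    reg_df = pd.DataFrame(
        [
            {
                "x": "proliferation_edu_48h", "y": "endpoint_viability",
                "slope": reg.slope, "intercept": reg.intercept,
                "r_squared": reg.r_squared, "p_value": reg.p_value, "n": reg.n,
            }
        ]
    )
    writer.add_table(reg_df, "biomarker_regression")
    return reg_df


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage and return the path of the written manifest."""
    writer = ResultWriter(
        config.out_dir, config=config.model_dump(), seed=config.seed
    )
    if config.input_table:
        studies = _load_studies(config)
    else:
        studies = _simulate_studies(config)
    _quantify(config, studies, writer)
    _heterogeneity(config, studies, writer)
    _growth(config, writer)
    _invitro(config, writer)
    return writer.write_manifest()
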