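"""End-to-end per-patient evaluation and cohort comparison.

Per patient the stages run in a fixed order: demons registration (follow-up ->
planning) -> warp of the pneumonitis mask -> GTV subtraction -> dose resampling
to the planning CT grid -> EQD2 conversion -> pneumonitis metrics / DVH / AUC ->
total-lung metrics. EQD2 conversion always precedes every dose metric and GTV
subtraction always precedes DVH extraction. All CSV outputs use fixed ordering
and float formatting, so identical inputs give byte-identical files.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort as cohort_mod
from .cohort import MatchedPairs, PatientRecord, match_pairs_by_ptv, records_to_frame, \
    summarize_cohort
from .dosimetry import DVH, DoseLevelConfig, FractionationScheme, compute_dvh, \
    compute_lung_metrics, compute_ptp_metrics, eqd2_convert, subtract_gtv
from .io_formats import BinaryMask, ImageGrid, coverage_mask, mask_volume_cm3, \
    read_json_sidecar, read_nifti, resample_to_grid, write_json_sidecar, write_nifti
from .registration import DemonsParams, demons_register, warp_mask

log = logging.getLogger(__name__)

FLOAT_FMT = "%.6f"


@dataclass
class PipelineConfig:
    """Defaults follow the stated analysis constants: alpha/beta = 3 Gy,
    dose levels at 20 and 40 Gy, 0.1 Gy DVH bins, significance at 0.05."""

    alpha_beta_gy: float = 3.0
    levels: DoseLevelConfig = field(default_factory=DoseLevelConfig)
    dvh_bin_width_gy: float = 0.1
    demons: DemonsParams = field(default_factory=DemonsParams)
    lung_dose_grid: str = "eqd2"  # "eqd2" | "physical"
    lung_excludes_gtv: bool = True
    alpha: float = 0.05
    min_n_for_tests: int = 5

    def __post_init__(self) -> None:
        if self.lung_dose_grid not in ("eqd2", "physical"):
            raise ValueError("lung_dose_grid must be 'eqd2' or 'physical'")


@dataclass
class EvaluationResult:
    """PatientRecord plus artifacts a caller may want to inspect or export."""

    record: PatientRecord
    dvh: DVH | None
    ptp_mask_planning: BinaryMask
    ptp_outside_dose_grid_pct: float
    gtv_overlap_pct: float  # share of the warped PTP removed as GTV


def evaluate_patient(
    planning_ct: ImageGrid,
    structures: dict[str, BinaryMask],
    dose: ImageGrid,
    followup_ct: ImageGrid,
    ptp_followup: BinaryMask,
    scheme: FractionationScheme,
    config: PipelineConfig | None = None,
    *,
    patient_id: str = "P000",
    group: str = "RCT",
    intent: str = "definitive",
    grade: int | None = None,
    onset_days: int | None = None,
    out_dir: str | Path | None = None,
) -> EvaluationResult:
    """Run the full per-patient evaluation; see module docstring for the stage
    order. An empty post-subtraction pneumonitis mask yields an
    evaluable-but-empty record (metrics absent) with a warning."""
    config = config or PipelineConfig()
    for roi in ("GTV", "PTV", "Lung_total"):
        if roi not in structures:
            raise KeyError(f"structure set is missing {roi!r}")
    if dose.frame_id and planning_ct.frame_id and dose.frame_id != planning_ct.frame_id:
        raise ValueError(
            f"dose frame {dose.frame_id!r} != planning frame {planning_ct.frame_id!r}")

    log.info("[%s] registration (follow-up -> planning)", patient_id)
    fld = demons_register(planning_ct, followup_ct, config.demons)
    ptp_plan = warp_mask(ptp_followup, fld)
    ptp_net = subtract_gtv(ptp_plan, structures["GTV"])
    overlap_vox = ptp_plan.count() - ptp_net.count()
    gtv_overlap_pct = 100.0 * overlap_vox / ptp_plan.count() if ptp_plan.count() else 0.0
    if gtv_overlap_pct > 0:
        log.info("[%s] GTV removed %.1f%% of the warped pneumonitis volume",
                 patient_id, gtv_overlap_pct)

    dose_on_ct = resample_to_grid(dose, planning_ct)
    # cubic resampling may undershoot slightly at sharp borders; clamp to >= 0
    if dose_on_ct.values.min() < 0:
        dose_on_ct = dose_on_ct.with_values(np.maximum(dose_on_ct.values, 0.0))
    covered = coverage_mask(dose, planning_ct)
    n_ptp = ptp_net.count()
    outside_pct = (100.0 * float((ptp_net.voxels & ~covered).sum()) / n_ptp
                   if n_ptp else 0.0)
    log.info("[%s] %.1f%% of pneumonitis voxels outside the exported dose grid "
             "(treated as 0 Gy)", patient_id, outside_pct)

    eqd2 = eqd2_convert(dose_on_ct, FractionationScheme(scheme.n_fractions,
                                                        config.alpha_beta_gy))
    lung = structures["Lung_total"]
    if config.lung_excludes_gtv:
        lung = subtract_gtv(lung, structures["GTV"])
    lung_dose = eqd2 if config.lung_dose_grid == "eqd2" else dose_on_ct
    lung_metrics = compute_lung_metrics(lung_dose, lung)

    if n_ptp == 0:
        log.warning("[%s] pneumonitis volume empty after GTV subtraction; "
                    "dose metrics skipped", patient_id)
        metrics, dvh = None, None
    else:
        metrics = compute_ptp_metrics(eqd2, ptp_net, config.levels,
                                      config.dvh_bin_width_gy)
        dvh = compute_dvh(eqd2, ptp_net, config.dvh_bin_width_gy)

    record = PatientRecord(
        patient_id=patient_id, group=group, intent=intent,
        ptv_cm3=mask_volume_cm3(structures["PTV"]),
        pneumonitis=True, grade=grade, onset_days=onset_days,
        metrics=metrics, lung=lung_metrics,
    )
    result = EvaluationResult(record, dvh, ptp_net, outside_pct, gtv_overlap_pct)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        cohort_mod.records_to_csv([record], out_dir / f"{patient_id}_record.csv")
        if dvh is not None:
            pd.DataFrame({"edge_gy": dvh.bin_edges_gy,
                          "volume_pct": dvh.cumulative_volume_pct}).to_csv(
                out_dir / f"{patient_id}_dvh.csv", index=False, float_format=FLOAT_FMT)
        write_json_sidecar({
            "patient_id": patient_id,
            "ptp_outside_dose_grid_pct": round(outside_pct, 6),
            "gtv_overlap_pct": round(gtv_overlap_pct, 6),
            "ptp_empty_after_gtv_subtraction": n_ptp == 0,
        }, out_dir / f"{patient_id}_log.json")
    return result


# ---------------------------------------------------------------------------
# cohort-level analysis
# ---------------------------------------------------------------------------

def run_cohort(
    records: list[PatientRecord],
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Cohort comparison: all-patient summary, definitive/palliative strata,
    and PTV-matched-pair summaries per stratum (p-values suppressed for small
    subgroups). Returns ``{"summary_all": DataFrame, "summary_<intent>": ...,
    "pairs_<intent>": MatchedPairs, "summary_matched_<intent>": ...}``."""
    if not records:
        raise ValueError("no patient records")
    config = config or PipelineConfig()
    out: dict = {}
    out["summary_all"] = summarize_cohort(
        records, alpha=config.alpha, min_n_for_tests=config.min_n_for_tests)
    for intent in ("definitive", "palliative"):
        stratum = [r for r in records if r.intent == intent]
        if not stratum:
            log.warning("stratum %r is empty; skipped", intent)
            continue
        out[f"summary_{intent}"] = summarize_cohort(
            stratum, alpha=config.alpha, min_n_for_tests=config.min_n_for_tests)
        a = [r for r in stratum if r.group == "RCT_ICI"]
        b = [r for r in stratum if r.group == "RCT"]
        if a and b:
            pairs = match_pairs_by_ptv(a, b)
            out[f"pairs_{intent}"] = pairs
            matched_ids = {pid for pair in pairs.pairs for pid in pair}
            matched = [r for r in stratum if r.patient_id in matched_ids]
            out[f"summary_matched_{intent}"] = summarize_cohort(
                matched, alpha=config.alpha, min_n_for_tests=config.min_n_for_tests)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name, value in sorted(out.items()):
            if isinstance(value, MatchedPairs):
                df = pd.DataFrame(value.pairs, columns=["rct_ici_id", "rct_id"])
                df["total_abs_ptv_diff_cm3"] = ""
                if len(df):
                    df.loc[0, "total_abs_ptv_diff_cm3"] = (
                        FLOAT_FMT % value.total_abs_ptv_diff_cm3)
                df.to_csv(out_dir / f"{name}.csv", index=False)
            else:
                value.to_csv(out_dir / f"{name}.csv", index=False,
                             float_format=FLOAT_FMT)
    return out


# ---------------------------------------------------------------------------
# patient fixture directories (NIfTI + JSON dialect)
# ---------------------------------------------------------------------------

_PATIENT_FILES = {
    "planning_ct": "planning_ct.nii.gz",
    "followup_ct": "followup_ct.nii.gz",
    "dose": "dose.nii.gz",
    "gtv": "mask_gtv.nii.gz",
    "ptv": "mask_ptv.nii.gz",
    "lung": "mask_lung.nii.gz",
    "ptp_followup": "mask_ptp_followup.nii.gz",
}


def save_patient_inputs(directory: str | Path, planning_ct: ImageGrid,
                        followup_ct: ImageGrid, dose: ImageGrid,
                        structures: dict[str, BinaryMask], ptp_followup: BinaryMask,
                        meta: dict) -> Path:
    """Write one patient's inputs in the NIfTI + JSON sidecar fixture dialect."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_nifti(planning_ct, directory / _PATIENT_FILES["planning_ct"])
    write_nifti(followup_ct, directory / _PATIENT_FILES["followup_ct"])
    write_nifti(dose, directory / _PATIENT_FILES["dose"])
    write_nifti(structures["GTV"], directory / _PATIENT_FILES["gtv"])
    write_nifti(structures["PTV"], directory / _PATIENT_FILES["ptv"])
    write_nifti(structures["Lung_total"], directory / _PATIENT_FILES["lung"])
    write_nifti(ptp_followup, directory / _PATIENT_FILES["ptp_followup"])
    meta = dict(meta)
    meta.setdefault("planning_frame_id", planning_ct.frame_id or "planning")
    meta.setdefault("followup_frame_id", followup_ct.frame_id or "followup")
    write_json_sidecar(meta, directory / "meta.json")
    return directory


def load_patient_inputs(directory: str | Path):
    """Read a patient fixture directory back into pipeline inputs."""
    directory = Path(directory)
    meta = read_json_sidecar(directory / "meta.json")
    plan_frame = meta.get("planning_frame_id", "planning")
    fu_frame = meta.get("followup_frame_id", "followup")
    planning_ct = read_nifti(directory / _PATIENT_FILES["planning_ct"], plan_frame)
    followup_ct = read_nifti(directory / _PATIENT_FILES["followup_ct"], fu_frame)
    dose = read_nifti(directory / _PATIENT_FILES["dose"], plan_frame)
    structures = {
        "GTV": read_nifti(directory / _PATIENT_FILES["gtv"], plan_frame,
                          as_mask=True, roi_name="GTV"),
        "PTV": read_nifti(directory / _PATIENT_FILES["ptv"], plan_frame,
                          as_mask=True, roi_name="PTV"),
        "Lung_total": read_nifti(directory / _PATIENT_FILES["lung"], plan_frame,
                                 as_mask=True, roi_name="Lung_total"),
    }
    ptp = read_nifti(directory / _PATIENT_FILES["ptp_followup"], fu_frame,
                     as_mask=True, roi_name="PTP")
    return planning_ct, followup_ct, dose, structures, ptp, meta
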