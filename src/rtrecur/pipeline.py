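"""Per-case orchestration: register, transform, voxelize, analyze, report.

The workflow mirrors a semi-automated recurrence analysis: the follow-up CT
is rigidly registered to the planning CT (or a manual override transform is
applied), the recurrence structure delineated on the follow-up scan is
carried into the planning frame, voxelized with subvoxel accuracy, and then
analyzed against each plan's dose grid separately (base and boost plans are
delivered sequentially, so their dose files are analyzed per plan).  The
report row mirrors the clinical summary: per-plan dose statistics, the
percentage of the recurrence inside the configured isodose volume, and the
location classification against the boost and its expanded shells.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import rt_io
from .dvh import compute_dvh, dose_stats, resample_dose, sample_dose, voxelize
from .geometry import ImageVolume
from .metrics import classify_location, isodose_mask, overlap
from .registration import (
    RegistrationParams,
    preinitialize,
    register_rigid,
    transform_roi,
)
from .structures import ROI
from .transforms import RigidTransform, load_transform

__all__ = [
    "PlanInfo",
    "AnalysisParams",
    "CaseConfig",
    "RecurrenceReport",
    "run_case",
    "analyze_case",
    "StageError",
]


class StageError(RuntimeError):
    """A pipeline stage failed; the message carries the stage tag."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PlanInfo:
    """One treatment plan: label, fractionation, prescription and dose grid."""

    plan_label: str
    fraction_count: int
    prescribed_dose_gy: float
    dose_path: str | None = None
    dose: ImageVolume | None = None

    def __post_init__(self):
        if self.fraction_count < 1:
            raise ValueError("fraction_count must be >= 1")
        if self.prescribed_dose_gy <= 0:
            raise ValueError("prescribed_dose must be positive")


@dataclass
class AnalysisParams:
    isodose_pct: float = 80.0
    margins_mm: tuple = (10.0, 15.0, 20.0)
    containment_threshold: float = 0.95
    dvh_bin_gy: float = 0.1
    max_voxelization_level: int = 3
    voxelization_tolerance: float = 5e-3
    isodose_reference: str = "prescription"  # or "grid_max"


@dataclass
class CaseConfig:
    """Everything needed to analyze one case, resolvable from a YAML file."""

    patient_id: str
    planning_ct: str
    followup_cts: list
    structures: list
    plans: list
    recurrence_structures: list = field(default_factory=list)
    recurrence_name: str = "Recurrence"
    boost_name: str = "Boost"
    ptv_name: str = "PTV"
    cord_name: str = "SpinalCord"
    recurrence_frame: str = "followup"  # or "planning"
    params: AnalysisParams = field(default_factory=AnalysisParams)
    registration: RegistrationParams = field(default_factory=RegistrationParams)
    preinit_hint_deg: float | None = None
    override_transform: str | None = None
    use_structure_mask: bool = False
    base_dir: Path = field(default_factory=Path)

    def __post_init__(self):
        if not self.followup_cts:
            raise ValueError("at least one follow-up CT is required")
        if not self.plans:
            raise ValueError("at least one plan is required")
        self.plans = [
            p if isinstance(p, PlanInfo) else PlanInfo(
                plan_label=p["label"],
                fraction_count=int(p["fraction_count"]),
                prescribed_dose_gy=float(p["prescribed_dose_gy"]),
                dose_path=p.get("dose"),
            )
            for p in self.plans
        ]
        if isinstance(self.params, dict):
            self.params = AnalysisParams(**self.params)
        if isinstance(self.registration, dict):
            self.registration = RegistrationParams(**self.registration)
        self.base_dir = Path(self.base_dir)

    @classmethod
    def from_yaml(cls, path) -> "CaseConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw.setdefault("base_dir", path.parent)
        return cls(**raw)

    def resolve(self, rel) -> Path:
        return self.base_dir / rel


_PLAN_STAT_FIELDS = ("vol_in_isodose_ml", "min_gy", "max_gy", "median_gy")


@dataclass
class RecurrenceReport:
    """Per-case record: per-plan dose statistics, isodose overlap, location."""

    patient_id: str
    recurrence_vol_ml: float | None = None
    fx_base: int | None = None
    fx_boost: int | None = None
    plan_stats: dict = field(default_factory=dict)   # label -> DoseStats | None
    plan_overlap: dict = field(default_factory=dict)  # label -> OverlapResult | None
    classification: object | None = None
    transform: RigidTransform | None = None
    transform_source: str = "automatic"
    voxelization_level: int | None = None
    isodose_pct: float = 80.0
    warnings: list = field(default_factory=list)
    stage_log: list = field(default_factory=list)

    def to_row(self) -> dict:
        def r2(value):
            return None if value is None else round(float(value), 2)

        row = {
            "patient_id": self.patient_id,
            "fx_base": self.fx_base,
            "fx_boost": self.fx_boost,
            "recurrence_vol_ml": r2(self.recurrence_vol_ml),
        }
        for label in ("base", "boost"):
            stats = self.plan_stats.get(label)
            for name in _PLAN_STAT_FIELDS:
                row[f"{label}_{name}"] = r2(getattr(stats, name, None))
            ov = self.plan_overlap.get(label)
            row[f"{label}_pct_in_isodose"] = r2(getattr(ov, "overlap_pct", None))
        cls = self.classification
        if cls is not None:
            for label in cls.shell_labels():
                key = label.replace("+", "_plus_")
                row[f"in_{key}"] = bool(cls.membership[label])
                row[f"coverage_{key}"] = r2(100.0 * cls.coverage[label])
            row["outfield_volume_ml"] = r2(cls.outfield_volume_ml)
            row["max_extension_cm_axial"] = r2(cls.max_extension_cm_axial)
            row["max_extension_cm_3d"] = r2(cls.max_extension_cm_3d)
        row["isodose_pct"] = r2(self.isodose_pct)
        row["voxelization_level"] = self.voxelization_level
        row["transform_source"] = self.transform_source
        if self.transform is not None:
            row["transform"] = ";".join(f"{v:.6f}" for v in self.transform.as_vector())
        row["warnings"] = "|".join(self.warnings)
        return row


def _find_roi(rois: list[ROI], name: str) -> ROI | None:
    for roi in rois:
        if roi.name == name:
            return roi
    return None


def analyze_case(
    *,
    patient_id: str,
    planning_ct: ImageVolume,
    recurrence_roi: ROI,
    plans: list[PlanInfo],
    boost_roi: ROI | None = None,
    transform: RigidTransform | None = None,
    transform_source: str = "manual",
    params: AnalysisParams | None = None,
    report: RecurrenceReport | None = None,
) -> RecurrenceReport:
    """Dose/location analysis of a recurrence already in the planning frame.

    ``recurrence_roi`` must be expressed in the planning frame; ``transform``
    is recorded for provenance only.  This is the computational core of
    :func:`run_case`, separated so in-memory fixtures can drive it directly.
    """
    params = params or AnalysisParams()
    report = report or RecurrenceReport(patient_id=patient_id)
    report.transform = transform
    report.transform_source = transform_source
    report.isodose_pct = params.isodose_pct

    t0 = time.perf_counter()
    mask = voxelize(
        recurrence_roi,
        planning_ct,
        max_level=params.max_voxelization_level,
        tolerance=params.voxelization_tolerance,
    )
    report.voxelization_level = mask.level
    report.recurrence_vol_ml = mask.volume_ml
    report.stage_log.append(
        {"stage": "voxelize", "seconds": time.perf_counter() - t0,
         "level": mask.level, "volume_ml": mask.volume_ml}
    )

    for plan in plans:
        label = plan.plan_label
        if plan.fraction_count is not None:
            if label == "base":
                report.fx_base = plan.fraction_count
            elif label == "boost":
                report.fx_boost = plan.fraction_count
        dose = plan.dose
        if dose is None:
            report.plan_stats[label] = None
            report.plan_overlap[label] = None
            continue
        if "sum-plan" in dose.flags:
            report.plan_stats[label] = None
            report.plan_overlap[label] = None
            report.warnings.append(
                f"plan {label!r}: composite/sum dose grid — per-plan analysis "
                "skipped"
            )
            continue
        t0 = time.perf_counter()
        reference = (
            plan.prescribed_dose_gy
            if params.isodose_reference == "prescription"
            else float(dose.voxels.max())
        )
        threshold = params.isodose_pct / 100.0 * reference
        samples = sample_dose(dose, mask)
        stats = dose_stats(samples, threshold)
        report.plan_stats[label] = stats
        report.warnings.extend(f"plan {label!r}: {w}" for w in stats.warnings)

        dose_on_grid = resample_dose(dose, mask)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            iso = isodose_mask(dose_on_grid, params.isodose_pct, reference)
        report.plan_overlap[label] = overlap(mask, iso)
        report.stage_log.append(
            {"stage": f"dose:{label}", "seconds": time.perf_counter() - t0,
             "isodose_threshold_gy": threshold}
        )

    if boost_roi is not None and not boost_roi.is_empty:
        t0 = time.perf_counter()
        boost_mask = voxelize(
            boost_roi,
            planning_ct,
            max_level=params.max_voxelization_level,
            tolerance=params.voxelization_tolerance,
        )
        report.classification = classify_location(
            mask,
            boost_mask,
            margins_mm=params.margins_mm,
            containment_threshold=params.containment_threshold,
        )
        report.stage_log.append(
            {"stage": "classify", "seconds": time.perf_counter() - t0}
        )
    else:
        report.warnings.append("no boost structure delineated: location "
                               "classification skipped")
    return report


def run_case(config: CaseConfig, out_dir=None) -> RecurrenceReport:
    """Execute the full workflow for one case configuration.

    Stages: read inputs, register follow-up to planning CT (or apply the
    manual override transform), carry the recurrence structure into the
    planning frame, then run :func:`analyze_case`.  Any stage failure raises
    :class:`StageError` naming the stage.  When ``out_dir`` is given, the
    report (CSV + JSON) and an effective-config snapshot are written there.
    """
    report = RecurrenceReport(patient_id=config.patient_id)

    try:
        planning = rt_io.read_ct_series(config.resolve(config.planning_ct))
        followup = rt_io.read_ct_series(config.resolve(config.followup_cts[0]))
    except Exception as exc:
        raise StageError("read-ct", str(exc)) from exc

    try:
        rois: list[ROI] = []
        for rel in config.structures:
            rois.extend(
                rt_io.read_rtstruct(
                    config.resolve(rel), planning.frame_of_reference_id
                )
            )
        recurrence_rois: list[ROI] = []
        rec_frame = (
            followup.frame_of_reference_id
            if config.recurrence_frame == "followup"
            else planning.frame_of_reference_id
        )
        for rel in config.recurrence_structures or []:
            recurrence_rois.extend(rt_io.read_rtstruct(config.resolve(rel), rec_frame))
        if not recurrence_rois:
            recurrence_rois = rois
    except Exception as exc:
        raise StageError("read-structures", str(exc)) from exc

    recurrence = _find_roi(recurrence_rois, config.recurrence_name)
    if recurrence is None or recurrence.is_empty:
        raise StageError(
            "read-structures",
            f"recurrence structure {config.recurrence_name!r} not found or empty",
        )
    for roi in rois + recurrence_rois:
        for flag in roi.flags:
            report.warnings.append(f"structure {roi.name!r}: {flag}")

    # --- registration (or manual override) -------------------------------
    t0 = time.perf_counter()
    if config.override_transform is not None:
        transform = load_transform(config.resolve(config.override_transform))
        source = "manual-override"
        report.stage_log.append({"stage": "register", "skipped": "override"})
    else:
        try:
            mask_rois = None
            if config.use_structure_mask:
                mask_rois = [
                    r
                    for r in (
                        _find_roi(rois, config.ptv_name),
                        _find_roi(rois, config.cord_name),
                    )
                    if r is not None and not r.is_empty
                ]
            init = preinitialize(planning, followup, config.preinit_hint_deg)
            ptv = _find_roi(rois, config.ptv_name)
            if ptv is not None and not ptv.is_empty:
                # rotation point at the PTV centroid, the structure the plan
                # was registered around
                centroid = ptv.all_vertices().mean(axis=0)
                init = init.with_rotation_point(centroid)
            result = register_rigid(
                planning,
                followup,
                init=init,
                params=config.registration,
                structure_mask_rois=mask_rois,
            )
            transform = result.transform
            source = "automatic"
            report.stage_log.append(
                {"stage": "register", "seconds": time.perf_counter() - t0,
                 "metric": result.metric_value, "iterations": result.iterations,
                 "seed": result.seed}
            )
        except Exception as exc:
            raise StageError("register", str(exc)) from exc

    # --- carry the recurrence into the planning frame ---------------------
    try:
        if config.recurrence_frame == "followup":
            recurrence_planning = transform_roi(recurrence, transform.inverse())
        else:
            recurrence_planning = recurrence
    except Exception as exc:
        raise StageError("transform-roi", str(exc)) from exc

    try:
        plans = []
        for plan in config.plans:
            dose = plan.dose
            if dose is None and plan.dose_path is not None:
                dose = rt_io.read_rtdose(config.resolve(plan.dose_path))
            plans.append(
                PlanInfo(
                    plan_label=plan.plan_label,
                    fraction_count=plan.fraction_count,
                    prescribed_dose_gy=plan.prescribed_dose_gy,
                    dose_path=plan.dose_path,
                    dose=dose,
                )
            )
    except Exception as exc:
        raise StageError("read-dose", str(exc)) from exc

    boost = _find_roi(rois, config.boost_name)
    try:
        report = analyze_case(
            patient_id=config.patient_id,
            planning_ct=planning,
            recurrence_roi=recurrence_planning,
            plans=plans,
            boost_roi=boost,
            transform=transform,
            transform_source=source,
            params=config.params,
            report=report,
        )
    except StageError:
        raise
    except Exception as exc:
        raise StageError("analyze", str(exc)) from exc

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        rt_io.write_report(report, out_dir / "report.csv", "csv")
        rt_io.write_report(report, out_dir / "report.json", "json")
        snapshot = {
            "patient_id": config.patient_id,
            "params": asdict(config.params),
            "registration": asdict(config.registration),
            "transform_source": report.transform_source,
            "transform": (
                report.transform.as_vector().tolist() if report.transform else None
            ),
        }
        with open(out_dir / "effective_config.yaml", "w") as fh:
            yaml.safe_dump(snapshot, fh, sort_keys=True)
    return report


def export_dvh(config: CaseConfig, structure_name: str, plan_label: str, path):
    """Compute and export the cumulative DVH of one structure vs one plan."""
    planning = rt_io.read_ct_series(config.resolve(config.planning_ct))
    rois = []
    for rel in config.structures + (config.recurrence_structures or []):
        rois.extend(rt_io.read_rtstruct(config.resolve(rel)))
    roi = _find_roi(rois, structure_name)
    if roi is None:
        raise StageError("dvh", f"structure {structure_name!r} not found")
    plan = next((p for p in config.plans if p.plan_label == plan_label), None)
    if plan is None:
        raise StageError("dvh", f"plan {plan_label!r} not found")
    dose = plan.dose or rt_io.read_rtdose(config.resolve(plan.dose_path))
    mask = voxelize(roi, planning, max_level=config.params.max_voxelization_level,
                    tolerance=config.params.voxelization_tolerance)
    samples = sample_dose(dose, mask)
    dvh = compute_dvh(samples, bin_width=config.params.dvh_bin_gy)
    return dvh.export_csv(path, structure=structure_name, plan=plan_label)
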