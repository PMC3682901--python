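"""Synthetic CT/dose/structure phantoms with analytically known answers.

The phantoms emulate the study conditions of an abdominal recurrence
analysis: a planning CT, a follow-up CT that differs from it by a known
rigid motion (follow-up acquisitions in oblique positioning can be rotated
by 20-60 degrees axially), optional body shrinkage emulating weight loss,
per-plan dose grids (base and sequential boost) and contoured structures.
Every fixture carries machine-readable expected values (closed-form volumes,
uniform-field dose statistics, sphere-union coverage fractions), so the full
pipeline can be checked end-to-end without any clinical data.

Fixtures are written as genuine DICOM through :mod:`rtrecur.rt_io`, so the
format code is exercised rather than bypassed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .geometry import ImageVolume
from .structures import ROI, Contour
from .transforms import RigidTransform

__all__ = [
    "SphereFeature",
    "BoxFeature",
    "StructureSpec",
    "DoseFieldSpec",
    "PhantomSpec",
    "Phantom",
    "make_phantom",
    "make_recurrence_fixture",
    "sphere_roi",
    "sphere_volume_ml",
]

AIR_HU = -1000.0
BODY_HU = 0.0


def sphere_volume_ml(radius_mm: float) -> float:
    return 4.0 / 3.0 * math.pi * radius_mm**3 / 1000.0


def _sphere_overlap_volume_ml(r1: float, r2: float, d: float) -> float:
    """Closed-form lens volume (ml) of two intersecting spheres."""
    if d >= r1 + r2:
        return 0.0
    if d <= abs(r1 - r2):
        return sphere_volume_ml(min(r1, r2))
    lens = (
        math.pi
        * (r1 + r2 - d) ** 2
        * (d**2 + 2 * d * (r1 + r2) - 3 * (r1 - r2) ** 2)
        / (12 * d)
    )
    return lens / 1000.0


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SphereFeature:
    center: tuple
    radius_mm: float
    hu: float


@dataclass(frozen=True)
class BoxFeature:
    center: tuple
    size_mm: tuple  # full extents (x, y, z)
    hu: float


@dataclass(frozen=True)
class StructureSpec:
    name: str
    shape: str  # "sphere" | "box"
    center: tuple
    size: tuple  # (radius,) for sphere, full extents for box

    def volume_ml(self) -> float:
        if self.shape == "sphere":
            return sphere_volume_ml(self.size[0])
        return float(np.prod(self.size)) / 1000.0


@dataclass(frozen=True)
class DoseFieldSpec:
    """Analytic dose field of one plan.

    kinds: ``uniform`` (prescription inside a spherical region, 0 outside;
    no region means the whole grid), ``linear_gradient`` (0 at the grid's low
    edge to ``prescribed_dose_gy`` at the high edge along ``axis``) and
    ``spherical_falloff`` (prescription inside ``radius_mm`` falling linearly
    to 0 over ``falloff_mm``).
    """

    label: str  # "base" | "boost"
    kind: str
    prescribed_dose_gy: float
    fraction_count: int
    center: tuple = (0.0, 0.0, 0.0)
    radius_mm: float | None = None
    falloff_mm: float = 20.0
    axis: int = 2


@dataclass(frozen=True)
class PhantomSpec:
    """Geometric phantom: grid, body ellipsoid, features, dose and motion."""

    shape: tuple = (36, 96, 96)            # (nz, ny, nx)
    spacing: tuple = (2.0, 2.0, 3.0)       # (x, y, z) mm
    body_semiaxes: tuple = (85.0, 70.0, 60.0)
    body_center: tuple = (0.0, 0.0, 0.0)
    features: tuple = (
        BoxFeature((0.0, 55.0, 0.0), (16.0, 16.0, 100.0), 700.0),   # spine
        BoxFeature((-45.0, -15.0, 5.0), (55.0, 45.0, 60.0), 60.0),  # liver-like
        SphereFeature((45.0, 35.0, -10.0), 14.0, 40.0),             # kidney
        SphereFeature((-45.0, 38.0, -8.0), 14.0, 40.0),             # kidney
        SphereFeature((30.0, -35.0, 12.0), 10.0, -800.0),           # bowel gas
    )
    structures: tuple = (
        StructureSpec("PTV", "sphere", (0.0, 10.0, 0.0), (35.0,)),
        StructureSpec("Boost", "sphere", (0.0, 10.0, 0.0), (20.0,)),
        StructureSpec("SpinalCord", "box", (0.0, 55.0, 0.0), (8.0, 8.0, 90.0)),
        StructureSpec("Recurrence", "sphere", (0.0, 10.0, 0.0), (12.0,)),
    )
    dose_fields: tuple = (
        DoseFieldSpec("base", "uniform", 44.5, 25, (0.0, 10.0, 0.0), 60.0),
        DoseFieldSpec("boost", "uniform", 9.0, 5, (0.0, 10.0, 0.0), 30.0),
    )
    ground_truth: RigidTransform = field(default_factory=RigidTransform)
    noise_sigma_hu: float = 10.0
    shrink_factor: float = 1.0
    seed: int = 0

    @property
    def origin(self) -> np.ndarray:
        nz, ny, nx = self.shape
        sx, sy, sz = self.spacing
        return np.array(
            [-(nx - 1) * sx / 2.0, -(ny - 1) * sy / 2.0, -(nz - 1) * sz / 2.0]
        )

    def physical_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        nz, ny, nx = self.shape
        sx, sy, sz = self.spacing
        lo = self.origin - 0.5 * np.array([sx, sy, sz])
        return lo, lo + np.array([nx * sx, ny * sy, nz * sz])


# ---------------------------------------------------------------------------
# analytic fields
# ---------------------------------------------------------------------------

def _hu_at(points: np.ndarray, spec: PhantomSpec, shrink: float) -> np.ndarray:
    hu = np.full(len(points), AIR_HU)
    semi = np.asarray(spec.body_semiaxes) * shrink
    rel = (points - np.asarray(spec.body_center)) / semi
    hu[np.sum(rel**2, axis=1) <= 1.0] = BODY_HU
    for feat in spec.features:
        if isinstance(feat, SphereFeature):
            inside = (
                np.sum((points - np.asarray(feat.center)) ** 2, axis=1)
                <= feat.radius_mm**2
            )
        else:
            half = 0.5 * np.asarray(feat.size_mm)
            inside = np.all(
                np.abs(points - np.asarray(feat.center)) <= half, axis=1
            )
        hu[inside] = feat.hu
    return hu


def _dose_at(points: np.ndarray, fld: DoseFieldSpec, lo, hi) -> np.ndarray:
    if fld.kind == "uniform":
        if fld.radius_mm is None:
            return np.full(len(points), fld.prescribed_dose_gy)
        inside = (
            np.sum((points - np.asarray(fld.center)) ** 2, axis=1)
            <= fld.radius_mm**2
        )
        return np.where(inside, fld.prescribed_dose_gy, 0.0)
    if fld.kind == "linear_gradient":
        a = fld.axis
        frac = (points[:, a] - lo[a]) / (hi[a] - lo[a])
        return fld.prescribed_dose_gy * np.clip(frac, 0.0, 1.0)
    if fld.kind == "spherical_falloff":
        r = np.sqrt(np.sum((points - np.asarray(fld.center)) ** 2, axis=1))
        excess = np.maximum(0.0, r - (fld.radius_mm or 0.0))
        return fld.prescribed_dose_gy * np.clip(1.0 - excess / fld.falloff_mm, 0.0, 1.0)
    raise ValueError(f"unknown dose field kind {fld.kind!r}")


# ---------------------------------------------------------------------------
# contour generation
# ---------------------------------------------------------------------------

def sphere_roi(
    name: str,
    center,
    radius_mm: float,
    slice_z: np.ndarray,
    n_vertices: int = 72,
    frame: str = "",
) -> ROI:
    """Per-slice circular contours of a sphere at the given slice positions."""
    cx, cy, cz = center
    contours = []
    theta = np.linspace(0.0, 2 * np.pi, n_vertices, endpoint=False)
    for z in slice_z:
        r2 = radius_mm**2 - (z - cz) ** 2
        if r2 <= 0:
            continue
        r = math.sqrt(r2)
        verts = np.column_stack(
            [cx + r * np.cos(theta), cy + r * np.sin(theta), np.full_like(theta, z)]
        )
        contours.append(Contour(verts))
    return ROI(name=name, contours=contours, frame_of_reference_id=frame)


def _box_roi(name, center, size, slice_z, frame="") -> ROI:
    cx, cy, cz = center
    hx, hy, hz = 0.5 * np.asarray(size)
    contours = []
    for z in slice_z:
        if abs(z - cz) > hz:
            continue
        verts = np.array(
            [
                [cx - hx, cy - hy, z],
                [cx + hx, cy - hy, z],
                [cx + hx, cy + hy, z],
                [cx - hx, cy + hy, z],
            ]
        )
        contours.append(Contour(verts))
    return ROI(name=name, contours=contours, frame_of_reference_id=frame)


def _structure_roi(s: StructureSpec, slice_z, frame="") -> ROI:
    if s.shape == "sphere":
        return sphere_roi(s.name, s.center, s.size[0], slice_z, frame=frame)
    if s.shape == "box":
        return _box_roi(s.name, s.center, s.size, slice_z, frame=frame)
    raise ValueError(f"unknown structure shape {s.shape!r}")


# ---------------------------------------------------------------------------
# phantom assembly
# ---------------------------------------------------------------------------

@dataclass
class Phantom:
    spec: PhantomSpec
    planning_ct: ImageVolume
    followup_ct: ImageVolume
    structures: dict            # name -> ROI, planning frame
    followup_structures: dict   # name -> ROI, follow-up frame
    doses: dict                 # label -> ImageVolume
    ground_truth: RigidTransform
    expected: dict
    paths: dict = field(default_factory=dict)


def _check_inside(name: str, lo, hi, center, half_extent) -> None:
    center = np.asarray(center, dtype=float)
    half = np.broadcast_to(np.asarray(half_extent, dtype=float), (3,))
    if np.any(center - half < lo) or np.any(center + half > hi):
        raise ValueError(f"feature/structure {name!r} extends outside the grid")


def make_phantom(spec: PhantomSpec, out_dir=None) -> Phantom:
    """Build a phantom case; optionally export it as DICOM + case config.

    The follow-up CT equals the planning CT moved by the ground-truth
    transform (evaluated analytically, so no resampling blur), with optional
    seeded Gaussian HU noise and body shrinkage.  Identical spec+seed gives
    bit-identical outputs.
    """
    lo, hi = spec.physical_bounds()
    for feat in spec.features:
        if isinstance(feat, SphereFeature):
            _check_inside("feature", lo, hi, feat.center, feat.radius_mm)
        else:
            _check_inside("feature", lo, hi, feat.center, 0.5 * np.asarray(feat.size_mm))
    for s in spec.structures:
        half = s.size[0] if s.shape == "sphere" else 0.5 * np.asarray(s.size)
        _check_inside(s.name, lo, hi, s.center, half)

    nz, ny, nx = spec.shape
    geometry = ImageVolume(
        np.zeros(spec.shape, dtype=np.float32), spec.origin, spec.spacing
    )
    points = geometry.voxel_center_points().reshape(-1, 3)

    rng = np.random.default_rng(spec.seed)
    planning = _hu_at(points, spec, 1.0)
    followup = _hu_at(
        spec.ground_truth.inverse().apply(points), spec, spec.shrink_factor
    )
    if spec.noise_sigma_hu > 0:
        planning = planning + rng.normal(0.0, spec.noise_sigma_hu, planning.shape)
        followup = followup + rng.normal(0.0, spec.noise_sigma_hu, followup.shape)

    from .rt_io import UIDFactory

    uids = UIDFactory(spec.seed)
    planning_frame = uids()
    followup_frame = uids()

    planning_ct = ImageVolume(
        np.round(planning).reshape(spec.shape),
        spec.origin,
        spec.spacing,
        frame_of_reference_id=planning_frame,
    )
    followup_ct = ImageVolume(
        np.round(followup).reshape(spec.shape),
        spec.origin,
        spec.spacing,
        frame_of_reference_id=followup_frame,
    )

    slice_z = geometry.slice_positions()
    structures = {
        s.name: _structure_roi(s, slice_z, frame=planning_frame)
        for s in spec.structures
    }
    # structures delineated on the follow-up scan live in the follow-up frame:
    # their planning-frame geometry carried through the ground-truth motion
    followup_structures = {}
    for name, roi in structures.items():
        moved = roi.transformed(spec.ground_truth)
        moved.frame_of_reference_id = followup_frame
        followup_structures[name] = moved

    dose_shape = (nz, 80, 80)
    dose_geom = ImageVolume(
        np.zeros(dose_shape, dtype=np.float32),
        np.array(
            [-(80 - 1) * 2.4 / 2.0, -(80 - 1) * 2.4 / 2.0, spec.origin[2]]
        ),
        np.array([2.4, 2.4, spec.spacing[2]]),
    )
    dose_points = dose_geom.voxel_center_points().reshape(-1, 3)
    doses = {}
    plans = []
    for fld in spec.dose_fields:
        values = _dose_at(dose_points, fld, lo, hi).reshape(dose_shape)
        doses[fld.label] = ImageVolume(
            values,
            dose_geom.origin.copy(),
            dose_geom.spacing.copy(),
            frame_of_reference_id=planning_frame,
        )
        plans.append(fld)

    expected = {
        "structure_volumes_ml": {s.name: s.volume_ml() for s in spec.structures},
        "ground_truth": spec.ground_truth.as_vector().tolist(),
    }
    rec = next((s for s in spec.structures if s.name == "Recurrence"), None)
    if rec is not None and rec.shape == "sphere":
        for fld in spec.dose_fields:
            if fld.kind != "uniform":
                continue
            if fld.radius_mm is not None:
                gap = np.linalg.norm(
                    np.asarray(rec.center) - np.asarray(fld.center)
                )
                if gap + rec.size[0] > fld.radius_mm:
                    continue  # recurrence not fully inside the uniform region
            expected.setdefault("dose_stats", {})[fld.label] = {
                "min_gy": fld.prescribed_dose_gy,
                "max_gy": fld.prescribed_dose_gy,
                "median_gy": fld.prescribed_dose_gy,
                "vol_in_isodose_ml": rec.volume_ml(),
                "pct_in_isodose": 100.0,
            }

    phantom = Phantom(
        spec=spec,
        planning_ct=planning_ct,
        followup_ct=followup_ct,
        structures=structures,
        followup_structures=followup_structures,
        doses=doses,
        ground_truth=spec.ground_truth,
        expected=expected,
    )
    if out_dir is not None:
        _export_phantom(phantom, Path(out_dir), uids)
    return phantom


def _export_phantom(phantom: Phantom, out_dir: Path, uids) -> None:
    from . import rt_io

    out_dir.mkdir(parents=True, exist_ok=True)
    spec = phantom.spec
    paths = {}
    rt_io.write_ct_series(phantom.planning_ct, out_dir / "planning_ct", uid_factory=uids)
    rt_io.write_ct_series(phantom.followup_ct, out_dir / "followup_ct", uid_factory=uids)
    paths["planning_ct"] = out_dir / "planning_ct"
    paths["followup_ct"] = out_dir / "followup_ct"

    planning_rois = [
        roi for name, roi in phantom.structures.items() if name != "Recurrence"
    ]
    paths["structures"] = rt_io.write_rtstruct(
        planning_rois,
        out_dir / "structures_planning.dcm",
        frame_of_reference=phantom.planning_ct.frame_of_reference_id,
        uid_factory=uids,
    )
    if "Recurrence" in phantom.followup_structures:
        paths["recurrence"] = rt_io.write_rtstruct(
            [phantom.followup_structures["Recurrence"]],
            out_dir / "structures_followup.dcm",
            frame_of_reference=phantom.followup_ct.frame_of_reference_id,
            uid_factory=uids,
        )

    plan_entries = []
    for fld in spec.dose_fields:
        dose_path = rt_io.write_rtdose(
            phantom.doses[fld.label],
            out_dir / f"dose_{fld.label}.dcm",
            uid_factory=uids,
        )
        paths[f"dose_{fld.label}"] = dose_path
        plan_entries.append(
            {
                "label": fld.label,
                "dose": dose_path.name,
                "prescribed_dose_gy": fld.prescribed_dose_gy,
                "fraction_count": fld.fraction_count,
            }
        )

    import yaml

    config = {
        "patient_id": f"phantom-{spec.seed}",
        "planning_ct": "planning_ct",
        "followup_cts": ["followup_ct"],
        "structures": ["structures_planning.dcm"],
        "recurrence_structures": ["structures_followup.dcm"],
        "recurrence_name": "Recurrence",
        "boost_name": "Boost",
        "ptv_name": "PTV",
        "plans": plan_entries,
        "registration": {"seed": spec.seed},
        "params": {},
    }
    config_path = out_dir / "case.yaml"
    with open(config_path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    paths["config"] = config_path
    phantom.paths = paths


# ---------------------------------------------------------------------------
# recurrence geometry fixtures
# ---------------------------------------------------------------------------

def make_recurrence_fixture(
    grid,
    boost_radius_mm: float = 20.0,
    extension_mm: float = 0.0,
    direction=(1.0, 0.0, 0.0),
    lobe_radius_mm: float = 8.0,
    center=(0.0, 0.0, 0.0),
    margins_mm=(10.0, 15.0, 20.0),
    containment_threshold: float = 0.95,
    n_vertices: int = 96,
) -> dict:
    """Boost sphere plus a recurrence protruding ``extension_mm`` beyond it.

    The recurrence is the union of the boost sphere and a lobe sphere whose
    far surface lies exactly ``extension_mm`` beyond the boost surface along
    ``direction``.  Expected coverage fractions of the margin shells, the
    membership flags at the containment threshold and the expected maximal
    extension are attached in closed form (sphere-union geometry).
    """
    if extension_mm < 0:
        raise ValueError("extension must be non-negative")
    from shapely.geometry import Point
    from shapely.ops import unary_union

    center = np.asarray(center, dtype=float)
    direction = np.asarray(direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    slice_z = grid.slice_positions()
    frame = getattr(grid, "frame_of_reference_id", "")

    boost = sphere_roi("Boost", center, boost_radius_mm, slice_z, frame=frame)

    if extension_mm == 0:
        recurrence = sphere_roi(
            "Recurrence", center, boost_radius_mm, slice_z, frame=frame
        )
        lobe_center = center
        lobe_distance = 0.0
    else:
        lobe_distance = boost_radius_mm + extension_mm - lobe_radius_mm
        lobe_center = center + direction * lobe_distance
        contours = []
        for z in slice_z:
            discs = []
            rb2 = boost_radius_mm**2 - (z - center[2]) ** 2
            if rb2 > 0:
                discs.append(
                    Point(center[0], center[1]).buffer(
                        math.sqrt(rb2), quad_segs=n_vertices // 4
                    )
                )
            rl2 = lobe_radius_mm**2 - (z - lobe_center[2]) ** 2
            if rl2 > 0:
                discs.append(
                    Point(lobe_center[0], lobe_center[1]).buffer(
                        math.sqrt(rl2), quad_segs=n_vertices // 4
                    )
                )
            if not discs:
                continue
            union = unary_union(discs)
            geoms = getattr(union, "geoms", [union])
            for geom in geoms:
                xy = np.asarray(geom.exterior.coords)[:-1]
                contours.append(
                    Contour(np.column_stack([xy, np.full(len(xy), z)]))
                )
        recurrence = ROI(
            name="Recurrence", contours=contours, frame_of_reference_id=frame
        )

    # closed-form expected values (sphere-union geometry)
    vb = sphere_volume_ml(boost_radius_mm)
    if extension_mm == 0:
        total = vb
        coverage = {"boost": 1.0}
        for m in margins_mm:
            coverage[f"boost+{m:g}mm"] = 1.0
    else:
        vl = sphere_volume_ml(lobe_radius_mm)
        lens_boost = _sphere_overlap_volume_ml(
            boost_radius_mm, lobe_radius_mm, lobe_distance
        )
        total = vb + vl - lens_boost
        coverage = {}
        for label, m in [("boost", 0.0)] + [
            (f"boost+{m:g}mm", float(m)) for m in margins_mm
        ]:
            inside = (
                vb
                + _sphere_overlap_volume_ml(
                    boost_radius_mm + m, lobe_radius_mm, lobe_distance
                )
                - lens_boost
            )
            coverage[label] = min(1.0, inside / total)

    membership = {k: v >= containment_threshold for k, v in coverage.items()}
    return {
        "boost": boost,
        "recurrence": recurrence,
        "expected": {
            "recurrence_vol_ml": total,
            "coverage": coverage,
            "membership": membership,
            "max_extension_cm": extension_mm / 10.0,
            "outfield_volume_ml": max(0.0, total - coverage[list(coverage)[-1]] * total),
        },
    }
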