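"""Rigid mutual-information registration of follow-up CT to the planning CT.

Follow-up scans in this workflow can be acquired in oblique positioning with
axial rotations of tens of degrees, far beyond the capture range of a local
optimizer; :func:`preinitialize` therefore aligns intensity centroids and
optionally applies a user-hinted axial rotation before the optimization
proper.  The optimization itself (Mattes mutual information over a
multi-resolution pyramid, Euler rigid transform) runs on ITK via SimpleITK;
the module's contract is the nine-component transform vector
``(tx, ty, tz, rpx, rpy, rpz, rx, ry, rz)`` described in
:mod:`rtrecur.transforms`, deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk

from .geometry import ImageVolume
from .structures import ROI
from .transforms import RigidTransform

__all__ = [
    "RegistrationParams",
    "RegistrationResult",
    "RegistrationDivergenceError",
    "preinitialize",
    "register_rigid",
    "apply_transform",
    "transform_roi",
]


@dataclass
class RegistrationParams:
    """Settings of the mutual-information registration (all configurable)."""

    histogram_bins: int = 50
    sampling_fraction: float = 0.25
    pyramid_levels: int = 3
    step_size_mm: float = 2.0
    min_step_mm: float = 1e-4
    max_iterations: int = 200
    convergence_tolerance: float = 1e-6
    seed: int = 0

    def __post_init__(self):
        if self.histogram_bins < 1 or self.pyramid_levels < 1 or self.max_iterations < 1:
            raise ValueError("counts must be >= 1")
        if not (0 < self.sampling_fraction <= 1):
            raise ValueError("sampling fraction must lie in (0, 1]")


@dataclass
class RegistrationResult:
    transform: RigidTransform
    metric_value: float  # final negative mutual information
    iterations: int
    params: RegistrationParams
    seed: int = field(init=False)

    def __post_init__(self):
        self.seed = self.params.seed


class RegistrationDivergenceError(RuntimeError):
    """Optimizer diverged; carries the best transform seen so far."""

    def __init__(self, message: str, best_transform: RigidTransform):
        super().__init__(message)
        self.best_transform = best_transform


# ---------------------------------------------------------------------------
# SimpleITK conversions
# ---------------------------------------------------------------------------

def _to_sitk(volume: ImageVolume) -> sitk.Image:
    img = sitk.GetImageFromArray(volume.voxels.astype(np.float64))
    img.SetOrigin(tuple(volume.origin))
    img.SetSpacing(tuple(volume.spacing))
    img.SetDirection(tuple(volume.orientation.ravel()))
    return img


def _to_sitk_euler(transform: RigidTransform) -> sitk.Euler3DTransform:
    t = sitk.Euler3DTransform()
    t.SetComputeZYX(True)  # matches the intrinsic z-y-x angle convention
    t.SetCenter(tuple(transform.rotation_point))
    t.SetRotation(*np.deg2rad(transform.angles_deg))
    t.SetTranslation(tuple(transform.translation))
    return t


def _from_sitk_euler(t: sitk.Euler3DTransform) -> RigidTransform:
    center = np.asarray(t.GetCenter())
    angles_deg = np.rad2deg([t.GetAngleX(), t.GetAngleY(), t.GetAngleZ()])
    translation = np.asarray(t.GetTranslation())
    return RigidTransform(
        *translation, *center, *angles_deg
    )


# ---------------------------------------------------------------------------
# pre-initialization
# ---------------------------------------------------------------------------

def _intensity_centroid(volume: ImageVolume) -> np.ndarray:
    """Physical centroid weighted by intensity above the volume minimum."""
    weights = volume.voxels - volume.voxels.min()
    total = float(weights.sum())
    if total <= 0:
        raise ValueError("all-constant image: intensity centroid undefined")
    nz, ny, nx = volume.shape
    wk = weights.sum(axis=(1, 2))
    wj = weights.sum(axis=(0, 2))
    wi = weights.sum(axis=(0, 1))
    idx = np.array(
        [
            float(np.dot(wi, np.arange(nx))) / total,
            float(np.dot(wj, np.arange(ny))) / total,
            float(np.dot(wk, np.arange(nz))) / total,
        ]
    )
    return volume.index_to_physical(idx)


def preinitialize(
    fixed: ImageVolume, moving: ImageVolume, hint_axial_deg: float | None = None
) -> RigidTransform:
    """Deterministic starting transform for heavily rotated acquisitions.

    Aligns intensity centroids; with a hint, additionally applies the hinted
    axial rotation (the known rotation of the moving acquisition relative to
    the fixed one) about the moving volume's centroid.
    """
    c_fixed = _intensity_centroid(fixed)
    c_moving = _intensity_centroid(moving)
    if hint_axial_deg is None:
        t = c_moving - c_fixed
        return RigidTransform(
            t[0], t[1], t[2], c_moving[0], c_moving[1], c_moving[2], 0.0, 0.0, 0.0
        )
    rotation = RigidTransform(
        0, 0, 0, c_moving[0], c_moving[1], c_moving[2], 0.0, 0.0, float(hint_axial_deg)
    )
    # choose t so the fixed centroid maps onto the moving centroid
    t = c_moving - rotation.apply(c_fixed)
    return RigidTransform(
        t[0], t[1], t[2], c_moving[0], c_moving[1], c_moving[2],
        0.0, 0.0, float(hint_axial_deg),
    )


# ---------------------------------------------------------------------------
# registration
# ---------------------------------------------------------------------------

def _foreground_overlap_fraction(
    fixed: ImageVolume, moving: ImageVolume, init: RigidTransform
) -> float:
    """Fraction of the fixed foreground mapping inside the moving volume."""
    fg = fixed.voxels > (fixed.voxels.min() + 1e-6)
    if not fg.any():
        fg = np.ones_like(fixed.voxels, dtype=bool)
    vox = np.argwhere(fg)
    if len(vox) > 20000:
        vox = vox[:: len(vox) // 20000 + 1]
    points = fixed.index_to_physical(vox[:, ::-1].astype(float))
    mapped = init.apply(points)
    idx = moving.physical_to_index(mapped)
    nz, ny, nx = moving.shape
    inside = np.all(
        (idx >= -0.5) & (idx <= np.array([nx, ny, nz]) - 0.5), axis=1
    )
    return float(inside.mean())


def _mask_image_from_rois(
    fixed: ImageVolume, rois: list[ROI], dilation_mm: float
) -> sitk.Image:
    from .dvh import voxelize
    from .metrics import expand_margin

    union = np.zeros(fixed.shape, dtype=bool)
    for roi in rois:
        mask = voxelize(roi, fixed, max_level=0)
        union |= mask.occupancy >= 0.5
    from .geometry import VoxelMask

    union_mask = VoxelMask(
        union.astype(float), fixed.origin, fixed.spacing, fixed.orientation
    )
    dilated = expand_margin(union_mask, dilation_mm)
    img = sitk.GetImageFromArray(dilated.occupancy.astype(np.uint8))
    img.SetOrigin(tuple(fixed.origin))
    img.SetSpacing(tuple(fixed.spacing))
    img.SetDirection(tuple(fixed.orientation.ravel()))
    return img


def register_rigid(
    fixed: ImageVolume,
    moving: ImageVolume,
    init: RigidTransform | None = None,
    params: RegistrationParams | None = None,
    structure_mask_rois: list[ROI] | None = None,
    mask_dilation_mm: float = 10.0,
    min_overlap_fraction: float = 0.10,
) -> RegistrationResult:
    """Mutual-information rigid registration refined from ``init``.

    The returned transform maps fixed-frame points into the moving frame.
    ``structure_mask_rois`` optionally restricts metric sampling to a dilated
    union of structures (e.g. PTV and spinal cord); default off.  Identical
    seeds give bit-identical transform parameters.
    """
    params = params or RegistrationParams()
    if init is None:
        init = preinitialize(fixed, moving)
    if _foreground_overlap_fraction(fixed, moving, init) < min_overlap_fraction:
        raise ValueError(
            "initial transform leaves less than "
            f"{100 * min_overlap_fraction:.0f}% of the fixed foreground inside "
            "the moving volume"
        )

    previous_threads = None
    try:
        previous_threads = sitk.ProcessObject.GetGlobalDefaultNumberOfThreads()
        sitk.ProcessObject.SetGlobalDefaultNumberOfThreads(1)
    except AttributeError:  # pragma: no cover
        pass

    try:
        fixed_img = _to_sitk(fixed)
        moving_img = _to_sitk(moving)

        method = sitk.ImageRegistrationMethod()
        method.SetMetricAsMattesMutualInformation(
            numberOfHistogramBins=params.histogram_bins
        )
        method.SetMetricSamplingStrategy(method.RANDOM)
        # seed 0 would mean "wall clock" to ITK; shift so every seed is reproducible
        method.SetMetricSamplingPercentage(
            params.sampling_fraction, (params.seed % (2**31 - 2)) + 1
        )
        if structure_mask_rois:
            method.SetMetricFixedMask(
                _mask_image_from_rois(fixed, structure_mask_rois, mask_dilation_mm)
            )
        method.SetInterpolator(sitk.sitkLinear)
        method.SetOptimizerAsRegularStepGradientDescent(
            learningRate=params.step_size_mm,
            minStep=params.min_step_mm,
            numberOfIterations=params.max_iterations,
            relaxationFactor=0.6,
            gradientMagnitudeTolerance=params.convergence_tolerance,
        )
        method.SetOptimizerScalesFromPhysicalShift()

        shrink = [2**l for l in range(params.pyramid_levels - 1, -1, -1)]
        smooth = [float(l) for l in range(params.pyramid_levels - 1, -1, -1)]
        method.SetShrinkFactorsPerLevel(shrink)
        method.SetSmoothingSigmasPerLevel(smooth)
        method.SmoothingSigmasAreSpecifiedInPhysicalUnitsOff()

        transform = _to_sitk_euler(init)
        method.SetInitialTransform(transform, inPlace=True)

        trace: list[tuple[int, float, np.ndarray]] = []

        def _record():
            trace.append(
                (
                    method.GetCurrentLevel(),
                    method.GetMetricValue(),
                    np.asarray(transform.GetParameters(), dtype=float),
                )
            )

        method.AddCommand(sitk.sitkIterationEvent, _record)
        method.Execute(fixed_img, moving_img)

        # divergence: the metric worsened monotonically through a whole level
        for level in range(params.pyramid_levels):
            values = [m for lv, m, _ in trace if lv == level]
            if len(values) >= 3 and all(b > a for a, b in zip(values, values[1:])):
                best_level, best_metric, best_params = min(
                    trace, key=lambda item: item[1]
                )
                best = sitk.Euler3DTransform()
                best.SetComputeZYX(True)
                best.SetCenter(transform.GetCenter())
                best.SetParameters(tuple(best_params))
                raise RegistrationDivergenceError(
                    f"metric worsened monotonically across pyramid level {level}",
                    _from_sitk_euler(best),
                )

        return RegistrationResult(
            transform=_from_sitk_euler(transform),
            metric_value=float(method.GetMetricValue()),
            iterations=len(trace),
            params=params,
        )
    finally:
        if previous_threads is not None:
            sitk.ProcessObject.SetGlobalDefaultNumberOfThreads(previous_threads)


# ---------------------------------------------------------------------------
# applying transforms
# ---------------------------------------------------------------------------

def apply_transform(
    moving: ImageVolume,
    transform: RigidTransform,
    target_grid: ImageVolume | None = None,
    interpolation: str = "linear",
    fill_value: float | None = None,
) -> ImageVolume:
    """Resample ``moving`` onto a target grid through a rigid transform.

    ``transform`` maps target-frame points into the moving frame (the
    registration output convention).  Out-of-field voxels receive
    ``fill_value`` (default: the moving volume's minimum) and their count is
    recorded in the result's flags.
    """
    target = target_grid if target_grid is not None else moving
    if fill_value is None:
        fill_value = float(moving.voxels.min())
    interpolator = {
        "linear": sitk.sitkLinear,
        "nearest": sitk.sitkNearestNeighbor,
    }[interpolation]

    moving_img = _to_sitk(moving)
    target_img = _to_sitk(target)
    resampled = sitk.Resample(
        moving_img,
        target_img,
        _to_sitk_euler(transform),
        interpolator,
        float(fill_value),
        sitk.sitkFloat64,
    )
    voxels = sitk.GetArrayFromImage(resampled)

    ones = sitk.Image(moving_img.GetSize(), sitk.sitkFloat32)
    ones.CopyInformation(moving_img)
    ones = ones + 1.0
    coverage = sitk.Resample(
        ones, target_img, _to_sitk_euler(transform), sitk.sitkNearestNeighbor, 0.0
    )
    n_outside = int((sitk.GetArrayFromImage(coverage) < 0.5).sum())

    flags = []
    if n_outside:
        flags.append(f"out-of-field voxels filled with {fill_value:g}: {n_outside}")
    return ImageVolume(
        voxels=voxels,
        origin=target.origin.copy(),
        spacing=target.spacing.copy(),
        orientation=target.orientation.copy(),
        frame_of_reference_id=target.frame_of_reference_id,
        flags=flags,
    )


def transform_roi(roi: ROI, transform: RigidTransform) -> ROI:
    """Map every contour vertex point-wise through a rigid transform."""
    return roi.transformed(transform)
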