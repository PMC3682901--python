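"""Regular-grid volumes in DICOM patient (LPS) coordinates.

All geometry is physical: millimetres, voxel indices 0-based, the origin at
the *center* of voxel ``(i, j, k) = (0, 0, 0)``.  Arrays are stored slice-major,
``array[k, j, i]`` for index ``(i, j, k)`` along the (x, y, z) grid axes, which
matches how DICOM slices stack and how SimpleITK exchanges buffers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ImageVolume", "VoxelMask", "validate_geometry", "grids_equal"]


def validate_geometry(origin, spacing, orientation):
    """Validate and canonicalize (origin, spacing, orientation).

    spacing must be strictly positive; orientation must be a 3x3 matrix whose
    columns are orthonormal direction cosines (within 1e-6).
    """
    origin = np.array(origin, dtype=float).reshape(3)
    spacing = np.array(spacing, dtype=float).reshape(3)
    orientation = np.array(orientation, dtype=float).reshape(3, 3)
    if not np.all(spacing > 0):
        raise ValueError(f"spacing must be strictly positive on all axes, got {spacing}")
    if not np.allclose(orientation.T @ orientation, np.eye(3), atol=1e-6):
        raise ValueError("orientation must be orthonormal within 1e-6")
    return origin, spacing, orientation


class _Gridded:
    """Mixin giving any gridded object its affine index<->physical mapping."""

    origin: np.ndarray
    spacing: np.ndarray
    orientation: np.ndarray

    @property
    def index_to_physical_matrix(self) -> np.ndarray:
        """3x3 matrix M with physical = origin + M @ (i, j, k)."""
        return self.orientation @ np.diag(self.spacing)

    @property
    def affine(self) -> np.ndarray:
        A = np.eye(4)
        A[:3, :3] = self.index_to_physical_matrix
        A[:3, 3] = self.origin
        return A

    def index_to_physical(self, idx) -> np.ndarray:
        """Map continuous voxel indices (..., 3) in (i, j, k) order to mm."""
        idx = np.asarray(idx, dtype=float)
        return idx @ self.index_to_physical_matrix.T + self.origin

    def physical_to_index(self, pts) -> np.ndarray:
        """Map physical points (..., 3) to continuous (i, j, k) indices."""
        pts = np.asarray(pts, dtype=float)
        M_inv = np.linalg.inv(self.index_to_physical_matrix)
        return (pts - self.origin) @ M_inv.T

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0

    @property
    def is_axis_aligned(self) -> bool:
        """True when grid axes coincide with the patient axes (identity cosines)."""
        return bool(np.allclose(self.orientation, np.eye(3), atol=1e-6))

    def slice_positions(self) -> np.ndarray:
        """Physical z position (mm) of each axial slice center."""
        nz = self._grid_array().shape[0]
        idx = np.zeros((nz, 3))
        idx[:, 2] = np.arange(nz)
        return self.index_to_physical(idx)[:, 2]

    def voxel_center_points(self) -> np.ndarray:
        """Physical centers of every voxel, shaped (nz, ny, nx, 3)."""
        nz, ny, nx = self._grid_array().shape
        kk, jj, ii = np.meshgrid(
            np.arange(nz), np.arange(ny), np.arange(nx), indexing="ij"
        )
        idx = np.stack([ii, jj, kk], axis=-1).astype(float)
        return self.index_to_physical(idx)

    def _grid_array(self) -> np.ndarray:  # pragma: no cover - overridden
        raise NotImplementedError

    def same_grid_as(self, other, atol: float = 1e-6) -> bool:
        return (
            self._grid_array().shape == other._grid_array().shape
            and np.allclose(self.origin, other.origin, atol=atol)
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.orientation, other.orientation, atol=atol)
        )


def grids_equal(a: _Gridded, b: _Gridded, atol: float = 1e-6) -> bool:
    """Whether two gridded objects share shape and geometry within ``atol`` mm."""
    return a.same_grid_as(b, atol=atol)


@dataclass
class ImageVolume(_Gridded):
    """A 3D scalar grid (CT in HU, or dose in Gy) with physical geometry.

    Attributes
    ----------
    voxels : ndarray, shape (nz, ny, nx)
        Scalar values, slice-major.
    origin : (3,) float
        Physical position (mm, LPS) of the center of voxel (0, 0, 0).
    spacing : (3,) float
        Voxel size along the (x, y, z) grid axes, mm.
    orientation : (3, 3) float
        Direction cosines; column j is the patient-space direction of grid
        axis j.
    frame_of_reference_id : str
        DICOM frame-of-reference UID, opaque.
    flags : list of str
        Non-fatal quality flags raised while reading (sum plan, frame
        mismatch, out-of-field counts, ...).
    """

    voxels: np.ndarray
    origin: np.ndarray
    spacing: np.ndarray
    orientation: np.ndarray = field(default_factory=lambda: np.eye(3))
    frame_of_reference_id: str = ""
    flags: list = field(default_factory=list)

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"voxels must be 3D, got ndim={self.voxels.ndim}")
        self.origin, self.spacing, self.orientation = validate_geometry(
            self.origin, self.spacing, self.orientation
        )

    def _grid_array(self) -> np.ndarray:
        return self.voxels

    @property
    def shape(self):
        return self.voxels.shape

    def geometry_like(self) -> "ImageVolume":
        """An empty volume sharing this geometry (for use as a target grid)."""
        return ImageVolume(
            np.zeros(self.shape, dtype=np.float32),
            self.origin.copy(),
            self.spacing.copy(),
            self.orientation.copy(),
            self.frame_of_reference_id,
        )


@dataclass
class VoxelMask(_Gridded):
    """Fractional-occupancy voxelization of a structure on a stated grid.

    ``occupancy`` holds the fraction of each voxel covered by the structure,
    in [0, 1].  ``level`` records the supersampling level actually used
    (in-plane subgrid factor ``2**level``).
    """

    occupancy: np.ndarray
    origin: np.ndarray
    spacing: np.ndarray
    orientation: np.ndarray = field(default_factory=lambda: np.eye(3))
    level: int = 0
    name: str = ""

    def __post_init__(self):
        self.occupancy = np.asarray(self.occupancy, dtype=float)
        if self.occupancy.ndim != 3:
            raise ValueError("occupancy must be 3D")
        if self.occupancy.size and (
            self.occupancy.min() < -1e-12 or self.occupancy.max() > 1 + 1e-12
        ):
            raise ValueError("occupancy values must lie in [0, 1]")
        self.occupancy = np.clip(self.occupancy, 0.0, 1.0)
        self.origin, self.spacing, self.orientation = validate_geometry(
            self.origin, self.spacing, self.orientation
        )

    def _grid_array(self) -> np.ndarray:
        return self.occupancy

    @property
    def shape(self):
        return self.occupancy.shape

    @property
    def volume_ml(self) -> float:
        return float(self.occupancy.sum()) * self.voxel_volume_ml

    def binarized(self, threshold: float = 0.5) -> "VoxelMask":
        """Binary version: occupancy >= threshold."""
        return VoxelMask(
            (self.occupancy >= threshold).astype(float),
            self.origin.copy(),
            self.spacing.copy(),
            self.orientation.copy(),
            level=self.level,
            name=self.name,
        )

    @classmethod
    def empty_like(cls, grid: _Gridded, name: str = "") -> "VoxelMask":
        return cls(
            np.zeros(grid._grid_array().shape, dtype=float),
            grid.origin.copy(),
            grid.spacing.copy(),
            grid.orientation.copy(),
            name=name,
        )
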