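"""Contoured structures (ROIs) in physical coordinates.

Structures stay in physical millimetres — never voxel units — until they are
voxelized, so rigid transforms and resampling act on them exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Contour", "ROI"]


@dataclass
class Contour:
    """One closed planar polygon; the first vertex implicitly follows the last."""

    vertices: np.ndarray  # (n, 3) physical mm

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("contour vertices must have shape (n, 3)")
        if len(self.vertices) < 3:
            raise ValueError("a contour needs at least 3 vertices")

    @property
    def z(self) -> float:
        """Representative axial position (mm) of the contour plane."""
        return float(self.vertices[:, 2].mean())

    @property
    def z_spread(self) -> float:
        return float(np.ptp(self.vertices[:, 2]))

    def is_axial(self, tol: float = 1e-3) -> bool:
        return self.z_spread <= tol


@dataclass
class ROI:
    """A named structure as a list of per-slice closed contours."""

    name: str
    contours: list = field(default_factory=list)
    frame_of_reference_id: str = ""
    flags: list = field(default_factory=list)

    def __post_init__(self):
        self.contours = [
            c if isinstance(c, Contour) else Contour(np.asarray(c)) for c in self.contours
        ]

    @property
    def is_empty(self) -> bool:
        return len(self.contours) == 0

    def all_vertices(self) -> np.ndarray:
        if self.is_empty:
            return np.zeros((0, 3))
        return np.vstack([c.vertices for c in self.contours])

    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        pts = self.all_vertices()
        if not len(pts):
            raise ValueError(f"ROI {self.name!r} has no contours")
        return pts.min(axis=0), pts.max(axis=0)

    def transformed(self, transform) -> "ROI":
        """Map every vertex point-wise through a rigid transform."""
        return ROI(
            name=self.name,
            contours=[Contour(transform.apply(c.vertices)) for c in self.contours],
            frame_of_reference_id=self.frame_of_reference_id,
            flags=list(self.flags),
        )
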