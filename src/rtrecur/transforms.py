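"""Nine-component rigid transforms.

A rigid motion is parameterized the way the analysis reports it:
``(tx, ty, tz, rpx, rpy, rpz, rx, ry, rz)`` — translation (mm), rotation
point (mm) and rotation angles (degrees).  Angles are intrinsic Euler angles
applied in z–y–x order about the rotation point, i.e. the rotation matrix is
``R = Rz(rz) @ Ry(ry) @ Rx(rx)`` and the point mapping is

    p' = R @ (p - rp) + rp + t.

In a registration the transform maps points of the *fixed* (planning) frame
into the *moving* (follow-up) frame — the resampling convention, so applying
it to the moving image pulls it onto the fixed grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = ["RigidTransform", "save_transform", "load_transform"]

CONVENTION = "euler-zyx-intrinsic-deg"


@dataclass(frozen=True)
class RigidTransform:
    tx: float = 0.0
    ty: float = 0.0
    tz: float = 0.0
    rpx: float = 0.0
    rpy: float = 0.0
    rpz: float = 0.0
    rx: float = 0.0
    ry: float = 0.0
    rz: float = 0.0

    # -- component views ---------------------------------------------------
    @property
    def translation(self) -> np.ndarray:
        return np.array([self.tx, self.ty, self.tz], dtype=float)

    @property
    def rotation_point(self) -> np.ndarray:
        return np.array([self.rpx, self.rpy, self.rpz], dtype=float)

    @property
    def angles_deg(self) -> np.ndarray:
        return np.array([self.rx, self.ry, self.rz], dtype=float)

    @property
    def rotation_matrix(self) -> np.ndarray:
        # intrinsic z-y-x: R = Rz @ Ry @ Rx
        return Rotation.from_euler(
            "ZYX", [self.rz, self.ry, self.rx], degrees=True
        ).as_matrix()

    def as_vector(self) -> np.ndarray:
        """The nine components in report order."""
        return np.array(
            [self.tx, self.ty, self.tz, self.rpx, self.rpy, self.rpz,
             self.rx, self.ry, self.rz],
            dtype=float,
        )

    # -- mapping -----------------------------------------------------------
    @property
    def matrix(self) -> np.ndarray:
        """Homogeneous 4x4 matrix of the point mapping."""
        R = self.rotation_matrix
        if abs(np.linalg.det(R) - 1.0) > 1e-9:
            raise ValueError("rotation is not a proper rotation (det != +1)")
        A = np.eye(4)
        A[:3, :3] = R
        rp = self.rotation_point
        A[:3, 3] = rp + self.translation - R @ rp
        return A

    def apply(self, points) -> np.ndarray:
        """Map physical points, shape (..., 3)."""
        pts = np.asarray(points, dtype=float)
        A = self.matrix
        return pts @ A[:3, :3].T + A[:3, 3]

    # -- group operations --------------------------------------------------
    @classmethod
    def from_matrix(cls, A, rotation_point=(0.0, 0.0, 0.0)) -> "RigidTransform":
        A = np.asarray(A, dtype=float)
        R = A[:3, :3]
        if abs(np.linalg.det(R) - 1.0) > 1e-9:
            raise ValueError("matrix is not a proper rigid motion (det != +1)")
        rz, ry, rx = Rotation.from_matrix(R).as_euler("ZYX", degrees=True)
        rp = np.asarray(rotation_point, dtype=float)
        t = A[:3, :3] @ rp + A[:3, 3] - rp  # t = A(rp) - rp
        return cls(t[0], t[1], t[2], rp[0], rp[1], rp[2], rx, ry, rz)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: the transform mapping p -> self(other(p)).

        The result keeps ``self``'s rotation point.
        """
        return RigidTransform.from_matrix(
            self.matrix @ other.matrix, self.rotation_point
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform.from_matrix(
            np.linalg.inv(self.matrix), self.rotation_point
        )

    def with_rotation_point(self, rotation_point) -> "RigidTransform":
        """Re-express the same rigid motion about a different rotation point."""
        return RigidTransform.from_matrix(self.matrix, rotation_point)

    def is_identity(self, atol: float = 1e-9) -> bool:
        return bool(np.allclose(self.matrix, np.eye(4), atol=atol))


def save_transform(transform: RigidTransform, path) -> None:
    """Serialize as a plain-text key=value file with the convention declared."""
    lines = [f"convention={CONVENTION}", "units=mm,deg"]
    for key, value in zip(
        ("tx", "ty", "tz", "rpx", "rpy", "rpz", "rx", "ry", "rz"),
        transform.as_vector(),
    ):
        lines.append(f"{key}={float(value):.17g}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def load_transform(path) -> RigidTransform:
    values = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or "=" not in line:
                continue
            key, _, raw = line.partition("=")
            values[key.strip()] = raw.strip()
    convention = values.pop("convention", CONVENTION)
    values.pop("units", None)
    if convention != CONVENTION:
        raise ValueError(f"unsupported transform convention {convention!r}")
    return RigidTransform(**{k: float(v) for k, v in values.items()})
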