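"""Shared rigid-body geometry primitives.

Conventions used throughout the package:

* lengths in millimetres, angles in degrees at every public surface;
* rigid transforms map segment-local coordinates to world coordinates,
  rotation applied before translation (``world = R @ local + t``);
* coordinate systems are right-handed orthonormal triads.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation as _Rotation

from .errors import DegenerateGeometryError

__all__ = [
    "unit",
    "angle_between_deg",
    "RigidTransform",
    "ACS",
    "mirror_matrix",
]

#: numerical tolerance for orthogonality / unit-determinant checks
ORTHO_TOL = 1e-9


def unit(v: np.ndarray) -> np.ndarray:
    """Return ``v`` normalised to unit length.

    Raises
    ------
    DegenerateGeometryError
        If ``v`` has (near-)zero norm.
    """
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise DegenerateGeometryError("cannot normalise a zero-length vector")
    return v / n


def angle_between_deg(a: np.ndarray, b: np.ndarray) -> float:
    """Unsigned angle between two vectors in degrees, in [0, 180]."""
    ua, ub = unit(a), unit(b)
    return float(np.degrees(np.arccos(np.clip(ua @ ub, -1.0, 1.0))))


def mirror_matrix(axis: int = 1) -> np.ndarray:
    """Reflection matrix across the plane normal to the given axis.

    ``axis=1`` mirrors across the sagittal (x-z) plane, the operation used
    to derive left-side geometry from right-side geometry.
    """
    m = np.eye(3)
    m[axis, axis] = -1.0
    return m


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid transform: ``world = rotation @ local + translation``."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.all(np.isfinite(R)) or not np.all(np.isfinite(t)):
            raise ValueError("non-finite rigid transform")
        err = np.abs(R @ R.T - np.eye(3)).max()
        if err > 1e-8 or abs(np.linalg.det(R) - 1.0) > 1e-8:
            raise ValueError(
                f"rotation is not proper orthogonal (orthogonality error {err:.3g}, "
                f"det {np.linalg.det(R):.12g})"
            )
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_quaternion(cls, qw: float, qx: float, qy: float, qz: float,
                        translation=(0.0, 0.0, 0.0)) -> "RigidTransform":
        """Build from a (w, x, y, z) unit quaternion; normalised on input."""
        q = np.array([qx, qy, qz, qw], dtype=float)  # scipy scalar-last
        n = np.linalg.norm(q)
        if n < 1e-12:
            raise ValueError("zero-norm quaternion")
        R = _Rotation.from_quat(q / n).as_matrix()
        return cls(R, np.asarray(translation, dtype=float))

    def to_quaternion(self) -> np.ndarray:
        """Rotation as a (w, x, y, z) unit quaternion with non-negative w."""
        q = _Rotation.from_matrix(self.rotation).as_quat()  # x, y, z, w
        q = np.array([q[3], q[0], q[1], q[2]])
        if q[0] < 0:
            q = -q
        return q

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map local points (shape (3,) or (n, 3)) to world coordinates."""
        p = np.asarray(points, dtype=float)
        return p @ self.rotation.T + self.translation

    def apply_direction(self, d: np.ndarray) -> np.ndarray:
        """Rotate a direction vector (no translation)."""
        return self.rotation @ np.asarray(d, dtype=float)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return ``self ∘ other`` (apply ``other`` first)."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)


@dataclass(frozen=True)
class ACS:
    """An anatomical coordinate system: origin plus right-handed triad.

    Axes are stored as unit vectors in whatever frame the ACS lives in
    (segment-local when built from morphology, world after animation).
    """

    name: str
    side: str
    origin: np.ndarray
    X: np.ndarray
    Y: np.ndarray
    Z: np.ndarray
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        o = np.asarray(self.origin, dtype=float).reshape(3)
        X = np.asarray(self.X, dtype=float).reshape(3)
        Y = np.asarray(self.Y, dtype=float).reshape(3)
        Z = np.asarray(self.Z, dtype=float).reshape(3)
        for v, lbl in ((X, "X"), (Y, "Y"), (Z, "Z")):
            if abs(np.linalg.norm(v) - 1.0) > ORTHO_TOL * 10:
                raise DegenerateGeometryError(
                    f"{self.name}: axis {lbl} is not unit length")
        dots = (abs(X @ Y), abs(X @ Z), abs(Y @ Z))
        if max(dots) > ORTHO_TOL * 10:
            raise DegenerateGeometryError(
                f"{self.name}: axes not orthogonal (max |dot| = {max(dots):.3g})")
        if np.linalg.det(np.column_stack([X, Y, Z])) < 0:
            raise DegenerateGeometryError(
                f"{self.name}: axes form a left-handed triad")
        object.__setattr__(self, "origin", o)
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "Y", Y)
        object.__setattr__(self, "Z", Z)

    @property
    def rotation(self) -> np.ndarray:
        """3x3 matrix with columns X, Y, Z (maps ACS coords to frame coords)."""
        return np.column_stack([self.X, self.Y, self.Z])

    def transformed(self, T: RigidTransform) -> "ACS":
        """The same ACS expressed after applying a rigid transform."""
        return ACS(self.name, self.side,
                   T.apply(self.origin),
                   T.apply_direction(self.X),
                   T.apply_direction(self.Y),
                   T.apply_direction(self.Z),
                   dict(self.meta))

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "side": self.side,
            "origin": self.origin.tolist(),
            "X": self.X.tolist(),
            "Y": self.Y.tolist(),
            "Z": self.Z.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ACS":
        return cls(d["name"], d["side"], np.array(d["origin"]),
                   np.array(d["X"]), np.array(d["Y"]), np.array(d["Z"]))


def register_transform(local: ACS, target_world: ACS) -> RigidTransform:
    """Rigid transform that maps a segment carrying ``local`` so that the
    local ACS lands exactly on ``target_world`` (origins and axes aligned).
    """
    R = target_world.rotation @ local.rotation.T
    t = target_world.origin - R @ local.origin
    return RigidTransform(R, t)
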