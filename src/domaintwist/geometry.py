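"""Rigid-body superposition and rotation algebra.

Kabsch least-squares superposition (via SVD, reflection-corrected),
axis-angle conversion with stable branches near 0 and 180 degrees, and the
swing-twist decomposition that extracts the signed rotation component about
a fixed axis.  The twist is the scalar used throughout the package as the
inter-domain rotation angle: for a unit quaternion (w, v) of the rotation
and unit axis u,

    twist = 2 * atan2(v . u, w),   wrapped to (-180, 180] degrees,

with the quaternion sign fixed by w >= 0 to remove the double cover.  A
rotation constructed as a pure rotation by theta about u has twist exactly
theta; composing it with any swing about an axis perpendicular to u leaves
the twist unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "RigidTransform",
    "AxisAngle",
    "DegenerateGeometryError",
    "kabsch_superpose",
    "rotation_to_axis_angle",
    "axis_angle_to_matrix",
    "twist_about_axis",
]

_ORTHO_TOL = 1e-9


class DegenerateGeometryError(ValueError):
    """Point sets too small or collinear for a unique superposition."""


def _check_rotation(matrix: np.ndarray) -> np.ndarray:
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape != (3, 3):
        raise ValueError(f"rotation must be 3x3, got {matrix.shape}")
    err = np.abs(matrix.T @ matrix - np.eye(3)).max()
    if err > 1e-6:
        raise ValueError(f"matrix is not orthonormal (max deviation {err:.2e})")
    if np.linalg.det(matrix) < 0:
        raise ValueError("matrix is a reflection (det = -1), not a proper rotation")
    return matrix


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion ``x -> R x + t`` (rotation then translation, A)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "rotation", _check_rotation(self.rotation))
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "translation", t)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))


@dataclass(frozen=True)
class AxisAngle:
    """Unit axis and non-negative angle in [0, 180] degrees."""

    axis: np.ndarray
    angle_deg: float

    def __post_init__(self) -> None:
        axis = np.asarray(self.axis, dtype=float).reshape(3)
        norm = np.linalg.norm(axis)
        if norm == 0:
            raise ValueError("axis must be non-zero")
        object.__setattr__(self, "axis", axis / norm)
        if not 0.0 <= self.angle_deg <= 180.0 + 1e-12:
            raise ValueError(f"angle {self.angle_deg} outside [0, 180] degrees")


def kabsch_superpose(
    mobile_coords: np.ndarray, target_coords: np.ndarray
) -> tuple[RigidTransform, float]:
    """Least-squares proper rigid superposition of ``mobile`` onto ``target``.

    Returns the transform minimizing the RMSD of the transformed mobile
    points onto the target over all proper rigid motions, and that minimal
    RMSD in Angstrom.  Reflections are excluded (determinant branch of the
    SVD solution corrected), so chirality is preserved.

    Raises :class:`DegenerateGeometryError` for fewer than 3 points or
    collinear point sets, where the rotation is not unique.
    """
    mobile = np.asarray(mobile_coords, dtype=float)
    target = np.asarray(target_coords, dtype=float)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError(f"point sets must share shape (N, 3); got {mobile.shape} vs {target.shape}")
    n = mobile.shape[0]
    if n < 3:
        raise DegenerateGeometryError(f"need >= 3 points for superposition, got {n}")
    mob_c = mobile.mean(axis=0)
    tgt_c = target.mean(axis=0)
    mob0 = mobile - mob_c
    tgt0 = target - tgt_c
    # collinearity check: second singular value of either centered cloud
    for cloud, label in ((mob0, "mobile"), (tgt0, "target")):
        sv = np.linalg.svd(cloud, compute_uv=False)
        if sv[1] <= 1e-9 * max(sv[0], 1.0):
            raise DegenerateGeometryError(f"{label} points are collinear; rotation underdetermined")
    rot, _ = Rotation.align_vectors(tgt0, mob0)
    matrix = rot.as_matrix()
    # recompute the residual directly: scipy's rssd loses precision near zero
    rmsd = float(np.sqrt(np.mean(np.sum((mob0 @ matrix.T - tgt0) ** 2, axis=1))))
    translation = tgt_c - matrix @ mob_c
    return RigidTransform(matrix, translation), rmsd


def rotation_to_axis_angle(rotation_matrix: np.ndarray) -> AxisAngle:
    """Axis and angle (degrees, [0, 180]) of a proper rotation matrix.

    The identity maps to angle 0 with axis (0, 0, 1) by convention.  The
    conversion goes through the quaternion representation, which is stable
    near both the 0- and 180-degree branches.
    """
    matrix = _check_rotation(rotation_matrix)
    rotvec = Rotation.from_matrix(matrix).as_rotvec()
    angle = np.linalg.norm(rotvec)
    if angle < 1e-14:
        return AxisAngle(np.array([0.0, 0.0, 1.0]), 0.0)
    return AxisAngle(rotvec / angle, float(np.degrees(angle)))


def axis_angle_to_matrix(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotation matrix for a rotation by ``angle_deg`` about unit ``axis``."""
    axis = np.asarray(axis, dtype=float).reshape(3)
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise ValueError("axis must be non-zero")
    return Rotation.from_rotvec(axis / norm * np.radians(angle_deg)).as_matrix()


def twist_about_axis(rotation_matrix: np.ndarray, axis: np.ndarray) -> float:
    """Signed twist (degrees, (-180, 180]) of a rotation about a fixed axis.

    Swing-twist decomposition: the rotation factors uniquely as
    ``R = R_swing . R_twist(axis, t)`` with the swing axis perpendicular to
    ``axis``; this returns t.  Pure rotations about ``axis`` return their
    own angle exactly; twist is antisymmetric under matrix transposition.
    """
    matrix = _check_rotation(rotation_matrix)
    axis = np.asarray(axis, dtype=float).reshape(3)
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise ValueError("axis must have non-zero norm")
    axis = axis / norm
    quat = Rotation.from_matrix(matrix).as_quat()  # (x, y, z, w)
    w, v = quat[3], quat[:3]
    if w < 0:  # fix double cover
        w, v = -w, -v
    twist = 2.0 * np.arctan2(float(v @ axis), w)
    deg = np.degrees(twist)
    # wrap to (-180, 180]
    deg = (deg + 180.0) % 360.0 - 180.0
    if deg == -180.0:
        deg = 180.0
    return float(deg)
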