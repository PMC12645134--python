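"""Proper rigid 3-D transforms in world (mm) coordinates.

A :class:`RigidTransform` maps a point ``p`` to ``R @ p + t``.  Composition is
written ``A @ B``, meaning *apply B first, then A* — the usual operator
convention, so ``(A @ B)(p) == A(B(p))``.

Euler angles use the extrinsic x-y-z convention, ``R = Rz @ Ry @ Rx``, with
angles in degrees.  Per-axis rotation values are convention dependent;
rotation-invariant quantities (total rotation, MTPM) are preferred wherever
results are compared across tools.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

_ORTHO_ATOL = 1e-6

_EULER_ORDER = "xyz"  # extrinsic: R = Rz @ Ry @ Rx


@dataclass(frozen=True)
class RigidTransform:
    """6-DOF rotation + translation; the registration currency of the package."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.array(self.rotation, dtype=float).reshape(3, 3)
        t = np.array(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if not np.allclose(R @ R.T, np.eye(3), atol=_ORTHO_ATOL):
            raise ValueError("rotation matrix is not orthonormal")
        if np.linalg.det(R) < 0.0:
            raise ValueError("rotation matrix is a reflection (det < 0)")

    # -- constructors ------------------------------------------------------
    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(3), np.zeros(3))

    @staticmethod
    def from_euler(
        angles_deg, translation=(0.0, 0.0, 0.0)
    ) -> "RigidTransform":
        """Build from extrinsic x-y-z Euler angles in degrees."""
        R = Rotation.from_euler(_EULER_ORDER, np.asarray(angles_deg, float), degrees=True)
        return RigidTransform(R.as_matrix(), np.asarray(translation, float))

    @staticmethod
    def from_axis_angle(
        axis, angle_deg: float, translation=(0.0, 0.0, 0.0), center=None
    ) -> "RigidTransform":
        """Rotation of ``angle_deg`` about ``axis``; if ``center`` is given the
        rotation axis passes through it."""
        axis = np.asarray(axis, float)
        axis = axis / np.linalg.norm(axis)
        R = Rotation.from_rotvec(np.deg2rad(angle_deg) * axis).as_matrix()
        t = np.asarray(translation, float)
        if center is not None:
            c = np.asarray(center, float)
            t = t + c - R @ c
        return RigidTransform(R, t)

    @staticmethod
    def from_dict(d: dict) -> "RigidTransform":
        return RigidTransform(np.asarray(d["R"], float), np.asarray(d["t_mm"], float))

    # -- algebra -----------------------------------------------------------
    def apply(self, points: np.ndarray) -> np.ndarray:
        """Transform an (N, 3) array (or a single 3-vector) of mm points."""
        pts = np.asarray(points, float)
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """``self.compose(other)`` applies ``other`` first."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    __matmul__ = compose

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    def orthonormalized(self) -> "RigidTransform":
        """Project the rotation back onto SO(3) (guards numerical drift)."""
        U, _, Vt = np.linalg.svd(self.rotation)
        R = U @ np.diag([1.0, 1.0, np.linalg.det(U @ Vt)]) @ Vt
        return RigidTransform(R, self.translation)

    # -- summaries ---------------------------------------------------------
    def euler_deg(self) -> np.ndarray:
        return Rotation.from_matrix(self.rotation).as_euler(_EULER_ORDER, degrees=True)

    def rotation_angle_deg(self) -> float:
        """Magnitude of the rotation (angle of the axis-angle form), degrees."""
        return float(np.rad2deg(np.linalg.norm(Rotation.from_matrix(self.rotation).as_rotvec())))

    def translation_norm(self) -> float:
        return float(np.linalg.norm(self.translation))

    def is_identity(self, atol_mm: float = 1e-9, atol_deg: float = 1e-9) -> bool:
        return (
            self.translation_norm() <= atol_mm
            and self.rotation_angle_deg() <= atol_deg
        )

    def allclose(self, other: "RigidTransform", atol_mm=1e-9, atol_deg=1e-9) -> bool:
        delta = self.inverse() @ other
        return delta.is_identity(atol_mm=atol_mm, atol_deg=atol_deg)

    def to_dict(self) -> dict:
        return {"R": self.rotation.tolist(), "t_mm": self.translation.tolist()}


def random_rigid(
    rng: np.random.Generator,
    max_translation_mm: float,
    max_rotation_deg: float,
    center=None,
) -> RigidTransform:
    """Uniform per-component translation and per-Euler-angle rotation within
    the given magnitudes (the repositioning model of the phantom series).
    If ``center`` is given the rotation pivots there — without it a small
    rotation about the world origin would drag a distant scene sideways by
    far more than ``max_translation_mm``."""
    t = rng.uniform(-max_translation_mm, max_translation_mm, size=3)
    ang = rng.uniform(-max_rotation_deg, max_rotation_deg, size=3)
    T = RigidTransform.from_euler(ang, t)
    if center is not None:
        c = np.asarray(center, float)
        T = RigidTransform(T.rotation, T.translation + c - T.rotation @ c)
    return T
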