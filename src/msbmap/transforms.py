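"""Proper rigid transforms in the package's canonical anatomical frame.

Axis convention, fixed everywhere in :mod:`msbmap`:

* ``x`` — mediolateral (mm), positive toward the subject's left;
* ``y`` — anterior-posterior (mm), positive anterior;
* ``z`` — longitudinal / craniocaudal (mm), positive superior.

The frame is right-handed.  All distances are millimetres; STL carries no
unit information, so meshes are interpreted as mm throughout.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = ["RigidTransform"]

_ORTHO_TOL = 1e-9


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid transform ``p -> R @ p + t``.

    ``rotation`` must be a proper orthogonal 3x3 matrix (det = +1,
    orthonormal columns, both within 1e-9).
    """

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if R.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.isfinite(R).all() or not np.isfinite(t).all():
            raise ValueError("non-finite transform")
        if abs(np.linalg.det(R) - 1.0) > 1e-6:
            raise ValueError("rotation determinant must be +1")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-6):
            raise ValueError("rotation must be orthonormal")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    # -- constructors ------------------------------------------------------
    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform()

    @staticmethod
    def from_euler_deg(angles_xyz: tuple[float, float, float],
                       translation: tuple[float, float, float] = (0.0, 0.0, 0.0)
                       ) -> "RigidTransform":
        """Intrinsic x-y-z Euler rotation (degrees) followed by a translation."""
        R = Rotation.from_euler("XYZ", angles_xyz, degrees=True).as_matrix()
        return RigidTransform(R, np.asarray(translation, dtype=float))

    @staticmethod
    def rotation_about(axis: str, angle_deg: float) -> "RigidTransform":
        R = Rotation.from_euler(axis, angle_deg, degrees=True).as_matrix()
        return RigidTransform(R, np.zeros(3))

    @staticmethod
    def translation_of(t: tuple[float, float, float]) -> "RigidTransform":
        return RigidTransform(np.eye(3), np.asarray(t, dtype=float))

    # -- algebra -----------------------------------------------------------
    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def compose(self, inner: "RigidTransform") -> "RigidTransform":
        """Return ``self o inner`` (``inner`` is applied first)."""
        return RigidTransform(self.rotation @ inner.rotation,
                              self.rotation @ inner.translation + self.translation)

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    def rotation_angle_deg(self) -> float:
        """Axis-angle magnitude of the rotation part, in degrees."""
        return float(np.degrees(np.linalg.norm(
            Rotation.from_matrix(self.rotation).as_rotvec())))

    def to_dict(self) -> dict:
        return {"rotation": self.rotation.tolist(),
                "translation": self.translation.tolist(),
                "convention": "x mediolateral / y anterior / z superior (mm)"}
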