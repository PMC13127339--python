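"""Proper rigid transforms (rotation + translation) in millimetres.

All bone poses, humeral superposition corrections and screw motions in this
package are represented by :class:`RigidTransform`.  The rotation part is a
3x3 proper orthogonal matrix (det = +1); the translation is a 3-vector in mm.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

_ORTHO_TOL = 1e-9


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid motion ``x -> R x + t``.

    Parameters
    ----------
    rotation : (3, 3) ndarray
        Proper orthogonal matrix, ``R^T R = I`` and ``det R = +1`` within
        1e-9.
    translation : (3,) ndarray
        Translation in mm.
    """

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        err = np.abs(R.T @ R - np.eye(3)).max()
        if err > 1e-6:
            raise ValueError(f"rotation is not orthogonal (max deviation {err:.2e})")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation is a reflection (det < 0)")
        if err > _ORTHO_TOL:
            # renormalize mild numerical drift via SVD projection
            U, _, Vt = np.linalg.svd(R)
            Rn = U @ Vt
            if np.linalg.det(Rn) < 0:
                U[:, -1] *= -1.0
                Rn = U @ Vt
            object.__setattr__(self, "rotation", Rn)

    # -- constructors ----------------------------------------------------
    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_matrix(cls, matrix: np.ndarray) -> "RigidTransform":
        """Build from a 4x4 homogeneous matrix (row-major)."""
        M = np.asarray(matrix, dtype=float).reshape(4, 4)
        return cls(M[:3, :3], M[:3, 3])

    @classmethod
    def from_rotvec(cls, rotvec_deg, translation=(0.0, 0.0, 0.0)) -> "RigidTransform":
        R = Rotation.from_rotvec(np.asarray(rotvec_deg, float), degrees=True).as_matrix()
        return cls(R, np.asarray(translation, float))

    # -- algebra ---------------------------------------------------------
    @property
    def matrix(self) -> np.ndarray:
        """4x4 homogeneous matrix."""
        M = np.eye(4)
        M[:3, :3] = self.rotation
        M[:3, 3] = self.translation
        return M

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply to one point or an (n, 3) array of points."""
        p = np.asarray(points, dtype=float)
        return p @ self.rotation.T + self.translation

    def apply_vector(self, vectors: np.ndarray) -> np.ndarray:
        """Rotate direction vectors (translation ignored)."""
        return np.asarray(vectors, dtype=float) @ self.rotation.T

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return ``self ∘ other`` (apply `other` first, then `self`)."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return self.compose(other)

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    def rotation_angle_deg(self) -> float:
        """Magnitude of the rotation part in degrees."""
        rv = Rotation.from_matrix(self.rotation).as_rotvec(degrees=True)
        return float(np.linalg.norm(rv))

    def is_close(self, other: "RigidTransform", atol: float = 1e-9) -> bool:
        return bool(
            np.allclose(self.rotation, other.rotation, atol=atol)
            and np.allclose(self.translation, other.translation, atol=atol)
        )

    # -- serialization ---------------------------------------------------
    def to_json_dict(self) -> dict:
        """Row-major 4x4 matrix, the on-disk format for transforms."""
        return {"matrix": self.matrix.tolist()}

    @classmethod
    def from_json_dict(cls, d: dict) -> "RigidTransform":
        return cls.from_matrix(np.asarray(d["matrix"], dtype=float))


def screw_motion(direction, point, angle_deg: float, pitch_mm_per_deg: float = 0.0) -> RigidTransform:
    """Rigid motion rotating about the line (point, direction) with axial pitch.

    Rotation is right-handed about `direction` by `angle_deg`; every point is
    additionally translated along `direction` by ``pitch_mm_per_deg * angle_deg``.
    """
    d = np.asarray(direction, dtype=float)
    n = np.linalg.norm(d)
    if n < 1e-12:
        raise ValueError("screw axis direction must be non-zero")
    d = d / n
    p = np.asarray(point, dtype=float).reshape(3)
    R = Rotation.from_rotvec(d * np.deg2rad(angle_deg)).as_matrix()
    t = p - R @ p + d * (pitch_mm_per_deg * angle_deg)
    return RigidTransform(R, t)
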