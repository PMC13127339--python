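"""Rotation-axis extraction and anatomical axis-change angles.

The relative motion of a forearm bone between two scan positions is reduced
to its finite helical (screw) axis: a line, a rotation angle about it and
an axial translation rate.  The extension axis (maximum extension vs 90
degrees) and flexion axis (maximum flexion vs 90 degrees) are compared in
the coronal plane (varus-valgus) and the axial plane (internal-external
rotation) of a humeral anatomical frame built from landmarks.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .transforms import RigidTransform, screw_motion

#: below this rotation magnitude the axis is numerically unreliable
#: (the severely stiff elbow degenerate case)
MIN_ANGLE_DEG = 5.0


@dataclass(frozen=True)
class AnatomicalFrame:
    """Right-handed humeral frame: mediolateral, anterior, proximal."""

    origin: np.ndarray
    medlat: np.ndarray
    anterior: np.ndarray
    proximal: np.ndarray

    def __post_init__(self):
        M = np.column_stack([self.medlat, self.anterior, self.proximal])
        if np.abs(M.T @ M - np.eye(3)).max() > 1e-9 or np.linalg.det(M) < 0:
            raise ValueError("frame axes must form a right-handed orthonormal triad")


@dataclass(frozen=True)
class AxisResult:
    """Finite helical axis of a rigid motion.

    `point` is the point on the axis closest to the frame origin;
    `pitch_mm_per_deg` is the translation along the axis per degree.
    """

    direction: np.ndarray
    point: np.ndarray
    angle_deg: float
    pitch_mm_per_deg: float

    def __post_init__(self):
        if abs(np.linalg.norm(self.direction) - 1.0) > 1e-9:
            raise ValueError("direction must be a unit vector")
        if self.angle_deg < 0:
            raise ValueError("angle_deg must be >= 0")

    def reconstruct(self) -> RigidTransform:
        """The rigid motion this axis represents (round-trip of `screw_axis`)."""
        return screw_motion(self.direction, self.point, self.angle_deg,
                            self.pitch_mm_per_deg)


@dataclass(frozen=True)
class AxisChange:
    """Flexion-axis shift relative to the extension axis (degrees).

    Valgus and internal rotation are positive, per the right-elbow
    convention; left elbows are mirrored at load time.
    """

    varus_valgus_deg: float
    int_ext_deg: float

    def __post_init__(self):
        if not (abs(self.varus_valgus_deg) < 90 and abs(self.int_ext_deg) < 90):
            raise ValueError("axis-change angles must lie in (-90, 90)")


def humeral_frame(landmarks: dict) -> AnatomicalFrame:
    """Anatomical frame from the epicondyles and a proximal shaft point.

    mediolateral = medial - lateral epicondyle; proximal = shaft direction
    orthogonalized against it; anterior completes the right-handed triad.
    The coronal plane is span(medlat, proximal), the axial plane
    span(medlat, anterior).
    """
    try:
        med = np.asarray(landmarks["medial_epicondyle"], float)
        lat = np.asarray(landmarks["lateral_epicondyle"], float)
        shaft = np.asarray(landmarks["humeral_shaft_proximal"], float)
    except KeyError as e:
        raise ValueError(f"missing landmark {e}") from e
    origin = 0.5 * (med + lat)
    ml = med - lat
    n_ml = np.linalg.norm(ml)
    if n_ml < 1e-9:
        raise ValueError("epicondyle landmarks coincide")
    ml = ml / n_ml
    up = shaft - origin
    up = up - (up @ ml) * ml
    n_up = np.linalg.norm(up)
    if n_up < 1e-9:
        raise ValueError("landmarks are collinear")
    up = up / n_up
    ant = np.cross(up, ml)
    return AnatomicalFrame(origin, ml, ant, up)


def screw_axis(t: RigidTransform, min_angle_deg: float = MIN_ANGLE_DEG,
               reference_direction=(1.0, 0.0, 0.0)) -> AxisResult:
    """Finite helical axis of a proper rigid motion.

    The direction and angle come from the rotation part; the axis point is
    the least-squares fixed point of the screw motion closest to the
    origin; the pitch is the axial translation per degree.  The direction
    sign is canonicalized to have a positive component along
    `reference_direction` (the frame's mediolateral axis in pipeline use).
    """
    rv = Rotation.from_matrix(t.rotation).as_rotvec()
    angle_rad = float(np.linalg.norm(rv))
    angle_deg = np.rad2deg(angle_rad)
    if angle_deg < min_angle_deg:
        raise ValueError(
            f"rotation angle {angle_deg:.2f} deg is below {min_angle_deg} deg; "
            "axis unreliable (motion arc too small)"
        )
    d = rv / angle_rad
    axial = float(t.translation @ d)
    # fixed point of the screw: (R - I) p = -t_perp, solved in the plane
    # orthogonal to the axis
    t_perp = t.translation - axial * d
    A = t.rotation - np.eye(3)
    p, *_ = np.linalg.lstsq(A, -t_perp, rcond=None)
    p = p - (p @ d) * d  # closest point to the origin on the axis
    ref = np.asarray(reference_direction, float)
    if d @ ref < 0:
        # same motion re-expressed about the flipped direction: rotation by
        # (360 - angle) about -d, with the axial translation sign flipped
        d = -d
        axial = -axial
        angle_deg = 360.0 - angle_deg
    return AxisResult(d, p, angle_deg, axial / angle_deg)


def axis_change(extension_axis: AxisResult, flexion_axis: AxisResult,
                frame: AnatomicalFrame) -> AxisChange:
    """Signed in-plane angles between the two axis directions.

    varus-valgus: angle between the coronal-plane projections, measured
    about the anterior normal (valgus positive); internal-external: angle
    between the axial-plane projections about the proximal normal (internal
    positive).
    """
    vv = _plane_angle(extension_axis.direction, flexion_axis.direction,
                      frame.anterior)
    ie = _plane_angle(extension_axis.direction, flexion_axis.direction,
                      frame.proximal)
    return AxisChange(vv, ie)


def _plane_angle(e: np.ndarray, f: np.ndarray, normal: np.ndarray) -> float:
    ep = e - (e @ normal) * normal
    fp = f - (f @ normal) * normal
    if min(np.linalg.norm(ep), np.linalg.norm(fp)) < 1e-6:
        raise ValueError("axis direction is degenerate after in-plane projection")
    return float(np.rad2deg(np.arctan2(normal @ np.cross(ep, fp), ep @ fp)))
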