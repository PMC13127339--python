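"""Rigid superposition of bone models across scan positions.

The humeral models from the three scan positions are superimposed
(centroid + principal-axes initialization, then point-to-point ICP with a
closed-form Kabsch step), and forearm-bone motion between positions is then
expressed in the common humeral frame.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh
from scipy.spatial import cKDTree

from .transforms import RigidTransform

#: default ICP controls
DEFAULT_MAX_ITER = 100
DEFAULT_TOL_MM = 1e-4
DEFAULT_SUBSAMPLE = 5000
#: an ICP solution with residual above this is reported as not converged
#: (same-bone scans of one patient superimpose far more tightly)
DEFAULT_MAX_RMS_MM = 1.0


@dataclass(frozen=True)
class RegistrationResult:
    transform: RigidTransform
    rms_mm: float
    iterations: int
    converged: bool

    def __post_init__(self):
        if self.rms_mm < 0:
            raise ValueError("rms_mm must be >= 0")


def kabsch(source_points: np.ndarray, target_points: np.ndarray) -> RigidTransform:
    """Least-squares rigid transform mapping paired `source` onto `target`.

    Closed-form SVD solution with the reflection corrected to a proper
    rotation.  Requires at least three non-collinear pairs.
    """
    src = np.asarray(source_points, float)
    tgt = np.asarray(target_points, float)
    if src.shape != tgt.shape or src.ndim != 2 or src.shape[1] != 3:
        raise ValueError("source and target must be matching (n, 3) arrays")
    if len(src) < 3:
        raise ValueError("need at least 3 point pairs")
    sc = src.mean(axis=0)
    tc = tgt.mean(axis=0)
    s0 = src - sc
    # collinearity check on the source cloud
    sv = np.linalg.svd(s0, compute_uv=False)
    if sv[1] < max(1e-9, 1e-9 * sv[0]):
        raise ValueError("points are collinear or degenerate")
    H = s0.T @ (tgt - tc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = tc - R @ sc
    return RigidTransform(R, t)


def _principal_axes(points: np.ndarray):
    c = points.mean(axis=0)
    cov = np.cov((points - c).T)
    w, V = np.linalg.eigh(cov)
    # descending eigenvalue order
    V = V[:, ::-1]
    if np.linalg.det(V) < 0:
        V[:, 2] *= -1.0
    return c, V


def initial_alignment(source_points: np.ndarray, target_points: np.ndarray) -> RigidTransform:
    """Centroid + principal-axes initialization.

    The axis signs are ambiguous; the four proper sign combinations are
    tried and the one with the lowest nearest-neighbour cost wins (the scan
    poses differ mainly by forearm position, so this disambiguation is
    rarely stressed for humeri).
    """
    sc, SV = _principal_axes(source_points)
    tc, TV = _principal_axes(target_points)
    tree = cKDTree(target_points)
    best = None
    for flip in ((1, 1, 1), (1, -1, -1), (-1, 1, -1), (-1, -1, 1)):
        R = (TV * np.asarray(flip)) @ SV.T
        T = RigidTransform(R, tc - R @ sc)
        d, _ = tree.query(T.apply(source_points[::7]))
        cost = float(np.mean(d**2))
        if best is None or cost < best[0]:
            best = (cost, T)
    return best[1]


def icp_register(source_mesh: trimesh.Trimesh, target_mesh: trimesh.Trimesh,
                 init: RigidTransform | None = None,
                 max_iter: int = DEFAULT_MAX_ITER,
                 tol_mm: float = DEFAULT_TOL_MM,
                 subsample: int = DEFAULT_SUBSAMPLE,
                 max_rms_mm: float = DEFAULT_MAX_RMS_MM,
                 trim_fraction: float = 0.0,
                 seed: int = 0) -> RegistrationResult:
    """Point-to-point ICP of `source_mesh` vertices onto `target_mesh`.

    Iterates nearest-neighbour correspondence + Kabsch until the RMS change
    drops below `tol_mm` or `max_iter` is reached.  The per-iteration RMS is
    monotone non-increasing.  `converged` additionally requires the final
    RMS to be below `max_rms_mm`, so registering unrelated shapes is
    reported as a failure with the best transform found.

    `trim_fraction` discards that fraction of worst correspondences from
    each Kabsch step (trimmed ICP), making the alignment robust to genuine
    shape differences such as resected osteophytes on post-operative bones.
    """
    if len(source_mesh.vertices) == 0 or len(target_mesh.vertices) == 0:
        raise ValueError("meshes must be non-empty")
    if not 0.0 <= trim_fraction < 0.5:
        raise ValueError("trim_fraction must be in [0, 0.5)")
    src_all = source_mesh.vertices.view(np.ndarray)
    rng = np.random.default_rng(seed)
    if len(src_all) > subsample:
        idx = rng.choice(len(src_all), subsample, replace=False)
        src = src_all[idx]
    else:
        src = src_all
    tgt = target_mesh.vertices.view(np.ndarray)
    tree = cKDTree(tgt)
    T = initial_alignment(src, tgt) if init is None else init
    n_keep = max(3, int(round(len(src) * (1.0 - trim_fraction))))
    prev_rms = np.inf
    rms = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        moved = T.apply(src)
        d, j = tree.query(moved)
        if n_keep < len(src):
            keep = np.argsort(d)[:n_keep]
        else:
            keep = slice(None)
        rms = float(np.sqrt(np.mean(d[keep] ** 2)))
        T = kabsch(src[keep], tgt[j[keep]])
        if prev_rms - rms < tol_mm:
            break
        prev_rms = rms
    converged = (prev_rms - rms < tol_mm) and (rms <= max_rms_mm)
    return RegistrationResult(T, rms, it, converged)


def superimpose_humeri(humeri: dict, **icp_kwargs) -> dict:
    """Superimpose the three humeral models onto the 90-degree scan.

    `humeri` maps pose name -> humeral mesh for the poses
    ``max_extension``, ``ninety``, ``max_flexion``.  Returns pose name ->
    RegistrationResult whose transforms map that pose's world frame into
    the reference (90-degree) frame; the reference entry is the identity.
    """
    required = {"max_extension", "ninety", "max_flexion"}
    if set(humeri) != required:
        raise ValueError(f"expected humeri for poses {sorted(required)}")
    ref = humeri["ninety"]
    out = {"ninety": RegistrationResult(RigidTransform.identity(), 0.0, 0, True)}
    for pose in ("max_extension", "max_flexion"):
        out[pose] = icp_register(humeri[pose], ref, **icp_kwargs)
    return out


def relative_motion(bone_pose_a: RigidTransform, bone_pose_b: RigidTransform,
                    humeral_correction_a: RigidTransform,
                    humeral_correction_b: RigidTransform) -> RigidTransform:
    """Forearm-bone motion from pose a to pose b in the common humeral frame.

    Each world pose is first corrected into the reference frame by its
    scan's humeral superposition transform; the relative motion is then the
    transform taking the corrected pose a to the corrected pose b.
    """
    Pa = humeral_correction_a @ bone_pose_a
    Pb = humeral_correction_b @ bone_pose_b
    return Pb @ Pa.inverse()
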