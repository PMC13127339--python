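"""Impinging-osteophyte detection and sizing.

The forearm bones are extrapolated from the scanned terminal positions to
the simulated full-extension (0 degree) and full-flexion (140 degree)
positions about the extracted rotation axes.  Regions of the ulna/radius
surface lying inside the humerus are the impinging osteophytes: they are
clustered into connected components, sized (maximum penetration depth, the
resection depth a surgeon would remove), and assigned to the five
anatomical measurement regions by partition planes through the olecranon
tip and the trochlea-capitellum boundary.

All elbow angles in this module are flexion-positive (0 = full extension,
140 = full flexion); clinical extension deficits are the negated values.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components as _cc

from . import registration as reg
from .kinematics import (AnatomicalFrame, AxisChange, AxisResult, axis_change,
                         humeral_frame, screw_axis)
from .meshquery import MeshDistance, sample_surface
from .regions import EXTENSION_REGIONS, FLEXION_REGIONS, RegionLabel
from .transforms import RigidTransform, screw_motion

SIMULATED_EXTENSION_DEG = 0.0
SIMULATED_FLEXION_DEG = 140.0

#: components shallower than the 0.1 mm reporting precision are mesh noise
MIN_COMPONENT_WIDTH_MM = 0.1


class StageError(RuntimeError):
    """Pipeline failure with the responsible stage attached."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass(frozen=True)
class MeasureConfig:
    """Tunable controls of the measurement pipeline."""

    sample_density_per_mm2: float = 8.0   # forearm surface sample density
    voxel_pitch_mm: float = 0.4           # component volume integration
    min_component_width_mm: float = MIN_COMPONENT_WIDTH_MM
    width_method: str = "depth"           # 'depth' or 'caliper'
    min_angle_deg: float = 5.0            # screw-axis reliability guard
    icp_max_iter: int = reg.DEFAULT_MAX_ITER
    icp_tol_mm: float = reg.DEFAULT_TOL_MM
    icp_subsample: int = reg.DEFAULT_SUBSAMPLE
    icp_max_rms_mm: float = reg.DEFAULT_MAX_RMS_MM
    side: str = "right"                   # left elbows mirrored at load
    seed: int = 0

    def __post_init__(self):
        if self.width_method not in ("depth", "caliper"):
            raise ValueError("width_method must be 'depth' or 'caliper'")
        if self.side not in ("right", "left"):
            raise ValueError("side must be 'right' or 'left'")

    def icp_kwargs(self) -> dict:
        return dict(max_iter=self.icp_max_iter, tol_mm=self.icp_tol_mm,
                    subsample=self.icp_subsample, max_rms_mm=self.icp_max_rms_mm,
                    seed=self.seed)


@dataclass
class OverlapRegion:
    """One connected component of forearm surface inside the humerus."""

    component_id: int
    bone: str
    points: np.ndarray            # (n, 3) inside surface samples
    depths_mm: np.ndarray         # unsigned distance to the humeral surface
    volume_mm3: float
    region: RegionLabel | None = None

    def __post_init__(self):
        if len(self.points) == 0:
            raise ValueError("an OverlapRegion must contain points")
        if self.volume_mm3 < 0:
            raise ValueError("volume must be >= 0")

    @property
    def max_depth_mm(self) -> float:
        return float(self.depths_mm.max())

    def caliper_extent_mm(self) -> float:
        """Largest pairwise extent of the component (sensitivity alternative)."""
        pts = self.points
        if len(pts) > 512:
            sel = np.linspace(0, len(pts) - 1, 512).astype(int)
            pts = pts[sel]
        d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
        return float(np.sqrt(d2.max()))


@dataclass(frozen=True)
class RegionWidths:
    """Per-region maximum widths (mm, 0.1 mm precision) for one position."""

    widths: dict
    position_deg: float

    def __post_init__(self):
        if self.position_deg not in (SIMULATED_EXTENSION_DEG, SIMULATED_FLEXION_DEG):
            raise ValueError("position must be 0 or 140 degrees")
        allowed = (EXTENSION_REGIONS if self.position_deg == SIMULATED_EXTENSION_DEG
                   else FLEXION_REGIONS)
        full = {}
        for region in RegionLabel:
            w = float(self.widths.get(region, 0.0))
            if w < 0:
                raise ValueError("widths must be >= 0")
            if w > 0 and region not in allowed:
                raise ValueError(f"{region} cannot be populated at "
                                 f"{self.position_deg:g} degrees")
            full[region] = round(w, 1)
        object.__setattr__(self, "widths", full)

    def __getitem__(self, region: RegionLabel) -> float:
        return self.widths[RegionLabel(region)]


@dataclass(frozen=True)
class CaseResult:
    """Complete per-case output of the measurement pipeline."""

    case_id: str
    extension_deg: float          # clinical, <= 0
    flexion_deg: float
    axis_change: AxisChange
    widths_0: RegionWidths
    widths_140: RegionWidths

    def __post_init__(self):
        if not (self.extension_deg <= 0.0 <= self.flexion_deg):
            raise ValueError("expected extension_deg <= 0 <= flexion_deg")

    def width(self, region: RegionLabel) -> float:
        region = RegionLabel(region)
        if region in EXTENSION_REGIONS:
            return self.widths_0[region]
        return self.widths_140[region]

    def to_json_dict(self) -> dict:
        return {
            "case_id": self.case_id,
            "extension_deg": round(self.extension_deg, 1),
            "flexion_deg": round(self.flexion_deg, 1),
            "axis_change": {
                "varus_valgus_deg": round(self.axis_change.varus_valgus_deg, 1),
                "int_ext_deg": round(self.axis_change.int_ext_deg, 1),
            },
            "widths_0": {str(k): v for k, v in self.widths_0.widths.items()},
            "widths_140": {str(k): v for k, v in self.widths_140.widths.items()},
        }


@dataclass
class MeasurementContext:
    """Reference-frame by-products of `measure_elbow`, for residual analysis."""

    reference_meshes: dict        # bone -> mesh at the 90-degree scan, ref frame
    extension_axis: AxisResult
    flexion_axis: AxisResult
    frame: AnatomicalFrame
    landmarks: dict


# ---------------------------------------------------------------------------
# operations


def extrapolate_pose(bone_mesh: trimesh.Trimesh, axis: AxisResult,
                     current_angle_deg: float, target_angle_deg: float) -> trimesh.Trimesh:
    """Rotate a bone about the screw axis from its current elbow angle to a
    target angle (flexion-positive scale; +1 degree about the canonical
    axis direction is one degree of flexion), translating along the axis by
    the screw pitch.
    """
    if not (np.isfinite(current_angle_deg) and np.isfinite(target_angle_deg)):
        raise ValueError("angles must be finite")
    delta = target_angle_deg - current_angle_deg
    if abs(delta) > 90.0:
        raise ValueError(f"extrapolation of {delta:.1f} deg is beyond plausibility "
                         "(limit 90 deg)")
    out = bone_mesh.copy()
    if delta != 0.0:
        T = screw_motion(axis.direction, axis.point, delta, axis.pitch_mm_per_deg)
        out.apply_transform(T.matrix)
    return out


def overlap_region(forearm_mesh: trimesh.Trimesh, humerus_mesh: trimesh.Trimesh,
                   config: MeasureConfig = MeasureConfig(),
                   bone: str = "forearm",
                   humerus_distance: MeshDistance | None = None) -> list:
    """Connected components of forearm surface penetrating the humerus.

    Dense seeded surface samples of the forearm bone are classified by
    signed distance to the humerus; inside samples are clustered by sample
    adjacency; per-component volume is integrated on a voxel grid over the
    component's bounding box.  Returns an empty list when disjoint.
    """
    if not forearm_mesh.is_watertight or not humerus_mesh.is_watertight:
        raise ValueError("overlap detection requires watertight meshes")
    hd = humerus_distance or MeshDistance(humerus_mesh)
    # sample only forearm faces near the humerus AABB (the distal shaft can
    # never overlap and dominates the surface area)
    lo, hi = humerus_mesh.bounds
    fc = forearm_mesh.triangles_center
    near = np.all((fc >= lo - 1.0) & (fc <= hi + 1.0), axis=1)
    if not near.any():
        return []
    sub = forearm_mesh.submesh([np.nonzero(near)[0]], append=True)
    pts = sample_surface(sub, config.sample_density_per_mm2, config.seed)
    box = np.all((pts >= lo - 0.25) & (pts <= hi + 0.25), axis=1)
    pts = pts[box]
    if len(pts) == 0:
        return []
    sd = hd.signed_distance(pts)
    inside = sd < 0
    if not inside.any():
        return []
    ipts = pts[inside]
    depths = -sd[inside]
    labels = _cluster(ipts, radius=2.5 / np.sqrt(config.sample_density_per_mm2))
    out = []
    fd = None
    for cid in range(labels.max() + 1):
        m = labels == cid
        if depths[m].max() < config.min_component_width_mm:
            continue
        comp_pts = ipts[m]
        pad = 1.0
        bounds = np.array([comp_pts.min(0) - pad, comp_pts.max(0) + pad])
        if fd is None:
            fd = MeshDistance(forearm_mesh)
        vol = _component_volume(fd, hd, bounds, config.voxel_pitch_mm)
        out.append(OverlapRegion(len(out), bone, comp_pts, depths[m], vol))
    return out


def _cluster(points: np.ndarray, radius: float) -> np.ndarray:
    from scipy.spatial import cKDTree

    tree = cKDTree(points)
    pairs = tree.query_pairs(radius, output_type="ndarray")
    n = len(points)
    if len(pairs):
        data = np.ones(len(pairs))
        adj = coo_matrix((data, (pairs[:, 0], pairs[:, 1])), shape=(n, n))
    else:
        adj = coo_matrix((n, n))
    _, labels = _cc(adj, directed=False)
    return labels


def _component_volume(fd: MeshDistance, hd: MeshDistance, bounds, pitch: float) -> float:
    from .meshquery import inside_fraction

    lo, hi = bounds
    axes = [np.arange(lo[i] + pitch / 2, hi[i], pitch) for i in range(3)]
    if any(len(a) == 0 for a in axes):
        return 0.0
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    ff = inside_fraction(fd.signed_distance(grid), pitch)
    occ = ff > 0
    if not occ.any():
        return 0.0
    fh = inside_fraction(hd.signed_distance(grid[occ]), pitch)
    return float((ff[occ] * fh).sum()) * pitch**3


def penetration_width(component: OverlapRegion,
                      humerus_mesh: trimesh.Trimesh | None = None,
                      method: str = "depth") -> float:
    """Maximum width of one impinging osteophyte, to 0.1 mm.

    The default reading is the maximum penetration depth of the forearm
    surface into the humerus (the resection depth); `method='caliper'`
    reports the component's largest extent instead, for sensitivity
    analysis.
    """
    if method == "depth":
        return round(component.max_depth_mm, 1)
    if method == "caliper":
        return round(component.caliper_extent_mm(), 1)
    raise ValueError("method must be 'depth' or 'caliper'")


def label_regions(components: list, landmarks: dict, position_deg: float,
                  frame: AnatomicalFrame | None = None,
                  method: str = "depth") -> RegionWidths:
    """Assign overlap components to measurement regions and report widths.

    Partition planes: the sagittal plane through the olecranon tip splits
    the posteromedial from the posterolateral humeroulnar joint; the
    trochlea-capitellum boundary plane splits the ulnar from the radial
    side; anterior vs posterior regions follow the simulated position.  A
    single component spanning the olecranon-tip plane contributes its
    medial-side maximum to PM and its lateral-side maximum to PL (the
    continuous-osteophyte rule).
    """
    if position_deg not in (SIMULATED_EXTENSION_DEG, SIMULATED_FLEXION_DEG):
        raise ValueError("position must be 0 or 140 degrees")
    if frame is None:
        frame = humeral_frame(landmarks)
    try:
        tip = np.asarray(landmarks["olecranon_tip"], float)
        tc = np.asarray(landmarks["trochlea_capitellum_boundary"], float)
    except KeyError as e:
        raise ValueError(f"missing landmark {e}") from e
    ml = frame.medlat
    widths: dict = {}
    for comp in components:
        s_tc = (comp.points - tc) @ ml
        s_tip = (comp.points - tip) @ ml
        if position_deg == SIMULATED_EXTENSION_DEG:
            masks = {
                RegionLabel.POST_CAP: s_tc < 0,
                RegionLabel.PM_HUJ: (s_tc >= 0) & (s_tip >= 0),
                RegionLabel.PL_HUJ: (s_tc >= 0) & (s_tip < 0),
            }
        else:
            masks = {
                RegionLabel.RAD_FOSSA: s_tc < 0,
                RegionLabel.ANT_HUJ: s_tc >= 0,
            }
        for region, m in masks.items():
            if not m.any():
                continue
            if method == "caliper":
                sub = OverlapRegion(comp.component_id, comp.bone,
                                    comp.points[m], comp.depths_mm[m], 0.0)
                w = sub.caliper_extent_mm()
            else:
                w = float(comp.depths_mm[m].max())
            widths[region] = max(widths.get(region, 0.0), w)
    return RegionWidths(widths, position_deg)


def mirror_sagittal(meshes: dict, landmarks: dict) -> tuple:
    """Mirror a left elbow across the sagittal plane into the right-elbow
    convention (x -> -x in the scan frame), fixing the face winding."""
    M = np.diag([-1.0, 1.0, 1.0, 1.0])
    out_meshes = {}
    for k, m in meshes.items():
        mm = m.copy()
        mm.apply_transform(M)
        mm.invert()
        out_meshes[k] = mm
    out_lm = {k: np.asarray(v, float) * np.array([-1.0, 1.0, 1.0])
              for k, v in landmarks.items()}
    return out_meshes, out_lm


def measure_elbow(pose_meshes: dict, landmarks: dict,
                  config: MeasureConfig = MeasureConfig(),
                  case_id: str = "case",
                  return_context: bool = False):
    """Run the full pre-operative simulation pipeline on one elbow.

    `pose_meshes` maps pose name (``max_extension``, ``ninety``,
    ``max_flexion``) to a dict of bone meshes (``humerus``, ``ulna``,
    ``radius``) in that scan's world frame; `landmarks` are humeral
    landmarks in the 90-degree scan frame.  Returns a :class:`CaseResult`
    (optionally with a :class:`MeasurementContext`).
    """
    if config.side == "left":
        pose_meshes = {p: dict(b) for p, b in pose_meshes.items()}
        mirrored = {}
        for p in pose_meshes:
            pose_meshes[p], mirrored_lm = mirror_sagittal(pose_meshes[p], landmarks)
        landmarks = mirrored_lm

    # 1. superimpose the humeral models onto the 90-degree scan
    try:
        humeri = {p: pose_meshes[p]["humerus"] for p in
                  ("max_extension", "ninety", "max_flexion")}
    except KeyError as e:
        raise StageError("inputs", f"missing pose or bone: {e}")
    sup = reg.superimpose_humeri(humeri, **config.icp_kwargs())
    for pose, res in sup.items():
        if not res.converged:
            raise StageError("superimpose_humeri",
                             f"humeral registration failed for pose {pose} "
                             f"(rms {res.rms_mm:.2f} mm)")
    corr = {p: sup[p].transform for p in sup}

    # 2. ulnar motion between positions via same-bone ICP, in the common frame
    frame = humeral_frame(landmarks)

    def bone_motion(pose_a, pose_b):
        r = reg.icp_register(pose_meshes[pose_a]["ulna"], pose_meshes[pose_b]["ulna"],
                             **config.icp_kwargs())
        if not r.converged:
            raise StageError("relative_motion",
                             f"ulna registration {pose_a}->{pose_b} failed "
                             f"(rms {r.rms_mm:.2f} mm)")
        return reg.relative_motion(RigidTransform.identity(), r.transform,
                                   corr[pose_a], corr[pose_b])

    m_ext = bone_motion("max_extension", "ninety")
    m_flex = bone_motion("ninety", "max_flexion")

    # 3. extension and flexion screw axes (canonical sign along mediolateral)
    try:
        ext_axis = screw_axis(m_ext, config.min_angle_deg, frame.medlat)
        flex_axis = screw_axis(m_flex, config.min_angle_deg, frame.medlat)
    except ValueError as e:
        raise StageError("screw_axis", str(e))

    change = axis_change(ext_axis, flex_axis, frame)

    # scanned elbow angles recovered from the motion arcs
    theta_ext = 90.0 - ext_axis.angle_deg
    theta_flex = 90.0 + flex_axis.angle_deg

    # 4. extrapolate to the simulated terminal positions and measure overlap
    humerus_ref = pose_meshes["ninety"]["humerus"].copy()
    humerus_ref.apply_transform(corr["ninety"].matrix)
    hd = MeshDistance(humerus_ref)

    widths = {}
    for position, pose, axis, theta in (
        (SIMULATED_EXTENSION_DEG, "max_extension", ext_axis, theta_ext),
        (SIMULATED_FLEXION_DEG, "max_flexion", flex_axis, theta_flex),
    ):
        comps = []
        for bone in ("ulna", "radius"):
            m = pose_meshes[pose][bone].copy()
            m.apply_transform(corr[pose].matrix)
            m = extrapolate_pose(m, axis, theta, position)
            comps.extend(overlap_region(m, humerus_ref, config, bone=bone,
                                        humerus_distance=hd))
        widths[position] = label_regions(comps, landmarks, position, frame,
                                         method=config.width_method)

    result = CaseResult(case_id, round(-theta_ext, 1), round(theta_flex, 1),
                        AxisChange(round(change.varus_valgus_deg, 1),
                                   round(change.int_ext_deg, 1)),
                        widths[SIMULATED_EXTENSION_DEG],
                        widths[SIMULATED_FLEXION_DEG])
    if not return_context:
        return result
    ref_meshes = {}
    for bone in ("humerus", "ulna", "radius"):
        m = pose_meshes["ninety"][bone].copy()
        m.apply_transform(corr["ninety"].matrix)
        ref_meshes[bone] = m
    ctx = MeasurementContext(ref_meshes, ext_axis, flex_axis, frame, dict(landmarks))
    return result, ctx


def residual_osteophytes(postop_bone_meshes: dict, preop: MeasurementContext,
                         planned: CaseResult | None = None,
                         config: MeasureConfig = MeasureConfig()) -> dict:
    """Residual osteophyte widths after surgery.

    The post-operative bone models (one scan near 90 degrees of flexion, in
    an arbitrary scan frame) are superimposed onto the pre-operative models:
    the humerus fixes the scan frame, each forearm bone is then refined onto
    its pre-operative counterpart.  The 0/140-degree overlap measurement is
    re-run on the post-operative bones about the *pre-operative* axes.
    Returns ``{0.0: RegionWidths, 140.0: RegionWidths}``.
    """
    r_h = reg.icp_register(postop_bone_meshes["humerus"],
                           preop.reference_meshes["humerus"], **config.icp_kwargs())
    if not r_h.converged:
        raise StageError("residual_registration",
                         f"post-op humerus failed to register (rms {r_h.rms_mm:.2f})")
    aligned = {}
    for bone in ("humerus", "ulna", "radius"):
        m = postop_bone_meshes[bone].copy()
        m.apply_transform(r_h.transform.matrix)
        aligned[bone] = m
    for bone in ("ulna", "radius"):
        # after humeral alignment the forearm is near its reference pose:
        # identity init, and trimmed ICP so resected regions cannot bias it
        r_b = reg.icp_register(aligned[bone], preop.reference_meshes[bone],
                               init=RigidTransform.identity(),
                               trim_fraction=0.2, **config.icp_kwargs())
        if not r_b.converged:
            raise StageError("residual_registration",
                             f"post-op {bone} failed to register "
                             f"(rms {r_b.rms_mm:.2f})")
        aligned[bone].apply_transform(r_b.transform.matrix)

    hd = MeshDistance(aligned["humerus"])
    out = {}
    for position, axis in ((SIMULATED_EXTENSION_DEG, preop.extension_axis),
                           (SIMULATED_FLEXION_DEG, preop.flexion_axis)):
        comps = []
        for bone in ("ulna", "radius"):
            m = extrapolate_pose(aligned[bone], axis, 90.0, position)
            comps.extend(overlap_region(m, aligned["humerus"], config, bone=bone,
                                        humerus_distance=hd))
        out[position] = label_regions(comps, preop.landmarks, position,
                                      preop.frame, method=config.width_method)
    return out
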