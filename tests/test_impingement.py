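import numpy as np
import pytest
import trimesh
from scipy.spatial.transform import Rotation

from impingesim import RegionLabel
from impingesim.impingement import (MeasureConfig, OverlapRegion, RegionWidths,
                                    extrapolate_pose, label_regions,
                                    overlap_region, penetration_width,
                                    residual_osteophytes)
from impingesim.kinematics import AxisResult
from impingesim.meshquery import MeshDistance, voxel_overlap_volume
from impingesim.synthetic import (ElbowSpec, OsteophyteSpec, make_elbow,
                                  make_poses)
from impingesim.transforms import RigidTransform

Z_AXIS = AxisResult(np.array([0.0, 0.0, 1.0]), np.zeros(3), 30.0, 0.0)

LANDMARKS = {
    "medial_epicondyle": np.array([25.0, 0.0, 0.0]),
    "lateral_epicondyle": np.array([-25.0, 0.0, 0.0]),
    "humeral_shaft_proximal": np.array([0.0, 0.0, 100.0]),
    "olecranon_tip": np.array([10.0, -20.0, 25.0]),
    "trochlea_capitellum_boundary": np.array([-1.0, 0.0, -12.0]),
}


# ------------------------------------------------------------- extrapolation

def test_extrapolate_zero_delta_is_identity(clean_scene):
    m = clean_scene.ulna_mesh
    out = extrapolate_pose(m, Z_AXIS, 24.0, 24.0)
    assert np.array_equal(out.vertices, m.vertices)


def test_extrapolate_matches_rotation_oracle():
    m = trimesh.creation.box(extents=(2, 2, 2))
    m.apply_translation([0.0, 10.0, 0.0])
    out = extrapolate_pose(m, Z_AXIS, 0.0, -20.0)
    R = Rotation.from_euler("z", -20.0, degrees=True).as_matrix()
    expect = (m.vertices.view(np.ndarray)) @ R.T
    assert np.allclose(out.vertices, expect, atol=1e-9)


def test_extrapolate_applies_screw_pitch():
    axis = AxisResult(np.array([0.0, 0.0, 1.0]), np.array([2.0, 0.0, 0.0]),
                      30.0, 0.05)
    m = trimesh.creation.box(extents=(2, 2, 2))
    out = extrapolate_pose(m, axis, 100.0, 120.0)
    dz = out.vertices[:, 2] - m.vertices[:, 2]
    assert np.allclose(dz, 1.0, atol=1e-9)   # 0.05 mm/deg * 20 deg


def test_extrapolate_rejects_implausible_arcs(clean_scene):
    with pytest.raises(ValueError, match="beyond plausibility"):
        extrapolate_pose(clean_scene.ulna_mesh, Z_AXIS, 0.0, 95.0)


# ----------------------------------------------------------------- overlap

@pytest.fixture(scope="module")
def sphere_slab():
    """r=5 sphere 3 mm above a thick slab's top face: 2 mm penetration."""
    slab = trimesh.creation.box(extents=(30.0, 30.0, 10.0))
    sphere = trimesh.creation.icosphere(subdivisions=4, radius=5.0)
    sphere.apply_translation([0.0, 0.0, 8.0])
    return sphere, slab


def test_overlap_disjoint_meshes_is_empty():
    a = trimesh.creation.icosphere(subdivisions=2, radius=5.0)
    b = trimesh.creation.box(extents=(4, 4, 4))
    b.apply_translation([30.0, 0, 0])
    assert overlap_region(a, b) == []


def test_overlap_sphere_slab_cap_volume_and_depth(sphere_slab):
    sphere, slab = sphere_slab
    comps = overlap_region(sphere, slab, MeasureConfig(sample_density_per_mm2=12))
    assert len(comps) == 1
    cap = np.pi * 2.0**2 * (3 * 5.0 - 2.0) / 3.0    # 54.45 mm^3
    assert comps[0].volume_mm3 == pytest.approx(cap, rel=0.05)
    assert penetration_width(comps[0]) == pytest.approx(2.0, abs=0.1)


def test_overlap_volume_agrees_with_fine_voxel_oracle(sphere_slab):
    sphere, slab = sphere_slab
    comps = overlap_region(sphere, slab, MeasureConfig(sample_density_per_mm2=12))
    oracle = voxel_overlap_volume(sphere, slab, pitch=0.2)
    assert comps[0].volume_mm3 == pytest.approx(oracle, rel=0.05)


def test_two_spheres_penetration_depth():
    a = trimesh.creation.icosphere(subdivisions=4, radius=5.0)
    b = a.copy()
    b.apply_translation([8.0, 0.0, 0.0])
    comps = overlap_region(a, b, MeasureConfig(sample_density_per_mm2=12))
    assert len(comps) == 1
    # deepest mutual penetration r1 + r2 - d = 2
    assert penetration_width(comps[0]) == pytest.approx(2.0, abs=0.1)


def test_two_separate_bumps_give_two_components():
    slab = trimesh.creation.box(extents=(60.0, 30.0, 10.0))
    s1 = trimesh.creation.icosphere(subdivisions=3, radius=5.0)
    s1.apply_translation([-15.0, 0.0, 8.0])
    s2 = trimesh.creation.icosphere(subdivisions=3, radius=5.0)
    s2.apply_translation([15.0, 0.0, 8.0])
    both = trimesh.util.concatenate([s1, s2])
    comps = overlap_region(both, slab, MeasureConfig(sample_density_per_mm2=8))
    assert len(comps) == 2


def test_overlap_requires_watertight_meshes():
    a = trimesh.creation.icosphere(subdivisions=2, radius=5.0)
    broken = trimesh.Trimesh(a.vertices, a.faces[:-5], process=False)
    with pytest.raises(ValueError, match="watertight"):
        overlap_region(broken, a)


def test_caliper_width_reads_component_extent(sphere_slab):
    sphere, slab = sphere_slab
    comps = overlap_region(sphere, slab, MeasureConfig(sample_density_per_mm2=12))
    # chord radius of the cap: sqrt(h (2r - h)) = 4 -> extent ~ 8
    assert penetration_width(comps[0], method="caliper") == pytest.approx(8.0, abs=0.5)


# ----------------------------------------------------------------- labeling

def _component(points, depths):
    return OverlapRegion(0, "ulna", np.asarray(points, float),
                         np.asarray(depths, float), 1.0)


def test_label_regions_medial_bump_goes_to_pm_only():
    comp = _component([[14.0, -30.0, 10.0], [15.0, -30.0, 11.0]], [3.0, 4.0])
    w = label_regions([comp], LANDMARKS, 0.0)
    assert w[RegionLabel.PM_HUJ] == 4.0
    assert all(w[r] == 0.0 for r in RegionLabel if r != RegionLabel.PM_HUJ)


def test_label_regions_splits_continuous_olecranon_osteophyte():
    """A single horseshoe component over the olecranon tip reports its
    medial-side maximum under PM and its lateral-side maximum under PL."""
    pts = [[6.0, -30.0, 10.0], [9.0, -30.0, 10.0],    # lateral of tip (x<10)
           [12.0, -30.0, 10.0], [15.0, -30.0, 10.0]]  # medial of tip
    comp = _component(pts, [2.5, 3.5, 1.0, 5.0])
    w = label_regions([comp], LANDMARKS, 0.0)
    assert w[RegionLabel.PM_HUJ] == 5.0
    assert w[RegionLabel.PL_HUJ] == 3.5
    assert w[RegionLabel.POST_CAP] == 0.0


def test_label_regions_radial_side_positions():
    comp = _component([[-13.0, 20.0, 10.0]], [1.8])
    w0 = label_regions([comp], LANDMARKS, 0.0)
    assert w0[RegionLabel.POST_CAP] == 1.8
    w140 = label_regions([comp], LANDMARKS, 140.0)
    assert w140[RegionLabel.RAD_FOSSA] == 1.8
    assert w140[RegionLabel.ANT_HUJ] == 0.0


def test_label_regions_rejects_unknown_position():
    comp = _component([[0.0, 0.0, 0.0]], [1.0])
    with pytest.raises(ValueError, match="position"):
        label_regions([comp], LANDMARKS, 45.0)


def test_region_widths_position_exclusivity():
    with pytest.raises(ValueError, match="cannot be populated"):
        RegionWidths({RegionLabel.ANT_HUJ: 2.0}, 0.0)
    with pytest.raises(ValueError, match="cannot be populated"):
        RegionWidths({RegionLabel.PM_HUJ: 2.0}, 140.0)


# ------------------------------------------------------------- monotonicity

def test_deeper_extrapolation_never_decreases_width(demo_case):
    scene = demo_case.scene
    hd = MeshDistance(scene.humerus_mesh)
    cfg = MeasureConfig(sample_density_per_mm2=6)
    widths = []
    for target in (0.0, -2.0):
        m = scene.ulna_mesh.copy()
        m.apply_transform(scene.pose_transform(target).matrix)
        comps = overlap_region(m, scene.humerus_mesh, cfg, humerus_distance=hd)
        widths.append(max(c.max_depth_mm for c in comps))
    assert widths[1] >= widths[0]


# ---------------------------------------------------------------- residuals

def _postop_meshes(spec, sizes, offset):
    postop_spec = ElbowSpec(
        osteophytes=tuple(OsteophyteSpec(o.region, sizes.get(o.region, 0.0),
                                         o.footprint_mm)
                          for o in spec.osteophytes
                          if sizes.get(o.region, 0.0) > 0),
        flexion_axis_perturbation=spec.flexion_axis_perturbation,
        rom_limits=spec.rom_limits, mesh_resolution=spec.mesh_resolution,
        seed=spec.seed)
    postop = make_elbow(postop_spec)
    T90 = postop.pose_transform(90.0)
    out = {}
    for bone in ("humerus", "ulna", "radius"):
        m = postop.mesh(bone).copy()
        if bone != "humerus":
            m.apply_transform(T90.matrix)
        m.apply_transform(offset.matrix)
        out[bone] = m
    return out


def test_residuals_after_partial_resection(demo_case):
    """Resection leaving 0.4 mm of each osteophyte reports ~0.4 mm residuals;
    carving everything away reports zeros."""
    offset = RigidTransform.from_rotvec((2.0, -1.0, 1.5), (3.0, -2.0, 1.0))
    sizes = {o.region: 0.4 for o in demo_case.spec.osteophytes}
    meshes = _postop_meshes(demo_case.spec, sizes, offset)
    out = residual_osteophytes(meshes, demo_case.ctx, demo_case.result)
    for region, truth in demo_case.truth.items():
        measured = (out[0.0] if region in (RegionLabel.PM_HUJ, RegionLabel.PL_HUJ,
                                           RegionLabel.POST_CAP)
                    else out[140.0])[region]
        assert measured == pytest.approx(0.4, abs=0.25), region

    carved = _postop_meshes(demo_case.spec, {}, offset)
    out = residual_osteophytes(carved, demo_case.ctx, demo_case.result)
    for pos in (0.0, 140.0):
        assert all(v == 0.0 for v in out[pos].widths.values())
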