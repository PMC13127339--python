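import numpy as np
import pandas as pd
import pytest

from impingesim import RegionLabel
from impingesim.meshquery import MeshDistance, sample_surface
from impingesim.regions import REGION_COLUMNS
from impingesim.stats import pearson_regression
from impingesim.synthetic import (CohortSpec, ElbowSpec, OsteophyteSpec,
                                  make_cohort, make_elbow, make_poses,
                                  noise_sd_for_r)


# ---------------------------------------------------------------- validation

def test_resolution_coarser_than_footprint_is_rejected():
    with pytest.raises(ValueError, match="too coarse"):
        ElbowSpec(osteophytes=(OsteophyteSpec(RegionLabel.PM_HUJ, 2.0,
                                              footprint_mm=3.0),),
                  mesh_resolution=10.0)


def test_nonpositive_radii_rejected():
    with pytest.raises(ValueError, match="radii"):
        ElbowSpec(trochlea_radius=0.0)


def test_oversized_osteophyte_rejected():
    with pytest.raises(ValueError, match="wall margins"):
        OsteophyteSpec(RegionLabel.PM_HUJ, 9.5)


def test_osteophyte_bone_mismatch_rejected():
    with pytest.raises(ValueError, match="carried on"):
        OsteophyteSpec(RegionLabel.PM_HUJ, 3.0, bone="humerus")


def test_rom_inside_flexion_arc_required(clean_scene):
    with pytest.raises(ValueError, match="max_extension"):
        make_poses(clean_scene, rom=(100.0, 120.0))
    with pytest.raises(ValueError, match="45"):
        make_poses(clean_scene, axis_perturbation=(50.0, 0.0))


# ------------------------------------------------------------------- meshes

def test_meshes_watertight_and_landmarks_distinct(clean_scene):
    for bone in ("humerus", "ulna", "radius"):
        assert clean_scene.mesh(bone).is_watertight
    lm = clean_scene.landmarks
    assert np.isfinite(np.concatenate(list(lm.values()))).all()
    assert not np.allclose(lm["medial_epicondyle"], lm["lateral_epicondyle"])


def test_osteophyte_free_elbow_never_interpenetrates(clean_scene):
    hd = MeshDistance(clean_scene.humerus_mesh)
    lo, hi = clean_scene.humerus_mesh.bounds
    for theta in (0.0, 40.0, 90.0, 140.0):
        T = clean_scene.pose_transform(theta)
        for bone in ("ulna", "radius"):
            pts = T.apply(sample_surface(clean_scene.mesh(bone), 2.0, 0))
            sel = np.all((pts > lo - 1) & (pts < hi + 1), axis=1)
            assert hd.signed_distance(pts[sel]).min() > 0.0


def test_osteophyte_penetration_depth_equals_its_size():
    """A 6 mm medial-olecranon osteophyte penetrates 6 mm at simulated 0."""
    spec = ElbowSpec(osteophytes=(OsteophyteSpec(RegionLabel.PM_HUJ, 6.0),),
                     mesh_resolution=0.7)
    scene = make_elbow(spec)
    hd = MeshDistance(scene.humerus_mesh)
    T = scene.pose_transform(0.0)
    pts = T.apply(sample_surface(scene.ulna_mesh, 8.0, 0))
    lo, hi = scene.humerus_mesh.bounds
    sel = np.all((pts > lo - 1) & (pts < hi + 1), axis=1)
    depth = -hd.signed_distance(pts[sel]).min()
    assert depth == pytest.approx(6.0, abs=0.3)


def test_identical_spec_and_seed_give_identical_meshes():
    spec = ElbowSpec(mesh_resolution=1.2, seed=11)
    a = make_elbow(spec)
    b = make_elbow(spec)
    for bone in ("humerus", "ulna", "radius"):
        assert np.array_equal(a.mesh(bone).vertices, b.mesh(bone).vertices)
        assert np.array_equal(a.mesh(bone).faces, b.mesh(bone).faces)


def test_achievable_rom_blocks_at_first_bone_contact():
    """A larger osteophyte blocks extension earlier, and the predicted
    contact angle matches the meshes: near-zero clearance at the limit,
    clear separation a few degrees short of it."""
    spec = ElbowSpec(osteophytes=(OsteophyteSpec(RegionLabel.PM_HUJ, 5.0),),
                     mesh_resolution=0.8)
    scene = make_elbow(spec)
    small = make_elbow(ElbowSpec(osteophytes=(OsteophyteSpec(RegionLabel.PM_HUJ, 2.0),),
                                 mesh_resolution=0.8))
    ext_big, flex_big = scene.achievable_rom()
    ext_small, _ = small.achievable_rom()
    assert ext_big < ext_small <= 0.0
    assert flex_big == pytest.approx(140.0)

    hd = MeshDistance(scene.humerus_mesh)
    lo, hi = scene.humerus_mesh.bounds

    def min_sd(theta):
        pts = scene.pose_transform(theta).apply(
            sample_surface(scene.ulna_mesh, 6.0, 0))
        sel = np.all((pts > lo - 1) & (pts < hi + 1), axis=1)
        return float(hd.signed_distance(pts[sel]).min())

    assert min_sd(-ext_big) == pytest.approx(0.0, abs=0.3)   # touching
    assert min_sd(-ext_big + 4.0) > 0.5                      # well clear


def test_pose_set_truth_angles_and_jitter(clean_scene):
    poses = make_poses(clean_scene, rom=(-20.0, 120.0), rigid_noise_sd=0.5,
                       seed=4)
    assert poses.truth_angles_deg == (20.0, 90.0, 120.0)
    for name in poses.POSE_NAMES:
        G = poses.poses[name]["humerus"]
        assert G.rotation_angle_deg() <= 1.0 + 1e-9
        assert np.linalg.norm(G.translation) <= 0.5 + 1e-9
    # unperturbed scene: extension and flexion motion share one axis
    again = make_poses(clean_scene, rom=(-20.0, 120.0), rigid_noise_sd=0.5,
                       seed=4)
    assert again.poses["ninety"]["ulna"].is_close(poses.poses["ninety"]["ulna"])


# ------------------------------------------------------------------- cohort

def test_noise_free_cohort_refits_the_generating_line_exactly():
    cs = CohortSpec(n_cases=30, noise_sd_mm=0.0, seed=5)
    df = make_cohort(cs)
    fit = pearson_regression(df["extension_deg"], df["pm_huj_mm"])
    assert fit.slope == pytest.approx(-0.16, abs=1e-9)
    assert fit.intercept == pytest.approx(2.52, abs=1e-9)
    assert fit.r == pytest.approx(-1.0, abs=1e-9)


def test_cohort_widths_truncated_at_zero_and_reproducible():
    cs = CohortSpec(n_cases=60, seed=9)
    df = make_cohort(cs)
    assert (df[list(REGION_COLUMNS.values())] >= 0).all().all()
    assert df.equals(make_cohort(cs))
    ext = df["extension_deg"]
    assert ext.between(-45, -5).all()
    assert df["flexion_deg"].between(75, 145).all()


def test_cohort_requires_at_least_one_case():
    with pytest.raises(ValueError, match="n_cases"):
        CohortSpec(n_cases=0)


def test_noise_sd_for_r_inverts_the_correlation():
    # with sd_x = 10, slope -0.16, r -0.48: check R recovered on a big draw
    sd = noise_sd_for_r(-0.16, 10.0, -0.48)
    rng = np.random.default_rng(1)
    x = rng.normal(-24, 10, 40000)
    y = -0.16 * x + 2.52 + rng.normal(0, sd, 40000)
    r = np.corrcoef(x, y)[0, 1]
    assert r == pytest.approx(-0.48, abs=0.02)
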