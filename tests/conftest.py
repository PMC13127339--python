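"""Shared fixtures: expensive synthetic scenes are built once per session."""
from types import SimpleNamespace

import numpy as np
import pytest

from impingesim import MeasureConfig, measure_elbow
from impingesim.synthetic import (ElbowSpec, make_case_spec, make_elbow,
                                  make_poses)


@pytest.fixture(scope="session")
def clean_scene():
    """Osteophyte-free elbow with the study's mean flexion-axis shift."""
    return make_elbow(ElbowSpec(flexion_axis_perturbation=(0.9, 5.2),
                                mesh_resolution=1.0))


@pytest.fixture(scope="session")
def demo_case():
    """One fully measured case with osteophytes from the calibration lines."""
    spec = make_case_spec(-24.0, 119.0, seed=3, axis_perturbation=(0.9, 5.2),
                          mesh_resolution=0.7)
    scene = make_elbow(spec)
    poses = make_poses(scene, rigid_noise_sd=0.3)
    result, ctx = measure_elbow(poses.posed_meshes(scene),
                                poses.landmarks_in_reference(scene),
                                MeasureConfig(), case_id="demo",
                                return_context=True)
    truth = {o.region: o.size_mm for o in spec.osteophytes}
    return SimpleNamespace(spec=spec, scene=scene, poses=poses,
                           result=result, ctx=ctx, truth=truth)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
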