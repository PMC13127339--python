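"""Standard-format I/O: STL/PLY meshes, JSON sidecars, cohort CSV.

Every file written carries a provenance record (config hash + seed):
JSON files as a ``provenance`` object, CSV files as a leading ``#`` comment
line (skipped on read).
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

from .regions import REGION_COLUMNS, RegionLabel
from .synthetic import ElbowScene, ElbowSpec, OsteophyteSpec, PoseSet

COHORT_COLUMNS = ["case", "extension_deg", "flexion_deg",
                  "pm_huj_mm", "pl_huj_mm", "post_cap_mm",
                  "ant_huj_mm", "rad_fossa_mm"]


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    payload = json.dumps(obj, sort_keys=True, default=_jsonable)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _jsonable(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, RegionLabel):
        return o.value
    if isinstance(o, (tuple, set)):
        return list(o)
    raise TypeError(f"not JSON-serializable: {type(o)}")


def provenance(seed: int, config) -> dict:
    return {"seed": int(seed), "config_hash": config_hash(config)}


# ---------------------------------------------------------------------------
# scenes


def spec_to_dict(spec: ElbowSpec) -> dict:
    d = asdict(spec)
    d["osteophytes"] = [
        {"region": o.region.value, "size_mm": o.size_mm,
         "footprint_mm": o.footprint_mm, "bone": o.bone}
        for o in spec.osteophytes
    ]
    return d


def spec_from_dict(d: dict) -> ElbowSpec:
    d = dict(d)
    d["osteophytes"] = tuple(
        OsteophyteSpec(RegionLabel(o["region"]), o["size_mm"],
                       o.get("footprint_mm", 5.0))
        for o in d.get("osteophytes", ())
    )
    d["hinge_axis_extension"] = tuple(map(tuple, d["hinge_axis_extension"]))
    d["flexion_axis_perturbation"] = tuple(d["flexion_axis_perturbation"])
    d["rom_limits"] = tuple(d["rom_limits"])
    return ElbowSpec(**d)


def write_scene(scene: ElbowScene, poses: PoseSet, out_dir, fmt: str = "stl") -> dict:
    """Write per-pose, per-bone meshes plus a JSON sidecar with landmarks,
    poses (4x4 row-major) and the ground truth.  Returns the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = {}
    meshes = poses.posed_meshes(scene)
    for pose in PoseSet.POSE_NAMES:
        for bone, mesh in meshes[pose].items():
            name = f"{pose}_{bone}.{fmt}"
            mesh.export(out / name)
            files[f"{pose}/{bone}"] = name
    sidecar = {
        "provenance": provenance(scene.truth.seed, spec_to_dict(scene.truth)),
        "landmarks_reference_frame": {
            k: list(v) for k, v in poses.landmarks_in_reference(scene).items()},
        "poses": {p: {b: poses.poses[p][b].to_json_dict()
                      for b in ("humerus", "ulna", "radius")}
                  for p in PoseSet.POSE_NAMES},
        "truth": spec_to_dict(scene.truth),
        "truth_angles_deg": list(poses.truth_angles_deg),
        "files": files,
    }
    (out / "scene.json").write_text(json.dumps(sidecar, indent=1, default=_jsonable))
    return sidecar


def read_scene_dir(scene_dir):
    """Load the meshes and sidecar written by `write_scene`.

    Returns (pose_meshes, landmarks, sidecar) in the layout `measure_elbow`
    expects.
    """
    d = Path(scene_dir)
    sidecar = json.loads((d / "scene.json").read_text())
    pose_meshes = {}
    for key, name in sidecar["files"].items():
        pose, bone = key.split("/")
        mesh = trimesh.load(d / name, force="mesh")
        pose_meshes.setdefault(pose, {})[bone] = mesh
    landmarks = {k: np.asarray(v, float)
                 for k, v in sidecar["landmarks_reference_frame"].items()}
    return pose_meshes, landmarks, sidecar


# ---------------------------------------------------------------------------
# cohort tables


def write_cohort_csv(df: pd.DataFrame, path, seed: int, config) -> None:
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table is missing columns: {missing}")
    p = provenance(seed, config)
    path = Path(path)
    with open(path, "w", newline="") as fh:
        fh.write(f"# impingesim cohort seed={p['seed']} config={p['config_hash']}\n")
        df[COHORT_COLUMNS].to_csv(fh, index=False, float_format="%.6g")


def read_cohort_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort CSV is missing required columns: {missing}")
    return df


def case_results_to_cohort(results) -> pd.DataFrame:
    """Measured per-case results in the same schema as a generated cohort."""
    rows = []
    for r in results:
        row = {"case": r.case_id, "extension_deg": r.extension_deg,
               "flexion_deg": r.flexion_deg}
        for region, col in REGION_COLUMNS.items():
            row[col] = r.width(region)
        rows.append(row)
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)
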