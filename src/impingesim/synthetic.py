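"""Parametric synthetic elbow scenes and cohorts with known ground truth.

The phantom replaces CT-derived bone models with constructive solids built
around an ideal hinge:

* the humeral frame is ``x`` mediolateral (medial positive), ``y`` anterior,
  ``z`` proximal, with the extension (hinge) axis along ``+x`` through the
  origin;
* the humerus is a shaft capsule, a trochlear cylinder and capitellar sphere
  coaxial with the hinge, and a "supracondylar hood" -- a radial slab
  spanning the azimuth range the forearm never visits -- whose two faces
  play the role of the olecranon fossa (posterior) and the coronoid/radial
  fossae (anterior);
* ulna and radius are shaft capsules plus C-shaped wedges hugging the
  trochlea/capitellum.  The wedge faces are built to stop exactly at the
  hood faces (with a small clearance) at the simulated 0 and 140 degree
  positions, so an osteophyte modelled as a Gaussian bump of height
  ``size_mm`` on a wedge face penetrates the humerus by exactly ``size_mm``
  at the blocked terminal pose.  This gives analytic ground truth for every
  downstream measurement.

Flexion beyond 90 degrees runs about a perturbed axis (valgus/internal
tilts relative to the extension axis), emulating the axis shift seen in
arthritic elbows; the flexion-side wedge faces are constructed in the
140-degree configuration under that same perturbed motion, so terminal
penetration stays exact.

Elbow angles are handled internally on a flexion-positive scale
(0 = full extension, 140 = full flexion); clinical extension deficits are
the negated values (e.g. -24 means extension stops 24 degrees short).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import pandas as pd
import trimesh
from scipy import stats as sps
from skimage.measure import marching_cubes

from .regions import EXTENSION_REGIONS, FLEXION_REGIONS, REGION_COLUMNS, RegionLabel
from .transforms import RigidTransform, screw_motion

FULL_FLEXION_DEG = 140.0
#: face-to-fossa gap at the blocked terminal pose, mm
CLEARANCE = 0.25
#: radial position (about the hinge axis) of osteophyte bump centres, mm
BUMP_RADIUS = 36.0
#: largest representable osteophyte height, limited by fossa wall margins
MAX_OSTEOPHYTE_MM = 7.5

# hood (fossa block) geometry: azimuth in degrees about the hinge axis,
# alpha = 0 pointing distally (-z), +90 anterior (+y), 180 proximal (+z)
_HOOD_ALPHA = (152.0, 220.0)
_HOOD_R = (28.0, 46.0)
_HOOD_X = (-26.0, 24.0)
_FILL_ALPHA = (158.0, 214.0)
_FILL_R_OUT = 46.0
_TROCHLEA_X = (0.0, 23.0)
_CAPITELLUM_CX = -12.0
_ULNA_WEDGE_X = (2.0, 18.0)
_ULNA_NOTCH_GAP = 3.5
_RADIUS_WEDGE_X = (-19.0, -7.0)
_RADIUS_NOTCH_GAP = 4.0
_WEDGE_R_OUT = 41.0
#: proximal forearm shafts taper as cones with this flank slope so their
#: azimuthal spread never reaches the hood faces at the terminal poses
_SHAFT_SLOPE = 0.0963  # tan(5.5 deg)
_EXT_FACE_ALPHA = -140.0   # posterior hood face: olecranon contact at 0 deg
_FLEX_FACE_ALPHA = 152.0   # anterior hood face: coronoid contact at 140 deg
_EXT_TRAIL_ALPHA = -20.0
_FLEX_TRAIL_ALPHA = 60.0

_OLECRANON_TIP_X = 10.0
_TC_BOUNDARY_X = -1.0

#: per-region placement: (bone, face, bump centre x in the humeral frame)
REGION_PLACEMENT = {
    RegionLabel.PM_HUJ: ("ulna", "ext", 15.0),
    RegionLabel.PL_HUJ: ("ulna", "ext", 5.0),
    RegionLabel.POST_CAP: ("radius", "ext", -13.0),
    RegionLabel.ANT_HUJ: ("ulna", "flex", 10.0),
    RegionLabel.RAD_FOSSA: ("radius", "flex", -13.0),
}

#: per-region width-vs-ROM calibration of the generator: (slope mm/deg,
#: intercept mm, correlation r).  The predictor is the clinical extension
#: angle for the three 0-degree regions and the flexion angle for the two
#: 140-degree regions.
DEFAULT_REGION_LINES = {
    RegionLabel.PM_HUJ: (-0.16, 2.52, -0.48),
    RegionLabel.PL_HUJ: (-0.08, 2.16, -0.29),
    RegionLabel.POST_CAP: (-0.06, 0.72, -0.34),
    RegionLabel.ANT_HUJ: (-0.14, 23.23, -0.45),
    RegionLabel.RAD_FOSSA: (-0.08, 11.20, -0.46),
}

#: cohort range-of-motion distribution: (mean, sd, min, max) in degrees
DEFAULT_ROM_DISTRIBUTION = {
    "extension": (-24.0, 10.0, -45.0, -5.0),
    "flexion": (119.0, 12.0, 75.0, 145.0),
}

#: cohort flexion-axis shift distribution: (mean, sd) in degrees
DEFAULT_AXIS_SHIFT = {"valgus": (0.9, 0.4), "internal": (5.2, 0.6)}


# ---------------------------------------------------------------------------
# specifications


@dataclass(frozen=True)
class OsteophyteSpec:
    """One osteophyte: a Gaussian bump of height `size_mm` on a wedge face.

    `footprint_mm` is the full width at half maximum of the bump.  The bone
    carrying the bump is implied by the region (impingement does not
    distinguish humeral-side from forearm-side outgrowths, so the phantom
    always carries the bump on the forearm surface).
    """

    region: RegionLabel
    size_mm: float
    footprint_mm: float = 5.0
    bone: str | None = None

    def __post_init__(self):
        object.__setattr__(self, "region", RegionLabel(self.region))
        if self.size_mm < 0:
            raise ValueError("osteophyte size_mm must be >= 0")
        if self.size_mm > MAX_OSTEOPHYTE_MM:
            raise ValueError(
                f"osteophyte size_mm > {MAX_OSTEOPHYTE_MM} mm exceeds the fossa "
                "wall margins of the phantom"
            )
        if self.footprint_mm <= 0:
            raise ValueError("footprint_mm must be > 0")
        expected = REGION_PLACEMENT[self.region][0]
        if self.bone is None:
            object.__setattr__(self, "bone", expected)
        elif self.bone != expected:
            raise ValueError(
                f"region {self.region} is carried on the {expected}; "
                f"got bone={self.bone!r} (humeral-side outgrowths are modelled "
                "on the opposing forearm surface)"
            )


@dataclass(frozen=True)
class ElbowSpec:
    """Full parametric description of one synthetic elbow."""

    trochlea_radius: float = 12.0
    capitellum_radius: float = 10.0
    humerus_length: float = 120.0
    ulna_length: float = 110.0
    radius_length: float = 100.0
    osteophytes: tuple = ()
    #: (unit direction, point) of the extension hinge in the output frame
    hinge_axis_extension: tuple = ((1.0, 0.0, 0.0), (0.0, 0.0, 0.0))
    #: (valgus_deg, internal_deg) tilt of the flexion axis vs the extension axis
    flexion_axis_perturbation: tuple = (0.0, 0.0)
    #: clinical (max_extension_deg <= 0, max_flexion_deg)
    rom_limits: tuple = (-24.0, 119.0)
    #: marching-cubes grid pitch == triangle edge-length target, mm
    mesh_resolution: float = 0.6
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "osteophytes", tuple(self.osteophytes))
        if min(self.trochlea_radius, self.capitellum_radius) <= 0:
            raise ValueError("articular radii must be > 0")
        if self.mesh_resolution <= 0:
            raise ValueError("mesh_resolution must be > 0")
        for o in self.osteophytes:
            if not isinstance(o, OsteophyteSpec):
                raise TypeError("osteophytes must be OsteophyteSpec instances")
            if self.mesh_resolution > o.footprint_mm:
                raise ValueError(
                    f"mesh_resolution {self.mesh_resolution} mm is too coarse to "
                    f"represent an osteophyte footprint of {o.footprint_mm} mm"
                )
        ext, flex = self.rom_limits
        if not flex > ext:
            raise ValueError("max_flexion_deg must exceed max_extension_deg")
        if ext > 0:
            raise ValueError("hyperextension (max_extension_deg > 0) is not modelled")
        vv, ir = self.flexion_axis_perturbation
        if max(abs(vv), abs(ir)) > 45.0:
            raise ValueError("flexion-axis perturbation beyond +-45 deg is non-physiologic")
        d, _ = self.hinge_axis_extension
        if abs(np.linalg.norm(np.asarray(d, float)) - 1.0) > 1e-6:
            raise ValueError("hinge axis direction must be a unit vector")

    def osteophyte_size(self, region: RegionLabel) -> float:
        for o in self.osteophytes:
            if o.region == region:
                return o.size_mm
        return 0.0


@dataclass
class ElbowScene:
    """Generated scene: meshes in canonical frames, landmarks and truth.

    The humerus mesh lives in the humeral frame; ulna and radius meshes are
    stored in their full-extension (0 degree) configuration and are posed by
    the elbow pose transform.  Landmarks are humeral-frame points.
    """

    humerus_mesh: trimesh.Trimesh
    ulna_mesh: trimesh.Trimesh
    radius_mesh: trimesh.Trimesh
    landmarks: dict
    truth: ElbowSpec
    _implicits: dict = field(default_factory=dict, repr=False)

    def mesh(self, bone: str) -> trimesh.Trimesh:
        return {"humerus": self.humerus_mesh, "ulna": self.ulna_mesh,
                "radius": self.radius_mesh}[bone]

    # -- ground-truth kinematics ---------------------------------------
    @property
    def extension_axis(self) -> tuple:
        """(unit direction, point) of the true extension axis."""
        d, p = self.truth.hinge_axis_extension
        return np.asarray(d, float), np.asarray(p, float)

    @property
    def flexion_axis(self) -> tuple:
        """(unit direction, point) of the true (perturbed) flexion axis."""
        d, p = self.extension_axis
        A = self._hinge_placement()
        d_local = _perturbed_axis_direction(*self.truth.flexion_axis_perturbation)
        return A.apply_vector(d_local), p

    def _hinge_placement(self) -> RigidTransform:
        """Rigid map from the construction frame (hinge = x axis through the
        origin) to the requested hinge placement."""
        d, p = self.extension_axis
        return _frame_from_axis(d, p)

    def pose_transform(self, theta_deg: float) -> RigidTransform:
        """Forearm pose at flexion-positive elbow angle `theta_deg`.

        Rotation about the extension axis up to 90 degrees, then about the
        perturbed flexion axis beyond.
        """
        d_ext, p = self.extension_axis
        if theta_deg <= 90.0:
            return screw_motion(d_ext, p, theta_deg)
        d_flex, _ = self.flexion_axis
        return screw_motion(d_flex, p, theta_deg - 90.0) @ screw_motion(d_ext, p, 90.0)

    def achievable_rom(self) -> tuple:
        """Clinical (max_extension, max_flexion) at first bone-on-bone contact.

        Closed form: a bump of height `s` at radius `BUMP_RADIUS` first
        touches its fossa wall ``atan(s / BUMP_RADIUS)`` short of the
        terminal angle.
        """
        ext_block = 0.0
        flex_block = 0.0
        for o in self.truth.osteophytes:
            angle = math.degrees(math.atan2(o.size_mm, BUMP_RADIUS))
            if REGION_PLACEMENT[o.region][1] == "ext":
                ext_block = max(ext_block, angle)
            else:
                flex_block = max(flex_block, angle)
        return (-ext_block, FULL_FLEXION_DEG - flex_block)


@dataclass
class PoseSet:
    """World-frame rigid poses of the three bones in the three scan positions."""

    poses: dict  # pose name -> {bone -> RigidTransform}
    truth_angles_deg: tuple  # flexion-positive elbow angles (ext, 90, flex)

    POSE_NAMES = ("max_extension", "ninety", "max_flexion")

    def __post_init__(self):
        a, b, c = self.truth_angles_deg
        if not (a < b < c):
            raise ValueError("truth angles must increase from extension to flexion")
        for name in self.POSE_NAMES:
            for bone in ("humerus", "ulna", "radius"):
                T = self.poses[name][bone]
                if abs(np.linalg.det(T.rotation) - 1.0) > 1e-9:
                    raise ValueError("pose transforms must be proper rigid")

    def posed_mesh(self, scene: ElbowScene, pose: str, bone: str) -> trimesh.Trimesh:
        m = scene.mesh(bone).copy()
        m.apply_transform(self.poses[pose][bone].matrix)
        return m

    def posed_meshes(self, scene: ElbowScene) -> dict:
        return {
            pose: {bone: self.posed_mesh(scene, pose, bone)
                   for bone in ("humerus", "ulna", "radius")}
            for pose in self.POSE_NAMES
        }

    def landmarks_in_reference(self, scene: ElbowScene) -> dict:
        """Landmarks expressed in the 90-degree scan frame (the reference)."""
        G = self.poses["ninety"]["humerus"]
        return {k: G.apply(v) for k, v in scene.landmarks.items()}


@dataclass(frozen=True)
class CohortSpec:
    """Tabular cohort generator: inverts the width-vs-ROM regression model."""

    n_cases: int = 92
    lines: dict = field(default_factory=lambda: dict(DEFAULT_REGION_LINES))
    noise_sd_mm: dict | float | None = None
    rom_distribution: dict = field(default_factory=lambda: dict(DEFAULT_ROM_DISTRIBUTION))
    seed: int = 0

    def __post_init__(self):
        if self.n_cases < 1:
            raise ValueError("n_cases must be >= 1")
        for key, (mean, sd, lo, hi) in self.rom_distribution.items():
            if not (lo <= mean <= hi) or sd < 0:
                raise ValueError(f"invalid ROM distribution for {key}")
        if isinstance(self.noise_sd_mm, (int, float)) and self.noise_sd_mm < 0:
            raise ValueError("noise_sd_mm must be >= 0")

    def region_noise_sd(self, region: RegionLabel) -> float:
        if self.noise_sd_mm is None:
            slope, _, r = self.lines[region]
            direction = "flexion" if region in FLEXION_REGIONS else "extension"
            sd_x = self.rom_distribution[direction][1]
            return noise_sd_for_r(slope, sd_x, r)
        if isinstance(self.noise_sd_mm, dict):
            return float(self.noise_sd_mm[region])
        return float(self.noise_sd_mm)


def noise_sd_for_r(slope: float, sd_x: float, r: float) -> float:
    """Residual SD that makes a line with `slope` over predictor spread
    `sd_x` yield Pearson correlation `r` (|r| in (0, 1]); ignores the
    zero-truncation of widths (see `calibrate_generating_line` for the
    truncation-aware inversion)."""
    if not 0 < abs(r) <= 1:
        raise ValueError("r must be in (0, 1]")
    return abs(slope) * sd_x * math.sqrt(1.0 / r**2 - 1.0)


@lru_cache(maxsize=64)
def calibrate_generating_line(slope_t: float, intercept_t: float, r_t: float,
                              rom: tuple, n_sim: int = 60_000,
                              iters: int = 12) -> tuple:
    """Generating (slope, intercept, noise_sd) whose zero-truncated widths
    REFIT to the target line and correlation.

    Widths are truncated at zero, which attenuates a naive refit whenever a
    noticeable fraction of cases carries no osteophyte (e.g. the radial
    fossa).  This solves the inverse problem by fixed-point iteration on a
    large common-random-numbers simulation, so the emitted cohort exhibits
    the target slope/intercept/R in expectation.
    """
    mean, sd_x, lo, hi = rom
    rng = np.random.default_rng(987654321)
    a, b = (lo - mean) / sd_x, (hi - mean) / sd_x
    x = sps.truncnorm.rvs(a, b, loc=mean, scale=sd_x, size=n_sim,
                          random_state=rng)
    eps = rng.standard_normal(n_sim)
    s, i = slope_t, intercept_t
    sd = noise_sd_for_r(slope_t, float(x.std()), r_t)
    for _ in range(iters):
        w = np.maximum(s * x + i + sd * eps, 0.0)
        fit = sps.linregress(x, w)
        s += slope_t - fit.slope
        i += intercept_t - fit.intercept
        ratio = (1.0 / r_t**2 - 1.0) / max(1.0 / fit.rvalue**2 - 1.0, 1e-12)
        sd *= math.sqrt(max(ratio, 0.25))
    return float(s), float(i), float(sd)


# ---------------------------------------------------------------------------
# implicit-solid primitives (negative inside)


def _capsule(p, a, b, r):
    a = np.asarray(a, float)
    ab = np.asarray(b, float) - a
    t = np.clip(((p - a) @ ab) / (ab @ ab), 0.0, 1.0)
    return np.linalg.norm(p - a - t[:, None] * ab, axis=1) - r


def _tapered_shaft(p, xc, z_top, z_end, slope, r_max):
    """Distal shaft along -z at (xc, 0): cone of flank `slope` from the
    joint, saturating at radius `r_max`, with flat end caps."""
    z = np.clip(p[:, 2], z_end, z_top)
    r = np.minimum(slope * np.abs(z), r_max)
    horiz = np.hypot(p[:, 0] - xc, p[:, 1])
    return np.maximum.reduce([horiz - r, p[:, 2] - z_top, z_end - p[:, 2]])


def _sphere(p, c, r):
    return np.linalg.norm(p - np.asarray(c, float), axis=1) - r


def _rho(p):
    """Distance from the hinge (x) axis."""
    return np.hypot(p[:, 1], p[:, 2])


def _cyl_x(p, r, x0, x1):
    return np.maximum(_rho(p) - r, np.maximum(x0 - p[:, 0], p[:, 0] - x1))


def _alpha_normal(alpha_deg):
    """Normal of the radial plane at azimuth `alpha_deg`; n . p = rho * sin(angle
    from the plane), positive on the greater-azimuth side."""
    a = math.radians(alpha_deg)
    return np.array([0.0, math.cos(a), math.sin(a)])


def _band(v, lo, hi):
    return np.maximum(lo - v, v - hi)


def _gaussian_bumps(p, bumps):
    """Summed bump relief on a face; bumps = [(x_centre, height, sigma), ...]."""
    if not bumps:
        return 0.0
    rel = np.zeros(len(p))
    rho = _rho(p)
    for xc, h, sigma in bumps:
        rel += h * np.exp(-((p[:, 0] - xc) ** 2 + (rho - BUMP_RADIUS) ** 2)
                          / (2.0 * sigma**2))
    return rel


def _wedge(p, face_alpha, face_side, trail_alpha, trail_side,
           r_in, r_out, x0, x1, bumps):
    """C-wedge segment between two radial planes with bump relief on the face.

    `face_side`/`trail_side` is +1 when the wedge lies on the greater-azimuth
    side of that plane.  The face plane is inset by CLEARANCE; bumps protrude
    through it by (height - CLEARANCE).
    """
    nf = _alpha_normal(face_alpha)
    nt = _alpha_normal(trail_alpha)
    face = face_side * (p @ nf) - CLEARANCE + _gaussian_bumps(p, bumps)
    trail = trail_side * (p @ nt)
    return np.maximum.reduce([
        -face,
        -trail,
        _band(_rho(p), r_in, r_out),
        _band(p[:, 0], x0, x1),
    ])


def _perturbed_axis_direction(valgus_deg: float, internal_deg: float) -> np.ndarray:
    """Flexion-axis direction in the construction frame.

    Valgus tilts the axis about the anterior (+y) axis, internal rotation
    about the proximal (+z) axis; both positive per the right-elbow sign
    convention used throughout.
    """
    Ry = screw_motion((0, 1, 0), (0, 0, 0), valgus_deg).rotation
    Rz = screw_motion((0, 0, 1), (0, 0, 0), internal_deg).rotation
    return Ry @ Rz @ np.array([1.0, 0.0, 0.0])


def _frame_from_axis(direction, point) -> RigidTransform:
    """Minimal rotation mapping x-hat to `direction`, origin to `point`."""
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    x = np.array([1.0, 0.0, 0.0])
    v = np.cross(x, d)
    s = np.linalg.norm(v)
    c = float(x @ d)
    if s < 1e-12:
        R = np.eye(3) if c > 0 else screw_motion((0, 0, 1), (0, 0, 0), 180.0).rotation
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        R = np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)
    return RigidTransform(R, np.asarray(point, float))


# ---------------------------------------------------------------------------
# bone implicit functions (construction frame)


def _bone_bumps(spec: ElbowSpec, bone: str, face: str):
    out = []
    for o in spec.osteophytes:
        b, f, xc = REGION_PLACEMENT[o.region]
        if b == bone and f == face:
            out.append((xc, o.size_mm + CLEARANCE, o.footprint_mm / 2.3548))
    return out


def _humerus_implicit(spec: ElbowSpec):
    def f(p):
        parts = [
            _capsule(p, (0, 0, 30), (0, 0, spec.humerus_length - 8), 14.0),
            _cyl_x(p, spec.trochlea_radius, *_TROCHLEA_X),
            _sphere(p, (_CAPITELLUM_CX, 0, 0), spec.capitellum_radius),
            # supracondylar hood (fossa block)
            np.maximum.reduce([
                -(p @ _alpha_normal(_HOOD_ALPHA[0])),
                p @ _alpha_normal(_HOOD_ALPHA[1]),
                _band(_rho(p), *_HOOD_R),
                _band(p[:, 0], *_HOOD_X),
            ]),
            # condylar fill joining trochlea, capitellum, hood and shaft
            np.maximum.reduce([
                -(p @ _alpha_normal(_FILL_ALPHA[0])),
                p @ _alpha_normal(_FILL_ALPHA[1]),
                _rho(p) - _FILL_R_OUT,
                _band(p[:, 0], *_HOOD_X),
            ]),
        ]
        return np.minimum.reduce(parts)
    return f


def _forearm_implicit(spec: ElbowSpec, bone: str, t140: RigidTransform):
    """Ulna or radius implicit in the full-extension configuration.

    The flexion-side wedge is defined in the 140-degree configuration and
    pulled back through `t140`, keeping its terminal contact exact under the
    perturbed flexion motion.
    """
    if bone == "ulna":
        x0, x1 = _ULNA_WEDGE_X
        r_in = spec.trochlea_radius + _ULNA_NOTCH_GAP
        shaft = (10.0, -18.0, -(spec.ulna_length - 4.0), _SHAFT_SLOPE, 7.0)
    else:
        x0, x1 = _RADIUS_WEDGE_X
        r_in = spec.capitellum_radius + _RADIUS_NOTCH_GAP
        shaft = (-13.0, -17.0, -(spec.radius_length - 4.0), _SHAFT_SLOPE, 5.0)
    ext_bumps = _bone_bumps(spec, bone, "ext")
    flex_bumps = _bone_bumps(spec, bone, "flex")

    def f(p):
        q = t140.apply(p)
        parts = [
            _tapered_shaft(p, *shaft),
            _wedge(p, _EXT_FACE_ALPHA, +1, _EXT_TRAIL_ALPHA, -1,
                   r_in, _WEDGE_R_OUT, x0, x1, ext_bumps),
            _wedge(q, _FLEX_FACE_ALPHA, -1, _FLEX_TRAIL_ALPHA, +1,
                   r_in, _WEDGE_R_OUT, x0, x1, flex_bumps),
        ]
        return np.minimum.reduce(parts)
    return f


def _mesh_from_implicit(f, bounds, pitch: float) -> trimesh.Trimesh:
    lo, hi = np.asarray(bounds, float)
    # offset the grid by an irrational fraction of the pitch so axis-aligned
    # construction planes never coincide with grid nodes (which would create
    # degenerate marching-cubes triangles)
    lo = lo - pitch * (np.sqrt(2.0) - 1.0) / 2.0
    axes = [np.arange(lo[i], hi[i] + pitch, pitch) for i in range(3)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
    vals = f(grid.reshape(-1, 3)).reshape(grid.shape[:3])
    verts, faces, _, _ = marching_cubes(vals, level=0.0, spacing=(pitch, pitch, pitch))
    verts += lo
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=True)
    if mesh.volume < 0:
        mesh.invert()
    return mesh


# ---------------------------------------------------------------------------
# operations


def make_elbow(spec: ElbowSpec) -> ElbowScene:
    """Generate the three watertight bone meshes, landmarks and ground truth."""
    t140 = _canonical_t140(spec)
    pitch = spec.mesh_resolution
    L = spec
    bounds = {
        "humerus": ((-30, -48, -28), (28, 48, L.humerus_length + 8)),
        "ulna": ((-6, -44, -(L.ulna_length + 4)), (26, 44, 44)),
        "radius": ((-28, -44, -(L.radius_length + 4)), (2, 44, 44)),
    }
    fns = {
        "humerus": _humerus_implicit(spec),
        "ulna": _forearm_implicit(spec, "ulna", t140),
        "radius": _forearm_implicit(spec, "radius", t140),
    }
    A = _frame_from_axis(*spec.hinge_axis_extension)
    meshes = {}
    implicits = {}
    Ainv = A.inverse()
    for bone in ("humerus", "ulna", "radius"):
        m = _mesh_from_implicit(fns[bone], bounds[bone], pitch)
        if not m.is_watertight:
            raise RuntimeError(f"generated {bone} mesh is not watertight")
        m.apply_transform(A.matrix)
        meshes[bone] = m
        implicits[bone] = (lambda p, g=fns[bone]: g(Ainv.apply(np.atleast_2d(p))))
    landmarks = {
        "medial_epicondyle": A.apply(np.array([24.0, 0.0, 0.0])),
        "lateral_epicondyle": A.apply(np.array([-26.0, 0.0, 0.0])),
        "humeral_shaft_proximal": A.apply(np.array([0.0, 0.0, L.humerus_length - 10.0])),
        "olecranon_tip": A.apply(np.array([_OLECRANON_TIP_X, -20.0, 25.0])),
        "trochlea_capitellum_boundary": A.apply(np.array([_TC_BOUNDARY_X, 0.0, -12.0])),
    }
    return ElbowScene(meshes["humerus"], meshes["ulna"], meshes["radius"],
                      landmarks, spec, implicits)


def _canonical_t140(spec: ElbowSpec) -> RigidTransform:
    d_flex = _perturbed_axis_direction(*spec.flexion_axis_perturbation)
    return (screw_motion(d_flex, (0, 0, 0), FULL_FLEXION_DEG - 90.0)
            @ screw_motion((1, 0, 0), (0, 0, 0), 90.0))


def make_poses(scene: ElbowScene, rom: tuple | None = None,
               axis_perturbation: tuple | None = None,
               rigid_noise_sd: float = 0.0,
               seed: int | None = None) -> PoseSet:
    """World poses of the three bones in the three scan positions.

    `rom` is clinical (max_extension_deg, max_flexion_deg); defaults to the
    scene's truth.  `rigid_noise_sd` adds a small seeded rigid jitter per
    scan (translation SD in mm, rotation SD the same number in degrees,
    clipped at 0.5 mm / 1 degree) modelling patient repositioning.
    """
    if rom is None:
        rom = scene.truth.rom_limits
    max_ext, max_flex = rom
    if not (max_ext < 90.0 < max_flex):
        raise ValueError("require max_extension_deg < 90 < max_flexion_deg")
    if max_ext > 0:
        raise ValueError("hyperextension (max_extension_deg > 0) is not modelled")
    if max_flex >= 150.0:
        raise ValueError("max_flexion_deg >= 150 is outside the modelled arc")
    if axis_perturbation is not None:
        vv, ir = axis_perturbation
        if max(abs(vv), abs(ir)) > 45.0:
            raise ValueError("axis perturbation beyond +-45 deg is non-physiologic")
        if tuple(axis_perturbation) != tuple(scene.truth.flexion_axis_perturbation):
            scene = replace_scene_perturbation(scene, axis_perturbation)
    theta = (-max_ext, 90.0, max_flex)
    rng = np.random.default_rng(np.random.SeedSequence(
        scene.truth.seed if seed is None else seed))
    poses = {}
    for name, th in zip(PoseSet.POSE_NAMES, theta):
        G = _jitter_transform(rng, rigid_noise_sd)
        T = scene.pose_transform(th)
        poses[name] = {"humerus": G, "ulna": G @ T, "radius": G @ T}
    return PoseSet(poses, theta)


def replace_scene_perturbation(scene: ElbowScene, perturbation: tuple) -> ElbowScene:
    """Scene with the same meshes but a different flexion-axis truth.

    The flexion-side contact construction is only exact for the spec's own
    perturbation; use for sensitivity checks, not ground-truth measurement.
    """
    new = ElbowScene(scene.humerus_mesh, scene.ulna_mesh, scene.radius_mesh,
                     scene.landmarks,
                     replace(scene.truth, flexion_axis_perturbation=tuple(perturbation)),
                     scene._implicits)
    return new


def _jitter_transform(rng: np.random.Generator, sd: float) -> RigidTransform:
    if sd <= 0:
        return RigidTransform.identity()
    rv = rng.normal(0.0, sd, 3)  # degrees
    n = np.linalg.norm(rv)
    if n > 1.0:
        rv *= 1.0 / n
    t = rng.normal(0.0, sd, 3)  # mm
    n = np.linalg.norm(t)
    if n > 0.5:
        t *= 0.5 / n
    return RigidTransform.from_rotvec(rv, t)


def make_cohort(cspec: CohortSpec) -> pd.DataFrame:
    """Tabular cohort: per-case ROM and per-region widths from the linear model.

    Widths are ``slope * angle + intercept + N(0, noise_sd)`` truncated at
    zero; each case draws from its own named substream so the table is
    reproducible independent of case order.  With the default
    ``noise_sd_mm=None`` the generating parameters are calibrated
    (truncation-aware) so the emitted cohort refits to the target lines and
    correlations; an explicit noise_sd uses the lines literally.
    """
    params = {}
    for region in RegionLabel:
        slope, intercept, r = cspec.lines[region]
        direction = "flexion" if region in FLEXION_REGIONS else "extension"
        if cspec.noise_sd_mm is None:
            params[region] = calibrate_generating_line(
                slope, intercept, r, tuple(cspec.rom_distribution[direction]))
        else:
            params[region] = (slope, intercept, cspec.region_noise_sd(region))
    streams = np.random.SeedSequence(cspec.seed).spawn(cspec.n_cases)
    rows = []
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        ext = _truncnorm(rng, *cspec.rom_distribution["extension"])
        flex = _truncnorm(rng, *cspec.rom_distribution["flexion"])
        row = {"case": i, "extension_deg": ext, "flexion_deg": flex}
        for region in RegionLabel:
            slope, intercept, sd = params[region]
            x = flex if region in FLEXION_REGIONS else ext
            w = slope * x + intercept + rng.normal(0.0, sd)
            row[REGION_COLUMNS[region]] = max(w, 0.0)
        rows.append(row)
    return pd.DataFrame(rows)


def _truncnorm(rng, mean, sd, lo, hi):
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(sps.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def make_case_spec(extension_deg: float, flexion_deg: float,
                   seed: int = 0,
                   axis_perturbation: tuple | None = None,
                   lines: dict | None = None,
                   mesh_resolution: float = 0.7) -> ElbowSpec:
    """ElbowSpec whose osteophyte sizes follow the width-vs-ROM calibration.

    Sizes are the per-region line evaluated at the case's ROM, clipped to
    the phantom's representable range; regions predicted non-positive carry
    no osteophyte.
    """
    lines = dict(DEFAULT_REGION_LINES) if lines is None else lines
    osteophytes = []
    for region in RegionLabel:
        slope, intercept, _ = lines[region]
        x = flexion_deg if region in FLEXION_REGIONS else extension_deg
        s = slope * x + intercept
        s = min(max(s, 0.0), MAX_OSTEOPHYTE_MM - 0.5)
        if s > 0.05:
            osteophytes.append(OsteophyteSpec(region, round(s, 2)))
    if axis_perturbation is None:
        axis_perturbation = (DEFAULT_AXIS_SHIFT["valgus"][0],
                             DEFAULT_AXIS_SHIFT["internal"][0])
    return ElbowSpec(osteophytes=tuple(osteophytes),
                     flexion_axis_perturbation=tuple(axis_perturbation),
                     rom_limits=(extension_deg, flexion_deg),
                     mesh_resolution=mesh_resolution, seed=seed)


def draw_case_specs(n_cases: int, seed: int = 0,
                    mesh_resolution: float = 0.7) -> list:
    """Seeded batch of case specs emulating the study cohort conditions.

    ROM is drawn from the cohort distribution, the flexion-axis shift from
    the study's valgus/internal shift distribution, and osteophyte sizes
    from the per-region calibration lines (noise-free inversion, so the
    scene truth is exactly the line value).
    """
    streams = np.random.SeedSequence(seed).spawn(n_cases)
    specs = []
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        # redraw ROMs whose motion arc to the 90-degree scan is below the
        # screw-axis reliability guard (the severely stiff elbow cannot be
        # simulated by the three-position protocol)
        while True:
            ext = _truncnorm(rng, *DEFAULT_ROM_DISTRIBUTION["extension"])
            flex = _truncnorm(rng, *DEFAULT_ROM_DISTRIBUTION["flexion"])
            if -ext >= 6.0 and flex >= 96.0:
                break
        vv = rng.normal(*DEFAULT_AXIS_SHIFT["valgus"])
        ir = rng.normal(*DEFAULT_AXIS_SHIFT["internal"])
        specs.append(make_case_spec(ext, flex, seed=int(rng.integers(2**31)),
                                    axis_perturbation=(vv, ir),
                                    mesh_resolution=mesh_resolution))
    return specs
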