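# impingesim

Three-position elbow motion simulation for osteoarthritis surgery planning,
on synthetic bone models with known ground truth.

## The problem

In arthroscopic surgery for elbow osteoarthritis the surgeon must decide
which impinging osteophytes to remove, and how much. One planning approach
images the elbow by CT in three positions (maximum extension, 90°, maximum
flexion), reconstructs bone surface models, computes the rotation axes of
the forearm, extrapolates the ulna and radius to simulated full extension
(0°) and full flexion (140°), and reads the bone-on-bone overlap in those
simulated positions as the osteophytes that block motion. The maximum width
of the overlap in five anatomical regions — posteromedial humeroulnar joint
(medial olecranon), posterolateral humeroulnar joint (lateral olecranon),
posterior capitellum, anterior humeroulnar joint (coronoid) and radial
fossa — is the planned resection depth, and relates linearly to the
pre-operative range of motion.

`impingesim` implements that whole chain as an open, testable pipeline:

* `synthetic` — a parametric elbow phantom (constructive-solid bones meshed
  by marching cubes) whose osteophytes are Gaussian bumps of known height
  placed so that their penetration at the simulated terminal pose equals
  the height exactly, plus a tabular cohort generator that inverts the
  width-vs-ROM regression model;
* `registration` — Kabsch superposition and point-to-point (optionally
  trimmed) ICP to superimpose the humeral models and express forearm
  motion in the common humeral frame;
* `kinematics` — finite helical (screw) axis extraction with the
  extension/flexion axis shift read in the coronal (varus–valgus) and
  axial (internal–external rotation) planes;
* `impingement` — pose extrapolation about the screw axes, mesh-overlap
  detection by signed distance, connected-component clustering, maximum
  penetration depth per region, and post-operative residual measurement;
* `stats` — OLS regression with 95% prediction intervals for one new case,
  exact/asymptotic rank tests (Mann–Whitney, Kruskal–Wallis, Friedman),
  single-measure intraclass correlations ICC(2,1)/ICC(1,1), and a-priori
  sample sizes for the Mann–Whitney test (ARE-adjusted noncentral *t*) and
  one-way ANOVA (noncentral *F*).

## The model in brief

For two scans of the same elbow, the relative forearm motion `T` (after
humeral superposition) is reduced to its screw axis: direction `n̂`, point
`p`, angle `θ` and pitch. The extension axis comes from the maximum
extension ↔ 90° pair, the flexion axis from the 90° ↔ maximum flexion pair.
A simulated angle `θ*` poses a bone by rotating it `θ* − θ` about the
relevant axis. The width of an overlap component is

    w = max over inside surface samples s of dist(s, humeral surface)

i.e. the deepest penetration, reported to 0.1 mm. Per region the cohort
model is `w = a·ROM + b + ε`, `ε ~ N(0, σ²)`, truncated at zero, with the
95% prediction interval `ŷ(x₀) ± t₍n−2₎ s √(1 + 1/n + (x₀−x̄)²/Sxx)`.

## Worked example

```python
from impingesim import (MeasureConfig, measure_elbow, make_case_spec,
                        make_elbow, make_poses)

spec = make_case_spec(extension_deg=-24, flexion_deg=119, seed=3,
                      axis_perturbation=(0.9, 5.2))   # valgus, internal
scene = make_elbow(spec)                              # three bone meshes
poses = make_poses(scene, rigid_noise_sd=0.3)         # three CT positions
res = measure_elbow(poses.posed_meshes(scene),
                    poses.landmarks_in_reference(scene), MeasureConfig())
print(res.to_json_dict())
```

prints (abridged)

```
extension -24.0, flexion 119.0
axis_change: 0.9 valgus, 5.2 internal
widths_0:   pm_huj 6.1, pl_huj 4.0, post_cap 2.1
widths_140: ant_huj 6.4, rad_fossa 1.7
```

— the generator placed osteophytes of 6.36 / 4.08 / 2.16 / 6.57 / 1.68 mm
(the per-region regression lines evaluated at this ROM), and the pipeline,
given only the posed meshes, recovers each width to within ~0.3 mm and the
flexion-axis shift to 0.1°.

The same flow from a shell:

```
impingesim generate --n 5 --seed 1 --out runs/demo
impingesim measure  --scenes runs/demo --out runs/demo_measured
impingesim stats    --cohort runs/demo/cohort.csv --out runs/demo_stats
impingesim power    --test mw --effect 1.56
```

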