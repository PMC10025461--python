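# gaitmesh

Markerless 3D gait tracking with a statistical body model, built for
robot-assisted gait therapy. A single RGB-D camera in front of a treadmill
yields per-frame colored point clouds; `gaitmesh` fits an articulated,
shape-parametric triangle mesh to every frame and quantifies how well the
tracked surface follows the body — even when an exoskeleton's cuffs, foot
straps and sliding bars contaminate the cloud and marker-based motion
capture is impractical.

## Who it is for

Movement scientists and rehabilitation engineers who want joint-level
kinematics during regular therapy sessions without attaching markers:
the patient just walks, the camera records, and the analysis happens
offline.

## The model and method

The body is a mesh `M(β, θ, t)` in the SMPL/STAR family:

- **shape** `β ∈ R¹⁰` — linear blend-shape coefficients
  (`V(β) = V₀ + B β`), with component 0 a global scale so body height can
  be imposed as a hard constraint;
- **pose** `θ ∈ R⁷²` — axis-angle rotations of 23 body joints + 1 root,
  applied by linear blend skinning along the kinematic tree, plus a root
  translation `t`;
- joint centers are regressed from the shaped template.

Each frame is registered by robust articulated ICP: correspondences from
cloud points to the closest model-surface point, then L-BFGS on

```
E = λ_data Σ_p ρ(d_p) + λ_aux ‖s_t − s_{t−1}‖² + λ_ankle Σ max(0, φ − φ_max)²
    + λ_prior ‖θ‖² + λ_temp ‖θ_t − θ_{t−1}‖²
```

with ρ a saturating (Geman–McClure) penalty. Shape is optimized only on
the first five frames and frozen to their mean. Two auxiliary rigid
8-vertex "foot strap" shapes (6 dof each) absorb the strap clusters near
the insteps so they cannot drag the feet; excessive ankle dorsiflexion is
charged quadratically.

Validation follows the sticker protocol: eight bright-green stickers
(left/right acromioclavicular, anterior spina iliaca, patella, hallux) are
detected by a hue filter, located by the median of their 3D points, and
tracked. For each sticker the best-matching model vertex over all frames
is selected, and the sticker-to-vertex distance series is decomposed into
a placement **offset**, a **systematic** error at stride-frequency
harmonics (survives averaging over strides) and a broadband **random**
error (averages out), together with the 3D Pearson correlation and the
fraction of frames under fixed error thresholds.

Because the learned STAR/SMIL bases are not redistributable, the package
ships a procedural capsule-body with identical tensor shapes (`make_toy_model`)
plus an OBJ+JSON loader for externally supplied bases, and a synthetic
recording generator with full ground truth, so the entire pipeline is
testable offline.

## Worked example

```python
import numpy as np
from gaitmesh import (FitConfig, default_gait_profile, fit_sequence,
                      generate_walk, joint_centers, make_toy_model)

model = make_toy_model(1000, seed=1)
rec = generate_walk(model, default_gait_profile(), duration_s=1.0, fps=30,
                    noise_sd=0.002, seed=3, n_points=1500,
                    include_floor=False)
fit = fit_sequence([f.points for f in rec.frames], model, height=1.70)

err = 1000 * np.linalg.norm(joint_centers(model, fit)
                            - rec.truth_joints(model), axis=2)
k = model.tree.index("left_knee")
r = np.corrcoef(rec.truth_poses[:, k, 0], fit.poses[:, k, 0])[0, 1]
print(f"mean joint error {err.mean():.1f} mm, knee flexion r = {r:.3f}")
```

prints (30 frames, ~3 min on one CPU):

```
mean joint error 1.1 mm, knee flexion r = 0.996
```

meaning the fitted joint centers track the generating skeleton to ~2 mm
on average and the knee flexion trace is nearly indistinguishable from
truth. `examples/` contains one narrative script per capability
(model, synthetic data, segmentation, fitting, sticker validation, power
analysis), and the `gaitmesh` CLI wires them into a reproducible pipeline
(`gaitmesh all --config cfg.yaml --out run/`).

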