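# Methods

## Body model

The model is a statistical body mesh in the SMPL/STAR family. Vertices in
the canonical (standing) pose are `V(β) = V₀ + B β` with a 10-component
linear shape basis `B`; a joint regressor maps shaped vertices to the 24
rest joint centers (pelvis root + 23 body joints); posing is linear blend
skinning with per-joint axis-angle rotations (72 pose parameters) plus a
root translation. Axis-angle vectors are canonicalized to magnitude < π so
temporal differences are meaningful.

The learned bases of STAR (adults) and SMIL (infants) are not
redistributable, so the package generates a procedural humanoid with the
same tensor shapes: 24 capsules (one per bone, each a closed orientable
surface) whose first cross-section ring is centered exactly on its joint,
which makes a sparse uniform joint regressor exact. Trunk, head and leg
capsules have elliptical cross-sections (the trunk is flattened
front-to-back like a real torso) — besides looking less like a lamp post,
this makes axial twist observable to a surface fitter, which it is not on
a surface of revolution. Shape component 0 is a global scale about the
ground point (8 % of stature per unit), the others are smooth per-segment
length/girth/width modes. Skinning weights are hard
(one bone per vertex): blending is unnecessary for disjoint capsules, and
every algorithm downstream treats the weights as general sparse rows, so a
learned model with soft weights loads and runs unchanged through the
OBJ + JSON loader (`save_model` / `load_model`, schema v1).

Adult/infant interpolation acts on **all** tensors (template, shape basis,
joint regressor, skin weights, with weight rows re-normalized), not only
the template; whether the original pipeline interpolated only templates is
not documented, and interpolating everything keeps the result a valid
model by construction. The default blending coefficient maps participant
height linearly from [0.8 m, 1.8 m] to [0, 1] (`height_to_alpha`).

Body height is a **hard** constraint: a 1-D root solve on shape
component 0 (Brent's method, 1 mm tolerance) with the other components
fixed. Height is defined as the canonical-pose vertical extent
(head-top to heel); the achievable range for the default model spans well
beyond the 1.25–1.76 m of children and adolescents.

## Synthetic recordings

The generator emulates a 30 fps depth camera 1.5 m in front of a treadmill:

- joint trajectories are sinusoids at the stride frequency (default
  1.2 Hz, the typical walking cadence), hips/knees/ankles antiphase
  left–right, small arm swing, root sway/bob with zero net displacement
  (treadmill walking);
- per frame, points are sampled area-weighted on camera-facing triangles
  (back-face culling; full z-buffer self-occlusion is deliberately not
  modeled, but points buried *inside* another body part — an artifact of
  the capsule junctions that no camera could produce — are removed by a
  step-along-the-normal containment test), then isotropic Gaussian noise
  is added (default sd 2 mm, the depth noise of the class of camera
  emulated);
- joint sinusoid phases are chosen so foot clearance peaks once per
  stride, putting the fundamental of the foot trajectory at the cadence
  (knee flexion peaking 3/8 cycle after hip flexion); the whole recording
  is lifted so the lowest body point always clears the floor plane, since
  pure sinusoids do not enforce ground contact;
- default 1,500 body points per frame — one to two orders of magnitude
  sparser than a real depth frame, chosen so a full pipeline run fits in
  minutes on one CPU; contaminant clusters are correspondingly a larger
  *fraction* of the cloud than in reality, which makes the robustness
  tests conservative in that respect;
- exoskeleton contaminants: partial tori around mid-thigh and mid-shank
  (cuffs), flat box clusters 5 cm above each instep that move rigidly with
  the foot (foot straps), and two vertical bars 20 cm lateral of the body
  midline (sliding bars);
- eight sticker discs (radius 8 mm, point-symmetric pattern so the
  noiseless centroid is exactly the landmark) at the posed landmark
  vertices, bright green, with an optional per-frame occlusion fraction;
- floor points with two red marker stripes for ground-plane estimation.

All randomness flows from explicit seeds; identical seeds give
byte-identical recordings. Ground truth (per-frame pose, shape, sticker
positions) is stored with the recording.

## Segmentation

Least-squares (SVD) plane through red-stripe points when color is
available, else the lowest 5 % height band; normal oriented camera-up.
Foreground keeps points more than a 2 cm clearance above the plane inside
a treadmill-sized working volume (1.2 m wide, depth band 0.8–2.5 m,
2.2 m tall). Robot points inside the volume are kept on purpose — they
cannot be separated reliably and the fitter is built to tolerate them.

## Fitting

Robust articulated ICP per frame:

1. **Correspondence.** Each cloud point is matched to the closest point on
   the current model surface. The fast path proposes candidate triangles
   from the k nearest vertices (k = 6); the certified path bounds the true
   closest triangle with a radius search (`r_nn + longest_edge/√3`) and is
   exact. Sweeps use the fast path while parameters move, and switch to
   certified correspondences once the update step falls below 1 mm/mrad
   (and always on the final sweep), which removes the small tangential
   bias of the k-NN proposals. With straps enabled, a point is assigned to
   a strap when the strap's box surface is closer than the body by more
   than a 6 mm margin — the margin prevents the strap from starving the
   instep of data.
2. **Refinement.** L-BFGS on the energy with the correspondences frozen
   (barycentric coordinates within the matched triangle), gradients by
   batched forward differences (one vectorized posing pass per parameter,
   h = 1e−6). Pose + translation (+ shape on initialization frames,
   + 6-dof strap states) are free.
3. **Annealing.** The robust scale starts `gnc_start`× larger (default 4×,
   8× for the cold start) and anneals to 1× on the last sweep (graduated
   non-convexity), so limbs far outside the final scale still feel a pull
   early. The trimmed-ICP gate (default 4 cm; points farther than the gate
   from their assigned target are dropped for that sweep) anneals with the
   same factor, so cold starts are never starved.

Defaults: Geman–McClure penalty with 3 cm scale (`robust="huber"` and
`"quadratic"` available; Huber is exactly quadratic below its scale),
λ_data = 1, λ_aux_motion = 10, λ_ankle = 10 rad⁻² with a 0.7 rad
dorsiflexion limit, λ_pose_prior = 1e−3 (root orientation excluded),
λ_temporal = 0.1. The data term uses the model **surface**; matching each
point to its closest *vertex* instead is available
(`data_term="vertex"`) but is biased at ~1,000-vertex resolution (a point
on a face is ~1 cm from the nearest vertex), so the surface term is the
default. The aux-motion weight charges the squared frame-to-frame change
of the strap's 6-dof state; 10 (m⁻², rad⁻²) lets a strap follow a foot
moving several cm per frame while damping jitter — a much stiffer strap
simply stays behind and stops absorbing its cluster.

Sequences: the first frame is bootstrapped from the canonical standing
pose at the cloud centroid with a long pose-only schedule (25 sweeps,
certified correspondences, 8× annealing). Each initialization frame is fit
pose-only first and only then jointly with shape, so shape modes cannot
absorb pose lag; during shape optimization a quadratic prior (weight 1)
pins the non-scale components that a single frontal view leaves ambiguous
(girth trades against depth translation), and the height constraint is
re-projected after every sweep — it is a hard constraint, not a loss. The
shape is frozen to the component-wise mean of the five initialization
estimates (re-projected), after which the initialization frames are
revisited backward with the frozen shape and warm starts from their
settled neighbors, removing the cold-start transient from the reported
poses. Tracking frames are warm-started by constant-velocity extrapolation
of the two previous frames (pose, translation and strap states) — at
1.2 Hz cadence and 30 fps a foot moves up to ~6 cm between frames, which
plain warm starts chase with a visible lag. Initialization can still fail
on an unlucky frame; `select_init_frame` ranks candidate start frames by a
cheap single-sweep residual, and `--init-frame` overrides it.

Determinism: fixed seeds subsample large clouds; there are no stochastic
optimizer steps; refitting identical inputs reproduces identical results.

## Validation statistics

- **Shape comparison**: per-vertex distances between two identically posed
  fits of the same subject, averaged per region (7 regions) and overall;
  across subjects the median and IQR with the linear (type-7) quartile
  convention.
- **Reference vertex**: the vertex minimizing the mean distance to the
  sticker over valid frames (ties to the lowest ID), then used for all
  frames.
- **Stride frequency**: dominant non-DC rfft peak of the mean-removed
  vertical trajectory over the longest valid run, Hann-windowed, refined
  by parabolic interpolation of the log-magnitude; a configured cadence
  overrides it.
- **Error decomposition**: `d_t = ‖sticker_t − vertex_t‖` on valid frames;
  offset = mean, sd = fluctuation. The mean-removed series is projected by
  least squares onto sin/cos pairs at harmonics k·f (k = 1..6, below
  Nyquist) evaluated at the valid time stamps — this handles gaps without
  interpolation and keeps the split exactly orthogonal
  (systematic² + random² = sd², Pythagoras in the sample space). The
  systematic magnitude convention is the **RMS of the harmonic
  component**; comparisons against other reports must match conventions.
  "3D Pearson r" is the unweighted mean of the three per-axis
  correlations. Threshold CDFs are computed on |d_t − offset| at
  {5, 10, 20, 30, 50, 100} mm. Gaps are never interpolated; invalid frames
  carry NaN sentinels so accidental use poisons the result visibly.
- **Power**: smallest n with two-sided one-sample noncentral-t power ≥ the
  target; minimum 2.

## Numerical choices and degenerate inputs

- Quartiles: type-7 (linear interpolation) everywhere.
- Harmonics above Nyquist are dropped from the projection.
- A constant vertical trajectory or a peak below 5× the median spectral
  floor raises an error suggesting manual cadence entry.
- Sticker clusters: single-linkage by 3 cm radius, minimum 4 points; two
  stickers closer than the linkage radius merge (documented failure
  mode). Track assignment is one-to-one (Hungarian) with a 6 cm gate that
  grows (capped at 4×) while a track is occluded.
- Empty segmentation output warns and returns an empty set rather than
  raising, so batch runs continue.

## What the synthetic tests do and do not show

Passing recovery tests shows the estimator is correct and robust under
the generator's assumptions: sinusoidal kinematics, isotropic noise,
back-face-culled visibility, rigid contaminant geometry, and a body that
lies exactly in the model family. Real recordings add soft tissue and
clothing deformation, depth-dependent noise and flying pixels, full
self-occlusion, model mismatch (a real child is not a capsule body), and
color variation in sticker detection. None of those are exercised here;
conclusions about absolute accuracy on real data require the sticker
protocol on real recordings.

## Known limitations

- Capsule limbs are rotationally symmetric, so axial twist is observable
  only through the pose prior; distal arm joints (wrists, hands) are
  weakly constrained when few points hit them.
- The fitter is offline (roughly 1–3 s per frame at the default problem
  sizes); no real-time claim.
- One subject per recording; no multi-person handling.
- Cuff clusters close to the shank surface (~2–4 cm) still bias the knees
  by a few millimeters in heavily contaminated clouds; the gate and the
  saturating penalty bound, but do not eliminate, that pull.
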