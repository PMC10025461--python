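"""Parametric articulated 3D body model.

A statistical body model in the SMPL/STAR family: a triangle-mesh template
whose vertices are deformed by a 10-component linear shape basis (identity)
and articulated by linear blend skinning over a 24-joint kinematic tree
(23 body joints + one root), 3 axis-angle degrees of freedom per joint plus
a root translation (72 + 3 pose parameters).

The learned bases of STAR/SMIL are not redistributable; this module ships a
procedurally generated humanoid (:func:`make_toy_model`) with identical
tensor shapes and a loader for externally supplied bases in an OBJ + JSON
layout, so the whole pipeline runs without any download.

Conventions: right-handed camera frame, +Y up after ground-plane alignment,
+Z from the camera toward the subject; all geometry in meters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import trimesh

__all__ = [
    "JOINT_NAMES",
    "PARENT_INDEX",
    "REGIONS",
    "KinematicTree",
    "BodyModel",
    "AuxStrap",
    "rodrigues",
    "canonicalize_pose",
    "pose_model",
    "apply_height_constraint",
    "interpolate_models",
    "make_toy_model",
    "make_foot_strap",
    "save_model",
    "load_model",
]

# SMPL-compatible joint naming: one root (pelvis) + 23 body joints.
JOINT_NAMES = [
    "pelvis", "left_hip", "right_hip", "spine1",
    "left_knee", "right_knee", "spine2",
    "left_ankle", "right_ankle", "spine3",
    "left_foot", "right_foot", "neck",
    "left_collar", "right_collar", "head",
    "left_shoulder", "right_shoulder",
    "left_elbow", "right_elbow",
    "left_wrist", "right_wrist",
    "left_hand", "right_hand",
]

PARENT_INDEX = [-1, 0, 0, 0, 1, 2, 3, 4, 5, 6, 7, 8, 9, 9, 9, 12,
                13, 14, 16, 17, 18, 19, 20, 21]

N_JOINTS = 24
N_SHAPE = 10

#: The seven body regions used for shape comparisons.
REGIONS = ["head", "trunk", "arms", "hands", "thighs", "shanks", "feet"]


@dataclass(frozen=True)
class KinematicTree:
    """Joint names and parent relation of the articulation skeleton."""

    joint_names: tuple = tuple(JOINT_NAMES)
    parent_index: tuple = tuple(PARENT_INDEX)

    def __post_init__(self):
        if len(self.joint_names) != N_JOINTS or len(self.parent_index) != N_JOINTS:
            raise ValueError(f"kinematic tree must have exactly {N_JOINTS} joints")
        roots = [i for i, p in enumerate(self.parent_index) if p < 0]
        if roots != [0]:
            raise ValueError("tree must have a single root at index 0")
        for i, p in enumerate(self.parent_index):
            if i > 0 and not (0 <= p < i):
                raise ValueError("parents must precede children (topological order)")

    def index(self, name: str) -> int:
        return self.joint_names.index(name)


@dataclass
class BodyModel:
    """Template mesh + shape basis + skinning data of a statistical body model.

    Attributes
    ----------
    template_vertices : (V, 3) float array
        Canonical-pose vertex positions in meters.
    faces : (F, 3) int array
        Triangle indices (outward-oriented winding).
    shape_basis : (V, 3, 10) float array
        Linear displacement basis; shaped vertices are
        ``template + shape_basis @ beta``.
    joint_regressor : (24, V) float array
        Maps shaped vertices to rest joint centers.
    skin_weights : (V, 24) float array
        Convex linear-blend-skinning weights (rows sum to 1).
    region_labels : (V,) array of str
        One of the seven regions per vertex.
    tree : KinematicTree
    """

    template_vertices: np.ndarray
    faces: np.ndarray
    shape_basis: np.ndarray
    joint_regressor: np.ndarray
    skin_weights: np.ndarray
    region_labels: np.ndarray
    tree: KinematicTree = field(default_factory=KinematicTree)

    # -- basic derived quantities -------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return self.template_vertices.shape[0]

    def validate(self) -> None:
        """Raise ``ValueError`` if any structural invariant is violated."""
        V = self.n_vertices
        if self.template_vertices.shape != (V, 3):
            raise ValueError("template_vertices must be (V, 3)")
        if self.shape_basis.shape != (V, 3, N_SHAPE):
            raise ValueError(f"shape_basis must be (V, 3, {N_SHAPE})")
        if self.joint_regressor.shape != (N_JOINTS, V):
            raise ValueError(f"joint_regressor must be ({N_JOINTS}, V)")
        if self.skin_weights.shape != (V, N_JOINTS):
            raise ValueError(f"skin_weights must be (V, {N_JOINTS})")
        if np.any(self.skin_weights < -1e-12):
            raise ValueError("skin weights must be nonnegative")
        if not np.allclose(self.skin_weights.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("skin weight rows must sum to 1")
        if self.region_labels.shape != (V,):
            raise ValueError("region_labels must be (V,)")
        bad = set(np.unique(self.region_labels)) - set(REGIONS)
        if bad:
            raise ValueError(f"unknown region labels: {sorted(bad)}")
        if self.faces.min() < 0 or self.faces.max() >= V:
            raise ValueError("face indices out of range")

    def shaped_vertices(self, beta: np.ndarray) -> np.ndarray:
        """Shaped (but unposed) vertices ``template + shape_basis @ beta``."""
        beta = _check_beta(beta)
        return self.template_vertices + self.shape_basis @ beta

    def rest_joints(self, beta: np.ndarray) -> np.ndarray:
        """(24, 3) rest joint centers regressed from the shaped vertices."""
        return self.joint_regressor @ self.shaped_vertices(beta)

    def height(self, beta: np.ndarray | None = None) -> float:
        """Vertical (head-top to heel) extent of the canonical-pose model."""
        v = self.shaped_vertices(np.zeros(N_SHAPE) if beta is None else beta)
        return float(v[:, 1].max() - v[:, 1].min())

    def as_trimesh(self, vertices: np.ndarray | None = None) -> trimesh.Trimesh:
        v = self.template_vertices if vertices is None else vertices
        return trimesh.Trimesh(vertices=v, faces=self.faces, process=False)

    def copy(self) -> "BodyModel":
        return BodyModel(
            template_vertices=self.template_vertices.copy(),
            faces=self.faces.copy(),
            shape_basis=self.shape_basis.copy(),
            joint_regressor=self.joint_regressor.copy(),
            skin_weights=self.skin_weights.copy(),
            region_labels=self.region_labels.copy(),
            tree=self.tree,
        )


#: triangulation of the 8 strap corners (ordering: x, y, z sign bits)
STRAP_FACES = np.array([
    [0, 1, 3], [0, 3, 2],      # -x
    [4, 7, 5], [4, 6, 7],      # +x
    [0, 5, 1], [0, 4, 5],      # -y
    [2, 3, 7], [2, 7, 6],      # +y
    [0, 2, 6], [0, 6, 4],      # -z
    [1, 5, 7], [1, 7, 3],      # +z
], dtype=np.int64)


@dataclass
class AuxStrap:
    """Auxiliary rigid foot-strap shape used only during fitting.

    A small 8-vertex rigid body (a flattened box over the instep,
    triangulated by :data:`STRAP_FACES`) with 6 degrees of freedom
    (axis-angle rotation + translation) attached near one foot. Strap
    vertices never carry a body-region label and are excluded from every
    shape/pose analysis output.
    """

    local_vertices: np.ndarray          # (8, 3), centered on the strap origin
    attachment_joint: int               # joint index (left_foot or right_foot)
    state: np.ndarray = field(default_factory=lambda: np.zeros(6))  # (rotvec, t)

    def world_vertices(self, state: np.ndarray | None = None) -> np.ndarray:
        s = self.state if state is None else np.asarray(state, dtype=float)
        if s.shape != (6,):
            raise ValueError("strap state must have 6 degrees of freedom")
        R = rodrigues(s[:3])
        return self.local_vertices @ R.T + s[3:]


# -----------------------------------------------------------------------------
# rotations and skinning
# -----------------------------------------------------------------------------

def rodrigues(axis_angle: np.ndarray) -> np.ndarray:
    """Axis-angle vectors (..., 3) to rotation matrices (..., 3, 3)."""
    aa = np.asarray(axis_angle, dtype=float)
    theta = np.linalg.norm(aa, axis=-1, keepdims=True)
    small = theta < 1e-12
    axis = np.where(small, 0.0, aa / np.where(small, 1.0, theta))
    t = theta[..., 0]
    c, s = np.cos(t), np.sin(t)
    x, y, z = axis[..., 0], axis[..., 1], axis[..., 2]
    zero = np.zeros_like(x)
    K = np.stack([
        np.stack([zero, -z, y], axis=-1),
        np.stack([z, zero, -x], axis=-1),
        np.stack([-y, x, zero], axis=-1),
    ], axis=-2)
    eye = np.broadcast_to(np.eye(3), K.shape)
    outer = axis[..., :, None] * axis[..., None, :]
    return (c[..., None, None] * eye
            + s[..., None, None] * K
            + (1.0 - c)[..., None, None] * outer)


def canonicalize_pose(pose: np.ndarray) -> np.ndarray:
    """Wrap per-joint axis-angle magnitudes into [0, pi).

    An axis-angle vector of magnitude theta >= pi represents the same
    rotation as one of magnitude 2*pi - theta about the flipped axis;
    canonicalizing avoids wrap-around jumps in temporal smoothing.
    """
    p = np.asarray(pose, dtype=float).reshape(-1, 3).copy()
    mag = np.linalg.norm(p, axis=1)
    fix = mag >= np.pi
    if np.any(fix):
        m = mag[fix]
        wrapped = np.mod(m, 2 * np.pi)
        new_mag = np.where(wrapped > np.pi, wrapped - 2 * np.pi, wrapped)
        p[fix] = p[fix] / m[:, None] * new_mag[:, None]
    return p.reshape(np.asarray(pose).shape)


def _check_beta(beta) -> np.ndarray:
    beta = np.asarray(beta, dtype=float).reshape(-1)
    if beta.shape != (N_SHAPE,):
        raise ValueError(f"shape parameters must have {N_SHAPE} components")
    if not np.all(np.isfinite(beta)):
        raise ValueError("shape parameters must be finite")
    return beta


def _check_pose(pose, translation):
    pose = np.asarray(pose, dtype=float)
    if pose.size != 3 * N_JOINTS:
        raise ValueError(f"pose must have {3 * N_JOINTS} parameters")
    pose = pose.reshape(-1, N_JOINTS, 3)
    t = np.asarray(translation, dtype=float)
    if t.size % 3 != 0:
        raise ValueError("root translation must be a 3-vector")
    if not (np.all(np.isfinite(pose)) and np.all(np.isfinite(t))):
        raise ValueError("pose parameters must be finite")
    return pose, t.reshape(-1, 3)


def _skinning_transforms(pose: np.ndarray, rest_joints: np.ndarray,
                         parents) -> tuple[np.ndarray, np.ndarray]:
    """World transforms per joint for a batch of poses.

    Parameters
    ----------
    pose : (B, 24, 3) axis-angle
    rest_joints : (24, 3)

    Returns
    -------
    R : (B, 24, 3, 3) world rotations
    t : (B, 24, 3) world translations such that a rest-frame point ``x``
        skinned to joint j maps to ``R[j] @ (x - j_rest) + j_posed``,
        i.e. ``R[j] @ x + t[j]`` with ``t[j] = j_posed - R[j] @ j_rest``.
    """
    B = pose.shape[0]
    Rl = rodrigues(pose)                       # (B, 24, 3, 3)
    Rw = np.empty_like(Rl)
    jw = np.empty((B, N_JOINTS, 3))
    Rw[:, 0] = Rl[:, 0]
    jw[:, 0] = rest_joints[0]
    for j in range(1, N_JOINTS):
        p = parents[j]
        Rw[:, j] = Rw[:, p] @ Rl[:, j]
        offset = rest_joints[j] - rest_joints[p]
        jw[:, j] = jw[:, p] + np.einsum("bij,j->bi", Rw[:, p], offset)
    t = jw - np.einsum("bjik,jk->bji", Rw, rest_joints)
    return Rw, t, jw


def lbs(shaped_vertices: np.ndarray, rest_joints: np.ndarray,
        skin_weights: np.ndarray, pose: np.ndarray, translation: np.ndarray,
        parents=PARENT_INDEX):
    """Linear blend skinning for a batch of poses.

    ``shaped_vertices`` may be (V, 3) (shared across the batch) or (B, V, 3).
    ``pose`` is (B, 24, 3), ``translation`` (B, 3). Returns posed vertices
    (B, V, 3) and posed joint centers (B, 24, 3).
    """
    Rw, t, jw = _skinning_transforms(pose, rest_joints, parents)
    # per-vertex blended transform: A_v = sum_j w_vj [Rw_j | t_j]
    Rv = np.einsum("vj,bjik->bvik", skin_weights, Rw)       # (B, V, 3, 3)
    tv = np.einsum("vj,bjk->bvk", skin_weights, t)          # (B, V, 3)
    if shaped_vertices.ndim == 2:
        posed = np.einsum("bvik,vk->bvi", Rv, shaped_vertices) + tv
    else:
        posed = np.einsum("bvik,bvk->bvi", Rv, shaped_vertices) + tv
    return posed + translation[:, None, :], jw + translation[:, None, :]


def pose_model(model: BodyModel, beta, pose, translation=(0.0, 0.0, 0.0)):
    """Pose the body model.

    Applies the shape blend shapes, regresses rest joint centers, then runs
    linear blend skinning along the kinematic tree and adds the root
    translation.

    Returns
    -------
    vertices : (V, 3) posed vertex positions (meters)
    joints : (24, 3) posed joint centers
    """
    beta = _check_beta(beta)
    pose, t = _check_pose(pose, translation)
    shaped = model.shaped_vertices(beta)
    rest_j = model.joint_regressor @ shaped
    v, j = lbs(shaped, rest_j, model.skin_weights, pose, t,
               model.tree.parent_index)
    return v[0], j[0]


# -----------------------------------------------------------------------------
# height constraint and model interpolation
# -----------------------------------------------------------------------------

def apply_height_constraint(model: BodyModel, beta, target_height: float,
                            prior_radius: float = 5.0) -> np.ndarray:
    """Solve for the global-scale shape component so the canonical-pose
    model height equals ``target_height`` (hard constraint, 1 mm tolerance).

    Only shape component 0 (global scale by construction of the basis) is
    adjusted; the remaining components are left untouched.
    """
    if not (0.5 < target_height < 2.2):
        raise ValueError("target height must be in (0.5, 2.2) m")
    beta = _check_beta(beta).copy()

    def h(b0):
        b = beta.copy()
        b[0] = b0
        return model.height(b) - target_height

    lo, hi = -prior_radius, prior_radius
    h_lo, h_hi = h(lo), h(hi)
    if h_lo * h_hi > 0:
        reachable = sorted([h_lo + target_height, h_hi + target_height])
        raise ValueError(
            f"target height {target_height:.3f} m unreachable; achievable "
            f"range within the shape prior is [{reachable[0]:.3f}, "
            f"{reachable[1]:.3f}] m")
    from scipy.optimize import brentq
    beta[0] = brentq(h, lo, hi, xtol=1e-6)
    assert abs(model.height(beta) - target_height) < 1e-3
    return beta


def interpolate_models(adult: BodyModel, infant: BodyModel,
                       alpha: float) -> BodyModel:
    """Convex combination ``alpha * adult + (1 - alpha) * infant``.

    Both models must share topology (vertex count, faces, joint count); all
    learned tensors (template, shape basis, joint regressor, skin weights)
    are interpolated, and skin weights are re-normalized to sum to 1.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    mism = []
    if adult.n_vertices != infant.n_vertices:
        mism.append(f"V: {adult.n_vertices} vs {infant.n_vertices}")
    elif adult.faces.shape != infant.faces.shape or np.any(adult.faces != infant.faces):
        mism.append("faces differ")
    if mism:
        raise ValueError("topology mismatch: " + "; ".join(mism))
    if alpha == 1.0:
        return adult.copy()
    if alpha == 0.0:
        return infant.copy()
    w = alpha
    sw = w * adult.skin_weights + (1 - w) * infant.skin_weights
    sw = sw / sw.sum(axis=1, keepdims=True)
    return BodyModel(
        template_vertices=w * adult.template_vertices + (1 - w) * infant.template_vertices,
        faces=adult.faces.copy(),
        shape_basis=w * adult.shape_basis + (1 - w) * infant.shape_basis,
        joint_regressor=w * adult.joint_regressor + (1 - w) * infant.joint_regressor,
        skin_weights=sw,
        region_labels=adult.region_labels.copy(),
        tree=adult.tree,
    )


def height_to_alpha(height_m: float, lo: float = 0.8, hi: float = 1.8) -> float:
    """Default adult/infant blending rule: participant height mapped
    linearly from [0.8 m, 1.8 m] to [0, 1], clipped."""
    return float(np.clip((height_m - lo) / (hi - lo), 0.0, 1.0))


# -----------------------------------------------------------------------------
# procedural toy model
# -----------------------------------------------------------------------------

def _capsule(p0, p1, r0, r1, n_rings, n_seg, phase=0.0, ellipticity=1.0):
    """Closed capsule (frustum with apex caps) from p0 to p1.

    Ring 0 is centered exactly on p0 (its centroid IS p0), which the joint
    regressor exploits. ``ellipticity`` scales the cross-section along the
    first transverse axis (the anterior direction for vertical capsules),
    making e.g. the trunk flatter front-to-back like a real torso — which
    also makes axial twist observable. Returns (vertices, faces) with
    outward winding.
    """
    p0, p1 = np.asarray(p0, float), np.asarray(p1, float)
    axis = p1 - p0
    length = np.linalg.norm(axis)
    u = axis / length
    # stable orthonormal frame
    ref = np.array([1.0, 0.0, 0.0]) if abs(u[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(u, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u, e1)

    theta = 2 * np.pi * np.arange(n_seg) / n_seg + phase
    circ = (ellipticity * np.cos(theta)[:, None] * e1
            + np.sin(theta)[:, None] * e2)                # (S, 3)

    verts = [p0 - 0.6 * r0 * u]
    for k in range(n_rings):
        t = k / (n_rings - 1)
        c = p0 + t * axis
        r = (1 - t) * r0 + t * r1
        verts.append(c + r * circ)
    verts.append(p1 + 0.6 * r1 * u)
    verts = np.vstack([np.atleast_2d(v) for v in verts])

    S = n_seg
    apex0, apex1 = 0, 1 + n_rings * S
    ring = lambda k, s: 1 + k * S + (s % S)
    faces = []
    for s in range(S):
        faces.append([apex0, ring(0, s), ring(0, s + 1)])
    for k in range(n_rings - 1):
        for s in range(S):
            a, b = ring(k, s), ring(k, s + 1)
            c, d = ring(k + 1, s + 1), ring(k + 1, s)
            faces.append([a, d, c])
            faces.append([a, c, b])
    for s in range(S):
        faces.append([apex1, ring(n_rings - 1, s + 1), ring(n_rings - 1, s)])
    faces = np.asarray(faces, dtype=np.int64)
    # orient outward: flip if the signed volume comes out negative
    v0, v1, v2 = (verts[faces[:, i]] for i in range(3))
    vol = np.einsum("ij,ij->i", v0, np.cross(v1, v2)).sum() / 6.0
    if vol < 0:
        faces = faces[:, [0, 2, 1]]
    return verts, faces


def _toy_skeleton(H: float) -> np.ndarray:
    """Rest joint positions (24, 3) for a standing humanoid of height ~H."""
    f = lambda x, y, z: np.array([x * H, y * H, z * H])
    hw = 0.055          # hip half-width
    sw = 0.115          # shoulder half-width
    arm = np.array([np.sin(np.deg2rad(20)), -np.cos(np.deg2rad(20)), 0.0])
    j = np.zeros((N_JOINTS, 3))
    j[0] = f(0.0, 0.57, 0.0)                       # pelvis
    j[1] = f(+hw, 0.53, 0.0)                       # left_hip
    j[2] = f(-hw, 0.53, 0.0)                       # right_hip
    j[3] = f(0.0, 0.65, 0.0)                       # spine1
    j[4] = f(+hw, 0.285, 0.0)                      # left_knee
    j[5] = f(-hw, 0.285, 0.0)                      # right_knee
    j[6] = f(0.0, 0.73, 0.0)                       # spine2
    j[7] = f(+hw, 0.055, 0.0)                      # left_ankle
    j[8] = f(-hw, 0.055, 0.0)                      # right_ankle
    j[9] = f(0.0, 0.81, 0.0)                       # spine3
    j[10] = f(+hw, 0.030, -0.10)                   # left_foot (toe base)
    j[11] = f(-hw, 0.030, -0.10)                   # right_foot
    j[12] = f(0.0, 0.875, 0.0)                     # neck
    j[13] = f(+0.045, 0.855, 0.0)                  # left_collar
    j[14] = f(-0.045, 0.855, 0.0)                  # right_collar
    j[15] = f(0.0, 0.915, 0.0)                     # head
    j[16] = f(+sw, 0.845, 0.0)                     # left_shoulder
    j[17] = f(-sw, 0.845, 0.0)                     # right_shoulder
    mirror = np.array([-1.0, 1.0, 1.0])
    j[18] = j[16] + 0.17 * H * arm                 # left_elbow
    j[19] = j[17] + 0.17 * H * (arm * mirror)      # right_elbow
    j[20] = j[18] + 0.16 * H * arm                 # left_wrist
    j[21] = j[19] + 0.16 * H * (arm * mirror)      # right_wrist
    j[22] = j[20] + 0.05 * H * arm                 # left_hand
    j[23] = j[21] + 0.05 * H * (arm * mirror)      # right_hand
    return j


def make_toy_model(n_vertices: int = 1000, seed: int = 0,
                   height: float = 1.70) -> BodyModel:
    """Deterministic procedural humanoid body model.

    Capsule-based limbs on the 24-joint tree; each capsule is a closed
    orientable surface. The 10-component shape basis is smooth with
    component 0 a global scale about the ground point and the others
    per-segment length/girth modes. Identical (n_vertices, seed, height)
    always yields a byte-identical model.
    """
    if n_vertices < 500:
        raise ValueError("n_vertices must be at least 500")
    rng = np.random.default_rng(seed)
    H = float(height)
    J = _toy_skeleton(H)
    idx = {n: i for i, n in enumerate(JOINT_NAMES)}

    def above(j, dy):  # head-top helper
        return J[j] + np.array([0.0, dy * H, 0.0])

    # (start, end, r0, r1, skin joint, region, cross-section ellipticity)
    # the trunk is flattened front-to-back like a real torso (which also
    # makes trunk axial twist observable to the fitter); the head is
    # slightly deeper than wide
    r = lambda x: x * H
    specs = [
        (J[0], J[3], r(0.082), r(0.070), 0, "trunk", 0.72),
        (J[3], J[6], r(0.070), r(0.066), 3, "trunk", 0.72),
        (J[6], J[9], r(0.066), r(0.074), 6, "trunk", 0.72),
        (J[9], J[12], r(0.074), r(0.045), 9, "trunk", 0.72),
        (J[12], J[15], r(0.032), r(0.034), 12, "head", 1.0),
        (J[15], above(15, 0.052), r(0.055), r(0.050), 15, "head", 1.12),
        (J[13], J[16], r(0.022), r(0.024), 13, "trunk", 1.0),
        (J[14], J[17], r(0.022), r(0.024), 14, "trunk", 1.0),
        (J[16], J[18], r(0.033), r(0.028), 16, "arms", 1.0),
        (J[17], J[19], r(0.033), r(0.028), 17, "arms", 1.0),
        (J[18], J[20], r(0.028), r(0.022), 18, "arms", 1.0),
        (J[19], J[21], r(0.028), r(0.022), 19, "arms", 1.0),
        (J[20], J[22], r(0.018), r(0.016), 20, "hands", 1.0),
        (J[21], J[23], r(0.018), r(0.016), 21, "hands", 1.0),
        (J[22], J[22] + 0.05 * H * (J[22] - J[20]) / np.linalg.norm(J[22] - J[20]),
         r(0.016), r(0.012), 22, "hands", 1.0),
        (J[23], J[23] + 0.05 * H * (J[23] - J[21]) / np.linalg.norm(J[23] - J[21]),
         r(0.016), r(0.012), 23, "hands", 1.0),
        (J[1], J[4], r(0.048), r(0.036), 1, "thighs", 0.85),
        (J[2], J[5], r(0.048), r(0.036), 2, "thighs", 0.85),
        (J[4], J[7], r(0.036), r(0.024), 4, "shanks", 0.88),
        (J[5], J[8], r(0.036), r(0.024), 5, "shanks", 0.88),
        (J[7], J[10], r(0.022), r(0.018), 7, "feet", 1.0),
        (J[8], J[11], r(0.022), r(0.018), 8, "feet", 1.0),
        (J[10], J[10] + np.array([0, -0.004 * H, -0.045 * H]), r(0.017), r(0.013), 10, "feet", 1.0),
        (J[11], J[11] + np.array([0, -0.004 * H, -0.045 * H]), r(0.017), r(0.013), 11, "feet", 1.0),
    ]

    # allocate the vertex budget by capsule surface area
    areas = np.array([np.linalg.norm(np.asarray(p1) - np.asarray(p0)) * (r0 + r1)
                      for p0, p1, r0, r1, _, _, _ in specs])
    share = areas / areas.sum()

    all_v, all_f, all_w, all_region = [], [], [], []
    regressor_rows = {}
    offset = 0
    for (p0, p1, r0, r1, joint, region, ell), frac in zip(specs, share):
        budget = max(14, int(round(frac * n_vertices)))
        S = 8 if budget >= 34 else 6
        R = max(2, int(round((budget - 2) / S)))
        phase = float(rng.uniform(0, 2 * np.pi / S))
        jr0 = r0 * float(1 + 0.02 * rng.standard_normal())
        jr1 = r1 * float(1 + 0.02 * rng.standard_normal())
        v, f = _capsule(p0, p1, jr0, jr1, R, S, phase=phase, ellipticity=ell)
        all_v.append(v)
        all_f.append(f + offset)
        w = np.zeros((v.shape[0], N_JOINTS))
        w[:, joint] = 1.0
        all_w.append(w)
        all_region.append(np.full(v.shape[0], region, dtype=object))
        # ring 0 (indices 1..S) is centered exactly on p0 == joint center
        if joint not in regressor_rows:
            regressor_rows[joint] = (offset + 1, S)
        offset += v.shape[0]

    verts = np.vstack(all_v)
    faces = np.vstack(all_f)
    weights = np.vstack(all_w)
    regions = np.concatenate(all_region).astype("U8")

    # rescale so canonical extent is exactly `height`
    extent = verts[:, 1].max() - verts[:, 1].min()
    ymin = verts[:, 1].min()
    scale = H / extent
    verts = verts * scale
    verts[:, 1] -= ymin * scale  # feet on y = 0

    regressor = np.zeros((N_JOINTS, verts.shape[0]))
    for joint, (start, S) in regressor_rows.items():
        regressor[joint, start:start + S] = 1.0 / S

    joints = regressor @ verts  # post-rescale joint centers

    basis = _toy_shape_basis(verts, joints, regions, H)
    model = BodyModel(
        template_vertices=verts, faces=faces, shape_basis=basis,
        joint_regressor=regressor, skin_weights=weights,
        region_labels=regions, tree=KinematicTree(),
    )
    model.validate()
    return model


def _smooth_bump(y, lo, hi):
    """C1 bump: 0 outside [lo, hi], 1 at center (cosine window)."""
    t = np.clip((y - lo) / (hi - lo), 0.0, 1.0)
    return 0.5 * (1 - np.cos(2 * np.pi * t)) * ((y >= lo) & (y <= hi))


def _toy_shape_basis(verts, joints, regions, H):
    """10 smooth displacement modes: global scale + segment length/girth."""
    V = verts.shape[0]
    idx = {n: i for i, n in enumerate(JOINT_NAMES)}
    B = np.zeros((V, 3, N_SHAPE))
    y = verts[:, 1]

    # 0: global scale about the ground point under the pelvis (8 % per unit)
    B[:, :, 0] = 0.08 * verts

    # 1: trunk girth
    w = _smooth_bump(y, 0.50 * H, 0.90 * H) * (regions == "trunk")
    B[:, 0, 1] = 0.35 * w * verts[:, 0]
    B[:, 2, 1] = 0.35 * w * verts[:, 2]

    # 2: leg length (stretch everything below the pelvis downward)
    yp = joints[idx["pelvis"], 1]
    B[:, 1, 2] = -0.10 * H * np.clip((yp - y) / yp, 0.0, 1.0)

    # 3: arm length/size about each shoulder
    for side, sh in (("left", "left_shoulder"), ("right", "right_shoulder")):
        m = np.isin(regions, ["arms", "hands"]) & (
            np.sign(verts[:, 0]) == np.sign(joints[idx[sh], 0]))
        B[m, :, 3] = 0.15 * (verts[m] - joints[idx[sh]])

    # 4: head size about the head joint
    m = regions == "head"
    B[m, :, 4] = 0.25 * (verts[m] - joints[idx["head"]])

    # 5/6: thigh and shank girth (radial from the vertical leg axis)
    for comp, reg in ((5, "thighs"), (6, "shanks")):
        m = regions == reg
        for hip in ("left_hip", "right_hip"):
            side = m & (np.sign(verts[:, 0]) == np.sign(joints[idx[hip], 0]))
            ax = joints[idx[hip]]
            B[side, 0, comp] = 0.30 * (verts[side, 0] - ax[0])
            B[side, 2, comp] = 0.30 * (verts[side, 2] - ax[2])

    # 7: foot length about each ankle
    m = regions == "feet"
    for ank in ("left_ankle", "right_ankle"):
        side = m & (np.sign(verts[:, 0]) == np.sign(joints[idx[ank], 0]))
        B[side, :, 7] = 0.30 * (verts[side] - joints[idx[ank]])

    # 8: shoulder width
    w = _smooth_bump(y, 0.75 * H, 0.92 * H)
    B[:, 0, 8] = 0.15 * w * verts[:, 0]

    # 9: trunk length (stretch between pelvis and neck, carry head/arms up)
    yn = joints[idx["neck"], 1]
    B[:, 1, 9] = 0.08 * H * np.clip((y - yp) / (yn - yp), 0.0, 1.0)
    return B


def make_foot_strap(model: BodyModel, side: str,
                    beta: np.ndarray | None = None) -> AuxStrap:
    """Build the auxiliary 8-vertex rigid foot-strap shape for one foot.

    A flattened box over the instep, 6 degrees of freedom; its rest state
    places it at the canonical-pose instep of the requested foot.
    """
    if side not in ("left", "right"):
        raise ValueError("side must be 'left' or 'right'")
    ji = model.tree.index(f"{side}_foot")
    ja = model.tree.index(f"{side}_ankle")
    rest = model.rest_joints(np.zeros(N_SHAPE) if beta is None else beta)
    center = 0.55 * rest[ja] + 0.45 * rest[ji] + np.array([0.0, 0.05, 0.0])
    dx, dy, dz = 0.045, 0.012, 0.035
    corners = np.array([[sx * dx, sy * dy, sz * dz]
                        for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)],
                       dtype=float)
    state = np.zeros(6)
    state[3:] = center
    return AuxStrap(local_vertices=corners, attachment_joint=ji, state=state)


# -----------------------------------------------------------------------------
# OBJ + JSON model I/O (documented schema, versioned)
# -----------------------------------------------------------------------------

MODEL_SCHEMA_VERSION = 1


def save_model(model: BodyModel, obj_path, json_path) -> None:
    """Write the template mesh as OBJ and all model tensors as a JSON sidecar."""
    mesh = model.as_trimesh()
    mesh.export(str(obj_path), file_type="obj")
    payload = {
        "schema_version": MODEL_SCHEMA_VERSION,
        "joint_names": list(model.tree.joint_names),
        "parent_index": list(model.tree.parent_index),
        "shape_basis": model.shape_basis.tolist(),
        "joint_regressor": model.joint_regressor.tolist(),
        "skin_weights": model.skin_weights.tolist(),
        "region_labels": model.region_labels.tolist(),
    }
    with open(json_path, "w") as fh:
        json.dump(payload, fh)


def load_model(obj_path, json_path) -> BodyModel:
    """Load a body model from an OBJ template + JSON sidecar (schema v1)."""
    mesh = trimesh.load(str(obj_path), file_type="obj", process=False)
    with open(json_path) as fh:
        payload = json.load(fh)
    if payload.get("schema_version") != MODEL_SCHEMA_VERSION:
        raise ValueError("unsupported model schema version")
    tree = KinematicTree(tuple(payload["joint_names"]),
                         tuple(payload["parent_index"]))
    model = BodyModel(
        template_vertices=np.asarray(mesh.vertices, dtype=float),
        faces=np.asarray(mesh.faces, dtype=np.int64),
        shape_basis=np.asarray(payload["shape_basis"], dtype=float),
        joint_regressor=np.asarray(payload["joint_regressor"], dtype=float),
        skin_weights=np.asarray(payload["skin_weights"], dtype=float),
        region_labels=np.asarray(payload["region_labels"], dtype="U8"),
        tree=tree,
    )
    model.validate()
    return model
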