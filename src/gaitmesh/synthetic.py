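"""Ground-truthed synthetic recordings of a walking subject.

Emulates a 30 fps depth camera ~1.5 m in front of a person walking on a
treadmill: per-frame colored point clouds sampled on the camera-facing body
surface with ~2 mm isotropic depth noise, optional floor points with two
red marker stripes, contaminant clusters from exoskeleton hardware (thigh
and shank cuffs, foot straps, lateral sliding bars), and eight bright-green
sticker blobs at body landmarks. Every recording carries its full ground
truth (per-frame pose, shape, sticker positions) so recovery can be scored
exactly.

The camera sits at the origin looking along +Z; the subject stands near
z = 1.5 m facing the camera (anterior = -Z), with +Y up and the floor at
y = 0. Treadmill walking is emulated by keeping the root near a fixed
position with small periodic sway instead of overground progression.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

from .body_model import BodyModel, JOINT_NAMES, N_SHAPE, pose_model

__all__ = [
    "GaitProfile",
    "Frame",
    "SyntheticRecording",
    "default_gait_profile",
    "default_landmarks",
    "LANDMARK_NAMES",
    "generate_walk",
    "add_robot_parts",
    "add_stickers",
    "write_recording",
    "load_frame_ply",
]

#: Canonical sticker landmark names (left/right of four anatomical sites).
LANDMARK_NAMES = [
    "left_acromioclavicular", "right_acromioclavicular",
    "left_spina_iliaca", "right_spina_iliaca",
    "left_patella", "right_patella",
    "left_hallux", "right_hallux",
]

STICKER_COLOR = np.array([0.10, 0.90, 0.15])   # bright green
FLOOR_COLOR = np.array([0.45, 0.45, 0.45])
STRIPE_COLOR = np.array([0.90, 0.08, 0.08])    # red marker stripes
BODY_COLOR = np.array([0.75, 0.62, 0.52])
ROBOT_COLOR = np.array([0.25, 0.25, 0.28])


@dataclass
class GaitProfile:
    """Sinusoidal joint-angle program for treadmill walking.

    Per-joint axis-angle trajectories are
    ``offset + amplitude * sin(2*pi*cadence*t + phase)`` with hips, knees
    and ankles antiphase between left and right. Cadence defaults to the
    typical 1.2 Hz stride frequency of walking.
    """

    cadence_hz: float = 1.2
    amplitude: dict = field(default_factory=dict)   # joint -> (3,) radians
    phase: dict = field(default_factory=dict)       # joint -> (3,) radians
    offset: dict = field(default_factory=dict)      # joint -> (3,) radians
    treadmill_speed: float = 0.8                    # m/s, net displacement 0

    def __post_init__(self):
        if not (0.5 < self.cadence_hz < 2.0):
            raise ValueError("cadence must be in (0.5, 2.0) Hz")

    def pose_at(self, t: float) -> np.ndarray:
        """(24, 3) axis-angle pose at time t (seconds)."""
        theta = np.zeros((24, 3))
        w = 2 * np.pi * self.cadence_hz
        for joint, amp in self.amplitude.items():
            ji = JOINT_NAMES.index(joint)
            ph = np.asarray(self.phase.get(joint, np.zeros(3)))
            off = np.asarray(self.offset.get(joint, np.zeros(3)))
            theta[ji] = off + np.asarray(amp) * np.sin(w * t + ph)
        return theta

    def root_translation_at(self, t: float, subject_z: float = 1.5) -> np.ndarray:
        """Root sway/bob around a fixed treadmill position (net zero)."""
        w = 2 * np.pi * self.cadence_hz
        sway = 0.010 * np.sin(w * t)
        bob = 0.012 * np.sin(2 * w * t)
        fore_aft = 0.015 * self.treadmill_speed * np.sin(w * t + 0.7)
        return np.array([sway, bob, subject_z + fore_aft])


def default_gait_profile(cadence_hz: float = 1.2,
                         treadmill_speed: float = 0.8) -> GaitProfile:
    """Walking program: hip/knee/ankle flexion sinusoids, antiphase L/R,
    with a small antiphase arm swing."""
    x = np.array([1.0, 0.0, 0.0])  # flexion axis
    amp = {
        "left_hip": 0.30 * x, "right_hip": 0.30 * x,
        "left_knee": 0.30 * x, "right_knee": 0.30 * x,
        "left_ankle": 0.12 * x, "right_ankle": 0.12 * x,
        "left_shoulder": 0.10 * x, "right_shoulder": 0.10 * x,
    }
    # knee flexion peaks 3/8 cycle after hip flexion (swing phase), which
    # also puts the foot-clearance fundamental at the stride frequency
    phase = {
        "left_hip": np.zeros(3), "right_hip": np.pi * x,
        "left_knee": 0.75 * np.pi * x, "right_knee": 1.75 * np.pi * x,
        "left_ankle": (np.pi / 3) * x, "right_ankle": (np.pi / 3 + np.pi) * x,
        "left_shoulder": np.pi * x, "right_shoulder": np.zeros(3),
    }
    offset = {
        "left_knee": -0.30 * x, "right_knee": -0.30 * x,
    }
    return GaitProfile(cadence_hz=cadence_hz, amplitude=amp, phase=phase,
                       offset=offset, treadmill_speed=treadmill_speed)


@dataclass
class Frame:
    """One observed point cloud: positions (N, 3) m, colors (N, 3) in [0,1],
    and a per-point origin label ('body', 'floor', 'cuff', 'strap', 'bar'
    or 'sticker:<landmark>')."""

    points: np.ndarray
    colors: np.ndarray
    origin: np.ndarray

    @property
    def contaminant_mask(self) -> np.ndarray:
        return np.isin(self.origin, ["cuff", "strap", "bar"])

    def subset(self, mask: np.ndarray) -> "Frame":
        return Frame(self.points[mask], self.colors[mask], self.origin[mask])


@dataclass
class SyntheticRecording:
    frames: list                      # list[Frame]
    truth_poses: np.ndarray           # (T, 24, 3)
    truth_translations: np.ndarray    # (T, 3)
    truth_shape: np.ndarray           # (10,)
    fps: float = 30.0
    noise_sd: float = 0.002
    sticker_truth: dict = field(default_factory=dict)   # name -> (T, 3)
    sticker_present: dict = field(default_factory=dict)  # name -> (T,) bool
    landmarks: dict = field(default_factory=dict)        # name -> vertex id

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def truth_joints(self, model: BodyModel) -> np.ndarray:
        """(T, 24, 3) ground-truth posed joint centers."""
        out = np.empty((self.n_frames, 24, 3))
        for t in range(self.n_frames):
            _, out[t] = pose_model(model, self.truth_shape,
                                   self.truth_poses[t],
                                   self.truth_translations[t])
        return out


# -----------------------------------------------------------------------------
# landmark selection on the model
# -----------------------------------------------------------------------------

def default_landmarks(model: BodyModel) -> dict:
    """Pick the eight canonical sticker landmark vertices geometrically.

    Acromioclavicular = highest vertex near each shoulder joint;
    anterior spina iliaca = most anterior pelvis-band trunk vertex;
    patella = most anterior vertex near each knee; hallux = most anterior
    foot vertex (toe tip). Anterior is -Z in the canonical frame.
    """
    v = model.template_vertices
    joints = model.rest_joints(np.zeros(N_SHAPE))
    H = model.height()
    ji = model.tree.index
    out = {}
    for side in ("left", "right"):
        sgn = np.sign(joints[ji(f"{side}_hip"), 0])
        near = np.linalg.norm(v - joints[ji(f"{side}_shoulder")], axis=1) < 0.06 * H
        out[f"{side}_acromioclavicular"] = int(np.flatnonzero(near)[
            np.argmax(v[near, 1])])
        band = ((model.region_labels == "trunk")
                & (np.abs(v[:, 1] - joints[ji(f"{side}_hip"), 1]) < 0.07 * H)
                & (np.sign(v[:, 0]) == sgn))
        out[f"{side}_spina_iliaca"] = int(np.flatnonzero(band)[
            np.argmin(v[band, 2])])
        near = np.linalg.norm(v - joints[ji(f"{side}_knee")], axis=1) < 0.06 * H
        out[f"{side}_patella"] = int(np.flatnonzero(near)[
            np.argmin(v[near, 2])])
        foot = (model.region_labels == "feet") & (np.sign(v[:, 0]) == sgn)
        out[f"{side}_hallux"] = int(np.flatnonzero(foot)[
            np.argmin(v[foot, 2])])
    return out


# -----------------------------------------------------------------------------
# recording generation
# -----------------------------------------------------------------------------

def _sample_surface(mesh_v, faces, n, rng, mesh_dist=None,
                    view_dir=np.array([0.0, 0.0, 1.0])):
    """Area-weighted sampling on camera-facing triangles.

    Back-facing triangles are culled; points buried inside another body
    part (capsule junctions produce interior surface patches a real camera
    can never see) are removed by testing whether a short step along the
    local surface normal stays inside the mesh.
    """
    tri = mesh_v[faces]                               # (F, 3, 3)
    n_vec = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    visible = n_vec @ view_dir < 0.0
    areas = 0.5 * np.linalg.norm(n_vec, axis=1) * visible
    p = areas / areas.sum()
    n_draw = int(np.ceil(1.25 * n)) if mesh_dist is not None else n
    fi = rng.choice(len(faces), size=n_draw, p=p)
    u, w = rng.random(n_draw), rng.random(n_draw)
    flip = u + w > 1
    u[flip], w[flip] = 1 - u[flip], 1 - w[flip]
    bary = np.stack([1 - u - w, u, w], axis=1)
    pts = np.einsum("nk,nkd->nd", bary, tri[fi])
    if mesh_dist is None:
        return pts
    nrm = n_vec[fi] / np.linalg.norm(n_vec[fi], axis=1, keepdims=True)
    q = pts + 0.004 * nrm
    _, fq, bq = mesh_dist.query(q, mesh_v, exact=False)
    tq = mesh_v[mesh_dist.faces[fq]]
    nq = np.cross(tq[:, 1] - tq[:, 0], tq[:, 2] - tq[:, 0])
    closest = np.einsum("nk,nki->ni", bq, tq)
    outside = np.einsum("ni,ni->n", q - closest, nq) > 0
    return pts[outside][:n]


def _floor_points(rng, n=220, z_range=(1.0, 2.2), x_range=(-0.6, 0.6),
                  stripes=((1.15, 1.25), (1.85, 1.95))):
    pts = np.column_stack([
        rng.uniform(*x_range, n), np.zeros(n), rng.uniform(*z_range, n)])
    colors = np.tile(FLOOR_COLOR, (n, 1))
    on_stripe = np.zeros(n, dtype=bool)
    for lo, hi in stripes:
        on_stripe |= (pts[:, 2] >= lo) & (pts[:, 2] <= hi)
    colors[on_stripe] = STRIPE_COLOR
    return pts, colors


def generate_walk(model: BodyModel, profile: GaitProfile, duration_s: float,
                  fps: float = 30.0, noise_sd: float = 0.002, seed: int = 0,
                  n_points: int = 1500, beta: np.ndarray | None = None,
                  include_floor: bool = True,
                  subject_z: float = 1.5) -> SyntheticRecording:
    """Render a synthetic walking recording with full ground truth.

    Per frame: the model is posed by the gait profile, points are sampled
    area-weighted on camera-facing triangles, and isotropic Gaussian noise
    of sd ``noise_sd`` is added. Deterministic for a given seed.
    """
    n_frames = int(round(duration_s * fps))
    if n_frames < 10:
        raise ValueError("duration * fps must be at least 10 frames")
    rng = np.random.default_rng(seed)
    beta = np.zeros(N_SHAPE) if beta is None else np.asarray(beta, float)

    poses = np.empty((n_frames, 24, 3))
    trans = np.empty((n_frames, 3))
    posed = []
    for t in range(n_frames):
        tt = t / fps
        poses[t] = profile.pose_at(tt)
        trans[t] = profile.root_translation_at(tt, subject_z=subject_z)
        posed_v, _ = pose_model(model, beta, poses[t], trans[t])
        posed.append(posed_v)
    # sinusoidal joint programs do not enforce ground contact; lift the
    # whole recording so the lowest body point always clears the floor
    lift = max(0.0, 0.03 - min(v[:, 1].min() for v in posed))
    trans[:, 1] += lift

    from .geometry import MeshDistance
    md = MeshDistance(model.faces, model.n_vertices)
    frames = []
    for t in range(n_frames):
        posed_v = posed[t]
        posed_v[:, 1] += lift
        pts = _sample_surface(posed_v, model.faces, n_points, rng,
                              mesh_dist=md)
        colors = np.tile(BODY_COLOR, (len(pts), 1))
        colors += rng.normal(0, 0.02, colors.shape)
        origin = np.full(len(pts), "body", dtype="U40")
        if include_floor:
            fp, fc = _floor_points(rng)
            pts = np.vstack([pts, fp])
            colors = np.vstack([colors, fc])
            origin = np.concatenate([origin, np.full(len(fp), "floor", dtype="U40")])
        if noise_sd > 0:
            pts = pts + rng.normal(0, noise_sd, pts.shape)
        frames.append(Frame(pts, np.clip(colors, 0, 1), origin))

    return SyntheticRecording(frames=frames, truth_poses=poses,
                              truth_translations=trans, truth_shape=beta,
                              fps=fps, noise_sd=noise_sd)


def _ring_cluster(center, axis, radius, n, rng, arc=(np.pi, 2 * np.pi),
                  tube_sd=0.006):
    """Partial torus (cuff) around an axis; arc is in the plane normal to it."""
    u = axis / np.linalg.norm(axis)
    ref = np.array([1.0, 0, 0]) if abs(u[0]) < 0.9 else np.array([0.0, 1, 0])
    e1 = np.cross(u, ref); e1 /= np.linalg.norm(e1)
    e2 = np.cross(u, e1)
    th = rng.uniform(*arc, n)
    pts = center + radius * (np.cos(th)[:, None] * e1 + np.sin(th)[:, None] * e2)
    return pts + rng.normal(0, tube_sd, pts.shape)


def add_robot_parts(rec: SyntheticRecording, model: BodyModel, seed: int = 0,
                    density: float = 1.0,
                    parts=("cuffs", "straps", "bars")) -> SyntheticRecording:
    """Append exoskeleton contaminant clusters to every frame.

    Partial tori around thigh and shank circumferences (cuffs), box-shaped
    clusters over instep/ankle that move with each foot (foot straps), and
    two vertical bar clusters lateral to the thighs (sliding bars). Body
    points are untouched; contaminants carry origin labels 'cuff', 'strap'
    and 'bar'. ``density`` scales the cluster point counts (0 = no-op);
    ``parts`` selects which cluster kinds to add.
    """
    if density <= 0 or not parts:
        return rec
    rng = np.random.default_rng(seed)
    ji = model.tree.index
    joints_t = rec.truth_joints(model)
    n_cuff = max(1, int(round(30 * density)))
    n_strap = max(1, int(round(45 * density)))
    n_bar = max(1, int(round(35 * density)))

    frames = []
    for t, fr in enumerate(rec.frames):
        J = joints_t[t]
        clusters, labels = [], []
        if "cuffs" in parts:
            # cuffs mid-thigh and mid-shank, open toward the camera side
            for top, bot, rad in [
                (ji("left_hip"), ji("left_knee"), 0.105),
                (ji("right_hip"), ji("right_knee"), 0.105),
                (ji("left_knee"), ji("left_ankle"), 0.085),
                (ji("right_knee"), ji("right_ankle"), 0.085),
            ]:
                center = 0.5 * (J[top] + J[bot])
                axis = J[bot] - J[top]
                clusters.append(_ring_cluster(center, axis, rad, n_cuff, rng,
                                              arc=(-0.75 * np.pi, 0.75 * np.pi)))
                labels.append(np.full(n_cuff, "cuff", dtype="U40"))
        if "straps" in parts:
            # foot straps: boxes over the instep, moving with each foot
            for ank, toe in [(ji("left_ankle"), ji("left_foot")),
                             (ji("right_ankle"), ji("right_foot"))]:
                c = 0.55 * J[ank] + 0.45 * J[toe] + np.array([0, 0.05, 0])
                box = rng.uniform(-1, 1, (n_strap, 3)) * np.array(
                    [0.045, 0.012, 0.035])
                clusters.append(c + box)
                labels.append(np.full(n_strap, "strap", dtype="U40"))
        if "bars" in parts:
            # two vertical sliding bars lateral to the thighs
            for sx in (-1, 1):
                x = sx * 0.20
                z = rec.truth_translations[t][2]
                ys = rng.uniform(0.30, 0.90, n_bar)
                bar = np.column_stack([
                    np.full(n_bar, x), ys, np.full(n_bar, z)])
                bar += rng.normal(0, 0.004, bar.shape)
                clusters.append(bar)
                labels.append(np.full(n_bar, "bar", dtype="U40"))
        pts = np.vstack(clusters)
        if rec.noise_sd > 0:
            pts = pts + rng.normal(0, rec.noise_sd, pts.shape)
        colors = np.tile(ROBOT_COLOR, (len(pts), 1))
        colors += rng.normal(0, 0.01, colors.shape)
        frames.append(Frame(
            np.vstack([fr.points, pts]),
            np.vstack([fr.colors, np.clip(colors, 0, 1)]),
            np.concatenate([fr.origin, np.concatenate(labels)])))

    return SyntheticRecording(
        frames=frames, truth_poses=rec.truth_poses,
        truth_translations=rec.truth_translations, truth_shape=rec.truth_shape,
        fps=rec.fps, noise_sd=rec.noise_sd, sticker_truth=dict(rec.sticker_truth),
        sticker_present=dict(rec.sticker_present), landmarks=dict(rec.landmarks))


def _disc_pattern(n: int, radius: float):
    """Point-symmetric disc pattern whose centroid is exactly the center."""
    n = max(4, n + n % 2)
    half = n // 2
    th = 2 * np.pi * np.arange(half) / half
    r = np.where(np.arange(half) % 2 == 0, radius, 0.55 * radius)
    pts = np.column_stack([r * np.cos(th), r * np.sin(th)])
    return np.vstack([pts, -pts])


def add_stickers(rec: SyntheticRecording, model: BodyModel,
                 landmarks: dict | None = None, radius: float = 0.008,
                 n_points: int = 12, occlusion_fraction: float = 0.0,
                 seed: int = 0) -> SyntheticRecording:
    """Add eight sticker blobs at body landmarks to every frame.

    Each sticker is a small disc of bright-green points tangent to the body
    surface at the posed landmark vertex, lifted 0.5 mm along the vertex
    normal. A configurable fraction of (sticker, frame) pairs is dropped to
    emulate occlusions (e.g. an arm swinging in front of a sticker).
    """
    landmarks = default_landmarks(model) if landmarks is None else landmarks
    unknown = set(landmarks) - set(LANDMARK_NAMES)
    if unknown:
        raise ValueError(f"unknown landmark names: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    disc2d = _disc_pattern(n_points, radius)
    m = len(disc2d)

    truth = {name: np.empty((rec.n_frames, 3)) for name in landmarks}
    present = {name: np.ones(rec.n_frames, dtype=bool) for name in landmarks}
    for name in landmarks:
        drop = rng.random(rec.n_frames) < occlusion_fraction
        present[name] = ~drop

    frames = []
    for t, fr in enumerate(rec.frames):
        posed_v, _ = pose_model(model, rec.truth_shape, rec.truth_poses[t],
                                rec.truth_translations[t])
        mesh = trimesh.Trimesh(posed_v, model.faces, process=False)
        normals = mesh.vertex_normals
        pts_add, col_add, lab_add = [], [], []
        for name, vid in landmarks.items():
            center = posed_v[vid]
            truth[name][t] = center
            if not present[name][t]:
                continue
            nrm = normals[vid]
            ref = np.array([1.0, 0, 0]) if abs(nrm[0]) < 0.9 else np.array([0.0, 1, 0])
            e1 = np.cross(nrm, ref); e1 /= np.linalg.norm(e1)
            e2 = np.cross(nrm, e1)
            disc = center + disc2d[:, :1] * e1 + disc2d[:, 1:] * e2 + 0.0005 * nrm
            if rec.noise_sd > 0:
                disc = disc + rng.normal(0, rec.noise_sd, disc.shape)
            pts_add.append(disc)
            col_add.append(np.tile(STICKER_COLOR, (m, 1)))
            lab_add.append(np.full(m, f"sticker:{name}", dtype="U40"))
        if pts_add:
            frames.append(Frame(np.vstack([fr.points] + pts_add),
                                np.vstack([fr.colors] + col_add),
                                np.concatenate([fr.origin] + lab_add)))
        else:
            frames.append(Frame(fr.points.copy(), fr.colors.copy(),
                                fr.origin.copy()))

    return SyntheticRecording(
        frames=frames, truth_poses=rec.truth_poses,
        truth_translations=rec.truth_translations, truth_shape=rec.truth_shape,
        fps=rec.fps, noise_sd=rec.noise_sd, sticker_truth=truth,
        sticker_present=present, landmarks=dict(landmarks))


# -----------------------------------------------------------------------------
# writers
# -----------------------------------------------------------------------------

def _write_ply(path, points, colors) -> None:
    """ASCII PLY with per-point 8-bit color."""
    rgb = np.clip(np.round(np.asarray(colors) * 255), 0, 255).astype(int)
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {len(points)}\n")
        fh.write("property float x\nproperty float y\nproperty float z\n")
        fh.write("property uchar red\nproperty uchar green\nproperty uchar blue\n")
        fh.write("end_header\n")
        for p, c in zip(points, rgb):
            fh.write(f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f} {c[0]} {c[1]} {c[2]}\n")


def load_frame_ply(path) -> Frame:
    """Read one frame written by :func:`write_recording` (colors in [0,1])."""
    cloud = trimesh.load(str(path), process=False)
    pts = np.asarray(cloud.vertices, dtype=float)
    colors = np.asarray(cloud.colors, dtype=float)[:, :3] / 255.0
    return Frame(pts, colors, np.full(len(pts), "unknown", dtype="U40"))


def write_recording(rec: SyntheticRecording, out_dir) -> None:
    """Write per-frame colored PLY files plus ground truth as CSV/JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for t, fr in enumerate(rec.frames):
        _write_ply(out / f"frame_{t:05d}.ply", fr.points, fr.colors)
    pose_df = pd.DataFrame(
        rec.truth_poses.reshape(rec.n_frames, -1),
        columns=[f"{j}_{ax}" for j in JOINT_NAMES for ax in "xyz"])
    pose_df[["trans_x", "trans_y", "trans_z"]] = rec.truth_translations
    pose_df.to_csv(out / "truth_poses.csv", index_label="frame")
    if rec.sticker_truth:
        rows = []
        for name, arr in rec.sticker_truth.items():
            for t in range(rec.n_frames):
                rows.append((t, name, *arr[t], bool(rec.sticker_present[name][t])))
        pd.DataFrame(rows, columns=["frame", "name", "x", "y", "z", "present"]) \
            .to_csv(out / "truth_stickers.csv", index=False)
    meta = {
        "fps": rec.fps, "n_frames": rec.n_frames, "noise_sd": rec.noise_sd,
        "truth_shape": rec.truth_shape.tolist(),
        "landmarks": {k: int(v) for k, v in rec.landmarks.items()},
    }
    with open(out / "metadata.json", "w") as fh:
        json.dump(meta, fh, indent=2)
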