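"""Registration of the body model to per-frame point clouds.

Each frame is fit by iterated-closest-point sweeps: point-to-model
correspondences are computed against the current surface, then shape
(first frames only), pose, root translation and auxiliary strap states are
refined by L-BFGS on a robust objective:

    E = lambda_data    * sum_p rho(d_p)
      + lambda_aux     * ||strap_t - strap_{t-1}||^2
      + lambda_ankle   * sum_ankles max(0, flexion - ankle_limit)^2
      + lambda_prior   * ||theta||^2
      + lambda_temporal* ||theta_t - theta_{t-1}||^2

where d_p is the distance from point p to its assigned model target (the
closest surface point by default, or the closest vertex) and rho is a
robust penalty that caps the influence of contaminant points (robot cuffs,
straps, bars). Auxiliary rigid foot-strap shapes may take over the
contaminant points near the instep: a cloud point is assigned to a strap
whenever a strap vertex is closer than the body surface, so straps absorb
the pull that would otherwise distort the feet. Strap motion between
frames is allowed but charged by the aux-motion term; excessive ankle
dorsiflexion is charged quadratically beyond ``ankle_limit``.

Shape parameters are optimized only during the first ``n_init_frames``
frames and then frozen to their component-wise mean; all later frames
optimize pose (and strap states) only, warm-started from the previous
frame. Everything is deterministic for a fixed config seed.

Gradients are exact-to-first-order forward differences evaluated in a
single vectorized batch per L-BFGS iteration (one extra objective
evaluation per free parameter), which keeps the optimizer free of
hand-coded derivatives while remaining fast at ~1000 model vertices.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.optimize import minimize

from .body_model import (AuxStrap, BodyModel, N_SHAPE, STRAP_FACES,
                         apply_height_constraint, canonicalize_pose,
                         make_foot_strap, rodrigues)
from .geometry import MeshDistance, closest_point_on_triangles

__all__ = ["FitConfig", "FitResult", "objective", "fit_frame",
           "fit_sequence", "posed_vertices", "joint_centers",
           "select_init_frame"]

log = logging.getLogger(__name__)

MM = 1000.0


@dataclass
class FitConfig:
    """Knobs of the fitting objective and optimizer.

    Loss weights are exposed because no single set is canonical; the
    defaults below reproduce stable tracking on synthetic recordings.
    ``robust_scale`` is the distance scale (m) beyond which the robust
    penalty saturates; ``ankle_limit`` the dorsiflexion limit in radians.
    """

    n_init_frames: int = 5
    lambda_data: float = 1.0
    lambda_aux_motion: float = 10.0     # per (rad, m)^2 of strap state change
    lambda_ankle: float = 10.0          # rad^-2
    lambda_pose_prior: float = 1e-3
    #: quadratic prior on the non-scale shape components while shape is
    #: optimized; pins modes that a single frontal view leaves ambiguous
    #: (girth trades against depth translation)
    lambda_shape_prior: float = 1.0
    lambda_temporal: float = 0.1
    ankle_limit: float = 0.7
    robust: str = "gm"                  # gm | huber | quadratic
    robust_scale: float = 0.03
    #: trimmed-ICP gate (m): points farther than this from their assigned
    #: target are dropped from the sweep's data term (0 disables). The
    #: gate is widened by the same annealing factor as the robust scale,
    #: so cold starts are never starved of correspondences.
    corr_gate: float = 0.04
    #: a strap claims a point only when its surface is closer than the body
    #: by this margin (m), so straps cannot starve the instep of data
    strap_margin: float = 0.006
    data_term: str = "surface"          # surface | vertex
    use_straps: bool = False
    n_sweeps: int = 14
    max_iter: int = 20
    tol: float = 1e-7
    seed: int = 0
    max_points: int = 1500
    #: graduated non-convexity — the robust scale starts this many times
    #: larger on the first sweep and anneals to 1x on the last, so distal
    #: limbs far outside the final scale still feel a pull early on
    gnc_start: float = 4.0
    #: use certified-exact correspondences on every sweep (slower; the
    #: default uses them only on the final sweep)
    exact_corr: bool = False
    #: ICP sweeps for the cold-started first frame of a sequence (a cold
    #: start from the canonical pose needs many correspondence updates)
    cold_sweeps: int = 25

    def __post_init__(self):
        if self.n_init_frames < 1:
            raise ValueError("n_init_frames must be >= 1")
        for name in ("lambda_data", "lambda_aux_motion", "lambda_ankle",
                     "lambda_pose_prior", "lambda_temporal"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.robust not in ("gm", "huber", "quadratic"):
            raise ValueError("robust must be gm, huber or quadratic")
        if self.data_term not in ("surface", "vertex"):
            raise ValueError("data_term must be surface or vertex")


@dataclass
class FitResult:
    """Output of :func:`fit_sequence`."""

    shape: np.ndarray                 # (10,) frozen shape parameters
    init_shapes: np.ndarray           # (n_init, 10) per-init-frame estimates
    shapes: np.ndarray                # (T, 10) per-frame shape actually used
    poses: np.ndarray                 # (T, 24, 3) axis-angle
    translations: np.ndarray          # (T, 3)
    strap_states: dict                # side -> (T, 6) or empty
    residual_mean_mm: np.ndarray      # (T,) mean body point-to-model distance
    residual_median_mm: np.ndarray    # (T,)
    converged: np.ndarray             # (T,) bool
    config: FitConfig

    @property
    def n_frames(self) -> int:
        return len(self.poses)


def _rho(d, kind: str, scale: float):
    """Robust penalty of a distance array.

    gm:        Geman-McClure  c^2 d^2 / (c^2 + d^2)  (saturates at c^2)
    huber:     d^2 below c, linear growth c(2d - c) beyond (exactly
               quadratic in the small-residual regime)
    quadratic: d^2
    """
    if kind == "quadratic":
        return d * d
    if kind == "huber":
        return np.where(d <= scale, d * d, scale * (2 * d - scale))
    c2 = scale * scale
    return c2 * d * d / (c2 + d * d)


# -----------------------------------------------------------------------------
# batched forward model
# -----------------------------------------------------------------------------

class _Forward:
    """Vectorized posing of a subset of model vertices for parameter batches.

    Exploits sparse skinning weights: each vertex is posed by gathering its
    (few) supporting joint transforms instead of blending all 24.
    """

    def __init__(self, model: BodyModel):
        self.model = model
        self.parents = model.tree.parent_index
        w = model.skin_weights
        nz = [np.flatnonzero(r > 1e-12) for r in w]
        jmax = max(len(x) for x in nz)
        V = model.n_vertices
        self.j_idx = np.zeros((V, jmax), dtype=np.int64)
        self.j_w = np.zeros((V, jmax))
        for v, ids in enumerate(nz):
            self.j_idx[v, :len(ids)] = ids
            self.j_w[v, :len(ids)] = w[v, ids]

    def transforms(self, pose_b: np.ndarray, rest_joints: np.ndarray):
        """(B,24,3,3) rotations and (B,24,3) translations; rest_joints may
        be (24,3) shared or (B,24,3) per batch element."""
        B = pose_b.shape[0]
        Rl = rodrigues(pose_b)
        Rw = np.empty((B, 24, 3, 3))
        jw = np.empty((B, 24, 3))
        shared = rest_joints.ndim == 2
        rj = rest_joints if shared else None
        Rw[:, 0] = Rl[:, 0]
        jw[:, 0] = rest_joints[0] if shared else rest_joints[:, 0]
        for j in range(1, 24):
            p = self.parents[j]
            Rw[:, j] = Rw[:, p] @ Rl[:, j]
            if shared:
                off = rj[j] - rj[p]
                jw[:, j] = jw[:, p] + np.einsum("bik,k->bi", Rw[:, p], off)
            else:
                off = rest_joints[:, j] - rest_joints[:, p]
                jw[:, j] = jw[:, p] + np.einsum("bik,bk->bi", Rw[:, p], off)
        rj_full = rest_joints[None] if shared else rest_joints
        t = jw - np.einsum("bjik,bjk->bji", Rw, np.broadcast_to(rj_full, jw.shape))
        return Rw, t, jw

    def pose_vertices(self, vert_ids: np.ndarray, shaped: np.ndarray,
                      Rw: np.ndarray, t: np.ndarray, trans: np.ndarray):
        """Posed positions of the requested vertex ids.

        shaped: (V,3) shared or (B,V,3); returns (B, len(vert_ids), 3).
        """
        ji = self.j_idx[vert_ids]            # (n, jmax)
        wv = self.j_w[vert_ids]              # (n, jmax)
        Rg = Rw[:, ji]                       # (B, n, jmax, 3, 3)
        tg = t[:, ji]                        # (B, n, jmax, 3)
        if shaped.ndim == 2:
            x = shaped[vert_ids]             # (n, 3)
            posed = np.einsum("bnjik,nk->bnji", Rg, x) + tg
        else:
            x = shaped[:, vert_ids]          # (B, n, 3)
            posed = np.einsum("bnjik,bnk->bnji", Rg, x) + tg
        posed = np.einsum("nj,bnji->bni", wv, posed)
        return posed + trans[:, None, :]


# -----------------------------------------------------------------------------
# correspondences and energy
# -----------------------------------------------------------------------------

def _strap_world(local: np.ndarray, states: np.ndarray) -> np.ndarray:
    """(B, 8, 3) strap vertices for a batch of 6-dof states (B, 6)."""
    R = rodrigues(states[:, :3])
    return np.einsum("bik,vk->bvi", R, local) + states[:, None, 3:]


def _correspond(points, verts, mesh_dist, straps, strap_states, data_term,
                exact=False, strap_margin=0.0):
    """Assign every point to a body target or a strap-surface target.

    A point belongs to a strap when the strap's box surface is closer than
    the body. Returns a dict with the assignment, the frozen (face,
    barycentric) body correspondences (surface term) or closest vertex ids
    (vertex term), and frozen (triangle, barycentric) strap correspondences.
    """
    if data_term == "surface":
        d_body, face, bary = mesh_dist.query(points, verts, exact=exact)
    else:
        from scipy.spatial import cKDTree
        d_body, vid = cKDTree(verts).query(points)
        face, bary = vid, None        # face slot holds the vertex id
    n = len(points)
    assign_strap = np.full(n, -1)
    strap_tri = np.zeros(n, dtype=np.int64)
    strap_bary = np.zeros((n, 3))
    d_best = d_body.copy()
    for si, (strap, state) in enumerate(zip(straps, strap_states)):
        sv = _strap_world(strap.local_vertices, state[None])[0]   # (8, 3)
        tri = sv[STRAP_FACES]                                     # (12, 3, 3)
        cl, sb = closest_point_on_triangles(
            points[:, None], tri[None, :, 0], tri[None, :, 1], tri[None, :, 2])
        diff = points[:, None] - cl
        d2 = np.einsum("pti,pti->pt", diff, diff)
        best = np.argmin(d2, axis=1)
        rows = np.arange(n)
        d = np.sqrt(d2[rows, best])
        take = d < d_best - strap_margin
        assign_strap = np.where(take, si, assign_strap)
        strap_tri = np.where(take, best, strap_tri)
        strap_bary = np.where(take[:, None], sb[rows, best], strap_bary)
        d_best = np.where(take, d, d_best)
    body_mask = assign_strap < 0
    return {
        "body_mask": body_mask,
        "face": face, "bary": bary,
        "strap_of_point": assign_strap,
        "strap_tri": strap_tri, "strap_bary": strap_bary,
        "d_at_assignment": d_best,
    }


class _Energy:
    """Batched objective with frozen correspondences."""

    def __init__(self, points, model, forward, corr, config, *,
                 beta_fixed, pose_prev, strap_prev, straps,
                 optimize_shape):
        self.points = points
        self.model = model
        self.fw = forward
        self.corr = corr
        self.cfg = config
        self.beta_fixed = beta_fixed
        self.pose_prev = pose_prev
        self.strap_prev = strap_prev
        self.straps = straps
        self.optimize_shape = optimize_shape
        self.n_straps = len(straps)

        # trimmed correspondences: points farther than the gate from their
        # assigned target are left out of this sweep's data term
        gate = getattr(config, "corr_gate", 0.0) or 0.0
        if gate > 0:
            within = corr["d_at_assignment"] <= gate
            if not within.any():
                within[:] = True    # never fit against an empty set
        else:
            within = np.ones(len(points), dtype=bool)

        body = corr["body_mask"] & within
        self.body_points = points[body]
        if config.data_term == "surface":
            faces = model.faces[corr["face"][body]]      # (n, 3)
            self.bary = corr["bary"][body]               # (n, 3)
            self.used = np.unique(faces)
            self.remap = np.searchsorted(self.used, faces)
        else:
            vids = corr["face"][body]
            self.used = np.unique(vids)
            self.remap = np.searchsorted(self.used, vids)
        self.strap_points = []
        self.strap_tris = []
        self.strap_barys = []
        for si in range(self.n_straps):
            sel = (corr["strap_of_point"] == si) & within
            self.strap_points.append(points[sel])
            self.strap_tris.append(corr["strap_tri"][sel])
            self.strap_barys.append(corr["strap_bary"][sel])

        # parameter layout
        n = 72 + 3 + (N_SHAPE if optimize_shape else 0) + 6 * self.n_straps
        self.n_params = n

        if not optimize_shape:
            self._shaped = model.shaped_vertices(beta_fixed)
            self._rest_j = model.joint_regressor @ self._shaped

    def pack(self, pose, trans, beta, strap_states):
        parts = [np.asarray(pose).ravel(), np.asarray(trans).ravel()]
        if self.optimize_shape:
            parts.append(np.asarray(beta).ravel())
        for s in strap_states:
            parts.append(np.asarray(s).ravel())
        return np.concatenate(parts)

    def unpack(self, x):
        x = np.atleast_2d(x)
        B = x.shape[0]
        pose = x[:, :72].reshape(B, 24, 3)
        trans = x[:, 72:75]
        o = 75
        if self.optimize_shape:
            beta = x[:, o:o + N_SHAPE]
            o += N_SHAPE
        else:
            beta = None
        straps = []
        for _ in range(self.n_straps):
            straps.append(x[:, o:o + 6])
            o += 6
        return pose, trans, beta, straps

    def __call__(self, x):
        """Energy for a batch (B, n_params) -> (B,). Also usable on (n,)."""
        single = np.ndim(x) == 1
        pose, trans, beta, strap_states = self.unpack(x)
        B = pose.shape[0]
        cfg = self.cfg

        if self.optimize_shape:
            basis = self.model.shape_basis            # (V, 3, 10)
            shaped = self.model.template_vertices[None] + \
                np.einsum("vkc,bc->bvk", basis, beta)
            rest_j = np.einsum("jv,bvk->bjk", self.model.joint_regressor, shaped)
        else:
            shaped = self._shaped
            rest_j = self._rest_j

        Rw, t, _ = self.fw.transforms(pose, rest_j)
        posed_used = self.fw.pose_vertices(self.used, shaped, Rw, t, trans)

        if cfg.data_term == "surface":
            tri = posed_used[:, self.remap]            # (B, n, 3, 3)
            target = np.einsum("nk,bnki->bni", self.bary, tri)
        else:
            target = posed_used[:, self.remap]
        diff = target - self.body_points[None]
        d = np.sqrt(np.einsum("bni,bni->bn", diff, diff) + 1e-18)
        energy = cfg.lambda_data * _rho(d, cfg.robust, cfg.robust_scale).sum(axis=1)

        for si in range(self.n_straps):
            pts = self.strap_points[si]
            st = strap_states[si]
            if len(pts):
                sv = _strap_world(self.straps[si].local_vertices, st)
                tri = sv[:, STRAP_FACES[self.strap_tris[si]]]   # (B, n, 3, 3)
                target = np.einsum("nk,bnki->bni", self.strap_barys[si], tri)
                diff = target - pts[None]
                d = np.sqrt(np.einsum("bni,bni->bn", diff, diff) + 1e-18)
                energy += cfg.lambda_data * _rho(d, cfg.robust,
                                                 cfg.robust_scale).sum(axis=1)
            if self.strap_prev is not None:
                dstate = st - self.strap_prev[si][None]
                energy += cfg.lambda_aux_motion * np.einsum(
                    "bk,bk->b", dstate, dstate)

        if cfg.lambda_ankle > 0:
            for j in (7, 8):  # left_ankle, right_ankle
                flex = pose[:, j, 0]
                over = np.maximum(0.0, flex - cfg.ankle_limit)
                energy += cfg.lambda_ankle * over * over
        if cfg.lambda_pose_prior > 0:
            body_pose = pose[:, 1:]  # root orientation unregularized
            energy += cfg.lambda_pose_prior * np.einsum(
                "bjk,bjk->b", body_pose, body_pose)
        if self.optimize_shape and cfg.lambda_shape_prior > 0:
            b_ns = beta[:, 1:]       # global scale is height-constrained
            energy += cfg.lambda_shape_prior * np.einsum(
                "bk,bk->b", b_ns, b_ns)
        if cfg.lambda_temporal > 0 and self.pose_prev is not None:
            dpose = pose - self.pose_prev[None]
            energy += cfg.lambda_temporal * np.einsum(
                "bjk,bjk->b", dpose, dpose)
        return energy[0] if single else energy

    def breakdown(self, x):
        """Per-term decomposition of the energy at parameters x."""
        pose, trans, beta, strap_states = self.unpack(x)
        cfg = self.cfg
        total = float(self(x))
        terms = {}
        saved = (cfg.lambda_aux_motion, cfg.lambda_ankle,
                 cfg.lambda_pose_prior, cfg.lambda_temporal)
        zeroed = FitConfig(**{**asdict(cfg), "lambda_aux_motion": 0.0,
                              "lambda_ankle": 0.0, "lambda_pose_prior": 0.0,
                              "lambda_temporal": 0.0})
        old_cfg, self.cfg = self.cfg, zeroed
        terms["data"] = float(self(x))
        self.cfg = old_cfg
        # analytic penalty terms
        aux = 0.0
        if self.strap_prev is not None:
            for si in range(self.n_straps):
                ds = strap_states[si][0] - self.strap_prev[si]
                aux += float(cfg.lambda_aux_motion * ds @ ds)
        terms["aux_motion"] = aux
        ank = 0.0
        for j in (7, 8):
            over = max(0.0, float(pose[0, j, 0]) - cfg.ankle_limit)
            ank += cfg.lambda_ankle * over * over
        terms["ankle"] = ank
        bp = pose[0, 1:]
        terms["pose_prior"] = float(cfg.lambda_pose_prior * np.sum(bp * bp))
        tmp = 0.0
        if self.pose_prev is not None:
            dp = pose[0] - self.pose_prev
            tmp = float(cfg.lambda_temporal * np.sum(dp * dp))
        terms["temporal"] = tmp
        terms["total"] = total
        return terms


def _grad_fd(energy: _Energy, x: np.ndarray, h: float = 1e-6):
    """(f, grad) by one batched forward-difference sweep."""
    n = len(x)
    X = np.tile(x, (n + 1, 1))
    X[1:] += h * np.eye(n)
    E = energy(X)
    return E[0], (E[1:] - E[0]) / h


# -----------------------------------------------------------------------------
# public objective
# -----------------------------------------------------------------------------

def objective(points, model: BodyModel, shape, pose, translation,
              straps=None, strap_states=None, strap_states_prev=None,
              pose_prev=None, config: FitConfig | None = None,
              mesh_dist: MeshDistance | None = None):
    """Evaluate the fitting energy and its per-term breakdown.

    Correspondences are computed at the given state (closest surface point
    or closest vertex per ``config.data_term``). Returns
    ``(energy, breakdown_dict)``.
    """
    config = config or FitConfig()
    if (config.lambda_data == 0 and config.lambda_aux_motion == 0
            and config.lambda_ankle == 0 and config.lambda_pose_prior == 0
            and config.lambda_temporal == 0):
        raise ValueError("all loss weights are zero")
    points = np.asarray(points, dtype=float)
    if len(points) == 0:
        raise ValueError("empty point set")
    straps = straps or []
    strap_states = [np.asarray(s, float) for s in (strap_states or
                                                   [s.state for s in straps])]
    from .body_model import pose_model
    verts, _ = pose_model(model, shape, pose, translation)
    md = mesh_dist or MeshDistance(model.faces, model.n_vertices)
    corr = _correspond(points, verts, md, straps, strap_states,
                       config.data_term, exact=True,
                       strap_margin=config.strap_margin)
    fw = _Forward(model)
    en = _Energy(points, model, fw, corr, config,
                 beta_fixed=np.asarray(shape, float), pose_prev=pose_prev,
                 strap_prev=strap_states_prev, straps=straps,
                 optimize_shape=False)
    x = en.pack(np.asarray(pose, float).reshape(24, 3),
                np.asarray(translation, float), None, strap_states)
    return float(en(x)), en.breakdown(x)


# -----------------------------------------------------------------------------
# per-frame fit
# -----------------------------------------------------------------------------

def fit_frame(points, model: BodyModel, shape, init_pose, init_translation,
              config: FitConfig | None = None, *, optimize_shape=False,
              straps=None, strap_states_prev=None, pose_prev=None,
              mesh_dist: MeshDistance | None = None, forward=None,
              n_sweeps=None, max_iter=None, height_constraint=None):
    """Fit one frame by ICP sweeps (correspondence + L-BFGS refinement).

    Returns ``(pose, translation, shape, strap_states, diagnostics)``;
    ``shape`` equals the input unless ``optimize_shape``. When
    ``height_constraint`` is given (meters) and shape is optimized, the
    global-scale component is re-projected after every sweep so the model
    height stays hard-constrained. The result is flagged non-converged if
    the sweep schedule ran out while parameters were still moving.
    """
    config = config or FitConfig()
    points = np.asarray(points, dtype=float)
    if len(points) == 0:
        raise ValueError("empty point set")
    if not np.all(np.isfinite(init_pose)):
        raise ValueError("initial pose must be finite")
    rng = np.random.default_rng(config.seed)
    if len(points) > config.max_points:
        keep = rng.choice(len(points), config.max_points, replace=False)
        points = points[keep]

    md = mesh_dist or MeshDistance(model.faces, model.n_vertices)
    fw = forward or _Forward(model)
    straps = straps or []
    n_sweeps = n_sweeps or config.n_sweeps
    max_iter = max_iter or config.max_iter

    beta = np.asarray(shape, float).copy()
    pose = np.asarray(init_pose, float).reshape(24, 3).copy()
    trans = np.asarray(init_translation, float).copy()
    if straps:
        strap_states = [s.state.copy() for s in straps]
    else:
        strap_states = []

    from .body_model import pose_model
    converged = False
    sweep = 0
    sweep_energies = []
    polish = False
    while sweep < n_sweeps:
        # exact correspondences on the final sweep — and from the moment
        # the parameter updates become small (polish phase) — remove the
        # small bias of the fast k-NN proposals near capsule junctions
        exact = config.exact_corr or polish or sweep == n_sweeps - 1
        # anneal the robust scale (graduated non-convexity)
        if n_sweeps > 1 and config.gnc_start > 1:
            frac = sweep / (n_sweeps - 1)
            scale_mult = config.gnc_start ** (1 - frac)
        else:
            scale_mult = 1.0
        sweep_cfg = (config if scale_mult == 1.0 else
                     FitConfig(**{**asdict(config),
                                  "robust_scale": config.robust_scale * scale_mult,
                                  "corr_gate": config.corr_gate * scale_mult}))
        verts, _ = pose_model(model, beta, pose, trans)
        corr = _correspond(points, verts, md, straps, strap_states,
                           config.data_term, exact=exact,
                           strap_margin=config.strap_margin)
        en = _Energy(points, model, fw, corr, sweep_cfg, beta_fixed=beta,
                     pose_prev=pose_prev, strap_prev=strap_states_prev,
                     straps=straps, optimize_shape=optimize_shape)
        x0 = en.pack(pose, trans, beta, strap_states)
        res = minimize(lambda x: _grad_fd(en, x), x0, jac=True,
                       method="L-BFGS-B",
                       options={"maxiter": max_iter, "ftol": config.tol,
                                "gtol": 1e-10})
        # each sweep is accepted under its own (correspondence, scale)
        # objective; L-BFGS never returns an iterate worse than x0, but
        # guard against line-search pathologies anyway
        x_acc = res.x if float(res.fun) <= float(en(x0)) else x0
        sweep_energies.append(float(en(x_acc)))
        step = float(np.max(np.abs(x_acc - x0)))
        p, tr, b, ss = en.unpack(x_acc)
        pose = canonicalize_pose(p[0])
        trans = tr[0].copy()
        if optimize_shape:
            beta = b[0].copy()
            if height_constraint is not None:
                beta = apply_height_constraint(model, beta,
                                               height_constraint)
        strap_states = [s[0].copy() for s in ss]
        if step < 1e-6:
            converged = True
            if exact:
                break
            sweep = n_sweeps - 1   # finish with one exact sweep
            continue
        if step < 1e-3:
            polish = True
        sweep += 1

    # body residuals at the final state (straps excluded)
    verts, _ = pose_model(model, beta, pose, trans)
    corr = _correspond(points, verts, md, straps, strap_states,
                       config.data_term, exact=True,
                       strap_margin=config.strap_margin)
    d_body = corr["d_at_assignment"][corr["body_mask"]]
    diagnostics = {
        "energy": sweep_energies[-1],
        "sweep_energies": sweep_energies,
        "residual_mean_mm": float(d_body.mean() * MM),
        "residual_median_mm": float(np.median(d_body) * MM),
        "n_body_points": int(corr["body_mask"].sum()),
        "n_strap_points": int((~corr["body_mask"]).sum()),
        "converged": converged,
    }
    return pose, trans, beta, strap_states, diagnostics


# -----------------------------------------------------------------------------
# sequence fit
# -----------------------------------------------------------------------------

def _init_translation(points, model, beta):
    """Place the canonical model at the cloud: lateral/depth by medians,
    vertical so the model stands on the lowest cloud points."""
    med = np.median(points, axis=0)
    v = model.shaped_vertices(beta)
    y0 = np.quantile(points[:, 1], 0.02) - v[:, 1].min()
    return np.array([med[0] - np.median(v[:, 0]), y0,
                     med[2] - np.median(v[:, 2])])


def select_init_frame(frames, model, height, config=None, n_candidates=5):
    """Rank candidate initialization frames by single-sweep fit residual.

    A cold-started fit can fall into a local minimum on an unlucky frame
    (e.g. mid-swing with a foot hidden); this heuristic fits the first
    ``n_candidates`` frames with a single cheap sweep each and returns the
    frame index with the smallest median residual.
    """
    config = config or FitConfig()
    beta = apply_height_constraint(model, np.zeros(N_SHAPE), height)
    md = MeshDistance(model.faces, model.n_vertices)
    fw = _Forward(model)
    scores = []
    for i, pts in enumerate(frames[:n_candidates]):
        trans0 = _init_translation(np.asarray(pts), model, beta)
        *_, diag = fit_frame(pts, model, beta, np.zeros((24, 3)), trans0,
                             config, mesh_dist=md, forward=fw,
                             n_sweeps=1, max_iter=15)
        scores.append(diag["residual_median_mm"])
    return int(np.argmin(scores))


def fit_sequence(frames, model: BodyModel, height: float,
                 config: FitConfig | None = None,
                 init_frame: int = 0) -> FitResult:
    """Fit the model to a sequence of foreground point clouds.

    Frame ``init_frame`` is bootstrapped from the canonical standing pose
    at the cloud centroid with a long pose-only ICP schedule. The shape is
    warm-started from the participant-height constraint and optimized
    (after a pose-only pass, so shape modes cannot absorb pose error)
    during the first ``n_init_frames`` frames, then frozen to the
    component-wise mean of those estimates; all remaining frames optimize
    pose (+ strap states) only, warm-started by constant-velocity
    extrapolation of the two previous frames.
    """
    config = config or FitConfig()
    T = len(frames)
    if T < config.n_init_frames:
        raise ValueError(
            f"need at least n_init_frames={config.n_init_frames} frames")

    md = MeshDistance(model.faces, model.n_vertices)
    fw = _Forward(model)
    beta = apply_height_constraint(model, np.zeros(N_SHAPE), height)

    if config.use_straps:
        straps = [make_foot_strap(model, "left", beta),
                  make_foot_strap(model, "right", beta)]
    else:
        straps = []

    poses = np.zeros((T, 24, 3))
    transs = np.zeros((T, 3))
    shapes = np.zeros((T, N_SHAPE))
    res_mean = np.zeros(T)
    res_med = np.zeros(T)
    conv = np.zeros(T, dtype=bool)
    strap_log = {s: np.zeros((T, 6)) for s in
                 (("left", "right") if straps else ())}

    cold_cfg = FitConfig(**{**asdict(config), "exact_corr": True,
                            "gnc_start": max(config.gnc_start, 8.0)})

    order = list(range(init_frame, T)) + list(range(init_frame - 1, -1, -1))
    betas_init = []
    prev = {"pose": None, "trans": None, "pose2": None, "trans2": None}
    strap_prev = None
    strap_prev2 = None
    n_init_done = 0
    frozen = None

    def warm_start():
        if prev["pose2"] is None:
            return prev["pose"], prev["trans"]
        return (prev["pose"] + (prev["pose"] - prev["pose2"]),
                prev["trans"] + (prev["trans"] - prev["trans2"]))

    for step, ti in enumerate(order):
        pts = np.asarray(frames[ti], dtype=float)
        cold = prev["pose"] is None
        if cold:
            init_pose = np.zeros((24, 3))
            init_trans = _init_translation(pts, model, beta)
        else:
            init_pose, init_trans = warm_start()
        optimize_shape = frozen is None and n_init_done < config.n_init_frames

        if straps:
            cur_straps = []
            for s, side in zip(straps, ("left", "right")):
                st = AuxStrap(s.local_vertices.copy(), s.attachment_joint,
                              s.state.copy())
                si = ("left", "right").index(side)
                if strap_prev is not None and strap_prev2 is not None:
                    st.state = 2 * strap_prev[si] - strap_prev2[si]
                elif strap_prev is not None:
                    st.state = strap_prev[si].copy()
                else:
                    from .body_model import pose_model as _pm
                    _, jts = _pm(model, beta, init_pose, init_trans)
                    ja = model.tree.index(f"{side}_ankle")
                    jf = model.tree.index(f"{side}_foot")
                    st.state = np.zeros(6)
                    st.state[3:] = (0.55 * jts[ja] + 0.45 * jts[jf]
                                    + np.array([0, 0.05, 0]))
                cur_straps.append(st)
        else:
            cur_straps = []

        t0 = time.perf_counter()
        if cold:
            # long pose-only bootstrap before anything else
            init_pose, init_trans, _, strap_boot, _ = fit_frame(
                pts, model, beta, init_pose, init_trans, cold_cfg,
                straps=cur_straps, mesh_dist=md, forward=fw,
                n_sweeps=config.cold_sweeps)
            for s, st in zip(cur_straps, strap_boot):
                s.state = st
        if optimize_shape:
            # pose-only pass first so shape modes cannot absorb pose lag
            init_pose, init_trans, _, strap_pre, _ = fit_frame(
                pts, model, beta, init_pose, init_trans, config,
                straps=cur_straps, strap_states_prev=strap_prev,
                pose_prev=prev["pose"], mesh_dist=md, forward=fw)
            for s, st in zip(cur_straps, strap_pre):
                s.state = st
        pose, trans, beta_out, strap_states, diag = fit_frame(
            pts, model, frozen if frozen is not None else beta,
            init_pose, init_trans, config,
            optimize_shape=optimize_shape, straps=cur_straps,
            strap_states_prev=strap_prev, pose_prev=prev["pose"],
            mesh_dist=md, forward=fw,
            n_sweeps=3 if optimize_shape else None,
            height_constraint=height if optimize_shape else None)
        poses[ti], transs[ti] = pose, trans
        shapes[ti] = beta_out if optimize_shape else frozen
        res_mean[ti], res_med[ti] = (diag["residual_mean_mm"],
                                     diag["residual_median_mm"])
        conv[ti] = diag["converged"]
        for side, st in zip(("left", "right"), strap_states):
            strap_log[side][ti] = st
        log.info("frame %d: residual mean %.1f mm, median %.1f mm, "
                 "energy %.4g (%.2f s)", ti, diag["residual_mean_mm"],
                 diag["residual_median_mm"], diag["energy"],
                 time.perf_counter() - t0)

        if optimize_shape:
            betas_init.append(beta_out)
            n_init_done += 1
            beta = beta_out
            if n_init_done == config.n_init_frames:
                frozen = apply_height_constraint(
                    model, np.mean(betas_init, axis=0), height)
        prev["pose2"], prev["trans2"] = prev["pose"], prev["trans"]
        prev["pose"], prev["trans"] = pose, trans
        strap_prev2 = strap_prev
        strap_prev = strap_states if strap_states else None
        if init_frame > 0 and step + 1 == T - init_frame:
            # about to jump back before init_frame: restart warm state there
            prev = {"pose": poses[init_frame], "trans": transs[init_frame],
                    "pose2": None, "trans2": None}

    if frozen is None:  # config.n_init_frames > 0 guarantees betas_init
        frozen = apply_height_constraint(model, np.mean(betas_init, axis=0),
                                         height)

    # revisit the initialization frames backward with the frozen shape:
    # they were fit during the cold-start transient with a still-moving
    # shape, and a warm start from their settled neighbor removes that
    n_init = min(config.n_init_frames, T - 1 - init_frame)
    for ti in range(init_frame + n_init - 1, init_frame - 1, -1):
        nb = ti + 1
        if straps:
            cur_straps = [AuxStrap(s.local_vertices.copy(),
                                   s.attachment_joint,
                                   strap_log[side][nb].copy())
                          for s, side in zip(straps, ("left", "right"))]
        else:
            cur_straps = []
        pose, trans, _, strap_states, diag = fit_frame(
            np.asarray(frames[ti], dtype=float), model, frozen,
            poses[nb], transs[nb], config, straps=cur_straps,
            pose_prev=poses[nb], mesh_dist=md, forward=fw,
            # the cold-started frame carries the largest leftover error
            n_sweeps=2 * config.n_sweeps if ti == init_frame else None)
        poses[ti], transs[ti] = pose, trans
        shapes[ti] = frozen
        res_mean[ti], res_med[ti] = (diag["residual_mean_mm"],
                                     diag["residual_median_mm"])
        conv[ti] = diag["converged"]
        for side, st in zip(("left", "right"), strap_states):
            strap_log[side][ti] = st

    return FitResult(shape=frozen, init_shapes=np.asarray(betas_init),
                     shapes=shapes, poses=poses, translations=transs,
                     strap_states={k: v for k, v in strap_log.items()},
                     residual_mean_mm=res_mean, residual_median_mm=res_med,
                     converged=conv, config=config)


# -----------------------------------------------------------------------------
# conveniences for validation
# -----------------------------------------------------------------------------

def posed_vertices(model: BodyModel, fit: FitResult) -> np.ndarray:
    """(T, V, 3) posed model vertices for every frame of a fit."""
    from .body_model import pose_model
    out = np.empty((fit.n_frames, model.n_vertices, 3))
    for t in range(fit.n_frames):
        out[t], _ = pose_model(model, fit.shapes[t], fit.poses[t],
                               fit.translations[t])
    return out


def joint_centers(model: BodyModel, fit: FitResult) -> np.ndarray:
    """(T, 24, 3) posed joint centers for every frame of a fit."""
    from .body_model import pose_model
    out = np.empty((fit.n_frames, 24, 3))
    for t in range(fit.n_frames):
        _, out[t] = pose_model(model, fit.shapes[t], fit.poses[t],
                               fit.translations[t])
    return out
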