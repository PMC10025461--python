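"""Detection and tracking of colored reference stickers in point clouds.

Bright-colored stickers at eight body landmarks (left/right
acromioclavicular joint, anterior spina iliaca, patella, hallux) serve as
reference points for validating the model fit. Sticker pixels are selected
with a color (hue-band) filter, clustered by 3D proximity, and each
cluster is summarized by its component-wise median position — a robust
statistic that tolerates depth-noise outliers. Tracks are assembled by
frame-to-frame nearest-neighbor assignment with a gating radius; frames
where a sticker is missing (occlusion) are masked invalid and never
interpolated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from matplotlib.colors import rgb_to_hsv
from scipy.optimize import linear_sum_assignment
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .synthetic import LANDMARK_NAMES

__all__ = ["StickerTrack", "detect_stickers", "cluster_position",
           "assemble_tracks", "GREEN_HUE_BAND"]

#: Default hue band (HSV hue in [0, 1]) for the bright-green stickers.
GREEN_HUE_BAND = (0.22, 0.48)


@dataclass
class StickerTrack:
    """Per-sticker 3D trajectory with a validity mask.

    ``positions`` holds NaN at invalid frames on purpose: any downstream
    consumer that forgets to honor the mask poisons its own result instead
    of silently using stale data.
    """

    name: str
    positions: np.ndarray        # (T, 3) meters, NaN where invalid
    valid: np.ndarray            # (T,) bool

    def __post_init__(self):
        if self.name not in LANDMARK_NAMES:
            raise ValueError(f"unknown sticker name {self.name!r}")
        if np.any(~np.isfinite(self.positions[self.valid])):
            raise ValueError("positions must be finite at valid frames")

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())


def detect_stickers(points: np.ndarray, colors: np.ndarray,
                    hue_band: tuple = GREEN_HUE_BAND,
                    min_saturation: float = 0.45,
                    linkage_radius: float = 0.03,
                    min_points: int = 4) -> list:
    """Find sticker point clusters in one colored frame.

    Points inside the hue band are grouped by single-linkage proximity
    (pairs closer than ``linkage_radius`` connect); clusters with fewer
    than ``min_points`` members are discarded. Zero clusters is a valid
    outcome (fully occluded frame).
    """
    points = np.asarray(points, dtype=float)
    if colors is None:
        raise ValueError("color information is required to detect stickers")
    hsv = rgb_to_hsv(np.clip(np.asarray(colors, dtype=float), 0, 1))
    mask = ((hsv[:, 0] >= hue_band[0]) & (hsv[:, 0] <= hue_band[1])
            & (hsv[:, 1] >= min_saturation))
    sel = points[mask]
    if len(sel) == 0:
        return []
    tree = cKDTree(sel)
    pairs = tree.query_pairs(linkage_radius, output_type="ndarray")
    n = len(sel)
    graph = coo_matrix((np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])),
                       shape=(n, n))
    n_comp, labels = connected_components(graph, directed=False)
    return [sel[labels == i] for i in range(n_comp)
            if (labels == i).sum() >= min_points]


def cluster_position(cluster: np.ndarray) -> np.ndarray:
    """Component-wise median position of a sticker cluster."""
    cluster = np.asarray(cluster, dtype=float)
    if cluster.size == 0:
        raise ValueError("empty sticker cluster")
    return np.median(cluster, axis=0)


def _canonical_layout(centroids: np.ndarray) -> dict:
    """Assign 8 cluster centroids to canonical landmark names by layout.

    Sorts the centroids into four height pairs (shoulders, hips, knees,
    feet, top to bottom) and splits each pair left/right by lateral
    position. The subject is assumed upright and roughly frontal, which is
    how a recording starts.
    """
    order = np.argsort(centroids[:, 1])[::-1]
    sites = ["acromioclavicular", "spina_iliaca", "patella", "hallux"]
    out = {}
    for level, site in enumerate(sites):
        pair = order[2 * level: 2 * level + 2]
        left, right = (pair if centroids[pair[0], 0] >= centroids[pair[1], 0]
                       else pair[::-1])
        out[f"left_{site}"] = centroids[left]
        out[f"right_{site}"] = centroids[right]
    return out


def assemble_tracks(frames_clusters: list, fps: float = 30.0,
                    init_positions: dict | None = None,
                    gating_radius: float = 0.06) -> dict:
    """Assemble eight named sticker tracks from per-frame cluster lists.

    Frame 1 is bootstrapped either from ``init_positions`` (name ->
    expected 3D position, e.g. posed model landmarks) or, when omitted,
    from the canonical upright layout of exactly eight clusters. Later
    frames assign clusters to tracks one-to-one (Hungarian) by distance to
    each track's predicted position — a constant-velocity extrapolation of
    its last two valid positions (a foot sticker moves several cm between
    frames at walking cadence, which a static gate around the last
    position would lose) — gated at ``gating_radius``; unmatched frames
    are marked invalid and never interpolated.

    Returns ``{name: StickerTrack}`` for the eight canonical names.
    """
    if len(frames_clusters) < 1:
        raise ValueError("need at least one frame")
    T = len(frames_clusters)
    centroids = [np.array([cluster_position(c) for c in frame])
                 if frame else np.empty((0, 3))
                 for frame in frames_clusters]

    if init_positions is None:
        if len(centroids[0]) != 8:
            raise ValueError(
                f"frame 1 has {len(centroids[0])} clusters, need exactly 8 "
                "for canonical-layout bootstrap; supply init_positions or "
                "choose a different start frame")
        init_positions = _canonical_layout(centroids[0])
    missing = set(LANDMARK_NAMES) - set(init_positions)
    if missing:
        raise ValueError(f"init_positions missing landmarks: {sorted(missing)}")

    names = list(LANDMARK_NAMES)
    last = np.array([init_positions[n] for n in names])
    last_t = np.full(8, -1)
    prev = last.copy()
    prev_t = np.full(8, -2)
    positions = np.full((T, 8, 3), np.nan)
    valid = np.zeros((T, 8), dtype=bool)

    # generous gate for the bootstrap frame (init may be a model guess)
    gates = np.full(8, 3 * gating_radius)
    for t in range(T):
        cents = centroids[t]
        # constant-velocity prediction from the last two valid positions
        dt = np.maximum(last_t - prev_t, 1)
        velo = (last - prev) / dt[:, None]
        predicted = last + velo * (t - np.maximum(last_t, 0))[:, None]
        if len(cents):
            cost = np.linalg.norm(predicted[:, None] - cents[None], axis=2)
            big = 1e6
            cost = np.where(cost <= gates[:, None], cost, big)
            rows, cols = linear_sum_assignment(cost)
            for r, c in zip(rows, cols):
                if cost[r, c] < big:
                    positions[t, r] = cents[c]
                    valid[t, r] = True
                    prev[r], prev_t[r] = last[r], last_t[r]
                    last[r], last_t[r] = cents[c], t
        # a track that missed a frame searches a growing (capped) radius
        gates = np.where(valid[t], gating_radius,
                         np.minimum(gates + 0.5 * gating_radius,
                                    4 * gating_radius))

    return {n: StickerTrack(n, positions[:, i], valid[:, i])
            for i, n in enumerate(names)}
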