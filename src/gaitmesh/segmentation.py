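"""Person/background segmentation by ground plane and distance thresholds.

The floor plane is estimated from red marker-stripe points when color is
available (two red stripes on the treadmill), falling back to the lowest
height band of the cloud. Foreground points are those above the plane by a
clearance margin and inside an axis-aligned working volume sized for a
treadmill footprint. Robot parts inside the volume are deliberately kept:
they cannot be reliably separated from the person and are handled
downstream by the robust fitting objective.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from matplotlib.colors import rgb_to_hsv

__all__ = ["GroundPlane", "WorkingVolume", "estimate_ground_plane",
           "segment_person"]


@dataclass(frozen=True)
class GroundPlane:
    """Plane ``normal . x = offset`` with unit normal oriented upward."""

    normal: np.ndarray
    offset: float

    def __post_init__(self):
        n = np.asarray(self.normal, dtype=float)
        if abs(np.linalg.norm(n) - 1.0) > 1e-9:
            raise ValueError("plane normal must be unit length")

    def height_above(self, points: np.ndarray) -> np.ndarray:
        """Signed distance of each point above the plane."""
        return np.asarray(points) @ self.normal - self.offset

    def to_dict(self) -> dict:
        return {"normal": np.asarray(self.normal).tolist(),
                "offset": float(self.offset)}

    @classmethod
    def from_dict(cls, d: dict) -> "GroundPlane":
        return cls(np.asarray(d["normal"], dtype=float), float(d["offset"]))


@dataclass(frozen=True)
class WorkingVolume:
    """Axis-aligned treadmill working volume (meters, camera frame)."""

    x_range: tuple = (-0.6, 0.6)       # lateral, ~1.2 m footprint width
    z_range: tuple = (0.8, 2.5)        # depth band in front of the camera
    max_height: float = 2.2            # above the ground plane


def _red_stripe_mask(colors: np.ndarray) -> np.ndarray:
    """Hue-band selector for the red treadmill marker stripes."""
    hsv = rgb_to_hsv(np.clip(colors, 0, 1))
    hue, sat, val = hsv[:, 0], hsv[:, 1], hsv[:, 2]
    return ((hue < 0.06) | (hue > 0.94)) & (sat > 0.5) & (val > 0.3)


def estimate_ground_plane(points: np.ndarray,
                          colors: np.ndarray | None = None,
                          up_hint=np.array([0.0, 1.0, 0.0])) -> GroundPlane:
    """Least-squares plane through floor candidate points.

    Candidates are red-stripe points when colors are given and enough
    stripe points exist, else the lowest 5 % height band (along the up
    hint). The normal is oriented into the camera-up hemisphere.
    """
    points = np.asarray(points, dtype=float)
    cand = None
    from_stripes = False
    if colors is not None:
        mask = _red_stripe_mask(np.asarray(colors))
        if mask.sum() >= 30:
            cand = points[mask]
            from_stripes = True
    if cand is None:
        h = points @ up_hint
        cut = np.quantile(h, 0.05)
        cand = points[h <= cut]
    plane = _fit_plane(cand, up_hint)
    if not from_stripes:
        # the lowest height band is the bottom tail of the noise and sits
        # below the true floor; refit on all points within a 1 cm inlier
        # band to remove that bias (one round is enough — anything not on
        # the floor is at least a clearance margin away)
        for _ in range(2):
            inliers = np.abs(plane.height_above(points)) < 0.01
            if inliers.sum() < 3:
                break
            plane = _fit_plane(points[inliers], up_hint)
    return plane


def _fit_plane(cand: np.ndarray, up_hint) -> GroundPlane:
    if len(cand) < 3:
        raise ValueError("need at least 3 floor candidate points")
    centroid = cand.mean(axis=0)
    centered = cand - centroid
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] < 1e-12 * max(1.0, s[0]):
        raise ValueError("floor candidates are collinear; cannot fit a plane")
    normal = vt[2]
    if normal @ up_hint < 0:
        normal = -normal
    return GroundPlane(normal / np.linalg.norm(normal),
                       float(normal @ centroid))


def segment_person(points: np.ndarray, plane: GroundPlane,
                   box: WorkingVolume = WorkingVolume(),
                   clearance: float = 0.02,
                   return_mask: bool = False):
    """Foreground = points above the plane by ``clearance`` and inside the
    working volume. Order-preserving; returns an empty set (with a warning)
    rather than failing when nothing survives."""
    points = np.asarray(points, dtype=float)
    h = plane.height_above(points)
    mask = ((h > clearance) & (h < box.max_height)
            & (points[:, 0] >= box.x_range[0]) & (points[:, 0] <= box.x_range[1])
            & (points[:, 2] >= box.z_range[0]) & (points[:, 2] <= box.z_range[1]))
    if not mask.any():
        warnings.warn("segmentation produced an empty foreground",
                      stacklevel=2)
    return mask if return_mask else points[mask]
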