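"""Validation statistics for markerless body-model tracking.

Two evaluation procedures:

* **Shape comparison** — per-vertex distances between two fitted models of
  the same subject (e.g. walking with and without an exoskeleton),
  averaged within seven body regions and aggregated across subjects as
  median / IQR.

* **Sticker-to-model error** — for each tracked sticker, the body-model
  vertex that best matches it across all frames is selected; the distance
  series between sticker and vertex is then decomposed into a constant
  placement offset, a *systematic* component at harmonics of the stride
  frequency (it survives averaging over strides), and a broadband *random*
  remainder (it averages out). Tracking quality is summarized by the
  fluctuation SD, the 3D Pearson correlation, and the fraction of frames
  below fixed error thresholds.

A noncentral-t power calculation translates the measured stride-to-stride
variability into the number of strides needed to detect a given effect.

All distances are reported in millimeters; inputs are in meters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .body_model import REGIONS
from .sticker_tracking import StickerTrack

__all__ = [
    "ShapeComparison", "ErrorDecomposition",
    "compare_shapes", "aggregate_across_subjects",
    "select_reference_vertex", "estimate_stride_frequency",
    "decompose_error", "error_cdf_table", "steps_needed",
    "ERROR_THRESHOLDS_MM",
]

#: Error thresholds for the cumulative distribution, in millimeters.
ERROR_THRESHOLDS_MM = (5.0, 10.0, 20.0, 30.0, 50.0, 100.0)

MM = 1000.0


@dataclass
class ShapeComparison:
    """Mean vertex-to-vertex distance per body region (mm)."""

    per_region_mean_mm: dict
    total_mean_mm: float


@dataclass
class ErrorDecomposition:
    """Sticker-to-vertex error summary for one sticker.

    ``offset_mm`` (= mean of the raw distance series) is the systematic
    placement offset between sticker and closest vertex; ``sd_mm`` is the
    fluctuation of that series, decomposed into ``systematic_rms_mm``
    (stride-harmonic component) and ``random_rms_mm`` (residual) with
    ``systematic² + random² = sd²`` exactly. ``pearson_r`` is the mean of
    the per-axis Pearson correlations between the sticker and vertex
    trajectories. ``cdf`` maps thresholds (mm) to the fraction of valid
    frames whose mean-removed error is below them.
    """

    offset_mm: float
    mean_error_mm: float
    sd_mm: float
    systematic_rms_mm: float
    random_rms_mm: float
    pearson_r: float
    cdf: dict
    stride_hz: float
    n_valid: int = 0


# -----------------------------------------------------------------------------
# shape comparison
# -----------------------------------------------------------------------------

def compare_shapes(model_a_vertices: np.ndarray, model_b_vertices: np.ndarray,
                   region_labels: np.ndarray) -> ShapeComparison:
    """Mean distance between corresponding vertices (same vertex ID) of two
    identically-posed models, per region and overall (mm)."""
    a = np.asarray(model_a_vertices, dtype=float)
    b = np.asarray(model_b_vertices, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"vertex count mismatch: {a.shape} vs {b.shape}")
    d = np.linalg.norm(a - b, axis=1) * MM
    per_region = {r: float(d[region_labels == r].mean())
                  for r in REGIONS if np.any(region_labels == r)}
    return ShapeComparison(per_region, float(d.mean()))


def aggregate_across_subjects(comparisons: list) -> pd.DataFrame:
    """Median and IQR of per-region mean distances across subjects.

    Quartiles use linear interpolation (type-7 convention). Returns a
    DataFrame indexed by region (plus 'total') with columns
    ``median_mm`` and ``iqr_mm``.
    """
    if len(comparisons) < 1:
        raise ValueError("need at least one subject")
    rows = {}
    regions = list(comparisons[0].per_region_mean_mm) + ["total"]
    for r in regions:
        vals = np.array([c.total_mean_mm if r == "total"
                         else c.per_region_mean_mm[r] for c in comparisons])
        q1, med, q3 = np.percentile(vals, [25, 50, 75])  # linear = type-7
        rows[r] = {"median_mm": med, "iqr_mm": q3 - q1}
    return pd.DataFrame.from_dict(rows, orient="index")


# -----------------------------------------------------------------------------
# reference-vertex selection and stride frequency
# -----------------------------------------------------------------------------

def select_reference_vertex(track: StickerTrack,
                            vertex_positions: np.ndarray,
                            min_valid: int = 10) -> int:
    """The single vertex matching the sticker best across all frames.

    ``vertex_positions`` is (T, V, 3) posed vertices per frame. Returns the
    vertex minimizing the mean Euclidean distance to the sticker over the
    track's valid frames; ties break to the lowest vertex ID (argmin).
    """
    if track.n_valid < min_valid:
        raise ValueError(
            f"only {track.n_valid} valid frames; need at least {min_valid}")
    v = np.asarray(vertex_positions)[track.valid]        # (Tv, V, 3)
    s = track.positions[track.valid][:, None, :]         # (Tv, 1, 3)
    mean_d = np.linalg.norm(v - s, axis=2).mean(axis=0)
    return int(np.argmin(mean_d))


def estimate_stride_frequency(track: StickerTrack, fps: float,
                              min_strides: int = 3) -> float:
    """Stride frequency from the vertical sticker trajectory.

    The dominant non-DC spectral peak of the mean-removed vertical signal
    over the longest contiguous valid run, refined by parabolic
    interpolation of the log-magnitude around the peak bin.
    """
    runs = _valid_runs(track.valid)
    if not runs:
        raise ValueError("track has no valid frames")
    start, stop = max(runs, key=lambda r: r[1] - r[0])
    y = track.positions[start:stop, 1]
    n = len(y)
    y = y - y.mean()
    if np.std(y) < 1e-9:
        raise ValueError("vertical trajectory is constant; no spectral peak "
                         "— supply the cadence manually")
    spec = np.abs(np.fft.rfft(y * np.hanning(n)))
    spec[0] = 0.0
    k = int(np.argmax(spec))
    if spec[k] < 5.0 * np.median(spec[1:]):
        raise ValueError("no spectral peak above the noise floor — supply "
                         "the cadence manually")
    f = k / n * fps
    if n / fps * f < min_strides:
        raise ValueError(
            f"only {n / fps * f:.1f} strides of contiguous valid data; "
            f"need at least {min_strides}")
    if 1 <= k < len(spec) - 1 and spec[k - 1] > 0 and spec[k + 1] > 0:
        la, lb, lc = np.log(spec[k - 1: k + 2])
        denom = la - 2 * lb + lc
        if denom < 0:
            f += 0.5 * (la - lc) / denom / n * fps
    return float(f)


def _valid_runs(valid: np.ndarray) -> list:
    """Contiguous [start, stop) runs of True."""
    v = np.asarray(valid, dtype=bool)
    edges = np.flatnonzero(np.diff(np.r_[0, v.astype(int), 0]))
    return list(zip(edges[::2], edges[1::2]))


# -----------------------------------------------------------------------------
# systematic / random error decomposition
# -----------------------------------------------------------------------------

def decompose_error(track: StickerTrack, vertex_trajectory: np.ndarray,
                    stride_hz: float, fps: float,
                    n_harmonics: int = 6) -> ErrorDecomposition:
    """Decompose the sticker-to-vertex distance series.

    Over valid frames, ``d_t = ||sticker_t - vertex_t||``. The mean-removed
    series is projected (least squares) onto sine/cosine pairs at the
    stride harmonics ``k * stride_hz`` (k = 1..n_harmonics, below Nyquist);
    the projection is the *systematic* error, the residual the *random*
    error. Because the residual is orthogonal to the fitted component,
    ``systematic_rms² + random_rms² = var(d)`` holds exactly, also across
    validity gaps (the projection is computed on the union of valid
    frames, never interpolating across gaps).
    """
    if stride_hz <= 0:
        raise ValueError("stride_hz must be positive")
    valid = track.valid
    n_valid = int(valid.sum())
    if n_valid / fps < 1.0 / stride_hz:
        raise ValueError("valid data shorter than one stride")
    vt = np.asarray(vertex_trajectory, dtype=float)
    d = np.linalg.norm(track.positions[valid] - vt[valid], axis=1) * MM
    t = np.flatnonzero(valid) / fps

    offset = float(d.mean())
    dc = d - offset
    sd = float(np.sqrt(np.mean(dc ** 2)))

    harmonics = [k * stride_hz for k in range(1, n_harmonics + 1)
                 if k * stride_hz < fps / 2]
    cols = []
    for f in harmonics:
        cols.append(np.sin(2 * np.pi * f * t))
        cols.append(np.cos(2 * np.pi * f * t))
    X = np.column_stack(cols) if cols else np.empty((len(t), 0))
    if X.shape[1]:
        beta, *_ = np.linalg.lstsq(X, dc, rcond=None)
        systematic = X @ beta
    else:
        systematic = np.zeros_like(dc)
    residual = dc - systematic
    sys_rms = float(np.sqrt(np.mean(systematic ** 2)))
    rand_rms = float(np.sqrt(np.mean(residual ** 2)))

    r_axes = []
    for ax in range(3):
        a = track.positions[valid, ax]
        b = vt[valid, ax]
        if np.std(a) < 1e-12 or np.std(b) < 1e-12:
            r_axes.append(np.nan)
        else:
            r_axes.append(stats.pearsonr(a, b).statistic)
    pearson = float(np.nanmean(r_axes))

    abs_err = np.abs(dc)
    cdf = {thr: float(np.mean(abs_err < thr)) for thr in ERROR_THRESHOLDS_MM}

    return ErrorDecomposition(
        offset_mm=offset, mean_error_mm=float(np.mean(np.abs(dc))),
        sd_mm=sd, systematic_rms_mm=sys_rms, random_rms_mm=rand_rms,
        pearson_r=pearson, cdf=cdf, stride_hz=float(stride_hz),
        n_valid=n_valid)


#: canonical mapping of sticker sites to the body segments of the summary table
SEGMENT_OF_SITE = {
    "hallux": "feet",
    "patella": "knees",
    "spina_iliaca": "hips",
    "acromioclavicular": "shoulders",
}
SEGMENT_ORDER = ["feet", "knees", "hips", "shoulders"]


def error_cdf_table(decompositions: dict) -> pd.DataFrame:
    """Left/right-averaged per-segment error summary.

    ``decompositions`` maps sticker names (left_/right_ + site) to
    :class:`ErrorDecomposition`. Returns one row per segment in the order
    feet, knees, hips, shoulders with the summary statistics and the
    threshold CDF columns; ``both_sides`` flags whether left and right
    were available (a missing side is reported single-sided).
    """
    rows = []
    for seg in SEGMENT_ORDER:
        site = next(s for s, g in SEGMENT_OF_SITE.items() if g == seg)
        sides = [decompositions[f"{side}_{site}"]
                 for side in ("left", "right")
                 if f"{side}_{site}" in decompositions]
        if not sides:
            continue
        row = {"segment": seg, "both_sides": len(sides) == 2}
        for attr in ("offset_mm", "mean_error_mm", "sd_mm",
                     "systematic_rms_mm", "random_rms_mm", "pearson_r"):
            row[attr] = float(np.mean([getattr(s, attr) for s in sides]))
        for thr in ERROR_THRESHOLDS_MM:
            row[f"cdf_{thr:g}mm"] = float(np.mean([s.cdf[thr] for s in sides]))
        rows.append(row)
    return pd.DataFrame(rows).set_index("segment")


# -----------------------------------------------------------------------------
# power calculation
# -----------------------------------------------------------------------------

def steps_needed(sd_mm: float, delta_mm: float, alpha: float = 0.05,
                 power: float = 0.8, n_max: int = 100000) -> int:
    """Smallest sample size for a two-sided one-sample t-test.

    Number of strides needed so that a t-test at level ``alpha`` detects a
    mean difference of ``delta_mm`` with the requested power, given
    stride-to-stride variability ``sd_mm``. Computed by iterating the
    noncentral-t power equation; the minimum meaningful n for a t-test
    is 2.
    """
    if not (np.isfinite(sd_mm) and np.isfinite(delta_mm)
            and sd_mm > 0 and delta_mm > 0):
        raise ValueError("sd and delta must be positive finite")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must be in (0, 1)")
    effect = delta_mm / sd_mm
    for n in range(2, n_max + 1):
        df = n - 1
        tcrit = stats.t.ppf(1 - alpha / 2, df)
        nc = effect * np.sqrt(n)
        achieved = (1 - stats.nct.cdf(tcrit, df, nc)
                    + stats.nct.cdf(-tcrit, df, nc))
        if achieved >= power:
            return n
    raise ValueError(f"required sample size exceeds {n_max}")
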