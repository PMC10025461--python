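"""Optional figures for validation outputs (matplotlib, headless)."""

from __future__ import annotations

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .validation import ERROR_THRESHOLDS_MM

__all__ = ["plot_region_boxes", "plot_error_cdf"]


def plot_region_boxes(aggregate_df, path) -> None:
    """Per-region shape-difference medians/IQRs as a bar-with-error plot."""
    fig, ax = plt.subplots(figsize=(6, 3.5))
    regions = list(aggregate_df.index)
    med = aggregate_df["median_mm"].to_numpy()
    iqr = aggregate_df["iqr_mm"].to_numpy()
    ax.bar(regions, med, yerr=iqr / 2, capsize=3, color="#7aa6c2")
    ax.set_ylabel("vertex-vertex distance (mm)")
    ax.set_title("shape difference per body region (median, IQR)")
    plt.setp(ax.get_xticklabels(), rotation=30, ha="right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_error_cdf(table, path) -> None:
    """Fraction of frames below each error threshold, per segment."""
    fig, ax = plt.subplots(figsize=(6, 3.5))
    thr = np.array(ERROR_THRESHOLDS_MM)
    for seg, row in table.iterrows():
        vals = [row[f"cdf_{t:g}mm"] * 100 for t in thr]
        ax.plot(thr, vals, marker="o", label=seg)
    ax.set_xscale("log")
    ax.set_xlabel("error threshold (mm)")
    ax.set_ylabel("% frames below")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
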