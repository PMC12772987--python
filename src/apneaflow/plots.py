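"""Figure helpers: Bland-Altman scatter and signal/relevance overlays."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .metrics import BlandAltman

__all__ = ["bland_altman_plot", "attribution_overlay"]


def bland_altman_plot(actual, estimated, ba: BlandAltman, path) -> None:
    """Scatter of (mean, difference) pairs with the limits of agreement."""
    actual = np.asarray(actual, dtype=float)
    estimated = np.asarray(estimated, dtype=float)
    means = (actual + estimated) / 2
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(means, ba.diffs, s=16, alpha=0.7)
    for y, style, label in [
        (ba.mean_diff, "-", f"mean {ba.mean_diff:.2f}"),
        (ba.loa_low, "--", f"-1.96 SD {ba.loa_low:.2f}"),
        (ba.loa_high, "--", f"+1.96 SD {ba.loa_high:.2f}"),
    ]:
        ax.axhline(y, linestyle=style, color="crimson", linewidth=1)
        ax.annotate(label, (means.max(), y), fontsize=8, va="bottom", ha="right")
    ax.set_xlabel("mean of actual and estimated AHI (e/h)")
    ax.set_ylabel("estimated - actual AHI (e/h)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def attribution_overlay(segment, values, path, fs: float = 4.0, kind: str = "gradcam") -> None:
    """Airflow segment colored by attribution values (warmer = more relevant)."""
    segment = np.asarray(segment, dtype=float)
    values = np.asarray(values, dtype=float)
    t = np.arange(segment.size) / fs
    fig, (ax0, ax1) = plt.subplots(
        2, 1, figsize=(10, 4), sharex=True, height_ratios=[3, 1]
    )
    color_vals = np.abs(values) if kind == "shap" else values
    sc = ax0.scatter(t, segment, c=color_vals, cmap="jet", s=2)
    fig.colorbar(sc, ax=ax0, label="relevance")
    ax0.set_ylabel("standardized airflow")
    ax1.plot(t, values, linewidth=0.8)
    ax1.set_xlabel("time (s)")
    ax1.set_ylabel(kind)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
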