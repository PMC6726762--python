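"""Publication-style summary plots: polar angle histograms, angle-vs-arm
scatter with centroid, and cumulative positioning curves."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .afm_io import QuantRecord


def polar_angle_histogram(records: list[QuantRecord], path: str | Path,
                          bin_deg: float = 15.0, color: str = "k") -> None:
    """Opening-angle distribution as a polar sector histogram."""
    thetas = np.array([r.theta_deg for r in records if not np.isnan(r.theta_deg)])
    edges = np.arange(0, 180 + bin_deg / 2, bin_deg)
    counts, _ = np.histogram(thetas, bins=edges)
    probs = counts / max(len(thetas), 1)
    fig, ax = plt.subplots(subplot_kw={"projection": "polar"})
    ax.bar(np.radians(edges[:-1] + bin_deg / 2), probs,
           width=np.radians(bin_deg), color=color, alpha=0.7, edgecolor="k")
    ax.set_thetamin(0)
    ax.set_thetamax(180)
    ax.set_title(f"opening angle (n={len(thetas)})")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def angle_vs_arm_scatter(records: list[QuantRecord], path: str | Path) -> None:
    """Opening angle against total protruding-arm contour, centroid marked."""
    pts = np.array([(r.theta_deg, r.short_arm_nm + r.long_arm_nm)
                    for r in records
                    if not (np.isnan(r.theta_deg) or np.isnan(r.short_arm_nm))])
    fig, ax = plt.subplots()
    if len(pts):
        ax.scatter(pts[:, 0], pts[:, 1], s=8, c="k", alpha=0.5)
        ax.scatter(*pts.mean(axis=0), s=120, c="tab:blue", marker="+",
                   linewidths=3, label="centroid")
        ax.legend()
    ax.set_xlabel("opening angle [deg]")
    ax.set_ylabel("protruding DNA arm contour length [nm]")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def cumulative_sa_ratio(groups: dict[str, list[QuantRecord]],
                        path: str | Path, bin_width: float = 0.01) -> None:
    """Relative cumulative frequency of the positioning ratio per class."""
    fig, ax = plt.subplots()
    edges = np.arange(0.0, 0.5 + bin_width / 2, bin_width)
    for label, records in groups.items():
        vals = np.array([r.sa_ratio_c for r in records
                         if not np.isnan(r.sa_ratio_c)])
        if not len(vals):
            continue
        counts, _ = np.histogram(vals, bins=edges)
        cum = np.cumsum(counts) / len(vals)
        ax.plot(edges[1:], cum, label=f"{label} (n={len(vals)})")
    ax.set_xlabel("sa-ratio$_c$")
    ax.set_ylabel("relative cumulative frequency")
    ax.legend()
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
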