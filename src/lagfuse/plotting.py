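"""Figure exports: critical-difference diagrams and error-grid scatters."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .metrics import surveillance_errors


def plot_cd_diagram(layout: dict, path: str | Path, title: str = "") -> Path:
    """Render a critical-difference diagram from :func:`stats.cd_diagram_data`.

    Models sit on a rank axis (best = lowest rank, left); the CD bar shows
    the minimum separation for significance; thick horizontal lines join
    linked groups per the layout's convention.
    """
    positions = layout["positions"]
    cd = layout["critical_distance"]
    ranks = [p["rank"] for p in positions]
    labels = [p["label"] for p in positions]
    lo = min(ranks) - 0.4
    hi = max(ranks) + 0.4

    fig, ax = plt.subplots(figsize=(6, 1.2 + 0.45 * len(positions)))
    ax.set_xlim(lo, hi)
    ax.xaxis.set_ticks_position("top")
    ax.spines[["left", "right", "bottom"]].set_visible(False)
    ax.get_yaxis().set_visible(False)

    for i, (r, lab) in enumerate(zip(ranks, labels)):
        y = -(i + 1)
        ax.plot([r, r], [0, y], color="k", lw=1)
        ax.annotate(f"{lab} ({r:.2f})", (r, y), ha="left", va="center",
                    xytext=(4, 0), textcoords="offset points")
    # CD reference bar
    ax.plot([lo + 0.05, lo + 0.05 + cd], [0.55, 0.55], color="k", lw=2)
    ax.annotate(f"CD = {cd:.3f}", (lo + 0.05, 0.65), va="bottom", fontsize=8)
    # group links
    rank_of = {p["label"]: p["rank"] for p in positions}
    for gi, group in enumerate(layout["links"]):
        rs = [rank_of[g] for g in group]
        y = -(len(positions) + 1) - 0.35 * gi
        ax.plot([min(rs), max(rs)], [y, y], color="k", lw=3, solid_capstyle="round")
    ax.set_ylim(-(len(positions) + 2 + 0.35 * len(layout["links"])), 1.2)
    if title:
        ax.set_title(title, fontsize=9)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path)
    plt.close(fig)
    return path


def plot_seg_scatter(ref, pred, path: str | Path, title: str = "") -> Path:
    """Reference-vs-predicted scatter coloured by surveillance risk."""
    ref = np.asarray(ref, float).ravel()
    pred = np.asarray(pred, float).ravel()
    risk = surveillance_errors(ref, pred)
    fig, ax = plt.subplots(figsize=(5, 4.5))
    sc = ax.scatter(ref, pred, c=risk, s=6, cmap="RdYlGn_r", vmin=0, vmax=4, alpha=0.8)
    ax.plot([20, 580], [20, 580], color="k", lw=0.8, ls="--")
    ax.set_xlabel("reference glucose (mg/dL)")
    ax.set_ylabel("predicted glucose (mg/dL)")
    fig.colorbar(sc, ax=ax, label="surveillance error")
    if title:
        ax.set_title(title, fontsize=9)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path)
    plt.close(fig)
    return path
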