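"""Diagnostic figures: stacked 2DFT images and DF scatter plots."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .criterion import CriterionResult
from .features import FeatureMatrix
from .model import DfScoreCloud

_COLORS = {"slow": "tab:blue", "normal": "tab:green", "fast": "tab:red"}


def plot_stacked_2dft(features: FeatureMatrix, path) -> None:
    """Stacked feature-vector image, one row per 2DFT, grouped by condition.

    Dark red marks high magnitude; white lines separate the condition
    blocks.
    """
    fig, ax = plt.subplots(figsize=(10, 6))
    im = ax.imshow(features.rows, aspect="auto", cmap="jet", interpolation="nearest")
    labels = features.labels
    boundaries = np.nonzero(labels[1:] != labels[:-1])[0] + 0.5
    for b in boundaries:
        ax.axhline(b, color="white", lw=1.5)
    # annotate block midpoints
    edges = np.concatenate(([-0.5], boundaries, [len(labels) - 0.5]))
    for lo, hi in zip(edges[:-1], edges[1:]):
        ax.text(
            -0.01, (lo + hi) / 2, str(labels[int(np.ceil(lo + 0.5))]),
            transform=ax.get_yaxis_transform(), ha="right", va="center", fontsize=9,
        )
    ax.set_xlabel("2DFT feature index (frequency-major flattening)")
    ax.set_ylabel(f"{features.density}-density spectrum")
    fig.colorbar(im, ax=ax, label="2DFT magnitude (a.u.)")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def plot_df_scatter(cloud: DfScoreCloud, path, result: CriterionResult | None = None) -> None:
    """DF-score scatter with per-condition colours and centroid markers."""
    fig, ax = plt.subplots(figsize=(6, 6))
    for cond in cloud.conditions:
        pts = cloud.points[cloud.labels == cond]
        ax.scatter(
            pts[:, 0], pts[:, 1], s=14, alpha=0.7,
            color=_COLORS.get(cond), label=cond,
        )
        c = pts.mean(axis=0)
        ax.scatter([c[0]], [c[1]], marker="X", s=140, color=_COLORS.get(cond),
                   edgecolor="black", linewidth=1.2, zorder=5)
    title = "Discriminant function scores"
    if result is not None:
        verdict = "success" if result.success else "failure"
        title += f"\ncriterion = {result.criterion:.0f} ({verdict}, threshold {result.threshold:g})"
    ax.set_title(title)
    ax.set_xlabel("DF score 1")
    ax.set_ylabel("DF score 2")
    ax.legend()
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
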