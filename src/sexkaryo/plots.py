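"""Diagnostic plots: classification scatter and gate boundaries."""

from __future__ import annotations

from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .config import GateConfig
from .features import FeatureTable
from .karyotype import SexStats
from .model import MixtureFit, SexCall, scale_features

_SEX_COLORS = {"male": "#1f77b4", "female": "#d62728"}


def classification_plot(
    table: FeatureTable,
    fit: MixtureFit,
    calls: Sequence[SexCall],
    out_path: str,
) -> None:
    """Scatter of samples on the discriminant axis between cluster means.

    Scaled features are projected onto the line joining the two component
    means (the most separating direction); the second axis is the
    uncertainty, so flagged outliers stand out.
    """
    scaled, _ = scale_features(table)
    direction = fit.means[1] - fit.means[0]
    norm = np.linalg.norm(direction)
    direction = direction / norm if norm > 0 else direction
    proj = scaled @ direction
    unc = np.array([c.uncertainty for c in calls])
    colors = [_SEX_COLORS[c.sex] for c in calls]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(proj, unc, c=colors, s=18, alpha=0.8, edgecolors="none")
    for c, x, y in zip(calls, proj, unc):
        if c.outlier:
            ax.scatter([x], [y], facecolors="none", edgecolors="black", s=60)
    ax.set_xlabel("discriminant projection (scaled features)")
    ax.set_ylabel("uncertainty (1 - max posterior)")
    handles = [
        plt.Line2D([], [], marker="o", ls="", color=c, label=s)
        for s, c in _SEX_COLORS.items()
    ]
    ax.legend(handles=handles, frameon=False)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)


def gate_plot(
    table: FeatureTable,
    calls: Sequence[SexCall],
    stats: SexStats,
    out_path: str,
    gate_config: GateConfig | None = None,
) -> None:
    """Xmap vs Ymap scatter with the normal bands and fold-change gates."""
    cfg = gate_config or GateConfig()
    xs = np.array([r.Xmap for r in table.rows], dtype=float)
    ys = np.array([r.Ymap for r in table.rows], dtype=float)
    colors = [_SEX_COLORS[c.sex] for c in calls]
    fig, ax = plt.subplots(figsize=(6, 4.5))
    ax.scatter(xs, ys, c=colors, s=18, alpha=0.8, edgecolors="none")
    m = cfg.sd_multiplier
    for which, color in (("m", _SEX_COLORS["male"]), ("f", _SEX_COLORS["female"])):
        x_lo, x_hi = stats.band(f"xmap_{which}", m)
        y_lo, y_hi = stats.band(f"ymap_{which}", m)
        ax.add_patch(
            plt.Rectangle(
                (x_lo, y_lo), x_hi - x_lo, y_hi - y_lo,
                fill=False, edgecolor=color, ls="--", lw=1,
            )
        )
    ax.axhline(cfg.xyy_y_mult * stats.mean_ymap_m, color="gray", lw=0.8, ls=":")
    ax.axvline(cfg.x_monosomy_mult * stats.mean_xmap_f, color="gray", lw=0.8, ls=":")
    ax.set_xlabel("Xmap")
    ax.set_ylabel("Ymap")
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
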