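"""Optional matplotlib exports: polygonogram, response surface, synergy map."""

from __future__ import annotations

from typing import Sequence

import numpy as np
import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .bliss import BlissResult
from .qpop import BANDS, PairScore, SurfaceMap

__all__ = ["plot_polygonogram", "plot_surface", "plot_bliss_map"]

_BAND_STYLE = {
    "75-100": dict(color="crimson", lw=2.5, ls="-"),
    "50-75": dict(color="lightpink", lw=1.8, ls="--"),
    "25-50": dict(color="lightblue", lw=1.2, ls="--"),
    "0-25": dict(color="navy", lw=0.8, ls="-"),
}


def plot_polygonogram(banded: Sequence[PairScore], path: str) -> None:
    """Drugs on a circle; each chord styled by its pair's effectiveness band."""
    names = sorted({n for s in banded for n in s.pair})
    angle = {n: 2 * np.pi * i / len(names) for i, n in enumerate(names)}
    fig, ax = plt.subplots(figsize=(6, 6))
    for s in sorted(banded, key=lambda s: BANDS.index(s.percentile_band), reverse=True):
        xa, ya = np.cos(angle[s.pair[0]]), np.sin(angle[s.pair[0]])
        xb, yb = np.cos(angle[s.pair[1]]), np.sin(angle[s.pair[1]])
        ax.plot([xa, xb], [ya, yb], **_BAND_STYLE[s.percentile_band])
    for n, a in angle.items():
        ax.text(1.12 * np.cos(a), 1.12 * np.sin(a), n, ha="center", va="center", fontsize=8)
    ax.set_xlim(-1.3, 1.3)
    ax.set_ylim(-1.3, 1.3)
    ax.set_aspect("equal")
    ax.axis("off")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def plot_surface(surf: SurfaceMap, path: str) -> None:
    """Parabolic response surface of projected viability for one pair."""
    fig = plt.figure(figsize=(6, 5))
    ax = fig.add_subplot(projection="3d")
    gi, gj = np.meshgrid(surf.axis_i, surf.axis_j, indexing="ij")
    ax.plot_surface(gi, gj, surf.surface, cmap="viridis", edgecolor="none")
    ax.set_xlabel(f"{surf.pair[0]} (coded)")
    ax.set_ylabel(f"{surf.pair[1]} (coded)")
    ax.set_zlabel("projected viability (%)")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def plot_bliss_map(result: BlissResult, path: str) -> None:
    """Synergy landscape: per-cell Bliss delta heatmap over the checkerboard."""
    fig, ax = plt.subplots(figsize=(6, 5))
    lim = max(10.0, np.nanmax(np.abs(result.delta)))
    im = ax.imshow(result.delta, origin="lower", cmap="RdBu_r", vmin=-lim, vmax=lim)
    ax.set_xticks(range(result.doses_b.size), [f"{d:g}" for d in result.doses_b], rotation=45)
    ax.set_yticks(range(result.doses_a.size), [f"{d:g}" for d in result.doses_a])
    ax.set_xlabel(f"{result.drug_b} dose")
    ax.set_ylabel(f"{result.drug_a} dose")
    ax.set_title(
        f"Bliss delta = {result.mean_delta:.2f} +/- {result.ci95:.2f} ({result.classification})"
    )
    fig.colorbar(im, ax=ax, label="delta (pp)")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
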