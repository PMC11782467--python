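"""Matplotlib figures: phase-diagram heatmaps and sex-ratio curves."""
from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402
from matplotlib.colors import ListedColormap  # noqa: E402
from matplotlib.patches import Patch  # noqa: E402

from .dynamics import Dominance  # noqa: E402
from .sweeps import RegionMap  # noqa: E402

__all__ = ["region_map_figure", "curve_figure", "trajectory_figure"]

_DOM_ORDER = [Dominance.MULTIPLE_MATING, Dominance.GUARDING,
              Dominance.COEXISTENCE, Dominance.EXTINCT]
_DOM_COLORS = ["#d95f02", "#1b9e77", "#7570b3", "#999999"]
_DOM_LABELS = ["multiple mating", "guarding", "coexistence", "extinct"]


def region_map_figure(
    region_map: RegionMap,
    contours: str = "osr",
    levels: int | list[float] = 8,
    ax: plt.Axes | None = None,
) -> plt.Figure:
    """Dominance regions coloured per cell with iso-ratio contour overlay.

    ``contours`` may be "osr", "asr", "both" or "none".
    """
    if ax is None:
        fig, ax = plt.subplots(figsize=(7, 5.5))
    else:
        fig = ax.figure
    x = np.asarray(region_map.axis2.values)
    y = np.asarray(region_map.axis1.values)
    codes = np.full(region_map.shape, np.nan)
    for idx, dom in enumerate(_DOM_ORDER):
        codes[region_map.dominance == dom] = idx
    cmap = ListedColormap(_DOM_COLORS)
    ax.pcolormesh(x, y, codes, cmap=cmap, vmin=-0.5, vmax=3.5,
                  shading="nearest")
    present = [int(i) for i in np.unique(codes[~np.isnan(codes)])]
    ax.legend(handles=[Patch(color=_DOM_COLORS[i], label=_DOM_LABELS[i])
                       for i in present],
              loc="upper right", framealpha=0.9)

    overlays = {"osr": [("osr", "k")], "asr": [("asr", "k")],
                "both": [("osr", "k"), ("asr", "w")], "none": []}
    for which, color in overlays[contours]:
        field = getattr(region_map, which)
        if np.isfinite(field).sum() >= 4:
            cs = ax.contour(x, y, field, levels=levels, colors=color,
                            linewidths=0.8)
            ax.clabel(cs, fontsize=7, fmt="%.1f")
    ax.set_xlabel(region_map.axis2.name)
    ax.set_ylabel(region_map.axis1.name)
    ax.set_title("dominant strategy at equilibrium")
    return fig


def curve_figure(
    curves: dict[str, pd.DataFrame],
    xlabel: str,
    ratio: str = "osr",
    ax: plt.Axes | None = None,
) -> plt.Figure:
    """Equilibrium sex-ratio curves, one line per labelled series."""
    if ax is None:
        fig, ax = plt.subplots(figsize=(6.5, 4.5))
    else:
        fig = ax.figure
    for label, df in curves.items():
        ax.plot(df["value"], df[ratio], marker="o", ms=3, label=label)
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ratio.upper())
    ax.legend()
    return fig


def trajectory_figure(df: pd.DataFrame,
                      compartments: list[str] | None = None,
                      logy: bool = False) -> plt.Figure:
    """Time evolution of selected compartments from a trajectory frame."""
    fig, ax = plt.subplots(figsize=(7, 4.5))
    cols = compartments or [c for c in df.columns
                            if c not in ("t", "asr", "osr")]
    for c in cols:
        ax.plot(df["t"], df[c], label=c, lw=1.2)
    if logy:
        ax.set_yscale("log")
    ax.set_xlabel("time (years)")
    ax.set_ylabel("density")
    ax.legend(ncol=3, fontsize=8)
    return fig


def save_figure(fig: plt.Figure, path: str | Path) -> None:
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
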