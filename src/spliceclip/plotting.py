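"""Basic profile/bar/box figures (non-normative presentation helpers)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .profiles import NormalizedProfile, PositionSummary
from .substrate import Substrate

__all__ = ["plot_profile", "plot_species_proportions", "plot_position_box"]


def plot_profile(
    profile: NormalizedProfile,
    substrate: Substrate | None = None,
    anchor: str = "brA",
    ax=None,
    **kwargs,
):
    """Smoothed crosslink curve, x-axis relative to a landmark if given."""
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    x = np.arange(len(profile))
    if substrate is not None and profile.reference_name == substrate.name:
        offset = substrate.brA if anchor == "brA" else substrate.ss3
        x = x - offset
        ax.axvline(0, color="grey", lw=0.8, ls="--")
        ax.set_xlabel(f"position relative to {anchor}")
    else:
        ax.set_xlabel("position")
    ax.plot(x, profile.values, **kwargs)
    ax.set_ylabel("crosslinks / background million")
    return ax


def plot_species_proportions(proportions, ax=None):
    """Bar chart of cDNA proportions per reference (from species_proportions)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    ax.bar(proportions.index, proportions["proportion"])
    ax.set_ylabel("proportion of cDNAs")
    ax.tick_params(axis="x", rotation=45)
    return ax


def plot_position_box(summary: PositionSummary, ax=None, y: float = 0.0):
    """Weighted box plot drawn from a PositionSummary."""
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 1.5))
    ax.hlines(y, summary.whisker_low, summary.whisker_high, color="k", lw=1)
    ax.add_patch(
        plt.Rectangle((summary.q1, y - 0.2), summary.iqr, 0.4,
                      fill=True, facecolor="#bbccee", edgecolor="k")
    )
    ax.vlines(summary.median, y - 0.2, y + 0.2, color="k", lw=2)
    if summary.outliers:
        ax.plot(summary.outliers, [y] * len(summary.outliers), "k.", ms=4)
    ax.set_yticks([])
    ax.set_xlabel("position")
    return ax
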