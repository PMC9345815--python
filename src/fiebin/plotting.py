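"""Diagnostic plots: infusion profile and within-bin spectra."""

from __future__ import annotations

from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .infusion import InfusionWindow, TicProfile
from .metrics import BinStats

__all__ = ["plot_infusion_profile", "plot_bin_spectrum"]


def plot_infusion_profile(
    profile: TicProfile,
    window: InfusionWindow | None = None,
    fraction: float = 0.5,
    path: str | None = None,
):
    """Plot an averaged TIC profile with the plug-flow window shaded.

    The dashed line marks ``fraction`` of the maximum TIC, above which
    scans are selected for processing.
    """
    fig, ax = plt.subplots(figsize=(6, 3.2))
    cycles = range(1, len(profile) + 1)
    ax.plot(cycles, profile.tic, marker="o", ms=3, lw=1, color="black")
    ax.axhline(fraction * profile.tic.max(), ls="--", color="red", lw=1)
    if window is not None:
        ax.axvspan(window.start - 0.5, window.end + 0.5, color="grey", alpha=0.3)
    ax.set_xlabel("scan (cycle ordinal)")
    ax.set_ylabel("total ion count")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_bin_spectrum(stats: BinStats, path: str | None = None):
    """Stem plot of a bin's member m/z vs abundance within the bin window."""
    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.stem(stats.m, stats.a, basefmt=" ")
    half = 0.5 * stats.width
    ax.axvline(stats.center, color="grey", ls=":", lw=1)
    ax.axvline(stats.mean_mz, color="red", ls="--", lw=1)
    ax.set_xlim(stats.center - half, stats.center + half)
    ax.set_xlabel("m/z")
    ax.set_ylabel("abundance")
    ax.set_title(
        f"purity {stats.purity:.3f}, centrality {stats.centrality:.3f}", fontsize=9
    )
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
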