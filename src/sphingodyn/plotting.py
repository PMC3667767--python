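"""Plot helpers mirroring the standard ensemble-figure layout."""

from __future__ import annotations

from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .ensemble import EnsembleSummary
from .inference import CandidateSolution

__all__ = ["plot_ensemble", "plot_fit"]


def plot_ensemble(summary: EnsembleSummary,
                  members: Sequence[CandidateSolution] = (),
                  enzymes: Sequence[str] | None = None,
                  path: str | None = None):
    """Per-enzyme panels: member traces (grey), mean (red), 95% band (blue)."""
    enzymes = list(enzymes or summary.enzymes)
    ncol = min(4, len(enzymes))
    nrow = -(-len(enzymes) // ncol)
    fig, axes = plt.subplots(nrow, ncol, figsize=(3.2 * ncol, 2.4 * nrow),
                             squeeze=False, sharex=True)
    for ax, enz in zip(axes.flat, enzymes):
        for c in members:
            ax.plot(c.schedule.grid, c.schedule.folds[enz], color="0.75",
                    lw=0.5, zorder=1)
        ax.plot(summary.grid, summary.lower[enz], "b:", lw=1, zorder=3)
        ax.plot(summary.grid, summary.upper[enz], "b:", lw=1, zorder=3)
        ax.plot(summary.grid, summary.mean[enz], "r-", lw=1.5, zorder=4)
        ax.set_title(enz, fontsize=9)
        ax.set_ylim(bottom=0)
    for ax in axes.flat[len(enzymes):]:
        ax.set_visible(False)
    fig.supxlabel("time (min)")
    fig.supylabel("activity (fold of baseline)")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_fit(fold_trajectory, targets, path: str | None = None):
    """Simulated fold curves (lines) against smoothed targets (symbols)."""
    species = [s for s in targets.fold.columns if s in fold_trajectory.columns]
    fig, axes = plt.subplots(2, 3, figsize=(10, 5), squeeze=False, sharex=True)
    for ax, sp in zip(axes.flat, species):
        ax.plot(targets.grid, targets.fold[sp], "ko", ms=3, label="target")
        ax.plot(fold_trajectory.index, fold_trajectory[sp], "-", label="model")
        ax.set_title(sp, fontsize=9)
    axes.flat[0].legend(fontsize=8)
    fig.supxlabel("time (min)")
    fig.supylabel("fold change")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
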