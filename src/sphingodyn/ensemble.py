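"""Summaries of selected ensembles: means, envelopes, identifiability, zones.

Each retained candidate contributes one fold-change trajectory per enzyme.
The summary reduces the member trajectories to a pointwise mean, a pointwise
2.5%/97.5% quantile envelope enclosing 95% of the members, and a relative
band width from which each enzyme is classified as identifiable ("tight") or
not ("loose"). Enzymes whose activity is constrained by the measured species
collapse to narrow bands regardless of the random initializations; enzymes
observable only through unmeasured pools retain the spread of their random
starts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .gma import ActivitySchedule
from .inference import CandidateSolution
from .pathway import load_registry

__all__ = [
    "EnsembleSummary",
    "summarize",
    "classify_identifiability",
    "mean_activity_model",
    "DEFAULT_TIGHT_THRESHOLD",
]

#: mean relative band width below which an enzyme counts as identifiable
DEFAULT_TIGHT_THRESHOLD = 0.75

#: normalization floor for relative band widths: bands are measured relative
#: to max(mean activity, one baseline fold), so an enzyme whose activity the
#: ensemble pins near zero is not spuriously classified non-identifiable by a
#: division with a vanishing mean
NORM_FLOOR = 1.0


@dataclass
class EnsembleSummary:
    """Per-enzyme ensemble statistics on the schedule grid.

    ``mean``, ``lower`` and ``upper`` are (grid x enzyme) DataFrames; the
    envelope is pointwise, so the mean is not guaranteed to stay inside it
    in pathological cases, but ``lower <= upper`` always holds.
    ``band_width`` is the grid-average of
    ``(upper - lower) / max(mean, NORM_FLOOR)`` per enzyme.
    """

    grid: np.ndarray
    mean: pd.DataFrame
    lower: pd.DataFrame
    upper: pd.DataFrame
    band_width: pd.Series
    n_members: int
    coverage: float = 95.0

    @property
    def enzymes(self) -> list[str]:
        return list(self.mean.columns)

    def zones(self) -> pd.Series:
        """Pathway zone per enzyme, via the bundled registry."""
        registry = load_registry()
        return pd.Series(
            {e: (registry[e].zone if e in registry else "unknown")
             for e in self.enzymes}, name="zone")

    def zone_report(self) -> pd.DataFrame:
        """Enzymes grouped by zone with band widths and classes."""
        df = pd.DataFrame({
            "zone": self.zones(),
            "band_width": self.band_width,
            "class": classify_identifiability(self),
        })
        return df.sort_values(["zone", "band_width"])

    def to_tidy(self) -> pd.DataFrame:
        rows = []
        for e in self.enzymes:
            for i, t in enumerate(self.grid):
                rows.append((e, t, self.mean[e].iloc[i],
                             self.lower[e].iloc[i], self.upper[e].iloc[i]))
        return pd.DataFrame(rows, columns=["enzyme", "time", "mean", "lower", "upper"])


def summarize(selected: Sequence[CandidateSolution],
              coverage: float = 95.0) -> EnsembleSummary:
    """Pointwise mean and central ``coverage``% envelope of member schedules.

    Requires at least two members. The envelope takes the pointwise
    ``(100-coverage)/2`` and ``(100+coverage)/2`` percentiles, matching a
    per-time-point reading of "enclosing 95% of the results".
    """
    if len(selected) < 2:
        raise ValueError("need at least 2 candidates to summarize")
    if not 0 < coverage < 100:
        raise ValueError("coverage must lie in (0, 100)")
    grid = selected[0].schedule.grid
    enzymes = selected[0].schedule.enzymes
    for c in selected[1:]:
        if not np.array_equal(c.schedule.grid, grid) or c.schedule.enzymes != enzymes:
            raise ValueError("candidates have incompatible schedules")
    stack = np.stack([[c.schedule.folds[e] for e in enzymes] for c in selected])
    # stack shape: (member, enzyme, time)
    alpha = (100.0 - coverage) / 2.0
    mean = pd.DataFrame(stack.mean(axis=0).T, index=grid, columns=enzymes)
    lower = pd.DataFrame(np.percentile(stack, alpha, axis=0).T,
                         index=grid, columns=enzymes)
    upper = pd.DataFrame(np.percentile(stack, 100.0 - alpha, axis=0).T,
                         index=grid, columns=enzymes)
    rel = (upper - lower) / np.maximum(mean, NORM_FLOOR)
    return EnsembleSummary(grid=np.asarray(grid, dtype=float), mean=mean,
                           lower=lower, upper=upper,
                           band_width=rel.mean(axis=0), n_members=len(selected),
                           coverage=coverage)


def classify_identifiability(summary: EnsembleSummary,
                             threshold: float = DEFAULT_TIGHT_THRESHOLD) -> pd.Series:
    """Label each enzyme ``"tight"`` (identifiable) or ``"loose"``.

    An enzyme is tight iff its mean relative band width is below
    ``threshold``. The threshold is a package default; the published
    classification is qualitative.
    """
    return pd.Series(
        np.where(summary.band_width < threshold, "tight", "loose"),
        index=summary.band_width.index, name="class")


def mean_activity_model(summary: EnsembleSummary) -> ActivitySchedule:
    """Activity schedule carrying the ensemble-mean folds, ready to simulate.

    Averages of good fits are not themselves guaranteed to be good fits;
    the refit validation quantifies how well the mean schedule reproduces
    the targets.
    """
    return ActivitySchedule(summary.grid,
                            {e: summary.mean[e].to_numpy() for e in summary.enzymes})
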