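"""Preparation of sparse duplicate fold-change measurements for inference.

The measurement design is two replicate time courses of six sphingolipids
(DHS, DHS-P, DHC, PHS, PHS-P, PHC) sampled at 0, 5, 10, 15, 20, 25 and
30 minutes after a temperature step, reported as fold changes relative to
the unstressed baseline. Replicates are averaged, each species' trend is
fitted with a cubic smoothing spline (generalized cross-validation picks the
smoothing level unless overridden), and the spline is evaluated on a dense
per-minute grid of 31 points. Fold curves are converted to absolute
concentrations by multiplying with per-species steady-state baselines.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline
from sklearn.base import BaseEstimator, TransformerMixin

from .pathway import MEASURED_SPECIES

__all__ = [
    "SAMPLE_TIMES",
    "DENSE_GRID",
    "FOLD_FLOOR",
    "ObservationSet",
    "SmoothedTargets",
    "TimeCourseSmoother",
    "average_replicates",
    "smooth_and_resample",
    "fold_to_absolute",
    "absolute_to_fold",
]

#: the experimental sampling design (minutes after the temperature step)
SAMPLE_TIMES = (0.0, 5.0, 10.0, 15.0, 20.0, 25.0, 30.0)

#: dense per-minute reconstruction grid
DENSE_GRID = np.arange(0.0, 31.0)

#: positive floor for smoothed fold curves (DHS-P sits near zero absolutely;
#: the spline must never undershoot to a non-positive fold)
FOLD_FLOOR = 1e-6


class ObservationSet:
    """Replicated fold-change observations in tidy form.

    Wraps a DataFrame with columns ``species``, ``time_min``, ``replicate``,
    ``fold_change``. All fold changes must be positive and the t=0 folds are
    expected to scatter around 1.
    """

    COLUMNS = ("species", "time_min", "replicate", "fold_change")

    def __init__(self, data: pd.DataFrame):
        missing = set(self.COLUMNS) - set(data.columns)
        if missing:
            raise ValueError(f"observation table missing columns: {sorted(missing)}")
        df = data.loc[:, list(self.COLUMNS)].copy()
        df["time_min"] = df["time_min"].astype(float)
        df["fold_change"] = df["fold_change"].astype(float)
        if (df["fold_change"] <= 0).any():
            bad = df.loc[df["fold_change"] <= 0, ["species", "time_min"]]
            raise ValueError(f"non-positive fold changes at:\n{bad}")
        self.data = df

    @property
    def species(self) -> list[str]:
        return sorted(self.data["species"].unique())

    @property
    def sample_times(self) -> np.ndarray:
        return np.sort(self.data["time_min"].unique())

    @classmethod
    def from_csv(cls, path: str | Path) -> "ObservationSet":
        return cls(pd.read_csv(path))

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)

    def replicate_stats(self) -> pd.DataFrame:
        """Per species x time replicate mean, standard deviation and CV.

        The inference itself uses only means; the scatter feeds the
        noise calibration of the synthetic-data generator.
        """
        g = self.data.groupby(["species", "time_min"])["fold_change"]
        out = g.agg(["mean", "std", "count"]).reset_index()
        out["cv"] = out["std"] / out["mean"]
        return out


def average_replicates(obs: ObservationSet) -> pd.DataFrame:
    """Arithmetic replicate means, as a (time x species) table.

    Raises if any species lacks a value at any of the set's sampling times.
    """
    wide = (obs.data.groupby(["time_min", "species"])["fold_change"]
            .mean().unstack("species"))
    if wide.isna().any().any():
        holes = [(sp, t) for sp in wide.columns for t in wide.index
                 if pd.isna(wide.loc[t, sp])]
        raise ValueError(f"missing observations at (species, time): {holes}")
    return wide


@dataclass
class SmoothedTargets:
    """Per-minute smoothed concentration targets.

    ``fold`` holds one positive fold-change curve per species on ``grid``;
    ``baselines`` are the per-species steady-state concentrations used to
    scale folds into absolute units.
    """

    grid: np.ndarray
    fold: pd.DataFrame
    baselines: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if len(self.fold) != len(self.grid):
            raise ValueError("fold table and grid have incongruent lengths")
        if (self.fold.to_numpy() <= 0).any():
            raise ValueError("fold curves must be positive")
        if self.baselines is None:
            self.baselines = pd.Series(1.0, index=self.fold.columns)
        else:
            self.baselines = pd.Series(self.baselines, dtype=float)
            if (self.baselines.loc[self.fold.columns] <= 0).any():
                raise ValueError("baselines must be positive")

    @property
    def species(self) -> list[str]:
        return list(self.fold.columns)

    def absolute(self) -> pd.DataFrame:
        """Absolute-concentration curves: fold x baseline per species."""
        return self.fold * self.baselines.loc[self.fold.columns]

    def to_tidy(self) -> pd.DataFrame:
        absolute = self.absolute()
        rows = []
        for sp in self.fold.columns:
            for i, t in enumerate(self.grid):
                rows.append((t, sp, self.fold[sp].iloc[i], absolute[sp].iloc[i]))
        return pd.DataFrame(rows, columns=["time", "species", "fold", "absolute"])


class TimeCourseSmoother(TransformerMixin, BaseEstimator):
    """Cubic smoothing-spline resampler for replicated fold-change series.

    Parameters
    ----------
    lam : float or None, default None
        Smoothing penalty passed to the spline fit. ``None`` selects the
        level by generalized cross-validation; ``0`` gives an interpolating
        spline through the replicate means.
    grid : array-like, default 0..30 min at 1-min steps
        Dense output grid.
    floor : float, default 1e-6
        Positive clip applied to the smoothed fold curves.

    After :meth:`fit`, ``splines_`` maps species to fitted spline callables
    and ``mean_`` holds the replicate means the splines were fitted to.
    """

    def __init__(self, lam: float | None = None, grid: Iterable[float] = DENSE_GRID,
                 floor: float = FOLD_FLOOR):
        self.lam = lam
        self.grid = grid
        self.floor = floor

    def fit(self, X: ObservationSet | pd.DataFrame, y=None) -> "TimeCourseSmoother":
        obs = X if isinstance(X, ObservationSet) else ObservationSet(X)
        grid = np.asarray(list(self.grid), dtype=float)
        if grid.ndim != 1 or np.any(np.diff(grid) <= 0):
            raise ValueError("output grid must be strictly increasing")
        mean = average_replicates(obs)
        times = mean.index.to_numpy(dtype=float)
        if np.any(np.diff(times) <= 0):
            raise ValueError("sample times must be strictly increasing")
        if len(times) < 4:
            raise ValueError("smoothing spline needs at least 4 time points per species")
        self.splines_ = {
            sp: make_smoothing_spline(times, mean[sp].to_numpy(), lam=self.lam)
            for sp in mean.columns
        }
        self.mean_ = mean
        self.grid_ = grid
        return self

    def transform(self, X=None) -> SmoothedTargets:
        if not hasattr(self, "splines_"):
            if X is None:
                raise RuntimeError("TimeCourseSmoother is not fitted")
            self.fit(X)
        fold = pd.DataFrame(
            {sp: np.clip(spl(self.grid_), self.floor, None)
             for sp, spl in self.splines_.items()},
            index=pd.Index(self.grid_, name="time"),
        )
        return SmoothedTargets(self.grid_, fold)


def smooth_and_resample(mean_series: pd.DataFrame | ObservationSet,
                        lam: float | None = None,
                        grid: Iterable[float] = DENSE_GRID,
                        baselines: Mapping[str, float] | None = None) -> SmoothedTargets:
    """Smooth replicate-mean series and resample on the dense grid.

    ``mean_series`` may be an :class:`ObservationSet` (replicates are averaged
    first) or a (time x species) mean table.
    """
    if isinstance(mean_series, pd.DataFrame):
        tidy = mean_series.reset_index().melt(
            id_vars=mean_series.index.name or "index",
            var_name="species", value_name="fold_change")
        tidy.columns = ["time_min", "species", "fold_change"]
        tidy["replicate"] = 1
        obs = ObservationSet(tidy)
    else:
        obs = mean_series
    targets = TimeCourseSmoother(lam=lam, grid=grid).fit_transform(obs)
    if baselines is not None:
        targets.baselines = pd.Series(baselines, dtype=float)
    return targets


def fold_to_absolute(fold: pd.DataFrame, baselines: Mapping[str, float]) -> pd.DataFrame:
    """Scale fold-change curves into absolute concentrations (fold x baseline)."""
    b = pd.Series(baselines, dtype=float)
    cols = list(fold.columns)
    if (b.loc[cols] <= 0).any():
        raise ValueError("baselines must be positive")
    return fold * b.loc[cols]


def absolute_to_fold(absolute: pd.DataFrame, baselines: Mapping[str, float]) -> pd.DataFrame:
    """Inverse of :func:`fold_to_absolute`; the round trip is the identity."""
    b = pd.Series(baselines, dtype=float)
    cols = list(absolute.columns)
    if (b.loc[cols] <= 0).any():
        raise ValueError("baselines must be positive")
    return absolute / b.loc[cols]


def default_observation_frame(folds: Mapping[str, Mapping[float, tuple[float, ...]]]
                              ) -> pd.DataFrame:
    """Build a tidy observation table from nested {species: {time: replicates}}."""
    rows = [
        (sp, t, r + 1, v)
        for sp, series in folds.items()
        for t, reps in series.items()
        for r, v in enumerate(reps)
    ]
    return pd.DataFrame(rows, columns=list(ObservationSet.COLUMNS))
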