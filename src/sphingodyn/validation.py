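"""Independent checks of an inferred ensemble.

Five validations mirror the study design: (1) refitting the data with the
ensemble-mean activity schedule, (2) flatness of the complex sphingolipids
that were never fitted, (3) a negative control that clamps the key
identifiable enzymes at baseline and shows the remaining enzymes cannot
rescue the fit, (4) cumulative precursor (3-KDHS) production with its
degradation bookkept separately, and (5) Arrhenius Q10 estimates from the
immediate activity rise after the 30->39 degC temperature step.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .ensemble import EnsembleSummary, mean_activity_model
from .gma import ActivitySchedule, GMAModel, SimulationError, TimeCourse, simulate
from .inference import (CandidateSolution, OptimizationConfig, _sse_from_folds,
                        run_ensemble)
from .preprocessing import SmoothedTargets

__all__ = [
    "RefitResult",
    "NegativeControlResult",
    "refit_with_means",
    "complex_lipid_flatness",
    "negative_control",
    "cumulative_production",
    "estimate_q10",
    "COMPLEX_SPECIES",
]

COMPLEX_SPECIES = ("IPC", "MIPC", "MIP2C")

#: temperature step (degC) of the heat-stress protocol, 30 -> 39
DELTA_T = 9.0


@dataclass
class RefitResult:
    trajectory: TimeCourse
    fold_trajectory: pd.DataFrame
    sse: float
    member_median_sse: float | None
    threshold_factor: float
    passed: bool | None

    def __repr__(self) -> str:  # pragma: no cover
        return (f"RefitResult(sse={self.sse:.4g}, "
                f"member_median_sse={self.member_median_sse}, passed={self.passed})")


def refit_with_means(summary: EnsembleSummary, model: GMAModel,
                     targets: SmoothedTargets,
                     selected: Sequence[CandidateSolution] | None = None,
                     threshold_factor: float = 2.0) -> RefitResult:
    """Simulate under the ensemble-mean schedule and score the fit.

    Averages of good fits need not be good fits, so the refit SSE is checked
    against ``threshold_factor`` x the median SSE of the selected members
    (when members are supplied); the SSE itself is always reported.
    """
    schedule = mean_activity_model(summary)
    trajectory = simulate(model, schedule)
    base = pd.Series({s: model.variable(s).baseline for s in model.dependent_ids})
    fold = trajectory.values / base
    measured = [s for s in targets.fold.columns if s in fold.columns]
    sse = _sse_from_folds(fold, targets.fold, measured)
    median = None
    passed = None
    if selected:
        median = float(np.median([c.sse for c in selected]))
        passed = bool(sse <= threshold_factor * median)
    return RefitResult(trajectory, fold, sse, median, threshold_factor, passed)


def complex_lipid_flatness(fold_trajectory: pd.DataFrame,
                           species: Sequence[str] = COMPLEX_SPECIES,
                           tolerance: float = 0.25) -> pd.Series:
    """Maximum absolute fold deviation from 1 per complex sphingolipid.

    The complex sphingolipids were not used in the optimization; their
    near-constancy under the inferred activities is an out-of-sample check.
    Values at or below ``tolerance`` count as flat.
    """
    missing = [s for s in species if s not in fold_trajectory.columns]
    if missing:
        raise ValueError(f"species absent from trajectory: {missing}")
    dev = (fold_trajectory.loc[:, list(species)] - 1.0).abs().max(axis=0)
    dev.name = "max_abs_fold_deviation"
    dev.attrs["tolerance"] = tolerance
    dev.attrs["flat"] = bool((dev <= tolerance).all())
    return dev


@dataclass
class NegativeControlResult:
    unconstrained_sse: np.ndarray
    constrained_sse: np.ndarray
    clamped: tuple[str, ...]
    passed: bool

    @property
    def best_unconstrained(self) -> float:
        return float(np.min(self.unconstrained_sse))

    @property
    def best_constrained(self) -> float:
        return float(np.min(self.constrained_sse))


def negative_control(targets: SmoothedTargets, model: GMAModel,
                     config: OptimizationConfig, clamp: Sequence[str],
                     n_runs: int = 20, base_seed: int = 0) -> NegativeControlResult:
    """Clamp enzymes at baseline and re-run the ensemble at equal seeds.

    The clamped enzymes are removed from the free set (held at fold 1) and
    all remaining enzymes are optimized exactly as before. The control
    passes when the constrained best SSE is strictly worse than the
    unconstrained best. With an empty clamp set the two ensembles are
    identical by construction.
    """
    clamp = tuple(clamp)
    unknown = [e for e in clamp if e not in config.free_enzymes]
    if unknown:
        raise ValueError(f"clamped enzymes not in the free set: {unknown}")
    free_rest = tuple(e for e in config.free_enzymes if e not in clamp)
    if not free_rest:
        raise ValueError("clamping removed every free enzyme")
    constrained = replace(config, free_enzymes=free_rest)
    unc = run_ensemble(targets, model, config, n_runs=n_runs, base_seed=base_seed)
    con = run_ensemble(targets, model, constrained, n_runs=n_runs, base_seed=base_seed)
    unc_sse = np.array([c.sse for c in unc])
    con_sse = np.array([c.sse for c in con])
    return NegativeControlResult(unc_sse, con_sse, clamp,
                                 passed=bool(con_sse.min() > unc_sse.min()))


def cumulative_production(model: GMAModel, schedule: ActivitySchedule | None,
                          species: str = "KDHS",
                          grid: np.ndarray | None = None,
                          rtol: float = 1e-10, atol: float = 1e-12) -> pd.DataFrame:
    """Cumulative production and consumption of one species along a simulation.

    The production column is the running integral of all fluxes producing
    ``species`` — the accumulation the species would show if its degradation
    were computationally omitted. Under baseline activities with a constant
    entry flux this curve is exactly linear; subtracting the consumption
    integral recovers the species' net concentration change (flux
    bookkeeping identity).
    """
    if species not in model.dependent_ids:
        raise ValueError(f"{species!r} is not a dependent variable")
    prod_fluxes, cons_fluxes = model.fluxes_for(species)
    if not prod_fluxes:
        raise ValueError(f"{species!r} has no producing flux")
    prod_coef = np.zeros(len(model.fluxes))
    cons_coef = np.zeros(len(model.fluxes))
    for j, f in enumerate(model.fluxes):
        prod_coef[j] = sum(c for sp, c in f.produces if sp == species)
        cons_coef[j] = sum(c for sp, c in f.consumes if sp == species)

    if schedule is None:
        if grid is None:
            grid = np.arange(0.0, 31.0)
        schedule = ActivitySchedule.baseline(np.asarray(grid, dtype=float))
    out_grid = schedule.grid if grid is None else np.asarray(grid, dtype=float)

    n_dep = model.n_dependent
    y = np.concatenate([model.baseline_state(), [0.0, 0.0]])
    times = [float(out_grid[0])]
    rows = [y.copy()]

    for k in range(schedule.n_intervals):
        t0, t1 = schedule.grid[k], schedule.grid[k + 1]
        indep = model.indep_from_folds(schedule.folds_at(k))

        def rhs(t, yy):
            flux = model.flux_values(yy[:n_dep], indep)
            return np.concatenate([
                model._stoich @ flux,
                [prod_coef @ flux, cons_coef @ flux],
            ])

        requested = out_grid[(out_grid > t0 + 1e-12) & (out_grid <= t1 + 1e-12)]
        t_eval = np.unique(np.append(requested, t1))
        sol = solve_ivp(rhs, (t0, t1), y, method="LSODA", t_eval=t_eval,
                        rtol=rtol, atol=atol)
        if not sol.success:
            raise SimulationError(f"integration failed on [{t0}, {t1}]",
                                  interval=(float(t0), float(t1)))
        for i, te in enumerate(sol.t):
            if requested.size and np.min(np.abs(requested - te)) <= 1e-9:
                times.append(float(te))
                rows.append(sol.y[:, i].copy())
        y = sol.y[:, -1].copy()

    arr = np.array(rows)
    return pd.DataFrame(
        {"production": arr[:, n_dep], "consumption": arr[:, n_dep + 1],
         "concentration": arr[:, model.dependent_ids.index(species)]},
        index=pd.Index(times, name="time"))


def estimate_q10(summary: EnsembleSummary | pd.DataFrame,
                 t_early: float = 3.0, delta_t: float = DELTA_T) -> pd.Series:
    """Q10 per enzyme from the initial activity rise after the heat step.

    The immediate activity jump is read as a pure Arrhenius effect of the
    ``delta_t`` = 9 degC shift, so ``Q10 = peak_fold ** (10 / delta_t)``
    where ``peak_fold`` is the maximum mean fold over the first ``t_early``
    minutes. An unmoved enzyme (fold 1) has Q10 = 1.
    """
    mean = summary.mean if isinstance(summary, EnsembleSummary) else summary
    grid = np.asarray(mean.index, dtype=float)
    early = mean.loc[grid <= t_early + 1e-9]
    if early.empty:
        raise ValueError("no grid points inside the early window")
    peak = early.max(axis=0)
    if (peak <= 0).any():
        bad = list(peak.index[peak <= 0])
        raise ValueError(f"non-positive early fold for {bad}")
    q10 = peak ** (10.0 / delta_t)
    q10.name = "Q10"
    return q10
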