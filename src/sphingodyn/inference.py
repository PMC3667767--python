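"""Piecewise inference of time-varying enzyme activities.

The dynamic inverse problem: given smoothed per-minute concentration targets
for the six measured sphingolipids, find piecewise-constant fold-change
profiles of the free enzyme activities such that the GMA model reproduces the
targets. Each 1-minute interval is optimized separately — the enzyme folds
are held constant over the interval and chosen to minimize the scaled
distance between the simulated and the target state at the interval's end —
and the dependent state is carried forward from the simulation, so a full
run chains 30 interval optimizations into one continuous trajectory.

Because six observed species cannot pin down all free enzymes, the problem
is underdetermined; a single run converges to one point on a solution
manifold that depends on its random initialization. The ensemble machinery
therefore repeats the run from many random starts, scores each candidate by
SSE and AICc, and retains the best fraction for summary analysis. With every
candidate carrying the same number of optimized parameters, AICc ranking
provably coincides with SSE ranking, which is the consistency the selection
step checks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator

from .gma import (ActivitySchedule, GMAModel, SimulationError, TimeCourse,
                  _integrate_interval, simulate)
from .pathway import MEASURED_SPECIES
from .preprocessing import SmoothedTargets

__all__ = [
    "OptimizationConfig",
    "CandidateSolution",
    "optimize_interval",
    "infer_trajectory",
    "run_ensemble",
    "compute_sse",
    "compute_aicc",
    "select_top",
    "criterion_agreement",
    "PiecewiseActivityInferrer",
    "EnsembleActivityInferrer",
]

#: residual value substituted when the simulator fails inside the objective
_PENALTY = 1e6


@dataclass(frozen=True)
class OptimizationConfig:
    """Settings for the per-interval optimizer.

    Parameters
    ----------
    free_enzymes : tuple of str
        Independent variables whose fold profiles are optimized; all others
        stay at fold 1.
    measured_species : tuple of str
        Dependent variables entering the objective.
    bounds : (lo, hi)
        Box constraints on the folds, ``lo >= 0``.
    init_range : (lo, hi)
        Support of the log-uniform random initialization at t = 0.
    objective : {"fold", "absolute"}
        Residual scaling: per-species baseline scaling (fold space, the
        default) or raw absolute concentrations.
    max_nfev : int
        Objective-evaluation budget per interval (<= 2000).
    reset_to_data : bool
        If True, reset the measured species to the target values at each
        interval start instead of carrying the simulated state forward.
    """

    free_enzymes: tuple[str, ...]
    measured_species: tuple[str, ...] = MEASURED_SPECIES
    bounds: tuple[float, float] = (0.0, 10.0)
    init_range: tuple[float, float] = (0.25, 4.0)
    objective: str = "fold"
    max_nfev: int = 100
    ftol: float = 1e-10
    xtol: float = 1e-10
    diff_step: float = 1e-3
    sim_rtol: float = 1e-9
    sim_atol: float = 1e-12
    reset_to_data: bool = False
    warm_start: bool = True

    def __post_init__(self) -> None:
        if not self.free_enzymes:
            raise ValueError("free_enzymes must be non-empty")
        lo, hi = self.bounds
        if not (0 <= lo < hi):
            raise ValueError("bounds must satisfy 0 <= lo < hi")
        ilo, ihi = self.init_range
        if not (0 < ilo < ihi):
            raise ValueError("init_range must satisfy 0 < lo < hi")
        if self.objective not in ("fold", "absolute"):
            raise ValueError("objective must be 'fold' or 'absolute'")
        if not 1 <= self.max_nfev <= 2000:
            raise ValueError("max_nfev must be in [1, 2000]")


@dataclass
class CandidateSolution:
    """One inferred activity schedule with its simulated fit and scores."""

    schedule: ActivitySchedule
    trajectory: TimeCourse
    fold_trajectory: pd.DataFrame
    sse: float
    aicc: float
    converged: np.ndarray
    seed: int | None = None
    config: OptimizationConfig | None = field(default=None, repr=False)


def _default_config(model: GMAModel,
                    free_enzymes: Iterable[str] | None = None,
                    **overrides) -> OptimizationConfig:
    free = tuple(free_enzymes) if free_enzymes is not None else tuple(model.independent_ids)
    unknown = [e for e in free if e not in model.independent_ids]
    if unknown:
        raise ValueError(f"free enzymes not in model: {unknown}")
    measured = overrides.pop(
        "measured_species",
        tuple(s for s in MEASURED_SPECIES if s in model.dependent_ids)
        or tuple(model.dependent_ids))
    return OptimizationConfig(free_enzymes=free, measured_species=measured, **overrides)


def _endpoint(model: GMAModel, state: np.ndarray, t0: float, t1: float,
              folds: dict[str, float], rtol: float, atol: float) -> np.ndarray:
    return _endpoint_vec(model, state, t0, t1, model.indep_from_folds(folds),
                         rtol, atol)


def _endpoint_vec(model: GMAModel, state: np.ndarray, t0: float, t1: float,
                  indep: np.ndarray, rtol: float, atol: float) -> np.ndarray:
    """Dependent state at t1; jitted RK45 with LSODA fallback on failure."""
    from ._fast import rk45_endpoint

    y, ok = rk45_endpoint(np.ascontiguousarray(state, dtype=np.float64),
                          np.ascontiguousarray(indep, dtype=np.float64),
                          float(t0), float(t1), model._gamma, model._ko,
                          model._stoich, rtol, atol)
    if not ok:
        _, ys = _integrate_interval(model, state, t0, t1, indep,
                                    np.array([t1]), rtol, atol)
        y = ys[:, -1]
    return np.clip(y, 0.0, None)


def optimize_interval(model: GMAModel, state: np.ndarray, target_next: np.ndarray,
                      previous_folds: np.ndarray | None, config: OptimizationConfig,
                      t0: float, t1: float) -> tuple[np.ndarray, bool, np.ndarray]:
    """Optimize the free-enzyme folds over one interval ``[t0, t1)``.

    Minimizes the sum over measured species of squared scaled residuals
    between the simulated and the target state at ``t1``, warm-started from
    ``previous_folds`` (or, at the first interval, from the caller's random
    initialization). Returns ``(folds, converged, end_state)``.
    """
    meas_idx = np.array([model.dependent_ids.index(s) for s in config.measured_species])
    if config.objective == "fold":
        scale = model.baseline_state()[meas_idx]
    else:
        scale = np.ones(len(meas_idx))
    target = np.asarray(target_next, dtype=float)
    if target.shape != meas_idx.shape:
        raise ValueError("target length must match the measured species")
    if np.any(target <= 0) or np.any(state < 0):
        raise ValueError("targets must be positive and state non-negative")
    free = list(config.free_enzymes)
    x0 = (np.ones(len(free)) if previous_folds is None
          else np.clip(np.asarray(previous_folds, dtype=float),
                       config.bounds[0], config.bounds[1]))

    free_idx = np.array([model.independent_ids.index(e) for e in free])
    indep_base = model.indep_from_folds(None)
    state = np.ascontiguousarray(state, dtype=np.float64)

    def residuals(x: np.ndarray) -> np.ndarray:
        indep = indep_base.copy()
        indep[free_idx] = x * indep_base[free_idx]
        try:
            end = _endpoint_vec(model, state, t0, t1, indep,
                                config.sim_rtol, config.sim_atol)
        except SimulationError:
            return np.full(len(meas_idx), _PENALTY)
        return (end[meas_idx] - target) / scale

    res = least_squares(residuals, x0, bounds=config.bounds, method="trf",
                        max_nfev=config.max_nfev, ftol=config.ftol,
                        xtol=config.xtol, gtol=1e-12, diff_step=config.diff_step)
    folds_opt = np.clip(res.x, config.bounds[0], config.bounds[1])
    try:
        end_state = _endpoint(model, state, t0, t1, dict(zip(free, folds_opt)),
                              config.sim_rtol, config.sim_atol)
        converged = bool(res.status > 0)
    except SimulationError:
        end_state = state.copy()
        converged = False
    return folds_opt, converged, end_state


def _targets_in_model_units(targets: SmoothedTargets, model: GMAModel,
                            measured: Sequence[str]) -> pd.DataFrame:
    """Target absolute curves, scaled with the *model's* baselines.

    The objective lives in the model's units, so target folds are converted
    with the model's steady-state values regardless of any display baselines
    the targets carry.
    """
    missing = [s for s in measured if s not in targets.fold.columns]
    if missing:
        raise ValueError(f"targets lack measured species: {missing}")
    base = {s: model.variable(s).baseline for s in measured}
    return targets.fold.loc[:, list(measured)] * pd.Series(base)


def infer_trajectory(targets: SmoothedTargets, model: GMAModel,
                     config: OptimizationConfig | None = None,
                     seed: int | None = None) -> CandidateSolution:
    """One full piecewise-optimization run over the target grid.

    Chains :func:`optimize_interval` over all intervals, carrying the
    simulated dependent state forward (or resetting measured species to the
    data when ``config.reset_to_data``). The fold vector of the first
    interval is initialized log-uniformly on ``config.init_range`` using
    ``seed``; later intervals warm-start from their predecessor.
    """
    if config is None:
        config = _default_config(model)
    grid = np.asarray(targets.grid, dtype=float)
    n_int = len(grid) - 1
    measured = config.measured_species
    target_abs = _targets_in_model_units(targets, model, measured)
    meas_idx = np.array([model.dependent_ids.index(s) for s in measured])

    rng = np.random.default_rng(seed)
    lo, hi = config.init_range
    x = np.exp(rng.uniform(np.log(lo), np.log(hi), size=len(config.free_enzymes)))
    x = np.clip(x, config.bounds[0], config.bounds[1])

    state = model.baseline_state()
    folds_out = np.empty((n_int + 1, len(config.free_enzymes)))
    states = [state.copy()]
    converged = np.empty(n_int, dtype=bool)
    for k in range(n_int):
        target_next = target_abs.iloc[k + 1].to_numpy()
        if k > 0 and not config.warm_start:
            # fresh random start each interval: ensemble members then sample
            # the per-interval solution manifold instead of inheriting their
            # t=0 draw, which is what gives the envelopes their width
            x = np.clip(np.exp(rng.uniform(np.log(lo), np.log(hi),
                                           size=len(config.free_enzymes))),
                        config.bounds[0], config.bounds[1])
        x, ok, state = optimize_interval(model, state, target_next, x, config,
                                         grid[k], grid[k + 1])
        folds_out[k] = x
        converged[k] = ok
        states.append(state.copy())
        if config.reset_to_data:
            state = state.copy()
            state[meas_idx] = target_next
    folds_out[n_int] = folds_out[n_int - 1]

    schedule = ActivitySchedule(
        grid, dict(zip(config.free_enzymes, folds_out.T)), seed=seed)
    if config.reset_to_data:
        trajectory = simulate(model, schedule, rtol=config.sim_rtol,
                              atol=config.sim_atol)
    else:
        # the chained interval endpoints ARE the continuous simulation
        trajectory = TimeCourse(grid, pd.DataFrame(np.array(states),
                                                   columns=model.dependent_ids))
    base = pd.Series({s: model.variable(s).baseline for s in model.dependent_ids})
    fold_traj = trajectory.values / base
    sse = _sse_from_folds(fold_traj, targets.fold, measured)
    cand = CandidateSolution(schedule, trajectory, fold_traj, sse, np.nan,
                             converged, seed=seed, config=config)
    cand.aicc = compute_aicc(cand, targets)
    return cand


# ---------------------------------------------------------------------- #
# Scoring and selection
# ---------------------------------------------------------------------- #

def _sse_from_folds(fold_traj: pd.DataFrame, target_fold: pd.DataFrame,
                    measured: Sequence[str]) -> float:
    resid = (fold_traj.loc[:, list(measured)].to_numpy()
             - target_fold.loc[:, list(measured)].to_numpy())
    # baseline point (t = 0) is the anchor, not a fitted residual
    return float(np.sum(resid[1:] ** 2))


def compute_sse(candidate: CandidateSolution, targets: SmoothedTargets) -> float:
    """Sum of squared scaled residuals over species and post-baseline grid points.

    With per-species baseline scaling the residuals are differences of fold
    changes, so the SSE is invariant under any common rescaling of the
    baselines.
    """
    measured = (candidate.config.measured_species if candidate.config is not None
                else tuple(c for c in candidate.fold_trajectory.columns
                           if c in targets.fold.columns))
    return _sse_from_folds(candidate.fold_trajectory, targets.fold, measured)


def compute_aicc(candidate: CandidateSolution, targets: SmoothedTargets,
                 n: int | None = None, k: int | None = None) -> float:
    """Small-sample-corrected Akaike criterion of a candidate fit.

    AICc = n ln(SSE/n) + 2k + 2k(k+1)/(n - k - 1), with n the number of
    residuals and k the effective number of optimized parameters. By package
    convention k defaults to the number of free enzyme *profiles* (one
    effective parameter per enzyme): counting every per-interval fold value
    individually would make n - k - 1 negative at the stated problem sizes,
    leaving AICc undefined. Since k is identical across ensemble candidates,
    AICc ranking coincides with SSE ranking either way.

    Raises
    ------
    ValueError
        If ``n - k - 1 <= 0`` (AICc undefined).
    """
    measured = (candidate.config.measured_species if candidate.config is not None
                else tuple(c for c in candidate.fold_trajectory.columns
                           if c in targets.fold.columns))
    if n is None:
        n = len(measured) * (len(targets.grid) - 1)
    if k is None:
        k = len(candidate.schedule.folds)
    if n - k - 1 <= 0:
        raise ValueError(
            f"AICc undefined for n={n}, k={k}: n - k - 1 = {n - k - 1} <= 0")
    sse = compute_sse(candidate, targets)
    return float(n * np.log(max(sse, 1e-300) / n)
                 + 2 * k + 2 * k * (k + 1) / (n - k - 1))


def select_top(candidates: Sequence[CandidateSolution], n: int,
               criterion: str = "sse") -> list[CandidateSolution]:
    """Top-``n`` candidates by ascending SSE or AICc; ties break by run order."""
    if not candidates:
        raise ValueError("empty candidate list")
    if criterion not in ("sse", "aicc"):
        raise ValueError("criterion must be 'sse' or 'aicc'")
    if n > len(candidates):
        raise ValueError(f"cannot select top {n} of {len(candidates)} candidates")
    order = sorted(range(len(candidates)),
                   key=lambda i: (getattr(candidates[i], criterion), i))
    return [candidates[i] for i in order[:n]]


def criterion_agreement(candidates: Sequence[CandidateSolution], n: int) -> float:
    """Percentage overlap between the top-``n`` sets by SSE and by AICc."""
    top_sse = {id(c) for c in select_top(candidates, n, "sse")}
    top_aicc = {id(c) for c in select_top(candidates, n, "aicc")}
    return 100.0 * len(top_sse & top_aicc) / n


def run_ensemble(targets: SmoothedTargets, model: GMAModel,
                 config: OptimizationConfig | None = None,
                 n_runs: int = 100, base_seed: int = 0) -> list[CandidateSolution]:
    """Repeat :func:`infer_trajectory` from ``n_runs`` distinct random starts.

    Run seeds are derived deterministically from ``base_seed``, so the whole
    ensemble is reproducible; each candidate records its own seed. A run
    that fails outright is recorded as a warning and omitted.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    seeds = _derive_seeds(base_seed, n_runs)
    out: list[CandidateSolution] = []
    for s in seeds:
        try:
            out.append(infer_trajectory(targets, model, config, seed=int(s)))
        except Exception as exc:  # noqa: BLE001 - individual failures are not fatal
            warnings.warn(f"ensemble run with seed {s} failed: {exc}",
                          RuntimeWarning, stacklevel=2)
    if not out:
        raise RuntimeError("every ensemble run failed")
    return out


def _derive_seeds(base_seed: int, n: int) -> np.ndarray:
    return (np.random.SeedSequence(base_seed).generate_state(n, dtype=np.uint64)
            % np.uint64(2**31)).astype(np.int64)


# ---------------------------------------------------------------------- #
# Estimator interfaces
# ---------------------------------------------------------------------- #

class PiecewiseActivityInferrer(BaseEstimator):
    """Estimator wrapper around one piecewise-optimization run.

    ``fit(X)`` takes a :class:`SmoothedTargets` and infers the activity
    schedule; fitted attributes are ``schedule_``, ``trajectory_``,
    ``fold_trajectory_``, ``sse_``, ``aicc_`` and ``converged_``.
    ``predict()`` returns the simulated fold trajectory of the fit.
    """

    def __init__(self, model: GMAModel | None = None,
                 free_enzymes: tuple[str, ...] | None = None,
                 bounds: tuple[float, float] = (0.0, 10.0),
                 init_range: tuple[float, float] = (0.25, 4.0),
                 objective: str = "fold", max_nfev: int = 100,
                 ftol: float = 1e-10, xtol: float = 1e-10,
                 diff_step: float = 1e-3,
                 sim_rtol: float = 1e-9, sim_atol: float = 1e-12,
                 reset_to_data: bool = False, random_state: int | None = None):
        self.model = model
        self.free_enzymes = free_enzymes
        self.bounds = bounds
        self.init_range = init_range
        self.objective = objective
        self.max_nfev = max_nfev
        self.ftol = ftol
        self.xtol = xtol
        self.diff_step = diff_step
        self.sim_rtol = sim_rtol
        self.sim_atol = sim_atol
        self.reset_to_data = reset_to_data
        self.random_state = random_state

    def _config(self) -> OptimizationConfig:
        if self.model is None:
            raise ValueError("model must be set before fitting")
        return _default_config(
            self.model, self.free_enzymes, bounds=self.bounds,
            init_range=self.init_range, objective=self.objective,
            max_nfev=self.max_nfev, ftol=self.ftol, xtol=self.xtol,
            diff_step=self.diff_step, sim_rtol=self.sim_rtol,
            sim_atol=self.sim_atol,
            reset_to_data=self.reset_to_data)

    def fit(self, X: SmoothedTargets, y=None) -> "PiecewiseActivityInferrer":
        cand = infer_trajectory(X, self.model, self._config(),
                                seed=self.random_state)
        self.candidate_ = cand
        self.schedule_ = cand.schedule
        self.trajectory_ = cand.trajectory
        self.fold_trajectory_ = cand.fold_trajectory
        self.sse_ = cand.sse
        self.aicc_ = cand.aicc
        self.converged_ = cand.converged
        return self

    def predict(self, X=None) -> pd.DataFrame:
        if not hasattr(self, "candidate_"):
            raise RuntimeError("inferrer is not fitted")
        return self.fold_trajectory_


class EnsembleActivityInferrer(BaseEstimator):
    """Monte-Carlo multi-start ensemble of piecewise-optimization runs.

    ``fit(X)`` runs ``n_runs`` randomly initialized inferences, scores each
    by SSE and AICc, and keeps the best ``top`` by ``criterion``. Fitted
    attributes: ``candidates_`` (all runs), ``selected_`` (retained subset)
    and ``agreement_`` (SSE/AICc top-set overlap, percent).
    """

    def __init__(self, estimator: PiecewiseActivityInferrer | None = None,
                 n_runs: int = 100, top: int = 48, criterion: str = "sse",
                 random_state: int = 0):
        self.estimator = estimator
        self.n_runs = n_runs
        self.top = top
        self.criterion = criterion
        self.random_state = random_state

    def fit(self, X: SmoothedTargets, y=None) -> "EnsembleActivityInferrer":
        if self.estimator is None or self.estimator.model is None:
            raise ValueError("estimator with a model must be provided")
        if not 1 <= self.top <= self.n_runs:
            raise ValueError("top must be in [1, n_runs]")
        config = self.estimator._config()
        self.candidates_ = run_ensemble(X, self.estimator.model, config,
                                        n_runs=self.n_runs,
                                        base_seed=self.random_state)
        n_sel = min(self.top, len(self.candidates_))
        self.selected_ = select_top(self.candidates_, n_sel, self.criterion)
        self.agreement_ = criterion_agreement(self.candidates_, n_sel)
        return self

    def predict(self, X=None) -> pd.DataFrame:
        """Pointwise mean fold trajectory of the selected candidates."""
        if not hasattr(self, "selected_"):
            raise RuntimeError("ensemble is not fitted")
        stack = np.stack([c.fold_trajectory.to_numpy() for c in self.selected_])
        first = self.selected_[0].fold_trajectory
        return pd.DataFrame(stack.mean(axis=0), index=first.index,
                            columns=first.columns)
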