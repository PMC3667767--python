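"""Core representation and simulation of GMA power-law ODE systems.

A General Mass Action (GMA) model describes a reaction network in which every
process rate is a product of a rate constant and of the influencing variables
raised to real-valued exponents (kinetic orders):

    v_j = gamma_j * prod_i  X_i ** f_ij

Dependent variables (metabolite pools) evolve under ODEs assembled from the
stoichiometry of these fluxes; independent variables (enzyme activities,
clamped cofactor pools) are held constant within each interval of a
piecewise-constant :class:`ActivitySchedule` and reset at interval boundaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

__all__ = [
    "VariableSpec",
    "PowerLawTerm",
    "FluxDef",
    "GMAModel",
    "TimeCourse",
    "ActivitySchedule",
    "ModelDefinitionError",
    "DomainError",
    "SimulationError",
    "evaluate_term",
    "assemble_odes",
    "simulate",
    "steady_state_residual",
]

#: floor applied to state values before power-law evaluation; fractional
#: negative kinetic orders are undefined at zero concentration
STATE_FLOOR = 1e-12


class ModelDefinitionError(ValueError):
    """A model references undefined variables or violates a structural invariant."""


class DomainError(ValueError):
    """A state value lies outside the domain of a power-law term."""


class SimulationError(RuntimeError):
    """The ODE integrator failed; carries the offending interval."""

    def __init__(self, message: str, interval: tuple[float, float] | None = None):
        super().__init__(message)
        self.interval = interval


@dataclass(frozen=True)
class VariableSpec:
    """One model variable.

    Parameters
    ----------
    id : str
        Short symbol, unique within a model (e.g. ``"DHS"`` or ``"X57"``).
    name : str
        Human-readable label.
    role : {"dependent", "independent"}
        Dependent variables satisfy ODEs; independent ones are set externally.
    baseline : float
        Reference (steady-state) value in model units; must be positive for
        any variable carrying a nonzero kinetic order.
    """

    id: str
    name: str
    role: str
    baseline: float = 1.0

    def __post_init__(self) -> None:
        if self.role not in ("dependent", "independent"):
            raise ModelDefinitionError(
                f"variable {self.id!r}: role must be 'dependent' or 'independent', "
                f"got {self.role!r}"
            )
        if not np.isfinite(self.baseline) or self.baseline < 0:
            raise ModelDefinitionError(
                f"variable {self.id!r}: baseline must be finite and >= 0"
            )


@dataclass(frozen=True)
class PowerLawTerm:
    """A single power-law rate term ``gamma * prod X_i**f_i``."""

    rate_constant: float
    kinetic_orders: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (np.isfinite(self.rate_constant) and self.rate_constant > 0):
            raise ModelDefinitionError("rate_constant must be finite and > 0")
        object.__setattr__(self, "kinetic_orders", dict(self.kinetic_orders))


@dataclass(frozen=True)
class FluxDef:
    """A flux: a power-law term with its stoichiometric couplings.

    ``consumes`` and ``produces`` map dependent-variable ids to positive
    stoichiometric coefficients. ``catalyst`` optionally names the independent
    variable (enzyme) driving the flux; it is bookkeeping only — the kinetic
    dependence lives in ``term.kinetic_orders``.
    """

    id: str
    term: PowerLawTerm
    consumes: tuple[tuple[str, float], ...] = ()
    produces: tuple[tuple[str, float], ...] = ()
    catalyst: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "consumes", tuple((str(k), float(v)) for k, v in self.consumes))
        object.__setattr__(self, "produces", tuple((str(k), float(v)) for k, v in self.produces))
        if not self.consumes and not self.produces:
            raise ModelDefinitionError(f"flux {self.id!r}: consumes and produces both empty")
        for sp, coef in (*self.consumes, *self.produces):
            if coef <= 0:
                raise ModelDefinitionError(
                    f"flux {self.id!r}: stoichiometric coefficient for {sp!r} must be > 0"
                )


class GMAModel:
    """A GMA model: variables plus power-law fluxes.

    Parameters
    ----------
    variables : sequence of VariableSpec
    fluxes : sequence of FluxDef
    name : str, optional

    Notes
    -----
    On construction the model is validated (unique ids, no dangling
    references, positive baselines wherever a nonzero kinetic order touches
    the variable) and compiled into dense arrays for fast simulation.
    """

    def __init__(self, variables: Sequence[VariableSpec], fluxes: Sequence[FluxDef],
                 name: str = "gma-model"):
        self.variables = list(variables)
        self.fluxes = list(fluxes)
        self.name = name
        self._validate()
        self._compile()

    # ------------------------------------------------------------------ #
    def _validate(self) -> None:
        ids = [v.id for v in self.variables]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ModelDefinitionError(f"duplicate variable ids: {dupes}")
        known = set(ids)
        dep = {v.id for v in self.variables if v.role == "dependent"}
        flux_ids = [f.id for f in self.fluxes]
        if len(set(flux_ids)) != len(flux_ids):
            raise ModelDefinitionError("duplicate flux ids")
        by_id = {v.id: v for v in self.variables}
        for f in self.fluxes:
            for var in f.term.kinetic_orders:
                if var not in known:
                    raise ModelDefinitionError(
                        f"flux {f.id!r}: kinetic order references unknown variable {var!r}"
                    )
                if f.term.kinetic_orders[var] != 0 and by_id[var].baseline <= 0:
                    raise ModelDefinitionError(
                        f"flux {f.id!r}: variable {var!r} has nonzero kinetic order "
                        "but baseline <= 0 (power law undefined)"
                    )
            for sp, _ in (*f.consumes, *f.produces):
                if sp not in dep:
                    raise ModelDefinitionError(
                        f"flux {f.id!r}: stoichiometry references {sp!r}, "
                        "which is not a dependent variable"
                    )
            if f.catalyst is not None and f.catalyst not in known:
                raise ModelDefinitionError(
                    f"flux {f.id!r}: catalyst {f.catalyst!r} not a model variable"
                )

    def _compile(self) -> None:
        self.dependent_ids: list[str] = [v.id for v in self.variables if v.role == "dependent"]
        self.independent_ids: list[str] = [v.id for v in self.variables if v.role == "independent"]
        order = self.dependent_ids + self.independent_ids
        self._index = {vid: i for i, vid in enumerate(order)}
        n_all, n_dep, n_flux = len(order), len(self.dependent_ids), len(self.fluxes)
        by_id = {v.id: v for v in self.variables}
        self._dep_baseline = np.array([by_id[i].baseline for i in self.dependent_ids])
        self._indep_baseline = np.array([by_id[i].baseline for i in self.independent_ids])
        self._gamma = np.array([f.term.rate_constant for f in self.fluxes])
        self._ko = np.zeros((n_flux, n_all))
        self._stoich = np.zeros((n_dep, n_flux))
        for j, f in enumerate(self.fluxes):
            for var, k in f.term.kinetic_orders.items():
                self._ko[j, self._index[var]] = k
            for sp, coef in f.produces:
                self._stoich[self._index[sp], j] += coef
            for sp, coef in f.consumes:
                self._stoich[self._index[sp], j] -= coef
        self._ko_dep = self._ko[:, :n_dep]
        self._ko_indep = self._ko[:, n_dep:]

    # ------------------------------------------------------------------ #
    @property
    def n_dependent(self) -> int:
        return len(self.dependent_ids)

    @property
    def n_independent(self) -> int:
        return len(self.independent_ids)

    def baseline_state(self) -> np.ndarray:
        """Baseline values of the dependent variables, in model units."""
        return self._dep_baseline.copy()

    def baselines(self) -> dict[str, float]:
        return {v.id: v.baseline for v in self.variables}

    def variable(self, vid: str) -> VariableSpec:
        for v in self.variables:
            if v.id == vid:
                return v
        raise KeyError(vid)

    def fluxes_for(self, species: str) -> tuple[list[FluxDef], list[FluxDef]]:
        """Return (producing, consuming) flux lists for a dependent variable."""
        if species not in self.dependent_ids:
            raise KeyError(f"{species!r} is not a dependent variable")
        prod = [f for f in self.fluxes if any(sp == species for sp, _ in f.produces)]
        cons = [f for f in self.fluxes if any(sp == species for sp, _ in f.consumes)]
        return prod, cons

    # ------------------------------------------------------------------ #
    def flux_values(self, dep_state: np.ndarray, indep_values: np.ndarray) -> np.ndarray:
        """All flux rates at the given (dependent, independent) state."""
        dep = np.maximum(np.asarray(dep_state, dtype=float), STATE_FLOOR)
        full = np.concatenate([dep, np.maximum(indep_values, 0.0)])
        # folds of 0 are legitimate (knocked-out enzyme): 0**k -> 0 for k>0
        with np.errstate(divide="ignore"):
            return self._gamma * np.prod(
                np.power(full[None, :], self._ko, where=self._ko != 0,
                         out=np.ones((len(self.fluxes), full.size))),
                axis=1,
            )

    def rhs(self, dep_state: np.ndarray, indep_values: np.ndarray) -> np.ndarray:
        return self._stoich @ self.flux_values(dep_state, indep_values)

    def indep_from_folds(self, folds: Mapping[str, float] | np.ndarray | None) -> np.ndarray:
        """Absolute independent-variable values from fold-change multipliers."""
        if folds is None:
            return self._indep_baseline.copy()
        if isinstance(folds, Mapping):
            vec = np.array([float(folds.get(i, 1.0)) for i in self.independent_ids])
        else:
            vec = np.asarray(folds, dtype=float)
            if vec.shape != (self.n_independent,):
                raise ValueError("fold vector length mismatch")
        return vec * self._indep_baseline

    def __repr__(self) -> str:  # pragma: no cover
        return (f"GMAModel({self.name!r}, {self.n_dependent} dependent, "
                f"{self.n_independent} independent, {len(self.fluxes)} fluxes)")


@dataclass
class TimeCourse:
    """Trajectories of the dependent variables on a time grid.

    ``values`` is a DataFrame indexed by time with one column per dependent
    variable; ``unit`` flags whether values are absolute model units or fold
    changes relative to baseline.
    """

    grid: np.ndarray
    values: pd.DataFrame
    unit: str = "absolute"

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if len(self.values) != len(self.grid):
            raise ValueError("grid and values have incongruent lengths")
        if self.unit not in ("absolute", "fold"):
            raise ValueError("unit must be 'absolute' or 'fold'")

    def to_fold(self, baselines: Mapping[str, float]) -> "TimeCourse":
        if self.unit == "fold":
            return self
        vals = self.values.copy()
        for col in vals.columns:
            b = baselines[col]
            if b <= 0:
                raise ValueError(f"baseline for {col!r} must be > 0")
            vals[col] = vals[col] / b
        return TimeCourse(self.grid, vals, unit="fold")

    def to_absolute(self, baselines: Mapping[str, float]) -> "TimeCourse":
        if self.unit == "absolute":
            return self
        vals = self.values.copy()
        for col in vals.columns:
            b = baselines[col]
            if b <= 0:
                raise ValueError(f"baseline for {col!r} must be > 0")
            vals[col] = vals[col] * b
        return TimeCourse(self.grid, vals, unit="absolute")

    def to_tidy(self) -> pd.DataFrame:
        """Long-format (time, variable, value, unit) table for CSV export."""
        long = self.values.copy()
        long.insert(0, "time", self.grid)
        long = long.melt(id_vars="time", var_name="variable", value_name="value")
        long["unit"] = self.unit
        return long


class ActivitySchedule:
    """Piecewise-constant enzyme fold-change profiles on a time grid.

    The fold value at grid index ``i`` applies over the interval
    ``[grid[i], grid[i+1])``; the value at the final grid point is retained
    for reporting but drives no interval. Enzymes absent from ``folds`` are
    implicitly held at fold 1 (baseline activity).
    """

    def __init__(self, grid: Iterable[float], folds: Mapping[str, Iterable[float]],
                 seed: int | None = None):
        self.grid = np.asarray(list(grid), dtype=float)
        if self.grid.ndim != 1 or len(self.grid) < 2 or np.any(np.diff(self.grid) <= 0):
            raise ValueError("schedule grid must be strictly increasing with >= 2 points")
        self.folds = {str(k): np.asarray(v, dtype=float) for k, v in folds.items()}
        for enz, arr in self.folds.items():
            if arr.shape != self.grid.shape:
                raise ValueError(f"fold profile for {enz!r} does not match the grid length")
            if not np.all(np.isfinite(arr)) or np.any(arr < 0):
                raise ValueError(f"fold profile for {enz!r} must be finite and >= 0")
        self.seed = seed

    @classmethod
    def baseline(cls, grid: Iterable[float], enzymes: Iterable[str] = ()) -> "ActivitySchedule":
        """All-ones schedule (no activity change)."""
        g = np.asarray(list(grid), dtype=float)
        return cls(g, {e: np.ones_like(g) for e in enzymes})

    @property
    def enzymes(self) -> list[str]:
        return list(self.folds)

    @property
    def n_intervals(self) -> int:
        return len(self.grid) - 1

    def folds_at(self, interval: int) -> dict[str, float]:
        if not 0 <= interval < self.n_intervals:
            raise IndexError(f"interval {interval} out of range")
        return {e: float(arr[interval]) for e, arr in self.folds.items()}

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.folds, index=pd.Index(self.grid, name="time"))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ActivitySchedule):
            return NotImplemented
        return (np.array_equal(self.grid, other.grid)
                and set(self.folds) == set(other.folds)
                and all(np.array_equal(self.folds[k], other.folds[k]) for k in self.folds))


# ---------------------------------------------------------------------- #
# Operations
# ---------------------------------------------------------------------- #

def evaluate_term(term: PowerLawTerm, state: Mapping[str, float]) -> float:
    """Evaluate ``gamma * prod X_i**f_i`` at a state.

    Raises
    ------
    ModelDefinitionError
        If a referenced variable is absent from ``state``.
    DomainError
        If a referenced value is negative, or zero under a negative order.
    """
    value = term.rate_constant
    for var, k in term.kinetic_orders.items():
        if var not in state:
            raise ModelDefinitionError(f"variable {var!r} missing from state")
        x = float(state[var])
        if x < 0:
            raise DomainError(f"negative state value for {var!r}: {x}")
        if x == 0 and k < 0:
            raise DomainError(f"{var!r} is 0 with negative kinetic order {k}")
        value *= x ** k
    return value


def assemble_odes(model: GMAModel) -> Callable[[np.ndarray, np.ndarray], np.ndarray]:
    """Return ``f(dependent_state, independent_values) -> d(state)/dt``.

    Each dependent variable's derivative is the stoichiometry-weighted sum of
    its producing fluxes minus its consuming fluxes.
    """
    return model.rhs


def _integrate_interval(model: GMAModel, y0: np.ndarray, t0: float, t1: float,
                        indep: np.ndarray, t_eval: np.ndarray | None,
                        rtol: float, atol: float) -> tuple[np.ndarray, np.ndarray]:
    n_dep = model.n_dependent
    full = np.empty(n_dep + model.n_independent)
    full[n_dep:] = np.maximum(indep, 0.0)
    gamma, ko, ko_dep, stoich = model._gamma, model._ko, model._ko_dep, model._stoich
    ones = np.ones((len(gamma), full.size))

    def rhs(t, y):
        full[:n_dep] = np.maximum(y, STATE_FLOOR)
        flux = gamma * np.prod(np.power(full[None, :], ko, where=ko != 0, out=ones.copy()),
                               axis=1)
        return stoich @ flux

    def jac(t, y):
        dep = np.maximum(y, STATE_FLOOR)
        full[:n_dep] = dep
        flux = gamma * np.prod(np.power(full[None, :], ko, where=ko != 0, out=ones.copy()),
                               axis=1)
        # d flux_j / d y_i = f_ij * flux_j / y_i
        return stoich @ (ko_dep * (flux[:, None] / dep[None, :]))

    sol = solve_ivp(rhs, (t0, t1), y0, method="LSODA", jac=jac,
                    t_eval=t_eval, rtol=rtol, atol=atol)
    if not sol.success:
        raise SimulationError(
            f"integration failed on [{t0}, {t1}]: {sol.message}", interval=(t0, t1))
    return sol.t, sol.y


def simulate(model: GMAModel, schedule: ActivitySchedule | None = None,
             grid: np.ndarray | None = None, initial_state: np.ndarray | None = None,
             rtol: float = 1e-8, atol: float = 1e-10) -> TimeCourse:
    """Integrate the model under a piecewise-constant activity schedule.

    Within each schedule interval the independent variables are held at
    ``fold * baseline``; the dependent state carries over continuously across
    interval boundaries (only activities are reset). With ``schedule=None``
    all activities stay at baseline and ``grid`` must be given.

    Returns a :class:`TimeCourse` in absolute model units on ``grid``
    (default: the schedule's own grid).
    """
    if schedule is None:
        if grid is None:
            raise ValueError("grid is required when no schedule is given")
        g = np.asarray(grid, dtype=float)
        schedule = ActivitySchedule.baseline(g)
    out_grid = schedule.grid if grid is None else np.asarray(grid, dtype=float)
    if out_grid[0] < schedule.grid[0] - 1e-12 or out_grid[-1] > schedule.grid[-1] + 1e-12:
        raise ValueError("output grid extends beyond the schedule")
    y = (model.baseline_state() if initial_state is None
         else np.asarray(initial_state, dtype=float).copy())
    if y.shape != (model.n_dependent,):
        raise ValueError("initial_state length mismatch")

    times: list[float] = []
    states: list[np.ndarray] = []
    if np.isclose(out_grid[0], schedule.grid[0]):
        times.append(float(out_grid[0]))
        states.append(y.copy())
    n_clip = 0
    for k in range(schedule.n_intervals):
        t0, t1 = schedule.grid[k], schedule.grid[k + 1]
        indep = model.indep_from_folds(schedule.folds_at(k))
        requested = out_grid[(out_grid > t0 + 1e-12) & (out_grid <= t1 + 1e-12)]
        t_eval = np.unique(np.append(requested, t1))
        _, ys = _integrate_interval(model, y, t0, t1, indep, t_eval, rtol, atol)
        n_clip += int(np.sum(ys < 0))
        for i, te in enumerate(t_eval):
            if requested.size and np.min(np.abs(requested - te)) <= 1e-9:
                times.append(float(te))
                states.append(ys[:, i].copy())
        y = ys[:, -1].copy()
    if n_clip > 0:
        warnings.warn(
            f"{n_clip} state value(s) dipped below 0 during integration and were "
            "floored before power-law evaluation", RuntimeWarning, stacklevel=2)
    values = pd.DataFrame(np.clip(np.array(states), 0.0, None),
                          columns=model.dependent_ids)
    return TimeCourse(np.array(times), values, unit="absolute")


def steady_state_residual(model: GMAModel) -> float:
    """Euclidean norm of the derivative vector at the baseline state.

    Zero iff the declared baselines form an exact steady state.
    """
    return float(np.linalg.norm(model.rhs(model.baseline_state(),
                                          model.indep_from_folds(None))))
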