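"""Core GMA representation and simulation."""

import numpy as np
import pandas as pd
import pytest
from scipy.linalg import expm

import sphingodyn as sd
from sphingodyn.gma import DomainError, ModelDefinitionError

from conftest import make_linear_model, make_toy_model


class TestEvaluateTerm:
    @pytest.mark.parametrize("gamma, orders, state, expected", [
        (2.0, {"A": 0.5}, {"A": 4.0}, 4.0),
        (3.0, {"A": 0.0}, {"A": 17.3}, 3.0),
        (1.0, {"A": 1.0, "E": 1.0}, {"A": 2.0, "E": 0.5}, 1.0),
        (1.5, {}, {}, 1.5),
    ])
    def test_values(self, gamma, orders, state, expected):
        term = sd.PowerLawTerm(gamma, orders)
        assert sd.evaluate_term(term, state) == pytest.approx(expected)

    def test_missing_variable_is_definition_error(self):
        term = sd.PowerLawTerm(1.0, {"A": 1.0})
        with pytest.raises(ModelDefinitionError, match="missing"):
            sd.evaluate_term(term, {"B": 1.0})

    def test_negative_state_is_domain_error(self):
        term = sd.PowerLawTerm(1.0, {"A": 0.5})
        with pytest.raises(DomainError):
            sd.evaluate_term(term, {"A": -1.0})

    def test_zero_state_with_negative_order_is_domain_error(self):
        term = sd.PowerLawTerm(1.0, {"A": -0.5})
        with pytest.raises(DomainError):
            sd.evaluate_term(term, {"A": 0.0})

    def test_zero_state_with_nonnegative_order_is_fine(self):
        assert sd.evaluate_term(sd.PowerLawTerm(2.0, {"A": 1.0}), {"A": 0.0}) == 0.0


class TestModelStructure:
    def test_duplicate_variable_ids_rejected(self):
        with pytest.raises(ModelDefinitionError, match="duplicate"):
            sd.GMAModel([sd.VariableSpec("A", "a", "dependent"),
                         sd.VariableSpec("A", "a2", "dependent")], [])

    def test_dangling_reference_rejected(self):
        with pytest.raises(ModelDefinitionError, match="unknown variable"):
            sd.GMAModel([sd.VariableSpec("A", "a", "dependent")],
                        [sd.FluxDef("v", sd.PowerLawTerm(1.0, {"Z": 1.0}),
                                    produces=(("A", 1.0),))])

    def test_constant_influx_derivative(self):
        m = sd.GMAModel([sd.VariableSpec("A", "a", "dependent")],
                        [sd.FluxDef("v", sd.PowerLawTerm(1.0), produces=(("A", 1.0),))])
        f = sd.assemble_odes(m)
        for state in ([0.2], [1.0], [5.0]):
            assert f(np.array(state), np.array([])) == pytest.approx([1.0])

    def test_balanced_model_has_zero_derivative_at_baseline(self, toy_model):
        f = sd.assemble_odes(toy_model)
        d = f(toy_model.baseline_state(), toy_model.indep_from_folds(None))
        assert np.allclose(d, 0.0, atol=1e-14)


class TestSteadyStateResidual:
    def test_core_model_balances(self, core_model):
        assert sd.steady_state_residual(core_model) < 1e-8

    def test_perturbed_rate_constant_breaks_balance(self, toy_model):
        fluxes = list(toy_model.fluxes)
        bad = sd.FluxDef("vin", sd.PowerLawTerm(1.1, {"E1": 1.0}),
                         produces=(("A", 1.0),), catalyst="E1")
        m = sd.GMAModel(toy_model.variables, [bad] + fluxes[1:])
        assert sd.steady_state_residual(m) > 1e-3

    def test_invariant_under_flux_relabeling(self, toy_model):
        r0 = sd.steady_state_residual(toy_model)
        shuffled = sd.GMAModel(toy_model.variables, toy_model.fluxes[::-1])
        assert sd.steady_state_residual(shuffled) == pytest.approx(r0, abs=1e-15)


class TestSimulate:
    def test_baseline_schedule_stays_at_steady_state(self, core_model):
        sched = sd.ActivitySchedule.baseline(sd.DENSE_GRID,
                                             core_model.independent_ids)
        tc = sd.simulate(core_model, sched)
        base = np.array([core_model.variable(s).baseline
                         for s in core_model.dependent_ids])
        assert np.max(np.abs(tc.values.to_numpy() / base - 1.0)) < 1e-6

    def test_constant_influx_without_efflux_accumulates_linearly(self):
        m = sd.GMAModel(
            [sd.VariableSpec("A", "a", "dependent", 1.0),
             sd.VariableSpec("E", "e", "independent", 1.0)],
            [sd.FluxDef("v", sd.PowerLawTerm(0.7, {"E": 1.0}),
                        produces=(("A", 1.0),), catalyst="E")])
        grid = np.arange(0.0, 11.0)
        tc = sd.simulate(m, sd.ActivitySchedule.baseline(grid, ["E"]))
        assert np.allclose(tc.values["A"].to_numpy(), 1.0 + 0.7 * grid, rtol=1e-8)

    def test_doubling_catalyst_doubles_first_order_flux(self, toy_model):
        # closed-form oracle: the power-law term itself
        term = toy_model.fluxes[1].term
        v1 = sd.evaluate_term(term, {"A": 1.3, "E2": 1.0})
        v2 = sd.evaluate_term(term, {"A": 1.3, "E2": 2.0})
        assert v2 == pytest.approx(2 * v1)
        # and through the assembled ODEs at fixed substrate
        f = sd.assemble_odes(toy_model)
        d1 = f(np.array([1.3, 1.0]), toy_model.indep_from_folds({"E2": 1.0}))
        d2 = f(np.array([1.3, 1.0]), toy_model.indep_from_folds({"E2": 2.0}))
        assert (d2 - d1)[1] == pytest.approx(v1, rel=1e-12)

    def test_matches_matrix_exponential_on_linear_case(self):
        m = make_linear_model(k1=0.7, k2=0.4, k3=0.3)
        A = np.array([[-0.7, 0.4], [0.7, -0.7]])
        y0 = np.array([2.0, 0.5])
        grid = np.linspace(0.0, 6.0, 7)
        tc = sd.simulate(m, grid=grid, initial_state=y0)
        exact = np.stack([expm(A * t) @ y0 for t in grid])
        assert np.max(np.abs(tc.values.to_numpy() - exact) / np.abs(exact)) < 1e-6

    def test_one_interval_schedule_equals_uninterrupted_run(self, toy_model):
        folds = {"E1": 1.6, "E2": 0.5}
        coarse = sd.ActivitySchedule([0.0, 5.0], {e: [v, v] for e, v in folds.items()})
        fine = sd.ActivitySchedule(np.linspace(0, 5, 11),
                                   {e: np.full(11, v) for e, v in folds.items()})
        tc1 = sd.simulate(toy_model, coarse, grid=np.array([0.0, 5.0]))
        tc2 = sd.simulate(toy_model, fine, grid=np.array([0.0, 5.0]))
        assert np.allclose(tc1.values.to_numpy(), tc2.values.to_numpy(),
                           rtol=1e-7, atol=1e-9)

    def test_mass_conserved_in_closed_subnetwork(self, core_model):
        # switch off entry and the two exit routes: remaining network only
        # interconverts, so total sphingoid material is invariant
        grid = np.arange(0.0, 16.0)
        folds = {e: np.ones_like(grid) for e in core_model.independent_ids}
        for e in ("X57", "X50", "X43"):
            folds[e] = np.zeros_like(grid)
        folds["X36"] = np.full_like(grid, 2.5)  # keep internal dynamics moving
        folds["X54"] = np.full_like(grid, 0.3)
        tc = sd.simulate(core_model, sd.ActivitySchedule(grid, folds))
        total = tc.values.sum(axis=1).to_numpy()
        assert np.max(np.abs(total - total[0])) < 1e-7

    def test_schedule_validation(self):
        with pytest.raises(ValueError, match="grid"):
            sd.ActivitySchedule([0.0], {"E": [1.0]})
        with pytest.raises(ValueError, match="finite"):
            sd.ActivitySchedule([0.0, 1.0], {"E": [1.0, np.nan]})


class TestTimeCourse:
    def test_unit_round_trip(self):
        grid = np.array([0.0, 1.0, 2.0])
        vals = pd.DataFrame({"A": [2.0, 3.0, 4.0]})
        tc = sd.TimeCourse(grid, vals, unit="absolute")
        back = tc.to_fold({"A": 2.0}).to_absolute({"A": 2.0})
        assert np.allclose(back.values["A"], vals["A"])

    def test_tidy_export_shape(self):
        tc = sd.TimeCourse(np.array([0.0, 1.0]),
                           pd.DataFrame({"A": [1.0, 2.0], "B": [3.0, 4.0]}))
        tidy = tc.to_tidy()
        assert list(tidy.columns) == ["time", "variable", "value", "unit"]
        assert len(tidy) == 4
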