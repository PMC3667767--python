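"""Per-interval optimization, run chaining, scoring and selection."""

import itertools

import numpy as np
import pandas as pd
import pytest

import sphingodyn as sd
from sphingodyn.inference import (_default_config, _endpoint_vec,
                                  criterion_agreement)
from sphingodyn.preprocessing import SmoothedTargets

from conftest import make_toy_model


def toy_targets(model, schedule, grid=None):
    """Noise-free fold targets from simulating a known schedule."""
    tc = sd.simulate(model, schedule, grid=grid)
    base = pd.Series(
        {s: model.variable(s).baseline for s in model.dependent_ids})
    fold = tc.values / base
    fold.index = tc.grid
    return SmoothedTargets(tc.grid, fold)


def grid_search_oracle(model, state, target, free, box=(0.05, 4.0), n=60):
    """Exhaustive search over the fold box; independent of the optimizer."""
    meas = [model.dependent_ids.index(s) for s in model.dependent_ids]
    ib = model.indep_from_folds(None)
    fidx = [model.independent_ids.index(e) for e in free]
    axis = np.linspace(box[0], box[1], n)
    best, best_sse = None, np.inf
    for combo in itertools.product(axis, repeat=len(free)):
        indep = ib.copy()
        indep[fidx] = np.array(combo) * ib[fidx]
        end = _endpoint_vec(model, state, 0.0, 1.0, indep, 1e-9, 1e-12)
        sse = float(np.sum((end[meas] - target) ** 2))
        if sse < best_sse:
            best, best_sse = np.array(combo), sse
    return best, best_sse


class TestOptimizeInterval:
    def test_recovers_generating_folds_on_toy_model(self, toy_model):
        truth = np.array([2.2, 0.6])
        cfg = _default_config(toy_model, ("E1", "E2"))
        state = toy_model.baseline_state()
        indep = toy_model.indep_from_folds(dict(zip(("E1", "E2"), truth)))
        target = _endpoint_vec(toy_model, state, 0.0, 1.0, indep, 1e-10, 1e-13)
        # grid-search oracle agrees with the truth up to its resolution
        oracle, _ = grid_search_oracle(toy_model, state, target, ("E1", "E2"))
        step = (4.0 - 0.05) / 59
        assert np.all(np.abs(oracle - truth) <= step)
        folds, ok, _ = sd.optimize_interval(
            toy_model, state, target, np.array([1.0, 1.0]), cfg, 0.0, 1.0)
        assert ok
        assert np.max(np.abs(folds - truth)) < 1e-3

    def test_warm_start_does_not_move_the_optimum(self, toy_model):
        truth = np.array([1.8, 1.3])
        cfg = _default_config(toy_model, ("E1", "E2"))
        state = toy_model.baseline_state()
        indep = toy_model.indep_from_folds(dict(zip(("E1", "E2"), truth)))
        target = _endpoint_vec(toy_model, state, 0.0, 1.0, indep, 1e-10, 1e-13)
        from_cold, _, _ = sd.optimize_interval(toy_model, state, target,
                                               np.array([1.0, 1.0]), cfg, 0.0, 1.0)
        from_far, _, _ = sd.optimize_interval(toy_model, state, target,
                                              np.array([3.5, 0.2]), cfg, 0.0, 1.0)
        assert np.allclose(from_cold, from_far, atol=1e-5)

    def test_steady_state_target_needs_no_change(self, toy_model):
        cfg = _default_config(toy_model, ("E1", "E2"))
        state = toy_model.baseline_state()
        folds, ok, _ = sd.optimize_interval(toy_model, state, state.copy(),
                                            np.array([1.0, 1.0]), cfg, 0.0, 1.0)
        assert ok and np.allclose(folds, 1.0, atol=1e-6)

    def test_objective_zero_at_generating_folds(self, toy_model):
        truth = {"E1": 1.4, "E2": 0.8}
        state = toy_model.baseline_state()
        indep = toy_model.indep_from_folds(truth)
        target = _endpoint_vec(toy_model, state, 0.0, 1.0, indep, 1e-10, 1e-13)
        again = _endpoint_vec(toy_model, state, 0.0, 1.0, indep, 1e-10, 1e-13)
        assert np.max(np.abs(again - target)) < 1e-12


@pytest.fixture(scope="module")
def toy_truth_run():
    """A short noise-free inference problem on the toy model."""
    model = make_toy_model()
    grid = np.arange(0.0, 6.0)
    truth = sd.ActivitySchedule(grid, {
        "E1": np.array([1.0, 2.0, 2.5, 1.5, 0.7, 0.7]),
        "E2": np.array([1.0, 0.5, 0.4, 0.8, 1.6, 1.6]),
    })
    targets = toy_targets(model, truth)
    cfg = _default_config(model, ("E1", "E2"))
    return model, truth, targets, cfg


class TestInferTrajectory:
    def test_recovers_known_schedule(self, toy_truth_run):
        model, truth, targets, cfg = toy_truth_run
        cand = sd.infer_trajectory(targets, model, cfg, seed=11)
        for e in ("E1", "E2"):
            # the determined toy problem pins every interval exactly
            assert np.max(np.abs(cand.schedule.folds[e][:-1]
                                 - truth.folds[e][:-1])) < 1e-3
        assert cand.sse < 1e-8

    def test_deterministic_under_fixed_seed(self, toy_truth_run):
        model, _, targets, cfg = toy_truth_run
        a = sd.infer_trajectory(targets, model, cfg, seed=42)
        b = sd.infer_trajectory(targets, model, cfg, seed=42)
        assert a.schedule == b.schedule
        assert a.sse == b.sse

    def test_baseline_targets_give_unit_folds(self, toy_model):
        grid = np.arange(0.0, 6.0)
        targets = toy_targets(toy_model,
                              sd.ActivitySchedule.baseline(grid, ("E1", "E2")))
        cfg = _default_config(toy_model, ("E1", "E2"))
        cand = sd.infer_trajectory(targets, toy_model, cfg, seed=3)
        for e in ("E1", "E2"):
            assert np.max(np.abs(cand.schedule.folds[e] - 1.0)) < 1e-3

    def test_data_reset_variant_also_recovers_noise_free_truth(self, toy_truth_run):
        from dataclasses import replace
        model, truth, targets, cfg = toy_truth_run
        cand = sd.infer_trajectory(targets, model,
                                   replace(cfg, reset_to_data=True), seed=11)
        # with exact targets, resetting to data equals carrying the state
        assert cand.sse < 1e-6
        assert np.max(np.abs(cand.schedule.folds["E1"][:-1]
                             - truth.folds["E1"][:-1])) < 1e-3

    def test_trajectory_matches_simulate_under_schedule(self, toy_truth_run):
        model, _, targets, cfg = toy_truth_run
        cand = sd.infer_trajectory(targets, model, cfg, seed=1)
        resim = sd.simulate(model, cand.schedule)
        assert np.allclose(cand.trajectory.values.to_numpy(),
                           resim.values.to_numpy(), atol=1e-6)


class TestScoring:
    def _candidate(self, toy_truth_run, seed=0):
        model, _, targets, cfg = toy_truth_run
        return sd.infer_trajectory(targets, model, cfg, seed=seed), targets

    def test_perfect_fit_has_zero_sse(self, toy_truth_run):
        cand, targets = self._candidate(toy_truth_run)
        assert sd.compute_sse(cand, targets) < 1e-8

    def test_uniform_residual_sums_squares(self):
        grid = np.arange(0.0, 4.0)
        fold = pd.DataFrame({"A": np.ones(4), "B": np.ones(4)}, index=grid)
        targets = SmoothedTargets(grid, fold * 1.0)
        shifted = fold + 0.1
        cand = sd.CandidateSolution(
            schedule=sd.ActivitySchedule.baseline(grid, ("E",)),
            trajectory=None, fold_trajectory=shifted, sse=np.nan, aicc=np.nan,
            converged=np.ones(3, bool))
        # 2 species x 3 post-baseline points x 0.1^2
        assert sd.compute_sse(cand, targets) == pytest.approx(6 * 0.01)

    def test_sse_invariant_under_common_baseline_rescaling(self, toy_truth_run):
        model, truth, targets, cfg = toy_truth_run
        cand = sd.infer_trajectory(targets, model, cfg, seed=2)
        sse0 = sd.compute_sse(cand, targets)
        # scaling every baseline by c (and compensating the rate constants so
        # baseline fluxes keep their values) leaves fold-space residuals unchanged
        c = 3.0
        dep = set(model.dependent_ids)
        scaled = sd.GMAModel(
            [sd.VariableSpec(v.id, v.name, v.role,
                             v.baseline * (c if v.role == "dependent" else 1.0))
             for v in model.variables],
            [sd.FluxDef(f.id,
                        sd.PowerLawTerm(
                            f.term.rate_constant * c ** (
                                1 - sum(o for var, o in f.term.kinetic_orders.items()
                                        if var in dep)),
                            f.term.kinetic_orders),
                        f.consumes, f.produces, f.catalyst)
             for f in model.fluxes])
        cand2 = sd.infer_trajectory(targets, scaled, cfg, seed=2)
        assert sd.compute_sse(cand2, targets) == pytest.approx(sse0, abs=1e-8)

    def test_aicc_formula_and_undefined_region(self, toy_truth_run):
        cand, targets = self._candidate(toy_truth_run)
        n, k = 10, 2
        sse = sd.compute_sse(cand, targets)
        expected = n * np.log(max(sse, 1e-300) / n) + 2 * k \
            + 2 * k * (k + 1) / (n - k - 1)
        assert sd.compute_aicc(cand, targets, n=n, k=k) == pytest.approx(expected)
        with pytest.raises(ValueError, match="undefined"):
            sd.compute_aicc(cand, targets, n=3, k=2)

    def test_equal_k_aicc_ordering_equals_sse_ordering(self, toy_truth_run):
        model, _, targets, cfg = toy_truth_run
        cands = [sd.infer_trajectory(targets, model, cfg, seed=s)
                 for s in (0, 1, 2, 3)]
        by_sse = sorted(cands, key=lambda c: c.sse)
        by_aicc = sorted(cands, key=lambda c: c.aicc)
        assert [id(c) for c in by_sse] == [id(c) for c in by_aicc]


class TestSelection:
    def _fake(self, sse, seed):
        grid = np.arange(0.0, 3.0)
        return sd.CandidateSolution(
            schedule=sd.ActivitySchedule.baseline(grid, ("E",)),
            trajectory=None, fold_trajectory=None, sse=sse,
            aicc=10 * np.log(max(sse, 1e-300) / 10), converged=np.ones(2, bool),
            seed=seed)

    def test_top_n_orders_ascending_with_stable_ties(self):
        cands = [self._fake(s, i) for i, s in enumerate([3.0, 1.0, 2.0, 1.0])]
        top = sd.select_top(cands, 2, "sse")
        assert [c.seed for c in top] == [1, 3]

    def test_agreement_is_100_for_identical_candidates(self):
        cands = [self._fake(1.0, i) for i in range(5)]
        assert criterion_agreement(cands, 3) == 100.0

    def test_agreement_is_100_when_selecting_all(self):
        cands = [self._fake(s, i) for i, s in enumerate([5.0, 1.0, 3.0])]
        assert criterion_agreement(cands, 3) == 100.0

    def test_empty_selection_errors(self):
        with pytest.raises(ValueError, match="empty"):
            sd.select_top([], 1)

    def test_selecting_more_than_available_errors(self):
        with pytest.raises(ValueError, match="top"):
            sd.select_top([self._fake(1.0, 0)], 2)


class TestEnsemble:
    def test_reproducible_under_base_seed(self, toy_truth_run):
        model, _, targets, cfg = toy_truth_run
        a = sd.run_ensemble(targets, model, cfg, n_runs=3, base_seed=7)
        b = sd.run_ensemble(targets, model, cfg, n_runs=3, base_seed=7)
        assert [c.sse for c in a] == [c.sse for c in b]
        assert [c.seed for c in a] == [c.seed for c in b]

    def test_single_run_reduces_to_infer_trajectory(self, toy_truth_run):
        model, _, targets, cfg = toy_truth_run
        ens = sd.run_ensemble(targets, model, cfg, n_runs=1, base_seed=5)
        direct = sd.infer_trajectory(targets, model, cfg, seed=ens[0].seed)
        assert ens[0].schedule == direct.schedule

    def test_derived_seeds_fit_in_31_bits(self):
        from sphingodyn.inference import _derive_seeds
        seeds = _derive_seeds(12345, 1000)
        assert seeds.min() >= 0 and seeds.max() < 2**31


class TestEstimators:
    def test_piecewise_inferrer_fits_and_predicts(self, toy_truth_run):
        model, truth, targets, _ = toy_truth_run
        est = sd.PiecewiseActivityInferrer(model=model, free_enzymes=("E1", "E2"),
                                           random_state=0)
        est.fit(targets)
        assert est.sse_ < 1e-8
        assert est.predict().shape == (len(targets.grid), model.n_dependent)
        assert est.get_params()["free_enzymes"] == ("E1", "E2")

    def test_ensemble_inferrer_selects_and_agrees(self, toy_truth_run):
        model, _, targets, _ = toy_truth_run
        base = sd.PiecewiseActivityInferrer(model=model, free_enzymes=("E1", "E2"))
        ens = sd.EnsembleActivityInferrer(estimator=base, n_runs=4, top=2,
                                          random_state=1).fit(targets)
        assert len(ens.candidates_) == 4 and len(ens.selected_) == 2
        assert ens.agreement_ == 100.0
        assert ens.predict().shape[0] == len(targets.grid)

    def test_sklearn_clone_compatible(self, toy_model):
        from sklearn.base import clone
        est = sd.PiecewiseActivityInferrer(model=toy_model, max_nfev=55)
        cloned = clone(est)
        assert cloned.max_nfev == 55
        assert cloned.model.name == toy_model.name
        assert not hasattr(cloned, "candidate_")
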