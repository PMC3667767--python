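"""Validation computations: refit, flatness, negative control, flux bookkeeping, Q10."""

import numpy as np
import pandas as pd
import pytest

import sphingodyn as sd
from sphingodyn.ensemble import summarize
from sphingodyn.inference import _default_config
from sphingodyn.validation import (complex_lipid_flatness, cumulative_production,
                                   estimate_q10, negative_control,
                                   refit_with_means)

from test_inference import toy_targets


@pytest.fixture(scope="module")
def toy_problem():
    from conftest import make_toy_model
    model = make_toy_model()
    grid = np.arange(0.0, 6.0)
    truth = sd.ActivitySchedule(grid, {
        "E1": np.array([1.0, 2.4, 2.0, 1.2, 0.6, 0.6]),
        "E2": np.ones(6),
    })
    targets = toy_targets(model, truth)
    cfg = _default_config(model, ("E1", "E2"))
    return model, truth, targets, cfg


class TestRefitWithMeans:
    def test_identical_members_refit_to_member_sse(self, toy_problem):
        model, _, targets, cfg = toy_problem
        cand = sd.infer_trajectory(targets, model, cfg, seed=0)
        summary = summarize([cand, cand])
        res = refit_with_means(summary, model, targets, selected=[cand, cand])
        assert res.sse == pytest.approx(cand.sse, abs=1e-8)
        assert res.member_median_sse == pytest.approx(cand.sse)

    def test_noise_free_truth_refits_to_near_zero(self, toy_problem):
        model, truth, targets, _ = toy_problem
        truth_cand = sd.CandidateSolution(
            schedule=truth, trajectory=None, fold_trajectory=None,
            sse=0.0, aicc=np.nan, converged=np.ones(5, bool))
        summary = summarize([truth_cand, truth_cand])
        res = refit_with_means(summary, model, targets)
        assert res.sse < 1e-10

    def test_pass_criterion_uses_member_median(self, toy_problem):
        model, _, targets, cfg = toy_problem
        cands = [sd.infer_trajectory(targets, model, cfg, seed=s) for s in (0, 1)]
        res = refit_with_means(summarize(cands), model, targets, selected=cands)
        assert res.passed is (res.sse <= 2.0 * res.member_median_sse)


class TestComplexLipidFlatness:
    def test_constant_trajectory_is_flat(self):
        fold = pd.DataFrame({"IPC": np.ones(5), "MIPC": np.ones(5),
                             "MIP2C": np.ones(5)})
        dev = complex_lipid_flatness(fold)
        assert np.allclose(dev, 0.0)
        assert dev.attrs["flat"]

    def test_deviation_is_max_abs_fold_excursion(self):
        fold = pd.DataFrame({"IPC": [0.9, 1.1, 1.0], "MIPC": [1.0, 1.0, 1.0],
                             "MIP2C": [1.0, 0.8, 1.2]})
        dev = complex_lipid_flatness(fold)
        assert dev["IPC"] == pytest.approx(0.1)
        assert dev["MIP2C"] == pytest.approx(0.2)

    def test_missing_species_is_an_error(self):
        with pytest.raises(ValueError, match="absent"):
            complex_lipid_flatness(pd.DataFrame({"IPC": [1.0]}))


class TestNegativeControl:
    def test_empty_clamp_reproduces_unconstrained(self, toy_problem):
        model, _, targets, cfg = toy_problem
        res = negative_control(targets, model, cfg, clamp=(), n_runs=2,
                               base_seed=3)
        assert np.allclose(res.unconstrained_sse, res.constrained_sse)
        assert not res.passed  # equal best SSE is not "strictly worse"

    def test_clamping_the_changing_enzyme_hurts(self, toy_problem):
        model, _, targets, cfg = toy_problem
        res = negative_control(targets, model, cfg, clamp=("E1",), n_runs=2,
                               base_seed=3)
        assert res.best_constrained > res.best_unconstrained
        assert res.passed

    def test_clamping_an_unmoved_enzyme_costs_nothing(self, toy_problem):
        model, _, targets, cfg = toy_problem
        # truth holds E2 at baseline, so fixing it there cannot hurt the fit
        res = negative_control(targets, model, cfg, clamp=("E2",), n_runs=2,
                               base_seed=3)
        assert res.best_constrained <= res.best_unconstrained + 1e-6

    def test_unknown_clamp_is_an_error(self, toy_problem):
        model, _, targets, cfg = toy_problem
        with pytest.raises(ValueError, match="not in the free set"):
            negative_control(targets, model, cfg, clamp=("X99",), n_runs=1)


class TestCumulativeProduction:
    def test_constant_rate_gives_linear_curve(self, core_model):
        curve = cumulative_production(core_model, None, "KDHS",
                                      grid=np.arange(0.0, 31.0))
        t = curve.index.to_numpy()
        assert np.allclose(curve["production"], 1.0 * t, atol=1e-8)

    def test_zero_production_when_entry_enzyme_is_off(self, core_model):
        grid = np.arange(0.0, 11.0)
        folds = {e: np.ones_like(grid) for e in core_model.independent_ids}
        folds["X57"] = np.zeros_like(grid)
        curve = cumulative_production(core_model,
                                      sd.ActivitySchedule(grid, folds), "KDHS",
                                      grid=grid)
        assert np.allclose(curve["production"], 0.0, atol=1e-10)

    def test_bookkeeping_identity_under_stress_schedule(self, core_model):
        grid = np.arange(0.0, 11.0)
        folds = {e: np.ones_like(grid) for e in core_model.independent_ids}
        folds["X57"] = np.concatenate([[1.0, 3.0, 2.0], np.full(8, 0.1)])
        folds["X27"] = np.linspace(1.0, 2.0, 11)
        curve = cumulative_production(core_model,
                                      sd.ActivitySchedule(grid, folds), "KDHS",
                                      grid=grid)
        net = curve["production"] - curve["consumption"]
        change = curve["concentration"] - curve["concentration"].iloc[0]
        assert np.max(np.abs(net - change)) < 1e-8

    def test_species_without_production_is_an_error(self, toy_model):
        with pytest.raises(ValueError, match="dependent"):
            cumulative_production(toy_model, None, "Z", grid=np.arange(3.0))


class TestQ10:
    def test_unmoved_enzyme_has_q10_one(self):
        mean = pd.DataFrame({"E": np.ones(31)}, index=np.arange(31.0))
        assert estimate_q10(mean)["E"] == pytest.approx(1.0)

    @pytest.mark.parametrize("peak, expected", [
        (2.0, 2.0 ** (10.0 / 9.0)),   # ~2.16
        (4.0, 4.0 ** (10.0 / 9.0)),   # ~4.67, the reported activation ceiling
    ])
    def test_peak_fold_maps_through_arrhenius_exponent(self, peak, expected):
        prof = np.ones(31)
        prof[2] = peak
        mean = pd.DataFrame({"E": prof}, index=np.arange(31.0))
        assert estimate_q10(mean)["E"] == pytest.approx(expected, rel=1e-12)

    def test_peak_outside_early_window_is_ignored(self):
        prof = np.ones(31)
        prof[20] = 5.0
        mean = pd.DataFrame({"E": prof}, index=np.arange(31.0))
        assert estimate_q10(mean, t_early=3.0)["E"] == pytest.approx(1.0)

    def test_non_positive_fold_is_an_error(self):
        mean = pd.DataFrame({"E": np.zeros(31)}, index=np.arange(31.0))
        with pytest.raises(ValueError, match="non-positive"):
            estimate_q10(mean)
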