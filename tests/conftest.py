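"""Shared fixtures: reduced pathway model, toy models, desk-scale ensemble."""

from __future__ import annotations

import numpy as np
import pytest

from sphingodyn import (FluxDef, GMAModel, PowerLawTerm, VariableSpec,
                        build_core_model, recovery_experiment)


@pytest.fixture(scope="session")
def core_model() -> GMAModel:
    return build_core_model()


def make_toy_model() -> GMAModel:
    """Two observable species, two enzymes; per-interval problem is determined.

    E1 drives a constant influx into A, E2 the conversion A -> B; B decays
    with a first-order efflux. Baselines form an exact steady state:
    influx 1 = conversion 1 = efflux 1 at A = B = 1.
    """
    variables = [
        VariableSpec("A", "species A", "dependent", 1.0),
        VariableSpec("B", "species B", "dependent", 1.0),
        VariableSpec("E1", "influx enzyme", "independent", 1.0),
        VariableSpec("E2", "conversion enzyme", "independent", 1.0),
    ]
    fluxes = [
        FluxDef("vin", PowerLawTerm(1.0, {"E1": 1.0}),
                produces=(("A", 1.0),), catalyst="E1"),
        FluxDef("vconv", PowerLawTerm(1.0, {"A": 1.0, "E2": 1.0}),
                consumes=(("A", 1.0),), produces=(("B", 1.0),), catalyst="E2"),
        FluxDef("vout", PowerLawTerm(1.0, {"B": 1.0}),
                consumes=(("B", 1.0),)),
    ]
    return GMAModel(variables, fluxes, name="toy-2sp")


@pytest.fixture()
def toy_model() -> GMAModel:
    return make_toy_model()


def make_linear_model(k1: float = 0.7, k2: float = 0.4, k3: float = 0.3) -> GMAModel:
    """All-kinetic-orders-1 two-species network with a matrix-exponential solution.

    dA/dt = -k1 A + k2 B ; dB/dt = k1 A - (k2 + k3) B.
    """
    variables = [
        VariableSpec("A", "A", "dependent", 1.0),
        VariableSpec("B", "B", "dependent", 1.0),
    ]
    fluxes = [
        FluxDef("f12", PowerLawTerm(k1, {"A": 1.0}),
                consumes=(("A", 1.0),), produces=(("B", 1.0),)),
        FluxDef("f21", PowerLawTerm(k2, {"B": 1.0}),
                consumes=(("B", 1.0),), produces=(("A", 1.0),)),
        FluxDef("fout", PowerLawTerm(k3, {"B": 1.0}),
                consumes=(("B", 1.0),)),
    ]
    return GMAModel(variables, fluxes, name="linear-2sp")


@pytest.fixture(scope="session")
def desk_ensemble():
    """Desk-scale Monte-Carlo recovery experiment (100 runs, top 48, seed 0).

    Shared by the acceptance checks on selection consistency and parameter
    recovery; scaled down from the published ensemble size (4144 runs,
    top 2004) at the same ~48% retention.
    """
    return recovery_experiment(build_core_model(), n_runs=100, top=48,
                               master_seed=0)
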