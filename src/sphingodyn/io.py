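"""Serialization: model definition files, tidy CSVs, ensemble JSON.

Model definition schema (YAML or JSON)
--------------------------------------
::

    name: my-model
    variables:
      - {id: A, name: species A, role: dependent, baseline: 1.0}
      - {id: E, name: enzyme, role: independent, baseline: 1.0}
    fluxes:
      - id: v1
        rate_constant: 0.5
        kinetic_orders: {A: 1.0, E: 1.0}
        consumes: [[A, 1.0]]
        produces: []
        catalyst: E

Ensembles are stored as versioned JSON carrying each candidate's schedule,
scores, seed and convergence flags; trajectories are recomputable from the
schedule and are not stored.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from .gma import ActivitySchedule, FluxDef, GMAModel, PowerLawTerm, VariableSpec
from .inference import CandidateSolution

__all__ = ["load_model", "save_model", "save_ensemble", "load_ensemble"]

ENSEMBLE_FORMAT_VERSION = 1


def _model_to_dict(model: GMAModel) -> dict:
    return {
        "name": model.name,
        "variables": [
            {"id": v.id, "name": v.name, "role": v.role, "baseline": v.baseline}
            for v in model.variables
        ],
        "fluxes": [
            {
                "id": f.id,
                "rate_constant": f.term.rate_constant,
                "kinetic_orders": dict(f.term.kinetic_orders),
                "consumes": [[sp, c] for sp, c in f.consumes],
                "produces": [[sp, c] for sp, c in f.produces],
                "catalyst": f.catalyst,
            }
            for f in model.fluxes
        ],
    }


def _model_from_dict(doc: dict) -> GMAModel:
    variables = [
        VariableSpec(str(v["id"]), str(v.get("name", v["id"])), str(v["role"]),
                     float(v.get("baseline", 1.0)))
        for v in doc.get("variables", [])
    ]
    fluxes = [
        FluxDef(
            str(f["id"]),
            PowerLawTerm(float(f["rate_constant"]),
                         {str(k): float(v)
                          for k, v in (f.get("kinetic_orders") or {}).items()}),
            consumes=tuple((str(sp), float(c)) for sp, c in f.get("consumes", [])),
            produces=tuple((str(sp), float(c)) for sp, c in f.get("produces", [])),
            catalyst=f.get("catalyst"),
        )
        for f in doc.get("fluxes", [])
    ]
    return GMAModel(variables, fluxes, name=str(doc.get("name", "gma-model")))


def save_model(model: GMAModel, path: str | Path) -> None:
    path = Path(path)
    doc = _model_to_dict(model)
    with open(path, "w") as fh:
        if path.suffix.lower() == ".json":
            json.dump(doc, fh, indent=1)
        else:
            yaml.safe_dump(doc, fh, sort_keys=False)


def load_model(path: str | Path) -> GMAModel:
    path = Path(path)
    with open(path) as fh:
        doc = json.load(fh) if path.suffix.lower() == ".json" else yaml.safe_load(fh)
    return _model_from_dict(doc)


def save_ensemble(candidates: list[CandidateSolution], path: str | Path,
                  meta: dict | None = None) -> None:
    doc = {
        "format_version": ENSEMBLE_FORMAT_VERSION,
        "meta": meta or {},
        "candidates": [
            {
                "seed": c.seed,
                "sse": c.sse,
                "aicc": None if c.aicc is None or not np.isfinite(c.aicc) else c.aicc,
                "converged": [bool(x) for x in c.converged],
                "grid": [float(t) for t in c.schedule.grid],
                "folds": {e: [float(x) for x in arr]
                          for e, arr in c.schedule.folds.items()},
            }
            for c in candidates
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_ensemble(path: str | Path) -> list[CandidateSolution]:
    """Load candidate schedules and scores (trajectories are not stored)."""
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("format_version") != ENSEMBLE_FORMAT_VERSION:
        raise ValueError(f"unsupported ensemble format: {doc.get('format_version')}")
    out = []
    for c in doc["candidates"]:
        schedule = ActivitySchedule(np.asarray(c["grid"]), c["folds"], seed=c["seed"])
        out.append(CandidateSolution(
            schedule=schedule, trajectory=None, fold_trajectory=None,  # type: ignore[arg-type]
            sse=float(c["sse"]),
            aicc=float(c["aicc"]) if c.get("aicc") is not None else np.nan,
            converged=np.asarray(c["converged"], dtype=bool), seed=c["seed"]))
    return out


def export_timecourse_csv(tc, path: str | Path) -> None:
    """Tidy (time, variable, value, unit) CSV for a TimeCourse."""
    tc.to_tidy().to_csv(path, index=False)


def export_summary(summary, path_prefix: str | Path) -> None:
    """Write an EnsembleSummary as JSON (scalars) plus tidy CSV (curves)."""
    prefix = Path(path_prefix)
    summary.to_tidy().to_csv(prefix.with_suffix(".csv"), index=False)
    doc = {
        "n_members": summary.n_members,
        "coverage": summary.coverage,
        "band_width": {k: float(v) for k, v in summary.band_width.items()},
        "zones": {k: str(v) for k, v in summary.zones().items()},
    }
    with open(prefix.with_suffix(".json"), "w") as fh:
        json.dump(doc, fh, indent=1)
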