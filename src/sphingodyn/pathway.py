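"""The yeast sphingolipid pathway: variable registry, zones, and models.

Two model sources are supported:

* :func:`load_full_model` reads the published full yeast model from an SBML
  file or zip archive (25 dependent, 41 independent variables); the archive
  itself is not bundled.
* :func:`build_core_model` constructs a self-contained reduced model of the
  core pathway (10 species, 14 enzymes) with normalized baselines chosen so
  that the unstressed state is an exact steady state. It reproduces the key
  topology of the full model — in particular the dihydrosphingosine node
  with three influx and three efflux terms — and serves as the test bed for
  the inference pipeline when the full model is unavailable.

Species
-------
de novo entry:  SPT (X57) -> KDHS -(X27)-> DHS
sphingoid bases and 1-phosphates:  DHS <-> DHS-P, PHS <-> PHS-P
  (kinase X36 forward, phosphatase X41 back)
ceramides:  DHS <-> DHC (synthase X34 / dihydro-CDase X29),
  PHS <-> PHC (synthase X34 / phyto-CDase X53)
hydroxylation:  DHS -> PHS and DHC -> PHC (4-hydroxylase X54)
complex sphingolipids:  DHC, PHC -(X33)-> IPC -(X35)-> MIPC -(X55)-> M(IP)2C,
  retrieval by IPCase X51 (IPC -> DHC, M(IP)2C -> PHC)
exits:  lyase X50 (DHS-P, PHS-P), GPI remodelase X43 (DHC, PHC)
"""

from __future__ import annotations

import io
import warnings
import zipfile
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from .gma import FluxDef, GMAModel, PowerLawTerm, VariableSpec

__all__ = [
    "RegistryEntry",
    "VariableRegistry",
    "load_registry",
    "zone_of",
    "build_core_model",
    "load_full_model",
    "MEASURED_SPECIES",
    "CORE_SPECIES",
    "CORE_ENZYMES",
    "TIGHT_SET",
]

#: the six sphingolipids measured in the heat-stress time courses
MEASURED_SPECIES = ("DHS", "DHSP", "DHC", "PHS", "PHSP", "PHC")

CORE_SPECIES = ("KDHS", "DHS", "DHSP", "DHC", "PHS", "PHSP", "PHC",
                "IPC", "MIPC", "MIP2C")

CORE_ENZYMES = ("X57", "X27", "X36", "X41", "X34", "X29", "X53", "X54",
                "X50", "X43", "X33", "X35", "X55", "X51")

#: the eight core-controlling enzymes expected to show tight activity ranges
TIGHT_SET = ("X34", "X36", "X41", "X43", "X50", "X54", "X57", "X59")


@dataclass(frozen=True)
class RegistryEntry:
    index: str
    name: str
    zone: str
    figure: int


class VariableRegistry:
    """Maps pathway index symbols (X-numbers) to names and zones."""

    def __init__(self, entries: dict[str, RegistryEntry]):
        self._entries = dict(entries)

    def __contains__(self, index: str) -> bool:
        return index in self._entries

    def __getitem__(self, index: str) -> RegistryEntry:
        try:
            return self._entries[index]
        except KeyError:
            raise KeyError(f"unknown pathway index {index!r}") from None

    def __len__(self) -> int:
        return len(self._entries)

    def indices(self) -> list[str]:
        return list(self._entries)

    def by_zone(self, zone: str) -> list[str]:
        return [i for i, e in self._entries.items() if e.zone == zone]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.index, e.name, e.zone, e.figure) for e in self._entries.values()],
            columns=["index", "name", "zone", "figure"],
        )


def load_registry() -> VariableRegistry:
    """Load the bundled, versioned zone annotation."""
    with resources.files("sphingodyn.data").joinpath("zones.csv").open() as fh:
        df = pd.read_csv(fh, comment="#")
    entries = {
        str(r["index"]): RegistryEntry(str(r["index"]), str(r["name"]),
                                       str(r["zone"]), int(r["figure"]))
        for _, r in df.iterrows()
    }
    return VariableRegistry(entries)


_REGISTRY: VariableRegistry | None = None


def zone_of(enzyme: str) -> str:
    """Pathway zone of an enzyme index (e.g. ``zone_of("X57") == "red"``)."""
    global _REGISTRY
    if _REGISTRY is None:
        _REGISTRY = load_registry()
    return _REGISTRY[enzyme].zone


# ---------------------------------------------------------------------- #
# Reduced core model
# ---------------------------------------------------------------------- #

# species baselines: normalized to 1 except the entry intermediate KDHS,
# which is kept small and fast-turning (the reductase step is very fast and
# its toxic substrate never accumulates)
_CORE_BASELINES = {sp: 1.0 for sp in CORE_SPECIES}
_CORE_BASELINES["KDHS"] = 0.05

# baseline flux distribution (units: concentration/min);
# chosen as a positive circulation satisfying exact steady state at every node
_CORE_FLUXES = [
    # (id, enzyme, substrate or None, products, baseline rate)
    ("v_spt",    "X57", None,    [("KDHS", 1.0)], 1.00),
    ("v_red",    "X27", "KDHS",  [("DHS", 1.0)],  1.00),
    ("v_kin_d",  "X36", "DHS",   [("DHSP", 1.0)], 0.20),
    ("v_pase_d", "X41", "DHSP",  [("DHS", 1.0)],  0.15),
    ("v_lyase_d", "X50", "DHSP", [],              0.05),
    ("v_cs_d",   "X34", "DHS",   [("DHC", 1.0)],  0.50),
    ("v_cdase_d", "X29", "DHC",  [("DHS", 1.0)],  0.20),
    ("v_hyd_s",  "X54", "DHS",   [("PHS", 1.0)],  0.65),
    ("v_hyd_c",  "X54", "DHC",   [("PHC", 1.0)],  0.15),
    ("v_rem_d",  "X43", "DHC",   [],              0.10),
    ("v_ipcs_d", "X33", "DHC",   [("IPC", 1.0)],  0.15),
    ("v_kin_p",  "X36", "PHS",   [("PHSP", 1.0)], 0.40),
    ("v_pase_p", "X41", "PHSP",  [("PHS", 1.0)],  0.10),
    ("v_lyase_p", "X50", "PHSP", [],              0.30),
    ("v_cs_p",   "X34", "PHS",   [("PHC", 1.0)],  0.60),
    ("v_cdase_p", "X53", "PHC",  [("PHS", 1.0)],  0.25),
    ("v_ipcs_p", "X33", "PHC",   [("IPC", 1.0)],  0.15),
    ("v_rem_p",  "X43", "PHC",   [],              0.55),
    ("v_mipcs",  "X35", "IPC",   [("MIPC", 1.0)], 0.20),
    ("v_mip2cs", "X55", "MIPC",  [("MIP2C", 1.0)], 0.20),
    ("v_ipcase_d", "X51", "IPC",   [("DHC", 1.0)], 0.10),
    ("v_ipcase_p", "X51", "MIP2C", [("PHC", 1.0)], 0.20),
]

_SPECIES_NAMES = {
    "KDHS": "3-ketodihydrosphingosine",
    "DHS": "dihydrosphingosine",
    "DHSP": "dihydrosphingosine 1-phosphate",
    "DHC": "dihydroceramide",
    "PHS": "phytosphingosine",
    "PHSP": "phytosphingosine 1-phosphate",
    "PHC": "phytoceramide",
    "IPC": "inositol phosphorylceramide",
    "MIPC": "mannosylinositol phosphorylceramide",
    "MIP2C": "mannosyldiinositol phosphorylceramide",
}


def build_core_model(substrate_order: float = 1.0,
                     enzyme_order: float = 1.0) -> GMAModel:
    """Build the reduced core sphingolipid model.

    All species and enzyme baselines are normalized to 1; rate constants are
    the baseline flux values of a positive steady-state circulation, so the
    unstressed model sits at an exact steady state. Kinetic orders default to
    1 for both substrate and enzyme and are configurable.
    """
    registry = load_registry()
    variables = [
        VariableSpec(sp, _SPECIES_NAMES[sp], "dependent", _CORE_BASELINES[sp])
        for sp in CORE_SPECIES
    ] + [
        VariableSpec(e, registry[e].name if e in registry else e, "independent", 1.0)
        for e in CORE_ENZYMES
    ]
    fluxes = []
    for fid, enzyme, substrate, products, rate in _CORE_FLUXES:
        orders = {enzyme: enzyme_order}
        consumes: list[tuple[str, float]] = []
        gamma = rate
        if substrate is not None:
            orders[substrate] = substrate_order
            consumes = [(substrate, 1.0)]
            # rate constant chosen so the baseline flux equals `rate`
            gamma = rate / _CORE_BASELINES[substrate] ** substrate_order
        if rate <= 0:
            raise ValueError(f"flux {fid}: non-positive baseline rate")
        fluxes.append(FluxDef(fid, PowerLawTerm(gamma, orders),
                              consumes=tuple(consumes), produces=tuple(products),
                              catalyst=enzyme))
    return GMAModel(variables, fluxes, name="sphingolipid-core")


# ---------------------------------------------------------------------- #
# Full model import
# ---------------------------------------------------------------------- #

def load_full_model(sbml_archive: str | Path,
                    expected_counts: tuple[int, int] = (25, 41)) -> GMAModel:
    """Load the full yeast sphingolipid model from an SBML file or zip.

    The published full model has 25 dependent variables (ODEs) and 41
    independent variables; a count mismatch emits a structural warning but
    the model is still returned.
    """
    from .sbml import load_sbml_model

    path = Path(sbml_archive)
    if not path.exists():
        raise FileNotFoundError(
            f"SBML archive not found: {path}. The published full-model archive "
            "is a journal supplement and is not bundled with this package; "
            "download it separately and pass its path here."
        )
    if path.suffix.lower() == ".zip":
        with zipfile.ZipFile(path) as zf:
            names = [n for n in zf.namelist() if n.lower().endswith((".xml", ".sbml"))]
            if not names:
                raise ValueError(f"no SBML file found inside {path}")
            with zf.open(names[0]) as fh:
                model = load_sbml_model(io.TextIOWrapper(fh, encoding="utf-8"))
    else:
        model = load_sbml_model(path)
    n_dep, n_indep = model.n_dependent, model.n_independent
    if (n_dep, n_indep) != expected_counts:
        warnings.warn(
            f"structural mismatch: loaded model has {n_dep} dependent and "
            f"{n_indep} independent variables, expected {expected_counts}",
            UserWarning, stacklevel=2)
    return model
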