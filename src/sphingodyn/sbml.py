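"""Read-only SBML import for GMA power-law models.

Parses SBML Level 2/3 documents whose kinetic laws are products — or sums of
products — of power-law factors, and maps them onto :class:`~sphingodyn.gma.GMAModel`:

* non-boundary, non-constant species -> dependent variables;
* boundary/constant species and global parameters referenced inside kinetic
  laws -> independent variables (enzyme activities, clamped pools);
* local kinetic-law parameters and compartment sizes -> numeric constants
  folded into the rate constant;
* a kinetic law that is a sum of power-law terms is split into one flux per
  term; negatively signed terms (reversible rate laws) become fluxes with
  reactants and products swapped.

Anything outside this power-law subset raises :class:`SBMLConversionError`
naming the reaction. The parser deliberately covers only the GMA subset; it
is not a general SBML implementation.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from pathlib import Path
from typing import IO

from .gma import FluxDef, GMAModel, PowerLawTerm, VariableSpec

__all__ = ["SBMLConversionError", "load_sbml_model"]


class SBMLConversionError(ValueError):
    """A kinetic law could not be converted to power-law form."""


def _tag(el: ET.Element) -> str:
    return el.tag.rsplit("}", 1)[-1]


def _children(el: ET.Element) -> list[ET.Element]:
    return list(el)


def _find(el: ET.Element, name: str) -> ET.Element | None:
    for child in el.iter():
        if _tag(child) == name:
            return child
    return None


def _findall_direct(el: ET.Element, name: str) -> list[ET.Element]:
    return [c for c in el if _tag(c) == name]


def _parse_cn(el: ET.Element) -> float:
    kind = el.get("type", "real")
    parts = [el.text or ""]
    for child in el:
        if _tag(child) == "sep":
            parts.append(child.tail or "")
    if kind in ("real", "integer", "double"):
        return float(parts[0].strip())
    if kind == "e-notation":
        mantissa = float(parts[0].strip())
        exponent = float(parts[1].strip()) if len(parts) > 1 else 0.0
        return mantissa * 10.0 ** exponent
    if kind == "rational":
        num = float(parts[0].strip())
        den = float(parts[1].strip()) if len(parts) > 1 else 1.0
        return num / den
    raise SBMLConversionError(f"unsupported <cn> type {kind!r}")


#: term representation: (signed coefficient, {variable id: kinetic order})
_Term = tuple[float, dict[str, float]]


def _mul(a: _Term, b: _Term) -> _Term:
    orders = dict(a[1])
    for k, v in b[1].items():
        orders[k] = orders.get(k, 0.0) + v
    return a[0] * b[0], orders


def _eval_math(el: ET.Element, constants: dict[str, float], reaction: str) -> list[_Term]:
    """Evaluate a MathML expression into a sum of power-law terms."""
    tag = _tag(el)
    if tag == "math":
        kids = _children(el)
        if len(kids) != 1:
            raise SBMLConversionError(f"reaction {reaction!r}: malformed <math>")
        return _eval_math(kids[0], constants, reaction)
    if tag == "cn":
        return [(_parse_cn(el), {})]
    if tag == "ci":
        name = (el.text or "").strip()
        if name in constants:
            return [(constants[name], {})]
        return [(1.0, {name: 1.0})]
    if tag != "apply":
        raise SBMLConversionError(f"reaction {reaction!r}: unsupported MathML node <{tag}>")

    kids = _children(el)
    op, args = _tag(kids[0]), kids[1:]
    if op == "times":
        terms: list[_Term] = [(1.0, {})]
        for arg in args:
            sub = _eval_math(arg, constants, reaction)
            if len(terms) > 1 and len(sub) > 1:
                raise SBMLConversionError(
                    f"reaction {reaction!r}: product of sums is not power-law")
            terms = [_mul(t, s) for t in terms for s in sub]
        return terms
    if op == "divide":
        if len(args) != 2:
            raise SBMLConversionError(f"reaction {reaction!r}: malformed <divide>")
        num = _eval_math(args[0], constants, reaction)
        den = _eval_math(args[1], constants, reaction)
        if len(den) != 1:
            raise SBMLConversionError(
                f"reaction {reaction!r}: division by a sum is not power-law")
        dcoef, dorders = den[0]
        inv = (1.0 / dcoef, {k: -v for k, v in dorders.items()})
        return [_mul(t, inv) for t in num]
    if op == "power":
        if len(args) != 2:
            raise SBMLConversionError(f"reaction {reaction!r}: malformed <power>")
        base = _eval_math(args[0], constants, reaction)
        expo = _eval_math(args[1], constants, reaction)
        if len(base) != 1 or len(expo) != 1 or expo[0][1]:
            raise SBMLConversionError(
                f"reaction {reaction!r}: exponent must be a numeric constant")
        (bcoef, borders), k = base[0], expo[0][0]
        return [(bcoef ** k, {var: o * k for var, o in borders.items()})]
    if op == "plus":
        out: list[_Term] = []
        for arg in args:
            out.extend(_eval_math(arg, constants, reaction))
        return out
    if op == "minus":
        if len(args) == 1:
            return [(-c, o) for c, o in _eval_math(args[0], constants, reaction)]
        if len(args) == 2:
            left = _eval_math(args[0], constants, reaction)
            right = [(-c, o) for c, o in _eval_math(args[1], constants, reaction)]
            return left + right
        raise SBMLConversionError(f"reaction {reaction!r}: malformed <minus>")
    raise SBMLConversionError(
        f"reaction {reaction!r}: operator <{op}> is not power-law")


def load_sbml_model(source: str | Path | IO[str]) -> GMAModel:
    """Parse an SBML document into a :class:`GMAModel`.

    Raises :class:`SBMLConversionError` on any kinetic law that is not a
    (sum of) power-law product(s).
    """
    tree = ET.parse(source)  # noqa: S314 - trusted local model files
    root = tree.getroot()
    model_el = _find(root, "model")
    if model_el is None:
        raise SBMLConversionError("document contains no <model>")
    model_id = model_el.get("id", "sbml-model")

    compartments: dict[str, float] = {}
    species_info: dict[str, dict] = {}
    global_params: dict[str, float] = {}
    for lst in model_el:
        name = _tag(lst)
        if name == "listOfCompartments":
            for c in lst:
                compartments[c.get("id", "")] = float(c.get("size", c.get("volume", 1.0)))
        elif name == "listOfSpecies":
            for s in lst:
                sid = s.get("id") or s.get("name", "")
                init = s.get("initialConcentration", s.get("initialAmount"))
                species_info[sid] = {
                    "name": s.get("name", sid),
                    "baseline": float(init) if init is not None else 1.0,
                    "boundary": s.get("boundaryCondition", "false") == "true"
                                or s.get("constant", "false") == "true",
                }
        elif name == "listOfParameters":
            for p in lst:
                val = p.get("value")
                global_params[p.get("id", "")] = float(val) if val is not None else 1.0

    dependent = {sid: info for sid, info in species_info.items() if not info["boundary"]}

    # first pass over reactions: collect terms and which ids each law references
    reactions = []
    reactions_el = [lst for lst in model_el if _tag(lst) == "listOfReactions"]
    used_param_ids: set[str] = set()
    for lst in reactions_el:
        for rxn in lst:
            rid = rxn.get("id", "reaction")
            reactants = [(sr.get("species", ""), float(sr.get("stoichiometry", 1.0)))
                         for sub in _findall_direct(rxn, "listOfReactants") for sr in sub]
            products = [(sr.get("species", ""), float(sr.get("stoichiometry", 1.0)))
                        for sub in _findall_direct(rxn, "listOfProducts") for sr in sub]
            klaw = _find(rxn, "kineticLaw")
            if klaw is None:
                raise SBMLConversionError(f"reaction {rid!r} has no kinetic law")
            local: dict[str, float] = dict(compartments)
            for sub in klaw:
                if _tag(sub) in ("listOfParameters", "listOfLocalParameters"):
                    for p in sub:
                        val = p.get("value")
                        local[p.get("id", "")] = float(val) if val is not None else 1.0
            math_el = next((c for c in klaw if _tag(c) == "math"), None)
            if math_el is None:
                raise SBMLConversionError(f"reaction {rid!r}: kinetic law has no <math>")
            terms = _eval_math(math_el, local, rid)
            for _, orders in terms:
                for var in orders:
                    if var not in species_info:
                        used_param_ids.add(var)
            reactions.append((rid, reactants, products, terms))

    for var in sorted(used_param_ids):
        if var not in global_params:
            raise SBMLConversionError(
                f"kinetic laws reference {var!r}, which is neither a species nor "
                "a declared parameter")

    variables = [
        VariableSpec(sid, info["name"], "dependent" if sid in dependent else "independent",
                     info["baseline"])
        for sid, info in species_info.items()
    ] + [
        VariableSpec(pid, pid, "independent", global_params[pid])
        for pid in sorted(used_param_ids)
    ]

    fluxes: list[FluxDef] = []
    for rid, reactants, products, terms in reactions:
        dep_reactants = tuple((s, c) for s, c in reactants if s in dependent)
        dep_products = tuple((s, c) for s, c in products if s in dependent)
        multi = len(terms) > 1
        for i, (coef, orders) in enumerate(terms):
            if coef == 0:
                continue
            if coef < 0:
                consumes, produces, coef = dep_products, dep_reactants, -coef
            else:
                consumes, produces = dep_reactants, dep_products
            fid = f"{rid}__t{i}" if multi else rid
            fluxes.append(FluxDef(fid, PowerLawTerm(coef, orders),
                                  consumes=consumes, produces=produces))
    return GMAModel(variables, fluxes, name=model_id)
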