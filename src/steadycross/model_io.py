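"""Reading, writing, curating and environmentally configuring constraint-based models.

A :class:`MetabolicNetwork` is the single-organism container used throughout the
package: a stoichiometric matrix ``S`` (held sparsely as per-reaction stoichiometry
maps), flux bounds in mmol/gDW/h, one designated biomass reaction and one objective
reaction.  Exchange reactions follow the standard COBRA sign convention: negative
flux is uptake, positive flux is secretion.

Two on-disk formats are supported: SBML Level 3 with the FBC v2 package, and a JSON
dialect that mirrors the FBC content model field-for-field so that test fixtures
need no XML tooling.  Reading and writing are exact round-trips for both.
"""

from __future__ import annotations

import copy
import json
import logging
import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import libsbml
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicNetwork",
    "CurationEdit",
    "Medium",
    "FiberSpec",
    "ModelIOError",
    "ValidationError",
    "read_model",
    "write_model",
    "apply_curation",
    "invert_edits",
    "load_curation_file",
    "load_medium_file",
    "apply_medium",
    "normalize_fiber_polymer",
    "parse_formula",
    "carbon_count",
]


class ModelIOError(Exception):
    """Malformed or inconsistent model file."""


class ValidationError(Exception):
    """A network, edit or fiber specification violates an invariant."""


_ELEMENT_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str | None) -> dict[str, int]:
    """Parse a chemical formula string like ``C6H12O6`` into element counts.

    Metabolites without a formula are treated as element-free (and hence
    carbon-free); callers that care should log this.
    """
    if not formula:
        return {}
    counts: dict[str, int] = {}
    pos = 0
    for match in _ELEMENT_RE.finditer(formula):
        if match.start() != pos:
            raise ValidationError(f"unparseable formula {formula!r} at position {pos}")
        element, number = match.groups()
        counts[element] = counts.get(element, 0) + (int(number) if number else 1)
        pos = match.end()
    if pos != len(formula):
        raise ValidationError(f"unparseable formula {formula!r} at position {pos}")
    return counts


def carbon_count(formula: str | None) -> int:
    return parse_formula(formula).get("C", 0)


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    formula: str = ""
    compartment: str = "c"


@dataclass(frozen=True)
class Reaction:
    id: str
    name: str = ""
    stoichiometry: Mapping[str, float] = field(default_factory=dict)
    lower_bound: float = 0.0
    upper_bound: float = 1000.0
    is_exchange: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "stoichiometry", dict(self.stoichiometry))
        if self.lower_bound > self.upper_bound:
            raise ValidationError(
                f"reaction {self.id}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )


@dataclass
class MetabolicNetwork:
    """One organism's stoichiometry, bounds, biomass and exchange reactions."""

    model_id: str
    metabolites: list[Metabolite]
    reactions: list[Reaction]
    biomass_reaction_id: str
    objective_reaction_id: str

    def __post_init__(self) -> None:
        self.validate()

    # -- lookups -------------------------------------------------------------
    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def metabolite(self, met_id: str) -> Metabolite:
        for m in self.metabolites:
            if m.id == met_id:
                return m
        raise KeyError(met_id)

    def reaction(self, rxn_id: str) -> Reaction:
        for r in self.reactions:
            if r.id == rxn_id:
                return r
        raise KeyError(rxn_id)

    def exchanges(self) -> list[Reaction]:
        return [r for r in self.reactions if r.is_exchange]

    def exchange_metabolite(self, rxn: Reaction) -> str:
        (met_id,) = rxn.stoichiometry.keys()
        return met_id

    def exchange_for_metabolite(self, met_id: str) -> Reaction | None:
        for r in self.exchanges():
            if self.exchange_metabolite(r) == met_id:
                return r
        return None

    def copy(self) -> "MetabolicNetwork":
        return copy.deepcopy(self)

    # -- invariants ----------------------------------------------------------
    def validate(self) -> None:
        met_ids = [m.id for m in self.metabolites]
        met_set = set(met_ids)
        if len(met_set) != len(met_ids):
            raise ValidationError(f"{self.model_id}: duplicate metabolite ids")
        rxn_ids = [r.id for r in self.reactions]
        if len(set(rxn_ids)) != len(rxn_ids):
            raise ValidationError(f"{self.model_id}: duplicate reaction ids")
        for r in self.reactions:
            unknown = set(r.stoichiometry) - met_set
            if unknown:
                raise ValidationError(
                    f"reaction {r.id} references undeclared metabolites {sorted(unknown)}"
                )
            if r.is_exchange and len(r.stoichiometry) != 1:
                raise ValidationError(
                    f"exchange reaction {r.id} must touch exactly one metabolite, "
                    f"touches {len(r.stoichiometry)}"
                )
        if self.biomass_reaction_id not in rxn_ids:
            raise ModelIOError(
                f"{self.model_id}: biomass reaction {self.biomass_reaction_id!r} not found"
            )
        if self.objective_reaction_id not in rxn_ids:
            raise ModelIOError(
                f"{self.model_id}: objective reaction {self.objective_reaction_id!r} not found"
            )


# ---------------------------------------------------------------------------
# JSON dialect
# ---------------------------------------------------------------------------

def _network_to_dict(net: MetabolicNetwork) -> dict:
    return {
        "model_id": net.model_id,
        "metabolites": [
            {"id": m.id, "name": m.name, "formula": m.formula, "compartment": m.compartment}
            for m in sorted(net.metabolites, key=lambda m: m.id)
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "stoichiometry": {k: r.stoichiometry[k] for k in sorted(r.stoichiometry)},
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "is_exchange": r.is_exchange,
            }
            for r in sorted(net.reactions, key=lambda r: r.id)
        ],
        "biomass_reaction_id": net.biomass_reaction_id,
        "objective_reaction_id": net.objective_reaction_id,
    }


def _network_from_dict(data: Mapping) -> MetabolicNetwork:
    try:
        mets = [Metabolite(**m) for m in data["metabolites"]]
        rxns = [Reaction(**r) for r in data["reactions"]]
        return MetabolicNetwork(
            model_id=data["model_id"],
            metabolites=mets,
            reactions=rxns,
            biomass_reaction_id=data["biomass_reaction_id"],
            objective_reaction_id=data["objective_reaction_id"],
        )
    except (KeyError, TypeError) as exc:
        raise ModelIOError(f"malformed JSON model: {exc}") from exc


# ---------------------------------------------------------------------------
# SBML Level 3 + FBC
# ---------------------------------------------------------------------------

_INF_BOUND = 1e6  # SBML has no literal infinity for parameters; this sentinel maps to inf


def _write_sbml(net: MetabolicNetwork, path: Path) -> None:
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    model = doc.createModel()
    model.setId(net.model_id)
    mplug = model.getPlugin("fbc")
    mplug.setStrict(True)

    compartments = sorted({m.compartment for m in net.metabolites})
    for comp in compartments:
        c = model.createCompartment()
        c.setId(comp)
        c.setConstant(True)

    for m in sorted(net.metabolites, key=lambda m: m.id):
        s = model.createSpecies()
        s.setId(m.id)
        s.setName(m.name)
        s.setCompartment(m.compartment)
        s.setConstant(False)
        s.setHasOnlySubstanceUnits(False)
        s.setBoundaryCondition(False)
        if m.formula:
            s.getPlugin("fbc").setChemicalFormula(m.formula)

    bounds_seen: dict[float, str] = {}

    def bound_param(value: float) -> str:
        if value not in bounds_seen:
            pid = f"bound_{len(bounds_seen)}"
            p = model.createParameter()
            p.setId(pid)
            p.setValue(_INF_BOUND if value == math.inf else (-_INF_BOUND if value == -math.inf else value))
            p.setConstant(True)
            bounds_seen[value] = pid
        return bounds_seen[value]

    for r in sorted(net.reactions, key=lambda r: r.id):
        rxn = model.createReaction()
        rxn.setId(r.id)
        rxn.setName(r.name)
        rxn.setFast(False)
        rxn.setReversible(r.lower_bound < 0)
        for met_id, coeff in sorted(r.stoichiometry.items()):
            if coeff < 0:
                ref = rxn.createReactant()
                ref.setStoichiometry(-coeff)
            else:
                ref = rxn.createProduct()
                ref.setStoichiometry(coeff)
            ref.setSpecies(met_id)
            ref.setConstant(True)
        rplug = rxn.getPlugin("fbc")
        rplug.setLowerFluxBound(bound_param(r.lower_bound))
        rplug.setUpperFluxBound(bound_param(r.upper_bound))
        if r.is_exchange:
            rxn.setSBOTerm("SBO:0000627")
        if r.id == net.biomass_reaction_id:
            rxn.setSBOTerm("SBO:0000629")

    objective = mplug.createObjective()
    objective.setId("obj")
    objective.setType("maximize")
    mplug.setActiveObjectiveId("obj")
    fobj = objective.createFluxObjective()
    fobj.setReaction(net.objective_reaction_id)
    fobj.setCoefficient(1.0)

    writer = libsbml.SBMLWriter()
    if not writer.writeSBMLToFile(doc, str(path)):
        raise ModelIOError(f"could not write SBML to {path}")


def _read_sbml(path: Path) -> MetabolicNetwork:
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise ModelIOError(f"SBML parse error in {path}: {err.getMessage().strip()}")
    model = doc.getModel()
    if model is None:
        raise ModelIOError(f"{path}: no <model> element")
    mplug = model.getPlugin("fbc")
    if mplug is None:
        raise ModelIOError(f"{path}: FBC package information missing")

    mets = []
    for i in range(model.getNumSpecies()):
        s = model.getSpecies(i)
        splug = s.getPlugin("fbc")
        formula = splug.getChemicalFormula() if splug and splug.isSetChemicalFormula() else ""
        mets.append(
            Metabolite(id=s.getId(), name=s.getName(), formula=formula,
                       compartment=s.getCompartment())
        )

    def bound_value(pid: str, rxn_id: str, which: str) -> float:
        p = model.getParameter(pid)
        if p is None:
            raise ModelIOError(f"reaction {rxn_id}: {which} flux bound parameter {pid!r} missing")
        v = p.getValue()
        if v >= _INF_BOUND:
            return math.inf
        if v <= -_INF_BOUND:
            return -math.inf
        return v

    rxns = []
    biomass_id = None
    for i in range(model.getNumReactions()):
        r = model.getReaction(i)
        stoich: dict[str, float] = {}
        for j in range(r.getNumReactants()):
            ref = r.getReactant(j)
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) - ref.getStoichiometry()
        for j in range(r.getNumProducts()):
            ref = r.getProduct(j)
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) + ref.getStoichiometry()
        rplug = r.getPlugin("fbc")
        if rplug is None or not rplug.isSetLowerFluxBound() or not rplug.isSetUpperFluxBound():
            raise ModelIOError(f"reaction {r.getId()}: missing FBC flux bounds")
        lb = bound_value(rplug.getLowerFluxBound(), r.getId(), "lower")
        ub = bound_value(rplug.getUpperFluxBound(), r.getId(), "upper")
        sbo = r.getSBOTermID()
        if sbo == "SBO:0000629":
            biomass_id = r.getId()
        rxns.append(
            Reaction(id=r.getId(), name=r.getName(), stoichiometry=stoich,
                     lower_bound=lb, upper_bound=ub, is_exchange=sbo == "SBO:0000627")
        )

    objective = mplug.getActiveObjective()
    if objective is None or objective.getNumFluxObjectives() == 0:
        raise ModelIOError(f"{path}: no active FBC objective")
    objective_id = objective.getFluxObjective(0).getReaction()
    if biomass_id is None:
        raise ModelIOError(f"{path}: no reaction annotated as biomass (SBO:0000629)")
    return MetabolicNetwork(
        model_id=model.getId(), metabolites=mets, reactions=rxns,
        biomass_reaction_id=biomass_id, objective_reaction_id=objective_id,
    )


# ---------------------------------------------------------------------------
# Public read/write
# ---------------------------------------------------------------------------

def read_model(path: str | Path, format: str | None = None) -> MetabolicNetwork:
    """Read a model from SBML-FBC (``sbml_fbc``) or the JSON dialect (``json``).

    The format is inferred from the suffix when not given.  The returned network
    satisfies all container invariants; a malformed file raises
    :class:`ModelIOError` naming the offending element.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or ("sbml_fbc" if path.suffix.lower() in {".xml", ".sbml"} else "json")
    if fmt == "json":
        try:
            data = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise ModelIOError(f"{path}: invalid JSON ({exc})") from exc
        return _network_from_dict(data)
    if fmt == "sbml_fbc":
        return _read_sbml(path)
    raise ValueError(f"unknown format {fmt!r}")


def write_model(net: MetabolicNetwork, path: str | Path, format: str | None = None) -> None:
    """Write a model; canonical ordering makes JSON output byte-reproducible."""
    path = Path(path)
    fmt = format or ("sbml_fbc" if path.suffix.lower() in {".xml", ".sbml"} else "json")
    if fmt == "json":
        path.write_text(json.dumps(_network_to_dict(net), indent=2, sort_keys=True) + "\n")
    elif fmt == "sbml_fbc":
        _write_sbml(net, path)
    else:
        raise ValueError(f"unknown format {fmt!r}")


# ---------------------------------------------------------------------------
# Curation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CurationEdit:
    """One manual refinement step: add/remove a reaction, set bounds or a formula."""

    action: str  # add_reaction | remove_reaction | set_bounds | set_formula
    payload: Mapping
    provenance_note: str = ""

    _ACTIONS = ("add_reaction", "remove_reaction", "set_bounds", "set_formula")

    def __post_init__(self) -> None:
        if self.action not in self._ACTIONS:
            raise ValidationError(f"unknown curation action {self.action!r}")


def _apply_one(net: MetabolicNetwork, edit: CurationEdit) -> CurationEdit:
    """Apply in place; return the inverse edit."""
    p = dict(edit.payload)
    if edit.action == "add_reaction":
        rxn = Reaction(
            id=p["id"], name=p.get("name", ""), stoichiometry=p.get("stoichiometry", {}),
            lower_bound=p.get("lower_bound", 0.0), upper_bound=p.get("upper_bound", 1000.0),
            is_exchange=p.get("is_exchange", False),
        )
        if rxn.id in net.reaction_ids:
            raise ValidationError(f"reaction {rxn.id} already present")
        net.reactions.append(rxn)
        net.validate()
        return CurationEdit("remove_reaction", {"id": rxn.id}, f"revert: {edit.provenance_note}")
    if edit.action == "remove_reaction":
        rxn = net.reaction(p["id"])
        if rxn.id in (net.biomass_reaction_id, net.objective_reaction_id):
            raise ValidationError(f"cannot remove designated reaction {rxn.id}")
        net.reactions.remove(rxn)
        inverse_payload = {
            "id": rxn.id, "name": rxn.name, "stoichiometry": dict(rxn.stoichiometry),
            "lower_bound": rxn.lower_bound, "upper_bound": rxn.upper_bound,
            "is_exchange": rxn.is_exchange,
        }
        return CurationEdit("add_reaction", inverse_payload, f"revert: {edit.provenance_note}")
    if edit.action == "set_bounds":
        rxn = net.reaction(p["id"])
        inverse = CurationEdit(
            "set_bounds",
            {"id": rxn.id, "lower_bound": rxn.lower_bound, "upper_bound": rxn.upper_bound},
            f"revert: {edit.provenance_note}",
        )
        new = replace(rxn, lower_bound=p.get("lower_bound", rxn.lower_bound),
                      upper_bound=p.get("upper_bound", rxn.upper_bound))
        net.reactions[net.reactions.index(rxn)] = new
        return inverse
    # set_formula
    met = net.metabolite(p["id"])
    inverse = CurationEdit("set_formula", {"id": met.id, "formula": met.formula},
                           f"revert: {edit.provenance_note}")
    net.metabolites[net.metabolites.index(met)] = replace(met, formula=p["formula"])
    return inverse


def apply_curation(
    net: MetabolicNetwork, edits: Sequence[CurationEdit]
) -> tuple[MetabolicNetwork, list[CurationEdit]]:
    """Apply edits in order, atomically (all or none).

    Returns the edited network and the audit log of applied edits.  An edit
    that references an unknown reaction or metabolite raises
    :class:`ValidationError` carrying the index of the failing edit, and the
    input network is left untouched.
    """
    out = net.copy()
    applied: list[CurationEdit] = []
    for i, edit in enumerate(edits):
        try:
            _apply_one(out, edit)
        except (KeyError, ValidationError, ModelIOError) as exc:
            raise ValidationError(f"curation edit {i} ({edit.action}) failed: {exc}") from exc
        applied.append(edit)
    return out, applied


def invert_edits(net: MetabolicNetwork, edits: Sequence[CurationEdit]) -> list[CurationEdit]:
    """Return the edit list that undoes ``edits`` (applied to ``net`` in order)."""
    out = net.copy()
    inverses = [_apply_one(out, e) for e in edits]
    return list(reversed(inverses))


def load_curation_file(path: str | Path) -> list[CurationEdit]:
    """Load curation edits from YAML, one document per edit, applied in file order."""
    docs = list(yaml.safe_load_all(Path(path).read_text()))
    edits = []
    for doc in docs:
        if doc is None:
            continue
        edits.append(CurationEdit(action=doc["action"], payload=doc.get("payload", {}),
                                  provenance_note=doc.get("provenance_note", "")))
    return edits


# ---------------------------------------------------------------------------
# Medium
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Medium:
    """In-silico growth medium at the exchange boundary.

    ``uptake_bounds`` are positive magnitudes; the loader applies them as
    negative lower bounds on the exchange reactions.  ``excess_value`` is the
    uptake magnitude for carbon-free nutrients (minerals, ions, vitamins) that
    are supplied "in excess" and never limit growth.
    """

    uptake_bounds: Mapping[str, float]
    carbon_source_id: str
    excess_value: float = 1000.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "uptake_bounds", dict(self.uptake_bounds))
        if self.carbon_source_id not in self.uptake_bounds:
            raise ValidationError(
                f"carbon source {self.carbon_source_id!r} not in uptake_bounds"
            )
        bad = {k: v for k, v in self.uptake_bounds.items() if v < 0}
        if bad:
            raise ValidationError(f"negative uptake magnitudes: {bad}")

    def with_carbon_source(self, exchange_id: str, magnitude: float) -> "Medium":
        bounds = {k: v for k, v in self.uptake_bounds.items() if k != self.carbon_source_id}
        bounds[exchange_id] = magnitude
        return Medium(bounds, exchange_id, self.excess_value)


def load_medium_file(path: str | Path) -> Medium:
    data = yaml.safe_load(Path(path).read_text())
    return Medium(
        uptake_bounds=data["uptake_bounds"],
        carbon_source_id=data["carbon_source_id"],
        excess_value=data.get("excess_value", 1000.0),
    )


def apply_medium(net: MetabolicNetwork, medium: Medium) -> MetabolicNetwork:
    """Constrain exchange uptakes to the medium.

    Exchanges listed in the medium get uptake bound ``-magnitude``.  Every
    other exchange whose metabolite contains carbon is closed to uptake
    (lower bound 0), so the medium's carbon source is the only carbon supply.
    Carbon-free unlisted exchanges are opened at ``excess_value``.  Secretion
    (upper) bounds are untouched.
    """
    exchange_ids = {r.id for r in net.exchanges()}
    unknown = set(medium.uptake_bounds) - exchange_ids
    if unknown:
        raise ValidationError(
            f"medium references exchanges absent from {net.model_id}: {sorted(unknown)}"
        )
    out = net.copy()
    for idx, r in enumerate(out.reactions):
        if not r.is_exchange:
            continue
        if r.id in medium.uptake_bounds:
            lb = -abs(medium.uptake_bounds[r.id])
        else:
            met = out.metabolite(out.exchange_metabolite(r))
            if not met.formula:
                logger.info("exchange %s: metabolite %s has no formula, treated as carbon-free",
                            r.id, met.id)
            lb = 0.0 if carbon_count(met.formula) > 0 else -abs(medium.excess_value)
        out.reactions[idx] = replace(r, lower_bound=lb)
    return out


# ---------------------------------------------------------------------------
# Fiber polymer normalization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FiberSpec:
    """A dietary fiber as an average-length homopolymer of one monomer.

    Real fibers (inulin: β-2,1 fructan, DP ≈ 10–30; xylan: xylose backbone,
    DP ≈ 10–100) have no fixed chain length; the in-silico fiber is a single
    species whose carbon content is ``average_dp × carbon_per_monomer``, so
    that uptake fluxes of different fibers are comparable on a per-carbon
    basis.
    """

    fiber_id: str
    monomer_id: str
    average_dp: int
    carbon_per_monomer: int

    def __post_init__(self) -> None:
        if self.average_dp <= 0 or self.carbon_per_monomer <= 0:
            raise ValidationError("average_dp and carbon_per_monomer must be positive")

    @property
    def carbon_per_unit(self) -> int:
        return self.average_dp * self.carbon_per_monomer


def normalize_fiber_polymer(net: MetabolicNetwork, fiber: FiberSpec,
                            degradation_id: str | None = None) -> MetabolicNetwork:
    """Normalize the fiber species so one uptake unit delivers ``average_dp`` monomers.

    Sets the fiber metabolite's formula to the polymer carbon content, locates
    (or creates) the degradation reaction ``fiber → average_dp · monomer`` and
    verifies its carbon balance exactly, in integer arithmetic.
    """
    out = net.copy()
    try:
        monomer = out.metabolite(fiber.monomer_id)
    except KeyError:
        raise ValidationError(f"monomer {fiber.monomer_id!r} not in network") from None
    monomer_c = carbon_count(monomer.formula)
    if monomer_c != fiber.carbon_per_monomer:
        raise ValidationError(
            f"monomer {monomer.id} formula {monomer.formula!r} has {monomer_c} C, "
            f"spec says {fiber.carbon_per_monomer}"
        )
    try:
        fib_met = out.metabolite(fiber.fiber_id)
        # polymer formula: dp condensations of the monomer minus (dp-1) waters
        counts = {el: n * fiber.average_dp for el, n in parse_formula(monomer.formula).items()}
        for el, n in (("H", 2), ("O", 1)):
            if el in counts:
                counts[el] -= n * (fiber.average_dp - 1)
        formula = "".join(f"{el}{counts[el]}" for el in sorted(counts))
        out.metabolites[out.metabolites.index(fib_met)] = replace(fib_met, formula=formula)
    except KeyError:
        raise ValidationError(f"fiber metabolite {fiber.fiber_id!r} not in network") from None

    degradation = None
    if degradation_id is not None:
        degradation = out.reaction(degradation_id)
    else:
        for r in out.reactions:
            if (r.stoichiometry.get(fiber.fiber_id, 0) < 0
                    and r.stoichiometry.get(fiber.monomer_id, 0) > 0):
                degradation = r
                break
    if degradation is None:
        degradation = Reaction(
            id=f"HYD_{fiber.fiber_id}", name=f"{fiber.fiber_id} hydrolysis",
            stoichiometry={fiber.fiber_id: -1.0, fiber.monomer_id: float(fiber.average_dp)},
            lower_bound=0.0, upper_bound=math.inf,
        )
        out.reactions.append(degradation)
    else:
        idx = out.reactions.index(degradation)
        stoich = dict(degradation.stoichiometry)
        stoich[fiber.fiber_id] = -1.0
        stoich[fiber.monomer_id] = float(fiber.average_dp)
        degradation = replace(degradation, stoichiometry=stoich)
        out.reactions[idx] = degradation

    balance = 0
    for met_id, coeff in degradation.stoichiometry.items():
        c = fiber.carbon_per_unit if met_id == fiber.fiber_id else carbon_count(
            out.metabolite(met_id).formula)
        balance += int(round(coeff)) * c
    if balance != 0:
        raise ValidationError(
            f"degradation reaction {degradation.id} is carbon-imbalanced by {balance} C"
        )
    out.validate()
    return out
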