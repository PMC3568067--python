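"""Metabolic network data model, stoichiometric matrix and structural diagnostics.

A :class:`MetabolicNetwork` is the in-memory container shared by every other
module: a list of metabolites (each assigned to a compartment), a list of
reactions with signed stoichiometric coefficients and flux bounds, and
free-form annotations.  Flux units throughout the package are
mmol·min⁻¹·(l cell)⁻¹.

Networks can be read from SBML (Level 2/3, with FBC bounds when present) or
round-tripped losslessly through a native JSON schema.  Structural
diagnostics — blocked reactions and dead-end metabolites — follow the usual
constraint-based-modelling definitions: a blocked reaction cannot carry
nonzero flux in any steady-state solution under the allowed exchanges, and a
dead-end metabolite is only ever produced or only ever consumed.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from ._lp import LPResult, solve_lp

logger = logging.getLogger(__name__)

#: Default cap for otherwise unconstrained fluxes, mmol·min⁻¹·(l cell)⁻¹.
DEFAULT_BOUND = 1000.0

#: Canonical sub-cellular compartments (user models may add their own).
STANDARD_COMPARTMENTS = ("ext", "cyto", "mito", "lyso", "peroxy", "micro")


class NetworkStructureError(ValueError):
    """Raised when a network violates its structural invariants."""


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "cyto"
    formula: str | None = None


@dataclass
class Reaction:
    """A reaction with signed stoichiometry and flux bounds.

    ``stoichiometry`` maps metabolite id to signed coefficient (negative =
    consumed, positive = produced).  Exchange reactions are single-metabolite
    columns; their direction semantics are carried by ``allowed_uptake`` /
    ``allowed_secretion`` so the sign convention is never ambiguous.
    """

    id: str
    stoichiometry: dict[str, float]
    reversible: bool = False
    lower_bound: float = 0.0
    upper_bound: float = DEFAULT_BOUND
    is_exchange: bool = False
    is_transport: bool = False
    allowed_uptake: bool = True
    allowed_secretion: bool = True

    def validate(self) -> None:
        if not self.stoichiometry:
            raise NetworkStructureError(f"reaction {self.id!r} has empty stoichiometry")
        if self.lower_bound > self.upper_bound:
            raise NetworkStructureError(
                f"reaction {self.id!r}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )
        if not self.reversible and self.lower_bound < 0:
            raise NetworkStructureError(
                f"reaction {self.id!r} is irreversible but has negative lower bound"
            )


@dataclass
class MetabolicNetwork:
    metabolites: list[Metabolite] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    compartments: list[str] = field(default_factory=lambda: list(STANDARD_COMPARTMENTS))
    annotations: dict = field(default_factory=dict)

    # -- lookups ---------------------------------------------------------

    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(f"no reaction {rid!r} in network")

    def metabolite(self, mid: str) -> Metabolite:
        for m in self.metabolites:
            if m.id == mid:
                return m
        raise KeyError(f"no metabolite {mid!r} in network")

    def validate(self) -> None:
        mids = self.metabolite_ids()
        if len(set(mids)) != len(mids):
            raise NetworkStructureError("duplicate metabolite ids")
        rids = self.reaction_ids()
        if len(set(rids)) != len(rids):
            raise NetworkStructureError("duplicate reaction ids")
        known = set(mids)
        comps = set(self.compartments)
        for m in self.metabolites:
            if m.compartment not in comps:
                raise NetworkStructureError(
                    f"metabolite {m.id!r} assigned to undeclared compartment "
                    f"{m.compartment!r}"
                )
        for r in self.reactions:
            r.validate()
            missing = set(r.stoichiometry) - known
            if missing:
                raise NetworkStructureError(
                    f"reaction {r.id!r} references unknown metabolites: "
                    f"{sorted(missing)}"
                )

    def copy(self) -> "MetabolicNetwork":
        return read_native_obj(write_native_obj(self))

    def summary(self) -> dict[str, int]:
        """Counts of reactions, transporters and metabolites."""
        return {
            "compartments": len(self.compartments),
            "reactions": len(self.reactions),
            "transporters": sum(r.is_transport for r in self.reactions),
            "metabolites": len(self.metabolites),
        }


# -- stoichiometric matrix ----------------------------------------------


def build_stoich_matrix(network: MetabolicNetwork) -> np.ndarray:
    """Dense stoichiometric matrix N: rows = metabolites, columns = reactions.

    Entry (i, j) is the signed coefficient of metabolite i in reaction j;
    column order matches reaction declaration order.
    """
    network.validate()
    index = {m.id: i for i, m in enumerate(network.metabolites)}
    N = np.zeros((len(network.metabolites), len(network.reactions)))
    for j, rxn in enumerate(network.reactions):
        for mid, coef in rxn.stoichiometry.items():
            N[index[mid], j] = coef
    return N


def summary_table(network: MetabolicNetwork) -> str:
    """TSV one-row overview (compartments, reactions, transporters, metabolites)."""
    s = network.summary()
    head = "\t".join(s)
    vals = "\t".join(str(v) for v in s.values())
    return f"{head}\n{vals}\n"


# -- native JSON I/O -----------------------------------------------------

_SCHEMA_VERSION = 1
_MET_KEYS = {"id", "name", "compartment", "formula"}
_RXN_KEYS = {
    "id",
    "stoichiometry",
    "reversible",
    "lower_bound",
    "upper_bound",
    "is_exchange",
    "is_transport",
    "allowed_uptake",
    "allowed_secretion",
}


def write_native_obj(network: MetabolicNetwork) -> dict:
    return {
        "schema_version": _SCHEMA_VERSION,
        "compartments": list(network.compartments),
        "metabolites": [asdict(m) for m in network.metabolites],
        "reactions": [asdict(r) for r in network.reactions],
        "annotations": dict(network.annotations),
    }


def write_native(network: MetabolicNetwork, path: str | Path) -> None:
    """Serialize to the native JSON schema (stable key order, diffable)."""
    obj = write_native_obj(network)
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n")


def _take(d: dict, keys: set, where: str, extras: dict) -> dict:
    unknown = {k: v for k, v in d.items() if k not in keys}
    if unknown:
        extras.setdefault(where, []).append(unknown)
    return {k: v for k, v in d.items() if k in keys}


def read_native_obj(obj: Mapping) -> MetabolicNetwork:
    try:
        extras: dict = {}
        mets = [
            Metabolite(**_take(dict(m), _MET_KEYS, f"metabolites[{i}]", extras))
            for i, m in enumerate(obj["metabolites"])
        ]
        rxns = [
            Reaction(**_take(dict(r), _RXN_KEYS, f"reactions[{i}]", extras))
            for i, r in enumerate(obj["reactions"])
        ]
        net = MetabolicNetwork(
            metabolites=mets,
            reactions=rxns,
            compartments=list(obj.get("compartments", STANDARD_COMPARTMENTS)),
            annotations=dict(obj.get("annotations", {})),
        )
        top_unknown = {
            k: v
            for k, v in obj.items()
            if k
            not in {
                "schema_version",
                "compartments",
                "metabolites",
                "reactions",
                "annotations",
            }
        }
        if top_unknown:
            net.annotations.setdefault("_extra", {}).update(top_unknown)
        if extras:
            net.annotations.setdefault("_extra", {}).update(extras)
    except (KeyError, TypeError) as exc:
        raise NetworkStructureError(f"invalid native model object: {exc}") from exc
    net.validate()
    return net


def read_native(path: str | Path) -> MetabolicNetwork:
    try:
        obj = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise NetworkStructureError(f"{path}: not valid JSON ({exc})") from exc
    return read_native_obj(obj)


# -- SBML ----------------------------------------------------------------


def read_sbml(path: str | Path) -> MetabolicNetwork:
    """Read an SBML Level 2/3 model.

    Species become metabolites (``boundaryCondition`` species are dropped
    from the mass-balance rows), reactions keep their stoichiometric
    coefficients, and bounds come from FBC attributes when present, else
    ±``DEFAULT_BOUND`` for reversible reactions and [0, ``DEFAULT_BOUND``]
    otherwise.  Kinetic laws and unrecognized constructs are logged and
    ignored.
    """
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        msgs = [
            doc.getError(i).getMessage()
            for i in range(doc.getNumErrors())
            if doc.getError(i).getSeverity() >= libsbml.LIBSBML_SEV_ERROR
        ]
        raise NetworkStructureError(f"SBML parse error in {path}: {msgs[:3]}")
    model = doc.getModel()
    if model is None:
        raise NetworkStructureError(f"{path}: no SBML model element")

    compartments = [model.getCompartment(i).getId() for i in range(model.getNumCompartments())]
    boundary: set[str] = set()
    mets: list[Metabolite] = []
    for i in range(model.getNumSpecies()):
        sp = model.getSpecies(i)
        if sp.getBoundaryCondition():
            boundary.add(sp.getId())
            continue
        mets.append(
            Metabolite(
                id=sp.getId(),
                name=sp.getName() or sp.getId(),
                compartment=sp.getCompartment() or (compartments[0] if compartments else "cyto"),
            )
        )

    fbc = model.getPlugin("fbc")

    def _fbc_bounds(rxn) -> tuple[float, float] | None:
        rp = rxn.getPlugin("fbc")
        if rp is None or fbc is None:
            return None
        lb_id, ub_id = rp.getLowerFluxBound(), rp.getUpperFluxBound()
        if not lb_id or not ub_id:
            return None
        lo = model.getParameter(lb_id)
        hi = model.getParameter(ub_id)
        if lo is None or hi is None:
            return None
        return lo.getValue(), hi.getValue()

    rxns: list[Reaction] = []
    for i in range(model.getNumReactions()):
        rx = model.getReaction(i)
        stoich: dict[str, float] = {}
        for k in range(rx.getNumReactants()):
            ref = rx.getReactant(k)
            if ref.getSpecies() in boundary:
                continue
            if math.isnan(ref.getStoichiometry()):
                raise NetworkStructureError(
                    f"reaction {rx.getId()!r}: missing stoichiometry"
                )
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) - ref.getStoichiometry()
        for k in range(rx.getNumProducts()):
            ref = rx.getProduct(k)
            if ref.getSpecies() in boundary:
                continue
            if math.isnan(ref.getStoichiometry()):
                raise NetworkStructureError(
                    f"reaction {rx.getId()!r}: missing stoichiometry"
                )
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) + ref.getStoichiometry()
        if not stoich:
            logger.warning(
                "reaction %s touches only boundary species; kept as empty exchange stub",
                rx.getId(),
            )
            continue
        rev = rx.getReversible()
        bounds = _fbc_bounds(rx)
        if bounds is None:
            lb, ub = (-DEFAULT_BOUND, DEFAULT_BOUND) if rev else (0.0, DEFAULT_BOUND)
        else:
            lb, ub = bounds
            # reversibility attribute wins over bound signs on conflict
            if not rev and lb < 0:
                logger.warning(
                    "reaction %s: irreversible but FBC lower bound %g < 0; clamping to 0",
                    rx.getId(),
                    lb,
                )
                lb = 0.0
        is_exchange = len(stoich) == 1
        rxns.append(
            Reaction(
                id=rx.getId(),
                stoichiometry=stoich,
                reversible=rev,
                lower_bound=lb,
                upper_bound=ub,
                is_exchange=is_exchange,
            )
        )

    net = MetabolicNetwork(
        metabolites=mets,
        reactions=rxns,
        compartments=compartments or list(STANDARD_COMPARTMENTS),
        annotations={"source": str(path), "sbml_level": model.getLevel()},
    )
    net.validate()
    return net


# -- structural diagnostics ---------------------------------------------

_BLOCKED_TOL = 1e-6


def _fva_bounds(
    network: MetabolicNetwork, open_exchanges: set[str]
) -> tuple[np.ndarray, list[tuple[float, float]]]:
    N = build_stoich_matrix(network)
    bounds = []
    for r in network.reactions:
        if r.is_exchange and r.id not in open_exchanges:
            bounds.append((0.0, 0.0))
        else:
            bounds.append((r.lower_bound, r.upper_bound))
    return N, bounds


def find_blocked_reactions(
    network: MetabolicNetwork, open_exchanges: Iterable[str] | None = None
) -> set[str]:
    """Reactions that can carry no nonzero steady-state flux.

    ``open_exchanges`` restricts which exchange reactions may be active;
    ``None`` leaves every exchange open.  A reaction is blocked when both the
    maximum and the minimum of its flux over the steady-state polytope are
    zero within tolerance.  If the base problem is infeasible every reaction
    is reported blocked, with a warning.
    """
    if open_exchanges is None:
        open_exchanges = {r.id for r in network.reactions if r.is_exchange}
    open_exchanges = set(open_exchanges)
    unknown = open_exchanges - set(network.reaction_ids())
    if unknown:
        raise KeyError(f"open_exchanges not in network: {sorted(unknown)}")
    N, bounds = _fva_bounds(network, open_exchanges)
    n = len(network.reactions)
    b = np.zeros(N.shape[0])
    feas = solve_lp(np.zeros(n), A_eq=N, b_eq=b, bounds=bounds)
    if feas.status == "infeasible":
        logger.warning("blocked-reaction base problem infeasible; reporting all blocked")
        return set(network.reaction_ids())
    blocked = set()
    for j, rxn in enumerate(network.reactions):
        c = np.zeros(n)
        c[j] = 1.0
        lo = solve_lp(c, A_eq=N, b_eq=b, bounds=bounds)
        hi = solve_lp(-c, A_eq=N, b_eq=b, bounds=bounds)
        vmin = lo.x[j] if lo.status == "optimal" else 0.0
        vmax = hi.x[j] if hi.status == "optimal" else 0.0
        if abs(vmin) <= _BLOCKED_TOL and abs(vmax) <= _BLOCKED_TOL:
            blocked.add(rxn.id)
    return blocked


def find_deadend_metabolites(network: MetabolicNetwork) -> set[str]:
    """Metabolites that are only produced or only consumed.

    Reversible reactions count as both producers and consumers of every
    metabolite they touch.  Metabolites appearing in no reaction are also
    reported.
    """
    produced: set[str] = set()
    consumed: set[str] = set()
    for r in network.reactions:
        for mid, coef in r.stoichiometry.items():
            if r.reversible:
                produced.add(mid)
                consumed.add(mid)
            elif coef > 0:
                produced.add(mid)
            elif coef < 0:
                consumed.add(mid)
    return {m.id for m in network.metabolites if not (m.id in produced and m.id in consumed)}
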