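"""Generator for a reduced cardiomyocyte core network.

The generator emits a small, fully closed network whose lumped stoichiometry
reproduces the substrate-level energetics of cardiac metabolism: per
substrate, an uptake exchange and a single lumped oxidation reaction

    substrate + o2_stoich · O2 + atp_yield · ADP  →  atp_yield · ATP + byproduct

plus an ATP-hydrolysis drain representing contractile and maintenance energy
expenditure.  Optional extensions add a glycogen store (ATP-costly synthesis,
capped degradation), lumped phospholipid-target reactions (ceramide,
cardiolipin, phosphatidylcholine, phosphatidylethanolamine, sphingomyelin)
whose acyl recipes require the essential fatty acids alpha-linoleate and
docosahexaenoate, and a lumped NADPH branch from glucose-6-phosphate.

ATP yields per mole of fully oxidized substrate follow the standard
per-mole totals (glucose 36, lactate 17, acetoacetate 22, acetate 9,
palmitate 120, stearate 136, oleate 134, alpha-linoleate 132, EPA 142,
DHA 156); oxygen coefficients are the combustion stoichiometry of each
molecular formula.  The glucose value uses the glycerophosphate-shuttle
convention (36 ATP), which makes a 21.6 ATP demand met by glucose alone
cost exactly 0.60 substrate and 3.60 oxygen.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field, replace
from pathlib import Path

from .netmodel import DEFAULT_BOUND, MetabolicNetwork, Metabolite, Reaction


class CoreConfigError(ValueError):
    """Raised when core-network options reference absent substrates."""


@dataclass(frozen=True)
class SubstrateSpec:
    """Energetic description of one oxidizable substrate.

    atp_yield: mol ATP per mol substrate fully oxidized.
    o2_stoich: mol O2 per mol substrate (combustion stoichiometry).
    essential_for_lipids: cannot be synthesized and appears in every
        phospholipid-target recipe, so its absence blocks those targets.
    lipid_usable: may be consumed by phospholipid-target reactions.
    """

    name: str
    atp_yield: float
    o2_stoich: float
    formula: str | None = None
    essential_for_lipids: bool = False
    lipid_usable: bool = False

    def __post_init__(self):
        if self.atp_yield <= 0 or self.o2_stoich <= 0:
            raise ValueError(f"substrate {self.name!r}: yields must be positive")


def default_yield_table() -> list[SubstrateSpec]:
    """The ten default substrates with per-mole ATP yields and O2 demands."""
    return [
        SubstrateSpec("glucose", 36.0, 6.0, "C6H12O6"),
        SubstrateSpec("lactate", 17.0, 3.0, "C3H6O3"),
        SubstrateSpec("acetoacetate", 22.0, 4.0, "C4H6O3"),
        SubstrateSpec("acetate", 9.0, 2.0, "C2H4O2"),
        SubstrateSpec("palmitate", 120.0, 23.0, "C16H32O2", lipid_usable=True),
        SubstrateSpec("stearate", 136.0, 26.0, "C18H36O2", lipid_usable=True),
        SubstrateSpec("oleate", 134.0, 25.5, "C18H34O2", lipid_usable=True),
        SubstrateSpec(
            "alpha_linoleate", 132.0, 24.5, "C18H30O2",
            essential_for_lipids=True, lipid_usable=True,
        ),
        SubstrateSpec("epa", 142.0, 26.5, "C20H30O2", lipid_usable=True),
        SubstrateSpec(
            "dha", 156.0, 29.0, "C22H32O2",
            essential_for_lipids=True, lipid_usable=True,
        ),
    ]


def yield_table_to_tsv(specs: list[SubstrateSpec]) -> str:
    buf = io.StringIO()
    w = csv.writer(buf, delimiter="\t", lineterminator="\n")
    w.writerow(["name", "atp_yield", "o2_stoich", "formula",
                "essential_for_lipids", "lipid_usable"])
    for s in specs:
        w.writerow([s.name, s.atp_yield, s.o2_stoich, s.formula or "",
                    int(s.essential_for_lipids), int(s.lipid_usable)])
    return buf.getvalue()


def yield_table_from_tsv(text: str) -> list[SubstrateSpec]:
    rows = list(csv.DictReader(io.StringIO(text), delimiter="\t"))
    return [
        SubstrateSpec(
            r["name"], float(r["atp_yield"]), float(r["o2_stoich"]),
            r.get("formula") or None,
            bool(int(r.get("essential_for_lipids", 0) or 0)),
            bool(int(r.get("lipid_usable", 0) or 0)),
        )
        for r in rows
    ]


#: Synthetic default acyl recipes for the lumped phospholipid targets
#: (mol fatty acid per mol target).  The exact acyl compositions of cardiac
#: membrane lipids are not part of this package; these defaults only preserve
#: the qualitative structure: every recipe needs alpha-linoleate and DHA.
DEFAULT_LIPID_RECIPES: dict[str, dict[str, float]] = {
    "cer": {"palmitate": 1.0, "alpha_linoleate": 0.25, "dha": 0.5},
    "cl": {"oleate": 2.0, "stearate": 0.5, "alpha_linoleate": 1.0, "dha": 0.5},
    "pc": {"palmitate": 1.0, "oleate": 0.5, "alpha_linoleate": 0.25, "dha": 0.25},
    "pe": {"stearate": 1.0, "alpha_linoleate": 0.25, "dha": 0.5},
    "sm": {"palmitate": 1.0, "alpha_linoleate": 0.125, "dha": 0.125},
}

#: Default demanded synthesis fluxes for the lipid targets,
#: mmol·min⁻¹·(l cell)⁻¹ (synthetic small rates, user-overridable).
DEFAULT_LIPID_TARGET_FLUXES: dict[str, float] = {
    "cer": 1e-3, "cl": 1e-3, "pc": 2e-3, "pe": 1e-3, "sm": 5e-4,
}

#: ATP cost per mol of lumped lipid-target assembly.
LIPID_ASSEMBLY_ATP = 5.0


@dataclass
class CoreOptions:
    """Configuration of targets and optional subsystems of the core network.

    All rates are mmol·min⁻¹·(l cell)⁻¹.  The ATP demand default (21.6) is
    the baseline contractile ATP consumption rate of a working cardiomyocyte.
    Glycogen synthesis costs ``glycogen_synthesis_cost`` ATP per glucosyl
    unit (hexokinase plus UDP-glucose activation); degradation is capped at
    ``glycogenolysis_max``.
    """

    atpase_demand: float = 21.6
    include_glycogen: bool = False
    glycogen_synthesis_cost: float = 2.0
    glycogenolysis_max: float = 0.9
    include_lipid_targets: bool = False
    target_fluxes: dict[str, float] = field(default_factory=dict)
    lipid_recipes: dict[str, dict[str, float]] = field(default_factory=dict)
    include_nadph: bool = False
    nadph_min: float = 1.42e-5

    def __post_init__(self):
        if self.atpase_demand < 0 or self.nadph_min < 0:
            raise CoreConfigError("rates must be nonnegative")
        if any(v < 0 for v in self.target_fluxes.values()):
            raise CoreConfigError("target fluxes must be nonnegative")
        if self.include_glycogen and not (self.glycogenolysis_max < float("inf")):
            raise CoreConfigError("glycogenolysis_max must be finite")


def uptake_id(substrate: str) -> str:
    return f"EX_{substrate}"


OXYGEN_UPTAKE = "EX_o2"
ATPASE = "ATPASE"
GLYCOGENOLYSIS = "GL"
GLYCOGEN_SYNTHESIS = "GS"


def build_core_network(
    yields: list[SubstrateSpec] | None = None,
    options: CoreOptions | None = None,
) -> MetabolicNetwork:
    """Assemble the reduced core network from a yield table and options.

    Deterministic: equal inputs produce identical networks (and identical
    bytes when written to the native JSON format).
    """
    yields = default_yield_table() if yields is None else list(yields)
    options = CoreOptions() if options is None else options
    if not yields:
        raise CoreConfigError("need at least one substrate")
    by_name = {s.name: s for s in yields}
    if len(by_name) != len(yields):
        raise CoreConfigError("duplicate substrate names in yield table")

    net = MetabolicNetwork(metabolites=[], reactions=[], compartments=["ext", "cyto"])
    net.annotations["generator"] = "cardiocore.coregen"

    def met(mid, name, comp="cyto", formula=None):
        net.metabolites.append(Metabolite(mid, name, comp, formula))

    def rxn(rid, stoich, **kw):
        net.reactions.append(Reaction(rid, stoich, **kw))

    met("o2", "oxygen", "cyto", "O2")
    met("atp", "ATP (lumped energy currency)")
    met("adp", "ADP")
    met("byp", "lumped oxidation byproduct (CO2/H2O pool)")

    rxn(OXYGEN_UPTAKE, {"o2": 1.0}, is_exchange=True, allowed_secretion=False)
    rxn("EX_byp", {"byp": -1.0}, is_exchange=True, allowed_uptake=False)
    rxn(ATPASE, {"atp": -1.0, "adp": 1.0})

    for s in yields:
        met(s.name, s.name, "cyto", s.formula)
        rxn(uptake_id(s.name), {s.name: 1.0}, is_exchange=True, allowed_secretion=False)
        rxn(
            f"OX_{s.name}",
            {
                s.name: -1.0,
                "o2": -s.o2_stoich,
                "adp": -s.atp_yield,
                "atp": s.atp_yield,
                "byp": 1.0,
            },
        )

    if options.include_glycogen:
        if "glucose" not in by_name:
            raise CoreConfigError("glycogen subsystem requires a 'glucose' substrate")
        met("glycogen", "glycogen (glucosyl units, buffered store)")
        c = options.glycogen_synthesis_cost
        rxn(GLYCOGEN_SYNTHESIS, {"glucose": -1.0, "atp": -c, "adp": c, "glycogen": 1.0})
        rxn(GLYCOGENOLYSIS, {"glycogen": -1.0, "glucose": 1.0},
            upper_bound=options.glycogenolysis_max)
        # Buffered store: the glycogen pool exchanges freely with an external
        # reservoir, so synthesis and capped degradation are independent.
        rxn("EX_glycogen_store", {"glycogen": -1.0}, reversible=True,
            lower_bound=-DEFAULT_BOUND, is_exchange=True)

    if options.include_lipid_targets:
        recipes = options.lipid_recipes or DEFAULT_LIPID_RECIPES
        for target, recipe in recipes.items():
            missing = set(recipe) - set(by_name)
            if missing:
                raise CoreConfigError(
                    f"lipid target {target!r} needs absent substrates: {sorted(missing)}"
                )
            bad = [f for f in recipe if not by_name[f].lipid_usable]
            if bad:
                raise CoreConfigError(
                    f"lipid target {target!r} uses non-lipid substrates: {bad}"
                )
            met(target, f"lumped membrane lipid {target}", "cyto")
            stoich = {f: -c for f, c in sorted(recipe.items())}
            stoich.update({"atp": -LIPID_ASSEMBLY_ATP, "adp": LIPID_ASSEMBLY_ATP,
                           target: 1.0})
            rxn(f"SYN_{target}", stoich)
            rxn(f"DEMAND_{target}", {target: -1.0})
        # De-novo synthesis of non-essential fatty acids at an ATP cost above
        # their oxidation yield, so carbon can be rerouted but no free-energy
        # cycle exists.  EPA is elongated from alpha-linoleate.
        for s in yields:
            if not s.lipid_usable or s.essential_for_lipids:
                continue
            if s.name == "epa":
                if "alpha_linoleate" in by_name:
                    cost = s.atp_yield - by_name["alpha_linoleate"].atp_yield + 2.0
                    rxn("FASYN_epa", {"alpha_linoleate": -1.0, "atp": -cost,
                                      "adp": cost, "epa": 1.0})
                continue
            cost = s.atp_yield + 2.0
            rxn(f"FASYN_{s.name}", {"atp": -cost, "adp": cost, s.name: 1.0})

    if options.include_nadph:
        if "glucose" not in by_name:
            raise CoreConfigError("NADPH subsystem requires a 'glucose' substrate")
        met("g6p", "glucose 6-phosphate")
        met("nadph", "NADPH (lumped reducing equivalent)")
        rxn("HK", {"glucose": -1.0, "atp": -1.0, "adp": 1.0, "g6p": 1.0})
        rxn("G6PD", {"g6p": -1.0, "nadph": 2.0, "byp": 1.0})
        rxn("NADPH_DEMAND", {"nadph": -1.0})

    if options.target_fluxes:
        known_targets = set(DEFAULT_LIPID_RECIPES) | {"atpase"}
        for t in options.target_fluxes:
            if t not in known_targets:
                raise CoreConfigError(f"unknown target {t!r} in target_fluxes")
            if t != "atpase" and not options.include_lipid_targets:
                raise CoreConfigError(
                    f"target {t!r} demanded but lipid targets are not included"
                )

    net.validate()
    return net


def core_flux_problem(network: MetabolicNetwork, options: CoreOptions | None = None):
    """Build the flux-minimization problem matching a generated core network.

    Pins the ATPase drain (and any lipid-target demands) as equality targets
    and the NADPH demand as a minimum rate.
    """
    from .fba import FluxProblem  # local import: fba depends on netmodel only

    options = CoreOptions() if options is None else options
    rids = set(network.reaction_ids())
    targets = {ATPASE: options.target_fluxes.get("atpase", options.atpase_demand)}
    if options.include_lipid_targets:
        defaults = dict(DEFAULT_LIPID_TARGET_FLUXES)
        defaults.update({k: v for k, v in options.target_fluxes.items() if k != "atpase"})
        for t, v in defaults.items():
            rid = f"DEMAND_{t}"
            if rid not in rids:
                raise CoreConfigError(f"network lacks lipid target reaction {rid!r}")
            targets[rid] = v
    min_fluxes = {}
    if options.include_nadph:
        min_fluxes["NADPH_DEMAND"] = options.nadph_min
    uptakes = [
        r.id
        for r in network.reactions
        if r.is_exchange and r.allowed_uptake and r.id not in (OXYGEN_UPTAKE,)
        and not r.id.startswith("EX_glycogen") and r.id != "EX_byp"
    ]
    return FluxProblem(
        network=network,
        target_fluxes=targets,
        uptake_set=uptakes,
        oxygen_id=OXYGEN_UPTAKE,
        min_fluxes=min_fluxes,
        glycogenolysis_id=GLYCOGENOLYSIS if GLYCOGENOLYSIS in rids else None,
        glycogen_synthesis_id=GLYCOGEN_SYNTHESIS if GLYCOGEN_SYNTHESIS in rids else None,
    )


def make_parallel_variant(
    network: MetabolicNetwork, reaction_id: str, n_copies: int
) -> MetabolicNetwork:
    """Add duplicate reactions with identical stoichiometry (degenerate optima fixture)."""
    variant = network.copy()
    template = variant.reaction(reaction_id)
    existing = set(variant.reaction_ids())
    for i in range(1, n_copies + 1):
        rid = f"{reaction_id}__dup{i}"
        if rid in existing:
            raise ValueError(f"duplicate id collision: {rid!r}")
        variant.reactions.append(replace(template, id=rid,
                                         stoichiometry=dict(template.stoichiometry)))
    variant.validate()
    return variant


def write_core_model(path: str | Path, yields=None, options=None) -> MetabolicNetwork:
    from .netmodel import write_native

    net = build_core_network(yields, options)
    write_native(net, path)
    return net
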