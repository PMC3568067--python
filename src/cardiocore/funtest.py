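"""Metabolic-function feasibility batteries and functional pruning.

A function test asks whether the network can sustain a demanded flux (e.g.
"produce ATP at 1 mmol·min⁻¹·(l cell)⁻¹") while exchanges are restricted to
a stated set of uptakeable and secretable metabolites — the usual
network-validation procedure for constraint-based reconstructions.  Tests
are plain data (JSON-serializable) so a battery can be transcribed or
extended without code changes.

Functional pruning removes every reaction that is blocked under the union of
the battery's exchange settings, producing a sub-network with no blocked
reactions on which every test remains feasible (asserted).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from ._lp import solve_lp
from .fba import minimize_total_flux
from .netmodel import MetabolicNetwork, build_stoich_matrix

logger = logging.getLogger(__name__)


@dataclass
class FunctionTest:
    """One feasibility test: exchange constraints plus demanded fluxes.

    ``allowed_uptakes`` / ``allowed_secretions`` are metabolite ids;
    exchanges for any other metabolite are closed in the corresponding
    direction.  ``objective`` maps reaction ids to minimum demanded fluxes.
    """

    name: str
    objective: dict[str, float]
    category: str = ""
    allowed_uptakes: set[str] = field(default_factory=set)
    allowed_secretions: set[str] = field(default_factory=set)
    required: bool = True

    def __post_init__(self):
        if not self.objective:
            raise ValueError(f"test {self.name!r}: objective must be non-empty")
        self.allowed_uptakes = set(self.allowed_uptakes)
        self.allowed_secretions = set(self.allowed_secretions)


@dataclass
class FunctionResult:
    name: str
    category: str
    status: str  # feasible / infeasible / not_applicable
    witness: dict[str, float] | None = None


@dataclass
class BatteryReport:
    results: list[FunctionResult]

    def counts(self) -> dict[str, int]:
        out = {"feasible": 0, "infeasible": 0, "not_applicable": 0}
        for r in self.results:
            out[r.status] += 1
        return out

    @property
    def all_feasible(self) -> bool:
        return all(r.status != "infeasible" for r in self.results)

    def to_tsv(self) -> str:
        lines = ["name\tcategory\tstatus"]
        lines += [f"{r.name}\t{r.category}\t{r.status}" for r in self.results]
        return "\n".join(lines) + "\n"


def load_battery(path: str | Path) -> list[FunctionTest]:
    data = json.loads(Path(path).read_text())
    return [FunctionTest(**t) for t in data]


def save_battery(tests: list[FunctionTest], path: str | Path) -> None:
    payload = []
    for t in tests:
        d = asdict(t)
        d["allowed_uptakes"] = sorted(t.allowed_uptakes)
        d["allowed_secretions"] = sorted(t.allowed_secretions)
        payload.append(d)
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def _exchange_bounds(
    network: MetabolicNetwork,
    allowed_uptakes: set[str],
    allowed_secretions: set[str],
) -> dict[str, tuple[float, float]]:
    """Clamp exchange bounds to the allowed uptake/secretion metabolite sets.

    For a single-metabolite exchange column with coefficient s, positive
    flux moves the metabolite into the system when s > 0; the reaction's own
    ``allowed_uptake`` / ``allowed_secretion`` flags are honoured on top.
    """
    out: dict[str, tuple[float, float]] = {}
    for r in network.reactions:
        if not r.is_exchange or len(r.stoichiometry) != 1:
            continue
        (mid, s), = r.stoichiometry.items()
        up_ok = mid in allowed_uptakes and r.allowed_uptake
        sec_ok = mid in allowed_secretions and r.allowed_secretion
        lo, hi = r.lower_bound, r.upper_bound
        if s > 0:  # positive flux = uptake
            if not up_ok:
                hi = min(hi, 0.0)
            if not sec_ok:
                lo = max(lo, 0.0)
        else:  # positive flux = secretion
            if not sec_ok:
                hi = min(hi, 0.0)
            if not up_ok:
                lo = max(lo, 0.0)
        if lo > hi:
            lo = hi = 0.0
        out[r.id] = (lo, hi)
    return out


def run_function_battery(
    network: MetabolicNetwork, tests: list[FunctionTest], witnesses: bool = True
) -> BatteryReport:
    """Check each test's feasibility; order-independent, failures reported not raised.

    Tests referencing reactions or metabolites absent from the network are
    reported ``not_applicable`` rather than failed.
    """
    rids = set(network.reaction_ids())
    mids = set(network.metabolite_ids())
    results = []
    for t in tests:
        referenced = set(t.objective) - rids
        missing_mets = (t.allowed_uptakes | t.allowed_secretions) - mids
        if referenced or missing_mets:
            results.append(FunctionResult(t.name, t.category, "not_applicable"))
            continue
        bounds = _exchange_bounds(network, t.allowed_uptakes, t.allowed_secretions)
        for rid, demand in t.objective.items():
            rxn = network.reaction(rid)
            lo, hi = bounds.get(rid, (rxn.lower_bound, rxn.upper_bound))
            bounds[rid] = (max(lo, demand), hi)
        if witnesses:
            dist = minimize_total_flux(network, bounds)
            ok = dist.optimal
            witness = dist.fluxes if ok else None
        else:
            idx = {rid: j for j, rid in enumerate(network.reaction_ids())}
            N = build_stoich_matrix(network)
            full = [(r.lower_bound, r.upper_bound) for r in network.reactions]
            for rid, bd in bounds.items():
                full[idx[rid]] = bd
            res = solve_lp(np.zeros(len(full)), A_eq=N,
                           b_eq=np.zeros(N.shape[0]), bounds=full)
            ok = res.status == "optimal"
            witness = None
        results.append(
            FunctionResult(t.name, t.category, "feasible" if ok else "infeasible",
                           witness)
        )
    return BatteryReport(results)


def prune_to_functional_subnetwork(
    network: MetabolicNetwork, tests: list[FunctionTest]
) -> MetabolicNetwork:
    """Remove reactions blocked under the union of the tests' exchange settings.

    Every test must be feasible on the input network, and remains feasible on
    the pruned network (asserted; a violation aborts with an error since it
    would indicate an internal inconsistency).
    """
    before = run_function_battery(network, tests, witnesses=False)
    infeasible = [r.name for r in before.results if r.status == "infeasible"]
    if infeasible:
        raise ValueError(f"tests infeasible on input network: {infeasible}")

    union_up = set().union(*(t.allowed_uptakes for t in tests)) if tests else set()
    union_sec = set().union(*(t.allowed_secretions for t in tests)) if tests else set()
    bounds_map = _exchange_bounds(network, union_up, union_sec)
    idx = {rid: j for j, rid in enumerate(network.reaction_ids())}
    N = build_stoich_matrix(network)
    bounds = [(r.lower_bound, r.upper_bound) for r in network.reactions]
    for rid, bd in bounds_map.items():
        bounds[idx[rid]] = bd

    blocked: set[str] = set()
    n = len(network.reactions)
    b = np.zeros(N.shape[0])
    for j, rxn in enumerate(network.reactions):
        c = np.zeros(n)
        c[j] = 1.0
        lo = solve_lp(c, A_eq=N, b_eq=b, bounds=bounds)
        hi = solve_lp(-c, A_eq=N, b_eq=b, bounds=bounds)
        vmin = lo.x[j] if lo.status == "optimal" else 0.0
        vmax = hi.x[j] if hi.status == "optimal" else 0.0
        if abs(vmin) <= 1e-6 and abs(vmax) <= 1e-6:
            blocked.add(rxn.id)

    pruned = network.copy()
    pruned.reactions = [r for r in pruned.reactions if r.id not in blocked]
    kept_mets = set()
    for r in pruned.reactions:
        kept_mets.update(r.stoichiometry)
    pruned.metabolites = [m for m in pruned.metabolites if m.id in kept_mets]
    pruned.annotations["pruned_reactions"] = sorted(blocked)

    after = run_function_battery(pruned, tests, witnesses=False)
    broken = [r.name for r in after.results if r.status == "infeasible"]
    if broken:
        raise RuntimeError(
            f"internal error: pruning broke feasibility of tests {broken}"
        )
    return pruned
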