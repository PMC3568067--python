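"""Two-stage flux-minimization flux balance analysis.

Stage 1 minimizes total substrate plus oxygen uptake,

    minimize  v_s + v_O2
    subject to  N·v = 0,  v_min ≤ v ≤ v_max,  pinned target fluxes,
                v_m = β_m · v_s  (substrate-composition coupling),

where v_s = Σ_m v_m is the total substrate uptake flux over the declared
uptake set.  Stage 2 is the flux-minimization tiebreak: with the stage-1
optimum pinned, it minimizes Σ_j |v_j| over all reactions (via the usual
split into nonnegative forward/backward components), selecting the sparsest
of the degenerate optimal distributions.  Stage 2 can be disabled with
``tiebreak=False``; the (v_s, v_O2) optimum is unaffected by the tiebreak.

Target fluxes are equality constraints; minimum-rate demands (e.g. a basal
NADPH requirement) are ≥ bounds, held in ``min_fluxes``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from ._lp import solve_lp
from .netmodel import MetabolicNetwork, build_stoich_matrix

logger = logging.getLogger(__name__)

#: absolute slack used when pinning the stage-1 objective in stage 2 / FVA
OBJECTIVE_PIN_TOL = 1e-7
#: bounds are considered respected within this absolute tolerance
BOUND_TOL = 1e-9


@dataclass
class FluxProblem:
    """A flux-minimization problem over a metabolic network."""

    network: MetabolicNetwork
    target_fluxes: dict[str, float]
    uptake_set: list[str]
    oxygen_id: str
    composition: object | None = None  # Composition or mapping uptake-id -> beta
    extra_bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    min_fluxes: dict[str, float] = field(default_factory=dict)
    glycogenolysis_id: str | None = None
    glycogen_synthesis_id: str | None = None
    tiebreak: bool = True

    def __post_init__(self):
        rids = set(self.network.reaction_ids())
        for rid in self.target_fluxes:
            if rid not in rids:
                raise KeyError(f"target reaction {rid!r} not in network")
        if not self.uptake_set:
            raise ValueError("uptake_set must be non-empty")
        missing = set(self.uptake_set) - rids
        if missing:
            raise KeyError(f"uptake reactions not in network: {sorted(missing)}")
        if self.oxygen_id not in rids:
            raise KeyError(f"oxygen reaction {self.oxygen_id!r} not in network")
        if self.oxygen_id in self.uptake_set:
            raise ValueError("oxygen_id must not be part of uptake_set")

    def betas(self) -> dict[str, float] | None:
        if self.composition is None:
            return None
        b = getattr(self.composition, "betas", self.composition)
        return dict(b)


@dataclass
class FluxDistribution:
    """A solved flux vector with objective value and convenience summaries."""

    fluxes: dict[str, float]
    objective: float | None
    status: str
    v_s: float = 0.0
    v_O2: float = 0.0
    v_GL: float = 0.0
    v_GS: float = 0.0

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    def steady_state_residual(self, network: MetabolicNetwork) -> float:
        N = build_stoich_matrix(network)
        v = np.array([self.fluxes.get(r.id, 0.0) for r in network.reactions])
        return float(np.max(np.abs(N @ v))) if len(v) else 0.0


def _stage1_arrays(problem: FluxProblem):
    net = problem.network
    rids = net.reaction_ids()
    idx = {rid: j for j, rid in enumerate(rids)}
    n = len(rids)
    N = build_stoich_matrix(net)
    bounds = [(r.lower_bound, r.upper_bound) for r in net.reactions]
    for rid, val in problem.target_fluxes.items():
        bounds[idx[rid]] = (val, val)
    for rid, val in problem.min_fluxes.items():
        lo, hi = bounds[idx[rid]]
        bounds[idx[rid]] = (max(lo, val), hi)
    # extra_bounds are the final override (also how alternate-optima
    # enumeration re-pins individual fluxes, including target fluxes)
    for rid, bd in problem.extra_bounds.items():
        bounds[idx[rid]] = tuple(bd)

    rows = [N]
    betas = problem.betas()
    if betas is not None:
        unknown = set(betas) - set(problem.uptake_set)
        if unknown:
            raise KeyError(f"composition keys not in uptake set: {sorted(unknown)}")
        up_idx = [idx[u] for u in problem.uptake_set]
        for rid in problem.uptake_set:
            beta = betas.get(rid, 0.0)
            if beta == 0.0:
                lo, hi = bounds[idx[rid]]
                bounds[idx[rid]] = (max(lo, 0.0), 0.0) if hi >= 0 else (0.0, 0.0)
                continue
            row = np.zeros(n)
            row[up_idx] = -beta
            row[idx[rid]] += 1.0
            rows.append(row.reshape(1, -1))
    A_eq = np.vstack(rows)
    b_eq = np.zeros(A_eq.shape[0])

    c = np.zeros(n)
    for rid in problem.uptake_set:
        c[idx[rid]] += 1.0
    c[idx[problem.oxygen_id]] += 1.0
    return rids, idx, A_eq, b_eq, bounds, c


def _empty(status: str) -> FluxDistribution:
    return FluxDistribution({}, None, status)


def _package(problem: FluxProblem, rids, v, objective) -> FluxDistribution:
    fluxes = {rid: float(x) for rid, x in zip(rids, v)}
    v_s = sum(fluxes[u] for u in problem.uptake_set)
    return FluxDistribution(
        fluxes=fluxes,
        objective=float(objective),
        status="optimal",
        v_s=float(v_s),
        v_O2=fluxes[problem.oxygen_id],
        v_GL=fluxes.get(problem.glycogenolysis_id or "", 0.0),
        v_GS=fluxes.get(problem.glycogen_synthesis_id or "", 0.0),
    )


def minimize_uptake(problem: FluxProblem) -> FluxDistribution:
    """Solve the two-stage flux-minimization problem.

    Returns the stage-2 (total-flux-minimal) distribution, or the stage-1
    distribution when the tiebreak is disabled.  Infeasible and unbounded
    problems are reported in the status with empty fluxes.
    """
    rids, idx, A_eq, b_eq, bounds, c = _stage1_arrays(problem)
    s1 = solve_lp(c, A_eq=A_eq, b_eq=b_eq, bounds=bounds)
    if s1.status != "optimal":
        if s1.status == "unbounded":
            logger.warning("stage-1 LP unbounded: a flux bound is missing")
        return _empty(s1.status)
    if not problem.tiebreak:
        return _package(problem, rids, s1.x, s1.objective)

    n = len(rids)
    # split v = p - q, p,q >= 0; bounds chosen so p - q spans exactly [lb, ub]
    sp_bounds = [(max(lo, 0.0), max(hi, 0.0)) for lo, hi in bounds] + [
        (max(-hi, 0.0), max(-lo, 0.0)) for lo, hi in bounds
    ]
    A_eq2 = np.hstack([A_eq, -A_eq])
    c_pin = np.concatenate([c, -c])
    A_ub = np.vstack([c_pin, -c_pin])
    b_ub = np.array([s1.objective + OBJECTIVE_PIN_TOL,
                     -(s1.objective - OBJECTIVE_PIN_TOL)])
    c2 = np.ones(2 * n)
    s2 = solve_lp(c2, A_eq=A_eq2, b_eq=b_eq, A_ub=A_ub, b_ub=b_ub, bounds=sp_bounds)
    if s2.status != "optimal":
        logger.warning("stage-2 tiebreak LP %s; returning stage-1 solution", s2.status)
        return _package(problem, rids, s1.x, s1.objective)
    v = s2.x[:n] - s2.x[n:]
    return _package(problem, rids, v, s1.objective)


def check_feasible(problem: FluxProblem) -> bool:
    """True iff the stage-1 constraint set admits a feasible point."""
    rids, idx, A_eq, b_eq, bounds, _ = _stage1_arrays(problem)
    res = solve_lp(np.zeros(len(rids)), A_eq=A_eq, b_eq=b_eq, bounds=bounds)
    return res.status == "optimal"


def flux_range(
    problem: FluxProblem, reaction_id: str, optimum: float | None = None
) -> tuple[float, float]:
    """Min and max of one flux over the stage-1 optimal face.

    The stage-1 objective is computed if not supplied, then pinned within
    ``OBJECTIVE_PIN_TOL`` while the named flux is minimized and maximized.
    """
    rids, idx, A_eq, b_eq, bounds, c = _stage1_arrays(problem)
    if reaction_id not in idx:
        raise KeyError(f"no reaction {reaction_id!r} in network")
    if optimum is None:
        s1 = solve_lp(c, A_eq=A_eq, b_eq=b_eq, bounds=bounds)
        if s1.status != "optimal":
            raise RuntimeError(f"base problem is {s1.status}")
        optimum = s1.objective
    A_ub = np.vstack([c, -c])
    b_ub = np.array([optimum + OBJECTIVE_PIN_TOL, -(optimum - OBJECTIVE_PIN_TOL)])
    e = np.zeros(len(rids))
    e[idx[reaction_id]] = 1.0
    lo = solve_lp(e, A_eq=A_eq, b_eq=b_eq, A_ub=A_ub, b_ub=b_ub, bounds=bounds)
    hi = solve_lp(-e, A_eq=A_eq, b_eq=b_eq, A_ub=A_ub, b_ub=b_ub, bounds=bounds)
    if lo.status != "optimal" or hi.status != "optimal":
        raise RuntimeError("flux range subproblem failed")
    return float(lo.x[idx[reaction_id]]), float(hi.x[idx[reaction_id]])


def maximize_flux(
    network: MetabolicNetwork,
    reaction_id: str,
    fixed: Mapping[str, float] | None = None,
    closed: list[str] | None = None,
) -> FluxDistribution:
    """Maximize one flux at steady state (plain FBA).

    ``fixed`` pins fluxes to exact values (e.g. one unit of substrate
    uptake); ``closed`` forces the named reactions to zero.  Used for yield
    recovery: maximizing the ATP-drain flux per fixed unit of a sole
    substrate uptake returns that substrate's ATP yield.
    """
    rids = network.reaction_ids()
    idx = {rid: j for j, rid in enumerate(rids)}
    N = build_stoich_matrix(network)
    bounds = [(r.lower_bound, r.upper_bound) for r in network.reactions]
    for rid in closed or []:
        bounds[idx[rid]] = (0.0, 0.0)
    for rid, val in (fixed or {}).items():
        bounds[idx[rid]] = (val, val)
    c = np.zeros(len(rids))
    c[idx[reaction_id]] = -1.0
    res = solve_lp(c, A_eq=N, b_eq=np.zeros(N.shape[0]), bounds=bounds)
    if res.status != "optimal":
        return _empty(res.status)
    fluxes = {rid: float(x) for rid, x in zip(rids, res.x)}
    return FluxDistribution(fluxes, -res.objective, "optimal",
                            v_O2=fluxes.get("EX_o2", 0.0))


def minimize_total_flux(
    network: MetabolicNetwork,
    extra_bounds: Mapping[str, tuple[float, float]] | None = None,
) -> FluxDistribution:
    """Minimize Σ|v| at steady state under the given bounds (witness solver).

    Returns the sparsest flux distribution satisfying the constraints, or an
    empty distribution with the solver status when none exists.
    """
    rids = network.reaction_ids()
    idx = {rid: j for j, rid in enumerate(rids)}
    N = build_stoich_matrix(network)
    bounds = [(r.lower_bound, r.upper_bound) for r in network.reactions]
    for rid, bd in (extra_bounds or {}).items():
        bounds[idx[rid]] = tuple(bd)
    n = len(rids)
    sp_bounds = [(max(lo, 0.0), max(hi, 0.0)) for lo, hi in bounds] + [
        (max(-hi, 0.0), max(-lo, 0.0)) for lo, hi in bounds
    ]
    A_eq = np.hstack([N, -N])
    res = solve_lp(np.ones(2 * n), A_eq=A_eq, b_eq=np.zeros(N.shape[0]),
                   bounds=sp_bounds)
    if res.status != "optimal":
        return _empty(res.status)
    v = res.x[:n] - res.x[n:]
    fluxes = {rid: float(x) for rid, x in zip(rids, v)}
    return FluxDistribution(fluxes, float(res.objective), "optimal")


def with_composition(problem: FluxProblem, composition) -> FluxProblem:
    """Return a copy of the problem constrained to one substrate composition."""
    return replace(problem, composition=composition)
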