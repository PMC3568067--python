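"""Thin wrapper around scipy's HiGHS linear-programming interface.

All linear programs in the package go through :func:`solve_lp`, which
normalizes solver statuses to ``optimal`` / ``infeasible`` / ``unbounded``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog

#: primal feasibility / optimality tolerance requested from HiGHS
FEASIBILITY_TOL = 1e-9

_STATUS = {0: "optimal", 1: "iteration_limit", 2: "infeasible", 3: "unbounded", 4: "numerical"}


@dataclass
class LPResult:
    status: str
    x: np.ndarray | None
    objective: float | None


def solve_lp(
    c,
    A_eq=None,
    b_eq=None,
    A_ub=None,
    b_ub=None,
    bounds=None,
) -> LPResult:
    res = linprog(
        c,
        A_eq=A_eq,
        b_eq=b_eq,
        A_ub=A_ub,
        b_ub=b_ub,
        bounds=bounds,
        method="highs",
        options={
            "primal_feasibility_tolerance": FEASIBILITY_TOL,
            "dual_feasibility_tolerance": FEASIBILITY_TOL,
        },
    )
    status = _STATUS.get(res.status, "numerical")
    if status == "optimal":
        return LPResult("optimal", np.asarray(res.x), float(res.fun))
    return LPResult(status, None, None)
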