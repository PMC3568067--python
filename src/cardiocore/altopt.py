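"""Alternate-optima enumeration and flux-uniqueness analysis.

The optimal flux distribution of a flux-minimization problem need not be
unique.  To probe degeneracy, each nonzero flux of the original solution v0
is re-constrained, one at a time, to 1.01·v0 and to 0.99·v0, and the problem
is re-solved.  Perturbed solutions whose objective matches the original
optimum are kept as alternate distributions; fluxes whose perturbation is
infeasible in both directions are recorded as dependent (they cannot be
varied without violating the demanded targets).  Per-reaction sample
variance over the original plus all alternates identifies the uniquely
determined fluxes (variance zero), and a one-way ANOVA across distributions
summarizes their overall similarity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .fba import FluxDistribution, FluxProblem, minimize_uptake

logger = logging.getLogger(__name__)

#: relative tolerance for "same optimal objective"
SAME_OPTIMUM_RTOL = 1e-6
#: fluxes smaller than this are not perturbed (scaling zero is no perturbation)
ZERO_FLUX_TOL = 1e-9
#: sample variances below this count as unique
UNIQUE_VARIANCE_TOL = 1e-10


@dataclass
class AltOptReport:
    original: FluxDistribution
    alternates: list[FluxDistribution]
    per_flux_variance: dict[str, float]
    unique_fraction: float
    dependent_fluxes: set[str]
    anova: tuple[float, float]

    def n_alternates(self) -> int:
        return len(self.alternates)

    def summary_frame(self):
        import pandas as pd

        rows = []
        dists = [self.original] + self.alternates
        for rid, v0 in self.original.fluxes.items():
            vals = [d.fluxes.get(rid, 0.0) for d in dists]
            s = self.per_flux_variance[rid]
            rows.append(
                dict(reaction=rid, v0=v0, vmin=min(vals), vmax=max(vals),
                     variance=s, unique=s <= UNIQUE_VARIANCE_TOL,
                     dependent=rid in self.dependent_fluxes)
            )
        return pd.DataFrame(rows)


def _same_objective(obj: float, optimum: float) -> bool:
    return abs(obj - optimum) <= SAME_OPTIMUM_RTOL * (1.0 + abs(optimum))


def enumerate_alternates(
    problem: FluxProblem, v0: FluxDistribution | None = None
) -> AltOptReport:
    """Enumerate alternate optimal distributions by ±1% flux re-constraining.

    ``v0`` defaults to the problem's own optimum; a supplied ``v0`` is
    verified to be optimal first.  Zero fluxes are skipped (scaling them
    changes nothing).
    """
    base = minimize_uptake(problem)
    if not base.optimal:
        raise RuntimeError(f"base problem is {base.status}; nothing to enumerate")
    if v0 is None:
        v0 = base
    elif v0.objective is None or not _same_objective(v0.objective, base.objective):
        raise ValueError(
            f"supplied v0 objective {v0.objective!r} does not match the "
            f"optimum {base.objective!r}"
        )
    optimum = base.objective

    alternates: list[FluxDistribution] = []
    dependent: set[str] = set()
    for rid, flux in v0.fluxes.items():
        if abs(flux) <= ZERO_FLUX_TOL:
            continue
        feasible_somewhere = False
        for factor in (1.01, 0.99):
            pinned = factor * flux
            bounds = dict(problem.extra_bounds)
            bounds[rid] = (pinned, pinned)
            sub = replace(problem, extra_bounds=bounds)
            try:
                dist = minimize_uptake(sub)
            except Exception as exc:
                logger.warning("perturbation of %s failed: %s", rid, exc)
                continue
            if dist.optimal:
                feasible_somewhere = True
                if _same_objective(dist.objective, optimum):
                    alternates.append(dist)
        if not feasible_somewhere:
            dependent.add(rid)

    dists = [v0] + alternates
    variance: dict[str, float] = {}
    for rid in v0.fluxes:
        vals = np.array([d.fluxes.get(rid, 0.0) for d in dists])
        variance[rid] = float(np.var(vals, ddof=1)) if len(vals) > 1 else 0.0
    n_unique = sum(1 for s in variance.values() if s <= UNIQUE_VARIANCE_TOL)
    unique_fraction = n_unique / len(variance) if variance else 1.0

    report = AltOptReport(
        original=v0,
        alternates=alternates,
        per_flux_variance=variance,
        unique_fraction=unique_fraction,
        dependent_fluxes=dependent,
        anova=(float("nan"), float("nan")),
    )
    if alternates:
        report.anova = compare_distributions_anova(report)
    return report


def compare_distributions_anova(report: AltOptReport) -> tuple[float, float]:
    """One-way ANOVA with flux distributions as groups, reactions as observations.

    Degenerate cases: identical groups give F = 0, p = 1; distinct group
    means with zero within-group variance give F = inf, p = 0 (flagged).
    """
    dists = [report.original] + list(report.alternates)
    if len(dists) < 2:
        raise ValueError("need at least two distributions for ANOVA")
    rids = list(report.original.fluxes)
    groups = [np.array([d.fluxes.get(r, 0.0) for r in rids]) for d in dists]
    means = np.array([g.mean() for g in groups])
    within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    between = sum(len(g) * (m - means.mean()) ** 2 for g, m in zip(groups, means))
    if between <= 1e-300:
        return (0.0, 1.0)
    if within <= 1e-300:
        logger.warning("zero within-group variance; ANOVA F capped at infinity")
        return (float("inf"), 0.0)
    f, p = stats.f_oneway(*groups)
    return (float(f), float(p))
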