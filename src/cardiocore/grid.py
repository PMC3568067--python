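"""Simplex-grid enumeration of substrate compositions and batch flux scans.

A composition β assigns each external substrate its relative share of the
total substrate uptake flux v_s (Σβ_m = 1, 0 ≤ β_m ≤ 1).  The scanner walks
a regular grid on the unit simplex — all vectors (a_1/k, …, a_ns/k) with
nonnegative integers a_i summing to k = 1/step — and runs one
flux-minimization per composition, recording oxygen demand, total substrate
uptake and the glycogen fluxes.  Infeasible compositions are recorded with
their status, never dropped.

For four substrates at step 0.01 the grid has C(103, 3) = 176,851 points.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import pandas as pd

from .fba import FluxProblem, minimize_uptake, with_composition

logger = logging.getLogger(__name__)

_SUM_TOL = 1e-9


@dataclass(frozen=True)
class Composition:
    """Relative substrate shares β_m keyed by uptake reaction id."""

    betas: tuple[tuple[str, float], ...]

    def __init__(self, betas):
        if hasattr(betas, "items"):
            betas = tuple(betas.items())
        else:
            betas = tuple((k, float(v)) for k, v in betas)
        object.__setattr__(self, "betas", betas)
        vals = [v for _, v in betas]
        if any(v < -1e-15 or v > 1 + 1e-12 for v in vals):
            raise ValueError("each beta must lie in [0, 1]")
        if abs(sum(vals) - 1.0) > _SUM_TOL:
            raise ValueError(f"betas must sum to 1 (got {sum(vals)!r})")

    def as_dict(self) -> dict[str, float]:
        return dict(self.betas)

    def __getitem__(self, key: str) -> float:
        return self.as_dict()[key]


def _integer_partitions(n: int, k: int) -> Iterator[tuple[int, ...]]:
    """All nonnegative integer vectors of length n summing to k, lexicographic."""
    if n == 1:
        yield (k,)
        return
    for a in range(k + 1):
        for rest in _integer_partitions(n - 1, k - a):
            yield (a,) + rest


def composition_count(n_s: int, step: float) -> int:
    k = _grid_k(step)
    return math.comb(k + n_s - 1, n_s - 1)


def _grid_k(step: float) -> int:
    k = round(1.0 / step)
    if k <= 0 or abs(k * step - 1.0) > 1e-9:
        raise ValueError(f"1/step must be a positive integer (step={step!r})")
    return k


def enumerate_compositions(
    n_s: int, step: float, uptake_ids: Sequence[str] | None = None
) -> list[Composition]:
    """Regular simplex grid of compositions in lexicographic order.

    Count is C(k + n_s − 1, n_s − 1) with k = 1/step.  Keys default to
    ``s1..s{n_s}`` when no uptake ids are given.
    """
    if n_s < 1:
        raise ValueError("n_s must be >= 1")
    k = _grid_k(step)
    if uptake_ids is None:
        uptake_ids = [f"s{i+1}" for i in range(n_s)]
    elif len(uptake_ids) != n_s:
        raise ValueError("uptake_ids length must equal n_s")
    return [
        Composition(zip(uptake_ids, (a / k for a in vec)))
        for vec in _integer_partitions(n_s, k)
    ]


def apply_composition(problem: FluxProblem, composition: Composition) -> FluxProblem:
    """Constrain a flux problem to one composition (v_m = β_m·v_s)."""
    unknown = set(composition.as_dict()) - set(problem.uptake_set)
    if unknown:
        raise KeyError(f"composition keys not in uptake set: {sorted(unknown)}")
    return with_composition(problem, composition)


@dataclass
class ScanConfig:
    """Configuration of a substrate-availability scan."""

    uptake_ids: list[str]
    oxygen_id: str
    step: float | None = None
    compositions: list[Composition] | None = None
    target_fluxes: dict[str, float] = field(default_factory=dict)
    min_fluxes: dict[str, float] = field(default_factory=dict)
    extra_bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    glycogenolysis_id: str | None = None
    glycogen_synthesis_id: str | None = None
    tiebreak: bool = True
    checkpoint: str | Path | None = None
    checkpoint_every: int = 1000

    def resolved_compositions(self) -> list[Composition]:
        if self.compositions is not None:
            return list(self.compositions)
        if self.step is None:
            raise ValueError("ScanConfig needs either step or explicit compositions")
        return enumerate_compositions(len(self.uptake_ids), self.step, self.uptake_ids)


@dataclass
class ScanResult:
    """Per-composition scan records backed by a DataFrame.

    Columns: one ``beta_<uptake-id>`` per substrate, then vO2, vs, vGL, vGS
    and status.  Row order follows the (deterministic) composition order.
    """

    frame: pd.DataFrame

    def feasible(self) -> pd.DataFrame:
        return self.frame[self.frame["status"] == "optimal"].copy()

    def to_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "ScanResult":
        return cls(pd.read_csv(path, sep="\t"))


def _scan_row(composition: Composition, dist) -> dict:
    row = {f"beta_{k}": v for k, v in composition.betas}
    if dist.status == "optimal":
        row.update(vO2=dist.v_O2, vs=dist.v_s, vGL=dist.v_GL, vGS=dist.v_GS,
                   status=dist.status)
    else:
        nan = float("nan")
        row.update(vO2=nan, vs=nan, vGL=nan, vGS=nan, status=dist.status)
    return row


def run_scan(network, config: ScanConfig) -> ScanResult:
    """Run one flux minimization per composition.

    Solver failures mark the affected row and the scan continues.  With a
    ``checkpoint`` path, partial results are flushed every
    ``checkpoint_every`` rows and a restarted scan resumes after the last
    flushed row.
    """
    comps = config.resolved_compositions()
    # Substrates outside the scanned uptake set are unavailable: close every
    # uptake-only exchange not scanned (oxygen and reversible store/sink
    # exchanges are untouched).  Explicit extra_bounds take precedence.
    closed = {
        r.id: (0.0, 0.0)
        for r in network.reactions
        if r.is_exchange
        and r.allowed_uptake
        and not r.allowed_secretion
        and r.id != config.oxygen_id
        and r.id not in config.uptake_ids
    }
    closed.update(config.extra_bounds)
    base = FluxProblem(
        network=network,
        target_fluxes=dict(config.target_fluxes),
        uptake_set=list(config.uptake_ids),
        oxygen_id=config.oxygen_id,
        extra_bounds=closed,
        min_fluxes=dict(config.min_fluxes),
        glycogenolysis_id=config.glycogenolysis_id,
        glycogen_synthesis_id=config.glycogen_synthesis_id,
        tiebreak=config.tiebreak,
    )
    rows: list[dict] = []
    start = 0
    ckpt = Path(config.checkpoint) if config.checkpoint else None
    if ckpt is not None and ckpt.exists():
        done = pd.read_csv(ckpt, sep="\t")
        rows = done.to_dict("records")
        start = len(rows)
        logger.info("resuming scan at row %d from %s", start, ckpt)

    def flush():
        if ckpt is not None:
            pd.DataFrame(rows).to_csv(ckpt, sep="\t", index=False, float_format="%.10g")

    for i in range(start, len(comps)):
        comp = comps[i]
        try:
            dist = minimize_uptake(apply_composition(base, comp))
        except Exception as exc:  # keep scanning; record the failure
            logger.warning("scan row %d failed: %s", i, exc)
            row = {f"beta_{k}": v for k, v in comp.betas}
            row.update(vO2=float("nan"), vs=float("nan"), vGL=float("nan"),
                       vGS=float("nan"), status="error")
            rows.append(row)
            continue
        rows.append(_scan_row(comp, dist))
        if ckpt is not None and (i + 1) % config.checkpoint_every == 0:
            flush()
    flush()
    return ScanResult(pd.DataFrame(rows))
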