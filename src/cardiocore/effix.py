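"""Euclidean ideal/anti-ideal efficiency index (TOPSIS closeness coefficient).

Given a criteria matrix q (rows = solutions, columns = "lower is better"
criteria such as oxygen demand v_O2, total substrate uptake v_s and
glycogenolysis v_GL), the per-criterion best case q⁺ is the column minimum
and the worst case q⁻ the column maximum.  Each row's Euclidean distances to
the best and worst points,

    S⁺_i = sqrt(Σ_j (q_ij − q⁺_j)²),   S⁻_i = sqrt(Σ_j (q_ij − q⁻_j)²),

yield the efficiency index C⁺_i = S⁻_i / (S⁺_i + S⁻_i) ∈ [0, 1]: 1 at the
ideal point, 0 at the anti-ideal.  Distances are computed in raw units by
default; the classic TOPSIS vector normalization is available behind a flag
but off by default, since raw distances are what reproduces published
substrate-efficiency rankings.  Criteria are always costs — benefit criteria
are unsupported by design, and no criterion weighting is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass
class EfficiencyTable:
    labels: list
    criteria: list[str]
    q: np.ndarray
    q_plus: np.ndarray
    q_minus: np.ndarray
    s_plus: np.ndarray
    s_minus: np.ndarray
    c_plus: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.q, columns=self.criteria)
        df.insert(0, "label", self.labels)
        df["s_plus"] = self.s_plus
        df["s_minus"] = self.s_minus
        df["c_plus"] = self.c_plus
        return df

    def c_plus_of(self, label) -> float:
        return float(self.c_plus[self.labels.index(label)])


def efficiency_index(
    q,
    labels: Sequence | None = None,
    criteria: Sequence[str] | None = None,
    normalize: bool = False,
) -> EfficiencyTable:
    """Score each row of a criteria matrix by closeness to the ideal point.

    Needs at least two rows (otherwise ideals are undefined) and finite
    values.  Rows where every criterion is degenerate (S⁺ + S⁻ = 0) get
    C⁺ = 1 with a warning.
    """
    if isinstance(q, pd.DataFrame):
        if criteria is None:
            criteria = list(q.columns)
        if labels is None:
            labels = list(q.index)
        q = q.to_numpy(dtype=float)
    q = np.asarray(q, dtype=float)
    if q.ndim != 2:
        raise ValueError("criteria matrix must be 2-D")
    n_i, n_j = q.shape
    if n_i < 2:
        raise ValueError("need at least two solutions to define ideals")
    if not np.all(np.isfinite(q)):
        raise ValueError("criteria matrix contains non-finite values")
    if labels is None:
        labels = list(range(n_i))
    if criteria is None:
        criteria = [f"q{j+1}" for j in range(n_j)]

    work = q
    if normalize:
        norms = np.sqrt((q**2).sum(axis=0))
        norms[norms == 0] = 1.0
        work = q / norms

    q_plus = work.min(axis=0)
    q_minus = work.max(axis=0)
    s_plus = np.sqrt(((work - q_plus) ** 2).sum(axis=1))
    s_minus = np.sqrt(((work - q_minus) ** 2).sum(axis=1))
    denom = s_plus + s_minus
    degenerate = denom == 0
    if degenerate.any():
        warnings.warn(
            "all criteria identical for some rows; their C+ is defined as 1",
            stacklevel=2,
        )
    c_plus = np.where(degenerate, 1.0, s_minus / np.where(degenerate, 1.0, denom))
    return EfficiencyTable(
        labels=list(labels),
        criteria=list(criteria),
        q=q,
        q_plus=q_plus,
        q_minus=q_minus,
        s_plus=s_plus,
        s_minus=s_minus,
        c_plus=c_plus,
    )


def rank_compositions(
    scan, criteria: Sequence[str] = ("vO2", "vs"), normalize: bool = False
) -> pd.DataFrame:
    """Rank the feasible rows of a scan by efficiency index, descending.

    Ideals are recomputed over the feasible rows only; infeasible rows are
    excluded.  Ties keep the original row order.  Returns the scan columns
    plus S⁺, S⁻, C⁺ and a 1-based rank.
    """
    frame = scan.feasible() if hasattr(scan, "feasible") else scan
    if len(frame) < 2:
        raise ValueError("need at least two feasible rows to rank")
    missing = [c for c in criteria if c not in frame.columns]
    if missing:
        raise KeyError(f"criteria not in scan columns: {missing}")
    table = efficiency_index(
        frame[list(criteria)].to_numpy(dtype=float),
        labels=list(frame.index),
        criteria=list(criteria),
        normalize=normalize,
    )
    out = frame.copy()
    out["s_plus"] = table.s_plus
    out["s_minus"] = table.s_minus
    out["c_plus"] = table.c_plus
    out = out.sort_values("c_plus", ascending=False, kind="stable")
    out["rank"] = np.arange(1, len(out) + 1)
    return out
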