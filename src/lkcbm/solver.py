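"""Thin LP/MILP layer over scipy's HiGHS interfaces.

All optimisation in the package funnels through :func:`solve_lp` and
:func:`solve_milp` so that solver options and status handling live in one
place.  Problems are stated as

    max/min  c @ x
    s.t.     A_eq @ x = b_eq,  A_ub @ x <= b_ub,  lb <= x <= ub
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import Bounds, LinearConstraint, linprog, milp

__all__ = ["LpResult", "solve_lp", "solve_milp", "FLUX_TOL"]

# LP-noise floor used for flux significance, viability and blocked detection
FLUX_TOL = 1e-6


@dataclass
class LpResult:
    status: str  # "optimal" | "infeasible" | "unbounded" | "failed"
    x: Optional[np.ndarray]
    objective: Optional[float]

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


_LINPROG_STATUS = {0: "optimal", 1: "failed", 2: "infeasible", 3: "unbounded", 4: "failed"}


def solve_lp(c, lb, ub, A_eq=None, b_eq=None, A_ub=None, b_ub=None, maximize=True) -> LpResult:
    c = np.asarray(c, dtype=float)
    sign = -1.0 if maximize else 1.0
    res = linprog(
        sign * c,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=np.column_stack([lb, ub]),
        method="highs",
    )
    status = _LINPROG_STATUS.get(res.status, "failed")
    if status != "optimal":
        return LpResult(status, None, None)
    return LpResult("optimal", res.x, float(c @ res.x))


def solve_milp(
    c, lb, ub, integrality, A_eq=None, b_eq=None, A_ub=None, b_ub=None, maximize=True
) -> LpResult:
    c = np.asarray(c, dtype=float)
    sign = -1.0 if maximize else 1.0
    constraints = []
    if A_eq is not None and len(A_eq):
        b_eq = np.asarray(b_eq, dtype=float)
        constraints.append(LinearConstraint(np.asarray(A_eq, dtype=float), b_eq, b_eq))
    if A_ub is not None and len(A_ub):
        b_ub = np.asarray(b_ub, dtype=float)
        constraints.append(
            LinearConstraint(np.asarray(A_ub, dtype=float), -np.inf, b_ub)
        )
    res = milp(
        sign * c,
        constraints=constraints,
        bounds=Bounds(np.asarray(lb, float), np.asarray(ub, float)),
        integrality=np.asarray(integrality),
    )
    if res.status == 0:
        return LpResult("optimal", res.x, float(c @ res.x))
    if res.status == 2:
        return LpResult("infeasible", None, None)
    if res.status == 3:
        return LpResult("unbounded", None, None)
    return LpResult("failed", None, None)
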