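"""Independent oracles used by the test-suite.

Everything here deliberately avoids the package's solver layer: the
stoichiometric matrix is rebuilt from the model objects directly, and
optima are found by vertex enumeration or direct scipy calls, so these
results can cross-check the FBA/FVA implementations.
"""

from itertools import combinations, product

import numpy as np
from scipy.optimize import linprog


def assemble(model, medium=None):
    """Stoichiometric matrix and bounds, built directly from model objects."""
    met_ids = list(model.metabolites)
    rxn_ids = list(model.reactions)
    S = np.zeros((len(met_ids), len(rxn_ids)))
    midx = {m: i for i, m in enumerate(met_ids)}
    lb, ub = [], []
    exchanges = {r.id for r in model.reactions.values() if len(r.stoichiometry) == 1}
    for j, rid in enumerate(rxn_ids):
        r = model.reactions[rid]
        for m, c in r.stoichiometry.items():
            S[midx[m], j] = c
        lo = r.lower_bound
        if medium is not None and rid in exchanges:
            lo = -medium.uptake_bound(rid)
        lb.append(lo)
        ub.append(r.upper_bound)
    return S, np.array(lb), np.array(ub), rxn_ids


def brute_force_fba(model, medium, objective):
    """Maximum objective flux by enumerating basic feasible solutions.

    Every vertex of {S v = 0, lb <= v <= ub} has n - rank(S) coordinates
    at a bound; enumerate all such fixings, solve the remaining linear
    system, keep feasible solutions, return the best objective value.
    """
    S, lb, ub, rxn_ids = assemble(model, medium)
    n = len(rxn_ids)
    r = np.linalg.matrix_rank(S)
    k = n - r
    c = np.zeros(n)
    c[rxn_ids.index(objective)] = 1.0
    best = None
    if k == 0:
        sol, *_ = np.linalg.lstsq(S, np.zeros(S.shape[0]), rcond=None)
        if np.allclose(S @ sol, 0) and np.all(sol >= lb - 1e-9) and np.all(sol <= ub + 1e-9):
            return float(c @ sol)
        raise AssertionError("no feasible vertex")
    for fixed in combinations(range(n), k):
        free = [j for j in range(n) if j not in fixed]
        A = S[:, free]
        for vals in product(*[(lb[j], ub[j]) for j in fixed]):
            rhs = -S[:, fixed] @ np.array(vals)
            sol, res, rank, _ = np.linalg.lstsq(A, rhs, rcond=None)
            v = np.zeros(n)
            v[free] = sol
            v[list(fixed)] = vals
            if np.max(np.abs(S @ v)) > 1e-7:
                continue
            if np.any(v < lb - 1e-7) or np.any(v > ub + 1e-7):
                continue
            val = float(c @ v)
            if best is None or val > best:
                best = val
    if best is None:
        raise AssertionError("no feasible vertex found")
    return best


def lp_flux_range(model, medium, rxn_id):
    """[min, max] achievable flux of one reaction via direct scipy linprog calls."""
    S, lb, ub, rxn_ids = assemble(model, medium)
    c = np.zeros(len(rxn_ids))
    c[rxn_ids.index(rxn_id)] = 1.0
    out = []
    for sign in (1.0, -1.0):
        res = linprog(sign * c, A_eq=S, b_eq=np.zeros(S.shape[0]),
                      bounds=np.column_stack([lb, ub]), method="highs")
        assert res.status == 0, f"oracle LP failed for {rxn_id}"
        out.append(sign * res.fun)
    return min(out), max(out)


def cobra_fba(model, medium):
    """Growth optimum via cobrapy (fully independent LP stack: optlang/GLPK)."""
    from lkcbm.io import to_cobra

    cm = to_cobra(model)
    exchanges = {r.id for r in model.reactions.values() if len(r.stoichiometry) == 1}
    for ex in exchanges:
        cm.reactions.get_by_id(ex).lower_bound = -medium.uptake_bound(ex)
    sol = cm.optimize()
    return cm, sol
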