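"""Flux balance analysis and its variants.

Implements the optimisation layer of the pipeline: FBA, flux variability
analysis (plain and loopless), MOMA knockout projection, respiratory
quotient and product yields, carbon-source viability screening,
biomass-coefficient sensitivity and phenotypic phase planes.

The steady-state problem is

    max  c @ v   s.t.  S v = 0,  lb <= v <= ub

where the objective is normally the biomass pseudo-reaction whose flux is
the specific growth rate mu (1/h).  Because LP optima are degenerate,
assertions about individual fluxes at the optimum should be made through
FVA intervals rather than the single vertex FBA returns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.linalg import null_space
from scipy.optimize import minimize

from .model import DEFAULT_BOUND, Medium, MetabolicModel, ModelError
from .solver import FLUX_TOL, solve_lp, solve_milp

__all__ = [
    "FluxSolution",
    "FluxInterval",
    "PhasePlane",
    "fba",
    "fva",
    "loopless_fva",
    "moma",
    "respiratory_quotient",
    "product_yield",
    "viability_screen",
    "biomass_sensitivity",
    "phenotypic_phase_plane",
    "OXYGEN_REGIMES",
]

# oxygen uptake bounds (mmol/gDW/h) for the named aeration regimes
OXYGEN_REGIMES = {"aerobic": 1000.0, "semi_aerobic": 3.0, "anaerobic": 0.25}


@dataclass
class FluxSolution:
    status: str
    objective_id: Optional[str] = None
    objective_value: Optional[float] = None
    fluxes: Dict[str, float] = field(default_factory=dict)

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    def __getitem__(self, rxn_id: str) -> float:
        return self.fluxes[rxn_id]


@dataclass
class FluxInterval:
    """Per-reaction [min, max] flux ranges and the optimality fraction used."""

    intervals: Dict[str, Tuple[float, float]]
    fraction_of_optimum: float
    loopless: bool = False
    unresolved: set = field(default_factory=set)

    def __getitem__(self, rxn_id: str) -> Tuple[float, float]:
        return self.intervals[rxn_id]

    def __contains__(self, rxn_id: str) -> bool:
        return rxn_id in self.intervals


@dataclass
class PhasePlane:
    rxn_a: str
    rxn_b: str
    a_values: np.ndarray
    b_values: np.ndarray
    mu: np.ndarray  # shape (len(a), len(b))
    phase: np.ndarray  # 1 optimal-growth, 2 growth-penalised, 3 infeasible
    mu_unconstrained: float


# ---------------------------------------------------------------------------
# problem assembly


def _assemble(
    model: MetabolicModel,
    medium: Optional[Medium],
    bounds_override: Optional[Mapping[str, Tuple[float, float]]] = None,
):
    S, met_ids, rxn_ids = model.stoichiometric_matrix()
    lb = np.array([model.reactions[r].lower_bound for r in rxn_ids])
    ub = np.array([model.reactions[r].upper_bound for r in rxn_ids])
    if medium is not None:
        medium.validate_against(model)
        exchange = set(model.exchanges)
        for j, rid in enumerate(rxn_ids):
            if rid in exchange:
                lb[j] = -medium.uptake_bound(rid)
    if bounds_override:
        idx = {r: j for j, r in enumerate(rxn_ids)}
        for rid, (lo, hi) in bounds_override.items():
            if rid not in idx:
                raise ModelError(f"unknown reaction {rid!r} in bounds override")
            lb[idx[rid]], ub[idx[rid]] = lo, hi
    return S, lb, ub, rxn_ids


def _objective_vector(rxn_ids: Sequence[str], objective: str) -> np.ndarray:
    if objective not in rxn_ids:
        raise ModelError(f"objective reaction {objective!r} not in model")
    c = np.zeros(len(rxn_ids))
    c[rxn_ids.index(objective)] = 1.0
    return c


def _resolve_objective(model: MetabolicModel, objective: Optional[str]) -> str:
    if objective is not None:
        return objective
    if model.biomass_reaction_id is None:
        raise ModelError("no objective given and model has no biomass reaction")
    return model.biomass_reaction_id


# ---------------------------------------------------------------------------
# FBA


def fba(
    model: MetabolicModel,
    medium: Optional[Medium] = None,
    objective: Optional[str] = None,
    bounds_override: Optional[Mapping[str, Tuple[float, float]]] = None,
) -> FluxSolution:
    """Maximise the objective flux subject to steady state and bounds."""
    objective = _resolve_objective(model, objective)
    S, lb, ub, rxn_ids = _assemble(model, medium, bounds_override)
    c = _objective_vector(rxn_ids, objective)
    res = solve_lp(c, lb, ub, A_eq=S, b_eq=np.zeros(S.shape[0]))
    if not res.optimal:
        return FluxSolution(res.status, objective_id=objective)
    return FluxSolution(
        "optimal",
        objective_id=objective,
        objective_value=res.objective,
        fluxes=dict(zip(rxn_ids, res.x)),
    )


# ---------------------------------------------------------------------------
# FVA


def _fva_arrays(S, lb, ub, rxn_ids, objective, fraction, reactions):
    """Shared FVA scaffolding: returns (A_ub, b_ub, target indices)."""
    c = _objective_vector(rxn_ids, objective)
    base = solve_lp(c, lb, ub, A_eq=S, b_eq=np.zeros(S.shape[0]))
    if not base.optimal:
        raise ModelError(f"FVA: base FBA is {base.status}")
    A_ub = -c[None, :]
    b_ub = np.array([-fraction * base.objective])
    targets = rxn_ids if reactions is None else list(reactions)
    return A_ub, b_ub, targets, base.objective


def fva(
    model: MetabolicModel,
    medium: Optional[Medium] = None,
    objective: Optional[str] = None,
    fraction_of_optimum: float = 1.0,
    reactions: Optional[Iterable[str]] = None,
    bounds_override: Optional[Mapping[str, Tuple[float, float]]] = None,
) -> FluxInterval:
    """Min and max flux per reaction subject to objective >= fraction * optimum."""
    objective = _resolve_objective(model, objective)
    S, lb, ub, rxn_ids = _assemble(model, medium, bounds_override)
    A_ub, b_ub, targets, _ = _fva_arrays(
        S, lb, ub, rxn_ids, objective, fraction_of_optimum, reactions
    )
    zeros = np.zeros(S.shape[0])
    intervals = {}
    for rid in targets:
        cj = _objective_vector(rxn_ids, rid)
        lo = solve_lp(cj, lb, ub, A_eq=S, b_eq=zeros, A_ub=A_ub, b_ub=b_ub, maximize=False)
        hi = solve_lp(cj, lb, ub, A_eq=S, b_eq=zeros, A_ub=A_ub, b_ub=b_ub, maximize=True)
        if not (lo.optimal and hi.optimal):
            raise ModelError(f"FVA subproblem for {rid} was {lo.status}/{hi.status}")
        intervals[rid] = (lo.objective, hi.objective)
    return FluxInterval(intervals, fraction_of_optimum, loopless=False)


def _internal_nullspace(S, rxn_ids, exchanges):
    internal = [j for j, r in enumerate(rxn_ids) if r not in exchanges]
    if not internal:
        return internal, None
    N = null_space(S[:, internal])
    if N.size == 0 or N.shape[1] == 0:
        return internal, None
    return internal, N


def loopless_fva(
    model: MetabolicModel,
    medium: Optional[Medium] = None,
    objective: Optional[str] = None,
    fraction_of_optimum: float = 1.0,
    reactions: Optional[Iterable[str]] = None,
    bounds_override: Optional[Mapping[str, Tuple[float, float]]] = None,
    big_m: float = DEFAULT_BOUND,
) -> FluxInterval:
    """FVA excluding thermodynamically infeasible internal cycles.

    Uses the mixed-integer loop-law formulation: each internal reaction i
    gets a binary direction indicator a_i and a "potential" G_i constrained
    to oppose the flux direction; G must be orthogonal to the nullspace of
    the internal stoichiometry, which forbids net flux around any closed
    internal cycle.  Exchange reactions cannot participate in loops.  On
    networks whose internal nullspace is trivial (acyclic flux space) this
    reduces exactly to plain FVA.
    """
    objective = _resolve_objective(model, objective)
    S, lb, ub, rxn_ids = _assemble(model, medium, bounds_override)
    internal, N = _internal_nullspace(S, rxn_ids, set(model.exchanges))
    if N is None:
        out = fva(
            model, medium, objective, fraction_of_optimum, reactions, bounds_override
        )
        out.loopless = True
        return out

    n = len(rxn_ids)
    p = len(internal)
    K = big_m
    # variable layout: [v (n), a (p, binary), G (p)]
    nvar = n + 2 * p
    A_ub, b_ub, targets, _ = _fva_arrays(
        S, lb, ub, rxn_ids, objective, fraction_of_optimum, reactions
    )

    lo = np.concatenate([lb, np.zeros(p), -K * np.ones(p)])
    hi = np.concatenate([ub, np.ones(p), K * np.ones(p)])
    integrality = np.concatenate([np.zeros(n), np.ones(p), np.zeros(p)])

    A_eq = np.zeros((S.shape[0] + N.shape[1], nvar))
    A_eq[: S.shape[0], :n] = S
    for k in range(N.shape[1]):
        for t, j in enumerate(internal):
            A_eq[S.shape[0] + k, n + p + t] = N[t, k]
    b_eq = np.zeros(A_eq.shape[0])

    rows = []
    rhs = []
    # objective-fraction constraint (pad to full variable width)
    pad = np.zeros((A_ub.shape[0], nvar))
    pad[:, :n] = A_ub
    rows.append(pad)
    rhs.append(b_ub)
    blk = np.zeros((4 * p, nvar))
    brhs = np.zeros(4 * p)
    for t, j in enumerate(internal):
        # v_j <= M a_t         ;  -v_j <= M (1 - a_t)
        blk[4 * t, j] = 1.0
        blk[4 * t, n + t] = -big_m
        blk[4 * t + 1, j] = -1.0
        blk[4 * t + 1, n + t] = big_m
        brhs[4 * t + 1] = big_m
        # a=1 -> G <= -1 ; a=0 -> G <= K    : G + (K+1) a <= K
        blk[4 * t + 2, n + p + t] = 1.0
        blk[4 * t + 2, n + t] = K + 1
        brhs[4 * t + 2] = K
        # a=0 -> G >= 1 ; a=1 -> G >= -K   : -G - (K+1) a <= -1
        blk[4 * t + 3, n + p + t] = -1.0
        blk[4 * t + 3, n + t] = -(K + 1)
        brhs[4 * t + 3] = -1.0
    rows.append(blk)
    rhs.append(brhs)
    A_ub_full = np.vstack(rows)
    b_ub_full = np.concatenate(rhs)

    intervals = {}
    unresolved = set()
    for rid in targets:
        cj = np.zeros(nvar)
        cj[rxn_ids.index(rid)] = 1.0
        res_lo = solve_milp(
            cj, lo, hi, integrality, A_eq=A_eq, b_eq=b_eq,
            A_ub=A_ub_full, b_ub=b_ub_full, maximize=False,
        )
        res_hi = solve_milp(
            cj, lo, hi, integrality, A_eq=A_eq, b_eq=b_eq,
            A_ub=A_ub_full, b_ub=b_ub_full, maximize=True,
        )
        if res_lo.optimal and res_hi.optimal:
            intervals[rid] = (res_lo.objective, res_hi.objective)
        else:
            unresolved.add(rid)
    return FluxInterval(intervals, fraction_of_optimum, loopless=True, unresolved=unresolved)


# ---------------------------------------------------------------------------
# MOMA


def moma(
    model: MetabolicModel,
    wildtype: FluxSolution,
    disabled_reactions: Iterable[str],
    medium: Optional[Medium] = None,
) -> FluxSolution:
    """Minimisation of metabolic adjustment.

    Among flux vectors feasible for the knockout (disabled reactions fixed
    to zero), returns the one minimising the squared Euclidean distance to
    the wild-type distribution, and reports the growth rate it realises.
    """
    if not wildtype.optimal:
        raise ModelError("MOMA requires an optimal wild-type solution")
    disabled = {rid: (0.0, 0.0) for rid in disabled_reactions}
    S, lb, ub, rxn_ids = _assemble(model, medium, disabled)
    w = np.array([wildtype.fluxes[r] for r in rxn_ids])

    feas = solve_lp(np.zeros(len(rxn_ids)), lb, ub, A_eq=S, b_eq=np.zeros(S.shape[0]))
    if not feas.optimal:
        return FluxSolution("infeasible", objective_id=wildtype.objective_id)

    def fun(v):
        d = v - w
        return float(d @ d)

    def jac(v):
        return 2.0 * (v - w)

    x0 = np.clip(w, lb, ub)
    cons = [{"type": "eq", "fun": lambda v: S @ v, "jac": lambda v: S}]
    bnds = list(zip(lb, ub))
    res = minimize(
        fun, x0, jac=jac, bounds=bnds, constraints=cons, method="SLSQP",
        options={"maxiter": 1000, "ftol": 1e-12},
    )
    if (not res.success) or np.max(np.abs(S @ res.x)) > 1e-5:
        res = minimize(fun, feas.x, jac=jac, bounds=bnds, constraints=cons,
                       method="SLSQP", options={"maxiter": 2000, "ftol": 1e-12})
    if not res.success:
        return FluxSolution("failed", objective_id=wildtype.objective_id)
    v = res.x
    obj_id = wildtype.objective_id
    mu = v[rxn_ids.index(obj_id)] if obj_id in rxn_ids else None
    return FluxSolution("optimal", objective_id=obj_id, objective_value=mu,
                        fluxes=dict(zip(rxn_ids, v)))


# ---------------------------------------------------------------------------
# derived quantities


def respiratory_quotient(sol: FluxSolution, co2_exchange: str, o2_exchange: str) -> float:
    """CO2 secretion flux divided by O2 uptake magnitude (dimensionless)."""
    o2_uptake = -sol.fluxes[o2_exchange]
    if o2_uptake <= FLUX_TOL:
        raise ValueError("respiratory quotient undefined: no oxygen uptake")
    return sol.fluxes[co2_exchange] / o2_uptake


def product_yield(
    sol: FluxSolution,
    product_exchange: str,
    substrate_exchange: str,
    product_molar_mass: float,
    substrate_molar_mass: float,
) -> float:
    """Mass yield (g product per g substrate) from exchange fluxes."""
    uptake = -sol.fluxes[substrate_exchange]
    if uptake <= FLUX_TOL:
        raise ValueError("yield undefined: no substrate uptake")
    return (sol.fluxes[product_exchange] * product_molar_mass) / (
        uptake * substrate_molar_mass
    )


def viability_screen(
    model: MetabolicModel,
    carbon_sources: Sequence[Tuple[str, float]],
    oxygen_regimes: Sequence[str] = ("aerobic", "anaerobic"),
    base_medium: Optional[Medium] = None,
    o2_exchange: str = "EX_o2_e",
    fraction_of_optimum: float = 0.9,
) -> pd.DataFrame:
    """Growth screen over carbon sources and aeration regimes.

    Each row gets the FBA growth rate plus the FVA range of the objective
    at the given optimality fraction; viability means mu > 1e-6/h.
    Unknown exchange ids are reported per-row and do not abort the screen.
    """
    base = base_medium or Medium("base")
    rows = []
    for ex_id, uptake in carbon_sources:
        for regime in oxygen_regimes:
            row = {"carbon_source": ex_id, "regime": regime, "mu": np.nan,
                   "mu_min": np.nan, "mu_max": np.nan, "viable": False, "error": ""}
            if ex_id not in model.reactions or ex_id not in model.exchanges:
                row["error"] = f"unknown exchange reaction {ex_id!r}"
                rows.append(row)
                continue
            limits = dict(base.uptake_limits)
            limits[ex_id] = uptake
            limits[o2_exchange] = OXYGEN_REGIMES[regime]
            medium = Medium(f"{ex_id}_{regime}", limits, set(base.unrestricted))
            sol = fba(model, medium)
            if not sol.optimal:
                row["error"] = sol.status
                rows.append(row)
                continue
            row["mu"] = sol.objective_value
            if sol.objective_value > FLUX_TOL:
                rng = fva(model, medium, reactions=[sol.objective_id],
                          fraction_of_optimum=fraction_of_optimum)
                row["mu_min"], row["mu_max"] = rng[sol.objective_id]
            else:
                row["mu_min"] = row["mu_max"] = sol.objective_value
            row["viable"] = sol.objective_value > FLUX_TOL
            rows.append(row)
    return pd.DataFrame(rows)


def biomass_sensitivity(
    model: MetabolicModel,
    medium: Optional[Medium] = None,
    relative_perturbation: float = 0.5,
) -> pd.DataFrame:
    """Growth response to +/- perturbation of each biomass precursor coefficient.

    Each biomass substrate coefficient is scaled by (1 +/- f) in turn with a
    fresh FBA per perturbation; the model is never mutated (a copy is used).
    """
    if not 0 <= relative_perturbation <= 1:
        raise ValueError("relative perturbation must lie in [0, 1]")
    biomass = model.biomass_reaction
    substrates = [m for m, c in biomass.stoichiometry.items() if c < 0]
    if not substrates:
        raise ModelError("biomass reaction has no substrates")
    base = fba(model, medium)
    if not base.optimal:
        raise ModelError("biomass sensitivity: base FBA not optimal")
    rows = []
    for met in substrates:
        work = model.copy()
        coeff = work.biomass_reaction.stoichiometry[met]
        mus = {}
        for sign, factor in (("minus", 1 - relative_perturbation),
                             ("plus", 1 + relative_perturbation)):
            work.biomass_reaction.stoichiometry[met] = coeff * factor
            sol = fba(work, medium)
            mus[sign] = sol.objective_value if sol.optimal else 0.0
            work.biomass_reaction.stoichiometry[met] = coeff
        rows.append({
            "metabolite": met, "coefficient": -coeff, "mu_base": base.objective_value,
            "mu_minus": mus["minus"], "mu_plus": mus["plus"],
            "delta_minus": mus["minus"] - base.objective_value,
            "delta_plus": mus["plus"] - base.objective_value,
        })
    df = pd.DataFrame(rows)
    # most sensitive first: largest |mu response| to the perturbation
    df["sensitivity"] = np.maximum(df.delta_minus.abs(), df.delta_plus.abs())
    return df.sort_values("sensitivity", ascending=False).reset_index(drop=True)


def phenotypic_phase_plane(
    model: MetabolicModel,
    medium: Optional[Medium],
    rxn_a: str,
    rxn_b: str,
    grid: int = 10,
    max_a: Optional[float] = None,
    max_b: Optional[float] = None,
    optimal_fraction: float = 0.99,
) -> PhasePlane:
    """Max growth over a grid of fixed production fluxes of two reactions.

    Phase 1: mu >= optimal_fraction * unconstrained optimum; phase 3:
    infeasible or mu below tolerance; phase 2: growth-penalised region in
    between.
    """
    base = fba(model, medium)
    if not base.optimal:
        raise ModelError("phase plane: unconstrained FBA not optimal")
    mu0 = base.objective_value

    def axis_max(rid):
        sol = fba(model, medium, objective=rid)
        if not sol.optimal or sol.objective_value <= FLUX_TOL:
            return 1.0
        return sol.objective_value

    a_hi = max_a if max_a is not None else axis_max(rxn_a)
    b_hi = max_b if max_b is not None else axis_max(rxn_b)
    a_vals = np.linspace(0.0, a_hi, grid)
    b_vals = np.linspace(0.0, b_hi, grid)
    mu = np.zeros((grid, grid))
    phase = np.zeros((grid, grid), dtype=int)
    for i, a in enumerate(a_vals):
        for j, b in enumerate(b_vals):
            sol = fba(model, medium,
                      bounds_override={rxn_a: (a, a), rxn_b: (b, b)})
            if not sol.optimal:
                mu[i, j] = np.nan
                phase[i, j] = 3
                continue
            mu[i, j] = sol.objective_value
            if sol.objective_value < FLUX_TOL:
                phase[i, j] = 3
            elif sol.objective_value >= optimal_fraction * mu0:
                phase[i, j] = 1
            else:
                phase[i, j] = 2
    return PhasePlane(rxn_a, rxn_b, a_vals, b_vals, mu, phase, mu0)
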