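"""Dynamic FBA: batch-fermentation simulation by iterated FBA.

The static-optimisation DFBA scheme: at each sampling interval an FBA is
solved with the current exchange bounds, the uptake/secretion fluxes are
held constant over the interval, and biomass and extracellular
concentrations are updated with the exponential solution of

    dX/dt = mu X,      dC/dt = v_EX * m * X

giving

    X(t+dt) = X(t) * exp(mu dt)
    C(t+dt) = C(t) - v_EX * m * X(t) * (1 - exp(mu dt)) / mu

with v_EX in mmol/gDW/h (uptake negative, so an uptake flux depletes the
pool), m the molar mass in g/mmol (g/mol / 1000) and concentrations in
g/L.  At mu = 0 the analytic limit C(t+dt) = C(t) + v_EX * m * X * dt is
used.  Once the primary substrate is exhausted, exchange bounds of
re-consumable products (e.g. ethanol) are opened for uptake so diauxic
growth can occur.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .fba import fba
from .model import Medium, MetabolicModel, ModelError
from .solver import FLUX_TOL, solve_lp

__all__ = ["TrackedSpecies", "DfbaParams", "BatchTrajectory",
           "step_update", "availability_bound", "simulate_batch"]

_MU_LIMIT = 1e-9  # below this, use the mu -> 0 limit of the update
_EXHAUSTED = 1e-6  # g/L; pool considered empty


@dataclass
class TrackedSpecies:
    name: str
    exchange_id: str
    molar_mass: float  # g/mol
    initial_concentration: float = 0.0  # g/L
    reconsume: bool = False  # open for uptake after primary substrate runs out


@dataclass
class DfbaParams:
    """Batch-culture set-up.

    Defaults follow a 20 g/L glucose batch inoculated at 0.05 g/L biomass,
    simulated for 50 h at a 0.5 h sampling interval.
    """

    substrate: TrackedSpecies
    products: List[TrackedSpecies] = field(default_factory=list)
    initial_biomass: float = 0.05  # g/L
    total_time: float = 50.0  # h
    sampling_interval: float = 0.5  # h
    substrate_uptake_bound: float = 2.28  # mmol/gDW/h
    oxygen_uptake_bound: float = 1000.0  # mmol/gDW/h
    oxygen_exchange: str = "EX_o2_e"
    base_medium: Optional[Medium] = None
    secondary_objective: Optional[str] = None  # exchange maximised at fixed mu

    def __post_init__(self):
        if self.sampling_interval <= 0 or self.sampling_interval > self.total_time:
            raise ModelError("need 0 < sampling_interval <= total_time")
        if self.initial_biomass <= 0 or self.substrate.initial_concentration <= 0:
            raise ModelError("initial biomass and substrate must be positive")


@dataclass
class BatchTrajectory:
    series: pd.DataFrame  # t, X, mu + one column per tracked species (g/L)
    fluxes: pd.DataFrame  # realised exchange fluxes per step (mmol/gDW/h)
    clamping_events: List[Tuple[float, str, float]] = field(default_factory=list)
    infeasible_steps: List[float] = field(default_factory=list)

    @property
    def final_biomass(self) -> float:
        return float(self.series["X"].iloc[-1])


def step_update(
    X: float,
    concentrations: Dict[str, float],
    exchange_fluxes: Dict[str, float],
    dt: float,
    molar_masses: Dict[str, float],
    mu: float,
) -> Tuple[float, Dict[str, float], List[Tuple[str, float]]]:
    """One exponential update step; returns (X', concentrations', clamps).

    Concentrations are clamped at zero; any overshoot is returned in
    ``clamps`` as (species, overshoot magnitude in g/L) rather than
    silently dropped.
    """
    if dt <= 0:
        raise ModelError("step_update needs dt > 0")
    X_new = X * math.exp(mu * dt)
    if abs(mu) > _MU_LIMIT:
        growth_factor = (math.exp(mu * dt) - 1.0) / mu
    else:
        growth_factor = dt
    new_conc = {}
    clamps = []
    for species, conc in concentrations.items():
        v = exchange_fluxes.get(species, 0.0)
        m = molar_masses[species] / 1000.0  # g/mmol
        c = conc + v * m * X * growth_factor
        if c < 0:
            clamps.append((species, -c))
            c = 0.0
        new_conc[species] = c
    return X_new, new_conc, clamps


def availability_bound(
    concentration: float, X: float, dt: float, molar_mass: float,
    kinetic_bound: float,
) -> float:
    """Largest uptake magnitude (mmol/gDW/h) that cannot overdraw the pool in dt.

    Inverts the update equation at the worst case mu = 0 (constant draw):
    a full-interval uptake v empties a pool of size C when
    v * (molar_mass/1000) * X * dt = C.
    """
    if X <= 0 or concentration <= 0:
        return 0.0
    max_draw = concentration / (molar_mass / 1000.0 * X * dt)
    return min(kinetic_bound, max_draw)


def _secondary_optimise(model, medium, overrides, sol, secondary):
    """Re-solve at (almost) fixed optimal mu, maximising a secondary exchange flux."""
    from .fba import _assemble, _objective_vector

    S, lb, ub, rxn_ids = _assemble(model, medium, overrides)
    c_obj = _objective_vector(rxn_ids, sol.objective_id)
    c_sec = _objective_vector(rxn_ids, secondary)
    A_ub = -c_obj[None, :]
    b_ub = np.array([-(sol.objective_value * (1 - 1e-9) - 1e-12)])
    res = solve_lp(c_sec, lb, ub, A_eq=S, b_eq=np.zeros(S.shape[0]),
                   A_ub=A_ub, b_ub=b_ub, maximize=True)
    if res.optimal:
        return dict(zip(rxn_ids, res.x))
    return sol.fluxes


def simulate_batch(model: MetabolicModel, params: DfbaParams) -> BatchTrajectory:
    """Iterate FBA + exponential updates over the sampling grid.

    An infeasible FBA step is continued as a stationary (mu = 0, zero
    exchange) interval and flagged in ``infeasible_steps``.
    """
    sub = params.substrate
    tracked = [sub] + list(params.products)
    conc = {sp.name: sp.initial_concentration for sp in tracked}
    masses = {sp.name: sp.molar_mass for sp in tracked}
    ex_of = {sp.name: sp.exchange_id for sp in tracked}
    base = params.base_medium or Medium("dfba_base")

    X = params.initial_biomass
    dt = params.sampling_interval
    n_steps = int(round(params.total_time / dt))
    t = 0.0
    rows = [{"t": t, "X": X, "mu": np.nan, **conc}]
    flux_rows = []
    clamp_log: List[Tuple[float, str, float]] = []
    infeasible: List[float] = []

    for _ in range(n_steps):
        limits = dict(base.uptake_limits)
        limits[params.oxygen_exchange] = params.oxygen_uptake_bound
        limits[sub.exchange_id] = availability_bound(
            conc[sub.name], X, dt, sub.molar_mass, params.substrate_uptake_bound
        )
        substrate_left = conc[sub.name] > _EXHAUSTED
        for sp in params.products:
            if sp.reconsume and not substrate_left:
                limits[sp.exchange_id] = availability_bound(
                    conc[sp.name], X, dt, sp.molar_mass, params.substrate_uptake_bound
                )
            else:
                limits[sp.exchange_id] = 0.0
        medium = Medium("dfba_step", limits, set(base.unrestricted))

        sol = fba(model, medium)
        if sol.optimal and sol.objective_value > FLUX_TOL:
            mu = sol.objective_value
            fluxes = sol.fluxes
            if params.secondary_objective is not None:
                fluxes = _secondary_optimise(model, medium, None, sol,
                                             params.secondary_objective)
        else:
            mu = 0.0
            fluxes = {}
            if not sol.optimal:
                infeasible.append(t)

        ex_fluxes = {name: fluxes.get(ex, 0.0) for name, ex in ex_of.items()}
        X, conc, clamps = step_update(X, conc, ex_fluxes, dt, masses, mu)
        for species, overshoot in clamps:
            clamp_log.append((t, species, overshoot))
        t += dt
        rows.append({"t": t, "X": X, "mu": mu, **conc})
        flux_rows.append({"t": t - dt, "mu": mu,
                          **{ex: fluxes.get(ex, 0.0) for ex in ex_of.values()}})

    return BatchTrajectory(pd.DataFrame(rows), pd.DataFrame(flux_rows),
                           clamp_log, infeasible)
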