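"""Model curation operators.

The operators mirror the manual curation steps applied to a draft
reconstruction: elemental/charge balance checks, directionality rules for
thermodynamically irreversible reaction classes, blocked-reaction
detection, biomass-precursor producibility, confidence scoring and
whole-pathway insertion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .fba import FluxSolution, fba, _assemble
from .model import Medium, MetabolicModel, ModelError, PathwaySpec, Reaction
from .solver import FLUX_TOL, solve_lp

__all__ = [
    "check_mass_charge_balance",
    "SpeciesRoles",
    "assign_reversibility",
    "find_blocked_reactions",
    "InfeasibleMediumError",
    "check_biomass_precursors",
    "assign_confidence",
    "add_pathway",
]


def check_mass_charge_balance(model: MetabolicModel) -> pd.DataFrame:
    """Elemental and charge residuals per reaction.

    A reaction is ``balanced`` iff every element (including the conserved
    alkyl pseudo-element "R") and the total charge sum to zero across its
    stoichiometry.  Exchange/sink reactions (single-metabolite boundary
    reactions) and the biomass pseudo-reaction are ``exempt``.  Reactions
    touching a metabolite without formula or charge are ``uncheckable``,
    never reported unbalanced.
    """
    exempt = set(model.exchanges)
    if model.biomass_reaction_id is not None:
        exempt.add(model.biomass_reaction_id)
    rows = []
    for rid, rxn in model.reactions.items():
        if rid in exempt:
            rows.append({"reaction_id": rid, "status": "exempt",
                         "element_residuals": {}, "charge_residual": 0.0})
            continue
        residual: Dict[str, float] = {}
        charge = 0.0
        checkable = True
        for met_id, coeff in rxn.stoichiometry.items():
            met = model.metabolites[met_id]
            if met.formula is None or met.charge is None:
                checkable = False
                break
            for el, n in met.formula.items():
                residual[el] = residual.get(el, 0.0) + coeff * n
            charge += coeff * met.charge
        if not checkable:
            rows.append({"reaction_id": rid, "status": "uncheckable",
                         "element_residuals": {}, "charge_residual": np.nan})
            continue
        residual = {el: v for el, v in residual.items() if abs(v) > 1e-9}
        ok = not residual and abs(charge) <= 1e-9
        rows.append({"reaction_id": rid,
                     "status": "balanced" if ok else "unbalanced",
                     "element_residuals": residual, "charge_residual": charge})
    return pd.DataFrame(rows)


@dataclass
class SpeciesRoles:
    """Metabolite ids (per compartment) driving the irreversibility rules."""

    atp: List[str] = field(default_factory=list)
    o2: List[str] = field(default_factory=list)
    nadh: List[str] = field(default_factory=list)
    nadph: List[str] = field(default_factory=list)

    def validate_against(self, model: MetabolicModel) -> None:
        for role in ("atp", "o2", "nadh", "nadph"):
            for mid in getattr(self, role):
                if mid not in model.metabolites:
                    raise ModelError(
                        f"reversibility rule species {mid!r} ({role}) absent from model"
                    )


def assign_reversibility(
    model: MetabolicModel,
    roles: SpeciesRoles,
    template_map: Optional[Mapping[str, Tuple[float, float]]] = None,
) -> Tuple[MetabolicModel, pd.DataFrame]:
    """Directionality curation: template bounds first, then three rules.

    Reactions (1) consuming ATP, (2) producing oxygen, or (3) involving
    NADH/NADPH are made irreversible in their annotated forward direction
    (lower bound 0).  Template-mapped reactions take the template bounds
    verbatim and are not rule-checked.  Exchange and biomass reactions are
    never touched.  Returns the curated copy and a change log
    (reaction_id, rule, old_lb, new_lb).  Idempotent.
    """
    roles.validate_against(model)
    out = model.copy()
    exempt = set(out.exchanges)
    if out.biomass_reaction_id:
        exempt.add(out.biomass_reaction_id)
    log = []
    template_map = dict(template_map or {})
    for rid, rxn in out.reactions.items():
        if rid in exempt:
            continue
        if rid in template_map:
            lb, ub = template_map[rid]
            if (lb, ub) != rxn.bounds:
                log.append({"reaction_id": rid, "rule": "template",
                            "old_lb": rxn.lower_bound, "new_lb": lb})
                rxn.bounds = (lb, ub)
            continue
        rule = None
        stoich = rxn.stoichiometry
        if any(stoich.get(m, 0) < 0 for m in roles.atp):
            rule = "atp_reactant"
        elif any(stoich.get(m, 0) > 0 for m in roles.o2):
            rule = "o2_product"
        elif any(stoich.get(m, 0) != 0 for m in roles.nadh + roles.nadph):
            rule = "nadh_nadph"
        if rule is not None and rxn.lower_bound < 0:
            log.append({"reaction_id": rid, "rule": rule,
                        "old_lb": rxn.lower_bound, "new_lb": 0.0})
            rxn.lower_bound = 0.0
    return out, pd.DataFrame(log, columns=["reaction_id", "rule", "old_lb", "new_lb"])


class InfeasibleMediumError(ModelError):
    """The medium admits no steady-state flux distribution at all."""


def find_blocked_reactions(model: MetabolicModel, medium: Optional[Medium] = None) -> set:
    """Reactions whose min and max achievable flux under the medium are both 0."""
    S, lb, ub, rxn_ids = _assemble(model, medium)
    zeros = np.zeros(S.shape[0])
    feas = solve_lp(np.zeros(len(rxn_ids)), lb, ub, A_eq=S, b_eq=zeros)
    if not feas.optimal:
        raise InfeasibleMediumError(
            f"medium {(medium.name if medium else 'default')!r} is infeasible"
        )
    blocked = set()
    for j, rid in enumerate(rxn_ids):
        c = np.zeros(len(rxn_ids))
        c[j] = 1.0
        hi = solve_lp(c, lb, ub, A_eq=S, b_eq=zeros, maximize=True)
        if hi.optimal and hi.objective > FLUX_TOL:
            continue
        lo = solve_lp(c, lb, ub, A_eq=S, b_eq=zeros, maximize=False)
        if lo.optimal and lo.objective < -FLUX_TOL:
            continue
        blocked.add(rid)
    return blocked


def check_biomass_precursors(
    model: MetabolicModel, medium: Optional[Medium] = None
) -> pd.DataFrame:
    """Producibility of each biomass substrate under the medium.

    A precursor is producible iff a temporary demand objective on it
    attains flux above tolerance.  While probing, the biomass reaction's
    product metabolites (the spent forms: ADP, Pi, protons...) are made
    freely available through reversible sinks — currency couples like
    ATP/ADP are moiety-conserved, so the charged form can only be drained
    if the spent form may re-enter the network.
    """
    biomass = model.biomass_reaction
    substrates = [m for m, c in biomass.stoichiometry.items() if c < 0]
    products = [m for m, c in biomass.stoichiometry.items() if c > 0]
    rows = []
    for met in substrates:
        work = model.copy()
        demand_id = f"DM_{met}__probe"
        probes = [Reaction(demand_id, stoichiometry={met: -1.0},
                           lower_bound=0.0, upper_bound=1000.0)]
        probes += [Reaction(f"SK_{p}__probe", stoichiometry={p: -1.0},
                            lower_bound=-1000.0, upper_bound=1000.0)
                   for p in products if p != met]
        work.add_reactions(probes)
        # the probe reactions are boundary reactions; shield them from the
        # medium's closed-uptake default
        keep_open = {r.id: r.bounds for r in probes}
        sol = fba(work, medium, objective=demand_id, bounds_override=keep_open)
        flux = sol.objective_value if sol.optimal else 0.0
        rows.append({"metabolite": met, "producible": flux > FLUX_TOL,
                     "max_demand_flux": flux})
    return pd.DataFrame(rows)


def assign_confidence(
    model: MetabolicModel, reference_flux: FluxSolution
) -> MetabolicModel:
    """Confidence scores from GPR presence and flux in a reference solution.

    4: GPR and significant flux (also exchanges carrying flux on the
    defined medium); 3: flux without GPR (internal reactions); 2: GPR
    without flux; 1: neither.
    """
    if not reference_flux.optimal:
        raise ModelError("confidence scoring needs an optimal reference flux")
    out = model.copy()
    exchanges = set(out.exchanges)
    for rid, rxn in out.reactions.items():
        has_flux = abs(reference_flux.fluxes.get(rid, 0.0)) > FLUX_TOL
        has_gpr = rxn.gpr is not None
        if has_gpr and has_flux:
            rxn.confidence = 4
        elif rid in exchanges and has_flux:
            rxn.confidence = 4  # exchange required on the defined medium
        elif has_flux:
            rxn.confidence = 3
        elif has_gpr:
            rxn.confidence = 2
        else:
            rxn.confidence = 1
    return out


def add_pathway(model: MetabolicModel, spec: PathwaySpec) -> MetabolicModel:
    """Insert a pathway (metabolites + reactions) as a unit, preserving invariants."""
    for m in spec.metabolites:
        if m.id in model.metabolites:
            raise ModelError(f"pathway {spec.name}: metabolite id collision {m.id!r}")
    for r in spec.reactions:
        if r.id in model.reactions:
            raise ModelError(f"pathway {spec.name}: reaction id collision {r.id!r}")
    out = model.copy()
    out.add_metabolites(spec.metabolites)
    out.add_reactions(spec.reactions)
    out.validate()
    return out
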