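"""Core data structures: metabolites, reactions, models, media, pathway specs.

Conventions used throughout the package:

* exchange fluxes follow the standard constraint-based sign convention —
  uptake is negative, secretion positive; a medium "uptake rate u" on an
  exchange reaction sets its lower bound to ``-u``;
* the default unconstrained flux magnitude is 1000 mmol/gDW/h;
* a reaction is an exchange iff its stoichiometry touches exactly one
  metabolite (boundary drains/sources);
* an empty GPR means "always catalysed" (spontaneous or orphan reaction).
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .gpr import Gpr, parse_gpr

__all__ = [
    "DEFAULT_BOUND",
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "Medium",
    "PathwaySpec",
    "ModelError",
]

DEFAULT_BOUND = 1000.0


class ModelError(ValueError):
    """Raised on model invariant violations (duplicate ids, dangling refs...)."""


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"
    formula: Optional[Dict[str, int]] = None  # element -> count; "R" allowed
    charge: Optional[int] = None

    def __post_init__(self):
        if self.formula is not None:
            for el, n in self.formula.items():
                if n < 0:
                    raise ModelError(f"negative {el} count in formula of {self.id}")

    def formula_string(self) -> Optional[str]:
        if self.formula is None:
            return None
        return "".join(
            f"{el}{'' if n == 1 else n}" for el, n in sorted(self.formula.items()) if n
        )


@dataclass
class Reaction:
    id: str
    name: str = ""
    stoichiometry: Dict[str, float] = field(default_factory=dict)
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    gpr: Optional[Gpr] = None
    subsystem: str = ""
    confidence: Optional[int] = None

    def __post_init__(self):
        if isinstance(self.gpr, str):
            self.gpr = parse_gpr(self.gpr)
        if self.lower_bound > self.upper_bound:
            raise ModelError(
                f"reaction {self.id}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0

    @property
    def bounds(self) -> Tuple[float, float]:
        return (self.lower_bound, self.upper_bound)

    @bounds.setter
    def bounds(self, lb_ub: Tuple[float, float]):
        lb, ub = lb_ub
        if lb > ub:
            raise ModelError(f"reaction {self.id}: invalid bounds ({lb}, {ub})")
        self.lower_bound, self.upper_bound = float(lb), float(ub)

    @property
    def genes(self) -> frozenset:
        return self.gpr.genes if self.gpr is not None else frozenset()

    def gpr_string(self) -> str:
        return self.gpr.to_string() if self.gpr is not None else ""


class MetabolicModel:
    """A genome-scale (or toy) metabolic model.

    Holds compartments, metabolites, reactions (with stoichiometry, bounds
    and GPRs) and the id of the biomass objective reaction.  The gene list
    is the union of GPR leaves plus any explicitly registered genes.
    """

    def __init__(
        self,
        model_id: str = "model",
        name: str = "",
        compartments: Optional[Dict[str, str]] = None,
    ):
        self.id = model_id
        self.name = name or model_id
        self.compartments: Dict[str, str] = dict(compartments or {})
        self.metabolites: Dict[str, Metabolite] = {}
        self.reactions: Dict[str, Reaction] = {}
        self.biomass_reaction_id: Optional[str] = None
        self._extra_genes: set = set()

    # -- construction ------------------------------------------------------

    def add_metabolites(self, mets: Iterable[Metabolite]) -> None:
        for m in mets:
            if m.id in self.metabolites:
                raise ModelError(f"duplicate metabolite id {m.id!r}")
            self.compartments.setdefault(m.compartment, m.compartment)
            self.metabolites[m.id] = m

    def add_reactions(self, rxns: Iterable[Reaction]) -> None:
        rxns = list(rxns)
        for r in rxns:
            if r.id in self.reactions:
                raise ModelError(f"duplicate reaction id {r.id!r}")
            for met_id in r.stoichiometry:
                if met_id not in self.metabolites:
                    raise ModelError(
                        f"reaction {r.id} references unknown metabolite {met_id!r}"
                    )
        for r in rxns:
            self.reactions[r.id] = r

    def register_genes(self, genes: Iterable[str]) -> None:
        self._extra_genes.update(genes)

    def remove_reactions(self, rxn_ids: Iterable[str], prune_orphans: bool = False) -> List[str]:
        """Remove reactions; optionally drop metabolites left without any reaction.

        Returns the ids of pruned orphan metabolites.
        """
        for rid in rxn_ids:
            self.reactions.pop(rid, None)
        orphans: List[str] = []
        if prune_orphans:
            used = set()
            for r in self.reactions.values():
                used.update(r.stoichiometry)
            orphans = [m for m in self.metabolites if m not in used]
            for m in orphans:
                del self.metabolites[m]
        return orphans

    def copy(self) -> "MetabolicModel":
        return _copy.deepcopy(self)

    # -- queries -----------------------------------------------------------

    @property
    def genes(self) -> frozenset:
        g = set(self._extra_genes)
        for r in self.reactions.values():
            g |= r.genes
        return frozenset(g)

    @property
    def exchanges(self) -> List[str]:
        """Ids of boundary reactions: stoichiometry touches exactly one metabolite."""
        return [r.id for r in self.reactions.values() if len(r.stoichiometry) == 1]

    @property
    def biomass_reaction(self) -> Reaction:
        if self.biomass_reaction_id is None:
            raise ModelError("model has no biomass reaction set")
        return self.reactions[self.biomass_reaction_id]

    def stoichiometric_matrix(self) -> Tuple[np.ndarray, List[str], List[str]]:
        """Dense S (metabolites x reactions) with row/column id orderings."""
        met_ids = list(self.metabolites)
        rxn_ids = list(self.reactions)
        met_index = {m: i for i, m in enumerate(met_ids)}
        S = np.zeros((len(met_ids), len(rxn_ids)))
        for j, rid in enumerate(rxn_ids):
            for met_id, coeff in self.reactions[rid].stoichiometry.items():
                S[met_index[met_id], j] = coeff
        return S, met_ids, rxn_ids

    def validate(self) -> None:
        """Raise ModelError on any violated model invariant."""
        if not self.reactions:
            raise ModelError("model has no reactions")
        for r in self.reactions.values():
            if r.lower_bound > r.upper_bound:
                raise ModelError(f"reaction {r.id}: inverted bounds")
            for met_id in r.stoichiometry:
                if met_id not in self.metabolites:
                    raise ModelError(
                        f"reaction {r.id} references unknown metabolite {met_id!r}"
                    )
        for m in self.metabolites.values():
            if m.compartment not in self.compartments:
                raise ModelError(
                    f"metabolite {m.id} in unknown compartment {m.compartment!r}"
                )
        if self.biomass_reaction_id is not None and (
            self.biomass_reaction_id not in self.reactions
        ):
            raise ModelError(
                f"biomass reaction {self.biomass_reaction_id!r} not in model"
            )

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<MetabolicModel {self.id}: {len(self.reactions)} reactions, "
            f"{len(self.metabolites)} metabolites, {len(self.genes)} genes, "
            f"{len(self.compartments)} compartments>"
        )


@dataclass
class Medium:
    """A named in silico growth condition.

    ``uptake_limits`` maps exchange-reaction ids to the maximum uptake
    magnitude (mmol/gDW/h); members of ``unrestricted`` are opened at the
    default bound (1000).  Exchanges not mentioned have uptake closed
    (lower bound 0); secretion bounds are never touched.
    """

    name: str = "medium"
    uptake_limits: Dict[str, float] = field(default_factory=dict)
    unrestricted: set = field(default_factory=set)

    def __post_init__(self):
        for ex, u in self.uptake_limits.items():
            if u < 0:
                raise ModelError(f"medium {self.name}: negative uptake for {ex}")

    def uptake_bound(self, exchange_id: str) -> float:
        if exchange_id in self.uptake_limits:
            return float(self.uptake_limits[exchange_id])
        if exchange_id in self.unrestricted:
            return DEFAULT_BOUND
        return 0.0

    def validate_against(self, model: MetabolicModel) -> None:
        exchanges = set(model.exchanges)
        for ex in list(self.uptake_limits) + list(self.unrestricted):
            if ex not in exchanges:
                raise ModelError(
                    f"medium {self.name}: {ex!r} is not an exchange reaction"
                )


@dataclass
class PathwaySpec:
    """A set of metabolites/reactions inserted into a model as one unit."""

    name: str
    metabolites: List[Metabolite] = field(default_factory=list)
    reactions: List[Reaction] = field(default_factory=list)
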