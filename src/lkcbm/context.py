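"""Expression-driven context-specific model extraction and comparison.

Workflow: map gene expression onto reactions through the GPRs (min over
AND, max over OR), prune low-expression reactions with GIMME while
protecting a required fraction of the parent objective, then compare two
context models by the Jaccard overlap of their (loopless) FVA intervals —
reactions whose intervals do not overlap at all (J = 0) carry
differential flux, and are ranked by parent pathway.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .fba import fba, fva, loopless_fva, _assemble, _objective_vector
from .model import Medium, MetabolicModel, ModelError
from .solver import FLUX_TOL, solve_lp

__all__ = [
    "ExpressionProfile",
    "map_expression_to_reactions",
    "ContextModel",
    "gimme",
    "interval_jaccard",
    "DifferentialFluxReport",
    "differential_flux",
    "rank_pathways",
]


@dataclass
class ExpressionProfile:
    """Normalised gene expression for one condition (higher = more expressed)."""

    condition: str
    values: Dict[str, float]

    def __post_init__(self):
        bad = [g for g, v in self.values.items() if not np.isfinite(v)]
        if bad:
            raise ValueError(f"non-finite expression for genes {bad[:5]}")

    def coverage(self, model: MetabolicModel) -> float:
        genes = model.genes
        if not genes:
            return 0.0
        return len(genes & set(self.values)) / len(genes)


def map_expression_to_reactions(
    model: MetabolicModel, profile: ExpressionProfile
) -> Dict[str, Optional[float]]:
    """Reaction expression scores via GPRs; None marks unscored reactions.

    AND nodes aggregate by minimum, OR nodes by maximum.  Reactions
    without a GPR are unscored; a measured-data gap inside an AND leaves
    the node (and possibly the reaction) unscored, with a warning.
    """
    if not profile.values:
        raise ValueError("empty expression profile")
    scores: Dict[str, Optional[float]] = {}
    gaps = []
    for rid, rxn in model.reactions.items():
        if rxn.gpr is None:
            scores[rid] = None
            continue
        s = rxn.gpr.score(profile.values)
        if s is None and rxn.genes & set(profile.values):
            gaps.append(rid)
        scores[rid] = s
    if gaps:
        warnings.warn(
            f"{len(gaps)} reactions unscored due to missing gene data "
            f"inside AND nodes (e.g. {gaps[:3]})"
        )
    return scores


@dataclass
class ContextModel:
    model: MetabolicModel
    removed_reactions: set
    pruned_metabolites: List[str]
    inconsistency_score: float
    threshold: float
    condition: str = ""


def gimme(
    model: MetabolicModel,
    scores: Mapping[str, Optional[float]],
    medium: Optional[Medium] = None,
    threshold_percentile: float = 25.0,
    required_objective_fraction: float = 0.9,
    objective: Optional[str] = None,
    condition: str = "",
) -> ContextModel:
    """Context-specific extraction by the GIMME linear program.

    The expression threshold is the given percentile of the scored-reaction
    distribution.  The LP minimises sum_i (threshold - score_i)+ * |v_i|
    over below-threshold reactions subject to steady state, bounds and
    objective >= fraction * parent optimum.  A below-threshold reaction is
    removed iff FVA (under the same constraints, with the penalty held at
    its optimum) confirms it cannot carry flux.  Unscored reactions are
    never removed; orphan metabolites are pruned and logged.
    """
    objective = objective or model.biomass_reaction_id
    parent = fba(model, medium, objective=objective)
    if not parent.optimal:
        raise ModelError(f"GIMME: parent model is {parent.status} under the medium")
    scored = {r: s for r, s in scores.items() if s is not None}
    if not scored:
        raise ModelError("GIMME: no scored reactions")
    threshold = float(np.percentile(list(scored.values()), threshold_percentile))
    weights = {r: threshold - s for r, s in scored.items() if s < threshold}

    S, lb, ub, rxn_ids = _assemble(model, medium)
    n = len(rxn_ids)
    pen = [r for r in rxn_ids if r in weights]
    k = len(pen)
    c_obj = _objective_vector(rxn_ids, objective)
    required = required_objective_fraction * parent.objective_value

    if k == 0:
        return ContextModel(model.copy(), set(), [], 0.0, threshold, condition)

    # variables [v (n), t (k)] with t_i >= |v_i| on penalised reactions
    nvar = n + k
    A_eq = np.hstack([S, np.zeros((S.shape[0], k))])
    b_eq = np.zeros(S.shape[0])
    A_ub = np.zeros((2 * k + 1, nvar))
    b_ub = np.zeros(2 * k + 1)
    for t_idx, rid in enumerate(pen):
        j = rxn_ids.index(rid)
        A_ub[2 * t_idx, j] = 1.0
        A_ub[2 * t_idx, n + t_idx] = -1.0
        A_ub[2 * t_idx + 1, j] = -1.0
        A_ub[2 * t_idx + 1, n + t_idx] = -1.0
    A_ub[2 * k, :n] = -c_obj
    b_ub[2 * k] = -required
    lo = np.concatenate([lb, np.zeros(k)])
    hi = np.concatenate([ub, np.full(k, np.inf)])
    w = np.concatenate([np.zeros(n), np.array([weights[r] for r in pen])])

    res = solve_lp(w, lo, hi, A_eq=A_eq, b_eq=b_eq, A_ub=A_ub, b_ub=b_ub,
                   maximize=False)
    if not res.optimal:
        raise ModelError(
            "GIMME LP infeasible: the required objective fraction "
            f"{required_objective_fraction} cannot be met under the medium"
        )
    inconsistency = res.objective
    v = res.x[:n]

    # candidates: penalised reactions carrying no flux in the minimising solution
    candidates = [r for r in pen if abs(v[rxn_ids.index(r)]) <= FLUX_TOL]
    # confirm by FVA at the penalty optimum
    A_ub2 = np.vstack([A_ub, w[None, :]])
    b_ub2 = np.concatenate([b_ub, [inconsistency + FLUX_TOL]])
    removed = set()
    for rid in candidates:
        cj = np.zeros(nvar)
        cj[rxn_ids.index(rid)] = 1.0
        hi_r = solve_lp(cj, lo, hi, A_eq=A_eq, b_eq=b_eq, A_ub=A_ub2, b_ub=b_ub2,
                        maximize=True)
        if not hi_r.optimal or hi_r.objective > FLUX_TOL:
            continue
        lo_r = solve_lp(cj, lo, hi, A_eq=A_eq, b_eq=b_eq, A_ub=A_ub2, b_ub=b_ub2,
                        maximize=False)
        if lo_r.optimal and lo_r.objective >= -FLUX_TOL:
            removed.add(rid)

    pruned = model.copy()
    orphans = pruned.remove_reactions(removed, prune_orphans=True)
    check = fba(pruned, medium, objective=objective)
    if not check.optimal or check.objective_value < required - 1e-6:
        raise ModelError("GIMME pruning violated the objective requirement")
    return ContextModel(pruned, removed, orphans, inconsistency, threshold, condition)


def interval_jaccard(a: Tuple[float, float], b: Tuple[float, float],
                     eps: float = 1e-9) -> float:
    """Jaccard index of two real intervals, J = |A ∩ B| / |A ∪ B|.

    Lengths are Lebesgue measure on the line; when the union is degenerate
    (two coincident points, within eps) the intervals are identical and
    J = 1.  Distinct points or disjoint intervals give 0.
    """
    (alo, ahi), (blo, bhi) = a, b
    if alo > ahi + eps or blo > bhi + eps:
        raise ValueError("intervals must have lo <= hi")
    union = max(ahi, bhi) - min(alo, blo)
    if union <= eps:
        return 1.0
    inter = max(0.0, min(ahi, bhi) - max(alo, blo))
    return inter / union


@dataclass
class DifferentialFluxReport:
    per_reaction: pd.DataFrame  # reaction_id, jaccard, flagged, subsystem
    exclusive_a: List[str] = field(default_factory=list)
    exclusive_b: List[str] = field(default_factory=list)
    unresolved: set = field(default_factory=set)

    @property
    def flagged(self) -> List[str]:
        df = self.per_reaction
        return list(df.loc[df["flagged"], "reaction_id"])


def differential_flux(
    ctx_a: ContextModel,
    ctx_b: ContextModel,
    medium_a: Optional[Medium] = None,
    medium_b: Optional[Medium] = None,
    fraction_of_optimum: float = 1.0,
    loopless: bool = True,
    eps: float = FLUX_TOL,
) -> DifferentialFluxReport:
    """Jaccard comparison of two contexts' (loopless) FVA intervals.

    Reactions present in both contexts are compared; J = 0 flags
    differential flux.  Reactions retained in only one context are
    reported separately as context-exclusive.  Reactions whose loopless
    FVA could not be resolved are propagated in ``unresolved``, never
    silently dropped.
    """
    runner = loopless_fva if loopless else fva
    iv_a = runner(ctx_a.model, medium_a, fraction_of_optimum=fraction_of_optimum)
    iv_b = runner(ctx_b.model, medium_b, fraction_of_optimum=fraction_of_optimum)
    rxns_a = set(ctx_a.model.reactions)
    rxns_b = set(ctx_b.model.reactions)
    common = sorted(rxns_a & rxns_b)
    unresolved = (iv_a.unresolved | iv_b.unresolved) & set(common)
    rows = []
    for rid in common:
        if rid in unresolved:
            continue
        j = interval_jaccard(iv_a[rid], iv_b[rid], eps=eps)
        rows.append({
            "reaction_id": rid, "jaccard": j, "flagged": j == 0.0,
            "subsystem": ctx_a.model.reactions[rid].subsystem or "unassigned",
        })
    return DifferentialFluxReport(
        pd.DataFrame(rows, columns=["reaction_id", "jaccard", "flagged", "subsystem"]),
        exclusive_a=sorted(rxns_a - rxns_b),
        exclusive_b=sorted(rxns_b - rxns_a),
        unresolved=unresolved,
    )


def rank_pathways(report: DifferentialFluxReport) -> pd.DataFrame:
    """Flagged-reaction counts per subsystem, descending; ties lexicographic."""
    df = report.per_reaction
    flagged = df[df["flagged"]]
    if flagged.empty:
        return pd.DataFrame(columns=["subsystem", "n_flagged"])
    counts = (
        flagged.groupby("subsystem").size().reset_index(name="n_flagged")
        .sort_values(["n_flagged", "subsystem"], ascending=[False, True])
        .reset_index(drop=True)
    )
    return counts
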