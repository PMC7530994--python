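"""Single-gene deletion screening and classification statistics.

Deleting a gene disables exactly those reactions whose GPR evaluates to
False without it (an isozyme OR keeps the reaction open); the knockout
growth rate is computed by FBA or MOMA and compared to the wild type.
Predictions are scored against an experimental truth table mapped through
an ortholog table with the usual confusion-matrix statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import sqrt
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .fba import fba, moma
from .gpr import evaluate_gpr
from .model import DEFAULT_BOUND, Medium, MetabolicModel, ModelError

__all__ = [
    "ESSENTIALITY_CUTOFF",
    "single_gene_deletion",
    "ConfusionStats",
    "confusion_statistics",
    "media_presets",
]

# growth ratio below which a knockout is called essential (exposed config)
ESSENTIALITY_CUTOFF = 0.01


def single_gene_deletion(
    model: MetabolicModel,
    medium: Optional[Medium] = None,
    method: str = "fba",
    genes: Optional[Iterable[str]] = None,
    cutoff: float = ESSENTIALITY_CUTOFF,
) -> pd.DataFrame:
    """Knock out each gene in turn; returns gene, growth_ratio, essential, method.

    Deterministic and order-independent: results depend only on the model,
    medium and method.
    """
    if method not in ("fba", "moma"):
        raise ValueError(f"unknown knockout method {method!r}")
    wildtype = fba(model, medium)
    if not wildtype.optimal or wildtype.objective_value <= 1e-9:
        raise ModelError(
            f"wild type is non-viable under medium "
            f"({wildtype.status}, mu={wildtype.objective_value})"
        )
    mu_wt = wildtype.objective_value
    gene_list = sorted(model.genes) if genes is None else sorted(genes)
    unknown = set(gene_list) - set(model.genes)
    if unknown:
        warnings.warn(f"genes not in model ignored: {sorted(unknown)}")
        gene_list = [g for g in gene_list if g not in unknown]

    rows = []
    for gene in gene_list:
        disabled = [
            r.id
            for r in model.reactions.values()
            if r.gpr is not None
            and gene in r.genes
            and not evaluate_gpr(r.gpr, {gene})
        ]
        if not disabled:
            ratio = 1.0
        elif method == "fba":
            ko = fba(model, medium,
                     bounds_override={rid: (0.0, 0.0) for rid in disabled})
            ratio = (ko.objective_value / mu_wt) if ko.optimal else 0.0
        else:
            ko = moma(model, wildtype, disabled, medium)
            ratio = (ko.objective_value / mu_wt) if ko.optimal else 0.0
        ratio = max(ratio, 0.0)
        rows.append({"gene": gene, "growth_ratio": ratio,
                     "essential": ratio < cutoff, "method": method})
    return pd.DataFrame(rows)


@dataclass
class ConfusionStats:
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f1: float
    mcc: float
    n_compared: int
    n_unmapped: int


def _mcc(tp, fp, tn, fn) -> float:
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return ((tp * tn) - (fp * fn)) / sqrt(denom)


def confusion_statistics(
    calls: pd.DataFrame,
    truth: Mapping[str, bool],
    orthologs: Optional[Mapping[str, Sequence[str]]] = None,
) -> ConfusionStats:
    """Score essentiality calls against an experimental truth table.

    ``truth`` maps reference-organism genes to essentiality.  When an
    ortholog map is given, only mapped model genes enter the statistics; a
    model gene with several reference orthologs is called experimentally
    essential only if *all* of them are essential (duplicate genes buffer
    lethality, so a dispensable ortholog marks the function dispensable).

    Positives are essential genes.  Sensitivity TP/(TP+FN), specificity
    TN/(FP+TN), F1 = 2PR/(P+R), and MCC with the square-rooted denominator
    so that perfect prediction scores 1.
    """
    tp = fp = tn = fn = 0
    n_unmapped = 0
    for _, row in calls.iterrows():
        gene = row["gene"]
        if orthologs is not None:
            refs = orthologs.get(gene, [])
            refs = [r for r in refs if r in truth]
            if not refs:
                n_unmapped += 1
                continue
            true_ess = all(truth[r] for r in refs)
        else:
            if gene not in truth:
                n_unmapped += 1
                continue
            true_ess = bool(truth[gene])
        pred_ess = bool(row["essential"])
        if pred_ess and true_ess:
            tp += 1
        elif pred_ess and not true_ess:
            fp += 1
        elif not pred_ess and true_ess:
            fn += 1
        else:
            tn += 1
    n = tp + fp + tn + fn
    if n == 0:
        raise ValueError("no genes could be compared against the truth table")
    sens = tp / (tp + fn) if (tp + fn) else 0.0
    spec = tn / (fp + tn) if (fp + tn) else 0.0
    prec = tp / (tp + fp) if (tp + fp) else 0.0
    f1 = 2 * prec * sens / (prec + sens) if (prec + sens) else 0.0
    return ConfusionStats(
        tp=tp, fp=fp, tn=tn, fn=fn,
        accuracy=(tp + tn) / n, sensitivity=sens, specificity=spec,
        precision=prec, f1=f1, mcc=_mcc(tp, fp, tn, fn),
        n_compared=n, n_unmapped=n_unmapped,
    )


# exchange ids by nutrient class used to assemble the named media presets
_TRACE = ["EX_h2o_e", "EX_h_e", "EX_pi_e"]
_NITROGEN = ["EX_nh4_e"]
_CARBOHYDRATES = ["EX_glc__D_e", "EX_gal_e", "EX_malt_e"]
_OTHER_CARBON = ["EX_etoh_e", "EX_glyc_e"]
_NUCLEOTIDES = ["EX_ura_e"]


def media_presets(
    model: MetabolicModel,
    o2_exchange: str = "EX_o2_e",
    carbon_uptake: float = 10.0,
) -> Dict[str, Medium]:
    """Named aerobic media: ypd_rich plus one minimal medium per carbon source.

    The rich medium opens every carbohydrate, alternative carbon source
    and nucleotide exchange present in the model; minimal media open a
    single carbon source plus ammonium and trace exchanges.  Preset
    components missing from the model are skipped with a warning.
    """
    exchanges = set(model.exchanges)

    def pick(ids):
        present = [i for i in ids if i in exchanges]
        for missing in set(ids) - set(present):
            warnings.warn(f"media preset component {missing!r} not in model; skipped")
        return present

    trace = pick(_TRACE)
    nitrogen = pick(_NITROGEN)
    presets: Dict[str, Medium] = {}

    rich_carbon = pick(_CARBOHYDRATES + _OTHER_CARBON + _NUCLEOTIDES)
    limits = {ex: carbon_uptake for ex in rich_carbon}
    limits.update({ex: DEFAULT_BOUND for ex in trace + nitrogen})
    limits[o2_exchange] = DEFAULT_BOUND
    presets["ypd_rich"] = Medium("ypd_rich", limits)

    for name, carbon in (("minimal_glucose", "EX_glc__D_e"),
                         ("minimal_galactose", "EX_gal_e"),
                         ("minimal_ethanol", "EX_etoh_e")):
        if carbon not in exchanges:
            warnings.warn(f"media preset {name!r}: {carbon!r} not in model; skipped")
            continue
        limits = {carbon: carbon_uptake, o2_exchange: DEFAULT_BOUND}
        limits.update({ex: DEFAULT_BOUND for ex in trace + nitrogen})
        presets[name] = Medium(name, limits)
    return presets
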