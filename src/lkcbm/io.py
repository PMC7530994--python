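"""Reading and writing models and media.

Two on-disk dialects are supported:

* **SBML Level 3 + FBC** — delegated to the COBRA/libSBML stack, with a
  lossless in-memory conversion between this package's model type and
  ``cobra.Model`` (also useful for cross-checking against cobrapy).
* **JSON dialect** — a single object with arrays ``metabolites``,
  ``reactions`` and ``genes``; GPRs serialised as parenthesised Boolean
  strings with keywords ``and``/``or``.  Human-diffable, used for all
  text fixtures.

Media are read/written as TSV (``exchange_id\\tmax_uptake``, magnitude
1000 meaning unrestricted) or TOML.
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Optional, Union

from .gpr import parse_gpr
from .model import DEFAULT_BOUND, Medium, Metabolite, MetabolicModel, ModelError, Reaction

__all__ = [
    "read_model",
    "write_model",
    "read_model_json",
    "write_model_json",
    "read_model_sbml",
    "write_model_sbml",
    "to_cobra",
    "from_cobra",
    "read_medium",
    "write_medium",
]

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(s: Optional[str]):
    """'C6H12O6' -> {'C': 6, 'H': 12, 'O': 6}; None/'' -> None."""
    if not s:
        return None
    out = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(s):
        if m.start() != pos:
            raise ModelError(f"cannot parse chemical formula {s!r}")
        out[m.group(1)] = out.get(m.group(1), 0) + int(m.group(2) or 1)
        pos = m.end()
    if pos != len(s):
        raise ModelError(f"cannot parse chemical formula {s!r}")
    return out


# ---------------------------------------------------------------------------
# JSON dialect


def write_model_json(model: MetabolicModel, path: Union[str, Path]) -> None:
    doc = {
        "id": model.id,
        "name": model.name,
        "compartments": model.compartments,
        "biomass_reaction_id": model.biomass_reaction_id,
        "metabolites": [
            {
                "id": m.id, "name": m.name, "compartment": m.compartment,
                "formula": m.formula, "charge": m.charge,
            }
            for m in model.metabolites.values()
        ],
        "reactions": [
            {
                "id": r.id, "name": r.name, "stoichiometry": r.stoichiometry,
                "lower_bound": r.lower_bound, "upper_bound": r.upper_bound,
                "gpr": r.gpr_string(), "subsystem": r.subsystem,
                "confidence": r.confidence,
            }
            for r in model.reactions.values()
        ],
        "genes": sorted(model.genes),
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=False) + "\n")


def read_model_json(path: Union[str, Path]) -> MetabolicModel:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        raise ModelError(f"malformed JSON model file {path}: {e}") from e
    model = MetabolicModel(doc.get("id", "model"), doc.get("name", ""),
                           doc.get("compartments", {}))
    mets = []
    for m in doc.get("metabolites", []):
        if "id" not in m:
            raise ModelError(f"metabolite entry without id in {path}")
        formula = m.get("formula")
        if isinstance(formula, str):
            formula = parse_formula(formula)
        mets.append(Metabolite(m["id"], m.get("name", ""), m.get("compartment", "c"),
                               formula, m.get("charge")))
    model.add_metabolites(mets)
    rxns = []
    for r in doc.get("reactions", []):
        if "id" not in r:
            raise ModelError(f"reaction entry without id in {path}")
        lb = r.get("lower_bound")
        ub = r.get("upper_bound")
        if lb is None or ub is None:  # missing bounds: fill defaults
            lb = -DEFAULT_BOUND if lb is None else lb
            ub = DEFAULT_BOUND if ub is None else ub
        rxns.append(Reaction(
            r["id"], r.get("name", ""), dict(r.get("stoichiometry", {})),
            float(lb), float(ub), parse_gpr(r.get("gpr") or None),
            r.get("subsystem", ""), r.get("confidence"),
        ))
    model.add_reactions(rxns)
    model.register_genes(doc.get("genes", []))
    model.biomass_reaction_id = doc.get("biomass_reaction_id")
    model.validate()
    return model


# ---------------------------------------------------------------------------
# SBML via cobra / libSBML


def to_cobra(model: MetabolicModel):
    """Convert to a cobra.Model (bounds, stoichiometry, GPR strings, biomass objective)."""
    import cobra

    cm = cobra.Model(model.id, name=model.name)
    cm.compartments = dict(model.compartments)
    cmets = {}
    for m in model.metabolites.values():
        cm_met = cobra.Metabolite(
            m.id, name=m.name or m.id, compartment=m.compartment,
            formula=m.formula_string(), charge=m.charge,
        )
        cmets[m.id] = cm_met
    cm.add_metabolites(list(cmets.values()))
    crxns = []
    for r in model.reactions.values():
        cr = cobra.Reaction(r.id, name=r.name or r.id,
                            lower_bound=r.lower_bound, upper_bound=r.upper_bound)
        cr.subsystem = r.subsystem
        crxns.append(cr)
    cm.add_reactions(crxns)
    for r in model.reactions.values():
        cr = cm.reactions.get_by_id(r.id)
        cr.add_metabolites({cmets[mid]: coeff for mid, coeff in r.stoichiometry.items()})
        if r.gpr is not None:
            cr.gene_reaction_rule = r.gpr_string()
        if r.confidence is not None:
            cr.annotation["confidence"] = str(r.confidence)
    if model.biomass_reaction_id:
        cm.objective = model.biomass_reaction_id
    return cm


def from_cobra(cm) -> MetabolicModel:
    model = MetabolicModel(cm.id or "model", cm.name or "",
                           dict(cm.compartments))
    model.add_metabolites([
        Metabolite(m.id, m.name or "", m.compartment or "c",
                   parse_formula(m.formula), m.charge)
        for m in cm.metabolites
    ])
    rxns = []
    for r in cm.reactions:
        conf = r.annotation.get("confidence")
        rxns.append(Reaction(
            r.id, r.name or "", {m.id: c for m, c in r.metabolites.items()},
            r.lower_bound, r.upper_bound,
            parse_gpr(r.gene_reaction_rule or None), r.subsystem or "",
            int(conf) if conf is not None else None,
        ))
    model.add_reactions(rxns)
    model.register_genes([g.id for g in cm.genes])
    objective_rxns = [r.id for r in cm.reactions
                      if r.objective_coefficient not in (0, None)]
    if objective_rxns:
        model.biomass_reaction_id = objective_rxns[0]
    return model


def write_model_sbml(model: MetabolicModel, path: Union[str, Path]) -> None:
    from cobra.io import write_sbml_model

    write_sbml_model(to_cobra(model), str(path))


def read_model_sbml(path: Union[str, Path]) -> MetabolicModel:
    from cobra.io import read_sbml_model

    try:
        cm = read_sbml_model(str(path))
    except Exception as e:  # libsbml raises a zoo of error types
        raise ModelError(f"malformed SBML model file {path}: {e}") from e
    model = from_cobra(cm)
    model.validate()
    return model


# ---------------------------------------------------------------------------
# dispatch


def _infer_format(path: Union[str, Path], fmt: Optional[str]) -> str:
    if fmt is not None:
        return fmt
    suffix = Path(path).suffix.lower()
    if suffix in (".json",):
        return "json"
    if suffix in (".xml", ".sbml"):
        return "sbml"
    raise ModelError(f"cannot infer model format from {path!r}; pass format=")


def read_model(path: Union[str, Path], format: Optional[str] = None) -> MetabolicModel:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    return read_model_json(path) if fmt == "json" else read_model_sbml(path)


def write_model(model: MetabolicModel, path: Union[str, Path],
                format: Optional[str] = None) -> None:
    fmt = _infer_format(path, format)
    if fmt == "json":
        write_model_json(model, path)
    else:
        write_model_sbml(model, path)


# ---------------------------------------------------------------------------
# media


def write_medium(medium: Medium, path: Union[str, Path]) -> None:
    lines = ["exchange_id\tmax_uptake"]
    for ex, u in medium.uptake_limits.items():
        lines.append(f"{ex}\t{u}")
    for ex in sorted(medium.unrestricted):
        lines.append(f"{ex}\t{DEFAULT_BOUND}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_medium(path: Union[str, Path], name: Optional[str] = None) -> Medium:
    path = Path(path)
    if path.suffix.lower() == ".toml":
        import tomllib

        doc = tomllib.loads(path.read_text())
        limits = {k: float(v) for k, v in doc.get("uptake_limits", doc).items()}
    else:
        limits = {}
        for i, line in enumerate(path.read_text().splitlines()):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if i == 0 and parts[0] == "exchange_id":
                continue
            limits[parts[0]] = float(parts[1])
    unrestricted = {ex for ex, u in limits.items() if u >= DEFAULT_BOUND}
    limits = {ex: u for ex, u in limits.items() if u < DEFAULT_BOUND}
    return Medium(name or path.stem, limits, unrestricted)
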