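"""Seeded generators for every input class the pipeline consumes.

The centrepiece is a multi-compartment yeast-like toy network with a
respiration/fermentation trade-off (weak Crabtree behaviour: fermentation
only under oxygen limitation), an ATP-yielding acetate overflow branch,
an ethyl acetate (AAT) condensation branch fed by ethanol + acetate, an
optional uracil-degradation (URC) branch that enables growth on uracil as
the sole nitrogen source, a glycerol redox valve for anaerobic growth,
and GPRs with single-gene, complex (AND) and isozyme-pair (OR) cases.

All internal reactions are elementally and charge balanced with real
molecular formulas, so balance checks and g/g yields are meaningful.
Ground truths (optimal yields, essential genes, blocked reactions) come
from closed-form analysis of the lumped stoichiometry and are recorded at
generation time; the test-suite re-derives them with the analysis
engines.

Closed forms, per mmol glucose taken up (P, A = biomass pyruvate and ATP
coefficients in mmol/gDW):

* aerobic (O2 unlimited):  mu = 32 / (A + 12.5 P)  — glycolysis yields
  2 ATP + 2 NADH + 2 pyruvate; respiring r = 2 - P mu pyruvate yields
  5 NADH each; each NADH pair gives 5 ATP (P/O = 2.5);
* anaerobic (O2 = 0):  mu = 2 / (A + 2 P) — redox closed by diverting
  s = P mu triose phosphate to glycerol (forgoing 2 ATP and sinking one
  NADH per triose), ethanol secreted at 2 - 2 P mu per glucose.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .context import ExpressionProfile
from .curation import add_pathway
from .model import DEFAULT_BOUND, Medium, Metabolite, MetabolicModel, ModelError, PathwaySpec, Reaction

__all__ = [
    "MOLAR_MASSES",
    "ToyModelConfig",
    "ToyGroundTruth",
    "make_toy_model",
    "urc_pathway_spec",
    "ethyl_acetate_pathway_spec",
    "ammonium_medium",
    "uracil_medium",
    "make_expression_profiles",
    "make_condition_table",
    "make_od_series",
    "make_truth_table",
    "make_chain_model",
    "make_branch_model",
    "make_loop_model",
]

# g/mol, used for g/L <-> mmol conversions in DFBA and yields
MOLAR_MASSES = {
    "glucose": 180.156, "galactose": 180.156, "maltose": 342.297,
    "ethanol": 46.069, "acetate": 59.044, "ethyl_acetate": 88.106,
    "glycerol": 92.094, "co2": 44.009, "o2": 31.998, "uracil": 112.087,
}

_FORMULAS = {
    "glc__D": ({"C": 6, "H": 12, "O": 6}, 0),
    "gal": ({"C": 6, "H": 12, "O": 6}, 0),
    "malt": ({"C": 12, "H": 22, "O": 11}, 0),
    "etoh": ({"C": 2, "H": 6, "O": 1}, 0),
    "ac": ({"C": 2, "H": 3, "O": 2}, -1),
    "etac": ({"C": 4, "H": 8, "O": 2}, 0),
    "glyc": ({"C": 3, "H": 8, "O": 3}, 0),
    "o2": ({"O": 2}, 0),
    "co2": ({"C": 1, "O": 2}, 0),
    "nh4": ({"H": 4, "N": 1}, 1),
    "pi": ({"H": 1, "O": 4, "P": 1}, -2),
    "h2o": ({"H": 2, "O": 1}, 0),
    "h": ({"H": 1}, 1),
    "pyr": ({"C": 3, "H": 3, "O": 3}, -1),
    "g3p": ({"C": 3, "H": 5, "O": 6, "P": 1}, -2),  # triose phosphate pool
    "atp": ({"C": 10, "H": 12, "N": 5, "O": 13, "P": 3}, -4),
    "adp": ({"C": 10, "H": 12, "N": 5, "O": 10, "P": 2}, -3),
    "nad": ({"C": 21, "H": 26, "N": 7, "O": 14, "P": 2}, -1),
    "nadh": ({"C": 21, "H": 27, "N": 7, "O": 14, "P": 2}, -2),
    "ura": ({"C": 4, "H": 4, "N": 2, "O": 2}, 0),
    "urea": ({"C": 1, "H": 4, "N": 2, "O": 1}, 0),
}

_COMPARTMENT_NAMES = {"e": "extracellular", "c": "cytosol", "m": "mitochondria"}


def _met(base: str, comp: str) -> Metabolite:
    formula, charge = _FORMULAS[base]
    return Metabolite(f"{base}_{comp}", name=base, compartment=comp,
                      formula=dict(formula), charge=charge)


@dataclass
class ToyModelConfig:
    seed: int = 0
    include_urc: bool = True
    include_ethyl_acetate: bool = True
    include_mitochondria: bool = True
    n_isozyme_pairs: int = 2  # 0..3: glucose transporter, ADH, GPD
    biomass_coefficients: Dict[str, float] = field(
        default_factory=lambda: {"pyr": 18.0, "nh4": 9.0, "atp": 180.0}
    )
    glucose_uptake: float = 10.0  # default medium bound, mmol/gDW/h
    aat_capacity: float = 0.2  # ethyl acetate synthase vmax, mmol/gDW/h

    def __post_init__(self):
        if not 0 <= self.n_isozyme_pairs <= 3:
            raise ModelError("n_isozyme_pairs must be 0..3")
        for key in ("pyr", "nh4", "atp"):
            if self.biomass_coefficients.get(key, 0) <= 0:
                raise ModelError(f"biomass coefficient {key!r} must be positive")


@dataclass
class ToyGroundTruth:
    """Analytic properties of the generated network (per mmol glucose)."""

    mu_per_glucose_aerobic: float
    mu_per_glucose_anaerobic: float
    o2_per_glucose_respiratory: float
    rq_aerobic: float
    ethanol_per_glucose_anaerobic: float
    biomass_carbon_mmol_per_g: float
    essential_genes_minimal_glucose: Set[str]
    blocked_minimal_glucose: Set[str]
    urc_reactions: Set[str]
    decoy_reactions: Set[str]
    molar_masses: Dict[str, float]


def urc_pathway_spec() -> PathwaySpec:
    """Uracil degradation branch: uptake, oxidative breakdown to urea, urease.

    Lumped but balanced: uracil + 5 H2O + 5 NAD+ -> urea + 3 CO2 +
    5 NADH + 5 H+, then urea + H2O + 2 H+ -> 2 NH4+ + CO2, releasing the
    ring nitrogen into the ammonium pool.
    """
    return PathwaySpec(
        name="urc_uracil_degradation",
        metabolites=[_met("ura", "e"), _met("ura", "c"), _met("urea", "c")],
        reactions=[
            Reaction("EX_ura_e", "uracil exchange", {"ura_e": -1.0}, 0.0,
                     DEFAULT_BOUND, subsystem="Exchange"),
            Reaction("URAt", "uracil permease", {"ura_e": -1.0, "ura_c": 1.0},
                     0.0, DEFAULT_BOUND, gpr="g_urc_t",
                     subsystem="Uracil degradation"),
            Reaction("URCDEG", "uracil degradation (lumped)",
                     {"ura_c": -1.0, "h2o_c": -5.0, "nad_c": -5.0,
                      "urea_c": 1.0, "co2_c": 3.0, "nadh_c": 5.0, "h_c": 5.0},
                     0.0, DEFAULT_BOUND, gpr="g_urc1 and g_urc4",
                     subsystem="Uracil degradation"),
            Reaction("UREASE", "urea amidolyase",
                     {"urea_c": -1.0, "h2o_c": -1.0, "h_c": -2.0,
                      "nh4_c": 2.0, "co2_c": 1.0},
                     0.0, DEFAULT_BOUND, gpr="g_urc3 and g_urc5",
                     subsystem="Uracil degradation"),
        ],
    )


def ethyl_acetate_pathway_spec(capacity: float = 0.2) -> PathwaySpec:
    """AAT condensation of ethanol + acetate to ethyl acetate, plus export.

    The condensation is ATP-neutral and capacity-limited (enzyme vmax), so
    ethyl acetate appears as an overflow product only when both precursors
    are available — i.e. under oxygen limitation but not strict anaerobiosis.
    """
    return PathwaySpec(
        name="ethyl_acetate_overflow",
        metabolites=[_met("etac", "c"), _met("etac", "e")],
        reactions=[
            Reaction("AAT", "alcohol acetyltransferase (lumped)",
                     {"etoh_c": -1.0, "ac_c": -1.0, "h_c": -1.0,
                      "etac_c": 1.0, "h2o_c": 1.0},
                     0.0, capacity, gpr="g_eat1",
                     subsystem="Ethyl acetate synthesis"),
            Reaction("ETACt", "ethyl acetate export",
                     {"etac_c": -1.0, "etac_e": 1.0}, 0.0, DEFAULT_BOUND,
                     subsystem="Transport"),
            Reaction("EX_etac_e", "ethyl acetate exchange", {"etac_e": -1.0},
                     0.0, DEFAULT_BOUND, subsystem="Exchange"),
        ],
    )


def make_toy_model(config: Optional[ToyModelConfig] = None) -> Tuple[MetabolicModel, ToyGroundTruth]:
    """Build the toy network and its analytic ground truth."""
    cfg = config or ToyModelConfig()
    P = cfg.biomass_coefficients["pyr"]
    N = cfg.biomass_coefficients["nh4"]
    A = cfg.biomass_coefficients["atp"]
    # closed-form validity: aerobic optimum must not be ATP-limited into
    # negative respiration, anaerobic ethanol secretion must stay positive
    if not (7 * P <= 2 * A):
        raise ModelError("biomass coefficients leave no pyruvate to respire")
    mu_aer = 32.0 / (A + 12.5 * P)
    mu_ana = 2.0 / (A + 2.0 * P)
    if 2 - 2 * P * mu_ana <= 0:
        raise ModelError("anaerobic regime infeasible for these coefficients")

    comp = "m" if cfg.include_mitochondria else "c"
    compartments = {"e": "extracellular", "c": "cytosol"}
    if cfg.include_mitochondria:
        compartments["m"] = "mitochondria"
    model = MetabolicModel("toy_lk", "toy weak-Crabtree yeast network", compartments)

    mets = [_met(b, "e") for b in
            ("glc__D", "gal", "malt", "etoh", "ac", "glyc", "o2", "co2",
             "nh4", "pi", "h2o", "h")]
    mets += [_met(b, "c") for b in
             ("glc__D", "gal", "malt", "etoh", "ac", "glyc", "o2", "co2",
              "nh4", "pi", "h2o", "h", "pyr", "g3p", "atp", "adp", "nad",
              "nadh")]
    if cfg.include_mitochondria:
        mets += [_met(b, "m") for b in
                 ("pyr", "o2", "co2", "nad", "nadh", "h", "h2o")]
    model.add_metabolites(mets)

    pairs = [("g_hxt1", "g_hxt2"), ("g_adh1", "g_adh2"), ("g_gpd1", "g_gpd2")]
    iso = ["{0} or {1}".format(*p) if i < cfg.n_isozyme_pairs else p[0]
           for i, p in enumerate(pairs)]
    hxt, adh, gpd = iso

    rxns: List[Reaction] = []

    def ex(base, lb=0.0):
        rxns.append(Reaction(f"EX_{base}_e", f"{base} exchange",
                             {f"{base}_e": -1.0}, lb, DEFAULT_BOUND,
                             subsystem="Exchange"))

    for base in ("glc__D", "gal", "malt", "etoh", "ac", "glyc", "o2", "co2",
                 "nh4", "pi"):
        ex(base)
    ex("h2o", -DEFAULT_BOUND)
    ex("h", -DEFAULT_BOUND)

    def rxn(rid, name, stoich, lb, ub, gpr=None, subsystem=""):
        rxns.append(Reaction(rid, name, stoich, lb, ub, gpr=gpr,
                             subsystem=subsystem))

    F = DEFAULT_BOUND
    rxn("GLCt", "glucose transport", {"glc__D_e": -1, "glc__D_c": 1}, 0, F,
        hxt, "Transport")
    rxn("GALt", "galactose transport", {"gal_e": -1, "gal_c": 1}, 0, F,
        "g_gal2", "Transport")
    rxn("MALTt", "maltose-proton symport",
        {"malt_e": -1, "h_e": -1, "malt_c": 1, "h_c": 1}, 0, F,
        "g_mal11", "Transport")
    rxn("ETOHt", "ethanol diffusion", {"etoh_c": -1, "etoh_e": 1}, -F, F,
        None, "Transport")
    rxn("ACt", "acetate-proton antiport",
        {"ac_c": -1, "h_c": -1, "ac_e": 1, "h_e": 1}, -F, F, "g_ady2",
        "Transport")
    rxn("GLYCt", "glycerol facilitator", {"glyc_c": -1, "glyc_e": 1}, -F, F,
        "g_stl1", "Transport")
    rxn("O2t", "oxygen diffusion", {"o2_e": -1, "o2_c": 1}, -F, F, None,
        "Transport")
    rxn("CO2t", "CO2 diffusion", {"co2_c": -1, "co2_e": 1}, -F, F, None,
        "Transport")
    rxn("NH4t", "ammonium transport", {"nh4_e": -1, "nh4_c": 1}, 0, F,
        "g_mep1", "Transport")
    rxn("PIt", "phosphate-proton symport",
        {"pi_e": -1, "h_e": -1, "pi_c": 1, "h_c": 1}, 0, F, "g_pho84",
        "Transport")
    rxn("H2Ot", "water diffusion", {"h2o_e": -1, "h2o_c": 1}, -F, F, None,
        "Transport")
    rxn("Ht", "proton leak", {"h_e": -1, "h_c": 1}, -F, F, None, "Transport")

    rxn("GLYC_UPPER", "upper glycolysis (lumped PFK)",
        {"glc__D_c": -1, "atp_c": -2, "g3p_c": 2, "adp_c": 2, "h_c": 2},
        0, F, "g_pfk1", "Glycolysis")
    rxn("GLYC_LOWER", "lower glycolysis (lumped GAPDH..PYK)",
        {"g3p_c": -1, "nad_c": -1, "adp_c": -2, "pi_c": -1,
         "pyr_c": 1, "nadh_c": 1, "atp_c": 2, "h2o_c": 1},
        0, F, "g_glyc1 and g_glyc2", "Glycolysis")
    rxn("GALISO", "Leloir pathway (lumped)", {"gal_c": -1, "glc__D_c": 1},
        0, F, "g_gal1", "Galactose metabolism")
    rxn("MALTHYD", "maltase", {"malt_c": -1, "h2o_c": -1, "glc__D_c": 2},
        0, F, "g_mal12", "Maltose metabolism")
    rxn("FERM", "pyruvate decarboxylase + ADH (lumped)",
        {"pyr_c": -1, "nadh_c": -1, "h_c": -2, "etoh_c": 1, "co2_c": 1,
         "nad_c": 1}, 0, F, f"({adh}) and g_pdc1", "Fermentation")
    rxn("ETOHDH", "ethanol -> acetate (lumped ADH + ALD)",
        {"etoh_c": -1, "nad_c": -2, "h2o_c": -1, "ac_c": 1, "nadh_c": 2,
         "h_c": 3}, 0, F, f"({adh}) and g_ald6", "Ethanol assimilation")
    rxn("ACK", "acetate overflow (PDH bypass, ATP-yielding)",
        {"pyr_c": -1, "nad_c": -1, "adp_c": -1, "pi_c": -1,
         "ac_c": 1, "co2_c": 1, "nadh_c": 1, "atp_c": 1},
        0, F, "g_ald4", "Acetate metabolism")
    rxn("PYRSYN", "acetate assimilation (ATP-activated carboxylation)",
        {"ac_c": -1, "co2_c": -1, "nadh_c": -1, "atp_c": -2, "h2o_c": -1,
         "pyr_c": 1, "nad_c": 1, "adp_c": 2, "pi_c": 2, "h_c": 1},
        0, F, "g_pyc1", "Acetate metabolism")
    rxn("GLYCSYN", "glycerol synthesis (redox valve, GPD + GPP)",
        {"g3p_c": -1, "nadh_c": -1, "h_c": -1, "h2o_c": -1,
         "glyc_c": 1, "nad_c": 1, "pi_c": 1},
        0, F, gpd, "Glycerol metabolism")
    rxn("GLYCUT", "glycerol utilisation (GUT kinase + dehydrogenase)",
        {"glyc_c": -1, "atp_c": -1, "nad_c": -1,
         "g3p_c": 1, "adp_c": 1, "nadh_c": 1, "h_c": 2},
        0, F, "g_gut1", "Glycerol metabolism")
    rxn("ATPM", "ATP maintenance / futile hydrolysis",
        {"atp_c": -1, "h2o_c": -1, "adp_c": 1, "pi_c": 1, "h_c": 1},
        0, F, None, "Energy metabolism")

    if cfg.include_mitochondria:
        rxn("PYRtm", "pyruvate-proton mitochondrial symport",
            {"pyr_c": -1, "h_c": -1, "pyr_m": 1, "h_m": 1}, 0, F, "g_mpc1",
            "Transport")
        rxn("O2tm", "oxygen diffusion (mito)", {"o2_c": -1, "o2_m": 1},
            -F, F, None, "Transport")
        rxn("CO2tm", "CO2 diffusion (mito)", {"co2_m": -1, "co2_c": 1},
            -F, F, None, "Transport")
        rxn("H2Otm", "water diffusion (mito)", {"h2o_c": -1, "h2o_m": 1},
            -F, F, None, "Transport")
        rxn("Htm", "proton transport (mito)", {"h_c": -1, "h_m": 1}, -F, F,
            None, "Transport")
        rxn("NADH_SHUTTLE", "cytosolic NADH shuttle",
            {"nadh_c": -1, "nad_m": -1, "nad_c": 1, "nadh_m": 1}, 0, F,
            "g_ndt1", "Transport")
        tca_c, ox_c = "m", "m"
    else:
        tca_c, ox_c = "c", "c"

    rxn("TCA", "pyruvate oxidation + TCA (lumped)",
        {f"pyr_{tca_c}": -1, f"h2o_{tca_c}": -3, f"nad_{tca_c}": -5,
         f"co2_{tca_c}": 3, f"nadh_{tca_c}": 5, f"h_{tca_c}": 4},
        0, F, "g_cit1 and g_kgd1", "TCA cycle")
    rxn("OXPHOS", "respiratory chain + ATP synthase (P/O 2.5)",
        {f"nadh_{ox_c}": -2, f"o2_{ox_c}": -1, f"h_{ox_c}": -7,
         "adp_c": -5, "pi_c": -5, f"nad_{ox_c}": 2, "atp_c": 5, "h2o_c": 7},
        0, F, "g_cox1 and g_atp1", "Oxidative phosphorylation")

    # biomass: P pyruvate + N ammonium + growth-associated ATP hydrolysis,
    # plus a net 2 mmol/gDW phosphate demand (nucleic acids / phospholipids)
    rxn("BIOMASS", "biomass pseudo-reaction",
        {"pyr_c": -P, "nh4_c": -N, "atp_c": -A, "h2o_c": -A,
         "adp_c": A, "pi_c": A - 2.0, "h_c": A}, 0, F, None, "Growth")

    model.add_reactions(rxns)
    model.biomass_reaction_id = "BIOMASS"

    if cfg.include_ethyl_acetate:
        model = add_pathway(model, ethyl_acetate_pathway_spec(cfg.aat_capacity))
        model.biomass_reaction_id = "BIOMASS"
    if cfg.include_urc:
        model = add_pathway(model, urc_pathway_spec())
        model.biomass_reaction_id = "BIOMASS"
    model.validate()

    r_aer = 2.0 - P * mu_aer
    o2_per_glc = (2.0 + 5.0 * r_aer) / 2.0
    essential = {"g_pfk1", "g_glyc1", "g_glyc2", "g_mep1", "g_pho84"}
    if cfg.n_isozyme_pairs < 1:
        essential.add("g_hxt1")
    blocked = {"GALt", "GALISO", "EX_gal_e", "MALTt", "MALTHYD", "EX_malt_e"}
    urc_rxns = {"URAt", "URCDEG", "UREASE"} if cfg.include_urc else set()
    if cfg.include_urc:
        blocked |= urc_rxns | {"EX_ura_e"}
    truth = ToyGroundTruth(
        mu_per_glucose_aerobic=mu_aer,
        mu_per_glucose_anaerobic=mu_ana,
        o2_per_glucose_respiratory=o2_per_glc,
        rq_aerobic=3.0 * r_aer / o2_per_glc,
        ethanol_per_glucose_anaerobic=2.0 - 2.0 * P * mu_ana,
        biomass_carbon_mmol_per_g=3.0 * P,
        essential_genes_minimal_glucose=essential,
        blocked_minimal_glucose=blocked,
        urc_reactions=urc_rxns,
        decoy_reactions={"GALt", "GALISO"},
        molar_masses=dict(MOLAR_MASSES),
    )
    return model, truth


# ---------------------------------------------------------------------------
# media helpers for the two nitrogen-source contexts


def _trace_limits() -> Dict[str, float]:
    return {"EX_pi_e": DEFAULT_BOUND, "EX_h2o_e": DEFAULT_BOUND,
            "EX_h_e": DEFAULT_BOUND, "EX_o2_e": DEFAULT_BOUND}


def ammonium_medium(glucose_uptake: float = 10.0) -> Medium:
    """Aerobic minimal glucose medium, ammonium as the sole nitrogen source."""
    limits = _trace_limits()
    limits["EX_glc__D_e"] = glucose_uptake
    limits["EX_nh4_e"] = DEFAULT_BOUND
    return Medium("minimal_glucose_ammonium", limits)


def uracil_medium(glucose_uptake: float = 10.0) -> Medium:
    """Aerobic minimal glucose medium, uracil as the sole nitrogen source."""
    limits = _trace_limits()
    limits["EX_glc__D_e"] = glucose_uptake
    limits["EX_ura_e"] = DEFAULT_BOUND
    return Medium("minimal_glucose_uracil", limits)


# ---------------------------------------------------------------------------
# expression profiles


def make_expression_profiles(
    model: MetabolicModel, seed: int = 0
) -> Tuple[ExpressionProfile, ExpressionProfile, Dict[str, object]]:
    """Paired two-condition expression profiles with built-in structure.

    Three log-normal tiers: a low tier (~5 a.u.) holding the galactose
    decoy branch in both conditions and the URC genes in the ammonium
    condition; a mid tier (~30 a.u.) of constitutive growth-essential
    transport/glycolysis genes (guaranteed to flank the 25th percentile
    without ever being prunable, since they carry flux); and a high tier
    (~100 a.u.).  URC genes are strongly induced (high tier) on uracil.
    Tier draws are clipped so the tiers can never overlap, making the
    GIMME outcome seed-independent.
    """
    rng = np.random.default_rng(seed)
    genes = sorted(model.genes)
    low_both = {"g_gal1", "g_gal2"}
    mid_both = {"g_hxt1", "g_hxt2", "g_glyc1", "g_glyc2", "g_ndt1", "g_mpc1"}
    urc = {g for g in genes if g.startswith("g_urc")}

    def draw(level, sigma, lo, hi):
        return float(np.clip(level * np.exp(rng.normal(0.0, sigma)), lo, hi))

    def tier_value(tier):
        if tier == "low":
            return draw(5.0, 0.2, 1.0, 9.0)
        if tier == "mid":
            return draw(30.0, 0.1, 22.0, 40.0)
        return draw(100.0, 0.15, 60.0, 250.0)

    values_a, values_u, tiers = {}, {}, {}
    for g in genes:
        if g in low_both:
            ta = tu = "low"
        elif g in mid_both:
            ta = tu = "mid"
        elif g in urc:
            ta, tu = "low", "high"
        else:
            ta = tu = "high"
        tiers[g] = (ta, tu)
        values_a[g] = tier_value(ta)
        values_u[g] = tier_value(tu)

    info = {
        "tiers": tiers,
        "decoy_genes": sorted(low_both),
        "urc_genes": sorted(urc),
        "decoy_reactions": {"GALt", "GALISO"},
        "urc_reactions": {"URAt", "URCDEG", "UREASE"} & set(model.reactions),
    }
    return (ExpressionProfile("ammonium", values_a),
            ExpressionProfile("uracil", values_u), info)


# ---------------------------------------------------------------------------
# condition tables and OD series


def make_condition_table(
    model: MetabolicModel,
    n_conditions: int = 8,
    noise_sd: float = 0.05,
    seed: int = 0,
    substrate_exchange: str = "EX_glc__D_e",
) -> pd.DataFrame:
    """Synthetic experimental-condition table spanning O2 regimes.

    Substrate/O2 uptake pairs are sampled over aerobic, semi-aerobic and
    anaerobic regimes; "measured" mu and RQ are the model's own FBA
    predictions perturbed by multiplicative Gaussian noise.  True
    (noise-free) values are recorded alongside.
    """
    from .validation import run_condition_table

    rng = np.random.default_rng(seed)
    regimes = ["aerobic", "semi_aerobic", "anaerobic"]
    rows = []
    for i in range(n_conditions):
        regime = regimes[i % 3]
        uptake = float(rng.uniform(1.5, 10.0))
        if regime == "aerobic":
            o2 = 1000.0
        elif regime == "semi_aerobic":
            o2 = float(rng.uniform(0.3, 0.6)) * uptake
        else:
            o2 = 0.25
        rows.append({"condition": f"cond_{i}", "regime": regime,
                     "substrate_exchange": substrate_exchange,
                     "substrate_uptake": uptake, "o2_uptake": o2})
    table = pd.DataFrame(rows)
    base = Medium("cond_base", {"EX_nh4_e": DEFAULT_BOUND, **_trace_limits()})
    del base.uptake_limits["EX_o2_e"]  # set per-row
    pred = run_condition_table(model, table, base_medium=base)
    table["true_mu"] = pred["predicted_mu"].to_numpy()
    table["true_rq"] = pred["predicted_rq"].to_numpy()
    table["measured_mu"] = table["true_mu"] * (1 + rng.normal(0, noise_sd, len(table)))
    table["measured_rq"] = table["true_rq"] * (1 + rng.normal(0, noise_sd, len(table)))
    return table


def make_od_series(
    mu_true: float,
    od0: float = 0.2,
    t_grid: Optional[Sequence[float]] = None,
    noise_sd: float = 0.02,
    seed: int = 0,
) -> pd.DataFrame:
    """OD600 time course OD(t) = od0 * exp(mu t) * (1 + eps), eps ~ N(0, sd)."""
    if mu_true < 0 or od0 <= 0:
        raise ValueError("need mu_true >= 0 and od0 > 0")
    t = np.asarray(t_grid if t_grid is not None else np.arange(0.0, 20.1, 2.0))
    rng = np.random.default_rng(seed)
    od = od0 * np.exp(mu_true * t) * (1 + rng.normal(0, noise_sd, len(t)))
    return pd.DataFrame({"t": t, "od": np.maximum(od, 1e-6)})


def make_truth_table(
    model: MetabolicModel,
    essential_genes: Set[str],
    n_flips: int = 2,
    n_unmapped: int = 2,
    seed: int = 0,
    reference_prefix: str = "ref_",
) -> Tuple[Dict[str, bool], Dict[str, List[str]]]:
    """Synthetic experimental essentiality truth and ortholog map.

    Reference labels mirror the model's own essential set except for
    ``n_flips`` randomly flipped genes (prediction errors by
    construction); ``n_unmapped`` genes get no ortholog.
    """
    rng = np.random.default_rng(seed)
    genes = sorted(model.genes)
    unmapped = set(rng.choice(genes, size=min(n_unmapped, len(genes)),
                              replace=False))
    mappable = [g for g in genes if g not in unmapped]
    flips = set(rng.choice(mappable, size=min(n_flips, len(mappable)),
                           replace=False))
    truth, orthologs = {}, {}
    for g in mappable:
        ref = reference_prefix + g
        orthologs[g] = [ref]
        ess = g in essential_genes
        truth[ref] = (not ess) if g in flips else ess
    return truth, orthologs


# ---------------------------------------------------------------------------
# mini fixtures for exact LP oracles


def _simple_model(model_id, met_ids, rxns, objective):
    m = MetabolicModel(model_id, compartments={"c": "cytosol", "e": "extracellular"})
    m.add_metabolites([Metabolite(i, compartment="c") for i in met_ids])
    m.add_reactions(rxns)
    m.biomass_reaction_id = objective
    return m


def make_chain_model(uptake: float = 10.0) -> MetabolicModel:
    """EX_A -> A -> B -> C -> demand: a fully coupled linear pathway."""
    F = DEFAULT_BOUND
    rxns = [
        Reaction("EX_A", stoichiometry={"A": 1.0}, lower_bound=0.0, upper_bound=uptake),
        Reaction("R1", stoichiometry={"A": -1.0, "B": 1.0}, lower_bound=0.0, upper_bound=F),
        Reaction("R2", stoichiometry={"B": -1.0, "C": 1.0}, lower_bound=0.0, upper_bound=F),
        Reaction("DM_C", stoichiometry={"C": -1.0}, lower_bound=0.0, upper_bound=F),
    ]
    return _simple_model("chain", ["A", "B", "C"], rxns, "DM_C")


def make_branch_model(demand_cap: float = 1.0) -> MetabolicModel:
    """Two parallel equivalent branches feeding one capped demand."""
    F = DEFAULT_BOUND
    rxns = [
        Reaction("EX_A", stoichiometry={"A": 1.0}, lower_bound=0.0, upper_bound=F),
        Reaction("V1", stoichiometry={"A": -1.0, "B": 1.0}, lower_bound=0.0, upper_bound=F),
        Reaction("V2", stoichiometry={"A": -1.0, "B": 1.0}, lower_bound=0.0, upper_bound=F),
        Reaction("DM_B", stoichiometry={"B": -1.0}, lower_bound=0.0, upper_bound=demand_cap),
    ]
    return _simple_model("branch", ["A", "B"], rxns, "DM_B")


def make_loop_model(uptake: float = 10.0) -> MetabolicModel:
    """A chain with a 3-reaction internal cycle B -> C -> D -> B bolted on.

    Plain FVA lets the cycle reactions run up to the default bound on top
    of the chain flux; loopless FVA removes the cycle contribution.
    """
    F = DEFAULT_BOUND
    rxns = [
        Reaction("EX_A", stoichiometry={"A": 1.0}, lower_bound=0.0, upper_bound=uptake),
        Reaction("R1", stoichiometry={"A": -1.0, "B": 1.0}, lower_bound=0.0, upper_bound=F),
        Reaction("L1", stoichiometry={"B": -1.0, "C": 1.0}, lower_bound=0.0, upper_bound=F),
        Reaction("L2", stoichiometry={"C": -1.0, "D": 1.0}, lower_bound=0.0, upper_bound=F),
        Reaction("L3", stoichiometry={"D": -1.0, "B": 1.0}, lower_bound=0.0, upper_bound=F),
        Reaction("DM_B", stoichiometry={"B": -1.0}, lower_bound=0.0, upper_bound=F),
    ]
    return _simple_model("loop", ["A", "B", "C", "D"], rxns, "DM_B")
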