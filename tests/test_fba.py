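"""Optimisation core: FBA vs brute-force/cobra oracles, FVA, loopless FVA,
MOMA, respiratory quotient, yields, sensitivity and phase planes."""

import copy

import numpy as np
import pytest

from lkcbm import (FluxSolution, Medium, Metabolite, MetabolicModel, Reaction,
                   biomass_sensitivity, fba, fva, loopless_fva, moma,
                   phenotypic_phase_plane, product_yield,
                   respiratory_quotient, viability_screen)
from lkcbm import synth

from _oracles import assemble, brute_force_fba, cobra_fba


def mini_overflow_model(o2_cap=1000.0):
    """9-reaction respiration/fermentation toy for exact vertex enumeration.

    Aerobic optimum per glucose: ATP 2 + 12.5 r + 5 nox = 10 b with
    r = 2 - b, nox = 1 -> b = 32/22.5.
    """
    m = MetabolicModel("mini", compartments={"c": "c"})
    m.add_metabolites([Metabolite(x, compartment="c")
                       for x in ("G", "P", "A", "N", "E", "C", "O")])
    F = 1000.0
    m.add_reactions([
        Reaction("EX_G", stoichiometry={"G": -1}, lower_bound=-1.0, upper_bound=0),
        Reaction("EX_O", stoichiometry={"O": -1}, lower_bound=-o2_cap, upper_bound=0),
        Reaction("EX_E", stoichiometry={"E": -1}, lower_bound=0, upper_bound=F),
        Reaction("EX_C", stoichiometry={"C": -1}, lower_bound=0, upper_bound=F),
        Reaction("GLY", stoichiometry={"G": -1, "P": 2, "A": 2, "N": 2},
                 lower_bound=0, upper_bound=F),
        Reaction("FERM", stoichiometry={"P": -1, "N": -1, "E": 1, "C": 1},
                 lower_bound=0, upper_bound=F),
        Reaction("RESP", stoichiometry={"P": -1, "O": -2.5, "C": 3, "A": 12.5},
                 lower_bound=0, upper_bound=F),
        Reaction("NOX", stoichiometry={"N": -2, "O": -1, "A": 5},
                 lower_bound=0, upper_bound=F),
        Reaction("BIO", stoichiometry={"P": -1, "A": -10}, lower_bound=0,
                 upper_bound=F),
    ])
    m.biomass_reaction_id = "BIO"
    return m


# ---------------------------------------------------------------------------
# FBA


@pytest.mark.parametrize("builder,objective", [
    (synth.make_chain_model, "DM_C"),
    (synth.make_branch_model, "DM_B"),
    (synth.make_loop_model, "DM_B"),
    (mini_overflow_model, "BIO"),
])
def test_fba_equals_brute_force_vertex_enumeration(builder, objective):
    model = builder()
    sol = fba(model, objective=objective)
    assert sol.optimal
    assert sol.objective_value == pytest.approx(
        brute_force_fba(model, None, objective), abs=1e-6
    )


def test_mini_model_matches_analytic_optimum():
    sol = fba(mini_overflow_model())
    assert sol.objective_value == pytest.approx(32 / 22.5, rel=1e-9)


def test_zero_carbon_gives_zero_growth(toy_model, minimal_glucose):
    starved = copy.deepcopy(minimal_glucose)
    starved.uptake_limits["EX_glc__D_e"] = 0.0
    sol = fba(toy_model, starved)
    assert sol.optimal
    assert sol.objective_value == pytest.approx(0.0, abs=1e-9)


def test_toy_optimum_matches_analytic_and_cobra(toy_model, toy_truth, minimal_glucose):
    sol = fba(toy_model, minimal_glucose)
    expected = 10.0 * toy_truth.mu_per_glucose_aerobic
    assert sol.objective_value == pytest.approx(expected, rel=1e-9)
    _, cobra_sol = cobra_fba(toy_model, minimal_glucose)
    assert sol.objective_value == pytest.approx(cobra_sol.objective_value, rel=1e-6)


def test_optimal_solution_satisfies_steady_state_and_bounds(toy_model, minimal_glucose):
    sol = fba(toy_model, minimal_glucose)
    S, lb, ub, rxn_ids = assemble(toy_model, minimal_glucose)
    v = np.array([sol.fluxes[r] for r in rxn_ids])
    assert np.max(np.abs(S @ v)) < 1e-6
    assert np.all(v >= lb - 1e-9) and np.all(v <= ub + 1e-9)


def test_infeasible_model_reported_without_flux_vector():
    m = synth.make_chain_model()
    m.reactions["R1"].bounds = (5.0, 1000.0)
    m.reactions["EX_A"].bounds = (0.0, 1.0)
    sol = fba(m, objective="DM_C")
    assert sol.status == "infeasible"
    assert sol.fluxes == {}


# ---------------------------------------------------------------------------
# respiratory quotient & yields


def test_rq_from_printed_fluxes():
    sol = FluxSolution("optimal", fluxes={"EX_co2_e": 6.4, "EX_o2_e": -6.2})
    assert round(respiratory_quotient(sol, "EX_co2_e", "EX_o2_e"), 2) == 1.03


def test_rq_of_equal_fluxes_is_one():
    sol = FluxSolution("optimal", fluxes={"EX_co2_e": 3.3, "EX_o2_e": -3.3})
    assert respiratory_quotient(sol, "EX_co2_e", "EX_o2_e") == pytest.approx(1.0)


def test_rq_fully_respiratory_glucose_oxidation_is_exactly_one():
    """6 CO2 per 6 O2: pure carbohydrate respiration has RQ = 1."""
    m = mini_overflow_model()
    # force everything through respiration: no biomass, maximise RESP-linked
    # CO2 by demanding ATP instead of growth
    m.add_metabolites([])
    m.reactions["BIO"].stoichiometry = {"A": -1}
    sol = fba(m, objective="BIO")
    rq = respiratory_quotient(sol, "EX_C", "EX_O")
    assert rq == pytest.approx(1.0, rel=1e-9)


def test_rq_undefined_without_oxygen_uptake():
    sol = FluxSolution("optimal", fluxes={"EX_co2_e": 1.0, "EX_o2_e": 0.0})
    with pytest.raises(ValueError):
        respiratory_quotient(sol, "EX_co2_e", "EX_o2_e")


def test_yield_worked_examples():
    sol = FluxSolution("optimal", fluxes={"EX_etoh_e": 2.0, "EX_glc__D_e": -1.0})
    y = product_yield(sol, "EX_etoh_e", "EX_glc__D_e", 46.069, 180.156)
    assert y == pytest.approx(0.5115, abs=1e-3)  # homo-fermentation, 2 EtOH/glc
    zero = FluxSolution("optimal", fluxes={"EX_etoh_e": 0.0, "EX_glc__D_e": -1.0})
    assert product_yield(zero, "EX_etoh_e", "EX_glc__D_e", 46.069, 180.156) == 0.0
    dry = FluxSolution("optimal", fluxes={"EX_etoh_e": 0.0, "EX_glc__D_e": 0.0})
    with pytest.raises(ValueError):
        product_yield(dry, "EX_etoh_e", "EX_glc__D_e", 46.069, 180.156)


def test_rq_and_yield_scale_invariant(toy_model, minimal_glucose):
    """Doubling uptake bounds on a yield-limited network leaves ratios unchanged."""
    sol1 = fba(toy_model, minimal_glucose)
    doubled = copy.deepcopy(minimal_glucose)
    doubled.uptake_limits["EX_glc__D_e"] *= 2
    sol2 = fba(toy_model, doubled)
    rq1 = respiratory_quotient(sol1, "EX_co2_e", "EX_o2_e")
    rq2 = respiratory_quotient(sol2, "EX_co2_e", "EX_o2_e")
    assert rq1 == pytest.approx(rq2, rel=1e-6)
    for prod, mm in (("EX_co2_e", 44.009),):
        y1 = product_yield(sol1, prod, "EX_glc__D_e", mm, 180.156)
        y2 = product_yield(sol2, prod, "EX_glc__D_e", mm, 180.156)
        assert y1 == pytest.approx(y2, rel=1e-6)


# ---------------------------------------------------------------------------
# FVA


def test_fva_chain_has_point_intervals():
    model = synth.make_chain_model()
    iv = fva(model, fraction_of_optimum=1.0)
    for rid, (lo, hi) in iv.intervals.items():
        assert lo == pytest.approx(10.0, abs=1e-6)
        assert hi == pytest.approx(10.0, abs=1e-6)


def test_fva_parallel_branches_each_span_zero_to_demand():
    model = synth.make_branch_model(demand_cap=1.0)
    iv = fva(model, fraction_of_optimum=1.0)
    for branch in ("V1", "V2"):
        lo, hi = iv[branch]
        assert lo == pytest.approx(0.0, abs=1e-6)
        assert hi == pytest.approx(1.0, abs=1e-6)


def test_fva_relaxing_fraction_widens_intervals(toy_model, minimal_glucose):
    tight = fva(toy_model, minimal_glucose, fraction_of_optimum=1.0)
    loose = fva(toy_model, minimal_glucose, fraction_of_optimum=0.9)
    for rid in tight.intervals:
        assert loose[rid][0] <= tight[rid][0] + 1e-6
        assert loose[rid][1] >= tight[rid][1] - 1e-6


def test_fva_contains_the_fba_optimum_flux(toy_model, minimal_glucose):
    sol = fba(toy_model, minimal_glucose)
    iv = fva(toy_model, minimal_glucose, fraction_of_optimum=1.0)
    for rid, (lo, hi) in iv.intervals.items():
        assert lo - 1e-6 <= sol.fluxes[rid] <= hi + 1e-6


# ---------------------------------------------------------------------------
# loopless FVA


def test_loopless_equals_plain_on_acyclic_networks():
    for builder in (synth.make_chain_model, synth.make_branch_model):
        model = builder()
        plain = fva(model, fraction_of_optimum=1.0)
        ll = loopless_fva(model, fraction_of_optimum=1.0)
        assert not ll.unresolved
        for rid in plain.intervals:
            assert ll[rid][0] == pytest.approx(plain[rid][0], abs=1e-6)
            assert ll[rid][1] == pytest.approx(plain[rid][1], abs=1e-6)


def test_loopless_removes_cycle_but_keeps_chain():
    """3-cycle bolted onto a chain: plain FVA inflates the shared edge to the
    default bound; loopless restores the chain-only interval."""
    model = synth.make_loop_model(uptake=10.0)
    plain = fva(model, fraction_of_optimum=1.0)
    ll = loopless_fva(model, fraction_of_optimum=1.0)
    assert plain["L1"][1] == pytest.approx(1000.0, abs=1e-6)
    assert plain["L2"][1] >= 989.0
    for rid in ("L1", "L2", "L3"):
        assert ll[rid] == (pytest.approx(0.0, abs=1e-6),) * 2 or (
            abs(ll[rid][0]) < 1e-6 and abs(ll[rid][1]) < 1e-6)
    assert ll["R1"][0] == pytest.approx(10.0, abs=1e-6)
    assert ll["R1"][1] == pytest.approx(10.0, abs=1e-6)


def test_loopless_intervals_contained_in_plain(toy_model, minimal_glucose):
    sample = ["GLYC_LOWER", "ATPM", "ACK", "PYRSYN", "GLYCSYN", "GLYCUT",
              "FERM", "ETOHDH", "BIOMASS", "EX_o2_e"]
    plain = fva(toy_model, minimal_glucose, fraction_of_optimum=0.9,
                reactions=sample)
    ll = loopless_fva(toy_model, minimal_glucose, fraction_of_optimum=0.9,
                      reactions=sample)
    assert not ll.unresolved
    for rid in sample:
        assert ll[rid][0] >= plain[rid][0] - 1e-6
        assert ll[rid][1] <= plain[rid][1] + 1e-6


# ---------------------------------------------------------------------------
# MOMA


def test_moma_empty_knockout_returns_wildtype():
    model = synth.make_branch_model()
    wt = FluxSolution("optimal", "DM_B", 1.0,
                      {"EX_A": 1.0, "V1": 1.0, "V2": 0.0, "DM_B": 1.0})
    sol = moma(model, wt, [])
    dist = sum((sol.fluxes[k] - wt.fluxes[k]) ** 2 for k in wt.fluxes)
    assert dist == pytest.approx(0.0, abs=1e-8)


def test_moma_branch_switch_matches_hand_qp():
    """Fixed demand 1 via two branches, WT on branch 1; deleting it moves all
    flux to branch 2 at squared distance 2."""
    model = synth.make_branch_model()
    model.reactions["DM_B"].bounds = (1.0, 1.0)
    wt = FluxSolution("optimal", "DM_B", 1.0,
                      {"EX_A": 1.0, "V1": 1.0, "V2": 0.0, "DM_B": 1.0})
    sol = moma(model, wt, ["V1"])
    assert sol.optimal
    assert sol.fluxes["V1"] == pytest.approx(0.0, abs=1e-6)
    assert sol.fluxes["V2"] == pytest.approx(1.0, abs=1e-6)
    dist = sum((sol.fluxes[k] - wt.fluxes[k]) ** 2 for k in wt.fluxes)
    assert dist == pytest.approx(2.0, abs=1e-6)


def test_moma_is_optimal_against_sampled_feasible_points():
    """No randomly sampled feasible knockout vector beats the MOMA distance."""
    model = mini_overflow_model()
    medium = None
    wt = fba(model)
    sol = moma(model, wt, ["RESP"])
    assert sol.optimal
    d_moma = sum((sol.fluxes[k] - wt.fluxes[k]) ** 2 for k in wt.fluxes)
    S, lb, ub, rxn_ids = assemble(model)
    j_resp = rxn_ids.index("RESP")
    rng = np.random.default_rng(7)
    from scipy.optimize import linprog
    for _ in range(40):
        c = rng.normal(size=len(rxn_ids))
        lb2, ub2 = lb.copy(), ub.copy()
        lb2[j_resp] = ub2[j_resp] = 0.0
        res = linprog(c, A_eq=S, b_eq=np.zeros(S.shape[0]),
                      bounds=np.column_stack([lb2, ub2]), method="highs")
        if res.status != 0:
            continue
        d = sum((res.x[i] - wt.fluxes[rxn_ids[i]]) ** 2
                for i in range(len(rxn_ids)))
        assert d_moma <= d + 1e-6


def test_moma_infeasible_knockout_reported():
    model = synth.make_chain_model()
    model.reactions["DM_C"].bounds = (1.0, 1000.0)  # demand forced
    wt = FluxSolution("optimal", "DM_C", 10.0,
                      {"EX_A": 10.0, "R1": 10.0, "R2": 10.0, "DM_C": 10.0})
    sol = moma(model, wt, ["R1"])
    assert sol.status == "infeasible"


# ---------------------------------------------------------------------------
# viability screen


def test_viability_screen_matches_reported_physiology(toy_model):
    base = Medium("base", {"EX_nh4_e": 1000.0, "EX_pi_e": 1000.0,
                           "EX_h2o_e": 1000.0, "EX_h_e": 1000.0})
    table = viability_screen(
        toy_model,
        [("EX_glc__D_e", 10.0), ("EX_gal_e", 10.0), ("EX_malt_e", 5.0),
         ("EX_etoh_e", 10.0), ("EX_glyc_e", 10.0)],
        base_medium=base,
    )
    t = table.set_index(["carbon_source", "regime"])
    # all sources viable aerobically
    assert t.loc[("EX_glc__D_e", "aerobic"), "viable"]
    assert t.loc[("EX_etoh_e", "aerobic"), "viable"]
    assert t.loc[("EX_glyc_e", "aerobic"), "viable"]
    # reduced substrates collapse under oxygen limitation
    for src in ("EX_etoh_e", "EX_glyc_e"):
        assert (t.loc[(src, "anaerobic"), "mu"]
                < 0.1 * t.loc[(src, "aerobic"), "mu"])
    # sugars still ferment anaerobically
    assert t.loc[("EX_glc__D_e", "anaerobic"), "mu"] > 1e-3
    # FVA range brackets the FBA optimum
    assert (t.mu_min <= t.mu + 1e-9).all() and (t.mu <= t.mu_max + 1e-9).all()


def test_viability_screen_unknown_exchange_is_per_row_error(toy_model):
    base = Medium("base", {"EX_nh4_e": 1000.0, "EX_pi_e": 1000.0,
                           "EX_h2o_e": 1000.0, "EX_h_e": 1000.0})
    table = viability_screen(toy_model, [("EX_bogus_e", 1.0),
                                         ("EX_glc__D_e", 10.0)],
                             base_medium=base)
    bogus = table[table.carbon_source == "EX_bogus_e"]
    assert (bogus.error != "").all()
    good = table[table.carbon_source == "EX_glc__D_e"]
    assert good.viable.any()


def test_carbon_free_medium_not_viable(toy_model):
    base = Medium("base", {"EX_nh4_e": 1000.0, "EX_pi_e": 1000.0,
                           "EX_h2o_e": 1000.0, "EX_h_e": 1000.0})
    table = viability_screen(toy_model, [("EX_glc__D_e", 0.0)], base_medium=base)
    assert not table.viable.any()


# ---------------------------------------------------------------------------
# biomass sensitivity


def test_single_precursor_sensitivity_is_inverse_coefficient():
    """With one yield-limiting precursor, mu ~ 1/coefficient: +50% -> 2/3."""
    m = MetabolicModel("sens", compartments={"c": "c"})
    m.add_metabolites([Metabolite("A", compartment="c")])
    m.add_reactions([
        Reaction("EX_A", stoichiometry={"A": 1}, lower_bound=0, upper_bound=1.0),
        Reaction("BIO", stoichiometry={"A": -1.0}, lower_bound=0, upper_bound=1000.0),
    ])
    m.biomass_reaction_id = "BIO"
    rep = biomass_sensitivity(m, relative_perturbation=0.5).iloc[0]
    assert rep.mu_base == pytest.approx(1.0)
    assert rep.mu_plus == pytest.approx(2.0 / 3.0, rel=1e-9)
    assert rep.mu_minus == pytest.approx(2.0, rel=1e-9)


def test_toy_sensitivity_ranks_atp_dominant_and_restores_model(toy_model, minimal_glucose):
    before = dict(toy_model.biomass_reaction.stoichiometry)
    rep = biomass_sensitivity(toy_model, minimal_glucose, relative_perturbation=0.5)
    assert toy_model.biomass_reaction.stoichiometry == before  # never mutated
    # growth-associated ATP dominates the toy biomass: largest mu response
    assert rep.iloc[0].metabolite in ("atp_c", "h2o_c")
    assert (rep.mu_plus <= rep.mu_base + 1e-9).all()


def test_sensitivity_rejects_negative_coefficients(toy_model):
    with pytest.raises(ValueError):
        biomass_sensitivity(toy_model, relative_perturbation=1.5)


# ---------------------------------------------------------------------------
# phenotypic phase plane


def test_phase_plane_origin_equals_unconstrained_optimum(toy_model, minimal_glucose):
    """Under full aeration the optimum secretes nothing, so fixing both
    production fluxes to zero at the origin reproduces it."""
    plane = phenotypic_phase_plane(toy_model, minimal_glucose,
                                   "ETACt", "ETOHt", grid=4)
    assert plane.mu[0, 0] == pytest.approx(plane.mu_unconstrained, rel=1e-6)
    assert plane.phase[0, 0] == 1


def test_phase_plane_mu_non_increasing_beyond_ridge(toy_model, semi_aerobic_glucose):
    plane = phenotypic_phase_plane(toy_model, semi_aerobic_glucose,
                                   "ETACt", "ETOHt", grid=8)
    mu = np.where(np.isnan(plane.mu), -1.0, plane.mu)
    for i in range(mu.shape[0]):
        ridge = int(np.argmax(mu[i]))
        assert np.all(np.diff(mu[i, ridge:]) <= 1e-9)
    for j in range(mu.shape[1]):
        ridge = int(np.argmax(mu[:, j]))
        assert np.all(np.diff(mu[ridge:, j]) <= 1e-9)


def test_phase_plane_shows_penalised_and_infeasible_phases(toy_model, semi_aerobic_glucose):
    plane = phenotypic_phase_plane(toy_model, semi_aerobic_glucose,
                                   "ETACt", "ETOHt", grid=8)
    phases = set(np.unique(plane.phase))
    assert 2 in phases  # production penalises growth
    assert 3 in phases  # and eventually becomes infeasible
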