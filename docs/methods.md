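# Methods

This note records the models, numerical choices and design decisions
behind `lkcbm`, in the spirit of a statistical-software methods appendix.
It states no empirical result that the test-suite or
`scripts/acceptance.py` does not itself compute.

## Steady-state model and sign conventions

All analyses operate on the linear steady-state model
`S v = 0, ℓ ≤ v ≤ u` with fluxes in mmol · gDW⁻¹ · h⁻¹ and the biomass
pseudo-reaction flux interpreted as the specific growth rate μ (h⁻¹),
which presumes biomass coefficients expressed in mmol per gram dry
weight.  Exchange reactions are defined structurally (stoichiometry
touching exactly one metabolite) and follow the uptake-negative
convention; a `Medium` assigns each exchange a maximum uptake magnitude
`u`, applied as lower bound `−u`, leaving secretion bounds untouched.
Exchanges not named in a medium have uptake closed.  The default
unconstrained magnitude is 1000 mmol/gDW/h.  An empty GPR means "always
catalysed", so spontaneous and orphan reactions survive every knockout.

All LPs and MILPs are solved with scipy's HiGHS interfaces through one
thin layer (`lkcbm.solver`).  The flux-significance, viability and
blocked-reaction tolerance is 10⁻⁶ mmol/gDW/h, above double-precision LP
noise and far below any modelled flux.  Because LP optima are degenerate,
no claim about an individual reaction's flux at the optimum is ever based
on the single FBA vertex; such claims go through FVA intervals.

## Curation operators

*Balance.* A reaction is balanced iff every element and the total charge
sum to zero over its stoichiometry.  The pseudo-element "R" (conserved
alkyl moiety) participates like any element, so acyl chemistry can be
checked without expanding chain length.  Exchanges, sinks and the biomass
pseudo-reaction are exempt; a metabolite lacking formula or charge makes
its reactions "uncheckable", never "unbalanced".

*Directionality.* Template bounds (when a curated reference model maps a
reaction) are applied first; remaining reactions matching any of three
rules — ATP as reactant, O₂ as product, NADH/NADPH involvement — get
lower bound 0 in their annotated forward direction.  The operator is
idempotent and logs every change with the triggering rule.

*Blocked reactions.* A reaction is blocked under a medium iff its
maximum and minimum achievable fluxes are both zero (each certified by an
LP).  An infeasible medium raises a distinct error rather than reporting
everything blocked.

*Biomass precursors.* Each biomass substrate is probed with a temporary
demand objective.  Currency couples (ATP/ADP) are moiety-conserved, so a
bare drain on the charged form is structurally impossible; while probing,
the biomass reaction's product metabolites (the spent forms — ADP, Pi,
protons) are therefore made freely available through reversible sinks.
This tests exactly the turnover the biomass reaction itself requires.

*Confidence scores.* 4 = GPR and significant reference flux (also
exchanges carrying flux on the defined medium), 3 = flux without GPR,
2 = GPR without flux, 1 = neither.

## Loopless FVA

The loopless variant uses the mixed-integer loop-law formulation: every
internal (non-exchange) reaction *i* gets a binary direction indicator
`a_i` (flux forced into [0, M] or [−M, 0]) and a potential `G_i`
constrained to the sign opposite the flux (`G_i ∈ [−K, −1]` when forward,
`[1, K]` when backward, M = K = 1000); `G` must be orthogonal to a basis
of the nullspace of the internal stoichiometric submatrix, which is
exactly the condition that no closed internal cycle carries net flux.
When that nullspace is trivial the flux space is acyclic and the
implementation falls back to plain FVA (identical by construction).  A
MILP that fails or times out marks the reaction "unresolved" in the
result, never silently.  Plain-FVA containment and acyclic equality are
enforced by tests.

## MOMA

The knockout flux is the minimiser of ‖v − v_wt‖² over the knockout
polytope.  No quadratic-programming library is assumed; the convex
problem is solved with scipy's SLSQP (equality constraints `S v = 0`,
box bounds, analytic gradient), warm-started from the clipped wild-type
vector, with a feasibility LP run first so infeasible knockouts are
reported as such.  Optimality is cross-checked in the tests against a
hand-solved QP and randomly sampled feasible vertices.

## Dynamic FBA

Static-optimisation DFBA: at each sampling interval an FBA is solved with
the current bounds and held constant, then
`X(t+Δt) = X e^{μΔt}` and `C(t+Δt) = C − v_EX · m · X · (1 − e^{μΔt})/μ`
(m = molar mass/1000, concentrations g/L; uptake-negative fluxes deplete
the pool).  Below |μ| = 10⁻⁹ the analytic limit `C + v_EX · m · X · Δt`
is used; the two branches agree to first order at the switch.  An
availability bound `min(v_max, C/(m X Δt))` prevents overdrawing a pool
within one interval; residual overshoots are clamped at zero and logged.
Product exchanges open for re-uptake only once the primary substrate is
exhausted (sequential, diauxic utilisation; co-consumption is not
modelled).  A step whose FBA is infeasible or growth-free is continued as
a stationary interval with zero exchange and flagged.

Because the optimum under oxygen limitation is degenerate in how the
overflow carbon is split between ethanol, acetate and ethyl acetate, the
simulator can apply a deterministic secondary objective — maximise a
named exchange (ethyl acetate by default in the toy set-up) at the fixed
optimal μ.  This selects the overflow vertex reproducibly and reflects
the organism's known preference for ester formation; it never trades
growth for product.  Default batch conditions: glucose 20 g/L, inoculum
0.05 g/L, 50 h, Δt = 0.5 h, glucose uptake bound 2.28 mmol/gDW/h, oxygen
bound 1000 / 3 / 0.25 mmol/gDW/h for the aerobic, semi-aerobic and
anaerobic regimes.

## Gene essentiality and classification statistics

Deleting a gene zeroes the bounds of exactly those reactions whose GPR
evaluates false without it (AND = complex, OR = isozymes).  The knockout
growth rate comes from FBA re-optimisation or MOMA; a gene is essential
when μ_KO/μ_WT < 0.01 (configurable).  Confusion statistics treat
essential as the positive class; MCC uses the square-rooted denominator
(the only form for which perfect prediction scores 1), and F₁ is the
harmonic precision/recall mean.  When an ortholog map is supplied, only
mapped genes are scored, and a model gene with several reference
orthologs is counted experimentally essential only if all of them are —
duplicate genes buffer lethality, so one dispensable ortholog marks the
function dispensable.  Degenerate comparisons (empty set) raise instead
of returning NaN statistics.

## Expression integration and differential flux

Gene expression maps to reactions by min over AND nodes and max over OR
nodes; a measured-data gap inside an AND leaves the reaction unscored
(logged), and unscored reactions are immune to pruning.  GIMME sets the
threshold θ at a percentile (default 25th) of the scored-reaction
distribution and minimises `Σ (θ − x_i)+ · |v_i|` subject to steady
state, bounds and objective ≥ f × parent optimum (default f = 0.9,
exposed).  A below-threshold reaction is removed only when FVA — under
the same constraints plus the penalty held at its optimum — certifies it
cannot carry flux; metabolites left without reactions are pruned and
logged, which is how a context model ends up with fewer metabolites than
its parent.

Two contexts are compared by the Jaccard index of their per-reaction
(loopless) FVA intervals, measured as interval lengths on the real line;
a degenerate union (two coincident points within 10⁻⁹, or solver noise
below 10⁻⁶ in the differential-flux path) counts as identical (J = 1),
so "J = 0 ⇔ no overlap" remains the differential criterion and identical
contexts flag nothing.  Reactions retained in only one context are
reported separately as context-exclusive; flagged reactions are ranked
by subsystem with lexicographic tie-breaking.

## Growth-rate estimation and validation

μ is estimated from OD₆₀₀ time courses as
`ln(OD(t_f)/OD(t_i))/(t_f − t_i)` over a user window (natural log,
positive for growth — the orientation consistent with the exponential
batch model).  Condition tables run row-wise FBA at stated substrate/O₂
uptakes, recording μ and RQ (CO₂ secretion over O₂ uptake; undefined
without oxygen uptake and signalled as such), with per-row error capture.
Pearson correlation with a one-sided p-value (t distribution, n − 2 df,
H₁: positive association) is delegated to scipy.

## The synthetic toy network

The generator emulates, at ~50 reactions, the metabolic features the
pipeline must exercise: three compartments; glucose/galactose/maltose/
ethanol/glycerol assimilation; glycolysis split into an upper (ATP-
investing, `g_pfk1`) and lower (`g_glyc1`·`g_glyc2`) half around a triose-
phosphate node; fermentation with an ADH isozyme pair; an ATP-yielding
acetate overflow; an ATP-activated acetate assimilation route; a glycerol
branch off the triose node serving as the anaerobic redox valve; lumped
TCA + oxidative phosphorylation at P/O 2.5 in the mitochondrion with a
cytosolic NADH shuttle; an ethyl acetate condensation (ATP-neutral,
capacity-limited at 0.2 mmol/gDW/h, mimicking enzyme saturation) and an
optional URC branch (uracil → urea + 3 CO₂ + 5 NADH, urea → 2 NH₄⁺ +
CO₂) that makes uracil a usable sole nitrogen source.  All internal
reactions carry real molecular formulas and balance exactly, so balance
checks and g/g yields are meaningful.

Biomass consumes 18 pyruvate + 9 ammonium + 180 ATP (+ a net
2 mmol/gDW phosphate demand) per gram.  These coefficients were chosen
once so that at the reference glucose uptake of 2.28 mmol/gDW/h the
aerobic optimum is ≈ 0.18 h⁻¹ with a fully respiratory oxygen demand of
≈ 5.6 mmol/gDW/h — placing the named oxygen regimes (1000 aerobic,
3 semi-aerobic, 0.25 anaerobic) in the physiologically right positions:
pure respiration aerobically, mixed overflow with acetate + ethanol (and
hence ethyl acetate) semi-aerobically, and ethanol + glycerol
fermentation near-anaerobically.  The optima have closed forms recorded
as ground truth (per mmol glucose): μ_aer = 32/(A + 12.5 P) and
μ_ana = 2/(A + 2 P) with P, A the pyruvate and ATP coefficients; the
generator validates the parameter region in which these expressions hold
(enough ATP demand to leave pyruvate for respiration).  Essential genes
(lower glycolysis, PFK, ammonium and phosphate transporters) and the
blocked set under minimal glucose are likewise known by construction and
re-derived by the engines in the tests.

Expression profiles use three clipped log-normal tiers — low ≈ 5,
mid ≈ 30, high ≈ 100 arbitrary units — so that the 25th percentile of
reaction scores always falls between the prunable low tier (the
galactose decoy branch in both conditions, the URC genes under ammonium)
and the constitutive mid tier of flux-carrying transport/glycolysis
genes.  The clipping makes the GIMME outcome identical for every seed;
what varies with the seed is only the within-tier noise.  Condition
tables and OD series use multiplicative Gaussian noise (default 5% and
2%), which respects the positivity of rates and optical densities; the
noise-free generating values are recorded alongside for self-consistency
checks.

What the toy does *not* emulate: genome-scale combinatorics (thousands of
reactions, extensive isozyme redundancy), compartment-specific cofactor
pools beyond NADH, proton-motive-force accounting, enzyme kinetics, and
biological noise structure in microarray data.  Passing tests therefore
demonstrate correctness of the algorithms and their couplings under known
ground truth, not predictive accuracy on any real organism.

## Degenerate inputs and error behaviour

Infeasible FBA returns a status, never a flux vector; RQ and yields on
zero uptake raise; empty GPRs always evaluate true; zero-variance
correlation input raises; GIMME with an unattainable objective fraction
names the binding constraint; pathway insertion rejects id collisions
with the offending id; media naming non-exchange reactions are rejected
at application time.

## Problem sizes

The test-suite and acceptance script run the toy network (51 reactions)
for FBA/FVA/knockout/GIMME analyses, ≤ 15-reaction fixtures for vertex
enumeration and loop elimination, 101-step batch simulations (201 at the
refined step), 1000 random confusion matrices, and 200 random GPR trees
— sizes at which every oracle (enumeration, exhaustive truth tables,
closed forms) is exact and the full suite completes in well under a
minute.
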