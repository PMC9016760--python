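# Methods

## The model

A metabolic network with *m* metabolites and *n* reactions is described by
its stoichiometric matrix *S* and per-reaction flux bounds. The feasible
flux space at steady state is the polyhedron

    FS = { v ∈ R^n : S·v = 0,  lb_j ≤ v_j ≤ ub_j },

with fluxes in mmol/gDW/h and growth (the biomass reaction flux) in h⁻¹.
Two instances of this polyhedron over the same network drive the whole
method: the wild-type space **FS_w** (optionally floored at a wild-type
growth rate, optionally pinned to a measured reference vector v\*) and the
production space **FS_m**, which carries the mutant growth floor and — in
step 1 only — a minimum-production requirement on the target reaction.

The production requirement in step 1 is scaffolding, not a phenotype
constraint: it is set to a fraction (default 1.0) of the maximum
theoretical production rate at the mutant growth floor, minus a 1e-6
slack because an exact-maximum lower bound is numerically brittle. Its only
role is to expose which reactions *must* carry different flux for the
target to be made at all.

## Step 1 — regulation candidates by noticeable flux change

Let v ∈ FS_w and v + Δv ∈ FS_m be a witness pair. A reaction is a
candidate for up-regulation if every such pair has Δv_j ≥ δ_j, and for
down-regulation if Δv_j ≤ −δ_j, where δ_j > 0 is the per-reaction
noticeable-change threshold (default 1 mmol/gDW/h). The MILP

    min (or max)  Σ_j (y_j⁺ + y_j⁻)

searches over witness pairs and binaries with the indicator semantics
y_j⁺ = 1 ⇒ Δv_j ≥ δ_j, y_j⁻ = 1 ⇒ Δv_j ≤ −δ_j, and both zero ⇒
|Δv_j| ≤ δ_j. Indicators are linearised with the FVA-derived flux-change
bounds Δv_j ∈ [m_lo − w_hi, m_hi − w_lo] as big-M constants, which makes
the encoding tight by construction:

    Δv_j ≤ δ_j + (Δv_j^max − δ_j)·y_j⁺ − 2δ_j·y_j⁻
    Δv_j ≥ −δ_j + 2δ_j·y_j⁺ + (Δv_j^min + δ_j)·y_j⁻
    y_j⁺ + y_j⁻ ≤ 1.

Maintenance pseudo-reactions (fixed positive demand, lb > 0) may not
decrease: their Δv lower bound is clamped at 0, which also removes them
from the down-regulation candidates.

Minimisation yields the minimal regulation set F⁺/F⁻; maximisation yields
the maximal set, useful when parallel routes exist and all of them should
surface. A direction of monotonicity worth stating precisely: scaling all
δ_j **up** never grows either set. For the minimal set this is a theorem —
the optimum equals the smallest k for which some k-subset can be left
unconstrained while all other reactions satisfy |Δv_j| ≤ δ_j, and those
caps only loosen as δ grows. The test suite asserts this direction.

Boundary semantics: "unflagged" uses the non-strict cap |Δv_j| ≤ δ_j, so a
reaction that can sit exactly at the threshold is not counted. The
enumeration oracles use the same convention; fixtures are built with slack
around thresholds so the boundary never decides an answer.

## Step 2 — design as network interdiction

Given candidates F⁺, F⁻ and a preprocessed knockout set F×, the engineer
picks at most K_m manipulations (≤ K_ko of them knockouts) and the host
then adopts the flux state worst for production among those that remain
feasible:

    max_y  min_{v_w ∈ FS_w, v_m}  c_P·v_m

subject to S·v_m = 0, mutant bounds with v_m,bio ≥ min_growth, and for
selected binaries: y_j^× = 1 ⇒ v_m,j = 0; y_j⁺ = 1 ⇒ v_m,j − v_w,j ≥ δ_j;
y_j⁻ = 1 ⇒ v_m,j − v_w,j ≤ −δ_j. A reaction eligible both as regulation and
knockout target carries mutually exclusive binaries (Σ ≤ 1), so a double
role never counts once. The inner problem is an LP in (v_w, v_m) whose
right-hand side is affine in y; by strong duality the bilevel program
collapses to one MILP: maximise the inner dual objective subject to dual
feasibility, with binary×dual products w = y·μ linearised by big-M bounds
on the duals (2× the largest primal bound magnitude, escalated ×10 if the
post-hoc check disagrees). The primal constraint block stays in the MILP so
that a selected manipulation set can never make the host infeasible, and
every returned strategy is re-verified by solving the inner LP directly;
the reported guaranteed production is that verified inner minimum.

A positive optimum certifies growth coupling: whatever feasible state the
host adopts at growth ≥ min_growth, production is forced above the
guaranteed value. Among optimal supports the solver prefers the smallest
(ties broken towards lexicographically earlier reaction ids) via a second
MILP with the objective fixed, so reported strategies carry no redundant
manipulations. Alternative strategies are enumerated best-first with
integer cuts on previously returned supports.

Final labels contrast absolute witness fluxes: |v_m,j| > |v_w,j| →
up-regulate, < → down-regulate, and |v_m,j| ≤ 1e-6 → knockout
recommendation (deactivating a reaction completely is experimentally easier
than tuning its expression to a minute flux).

## Preprocessing

Blocked reactions (FVA range exactly {0} in the open model) are removed.
Unbranched linear chains (metabolite with exactly one producer and one
consumer) can be compressed into composite reactions with recorded scale
factors; compression is off by default below 50 reactions so tests read
original identifiers. Knockout candidates F× exclude: growth-essential
reactions (single-knockout FBA below min_growth), exchanges, biomass, the
target and its sole-consumer sink chain, blocked and FVA-fixed-nonzero
reactions, maintenance demands, and spontaneous-annotated reactions. The
exact exclusion heuristics used at genome scale in prior work are not
published in detail; this rule set is a documented, auditable stand-in.

## Parameters

| parameter | default | meaning |
|---|---|---|
| δ_j | 1 mmol/gDW/h | noticeable flux change (per-reaction override allowed) |
| min_growth | 0.1 h⁻¹ | mutant growth floor |
| wt_min_growth | = min_growth | wild-type growth floor (0 disables) |
| production_fraction | 1.0 | step-1 production floor as fraction of the max theoretical rate |
| K_m / K_ko | 10 / 5 | manipulation and knockout budgets |
| gap / time limit | 0 / none | MILP stopping criteria (genome scale: 5% / 10⁴ s) |

Numerical choices: LP primal/dual tolerance 1e-9; MIP feasibility
tolerance 1e-8 (the default 1e-6 can absorb the 1e-6-scale row
coefficients created by the production-floor slack and mis-certify a
boundary solution); reported fluxes rounded to 1e-6; knockout-relabel
threshold 1e-6; strategy verification tolerance 1e-6. The parsimonious
reference flux defaults to the l1 (minimum total flux) objective; an l2
(minimum sum of squares) variant is provided because both conventions
appear in the literature for reference-guided design.

## What the synthetic fixtures emulate — and what they do not

The generators mimic the canonical production-host motif: substrate uptake,
a growth reaction that also produces a reduced cofactor which must be
drained, competing overflow branches with random capacities, and a
heterologous production route (closed in FS_w) whose activity both drains
the cofactor and consumes carbon. This creates the real trade-offs the
method exploits: byproduct interdiction, forced coupling through cofactor
balance, and regulation thresholds that bind. Planted instances are
certified at generation time by the brute-force oracle (exhaustive
enumeration of ≤K manipulation sets, inner LP each) and always strictly
beat the no-intervention baseline.

They do not emulate genome scale: no cofactor multiplicity, no gene–protein–
reaction structure, no thermodynamic constraints, and 5–12 reactions rather
than thousands. Passing tests therefore demonstrates the correctness of the
optimisation machinery (exact agreement with exhaustive oracles, coupling
guarantees, monotone budget behaviour), not predictive accuracy on real
organisms. Problem sizes in the suite and the acceptance script (30 seeded
instances per step, ≤12 reactions, K ≤ 3, 3^n-assignment oracles pruned by
FVA direction feasibility) were chosen so exhaustive certification stays
exact.

## Known limitations

- Alternative-optimum enumeration uses integer cuts; a Benders-style
  decomposition for mass enumeration is out of scope.
- The dual big-M bound is heuristic; it is verified per strategy against
  the inner LP and escalated on mismatch, but pathological duals beyond the
  escalated bound would surface as a reported verification failure rather
  than silently wrong output.
- Reaction-level only: gene-level designs via GPR-expanded stoichiometry
  are not modelled.
- The sole-substrate medium rule closes any exchange whose metabolite has
  carbon (or unknown composition); models without formulas get the
  conservative behaviour.
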