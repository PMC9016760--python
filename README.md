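# fluxdesign

Two-step, growth-coupled strain design for constraint-based metabolic
models.

Metabolic engineers want genetic interventions — reaction knockouts and
up/down-regulations — that force a microbe to overproduce a target
chemical. Most classical tools predict one intervention type, assume the
cell grows optimally, or require exact flux values that wet-lab regulation
cannot hit. `fluxdesign` takes a different route in two optimisation steps
over the steady-state flux space `FS = {v : S·v = 0, lb ≤ v ≤ ub}`:

1. **Regulation candidates.** Find the minimal (or maximal) set of
   reactions whose flux *must* change by at least a noticeable threshold
   δ_j between the wild-type space FS_w and a production space FS_m:

       min Σ_j (y_j⁺ + y_j⁻)   s.t.  v ∈ FS_w,  v + Δv ∈ FS_m,
       y_j⁺ = 1 ⇒ Δv_j ≥ δ_j,   y_j⁻ = 1 ⇒ Δv_j ≤ −δ_j,
       y_j⁺ = y_j⁻ = 0 ⇒ |Δv_j| ≤ δ_j,   y_j⁺ + y_j⁻ ≤ 1.

   No exact fluxes or fold changes are imposed — only "change by at least
   δ", which tolerates expression uncertainty.

2. **Interdiction design.** Choose at most K_m manipulations (≤ K_ko
   knockouts) from the candidates F⁺ ∪ F⁻ ∪ F× that maximise the *minimum*
   production the host can be forced into, whatever flux state it adopts:

       max_y  min_v  c_P·v_m   over the coupled (v_w, v_m) polyhedron.

   The bilevel max–min collapses to a single MILP by LP strong duality.
   A positive optimum is a growth-coupling certificate: at every feasible
   growth rate above the floor, production is at least that value.

Everything runs on scipy's HiGHS LP/MILP interface; models load from SBML
(L3+FBC), COBRA-style JSON (via cobrapy) or the package's own JSON dialect.
Production envelopes, coupling classification (strong/weak/none), a
(δ × min-growth) sensitivity surface, reference-flux (pFBA) support and
deterministic toy-network generators with oracle-certified answers are
included.

## Worked example

The bundled five-reaction branch-point network routes carbon S → M1 → M2,
where it splits to biomass (R3, capacity 6), a secreted byproduct (R4) or —
once the heterologous pathway is expressed — the product (R5). The wild
type takes up 10 units and cannot produce, so ≥ 4 units overflow through
R4.

```python
from fluxdesign import (
    build_design_problem, coupling_class, knockout_candidates,
    minimal_regulation_set, production_envelope, solve_interdiction,
)
from fluxdesign.fixtures import toy_fig1_network

model, fs_w, fs_m = toy_fig1_network()

cands = minimal_regulation_set(fs_w, fs_m, delta=2.0)
print("must change:", sorted(cands.F_plus), "up,", sorted(cands.F_minus), "down")

fx = knockout_candidates(model, target="R5", min_growth=1.0)
problem = build_design_problem(model, "R5", cands, sorted(fx),
                               K_m=2, K_ko=1, min_growth=1.0, fs_w=fs_w)
best = solve_interdiction(problem)[0]
print("strategy:", best.selection(), "-> guaranteed", best.guaranteed_production)

env = production_envelope(problem, best, n_points=5)
print("envelope floor:", env.min_production.tolist())
print("coupling:", coupling_class(env))
```

prints

```
must change: ['R5'] up, ['R4'] down
strategy: {'R5': 'up'} -> guaranteed 2.0
envelope floor: [2.0, 2.0, 2.0, 2.0, 2.0]
coupling: strong
```

Read: to reach the production phenotype at all, exactly the product branch
R5 must gain ≥ 2 flux units and the byproduct branch R4 must lose ≥ 2
(trunk reactions need not change noticeably). A single manipulation —
up-regulating R5 — already guarantees 2 mmol/gDW/h of product at *every*
feasible growth rate, i.e. a strongly growth-coupled design; the envelope
floor confirms it.

The same pipeline is scriptable from the shell:

```sh
fluxdesign candidates -c run.yaml     # step 1 only
fluxdesign design     -c run.yaml     # both steps + verification report
fluxdesign envelope   -c run.yaml     # coupling class of the best design
fluxdesign sensitivity -c run.yaml --deltas 0.5,1,2 --growths 0.5,1,2
```

where `run.yaml` names the model file, target reaction, δ, growth floor,
budgets (K_m, K_ko) and optional medium/pathway/bound overrides; every run
writes a manifest with the full configuration hash for reproducibility.

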