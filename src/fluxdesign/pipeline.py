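"""End-to-end two-step design pipeline.

Wires together the step-1 regulation-candidate MILP and the step-2
interdiction MILP with the preprocessing conventions used throughout the
package:

* FS_w is the wild-type space, optionally floored at ``wt_min_growth``;
* FS_m carries the mutant growth floor and a minimum production requirement
  set to ``production_fraction`` x the maximum theoretical production rate
  of the target at that growth floor (the production floor exists only to
  expose which reactions must change flux; it is not imposed on the final
  strain);
* knockout candidates default to the preprocessed F-times set.
"""

from __future__ import annotations

from dataclasses import dataclass

from .design import (
    DesignProblem,
    DesignStrategy,
    SolverOptions,
    build_design_problem,
    solve_interdiction,
)
from .fluxspace import FluxSpace, max_theoretical_production
from .model import MetabolicModel
from .reduction import knockout_candidates
from .regulation import RegulationCandidates, maximal_regulation_set, minimal_regulation_set

#: tiny slack subtracted from exact-maximum production floors, which are
#: numerically brittle as lower bounds
PRODUCTION_SLACK = 1e-6


@dataclass
class PipelineResult:
    candidates: RegulationCandidates
    problem: DesignProblem
    strategies: list[DesignStrategy]
    max_theoretical: float
    maximal_candidates: RegulationCandidates | None = None


def step1_spaces(
    model: MetabolicModel,
    target: str,
    min_growth: float,
    wt_min_growth: float | None = None,
    production_fraction: float = 1.0,
    wt_overrides: dict | None = None,
    mutant_overrides: dict | None = None,
) -> tuple[FluxSpace, FluxSpace, float]:
    """Construct (FS_w, FS_m, max theoretical production) for step 1."""
    fs_w = FluxSpace(model, bound_overrides=dict(wt_overrides or {}),
                     min_growth=wt_min_growth)
    fs_prod = FluxSpace(model, bound_overrides=dict(mutant_overrides or {}),
                        min_growth=min_growth)
    vmax = max_theoretical_production(fs_prod, target, min_growth)
    floor = max(production_fraction * vmax - PRODUCTION_SLACK, 0.0)
    fs_m = fs_prod.with_requirements(min_production=(target, floor))
    return fs_w, fs_m, vmax


def design_pipeline(
    model: MetabolicModel,
    target: str,
    delta=1.0,
    min_growth: float = 0.1,
    K_m: int = 10,
    K_ko: int = 5,
    knockout_set=None,
    wt_min_growth: float | None = None,
    production_fraction: float = 1.0,
    wt_overrides: dict | None = None,
    mutant_overrides: dict | None = None,
    reference_v: dict | None = None,
    exclude=None,
    use_maximal: bool = False,
    opts: SolverOptions | None = None,
) -> PipelineResult:
    """Run both computational steps and return candidates + strategies.

    By default the wild-type space shares the mutant growth floor
    (``wt_min_growth=None`` means "same as min_growth"); pass ``0.0`` to
    leave the wild type unconstrained.
    """
    if wt_min_growth is None:
        wt_min_growth = min_growth
    fs_w, fs_m, vmax = step1_spaces(
        model, target, min_growth,
        wt_min_growth=wt_min_growth,
        production_fraction=production_fraction,
        wt_overrides=wt_overrides,
        mutant_overrides=mutant_overrides,
    )
    candidates = minimal_regulation_set(fs_w, fs_m, delta, exclude=exclude)
    maximal = None
    if use_maximal:
        maximal = maximal_regulation_set(fs_w, fs_m, delta, exclude=exclude)
    chosen = maximal if use_maximal else candidates
    if knockout_set is None:
        knockout_set = knockout_candidates(model, target, min_growth)
    problem = build_design_problem(
        model, target, chosen, sorted(knockout_set),
        K_m=K_m, K_ko=K_ko, min_growth=min_growth,
        reference_v=reference_v, fs_w=fs_w,
        mutant_overrides=dict(mutant_overrides or {}),
        delta=delta,
    )
    strategies = solve_interdiction(problem, opts)
    return PipelineResult(
        candidates=candidates,
        problem=problem,
        strategies=strategies,
        max_theoretical=vmax,
        maximal_candidates=maximal,
    )
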