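"""Production envelopes, growth-coupling classification and parameter
sensitivity.

The production envelope of a strain (wild type or a design strategy) plots
the minimum and maximum achievable production rate as a function of the
growth rate.  A design is *strongly* growth-coupled when the minimum
production is positive at every feasible growth rate, and *weakly* coupled
when it is positive at the maximum growth rate only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import DesignProblem, DesignStrategy, SolverOptions, _inner_lp
from .lp import InfeasibleProblemError, round_flux

COUPLING_TOL = 1e-6


@dataclass
class ProductionEnvelope:
    growth_grid: np.ndarray
    min_production: np.ndarray
    max_production: np.ndarray
    diagnostic: str = ""

    @property
    def empty(self) -> bool:
        return self.growth_grid.size == 0

    def to_tsv(self, path) -> None:
        pd.DataFrame({
            "growth": self.growth_grid,
            "min_production": self.min_production,
            "max_production": self.max_production,
        }).to_csv(path, sep="\t", index=False)

    def sparkline(self, width: int = 40) -> str:
        """Plain-text rendering of the minimum-production curve."""
        if self.empty:
            return "(empty envelope)"
        blocks = " .:-=+*#%@"
        top = max(self.max_production.max(), 1e-12)
        idx = np.clip(
            (self.min_production / top * (len(blocks) - 1)).astype(int), 0, len(blocks) - 1
        )
        pts = np.linspace(0, len(idx) - 1, min(width, len(idx))).astype(int)
        return "".join(blocks[idx[p]] for p in pts)


def production_envelope(
    problem: DesignProblem,
    strategy: DesignStrategy | None,
    n_points: int = 20,
) -> ProductionEnvelope:
    """Min/max target flux at each growth rate under a strategy.

    The biomass flux is fixed by equality at each grid point; the grid spans
    the feasible growth range of the manipulated (coupled) system.  With
    ``strategy=None`` the envelope is that of the unmanipulated mutant
    space.
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    selection = strategy.selection() if strategy is not None else {}
    model = problem.model

    def at_growth(g: float | None, sense: str, objective_bio: bool = False):
        prob = problem
        if g is not None:
            over = dict(problem.mutant_overrides)
            over[model.biomass_id] = (g, g)
            prob = DesignProblem(
                model=model, target=problem.target,
                F_plus=problem.F_plus, F_minus=problem.F_minus,
                F_times=problem.F_times, delta=problem.delta,
                K_m=problem.K_m, K_ko=problem.K_ko,
                min_growth=min(problem.min_growth, g),
                fs_w=problem.fs_w, reference_v=problem.reference_v,
                mutant_overrides=over,
            )
        if objective_bio:
            prob = _with_target(prob, model.biomass_id)
        return _inner_lp(prob, selection, sense=sense)

    def _with_target(prob: DesignProblem, target: str) -> DesignProblem:
        p = DesignProblem(
            model=prob.model, target=target, F_plus=prob.F_plus,
            F_minus=prob.F_minus, F_times=prob.F_times, delta=prob.delta,
            K_m=prob.K_m, K_ko=prob.K_ko, min_growth=prob.min_growth,
            fs_w=prob.fs_w, reference_v=prob.reference_v,
            mutant_overrides=prob.mutant_overrides,
        )
        return p

    try:
        g_lo, _, _ = at_growth(None, "min", objective_bio=True)
        g_hi, _, _ = at_growth(None, "max", objective_bio=True)
    except InfeasibleProblemError as exc:
        return ProductionEnvelope(
            np.array([]), np.array([]), np.array([]),
            diagnostic=f"strategy infeasible: {exc}",
        )
    grid = np.linspace(g_lo, g_hi, n_points)
    mins = np.empty(n_points)
    maxs = np.empty(n_points)
    for i, g in enumerate(grid):
        lo, _, _ = at_growth(float(g), "min")
        hi, _, _ = at_growth(float(g), "max")
        mins[i] = round_flux(lo)
        maxs[i] = round_flux(hi)
    return ProductionEnvelope(round_flux(grid), mins, maxs)


def coupling_class(env: ProductionEnvelope, tol: float = COUPLING_TOL) -> str:
    """Classify an envelope as ``strong``, ``weak`` or ``none`` coupling."""
    if env.empty:
        return "none"
    positive = env.min_production > tol
    if positive.all():
        return "strong"
    if positive[-1]:
        return "weak"
    return "none"


@dataclass
class SensitivityGrid:
    delta_values: list[float]
    growth_values: list[float]
    best_guaranteed_production: np.ndarray  # shape (len(delta), len(growth))
    notes: dict[tuple[int, int], str] = field(default_factory=dict)

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(
            self.best_guaranteed_production,
            index=pd.Index(self.delta_values, name="delta"),
            columns=pd.Index(self.growth_values, name="min_growth"),
        )
        df.to_csv(path, sep="\t")


def sensitivity_grid(
    model,
    target: str,
    delta_values: list[float],
    growth_values: list[float],
    K_m: int,
    K_ko: int,
    knockout_set=None,
    wt_min_growth: float | None = None,
    production_fraction: float = 1.0,
    opts: SolverOptions | None = None,
) -> SensitivityGrid:
    """Best guaranteed production over a (delta, min_growth) parameter grid.

    Each cell runs the full two-step pipeline; infeasible cells (for
    example a growth floor above the achievable maximum) are NaN and carry
    a note rather than aborting the sweep.
    """
    from .pipeline import design_pipeline

    if not delta_values or not growth_values:
        raise ValueError("delta_values and growth_values must be nonempty")
    out = np.full((len(delta_values), len(growth_values)), math.nan)
    notes: dict[tuple[int, int], str] = {}
    for a, d in enumerate(delta_values):
        for b, g in enumerate(growth_values):
            try:
                result = design_pipeline(
                    model, target, delta=d, min_growth=g,
                    K_m=K_m, K_ko=K_ko, knockout_set=knockout_set,
                    wt_min_growth=wt_min_growth,
                    production_fraction=production_fraction, opts=opts,
                )
                if result.strategies:
                    out[a, b] = result.strategies[0].guaranteed_production
            except InfeasibleProblemError as exc:
                notes[(a, b)] = str(exc)
    return SensitivityGrid(list(delta_values), list(growth_values), out, notes)
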