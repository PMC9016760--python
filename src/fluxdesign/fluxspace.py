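"""Flux spaces and linear-programming primitives (FBA, FVA, pFBA).

A :class:`FluxSpace` is the steady-state polyhedron

    FS = { v : S.v = 0,  lb_j <= v_j <= ub_j }

optionally tightened by named physiological requirements: a minimum growth
rate (floor on the biomass flux) and a minimum production rate (floor on a
target reaction).  The wild-type space FS_w and the production-mutant space
FS_m of a design problem are two such objects over the same model with
different requirements.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .lp import (
    InfeasibleProblemError,
    round_flux,
    solve_lp,
)
from .model import MetabolicModel


@dataclass
class FluxSpace:
    model: MetabolicModel
    bound_overrides: dict[str, tuple[float, float]] = field(default_factory=dict)
    min_growth: float | None = None
    min_production: tuple[str, float] | None = None

    def effective_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """Model bounds with overrides and requirement floors applied."""
        lb = self.model.lb.copy()
        ub = self.model.ub.copy()
        for rid, (lo, hi) in self.bound_overrides.items():
            j = self.model.index(rid)
            lb[j], ub[j] = lo, hi
        if self.min_growth is not None:
            j = self.model.index(self.model.biomass_id)
            lb[j] = max(lb[j], self.min_growth)
        if self.min_production is not None:
            target, rate = self.min_production
            j = self.model.index(target)
            lb[j] = max(lb[j], rate)
        return lb, ub

    def _requirement_text(self) -> str:
        parts = []
        if self.min_growth is not None:
            parts.append(f"min_growth={self.min_growth}")
        if self.min_production is not None:
            parts.append(f"min_production={self.min_production[1]} on {self.min_production[0]}")
        return ", ".join(parts) or "no requirements"

    def with_requirements(self, min_growth=None, min_production=None) -> "FluxSpace":
        return FluxSpace(
            model=self.model,
            bound_overrides=dict(self.bound_overrides),
            min_growth=self.min_growth if min_growth is None else min_growth,
            min_production=self.min_production if min_production is None else min_production,
        )


def fba(fs: FluxSpace, objective: str, sense: str = "max") -> tuple[float, np.ndarray]:
    """Flux balance analysis: optimise one reaction's flux over ``fs``.

    Returns the optimum and an attaining flux vector (rounded to the
    package reporting precision).
    """
    model = fs.model
    lb, ub = fs.effective_bounds()
    c = np.zeros(model.n_reactions)
    c[model.index(objective)] = 1.0
    try:
        res = solve_lp(
            c,
            A_eq=model.S,
            b_eq=np.zeros(model.n_metabolites),
            lo=lb,
            up=ub,
            sense=sense,
            context=fs._requirement_text(),
        )
    except InfeasibleProblemError:
        raise InfeasibleProblemError(
            f"flux space infeasible under {fs._requirement_text()}"
        ) from None
    return float(round_flux(res.objective)), round_flux(res.x)


def fva(fs: FluxSpace, reactions: list[str] | None = None) -> dict[str, tuple[float, float]]:
    """Flux variability analysis: per-reaction min/max flux over ``fs``."""
    model = fs.model
    lb, ub = fs.effective_bounds()
    if reactions is None:
        reactions = list(model.reaction_ids)
    out: dict[str, tuple[float, float]] = {}
    c = np.zeros(model.n_reactions)
    for rid in reactions:
        j = model.index(rid)
        c[:] = 0.0
        c[j] = 1.0
        lo = solve_lp(c, A_eq=model.S, b_eq=np.zeros(model.n_metabolites),
                      lo=lb, up=ub, sense="min", context=f"FVA min {rid}").objective
        hi = solve_lp(c, A_eq=model.S, b_eq=np.zeros(model.n_metabolites),
                      lo=lb, up=ub, sense="max", context=f"FVA max {rid}").objective
        out[rid] = (float(round_flux(lo)), float(round_flux(hi)))
    return out


def reference_flux(fs: FluxSpace, mode: str = "l1") -> np.ndarray:
    """Parsimonious reference flux: among growth-optimal vectors, minimise
    total flux.

    ``mode="l1"`` minimises the sum of absolute fluxes (classic pFBA);
    ``mode="l2"`` minimises the sum of squared fluxes.  Both first fix the
    biomass flux at its FBA optimum.
    """
    model = fs.model
    growth_opt, _ = fba(fs, model.biomass_id, "max")
    lb, ub = fs.effective_bounds()
    j_bio = model.index(model.biomass_id)
    slack = 1e-9 + 1e-9 * abs(growth_opt)
    lb = lb.copy()
    ub = ub.copy()
    lb[j_bio] = growth_opt - slack
    ub[j_bio] = max(ub[j_bio], growth_opt + slack)
    ub[j_bio] = min(ub[j_bio], growth_opt + slack)

    n = model.n_reactions
    if mode == "l1":
        # v = p - q with p, q >= 0; minimise sum(p + q)
        c = np.ones(2 * n)
        A_eq = sp.hstack([model.S, -model.S]).tocsc()
        # bounds on v become inequality rows on (p, q)
        eye = sp.identity(n)
        A_ub = sp.vstack([sp.hstack([-eye, eye]), sp.hstack([eye, -eye])]).tocsc()
        b_ub = np.concatenate([-lb, ub])
        res = solve_lp(
            c,
            A_eq=A_eq,
            b_eq=np.zeros(model.n_metabolites),
            A_ub=A_ub,
            b_ub=b_ub,
            lo=np.zeros(2 * n),
            up=np.full(2 * n, np.inf),
            sense="min",
            context="pFBA (l1)",
        )
        v = res.x[:n] - res.x[n:]
        return round_flux(v)
    if mode == "l2":
        from scipy.optimize import LinearConstraint, minimize

        start = reference_flux(fs, mode="l1").astype(float)
        cons = LinearConstraint(model.S.toarray(), 0.0, 0.0)
        res = minimize(
            lambda v: float(v @ v),
            start,
            jac=lambda v: 2.0 * v,
            bounds=np.column_stack([lb, ub]),
            constraints=[cons],
            method="SLSQP",
            options={"maxiter": 500, "ftol": 1e-12},
        )
        if not res.success:  # pragma: no cover - small problems converge
            raise RuntimeError(f"l2 reference flux failed: {res.message}")
        return round_flux(res.x)
    raise ValueError(f"unknown reference mode {mode!r}")


def max_theoretical_production(
    model_or_fs: MetabolicModel | FluxSpace,
    target: str,
    min_growth: float = 0.0,
) -> float:
    """Maximum flux through ``target`` subject to growth >= ``min_growth``."""
    if isinstance(model_or_fs, FluxSpace):
        fs = model_or_fs.with_requirements(min_growth=min_growth)
    else:
        fs = FluxSpace(model_or_fs, min_growth=min_growth)
    value, _ = fba(fs, target, "max")
    return value
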