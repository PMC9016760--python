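"""Step 1: select up/down-regulation candidates by a flux-change MILP.

Given a wild-type flux space FS_w and a production space FS_m over the same
network, we look for a witness pair (v, v + dv) with v in FS_w and
v + dv in FS_m, and count the reactions whose flux must change noticeably:
binary y+_j (y-_j) marks that reaction j increases (decreases) by at least
the threshold delta_j > 0.  Minimising the count yields the minimal
regulation set F+ / F-; maximising it yields the maximal set used when many
parallel routes should all be listed.

Indicator logic is linearised with big-M constants taken from
:class:`DeltaBounds`, the FVA-derived bounds on the flux change, which makes
the encoding tight by construction:

    dv_j <= delta_j + (dv_max_j - delta_j) y+_j - 2 delta_j y-_j
    dv_j >= -delta_j + 2 delta_j y+_j + (dv_min_j + delta_j) y-_j
    y+_j + y-_j <= 1

so that y=0 on both sides confines |dv_j| <= delta_j, while a set binary
forces the change past the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.optimize import LinearConstraint

from .fluxspace import FluxSpace, fva
from .lp import InfeasibleProblemError, round_flux, solve_milp
from .model import MetabolicModel
from .reduction import is_maintenance


@dataclass
class DeltaBounds:
    """Per-reaction bounds on the flux change dv between FS_w and FS_m."""

    reaction_ids: list[str]
    dv_min: np.ndarray
    dv_max: np.ndarray

    def for_reaction(self, rid: str) -> tuple[float, float]:
        j = self.reaction_ids.index(rid)
        return float(self.dv_min[j]), float(self.dv_max[j])


@dataclass
class RegulationCandidates:
    """Result of the step-1 MILP."""

    F_plus: set[str]
    F_minus: set[str]
    delta_v: dict[str, float]
    delta: dict[str, float]
    objective_count: int
    sense: str  # "minimal" | "maximal"
    witness_wild: dict[str, float] = field(default_factory=dict)

    def to_tsv(self, path) -> None:
        rows = [
            (rid, "up" if rid in self.F_plus else "down", self.delta_v[rid], self.delta[rid])
            for rid in sorted(self.F_plus | self.F_minus)
        ]
        pd.DataFrame(rows, columns=["reaction_id", "direction", "delta_v", "delta"]).to_csv(
            path, sep="\t", index=False
        )


def build_delta_bounds(fs_w: FluxSpace, fs_m: FluxSpace) -> DeltaBounds:
    """FVA-derived bounds on dv_j = v_m,j - v_w,j.

    ``dv_max_j = max(FS_m)_j - min(FS_w)_j`` and symmetrically for the
    minimum.  Reactions whose flux may not decrease (maintenance demands
    with a fixed positive lower bound in both spaces) have their dv lower
    bound clamped at zero.
    """
    model = fs_w.model
    ranges_w = fva(fs_w)
    ranges_m = fva(fs_m)
    dv_min = np.empty(model.n_reactions)
    dv_max = np.empty(model.n_reactions)
    for j, rid in enumerate(model.reaction_ids):
        w_lo, w_hi = ranges_w[rid]
        m_lo, m_hi = ranges_m[rid]
        dv_min[j] = m_lo - w_hi
        dv_max[j] = m_hi - w_lo
        if is_maintenance(model, rid):
            dv_min[j] = max(dv_min[j], 0.0)
            dv_max[j] = max(dv_max[j], dv_min[j])
    return DeltaBounds(list(model.reaction_ids), dv_min, dv_max)


def _as_delta_array(model: MetabolicModel, delta) -> np.ndarray:
    if np.isscalar(delta):
        arr = np.full(model.n_reactions, float(delta))
    else:
        arr = np.array([float(delta[r]) for r in model.reaction_ids])
    if np.any(arr <= 0):
        raise ValueError("all flux-change thresholds delta_j must be > 0")
    return arr


def _diagnose_infeasibility(fs_w: FluxSpace, fs_m: FluxSpace) -> str:
    from .fluxspace import fba

    for name, fs in (("FS_w", fs_w), ("FS_m", fs_m)):
        try:
            fba(fs, fs.model.biomass_id, "max")
        except InfeasibleProblemError:
            return f"{name} is infeasible on its own ({fs._requirement_text()})"
    return "FS_w and FS_m are individually feasible; the coupled system is not"


def _regulation_milp(
    fs_w: FluxSpace,
    fs_m: FluxSpace,
    delta,
    exclude: set[str] | None,
    sense: str,
    bounds: DeltaBounds | None = None,
    mip_gap: float = 0.0,
    time_limit: float | None = None,
) -> RegulationCandidates:
    model = fs_w.model
    if fs_m.model is not model and fs_m.model.reaction_ids != model.reaction_ids:
        raise ValueError("FS_w and FS_m must be defined over the same reactions")
    exclude = set(exclude or ())
    delta_arr = _as_delta_array(model, delta)
    if bounds is None:
        bounds = build_delta_bounds(fs_w, fs_m)
    dv_min = np.minimum(bounds.dv_min, 0.0)  # dv = 0 must stay representable
    dv_max = np.maximum(bounds.dv_max, 0.0)

    n = model.n_reactions
    m = model.n_metabolites
    lb_w, ub_w = fs_w.effective_bounds()
    lb_m, ub_m = fs_m.effective_bounds()

    # variables: x = [v (n), dv (n), y+ (n), y- (n)]
    nv = 4 * n
    lo = np.concatenate([lb_w, dv_min, np.zeros(n), np.zeros(n)])
    up = np.concatenate([ub_w, dv_max, np.ones(n), np.ones(n)])
    # binaries that are excluded or whose direction is unreachable are fixed 0
    for j, rid in enumerate(model.reaction_ids):
        if rid in exclude or dv_max[j] < delta_arr[j]:
            up[2 * n + j] = 0.0
        if rid in exclude or dv_min[j] > -delta_arr[j]:
            up[3 * n + j] = 0.0

    integrality = np.zeros(nv)
    integrality[2 * n:] = 1

    Z = sp.csc_matrix((m, n))
    S = sp.csc_matrix(model.S)
    eye = sp.identity(n, format="csc")
    zee = sp.csc_matrix((n, n))

    constraints = [
        # steady state for wild type and for the flux change
        LinearConstraint(sp.hstack([S, Z, Z, Z]), 0.0, 0.0),
        LinearConstraint(sp.hstack([Z, S, Z, Z]), 0.0, 0.0),
        # mutant bounds: lb_m <= v + dv <= ub_m
        LinearConstraint(sp.hstack([eye, eye, zee, zee]), lb_m, ub_m),
        # indicator upper side: dv - (dv_max - d) y+ + 2 d y- <= d
        LinearConstraint(
            sp.hstack([zee, eye, -sp.diags(dv_max - delta_arr), sp.diags(2 * delta_arr)]),
            -np.inf,
            delta_arr,
        ),
        # indicator lower side: dv - 2 d y+ - (dv_min + d) y- >= -d
        LinearConstraint(
            sp.hstack([zee, eye, -sp.diags(2 * delta_arr), -sp.diags(dv_min + delta_arr)]),
            -delta_arr,
            np.inf,
        ),
        # a reaction cannot increase and decrease at once
        LinearConstraint(sp.hstack([zee, zee, eye, eye]), -np.inf, np.ones(n)),
    ]

    c = np.zeros(nv)
    c[2 * n:] = 1.0
    try:
        res = solve_milp(
            c,
            constraints,
            integrality,
            lo,
            up,
            sense="min" if sense == "minimal" else "max",
            mip_gap=mip_gap,
            time_limit=time_limit,
            context=f"{sense} regulation set",
        )
    except InfeasibleProblemError:
        raise InfeasibleProblemError(
            "regulation MILP infeasible: " + _diagnose_infeasibility(fs_w, fs_m)
        ) from None

    v = round_flux(res.x[:n])
    dv = round_flux(res.x[n:2 * n])
    yp = res.x[2 * n:3 * n] > 0.5
    ym = res.x[3 * n:] > 0.5
    rid = model.reaction_ids
    return RegulationCandidates(
        F_plus={rid[j] for j in range(n) if yp[j]},
        F_minus={rid[j] for j in range(n) if ym[j]},
        delta_v={rid[j]: float(dv[j]) for j in range(n)},
        delta={rid[j]: float(delta_arr[j]) for j in range(n)},
        objective_count=int(round(res.objective)),
        sense=sense,
        witness_wild={rid[j]: float(v[j]) for j in range(n)},
    )


def minimal_regulation_set(
    fs_w: FluxSpace,
    fs_m: FluxSpace,
    delta,
    exclude: set[str] | None = None,
    bounds: DeltaBounds | None = None,
    mip_gap: float = 0.0,
    time_limit: float | None = None,
) -> RegulationCandidates:
    """Smallest set of reactions that must change flux by >= delta_j to move
    the cell from FS_w into FS_m."""
    return _regulation_milp(fs_w, fs_m, delta, exclude, "minimal",
                            bounds=bounds, mip_gap=mip_gap, time_limit=time_limit)


def maximal_regulation_set(
    fs_w: FluxSpace,
    fs_m: FluxSpace,
    delta,
    exclude: set[str] | None = None,
    bounds: DeltaBounds | None = None,
    mip_gap: float = 0.0,
    time_limit: float | None = None,
) -> RegulationCandidates:
    """Largest set of reactions that can simultaneously show a noticeable
    flux change while reaching FS_m; useful when parallel routes exist and
    all of them should be surfaced as candidates."""
    return _regulation_milp(fs_w, fs_m, delta, exclude, "maximal",
                            bounds=bounds, mip_gap=mip_gap, time_limit=time_limit)
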