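"""Exhaustive oracles for the regulation-selection step.

These enumerate flagged-reaction subsets directly and test plain LP
feasibility for each, providing an independent route to the step-1 MILP
optima on small networks.  Complexity is exponential, so the functions are
guarded to toy sizes and used only in tests and verification scripts.
"""

from __future__ import annotations

import itertools

import numpy as np
import scipy.sparse as sp

from .fluxspace import FluxSpace
from .lp import InfeasibleProblemError, solve_lp
from .regulation import DeltaBounds, _as_delta_array, build_delta_bounds

_MAX_CANDIDATES = 12


def _pair_feasible(
    fs_w: FluxSpace,
    fs_m: FluxSpace,
    delta_arr: np.ndarray,
    directions: dict[int, str],
    capped: list[int],
) -> bool:
    """Is there a witness pair (v, v+dv) with the stated flux-change
    pattern?  ``directions`` forces dv_j >= delta (``+``) or <= -delta
    (``-``); reactions in ``capped`` must keep |dv_j| <= delta_j."""
    model = fs_w.model
    n, m = model.n_reactions, model.n_metabolites
    lb_w, ub_w = fs_w.effective_bounds()
    lb_m, ub_m = fs_m.effective_bounds()
    dv_lo = np.full(n, -np.inf)
    dv_hi = np.full(n, np.inf)
    for j in capped:
        dv_lo[j] = -delta_arr[j]
        dv_hi[j] = delta_arr[j]
    for j, sign in directions.items():
        if sign == "+":
            dv_lo[j] = delta_arr[j]
            dv_hi[j] = np.inf
        else:
            dv_lo[j] = -np.inf
            dv_hi[j] = -delta_arr[j]
    S = sp.csc_matrix(model.S)
    Z = sp.csc_matrix((m, n))
    eye = sp.identity(n, format="csc")
    A_eq = sp.vstack([sp.hstack([S, Z]), sp.hstack([Z, S])]).tocsc()
    A_ub = sp.vstack([sp.hstack([eye, eye]), sp.hstack([-eye, -eye])]).tocsc()
    b_ub = np.concatenate([ub_m, -lb_m])
    try:
        solve_lp(
            np.zeros(2 * n),
            A_eq=A_eq,
            b_eq=np.zeros(2 * m),
            A_ub=A_ub,
            b_ub=b_ub,
            lo=np.concatenate([lb_w, dv_lo]),
            up=np.concatenate([ub_w, dv_hi]),
        )
        return True
    except InfeasibleProblemError:
        return False


def minimal_regulation_count_oracle(
    fs_w: FluxSpace,
    fs_m: FluxSpace,
    delta,
    exclude: set[str] | None = None,
) -> int:
    """Smallest k such that all but k reactions can keep |dv_j| <= delta_j.

    Direction does not need enumerating here: any witness for a relaxed
    k-subset yields flagged directions for free.
    """
    model = fs_w.model
    delta_arr = _as_delta_array(model, delta)
    exclude = set(exclude or ())
    cand = [j for j, r in enumerate(model.reaction_ids) if r not in exclude]
    if len(cand) > _MAX_CANDIDATES:
        raise ValueError("oracle guard: too many candidate reactions")
    all_idx = list(range(model.n_reactions))
    for k in range(len(cand) + 1):
        for subset in itertools.combinations(cand, k):
            capped = [j for j in all_idx if j not in subset]
            if _pair_feasible(fs_w, fs_m, delta_arr, {}, capped):
                return k
    raise InfeasibleProblemError("no flagged subset admits a witness pair")


def maximal_regulation_count_oracle(
    fs_w: FluxSpace,
    fs_m: FluxSpace,
    delta,
    exclude: set[str] | None = None,
    bounds: DeltaBounds | None = None,
) -> int:
    """Largest number of reactions that can simultaneously change by
    >= delta_j (with explicit per-reaction direction enumeration)."""
    model = fs_w.model
    delta_arr = _as_delta_array(model, delta)
    exclude = set(exclude or ())
    if bounds is None:
        bounds = build_delta_bounds(fs_w, fs_m)
    options: list[tuple[int, list[str]]] = []
    for j, r in enumerate(model.reaction_ids):
        if r in exclude:
            continue
        opts = []
        if bounds.dv_max[j] >= delta_arr[j]:
            opts.append("+")
        if bounds.dv_min[j] <= -delta_arr[j]:
            opts.append("-")
        if opts:
            options.append((j, opts))
    if len(options) > _MAX_CANDIDATES:
        raise ValueError("oracle guard: too many candidate reactions")
    all_idx = list(range(model.n_reactions))
    for k in range(len(options), -1, -1):
        for chosen in itertools.combinations(options, k):
            idxs = [j for j, _ in chosen]
            capped = [j for j in all_idx if j not in idxs]
            for assignment in itertools.product(*[opts for _, opts in chosen]):
                directions = dict(zip(idxs, assignment))
                if _pair_feasible(fs_w, fs_m, delta_arr, directions, capped):
                    return k
    raise InfeasibleProblemError("no flagged subset admits a witness pair")
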