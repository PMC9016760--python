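"""Step 2: bilevel network-interdiction design of manipulation strategies.

The metabolic engineer picks at most ``K_m`` manipulations — knockouts from
F-times (at most ``K_ko`` of them) and up/down-regulations from F+ / F- —
and the host then realises the flux distribution *worst* for production
among all that remain feasible.  The design objective is therefore a
max-min game:

    max_y  min_{v_w, v_m}  c_P . v_m

subject to, for the inner (host) problem with binaries y fixed:

    S v_w = 0,  lb_w <= v_w <= ub_w            (wild-type space, or v_w = v*)
    S v_m = 0,  lb_m <= v_m <= ub_m,  v_m,bio >= min_growth
    y_j^x = 1  =>  v_m,j = 0                   (knockout)
    y_j^+ = 1  =>  v_m,j - v_w,j >=  delta_j   (up-regulation)
    y_j^- = 1  =>  v_m,j - v_w,j <= -delta_j   (down-regulation)

The inner minimisation is an LP in (v_w, v_m) whose right-hand side is
affine in y, so by strong duality the bilevel program collapses to a single
MILP: maximise the inner dual objective subject to dual feasibility, with
the bilinear products (binary x dual) linearised by big-M bounds on the
dual variables.  The primal constraint block is kept in the MILP as well so
that selected manipulation sets always leave the host viable, and every
returned strategy is re-verified post hoc by solving the inner LP directly.

A positive optimum certifies growth coupling: production is forced above
that value no matter which feasible flux state the host adopts.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp
from scipy.optimize import LinearConstraint

from .fluxspace import FluxSpace, fva
from .lp import (
    InfeasibleProblemError,
    OptimizationError,
    round_flux,
    solve_lp,
    solve_milp,
)
from .model import MetabolicModel

#: below this |flux| a regulated reaction is easier to knock out than to tune
ZERO_FLUX_THRESHOLD = 1e-6
VERIFY_TOL = 1e-6


@dataclass
class SolverOptions:
    mip_gap: float = 0.0
    time_limit: float | None = None
    pool_size: int = 1
    dual_bound: float | None = None  # big-M on dual variables; None = auto
    prune: bool = True  # secondary solve for a minimal, lexicographic support


@dataclass
class DesignStrategy:
    knockouts: set[str] = field(default_factory=set)
    upregulated: set[str] = field(default_factory=set)
    downregulated: set[str] = field(default_factory=set)
    guaranteed_production: float = 0.0
    classification: dict[str, str] = field(default_factory=dict)
    solver_status: str = "optimal"
    witness_wild: dict[str, float] = field(default_factory=dict)
    witness_mutant: dict[str, float] = field(default_factory=dict)

    @property
    def manipulations(self) -> set[str]:
        return self.knockouts | self.upregulated | self.downregulated

    def selection(self) -> dict[str, str]:
        sel = {r: "ko" for r in self.knockouts}
        sel.update({r: "up" for r in self.upregulated})
        sel.update({r: "down" for r in self.downregulated})
        return sel


@dataclass
class DesignProblem:
    model: MetabolicModel
    target: str
    F_plus: list[str]
    F_minus: list[str]
    F_times: list[str]
    delta: dict[str, float]
    K_m: int
    K_ko: int
    min_growth: float
    fs_w: FluxSpace
    reference_v: dict[str, float] | None = None
    mutant_overrides: dict[str, tuple[float, float]] = field(default_factory=dict)
    _dv_bounds: tuple[np.ndarray, np.ndarray] | None = None

    @property
    def fs_m(self) -> FluxSpace:
        return FluxSpace(
            self.model,
            bound_overrides=dict(self.mutant_overrides),
            min_growth=self.min_growth,
        )

    def wild_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        if self.reference_v is not None:
            v = np.array([self.reference_v.get(r, 0.0) for r in self.model.reaction_ids])
            return v.copy(), v.copy()
        return self.fs_w.effective_bounds()

    def entries(self) -> list[tuple[str, str]]:
        """Ordered candidate entries (reaction, role); deterministic."""
        out = [(r, "up") for r in sorted(self.F_plus)]
        out += [(r, "down") for r in sorted(self.F_minus)]
        out += [(r, "ko") for r in sorted(self.F_times)]
        return out

    def dv_hull(self) -> tuple[np.ndarray, np.ndarray]:
        """FVA-derived hull on v_m - v_w used as big-M for couplings."""
        if self._dv_bounds is None:
            ranges_w = fva(self.fs_w)
            ranges_m = fva(self.fs_m)
            dv_min = np.empty(self.model.n_reactions)
            dv_max = np.empty(self.model.n_reactions)
            for j, rid in enumerate(self.model.reaction_ids):
                w_lo, w_hi = ranges_w[rid]
                m_lo, m_hi = ranges_m[rid]
                dv_min[j] = min(m_lo - w_hi, 0.0)
                dv_max[j] = max(m_hi - w_lo, 0.0)
            self._dv_bounds = (dv_min, dv_max)
        return self._dv_bounds


def build_design_problem(
    model: MetabolicModel,
    target: str,
    candidates,
    F_times,
    K_m: int,
    K_ko: int,
    min_growth: float,
    reference_v: dict[str, float] | None = None,
    fs_w: FluxSpace | None = None,
    mutant_overrides: dict[str, tuple[float, float]] | None = None,
    delta=1.0,
) -> DesignProblem:
    """Validate and assemble a :class:`DesignProblem`.

    ``candidates`` is a :class:`RegulationCandidates` (or any object with
    ``F_plus``/``F_minus``/``delta``); ``F_times`` the knockout candidate
    set.  A reaction present both as regulation and knockout candidate keeps
    both roles; the solver picks at most one.
    """
    if target not in model.reaction_ids:
        raise ValueError(f"target reaction {target!r} not in model")
    if K_ko > K_m:
        raise ValueError(f"K_ko={K_ko} exceeds K_m={K_m}")
    if K_m < 0 or K_ko < 0:
        raise ValueError("manipulation budgets must be non-negative")
    F_plus = sorted(set(candidates.F_plus))
    F_minus = sorted(set(candidates.F_minus))
    if set(F_plus) & set(F_minus):
        raise ValueError("a reaction cannot be both an up- and a down-candidate")
    delta_map = dict(getattr(candidates, "delta", {}) or {})
    if np.isscalar(delta):
        for r in F_plus + F_minus:
            delta_map.setdefault(r, float(delta))
    for r in F_plus + F_minus:
        if delta_map.get(r, 0.0) <= 0:
            raise ValueError(f"regulation candidate {r!r} needs a threshold delta > 0")
    unknown = (set(F_plus) | set(F_minus) | set(F_times)) - set(model.reaction_ids)
    if unknown:
        raise ValueError(f"candidate reactions not in model: {sorted(unknown)}")
    if model.biomass_id in F_times:
        raise ValueError("the biomass reaction cannot be a knockout candidate")
    return DesignProblem(
        model=model,
        target=target,
        F_plus=F_plus,
        F_minus=F_minus,
        F_times=sorted(set(F_times)),
        delta=delta_map,
        K_m=K_m,
        K_ko=K_ko,
        min_growth=min_growth,
        fs_w=fs_w if fs_w is not None else FluxSpace(model),
        reference_v=reference_v,
        mutant_overrides=dict(mutant_overrides or {}),
    )


# --------------------------------------------------------------------------
# inner (host) LP for a fixed manipulation set
# --------------------------------------------------------------------------

def _inner_lp(problem: DesignProblem, selection: dict[str, str], sense: str = "min"):
    """Optimise target flux over the coupled (v_w, v_m) polyhedron with the
    given manipulations applied.  Returns (objective, v_w, v_m)."""
    model = problem.model
    n, m = model.n_reactions, model.n_metabolites
    lbw, ubw = problem.wild_bounds()
    lbm, ubm = problem.fs_m.effective_bounds()
    lbm, ubm = lbm.copy(), ubm.copy()
    rows = []
    lo_r = []
    up_r = []
    for rid, role in selection.items():
        j = model.index(rid)
        if role == "ko":
            lbm[j] = 0.0
            ubm[j] = 0.0
        else:
            row = np.zeros(2 * n)
            row[n + j] = 1.0
            row[j] = -1.0
            d = problem.delta[rid]
            if role == "up":
                rows.append(row)
                lo_r.append(d)
                up_r.append(np.inf)
            else:
                rows.append(row)
                lo_r.append(-np.inf)
                up_r.append(-d)
    S = sp.csc_matrix(model.S)
    Z = sp.csc_matrix((m, n))
    A_eq = sp.vstack([sp.hstack([S, Z]), sp.hstack([Z, S])]).tocsc()
    A_ub = None
    b_ub = None
    if rows:
        R = np.vstack(rows)
        blocks = []
        rhs = []
        for row, lo, hi in zip(R, lo_r, up_r):
            if np.isfinite(hi):
                blocks.append(row)
                rhs.append(hi)
            if np.isfinite(lo):
                blocks.append(-row)
                rhs.append(-lo)
        A_ub = sp.csc_matrix(np.vstack(blocks))
        b_ub = np.array(rhs)
    c = np.zeros(2 * n)
    c[n + model.index(problem.target)] = 1.0
    res = solve_lp(
        c,
        A_eq=A_eq,
        b_eq=np.zeros(2 * m),
        A_ub=A_ub,
        b_ub=b_ub,
        lo=np.concatenate([lbw, lbm]),
        up=np.concatenate([ubw, ubm]),
        sense=sense,
        context=f"inner LP with {selection}" if selection else "inner LP (no manipulations)",
    )
    return float(res.objective), res.x[:n], res.x[n:]


# --------------------------------------------------------------------------
# single-level MILP via strong duality
# --------------------------------------------------------------------------

class _OuterMILP:
    """Assembles the duality reformulation of the max-min design problem."""

    def __init__(self, problem: DesignProblem, dual_bound: float):
        self.problem = problem
        model = problem.model
        self.n = n = model.n_reactions
        self.m = m = model.n_metabolites
        self.entries = problem.entries()
        self.nb = len(self.entries)
        self.M = dual_bound
        lbw, ubw = problem.wild_bounds()
        lbm, ubm = problem.fs_m.effective_bounds()
        dv_min, dv_max = problem.dv_hull()

        ko_entry = {
            k: model.index(r) for k, (r, role) in enumerate(self.entries) if role == "ko"
        }

        # inner primal: min c.x, A_eq x = 0, G x >= h0 + H y, x free
        G_rows = []      # (coef dict over x indices)
        h0 = []
        coupling = []    # (row index, entry index, H coefficient)
        for j in range(n):
            G_rows.append({j: 1.0}); h0.append(lbw[j])
            G_rows.append({j: -1.0}); h0.append(-ubw[j])
        for j in range(n):
            r_lo = len(G_rows)
            G_rows.append({n + j: 1.0}); h0.append(lbm[j])
            r_hi = len(G_rows)
            G_rows.append({n + j: -1.0}); h0.append(-ubm[j])
            for k, jj in ko_entry.items():
                if jj == j:
                    if lbm[j] != 0.0:
                        coupling.append((r_lo, k, -lbm[j]))
                    if ubm[j] != 0.0:
                        coupling.append((r_hi, k, ubm[j]))
        for k, (rid, role) in enumerate(self.entries):
            if role == "ko":
                continue
            j = model.index(rid)
            d = problem.delta[rid]
            r = len(G_rows)
            if role == "up":
                G_rows.append({n + j: 1.0, j: -1.0})
                h0.append(dv_min[j])
                coupling.append((r, k, d - dv_min[j]))
            else:
                G_rows.append({j: 1.0, n + j: -1.0})
                h0.append(-dv_max[j])
                coupling.append((r, k, d + dv_max[j]))

        self.K = len(G_rows)
        G = sp.lil_matrix((self.K, 2 * n))
        for r, coefs in enumerate(G_rows):
            for idx, val in coefs.items():
                G[r, idx] = val
        self.G = sp.csc_matrix(G)
        self.h0 = np.array(h0)
        self.coupling = coupling
        S = sp.csc_matrix(model.S)
        Z = sp.csc_matrix((m, n))
        self.A_eq = sp.vstack([sp.hstack([S, Z]), sp.hstack([Z, S])]).tocsc()
        self.c_inner = np.zeros(2 * n)
        self.c_inner[n + model.index(problem.target)] = 1.0

        # x hull bounds for the primal feasibility block
        self.x_lo = np.concatenate([lbw, lbm]).astype(float)
        self.x_hi = np.concatenate([ubw, ubm]).astype(float)
        for k, j in ko_entry.items():
            self.x_lo[n + j] = min(self.x_lo[n + j], 0.0)
            self.x_hi[n + j] = max(self.x_hi[n + j], 0.0)

        # variable layout: [y (nb) | lambda (2m) | mu (K) | w (nc) | x (2n)]
        self.nc = len(coupling)
        self.off_y = 0
        self.off_l = self.nb
        self.off_mu = self.off_l + 2 * m
        self.off_w = self.off_mu + self.K
        self.off_x = self.off_w + self.nc
        self.nv = self.off_x + 2 * n

    def objective_vector(self) -> np.ndarray:
        c = np.zeros(self.nv)
        c[self.off_mu:self.off_mu + self.K] = self.h0
        for t, (_r, _k, coef) in enumerate(self.coupling):
            c[self.off_w + t] = coef
        return c

    def constraints(self, cuts: list[set[int]]) -> list[LinearConstraint]:
        n, m, K, nb, nc, nv = self.n, self.m, self.K, self.nb, self.nc, self.nv
        cons = []
        # dual feasibility: A_eq^T lambda + G^T mu = c_inner
        D = sp.lil_matrix((2 * n, nv))
        D[:, self.off_l:self.off_l + 2 * m] = self.A_eq.T
        D[:, self.off_mu:self.off_mu + K] = self.G.T
        cons.append(LinearConstraint(sp.csc_matrix(D), self.c_inner, self.c_inner))
        # w linearisation: w <= mu; w <= M y; w >= mu - M (1 - y)
        if nc:
            W1 = sp.lil_matrix((nc, nv))
            W2 = sp.lil_matrix((nc, nv))
            W3 = sp.lil_matrix((nc, nv))
            for t, (r, k, _coef) in enumerate(self.coupling):
                W1[t, self.off_w + t] = 1.0
                W1[t, self.off_mu + r] = -1.0
                W2[t, self.off_w + t] = 1.0
                W2[t, self.off_y + k] = -self.M
                W3[t, self.off_w + t] = 1.0
                W3[t, self.off_mu + r] = -1.0
                W3[t, self.off_y + k] = -self.M
            cons.append(LinearConstraint(sp.csc_matrix(W1), -np.inf, np.zeros(nc)))
            cons.append(LinearConstraint(sp.csc_matrix(W2), -np.inf, np.zeros(nc)))
            cons.append(LinearConstraint(sp.csc_matrix(W3), np.full(nc, -self.M), np.inf))
        # primal feasibility: A_eq x = 0 ; G x - H y >= h0
        P1 = sp.lil_matrix((2 * m, nv))
        P1[:, self.off_x:] = self.A_eq
        cons.append(LinearConstraint(sp.csc_matrix(P1), np.zeros(2 * m), np.zeros(2 * m)))
        P2 = sp.lil_matrix((K, nv))
        P2[:, self.off_x:] = self.G
        for r, k, coef in self.coupling:
            P2[r, self.off_y + k] = -coef
        cons.append(LinearConstraint(sp.csc_matrix(P2), self.h0, np.inf))
        # budgets
        B = sp.lil_matrix((2, nv))
        for k, (_rid, role) in enumerate(self.entries):
            B[0, self.off_y + k] = 1.0
            if role == "ko":
                B[1, self.off_y + k] = 1.0
        cons.append(LinearConstraint(
            sp.csc_matrix(B), -np.inf,
            np.array([self.problem.K_m, self.problem.K_ko], dtype=float),
        ))
        # one role per reaction
        by_rxn: dict[str, list[int]] = {}
        for k, (rid, _role) in enumerate(self.entries):
            by_rxn.setdefault(rid, []).append(k)
        multi = [ks for ks in by_rxn.values() if len(ks) > 1]
        if multi:
            R = sp.lil_matrix((len(multi), nv))
            for i, ks in enumerate(multi):
                for k in ks:
                    R[i, self.off_y + k] = 1.0
            cons.append(LinearConstraint(sp.csc_matrix(R), -np.inf, np.ones(len(multi))))
        # integer cuts excluding previous supports
        for supp in cuts:
            row = sp.lil_matrix((1, nv))
            for k in supp:
                row[0, self.off_y + k] = 1.0
            cons.append(LinearConstraint(
                sp.csc_matrix(row), -np.inf, np.array([len(supp) - 1.0])
            ))
        return cons

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.empty(self.nv)
        hi = np.empty(self.nv)
        lo[:self.nb] = 0.0
        hi[:self.nb] = 1.0
        lo[self.off_l:self.off_mu] = -self.M
        hi[self.off_l:self.off_mu] = self.M
        lo[self.off_mu:self.off_w] = 0.0
        hi[self.off_mu:self.off_w] = self.M
        lo[self.off_w:self.off_x] = 0.0
        hi[self.off_w:self.off_x] = self.M
        lo[self.off_x:] = self.x_lo
        hi[self.off_x:] = self.x_hi
        return lo, hi

    def integrality(self) -> np.ndarray:
        integ = np.zeros(self.nv)
        integ[:self.nb] = 1
        return integ

    def solve(self, opts: SolverOptions, cuts: list[set[int]]):
        c = self.objective_vector()
        cons = self.constraints(cuts)
        lo, hi = self.bounds()
        res = solve_milp(
            c, cons, self.integrality(), lo, hi,
            sense="max", mip_gap=opts.mip_gap, time_limit=opts.time_limit,
            context="interdiction MILP",
        )
        y = res.x[:self.nb]
        if opts.prune:
            y = self._prune(res.objective, c, cons, lo, hi, opts)
        support = {k for k in range(self.nb) if y[k] > 0.5}
        return res.objective, support

    def _prune(self, best, c, cons, lo, hi, opts: SolverOptions):
        """Among optimal supports, pick the smallest (lexicographic ties)."""
        nv = self.nv
        row = sp.lil_matrix((1, nv))
        row[0, :] = c
        cons2 = cons + [LinearConstraint(
            sp.csc_matrix(row), np.array([best - 1e-7 - 1e-9 * abs(best)]), np.inf
        )]
        c2 = np.zeros(nv)
        for k in range(self.nb):
            c2[self.off_y + k] = 1.0 + k / (10.0 * max(self.nb, 1))
        res = solve_milp(
            c2, cons2, self.integrality(), lo, hi,
            sense="min", mip_gap=opts.mip_gap, time_limit=opts.time_limit,
            context="support pruning MILP",
        )
        return res.x[:self.nb]


def _auto_dual_bound(problem: DesignProblem) -> float:
    lbw, ubw = problem.wild_bounds()
    lbm, ubm = problem.fs_m.effective_bounds()
    mags = np.concatenate([np.abs(lbw), np.abs(ubw), np.abs(lbm), np.abs(ubm),
                           [abs(d) for d in problem.delta.values()] or [1.0]])
    return 2.0 * max(float(mags.max()), 1.0)


def _strategy_from_support(problem: DesignProblem, support: set[int]) -> DesignStrategy:
    entries = problem.entries()
    s = DesignStrategy()
    for k in support:
        rid, role = entries[k]
        if role == "ko":
            s.knockouts.add(rid)
        elif role == "up":
            s.upregulated.add(rid)
        else:
            s.downregulated.add(rid)
    return s


def solve_interdiction(problem: DesignProblem, opts: SolverOptions | None = None) -> list[DesignStrategy]:
    """Solve the max-min design problem; return strategies best-first.

    Alternative strategies (``opts.pool_size`` > 1) are generated by integer
    cuts that exclude previously returned binary supports.  Each strategy's
    ``guaranteed_production`` is re-verified by solving the inner LP with
    its manipulations fixed.
    """
    opts = opts or SolverOptions()
    # configuration sanity: the unmanipulated coupled system must be viable
    try:
        baseline, _, _ = _inner_lp(problem, {})
    except InfeasibleProblemError:
        raise InfeasibleProblemError(
            "design problem infeasible with zero manipulations; "
            "check growth floor, medium and bound overrides"
        ) from None
    M = opts.dual_bound if opts.dual_bound is not None else _auto_dual_bound(problem)
    strategies: list[DesignStrategy] = []
    cuts: list[set[int]] = []
    for _ in range(max(opts.pool_size, 1)):
        strategy = None
        for attempt in range(3):
            outer = _OuterMILP(problem, M * (10 ** attempt))
            try:
                obj, support = outer.solve(opts, cuts)
            except InfeasibleProblemError:
                return strategies  # pool exhausted
            cand = _strategy_from_support(problem, support)
            inner, v_w, v_m = _inner_lp(problem, cand.selection())
            if abs(inner - obj) <= 1e-4 * (1.0 + abs(inner)):
                cand.guaranteed_production = float(round_flux(inner))
                cand.witness_wild = {
                    r: float(round_flux(v_w[j])) for j, r in enumerate(problem.model.reaction_ids)
                }
                cand.witness_mutant = {
                    r: float(round_flux(v_m[j])) for j, r in enumerate(problem.model.reaction_ids)
                }
                strategy = cand
                break
        if strategy is None:  # pragma: no cover - big-M escalation exhausted
            raise OptimizationError(
                "duality reformulation did not certify the inner optimum; "
                "increase SolverOptions.dual_bound"
            )
        strategy = classify_regulations(
            strategy, strategy.witness_wild, strategy.witness_mutant
        )
        strategies.append(strategy)
        if not strategy.manipulations:
            break  # the empty support cannot be cut away
        cuts.append({k for k, e in enumerate(problem.entries())
                     if (e[0] in strategy.selection() and strategy.selection()[e[0]] == e[1])})
    return strategies


def classify_regulations(
    strategy: DesignStrategy,
    v_w_witness: dict[str, float],
    v_m_witness: dict[str, float],
    zero_threshold: float = ZERO_FLUX_THRESHOLD,
) -> DesignStrategy:
    """Label each manipulation by contrasting absolute witness fluxes.

    A regulation target whose mutant flux is essentially zero is relabelled
    as a knockout recommendation: complete deactivation is experimentally
    easier than tuning expression to a minute flux.
    """
    labels: dict[str, str] = {r: "knockout" for r in strategy.knockouts}
    for rid in strategy.upregulated | strategy.downregulated:
        try:
            vw = v_w_witness[rid]
            vm = v_m_witness[rid]
        except KeyError:
            raise ValueError(f"missing witness flux for regulated reaction {rid!r}")
        if abs(vm) <= zero_threshold:
            labels[rid] = "knockout-recommendation"
        elif abs(vm) > abs(vw):
            labels[rid] = "up-regulate"
        elif abs(vm) < abs(vw):
            labels[rid] = "down-regulate"
        else:
            labels[rid] = "unchanged-magnitude"
    return replace(strategy, classification=labels)


@dataclass
class VerificationRecord:
    min_production: float
    max_production: float
    matches_guarantee: bool
    discrepancy: float


def verify_strategy(
    problem: DesignProblem,
    strategy: DesignStrategy,
) -> VerificationRecord:
    """Re-derive the guaranteed minimum production for a strategy by direct
    LP and compare with the stored value."""
    lo, _, _ = _inner_lp(problem, strategy.selection())
    hi, _, _ = _inner_lp(problem, strategy.selection(), sense="max")
    disc = abs(lo - strategy.guaranteed_production)
    return VerificationRecord(
        min_production=float(round_flux(lo)),
        max_production=float(round_flux(hi)),
        matches_guarantee=disc <= VERIFY_TOL,
        discrepancy=float(disc),
    )


def brute_force_oracle(problem: DesignProblem, max_size: int) -> DesignStrategy:
    """Exact max-min optimum by exhaustive enumeration (test oracle).

    Guarded to small instances: at most 20 candidate entries and subsets of
    size <= 3.  Infeasible manipulation sets (which would kill the host) are
    skipped, mirroring the primal feasibility block of the MILP.
    """
    entries = problem.entries()
    if len(entries) > 20 or max_size > 3:
        raise ValueError(
            f"oracle guard exceeded: {len(entries)} entries, max_size={max_size}"
        )
    best_obj = -np.inf
    best_sel: dict[str, str] = {}
    best_witness = None
    for size in range(0, min(max_size, problem.K_m) + 1):
        for combo in itertools.combinations(range(len(entries)), size):
            rxns = [entries[k][0] for k in combo]
            if len(set(rxns)) < len(rxns):
                continue
            if sum(1 for k in combo if entries[k][1] == "ko") > problem.K_ko:
                continue
            selection = {entries[k][0]: entries[k][1] for k in combo}
            try:
                obj, v_w, v_m = _inner_lp(problem, selection)
            except InfeasibleProblemError:
                continue
            if obj > best_obj + 1e-9:
                best_obj = obj
                best_sel = selection
                best_witness = (v_w, v_m)
    if best_witness is None:
        raise InfeasibleProblemError("no feasible manipulation set (including empty)")
    s = DesignStrategy(
        knockouts={r for r, role in best_sel.items() if role == "ko"},
        upregulated={r for r, role in best_sel.items() if role == "up"},
        downregulated={r for r, role in best_sel.items() if role == "down"},
        guaranteed_production=float(round_flux(best_obj)),
    )
    rid = problem.model.reaction_ids
    s.witness_wild = {r: float(round_flux(best_witness[0][j])) for j, r in enumerate(rid)}
    s.witness_mutant = {r: float(round_flux(best_witness[1][j])) for j, r in enumerate(rid)}
    return s
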