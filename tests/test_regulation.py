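"""Step-1 flux-change MILP: delta bounds, minimal/maximal sets, oracles."""

import numpy as np
import pytest

from fluxdesign.fixtures import random_branched_network
from fluxdesign.fluxspace import FluxSpace
from fluxdesign.lp import InfeasibleProblemError
from fluxdesign.oracles import (
    maximal_regulation_count_oracle,
    minimal_regulation_count_oracle,
)
from fluxdesign.pipeline import step1_spaces
from fluxdesign.regulation import (
    build_delta_bounds,
    maximal_regulation_set,
    minimal_regulation_set,
)


def _random_step1(seed):
    # wild type lacks the production pathway (heterologous route closed)
    model = random_branched_network(2 + seed % 2, seed=seed)
    return step1_spaces(model, "EX_P", min_growth=0.3, wt_min_growth=0.3,
                        wt_overrides={"PRODSYN": (0.0, 0.0)})[:2]


def test_delta_bounds_identical_spaces(fig1):
    model, _, _ = fig1
    fs = FluxSpace(model)
    b = build_delta_bounds(fs, fs)
    j = model.index("R4")  # open model: R4 range [0, 6] (trunk cap via R3?)
    lo, hi = b.for_reaction("R4")
    assert lo == pytest.approx(-hi)  # symmetric for identical spaces
    assert hi > 0


def test_delta_bounds_maintenance_clamped():
    import scipy.sparse as sp

    from fluxdesign.model import MetabolicModel

    # ATPM-style demand with fixed positive lower bound
    S = sp.csc_matrix(np.array([[1.0, -1.0, -1.0]]))
    model = MetabolicModel(
        metabolite_ids=["atp"], reaction_ids=["SRC", "ATPM", "BIO"],
        S=S, lb=np.array([0.0, 6.86, 0.0]), ub=np.array([100.0, 6.86, 50.0]),
        biomass_id="BIO", exchange_ids=["SRC"],
    )
    fs = FluxSpace(model)
    b = build_delta_bounds(fs, fs)
    lo, hi = b.for_reaction("ATPM")
    assert lo == 0.0 and hi >= 0.0


def test_delta_bounds_contain_sampled_pairs(fig1):
    model, fs_w, fs_m = fig1
    b = build_delta_bounds(fs_w, fs_m)
    rng = np.random.default_rng(0)
    # random feasible pairs via FBA with random objectives
    lbw, ubw = fs_w.effective_bounds()
    lbm, ubm = fs_m.effective_bounds()
    from fluxdesign.lp import solve_lp

    for _ in range(200):
        c = rng.normal(size=model.n_reactions)
        vw = solve_lp(c, A_eq=model.S, b_eq=np.zeros(model.n_metabolites),
                      lo=lbw, up=ubw).x
        vm = solve_lp(rng.normal(size=model.n_reactions), A_eq=model.S,
                      b_eq=np.zeros(model.n_metabolites), lo=lbm, up=ubm).x
        dv = vm - vw
        assert np.all(dv >= b.dv_min - 1e-6)
        assert np.all(dv <= b.dv_max + 1e-6)


def test_fig1_minimal_set_is_r5_up_r4_down(fig1):
    _, fs_w, fs_m = fig1
    cands = minimal_regulation_set(fs_w, fs_m, 2.0)
    assert cands.F_plus == {"R5"}
    assert cands.F_minus == {"R4"}
    assert cands.objective_count == 2
    # witness pair is consistent with the flagged directions
    assert cands.delta_v["R5"] >= 2.0 - 1e-6
    assert cands.delta_v["R4"] <= -2.0 + 1e-6
    for rid in ("R1", "R2", "R3"):
        assert abs(cands.delta_v[rid]) <= 2.0 + 1e-6


def test_identical_spaces_need_no_change(fig1):
    model, _, _ = fig1
    fs = FluxSpace(model, min_growth=1.0)
    cands = minimal_regulation_set(fs, fs, 2.0)
    assert cands.objective_count == 0
    assert cands.F_plus == set() and cands.F_minus == set()


def test_minimal_count_matches_subset_oracle():
    for seed in (1, 4, 9):
        fs_w, fs_m = _random_step1(seed)
        got = minimal_regulation_set(fs_w, fs_m, 1.0).objective_count
        exp = minimal_regulation_count_oracle(fs_w, fs_m, 1.0)
        assert got == exp, f"seed {seed}"


def test_maximal_count_matches_assignment_oracle():
    for seed in (2, 5):
        fs_w, fs_m = _random_step1(seed)
        got = maximal_regulation_set(fs_w, fs_m, 1.0).objective_count
        exp = maximal_regulation_count_oracle(fs_w, fs_m, 1.0)
        assert got == exp, f"seed {seed}"


def test_maximal_at_least_minimal_and_disjoint_directions(fig1):
    _, fs_w, fs_m = fig1
    mini = minimal_regulation_set(fs_w, fs_m, 2.0)
    maxi = maximal_regulation_set(fs_w, fs_m, 2.0)
    assert maxi.objective_count >= mini.objective_count
    for c in (mini, maxi):
        assert not (c.F_plus & c.F_minus)
        assert c.objective_count == len(c.F_plus) + len(c.F_minus)


def test_delta_monotonicity():
    """Raising every threshold never grows either regulation set."""
    minimal_counts = []
    maximal_counts = []
    for seed in (1, 4):
        fs_w, fs_m = _random_step1(seed)
        minimal_counts = [
            minimal_regulation_set(fs_w, fs_m, d).objective_count
            for d in (0.5, 1.0, 2.0)
        ]
        maximal_counts = [
            maximal_regulation_set(fs_w, fs_m, d).objective_count
            for d in (0.5, 1.0, 2.0)
        ]
        assert minimal_counts == sorted(minimal_counts, reverse=True)
        assert maximal_counts == sorted(maximal_counts, reverse=True)


def test_excluding_everything_with_binding_production_is_infeasible(fig1):
    model, fs_w, fs_m = fig1
    # wild type cannot produce (R5 closed); if no reaction may change
    # noticeably, the production requirement cannot be met
    with pytest.raises(InfeasibleProblemError):
        minimal_regulation_set(fs_w, fs_m, 2.0, exclude=set(model.reaction_ids))


def test_witness_lp_reproduces_binaries(fig1):
    """Fixing the chosen binaries leaves a feasible (v, dv) pair."""
    model, fs_w, fs_m = fig1
    cands = minimal_regulation_set(fs_w, fs_m, 2.0)
    v = np.array([cands.witness_wild[r] for r in model.reaction_ids])
    dv = np.array([cands.delta_v[r] for r in model.reaction_ids])
    lbw, ubw = fs_w.effective_bounds()
    lbm, ubm = fs_m.effective_bounds()
    tol = 1e-5
    assert np.all(v >= lbw - tol) and np.all(v <= ubw + tol)
    assert np.all(v + dv >= lbm - tol) and np.all(v + dv <= ubm + tol)
    assert np.allclose(model.S @ v, 0, atol=tol)
    assert np.allclose(model.S @ (v + dv), 0, atol=tol)
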