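"""Step-2 interdiction MILP, duality soundness, classification, budgets."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fluxdesign.design import (
    DesignStrategy,
    SolverOptions,
    brute_force_oracle,
    build_design_problem,
    classify_regulations,
    solve_interdiction,
    verify_strategy,
    _inner_lp,
)
from fluxdesign.fixtures import planted_design_instance, toy_fig1_network
from fluxdesign.fluxspace import FluxSpace
from fluxdesign.reduction import knockout_candidates
from fluxdesign.regulation import RegulationCandidates, minimal_regulation_set


def _fig1_problem(K_m=2, K_ko=1):
    model, fs_w, fs_m = toy_fig1_network()
    cands = minimal_regulation_set(fs_w, fs_m, 2.0)
    fx = knockout_candidates(model, "R5", 1.0)
    return build_design_problem(
        model, "R5", cands, sorted(fx), K_m=K_m, K_ko=K_ko,
        min_growth=1.0, fs_w=fs_w,
    )


def test_build_design_problem_validation():
    model, fs_w, fs_m = toy_fig1_network()
    cands = minimal_regulation_set(fs_w, fs_m, 2.0)
    # paper-scale budgets are accepted
    p = build_design_problem(model, "R5", cands, ["R4"], K_m=10, K_ko=5,
                             min_growth=1.0, fs_w=fs_w)
    assert p.K_m == 10 and p.K_ko == 5
    with pytest.raises(ValueError, match="K_ko"):
        build_design_problem(model, "R5", cands, ["R4"], K_m=5, K_ko=6,
                             min_growth=1.0, fs_w=fs_w)
    with pytest.raises(ValueError, match="target"):
        build_design_problem(model, "NOPE", cands, ["R4"], K_m=2, K_ko=1,
                             min_growth=1.0, fs_w=fs_w)
    # empty F-times is fine: knockouts simply impossible
    p = build_design_problem(model, "R5", cands, [], K_m=2, K_ko=1,
                             min_growth=1.0, fs_w=fs_w)
    assert p.F_times == []


def test_interdiction_beats_byproduct_drain():
    """Forcing the product pathway active yields a positive guarantee."""
    problem = _fig1_problem()
    strategies = solve_interdiction(problem)
    best = strategies[0]
    assert best.guaranteed_production == pytest.approx(2.0)
    assert "R5" in best.upregulated
    oracle = brute_force_oracle(problem, 2)
    assert oracle.guaranteed_production == pytest.approx(best.guaranteed_production)


def test_zero_budget_baseline():
    problem = _fig1_problem(K_m=0, K_ko=0)
    strategies = solve_interdiction(problem)
    assert strategies[0].manipulations == set()
    lo, _, _ = _inner_lp(problem, {})
    assert strategies[0].guaranteed_production == pytest.approx(lo)
    assert lo == pytest.approx(0.0)


@pytest.mark.parametrize("seed", [2, 3, 5, 8, 13])
def test_interdiction_matches_oracle_on_planted_instances(seed):
    inst = planted_design_instance(seed, K=1 + seed % 3)
    problem = inst.problem()
    best = solve_interdiction(problem)[0]
    assert best.guaranteed_production == pytest.approx(
        inst.expected_best_objective, abs=1e-6
    )
    assert inst.expected_best_objective > inst.baseline_objective


def test_budget_monotonicity_fig1():
    values = []
    for K in range(4):
        problem = _fig1_problem(K_m=K, K_ko=min(K, 1))
        values.append(solve_interdiction(problem)[0].guaranteed_production)
    assert values == sorted(values)


@settings(deadline=None, max_examples=6, derandomize=True)
@given(seed=st.integers(min_value=1, max_value=40))
def test_oracle_budget_monotonicity(seed):
    """The exact max-min optimum never decreases with a larger budget."""
    inst = planted_design_instance(seed, K=2)
    problem = inst.problem()
    o1 = brute_force_oracle(problem, 1).guaranteed_production
    o2 = brute_force_oracle(problem, 2).guaranteed_production
    assert o2 >= o1 - 1e-9


def test_strong_duality_certificate():
    """The MILP objective equals the inner LP optimum for the chosen y."""
    problem = _fig1_problem()
    best = solve_interdiction(problem)[0]
    inner, _, _ = _inner_lp(problem, best.selection())
    assert inner == pytest.approx(best.guaranteed_production, abs=1e-6)


def test_verify_strategy_contract():
    problem = _fig1_problem()
    best = solve_interdiction(problem)[0]
    rec = verify_strategy(problem, best)
    assert rec.matches_guarantee
    assert rec.min_production <= rec.max_production
    # no growth-essential reaction is ever knocked out
    from fluxdesign.reduction import essential_reactions

    ess = essential_reactions(problem.model, problem.min_growth)
    assert best.knockouts & ess == set()


def test_pool_returns_distinct_strategies():
    problem = _fig1_problem(K_m=2, K_ko=1)
    strategies = solve_interdiction(problem, SolverOptions(pool_size=3))
    supports = [frozenset(s.selection().items()) for s in strategies]
    assert len(supports) == len(set(supports))
    values = [s.guaranteed_production for s in strategies]
    assert values == sorted(values, reverse=True)


def test_classification_rule():
    s = DesignStrategy(upregulated={"A", "C"}, downregulated={"B"})
    out = classify_regulations(
        s,
        v_w_witness={"A": 5.0, "B": -5.0, "C": 2.0},
        v_m_witness={"A": 8.0, "B": -1.0, "C": 1e-8},
    )
    assert out.classification["A"] == "up-regulate"
    assert out.classification["B"] == "down-regulate"  # absolute values
    assert out.classification["C"] == "knockout-recommendation"
    with pytest.raises(ValueError, match="witness"):
        classify_regulations(s, {}, {})


def test_reference_mode_agrees_on_singleton_wild_space():
    model, fs_w, fs_m = toy_fig1_network()
    # pin the wild type to a single vector (measured reference)
    fs_w_pinned = FluxSpace(
        model,
        bound_overrides={"R1": (10.0, 10.0), "R5": (0.0, 0.0),
                         "R3": (6.0, 6.0), "R4": (4.0, 4.0), "R2": (10.0, 10.0)},
    )
    vstar = {r: fs_w_pinned.effective_bounds()[0][model.index(r)]
             for r in model.reaction_ids}
    cands = RegulationCandidates(
        F_plus={"R5"}, F_minus={"R4"}, delta_v={}, delta={"R5": 2.0, "R4": 2.0},
        objective_count=2, sense="minimal",
    )
    free = build_design_problem(model, "R5", cands, ["R4"], K_m=2, K_ko=1,
                                min_growth=1.0, fs_w=fs_w_pinned)
    ref = build_design_problem(model, "R5", cands, ["R4"], K_m=2, K_ko=1,
                               min_growth=1.0, fs_w=fs_w_pinned,
                               reference_v=vstar)
    v_free = solve_interdiction(free)[0].guaranteed_production
    v_ref = solve_interdiction(ref)[0].guaranteed_production
    assert v_free == pytest.approx(v_ref, abs=1e-6)


def test_oracle_guard():
    problem = _fig1_problem()
    with pytest.raises(ValueError, match="guard"):
        brute_force_oracle(problem, 4)
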