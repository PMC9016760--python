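"""FBA/FVA/pFBA primitives, cross-checked against cobrapy on GLPK."""

import numpy as np
import pytest

from fluxdesign.fluxspace import (
    FluxSpace,
    fba,
    fva,
    max_theoretical_production,
    reference_flux,
)
from fluxdesign.lp import InfeasibleProblemError
from fluxdesign.model import to_cobra


def _cobra_fba(model, objective, fs=None):
    cm = to_cobra(model)
    cm.solver = "glpk"
    if fs is not None:
        lb, ub = fs.effective_bounds()
        for j, rid in enumerate(model.reaction_ids):
            cm.reactions.get_by_id(rid).bounds = (lb[j], ub[j])
    cm.objective = objective
    return cm.optimize().objective_value


def test_fba_capacity_bound_on_chain(chain4):
    val, v = fba(FluxSpace(chain4), "BIO", "max")
    assert val == pytest.approx(10.0)
    # the returned vector is feasible and attains the optimum
    assert np.allclose(chain4.S @ v, 0.0, atol=1e-6)
    assert v[chain4.index("BIO")] == pytest.approx(val)


def test_fba_matches_independent_solver(fig1):
    model, fs_w, fs_m = fig1
    for fs in (FluxSpace(model), fs_w, fs_m):
        ours, _ = fba(fs, model.biomass_id, "max")
        theirs = _cobra_fba(model, model.biomass_id, fs)
        assert ours == pytest.approx(theirs, abs=1e-6)


def test_fba_reports_infeasibility_with_requirement(fig1):
    model, _, _ = fig1
    fs = FluxSpace(model, min_growth=50.0)  # far above the achievable 6
    with pytest.raises(InfeasibleProblemError, match="min_growth=50"):
        fba(fs, model.biomass_id, "max")


def test_fba_min_max_ordering(fig1):
    model, fs_w, _ = fig1
    hi, _ = fba(fs_w, "R3", "max")
    lo, _ = fba(fs_w, "R3", "min")
    assert hi >= lo


def test_fva_parallel_routes_and_blocked(parallel_routes_model):
    ranges = fva(FluxSpace(parallel_routes_model))
    assert ranges["ROUTE_A"] == (0.0, 10.0)
    assert ranges["ROUTE_B"] == (0.0, 10.0)


def test_fva_matches_cobra(fig1):
    from cobra.flux_analysis import flux_variability_analysis

    model, fs_w, _ = fig1
    ours = fva(fs_w)
    cm = to_cobra(model)
    cm.solver = "glpk"
    lb, ub = fs_w.effective_bounds()
    for j, rid in enumerate(model.reaction_ids):
        cm.reactions.get_by_id(rid).bounds = (lb[j], ub[j])
    theirs = flux_variability_analysis(cm, fraction_of_optimum=0.0)
    for rid in model.reaction_ids:
        assert ours[rid][0] == pytest.approx(theirs.loc[rid, "minimum"], abs=1e-6)
        assert ours[rid][1] == pytest.approx(theirs.loc[rid, "maximum"], abs=1e-6)


def test_fva_interval_contains_fba_optimum_and_contracts(fig1):
    model, _, _ = fig1
    open_fs = FluxSpace(model)
    ranges_open = fva(open_fs)
    _, v = fba(open_fs, "R5", "max")
    for j, rid in enumerate(model.reaction_ids):
        lo, hi = ranges_open[rid]
        assert lo - 1e-6 <= v[j] <= hi + 1e-6
    # adding a constraint never widens any interval
    ranges_tight = fva(FluxSpace(model, min_growth=2.0))
    for rid in model.reaction_ids:
        assert ranges_tight[rid][0] >= ranges_open[rid][0] - 1e-9
        assert ranges_tight[rid][1] <= ranges_open[rid][1] + 1e-9


def test_reference_flux_unique_chain(chain4):
    fs = FluxSpace(chain4)
    expected = np.full(chain4.n_reactions, 10.0)
    for mode in ("l1", "l2"):
        np.testing.assert_allclose(reference_flux(fs, mode), expected, atol=1e-5)


def test_reference_flux_l2_splits_parallel_routes(parallel_routes_model):
    v = reference_flux(FluxSpace(parallel_routes_model), "l2")
    m = parallel_routes_model
    assert v[m.index("ROUTE_A")] == pytest.approx(5.0, abs=1e-4)
    assert v[m.index("ROUTE_B")] == pytest.approx(5.0, abs=1e-4)


def test_reference_flux_l1_total_not_above_l2(fig1):
    model, fs_w, _ = fig1
    l1 = np.abs(reference_flux(fs_w, "l1")).sum()
    l2 = np.abs(reference_flux(fs_w, "l2")).sum()
    assert l1 <= l2 + 1e-6


def test_max_theoretical_production(fig1, chain4):
    model, _, _ = fig1
    assert max_theoretical_production(chain4, "BIO", 0.0) == pytest.approx(10.0)
    # toy net: growth floor 1 leaves 9 units of carbon for product
    assert max_theoretical_production(model, "R5", 1.0) == pytest.approx(9.0)
    # full competition: at maximum growth nothing is left for the product
    from fluxdesign.fixtures import chain_model

    cm = chain_model(2)
    # add competition by capping: growth at max 10 consumes all uptake
    fs = FluxSpace(cm, min_growth=10.0)
    val, _ = fba(fs, cm.biomass_id, "max")
    assert val == pytest.approx(10.0)
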