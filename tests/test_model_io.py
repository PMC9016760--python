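"""Model container, file round-trips, pathway grafting and media."""

import numpy as np
import pytest
import scipy.sparse as sp

from fluxdesign.design import DesignStrategy
from fluxdesign.fluxspace import FluxSpace, fba
from fluxdesign.model import (
    BalanceError,
    MetabolicModel,
    ModelValidationError,
    PathwaySpec,
    add_pathway,
    load_model,
    parse_formula,
    read_design_report,
    read_native_json,
    set_medium,
    to_cobra,
    write_design_report,
    write_native_json,
)


def _model_fingerprint(m):
    return (
        tuple(m.reaction_ids), tuple(m.metabolite_ids),
        m.S.toarray().tobytes(), m.lb.tobytes(), m.ub.tobytes(),
    )


def test_native_json_round_trip(fig1, tmp_path):
    model, _, _ = fig1
    path = tmp_path / "toy.json"
    write_native_json(model, path)
    back = read_native_json(path)
    assert _model_fingerprint(back) == _model_fingerprint(model)
    assert back.biomass_id == model.biomass_id
    assert back.exchange_ids == model.exchange_ids
    assert back.subsystem == model.subsystem


def test_cobra_json_and_sbml_loading(fig1, tmp_path):
    import cobra.io

    model, _, _ = fig1
    cm = to_cobra(model)
    cobra.io.save_json_model(cm, str(tmp_path / "toy_cobra.json"))
    cobra.io.write_sbml_model(cm, str(tmp_path / "toy.xml"))
    for fmt, name in [("cobra-json", "toy_cobra.json"), ("sbml", "toy.xml")]:
        loaded = load_model(tmp_path / name, fmt)
        assert loaded.reaction_ids == model.reaction_ids
        np.testing.assert_allclose(loaded.lb, model.lb)
        np.testing.assert_allclose(loaded.ub, model.ub)
        np.testing.assert_allclose(loaded.S.toarray(), model.S.toarray())
        assert loaded.biomass_id == "R3"


def test_validation_rejects_inverted_bounds_and_duplicates():
    with pytest.raises(ModelValidationError, match="R1"):
        MetabolicModel(
            metabolite_ids=["A"], reaction_ids=["R1"],
            S=sp.csc_matrix(np.array([[1.0]])),
            lb=np.array([5.0]), ub=np.array([2.0]),
            biomass_id="R1", exchange_ids=["R1"],
        )
    with pytest.raises(ModelValidationError, match="duplicate"):
        MetabolicModel(
            metabolite_ids=["A"], reaction_ids=["R1", "R1"],
            S=sp.csc_matrix(np.array([[1.0, -1.0]])),
            lb=np.zeros(2), ub=np.ones(2),
            biomass_id="R1", exchange_ids=["R1"],
        )


def test_add_pathway_appends_without_mutating(fig1):
    model, _, _ = fig1
    before = _model_fingerprint(model)
    spec = PathwaySpec(
        reactions=[
            ("P1", {"M2": -1.0, "Q1": 1.0}, 0.0, 100.0),
            ("P2", {"Q1": -1.0, "Q2": 1.0}, 0.0, 100.0),
            ("EX_Q", {"Q2": -1.0}, 0.0, 100.0),
        ],
        new_metabolites=[("Q1", None, None), ("Q2", None, None)],
    )
    grown = add_pathway(model, spec)
    assert _model_fingerprint(model) == before
    assert grown.n_reactions == model.n_reactions + 3
    assert "EX_Q" in grown.exchange_ids
    # the grafted route carries flux: production through the new sink
    val, _ = fba(FluxSpace(grown), "EX_Q", "max")
    assert val > 0


def test_add_pathway_rejects_id_collision(fig1):
    model, _, _ = fig1
    spec = PathwaySpec(reactions=[("R2", {"M1": -1.0}, 0.0, 10.0)])
    with pytest.raises(ModelValidationError, match="R2"):
        add_pathway(model, spec)


def test_pathway_balance_check_strict_and_advisory():
    model = MetabolicModel(
        metabolite_ids=["A"], reaction_ids=["EX_A", "BIO"],
        S=sp.csc_matrix(np.array([[1.0, -1.0]])),
        lb=np.zeros(2), ub=np.full(2, 10.0),
        biomass_id="BIO", exchange_ids=["EX_A"],
        metabolite_formula={"A": "C6H12O6"},
    )
    bad = PathwaySpec(
        reactions=[("SPLIT", {"A": -1.0, "B": 1.0}, 0.0, 10.0)],
        new_metabolites=[("B", "C3H6O3", 0)],  # half a glucose: unbalanced
    )
    with pytest.warns(UserWarning, match="unbalanced"):
        add_pathway(model, bad)
    with pytest.raises(BalanceError, match="SPLIT"):
        add_pathway(model, bad, strict_balance=True)
    ok = PathwaySpec(
        reactions=[("ISO", {"A": -1.0, "B2": 1.0}, 0.0, 10.0)],
        new_metabolites=[("B2", "C6H12O6", 0)],
    )
    add_pathway(model, ok, strict_balance=True)  # balanced: no error


def test_parse_formula():
    assert parse_formula("C6H12O6") == {"C": 6, "H": 12, "O": 6}
    assert parse_formula("CO2") == {"C": 1, "O": 2}
    with pytest.raises(ValueError):
        parse_formula("c6")


def test_set_medium_uptake_and_sole_substrate():
    # two carbon exchanges + one mineral exchange
    S = sp.csc_matrix(np.array([
        [-1.0, 0.0, 0.0, -1.0],
        [0.0, -1.0, 0.0, -1.0],
        [0.0, 0.0, -1.0, -1.0],
    ]))
    model = MetabolicModel(
        metabolite_ids=["glc", "fru", "pi"],
        reaction_ids=["EX_glc", "EX_fru", "EX_pi", "BIO"],
        S=S,
        lb=np.array([-5.0, -5.0, -5.0, 0.0]),
        ub=np.full(4, 1000.0),
        biomass_id="BIO",
        exchange_ids=["EX_glc", "EX_fru", "EX_pi"],
        metabolite_formula={"glc": "C6H12O6", "fru": "C6H12O6", "pi": "HO4P"},
    )
    out = set_medium(model, {"EX_glc": 10.0}, sole_substrate=True)
    assert out.lb[out.index("EX_glc")] == -10.0
    assert out.lb[out.index("EX_fru")] == 0.0   # competing carbon closed
    assert out.lb[out.index("EX_pi")] == -5.0   # mineral stays open
    assert set_medium(model, {}).lb.tolist() == model.lb.tolist()
    with pytest.raises(ModelValidationError, match="BIO"):
        set_medium(model, {"BIO": 1.0})


def test_design_report_round_trip(tmp_path):
    strategies = [
        DesignStrategy(knockouts={"R4"}, upregulated={"R5"},
                       guaranteed_production=2.0),
        DesignStrategy(downregulated={"R2"}, guaranteed_production=1.5),
    ]
    path = tmp_path / "report.tsv"
    write_design_report(strategies, path)
    back = read_design_report(path)
    assert len(back) == 2
    assert back[0].knockouts == {"R4"}
    assert back[0].upregulated == {"R5"}
    assert back[0].guaranteed_production == 2.0
    assert back[1].downregulated == {"R2"}
    # empty report: header only, read back as empty
    write_design_report([], tmp_path / "empty.tsv")
    assert read_design_report(tmp_path / "empty.tsv") == []
    assert (tmp_path / "empty.tsv").read_text().startswith("strategy\t")
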