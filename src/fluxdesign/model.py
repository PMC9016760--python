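"""Metabolic model container, file I/O, pathway augmentation and media.

The in-memory representation is a plain stoichiometric description: a sparse
metabolite x reaction matrix ``S`` with per-reaction flux bounds
(mmol/gDW/h), a designated biomass reaction and the set of exchange
(boundary) reactions.  Models can be read from SBML (Level 3 + FBC) or
COBRA-style JSON via cobrapy, or from the package's own JSON dialect, which
round-trips field-for-field.

Sign conventions follow the community standard: uptake through an exchange
reaction is a negative flux, secretion positive.  Bounds absent from a file
default to +/-1000.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

DEFAULT_BOUND = 1000.0


class ModelValidationError(ValueError):
    """Raised when a model or pathway violates structural invariants."""


class BalanceError(ModelValidationError):
    """Raised in strict mode when a reaction is not mass/charge balanced."""


# --------------------------------------------------------------------------
# core container
# --------------------------------------------------------------------------

@dataclass
class MetabolicModel:
    """A constraint-based metabolic model.

    Parameters
    ----------
    metabolite_ids, reaction_ids
        Unique identifiers; ``S`` has one row per metabolite and one column
        per reaction, in this order.
    S
        Sparse stoichiometric matrix (metabolites x reactions).
    lb, ub
        Per-reaction flux bounds in mmol/gDW/h, ``lb <= ub``.
    biomass_id
        Identifier of the growth (biomass) reaction.
    exchange_ids
        Boundary pseudo-reactions; uptake is negative flux.
    subsystem
        Optional reaction id -> pathway/subsystem label.
    metabolite_formula
        Optional metabolite id -> chemical formula (used for balance checks
        and sole-substrate media handling).
    """

    metabolite_ids: list[str]
    reaction_ids: list[str]
    S: sp.csc_matrix
    lb: np.ndarray
    ub: np.ndarray
    biomass_id: str
    exchange_ids: list[str] = field(default_factory=list)
    subsystem: dict[str, str] = field(default_factory=dict)
    metabolite_formula: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        self.S = sp.csc_matrix(self.S, dtype=float)
        self.lb = np.asarray(self.lb, dtype=float)
        self.ub = np.asarray(self.ub, dtype=float)
        self.validate()

    # -- basic queries ---------------------------------------------------
    @property
    def n_metabolites(self) -> int:
        return len(self.metabolite_ids)

    @property
    def n_reactions(self) -> int:
        return len(self.reaction_ids)

    def index(self, reaction_id: str) -> int:
        try:
            return self._rxn_index[reaction_id]
        except AttributeError:
            self._rxn_index = {r: i for i, r in enumerate(self.reaction_ids)}
            return self._rxn_index[reaction_id]

    def metabolite_index(self, metabolite_id: str) -> int:
        return self.metabolite_ids.index(metabolite_id)

    def stoichiometry(self, reaction_id: str) -> dict[str, float]:
        j = self.index(reaction_id)
        col = self.S.getcol(j).tocoo()
        return {self.metabolite_ids[i]: v for i, v in zip(col.row, col.data)}

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            metabolite_ids=list(self.metabolite_ids),
            reaction_ids=list(self.reaction_ids),
            S=self.S.copy(),
            lb=self.lb.copy(),
            ub=self.ub.copy(),
            biomass_id=self.biomass_id,
            exchange_ids=list(self.exchange_ids),
            subsystem=dict(self.subsystem),
            metabolite_formula=dict(self.metabolite_formula),
        )

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        if len(set(self.reaction_ids)) != len(self.reaction_ids):
            dup = _first_duplicate(self.reaction_ids)
            raise ModelValidationError(f"duplicate reaction id: {dup!r}")
        if len(set(self.metabolite_ids)) != len(self.metabolite_ids):
            dup = _first_duplicate(self.metabolite_ids)
            raise ModelValidationError(f"duplicate metabolite id: {dup!r}")
        if self.S.shape != (self.n_metabolites, self.n_reactions):
            raise ModelValidationError(
                f"S has shape {self.S.shape}, expected "
                f"({self.n_metabolites}, {self.n_reactions})"
            )
        if self.lb.shape != (self.n_reactions,) or self.ub.shape != (self.n_reactions,):
            raise ModelValidationError("bound vectors must have one entry per reaction")
        bad = np.where(self.lb > self.ub + 1e-12)[0]
        if bad.size:
            rid = self.reaction_ids[bad[0]]
            raise ModelValidationError(
                f"reaction {rid!r} has lb={self.lb[bad[0]]} > ub={self.ub[bad[0]]}"
            )
        if self.biomass_id not in self.reaction_ids:
            raise ModelValidationError(f"biomass reaction {self.biomass_id!r} not in model")
        for ex in self.exchange_ids:
            if ex not in self.reaction_ids:
                raise ModelValidationError(f"exchange reaction {ex!r} not in model")
        nnz_per_col = np.diff(self.S.tocsc().indptr)
        empty = [
            self.reaction_ids[j]
            for j in np.where(nnz_per_col == 0)[0]
            if self.reaction_ids[j] not in self.exchange_ids
        ]
        if empty:
            raise ModelValidationError(
                f"non-exchange reaction(s) with empty stoichiometry: {empty}"
            )

    def detect_exchanges(self) -> list[str]:
        """Reactions whose column touches a single metabolite (boundary)."""
        nnz_per_col = np.diff(self.S.tocsc().indptr)
        return [r for j, r in enumerate(self.reaction_ids) if nnz_per_col[j] <= 1]


def _first_duplicate(items):
    seen = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return None


# --------------------------------------------------------------------------
# heterologous pathways
# --------------------------------------------------------------------------

@dataclass
class PathwaySpec:
    """A set of reactions (e.g. a heterologous biosynthesis route) to graft
    onto a model.

    ``reactions`` is a list of ``(id, {metabolite: coefficient}, lb, ub)``;
    ``new_metabolites`` lists ``(id, formula, charge)`` for metabolites not
    already in the host model (formula/charge may be ``None``).
    """

    reactions: list[tuple[str, dict[str, float], float, float]]
    new_metabolites: list[tuple[str, str | None, int | None]] = field(default_factory=list)


_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a Hill-style chemical formula into element counts."""
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_RE.finditer(formula):
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r}")
        pos = m.end()
        counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2) or 1)
    if pos != len(formula):
        raise ValueError(f"cannot parse formula {formula!r}")
    return counts


def _element_imbalance(stoich: dict[str, float], formulas: dict[str, str]) -> dict[str, float] | None:
    """Net element delta of a reaction, or None if any formula is missing."""
    delta: dict[str, float] = {}
    for met, coef in stoich.items():
        f = formulas.get(met)
        if not f:
            return None
        for el, cnt in parse_formula(f).items():
            delta[el] = delta.get(el, 0.0) + coef * cnt
    return {el: d for el, d in delta.items() if abs(d) > 1e-9}


def add_pathway(model: MetabolicModel, spec: PathwaySpec, strict_balance: bool = False) -> MetabolicModel:
    """Return a new model with the pathway's reactions/metabolites appended.

    The input model is never mutated.  When chemical formulas are known for
    every participant of a reaction, mass balance is checked; imbalances are
    a warning by default and an error under ``strict_balance`` (many
    published models contain deliberately unbalanced pseudo-reactions, so
    the check is advisory).
    """
    existing_rxns = set(model.reaction_ids)
    for rid, _, _, _ in spec.reactions:
        if rid in existing_rxns:
            raise ModelValidationError(f"pathway reaction id {rid!r} already in model")
    new_met_ids = [m for m, _, _ in spec.new_metabolites]
    for mid in new_met_ids:
        if mid in model.metabolite_ids:
            raise ModelValidationError(f"pathway metabolite id {mid!r} already in model")

    formulas = dict(model.metabolite_formula)
    for mid, formula, _charge in spec.new_metabolites:
        if formula:
            formulas[mid] = formula

    met_ids = list(model.metabolite_ids)
    met_index = {m: i for i, m in enumerate(met_ids)}
    for mid in new_met_ids:
        met_index[mid] = len(met_ids)
        met_ids.append(mid)
    # metabolites referenced by the pathway but declared nowhere
    for rid, stoich, _, _ in spec.reactions:
        for met in stoich:
            if met not in met_index:
                raise ModelValidationError(
                    f"reaction {rid!r} references unknown metabolite {met!r}"
                )

    for rid, stoich, _, _ in spec.reactions:
        imbalance = _element_imbalance(stoich, formulas)
        if imbalance:
            msg = f"reaction {rid!r} is elementally unbalanced: {imbalance}"
            if strict_balance:
                raise BalanceError(msg)
            warnings.warn(msg, stacklevel=2)

    n_new_m = len(new_met_ids)
    n_new_r = len(spec.reactions)
    S = sp.lil_matrix((len(met_ids), model.n_reactions + n_new_r))
    S[: model.n_metabolites, : model.n_reactions] = model.S
    for k, (rid, stoich, _, _) in enumerate(spec.reactions):
        for met, coef in stoich.items():
            S[met_index[met], model.n_reactions + k] = coef

    lb = np.concatenate([model.lb, [r[2] for r in spec.reactions]])
    ub = np.concatenate([model.ub, [r[3] for r in spec.reactions]])
    rxn_ids = list(model.reaction_ids) + [r[0] for r in spec.reactions]
    nnz = np.diff(sp.csc_matrix(S).indptr)
    new_exchanges = [
        r[0]
        for k, r in enumerate(spec.reactions)
        if nnz[model.n_reactions + k] <= 1
    ]
    return MetabolicModel(
        metabolite_ids=met_ids,
        reaction_ids=rxn_ids,
        S=sp.csc_matrix(S),
        lb=lb,
        ub=ub,
        biomass_id=model.biomass_id,
        exchange_ids=list(model.exchange_ids) + new_exchanges,
        subsystem=dict(model.subsystem),
        metabolite_formula=formulas,
    )


# --------------------------------------------------------------------------
# media
# --------------------------------------------------------------------------

def set_medium(
    model: MetabolicModel,
    uptake_bounds: dict[str, float],
    sole_substrate: bool = False,
) -> MetabolicModel:
    """Return a model with uptake limits applied to exchange reactions.

    ``uptake_bounds`` maps exchange reaction ids to maximum uptake rates
    (positive magnitudes); the exchange lower bound is set to ``-rate``.
    With ``sole_substrate=True``, every other exchange that could import a
    carbon-containing metabolite is closed (lower bound 0).  When a
    metabolite's formula is unknown the exchange is treated as a potential
    carbon source and closed conservatively.
    """
    exchanges = set(model.exchange_ids)
    for rid in uptake_bounds:
        if rid not in exchanges:
            raise ModelValidationError(f"{rid!r} is not an exchange reaction")
    out = model.copy()
    for rid, rate in uptake_bounds.items():
        j = out.index(rid)
        out.lb[j] = -abs(rate)
    if sole_substrate:
        listed = set(uptake_bounds)
        for rid in model.exchange_ids:
            if rid in listed:
                continue
            j = out.index(rid)
            if out.lb[j] >= 0:
                continue
            if _exchange_is_carbon_source(out, rid):
                out.lb[j] = 0.0
    out.validate()
    return out


def _exchange_is_carbon_source(model: MetabolicModel, rid: str) -> bool:
    stoich = model.stoichiometry(rid)
    if not stoich:
        return False
    (met, _coef), = stoich.items()
    formula = model.metabolite_formula.get(met)
    if formula is None:
        return True  # unknown composition: close it to be safe
    return parse_formula(formula).get("C", 0) > 0


# --------------------------------------------------------------------------
# file I/O
# --------------------------------------------------------------------------

def load_model(path, format: str = "json") -> MetabolicModel:
    """Read a model from ``sbml``, ``cobra-json`` or the native ``json``
    dialect."""
    if format == "json":
        return read_native_json(path)
    if format in ("sbml", "cobra-json"):
        import cobra.io

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if format == "sbml":
                cm = cobra.io.read_sbml_model(str(path))
            else:
                cm = cobra.io.load_json_model(str(path))
        return from_cobra(cm)
    raise ValueError(f"unknown model format {format!r}")


def from_cobra(cm) -> MetabolicModel:
    """Convert a cobrapy model into the package representation."""
    met_ids = [m.id for m in cm.metabolites]
    rxn_ids = [r.id for r in cm.reactions]
    met_index = {m: i for i, m in enumerate(met_ids)}
    S = sp.lil_matrix((len(met_ids), len(rxn_ids)))
    lb = np.empty(len(rxn_ids))
    ub = np.empty(len(rxn_ids))
    subsystem = {}
    for j, r in enumerate(cm.reactions):
        for met, coef in r.metabolites.items():
            S[met_index[met.id], j] = coef
        lb[j] = r.lower_bound if r.lower_bound is not None else -DEFAULT_BOUND
        ub[j] = r.upper_bound if r.upper_bound is not None else DEFAULT_BOUND
        if getattr(r, "subsystem", None):
            subsystem[r.id] = r.subsystem
    biomass = None
    for r in cm.reactions:
        if r.objective_coefficient:
            biomass = r.id
            break
    if biomass is None:
        raise ModelValidationError("model declares no objective/biomass reaction")
    formulas = {m.id: m.formula for m in cm.metabolites if m.formula}
    return MetabolicModel(
        metabolite_ids=met_ids,
        reaction_ids=rxn_ids,
        S=sp.csc_matrix(S),
        lb=lb,
        ub=ub,
        biomass_id=biomass,
        exchange_ids=[r.id for r in cm.exchanges],
        subsystem=subsystem,
        metabolite_formula=formulas,
    )


def to_cobra(model: MetabolicModel):
    """Convert to a cobrapy model (objective = biomass reaction)."""
    import cobra

    cm = cobra.Model("fluxdesign")
    mets = {m: cobra.Metabolite(m, formula=model.metabolite_formula.get(m),
                                compartment="c")
            for m in model.metabolite_ids}
    for j, rid in enumerate(model.reaction_ids):
        rxn = cobra.Reaction(rid, lower_bound=float(model.lb[j]),
                             upper_bound=float(model.ub[j]))
        cm.add_reactions([rxn])
        rxn.add_metabolites({mets[m]: c for m, c in model.stoichiometry(rid).items()})
        if rid in model.subsystem:
            rxn.subsystem = model.subsystem[rid]
    cm.objective = model.biomass_id
    return cm


def read_native_json(path) -> MetabolicModel:
    if hasattr(path, "read"):
        data = json.load(path)
    else:
        with open(path) as fh:
            data = json.load(fh)
    met_ids = [m["id"] for m in data["metabolites"]]
    met_index = {m: i for i, m in enumerate(met_ids)}
    rxns = data["reactions"]
    S = sp.lil_matrix((len(met_ids), len(rxns)))
    lb = np.empty(len(rxns))
    ub = np.empty(len(rxns))
    subsystem = {}
    for j, r in enumerate(rxns):
        for met, coef in r["stoichiometry"].items():
            S[met_index[met], j] = coef
        lb[j] = r.get("lb", -DEFAULT_BOUND)
        ub[j] = r.get("ub", DEFAULT_BOUND)
        if r.get("subsystem"):
            subsystem[r["id"]] = r["subsystem"]
    return MetabolicModel(
        metabolite_ids=met_ids,
        reaction_ids=[r["id"] for r in rxns],
        S=sp.csc_matrix(S),
        lb=lb,
        ub=ub,
        biomass_id=data["biomass"],
        exchange_ids=data.get("exchanges", []),
        subsystem=subsystem,
        metabolite_formula={
            m["id"]: m["formula"] for m in data["metabolites"] if m.get("formula")
        },
    )


def write_native_json(model: MetabolicModel, path) -> None:
    data = {
        "metabolites": [
            {"id": m, **({"formula": model.metabolite_formula[m]} if m in model.metabolite_formula else {})}
            for m in model.metabolite_ids
        ],
        "reactions": [
            {
                "id": r,
                "stoichiometry": model.stoichiometry(r),
                "lb": float(model.lb[j]),
                "ub": float(model.ub[j]),
                **({"subsystem": model.subsystem[r]} if r in model.subsystem else {}),
            }
            for j, r in enumerate(model.reaction_ids)
        ],
        "biomass": model.biomass_id,
        "exchanges": list(model.exchange_ids),
    }
    if hasattr(path, "write"):
        json.dump(data, path, indent=1, sort_keys=False)
    else:
        with open(path, "w") as fh:
            json.dump(data, fh, indent=1, sort_keys=False)


# --------------------------------------------------------------------------
# design reports
# --------------------------------------------------------------------------

REPORT_COLUMNS = ["strategy", "reaction_id", "manipulation", "guaranteed_production"]


def write_design_report(strategies, path) -> None:
    """Serialise design strategies as a deterministic TSV table."""
    rows = []
    for k, s in enumerate(strategies):
        for rid in sorted(s.knockouts):
            rows.append((k, rid, "knockout", s.guaranteed_production))
        for rid in sorted(s.upregulated):
            rows.append((k, rid, "up", s.guaranteed_production))
        for rid in sorted(s.downregulated):
            rows.append((k, rid, "down", s.guaranteed_production))
    df = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_design_report(path):
    """Reconstruct strategies (sets + guaranteed production) from a TSV."""
    from .design import DesignStrategy

    df = pd.read_csv(path, sep="\t")
    strategies = []
    if df.empty:
        return strategies
    for _k, grp in df.groupby("strategy", sort=True):
        strategies.append(
            DesignStrategy(
                knockouts=set(grp.loc[grp.manipulation == "knockout", "reaction_id"]),
                upregulated=set(grp.loc[grp.manipulation == "up", "reaction_id"]),
                downregulated=set(grp.loc[grp.manipulation == "down", "reaction_id"]),
                guaranteed_production=float(grp.guaranteed_production.iloc[0]),
            )
        )
    return strategies
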