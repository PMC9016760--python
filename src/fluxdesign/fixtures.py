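"""Deterministic toy metabolic networks with known design answers.

These generators stand in for genome-scale models in tests and demos: a
substrate uptake, a biomass reaction, a target product and competing
byproduct branches, small enough that every design question can be answered
by exhaustive enumeration.

The five-reaction network mirrors the classic textbook sketch of a
production host: carbon enters (R1), is converted through a linear trunk
(R2) to a branch-point metabolite, and from there flows to biomass (R3), to
a secreted byproduct (R4) or — once the production pathway is active — to
the product (R5).  Its constants are chosen so that with a flux-change
threshold of 2 the minimal regulation set is exactly {R5 up, R4 down}.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .design import (
    DesignProblem,
    brute_force_oracle,
    build_design_problem,
    _inner_lp,
)
from .fluxspace import FluxSpace
from .model import MetabolicModel, read_native_json, write_native_json
from .pipeline import step1_spaces
from .regulation import RegulationCandidates


def toy_fig1_network(
    delta: float = 2.0,
    min_growth: float = 1.0,
) -> tuple[MetabolicModel, FluxSpace, FluxSpace]:
    """Five-reaction branch-point network and its wild/production spaces.

    Reactions (S, X, P and the byproduct M3 are external):

    ==== =================== ============ =========================
    id   conversion          bounds       role
    ==== =================== ============ =========================
    R1   S -> M1             [0, 10]      substrate uptake
    R2   M1 -> M2            [0, 10]      trunk pathway
    R3   M2 -> X             [0, 6]       biomass (machinery cap 6)
    R4   M2 -> M3            [0, 10]      byproduct secretion
    R5   M2 -> P             [0, 10]      product secretion
    ==== =================== ============ =========================

    The wild type has a measured uptake of 10 and no production pathway
    (R5 closed), so at least 4 units overflow through R4.  The production
    space requires growth >= ``min_growth`` and production at the maximum
    theoretical rate, which forces R4 to (near) zero and R5 to 9: with
    ``delta = 2`` exactly R4 (down) and R5 (up) must change noticeably.
    """
    S = sp.csc_matrix(np.array([
        # R1  R2  R3  R4  R5
        [1., -1., 0., 0., 0.],   # M1
        [0., 1., -1., -1., -1.],  # M2
    ]))
    model = MetabolicModel(
        metabolite_ids=["M1", "M2"],
        reaction_ids=["R1", "R2", "R3", "R4", "R5"],
        S=S,
        lb=np.zeros(5),
        ub=np.array([10.0, 10.0, 6.0, 10.0, 10.0]),
        biomass_id="R3",
        exchange_ids=["R1"],
        subsystem={"R4": "overflow", "R5": "product"},
    )
    fs_w, fs_m, _vmax = step1_spaces(
        model, "R5", min_growth,
        wt_min_growth=min_growth,
        wt_overrides={"R1": (10.0, 10.0), "R5": (0.0, 0.0)},
    )
    return model, fs_w, fs_m


def random_branched_network(
    n_branches: int,
    seed: int,
    dead_end: bool = False,
) -> MetabolicModel:
    """Seeded toy network with ``n_branches`` competing overflow routes.

    Growth (BIO) converts the carbon pool M0 into a reduced cofactor W
    that must be drained, either through overflow branches (OVF_i, random
    capacities) or through product synthesis (PRODSYN), which also draws
    carbon.  The target is the product sink EX_P.  With ``dead_end=True``
    an extra blocked reaction to an orphan metabolite is included.
    """
    if not 2 <= n_branches <= 8:
        raise ValueError("n_branches must be in [2, 8]")
    rng = np.random.default_rng(seed)
    w_yield = float(np.round(rng.uniform(0.5, 2.0), 3))
    growth_cap = float(np.round(rng.uniform(2.0, 6.0), 3))
    caps = np.round(rng.uniform(0.5, 4.0, size=n_branches), 3)

    mets = ["M0", "W", "P"]
    rxns: list[tuple[str, dict[str, float], float, float]] = [
        ("UPT", {"M0": 1.0}, 0.0, 10.0),
        ("BIO", {"M0": -1.0, "W": w_yield}, 0.0, growth_cap),
    ]
    for i in range(n_branches):
        rxns.append((f"OVF{i + 1}", {"W": -1.0}, 0.0, float(caps[i])))
    rxns.append(("PRODSYN", {"M0": -1.0, "W": -1.0, "P": 1.0}, 0.0, 1000.0))
    rxns.append(("EX_P", {"P": -1.0}, 0.0, 1000.0))
    if dead_end:
        mets.append("DEAD")
        rxns.append(("ORPHAN", {"M0": -1.0, "DEAD": 1.0}, 0.0, 5.0))

    S = sp.lil_matrix((len(mets), len(rxns)))
    midx = {m: i for i, m in enumerate(mets)}
    for j, (_rid, stoich, _lo, _hi) in enumerate(rxns):
        for met, coef in stoich.items():
            S[midx[met], j] = coef
    return MetabolicModel(
        metabolite_ids=mets,
        reaction_ids=[r[0] for r in rxns],
        S=sp.csc_matrix(S),
        lb=np.array([r[2] for r in rxns]),
        ub=np.array([r[3] for r in rxns]),
        biomass_id="BIO",
        exchange_ids=["UPT", "EX_P"],
        subsystem={f"OVF{i + 1}": "overflow" for i in range(n_branches)},
    )


@dataclass
class PlantedInstance:
    """A toy design problem whose optimum was certified at generation time
    by the brute-force oracle."""

    model: MetabolicModel
    target: str
    seed: int
    K: int
    min_growth: float
    delta: float
    F_plus: list[str]
    F_minus: list[str]
    F_times: list[str]
    expected_best_objective: float
    expected_best_interventions: dict[str, str]
    baseline_objective: float
    expected_minimal_count: int | None = None

    def problem(self) -> DesignProblem:
        cands = RegulationCandidates(
            F_plus=set(self.F_plus), F_minus=set(self.F_minus),
            delta_v={}, delta={r: self.delta for r in self.F_plus + self.F_minus},
            objective_count=len(self.F_plus) + len(self.F_minus),
            sense="minimal",
        )
        return build_design_problem(
            self.model, self.target, cands, self.F_times,
            K_m=self.K, K_ko=self.K, min_growth=self.min_growth,
            fs_w=FluxSpace(self.model, min_growth=self.min_growth),
            delta=self.delta,
        )

    # -- lossless (de)serialisation -------------------------------------
    def to_json(self, path) -> None:
        import io

        buf = io.StringIO()
        # reuse the native model dialect inline
        tmp = {"target": self.target, "seed": self.seed, "K": self.K,
               "min_growth": self.min_growth, "delta": self.delta,
               "F_plus": self.F_plus, "F_minus": self.F_minus,
               "F_times": self.F_times,
               "expected_best_objective": self.expected_best_objective,
               "expected_best_interventions": self.expected_best_interventions,
               "baseline_objective": self.baseline_objective,
               "expected_minimal_count": self.expected_minimal_count}
        write_native_json(self.model, buf)
        tmp["model"] = json.loads(buf.getvalue())
        with open(path, "w") as fh:
            json.dump(tmp, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "PlantedInstance":
        import io

        with open(path) as fh:
            data = json.load(fh)
        model = read_native_json(io.StringIO(json.dumps(data.pop("model"))))
        return cls(model=model, **data)


def planted_design_instance(seed: int, K: int) -> PlantedInstance:
    """Generate a seeded instance whose best <=K-intervention strategy is
    known exactly and strictly beats the no-intervention baseline."""
    if not 1 <= K <= 3:
        raise ValueError("K must be in [1, 3]")
    rng = np.random.default_rng(seed)
    for trial in range(40):
        sub_seed = int(rng.integers(0, 2**30 - 1))
        model = random_branched_network(n_branches=min(K + 1, 4), seed=sub_seed)
        aux = np.random.default_rng(sub_seed + 1)
        min_growth = float(np.round(aux.uniform(0.3, 1.0), 3))
        delta = float(aux.choice([0.5, 1.0, 1.5, 2.0]))
        include_up = sub_seed % 3 != 0  # sometimes force knockout-only designs
        F_plus = ["PRODSYN"] if include_up else []
        F_minus = [r for r in model.reaction_ids if r.startswith("OVF")][:1]
        F_times = sorted(r for r in model.reaction_ids if r.startswith("OVF"))
        cands = RegulationCandidates(
            F_plus=set(F_plus), F_minus=set(F_minus), delta_v={},
            delta={r: delta for r in F_plus + F_minus},
            objective_count=len(F_plus) + len(F_minus), sense="minimal",
        )
        try:
            problem = build_design_problem(
                model, "EX_P", cands, F_times, K_m=K, K_ko=K,
                min_growth=min_growth,
                fs_w=FluxSpace(model, min_growth=min_growth), delta=delta,
            )
            baseline, _, _ = _inner_lp(problem, {})
            best = brute_force_oracle(problem, max_size=K)
        except Exception:
            continue
        if best.guaranteed_production > baseline + 0.05:
            return PlantedInstance(
                model=model, target="EX_P", seed=seed, K=K,
                min_growth=min_growth, delta=delta,
                F_plus=F_plus, F_minus=F_minus, F_times=F_times,
                expected_best_objective=best.guaranteed_production,
                expected_best_interventions=best.selection(),
                baseline_objective=float(baseline),
            )
    raise RuntimeError(f"could not plant a design instance for seed {seed}")


def chain_model(n_steps: int = 3, cap: float = 10.0) -> MetabolicModel:
    """Unbranched uptake -> ... -> biomass chain (compression test bed)."""
    mets = [f"C{i}" for i in range(n_steps)]
    rxns = [("UPT", {mets[0]: 1.0}, 0.0, cap)]
    for i in range(n_steps - 1):
        rxns.append((f"STEP{i + 1}", {mets[i]: -1.0, mets[i + 1]: 1.0}, 0.0, cap))
    rxns.append(("BIO", {mets[-1]: -1.0}, 0.0, cap))
    S = sp.lil_matrix((len(mets), len(rxns)))
    midx = {m: i for i, m in enumerate(mets)}
    for j, (_r, st, _lo, _hi) in enumerate(rxns):
        for met, coef in st.items():
            S[midx[met], j] = coef
    return MetabolicModel(
        metabolite_ids=mets,
        reaction_ids=[r[0] for r in rxns],
        S=sp.csc_matrix(S),
        lb=np.array([r[2] for r in rxns]),
        ub=np.array([r[3] for r in rxns]),
        biomass_id="BIO",
        exchange_ids=["UPT"],
    )
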