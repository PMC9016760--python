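"""Model reduction and knockout-candidate preprocessing.

Genome-scale models carry many reactions that can never participate in a
design: blocked (dead-end) reactions, growth-essential reactions, boundary
pseudo-reactions and maintenance demands.  This module removes or excludes
them and can compress unbranched linear chains into composite reactions,
recording everything in a :class:`ReductionMap` so reduced-model fluxes can
be projected back onto the original network.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .fluxspace import FluxSpace, fba, fva
from .lp import InfeasibleProblemError
from .model import MetabolicModel

BLOCKED_TOL = 1e-9


@dataclass
class ReductionMap:
    """Audit trail of a model reduction.

    ``merged_groups`` maps each composite reaction to the ordered original
    reactions it stands for and per-member scale factors: the member flux is
    ``scale * v_composite``.  ``removed_blocked`` lists dropped dead-end
    reactions (their flux is identically zero in every steady state).
    """

    merged_groups: list[tuple[str, list[str], list[float]]] = field(default_factory=list)
    removed_blocked: list[str] = field(default_factory=list)

    def project(self, reduced_fluxes: dict[str, float]) -> dict[str, float]:
        """Lift a reduced-model flux assignment onto original reactions."""
        out = dict(reduced_fluxes)
        for comp, members, scales in self.merged_groups:
            vc = out.pop(comp, 0.0)
            for rid, s in zip(members, scales):
                out[rid] = s * vc
        for rid in self.removed_blocked:
            out[rid] = 0.0
        return out

    def to_tsv(self, path) -> None:
        rows = [
            (comp, rid, s, "merged")
            for comp, members, scales in self.merged_groups
            for rid, s in zip(members, scales)
        ] + [(None, rid, 0.0, "blocked") for rid in self.removed_blocked]
        pd.DataFrame(rows, columns=["composite", "reaction_id", "scale", "kind"]).to_csv(
            path, sep="\t", index=False
        )


def _drop_reactions(model: MetabolicModel, drop: set[str]) -> MetabolicModel:
    keep = [j for j, r in enumerate(model.reaction_ids) if r not in drop]
    S = model.S[:, keep]
    # keep rows with at least one nonzero to avoid orphan metabolites
    row_mask = np.zeros(model.n_metabolites, dtype=bool)
    row_mask[np.unique(sp.coo_matrix(S).row)] = True
    return MetabolicModel(
        metabolite_ids=[m for i, m in enumerate(model.metabolite_ids) if row_mask[i]],
        reaction_ids=[model.reaction_ids[j] for j in keep],
        S=sp.csc_matrix(S[row_mask]),
        lb=model.lb[keep],
        ub=model.ub[keep],
        biomass_id=model.biomass_id,
        exchange_ids=[r for r in model.exchange_ids if r not in drop],
        subsystem={r: s for r, s in model.subsystem.items() if r not in drop},
        metabolite_formula={
            m: f
            for m, f in model.metabolite_formula.items()
            if m in set(np.array(model.metabolite_ids)[row_mask])
        },
    )


def remove_blocked(model: MetabolicModel) -> tuple[MetabolicModel, ReductionMap]:
    """Drop reactions whose FVA range is exactly {0} in the open model."""
    ranges = fva(FluxSpace(model))
    blocked = sorted(
        rid for rid, (lo, hi) in ranges.items()
        if abs(lo) <= BLOCKED_TOL and abs(hi) <= BLOCKED_TOL
    )
    if model.biomass_id in blocked:
        raise InfeasibleProblemError("biomass reaction is blocked in the open model")
    reduced = _drop_reactions(model, set(blocked))
    return reduced, ReductionMap(removed_blocked=blocked)


def _mergeable_metabolites(model: MetabolicModel, protected: set[str]):
    """Metabolites with exactly one producing and one consuming reaction,
    where neither reaction is protected or reversible across the junction."""
    S = sp.csc_matrix(model.S).tocoo()
    touching: dict[int, list[int]] = {}
    for i, j in zip(S.row, S.col):
        touching.setdefault(i, []).append(j)
    for i, cols in touching.items():
        cols = sorted(set(cols))
        if len(cols) != 2:
            continue
        j1, j2 = cols
        r1, r2 = model.reaction_ids[j1], model.reaction_ids[j2]
        if r1 in protected or r2 in protected:
            continue
        yield i, j1, j2


def compress_linear(
    model: MetabolicModel,
    protect: set[str] | None = None,
) -> tuple[MetabolicModel, ReductionMap]:
    """Merge maximal linear chains through unbranched metabolites.

    A metabolite touched by exactly two reactions forces their fluxes to be
    proportional at steady state (a.v1 + b.v2 = 0), so the pair collapses to
    one composite column carrying the first member's flux scale.  Biomass,
    exchanges and explicitly protected reactions are never merged.
    """
    protected = set(protect or ())
    protected.add(model.biomass_id)
    protected.update(model.exchange_ids)

    work = model.copy()
    groups: dict[str, tuple[list[str], list[float]]] = {}

    while True:
        merged = False
        for i, j1, j2 in _mergeable_metabolites(work, protected):
            a = work.S[i, j1]
            b = work.S[i, j2]
            scale = -a / b  # v2 = scale * v1 at steady state
            r1, r2 = work.reaction_ids[j1], work.reaction_ids[j2]
            # composite column: col1 + scale * col2 (metabolite i cancels)
            new_col = (work.S[:, j1] + scale * work.S[:, j2]).toarray().ravel()
            new_col[np.abs(new_col) < 1e-12] = 0.0
            # bounds on v1 implied by v2's bounds
            if scale > 0:
                lo2, hi2 = work.lb[j2] / scale, work.ub[j2] / scale
            else:
                lo2, hi2 = work.ub[j2] / scale, work.lb[j2] / scale
            lo = max(work.lb[j1], lo2)
            hi = min(work.ub[j1], hi2)
            if lo > hi:
                continue  # incompatible bounds: not a real chain
            comp_id = f"{r1}+{r2}"
            members1, scales1 = groups.pop(r1, ([r1], [1.0]))
            members2, scales2 = groups.pop(r2, ([r2], [1.0]))
            members = members1 + members2
            scales = scales1 + [scale * s for s in scales2]
            groups[comp_id] = (members, scales)

            keep = [j for j in range(work.n_reactions) if j not in (j1, j2)]
            S_new = sp.hstack([work.S[:, keep], sp.csc_matrix(new_col[:, None])]).tocsc()
            rxn_ids = [work.reaction_ids[j] for j in keep] + [comp_id]
            lb = np.append(work.lb[keep], lo)
            ub = np.append(work.ub[keep], hi)
            row_mask = np.ones(work.n_metabolites, dtype=bool)
            if S_new.getrow(i).nnz == 0:
                row_mask[i] = False
            work = MetabolicModel(
                metabolite_ids=[m for k, m in enumerate(work.metabolite_ids) if row_mask[k]],
                reaction_ids=rxn_ids,
                S=sp.csc_matrix(S_new[row_mask]),
                lb=lb,
                ub=ub,
                biomass_id=work.biomass_id,
                exchange_ids=list(work.exchange_ids),
                subsystem={r: s for r, s in work.subsystem.items() if r in set(rxn_ids)},
                metabolite_formula=dict(work.metabolite_formula),
            )
            merged = True
            break
        if not merged:
            break

    rmap = ReductionMap(
        merged_groups=[(comp, m, s) for comp, (m, s) in groups.items()]
    )
    return work, rmap


def essential_reactions(model: MetabolicModel, min_growth: float) -> set[str]:
    """Reactions whose knockout drops the maximum growth below ``min_growth``."""
    essential = set()
    for rid in model.reaction_ids:
        fs = FluxSpace(model, bound_overrides={rid: (0.0, 0.0)})
        try:
            gmax, _ = fba(fs, model.biomass_id, "max")
        except InfeasibleProblemError:
            essential.add(rid)
            continue
        if gmax < min_growth - 1e-9:
            essential.add(rid)
    return essential


def is_maintenance(model: MetabolicModel, rid: str) -> bool:
    """Maintenance pseudo-reactions carry a fixed positive demand (lb > 0)."""
    return model.lb[model.index(rid)] > 0


def _target_sink_chain(model: MetabolicModel, target: str) -> set[str]:
    """The target reaction plus sole-consumer chains draining its products."""
    sinks = {target}
    S = sp.csc_matrix(model.S)
    frontier = [target]
    while frontier:
        rid = frontier.pop()
        j = model.index(rid)
        col = S.getcol(j).tocoo()
        for i, coef in zip(col.row, col.data):
            if coef <= 0:
                continue
            consumers = [
                model.reaction_ids[jj]
                for jj in range(model.n_reactions)
                if S[i, jj] < 0
            ]
            if len(consumers) == 1 and consumers[0] not in sinks:
                sinks.add(consumers[0])
                frontier.append(consumers[0])
    return sinks


def knockout_candidates(
    model: MetabolicModel,
    target: str,
    min_growth: float,
    extra_exclude: set[str] | None = None,
) -> set[str]:
    """Candidate knockout set F-times.

    Excluded are: growth-essential reactions, exchanges, biomass, the target
    reaction and its product sink chain, blocked reactions, maintenance
    demands, reactions annotated as spontaneous, reactions FVA-fixed at a
    nonzero flux (they cannot feasibly be zeroed), and anything in
    ``extra_exclude``.
    """
    excluded = set(extra_exclude or ())
    excluded.add(model.biomass_id)
    excluded.update(model.exchange_ids)
    excluded.update(_target_sink_chain(model, target))
    excluded.update(r for r in model.reaction_ids if is_maintenance(model, r))
    excluded.update(
        r for r, s in model.subsystem.items() if "spontaneous" in s.lower()
    )
    ranges = fva(FluxSpace(model))
    for rid, (lo, hi) in ranges.items():
        blocked = abs(lo) <= BLOCKED_TOL and abs(hi) <= BLOCKED_TOL
        fixed_nonzero = (hi - lo) <= BLOCKED_TOL and (abs(lo) > BLOCKED_TOL or abs(hi) > BLOCKED_TOL)
        if blocked or fixed_nonzero:
            excluded.add(rid)
    excluded.update(essential_reactions(model, min_growth))
    return {r for r in model.reaction_ids if r not in excluded}
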