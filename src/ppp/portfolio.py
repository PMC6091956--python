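"""Ranking and budget-constrained portfolio selection.

Projects are ranked by descending priority score P = B*L/C (rank 1 best; ties
broken by lower cost, then project id).  Budget selection runs iteratively:
score and rank the surviving projects, and while their total cost exceeds the
budget drop the last-ranked project, dissolve any cost-sharing it
participated in (its partners revert toward their own full proposals), and
repeat.  Benefit and
likelihood are fixed by the project definitions; only costs change as sharing
dissolves.
"""

from __future__ import annotations

import warnings
from typing import Sequence

from .model import DataValidationError, PriorityRecord, SpeciesProject
from .scoring import DiscountSpec, compute_likelihood, priority_score, project_cost
from .sharing import apportionment_map

__all__ = [
    "score_projects",
    "rank_projects",
    "select_under_budget",
    "roi_curve",
]


def score_projects(
    projects: Sequence[SpeciesProject],
    spec: DiscountSpec = DiscountSpec(),
    *,
    use_sharing: bool = True,
    use_stored_costs: bool = True,
) -> list[PriorityRecord]:
    """Compute B, L, C and the priority score for every project.

    Cost sharing is resolved across the whole input set unless
    ``use_sharing`` is false.  Projects carrying a pre-aggregated
    ``cost_total_npv`` (already shared, as in published per-species tables)
    use it directly when ``use_stored_costs`` is true.
    """
    all_actions = [a for p in projects for a in p.actions]
    shares = apportionment_map(all_actions) if use_sharing else {}
    records = []
    for p in projects:
        benefit = p.benefit
        likelihood = compute_likelihood(p.actions)
        cost = project_cost(p, shares, spec, use_stored=use_stored_costs)
        records.append(
            PriorityRecord(
                project_id=p.project_id,
                benefit=benefit,
                likelihood=likelihood,
                cost=cost,
                score=priority_score(benefit, likelihood, cost),
            )
        )
    return records


def rank_projects(records: Sequence[PriorityRecord]) -> list[PriorityRecord]:
    """Return records sorted best-first with ``rank`` assigned 1..N.

    Descending score; ties broken by lower cost, then lexicographic
    project id, so the ranking is a deterministic permutation.
    """
    ranked = sorted(records, key=lambda r: (-r.score, r.cost, r.project_id))
    for i, r in enumerate(ranked, start=1):
        r.rank = i
    return ranked


def select_under_budget(
    projects: Sequence[SpeciesProject],
    budget: float,
    spec: DiscountSpec = DiscountSpec(),
    *,
    freeze_ranks: bool = False,
    use_stored_costs: bool = True,
) -> tuple[list[PriorityRecord], list[PriorityRecord], list[dict]]:
    """Iteratively remove last-ranked projects until the portfolio fits the budget.

    Returns ``(kept, removed, log)``: kept records ranked best-first, removed
    records in removal order, and one log entry per iteration recording the
    removal and the cost changes it caused among survivors.  ``budget`` is
    on the same scale as C (50-year NPV).  With ``freeze_ranks`` the initial
    ranking decides the removal order; costs are still recomputed as sharing
    dissolves.
    """
    if budget <= 0:
        raise DataValidationError("budget must be > 0")
    by_id = {p.project_id: p for p in projects}
    surviving = list(by_id)
    frozen_order: dict[str, int] | None = None
    removed: list[PriorityRecord] = []
    log: list[dict] = []

    while True:
        subset = [by_id[pid] for pid in surviving]
        if not subset:
            warnings.warn("budget is smaller than the cheapest single project; "
                          "nothing can be funded", stacklevel=2)
            return [], removed, log
        all_actions = [a for p in subset for a in p.actions]
        shares = apportionment_map(all_actions, restrict_to=surviving)
        records = []
        for p in subset:
            cost = project_cost(p, shares, spec, use_stored=use_stored_costs)
            records.append(
                PriorityRecord(
                    project_id=p.project_id,
                    benefit=p.benefit,
                    likelihood=compute_likelihood(p.actions),
                    cost=cost,
                    score=priority_score(p.benefit, compute_likelihood(p.actions), cost),
                )
            )
        ranked = rank_projects(records)
        if freeze_ranks:
            if frozen_order is None:
                frozen_order = {r.project_id: r.rank for r in ranked}
            ranked.sort(key=lambda r: frozen_order[r.project_id])
            for i, r in enumerate(ranked, start=1):
                r.rank = i
        total = sum(r.cost for r in ranked)
        if total < budget:
            return ranked, removed, log

        worst = ranked[-1]
        surviving = [pid for pid in surviving if pid != worst.project_id]
        cost_before = {r.project_id: r.cost for r in ranked}
        new_shares = apportionment_map(
            [a for pid in surviving for a in by_id[pid].actions],
            restrict_to=surviving,
        )
        deltas = {}
        for pid in surviving:
            new_cost = project_cost(by_id[pid], new_shares, spec, use_stored=use_stored_costs)
            if abs(new_cost - cost_before[pid]) > 1e-9:
                deltas[pid] = new_cost - cost_before[pid]
        removed.append(worst)
        log.append({
            "iteration": len(log) + 1,
            "removed": worst.project_id,
            "removed_rank": worst.rank,
            "total_cost_before": total,
            "cost_changes": deltas,
        })


def roi_curve(ranked: Sequence[PriorityRecord]) -> list[tuple[int, float]]:
    """Cumulative mean annual cost of securing the top-k projects.

    Point k is ``(k, sum_{i<=k} C_i / 50)`` over the ranked list — the
    return-on-investment curve of average annual spend against number of
    species secured.
    """
    points = []
    cumulative = 0.0
    for k, r in enumerate(ranked, start=1):
        cumulative += r.cost
        points.append((k, cumulative / 50.0))
    return points
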