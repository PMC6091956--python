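"""Independent oracles used by the test suite.

These deliberately avoid the library's sharing/portfolio code paths: costs,
shares, scores and removal order are recomputed with plain dict arithmetic.
"""

from __future__ import annotations

import numpy as np

from ppp import ManagementAction, SpeciesProject


def naive_project_costs(projects, rate=0.01):
    """Per-project discounted cost with cost sharing, from first principles."""
    # proposals[(loc, type, year)] -> list of (project_id, action_id, annual_cost)
    proposals: dict[tuple, list[tuple[str, str, float]]] = {}
    for p in projects:
        for a in p.actions:
            for y in a.schedule:
                proposals.setdefault((a.location_key, a.action_type, y), []).append(
                    (p.project_id, a.action_id, a.annual_cost)
                )
    costs = {p.project_id: 0.0 for p in projects}
    for (_, _, year), members in proposals.items():
        by_project: dict[str, float] = {}
        for pid, _, c in members:
            by_project[pid] = by_project.get(pid, 0.0) + c
        factor = (1.0 + rate) ** -year
        if len(by_project) >= 2:
            mx, tot = max(by_project.values()), sum(by_project.values())
            for pid, c in by_project.items():
                costs[pid] += mx * c / tot * factor
        else:
            ((pid, c),) = by_project.items()
            costs[pid] += c * factor
    return costs


def naive_scores(projects, rate=0.01):
    costs = naive_project_costs(projects, rate)
    out = {}
    for p in projects:
        l = 1.0
        for a in p.actions:
            l *= a.input_success * a.threat_outcome_success * a.species_outcome_success
        out[p.project_id] = ((p.p_with - p.p_without) * l / costs[p.project_id],
                             costs[p.project_id])
    return out


def brute_force_select(projects, budget, rate=0.01):
    """Reference budget selection: re-score, drop the worst, dissolve, repeat."""
    surviving = list(projects)
    removal_order = []
    while surviving:
        scored = naive_scores(surviving, rate)
        total = sum(c for _, c in scored.values())
        if total < budget:
            break
        worst = sorted(surviving,
                       key=lambda p: (-scored[p.project_id][0],
                                      scored[p.project_id][1], p.project_id))[-1]
        removal_order.append(worst.project_id)
        surviving = [p for p in surviving if p.project_id != worst.project_id]
    return {p.project_id for p in surviving}, removal_order


def random_portfolio(rng: np.random.Generator, n_projects: int):
    """Small random portfolio with a random co-location graph."""
    shared_locs = [f"SH-{k}" for k in range(max(1, n_projects // 2))]
    projects = []
    for i in range(n_projects):
        pid = f"P{i:02d}"
        actions = []
        for j in range(int(rng.integers(1, 4))):
            if rng.random() < 0.4:
                loc, typ = str(rng.choice(shared_locs)), "weed control"
            else:
                loc, typ = f"OWN-{pid}-{j}", str(rng.choice(["fencing", "survey"]))
            start = int(rng.integers(1, 5))
            actions.append(ManagementAction(
                action_id=f"{pid}-A{j}", project_id=pid, site_id="S",
                location_key=loc, action_type=typ,
                schedule=frozenset(range(start, start + int(rng.integers(1, 6)))),
                annual_cost=float(rng.uniform(10, 1000)),
                input_success=float(rng.uniform(0.3, 1.0)),
                threat_outcome_success=float(rng.uniform(0.3, 1.0)),
                species_outcome_success=float(rng.uniform(0.3, 1.0)),
            ))
        projects.append(SpeciesProject(
            project_id=pid, species_name=f"sp{i}", taxon_group="plant",
            p_without=float(rng.uniform(0.0, 0.9)),
            actions=tuple(actions),
        ))
    return projects
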