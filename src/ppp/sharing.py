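"""Cost sharing between co-located actions of different projects.

Where two or more projects propose the same type of action at the same
location in the same year, only the most expensive proposal (assumed
sufficient for all of them) needs to be paid for.  That maximum is
apportioned among the participating projects in proportion to what each
proposed, so equal proposals split equally and the shares always sum to the
group maximum.  Sharing is resolved year by year: schedules that overlap
only partially share only the overlapping years.

When a project is removed from the portfolio its partners stop sharing with
it — the group re-apportions among the survivors (their shares can only go
up), and a lone survivor reverts to its full proposed cost.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

from .model import (
    DataValidationError,
    ManagementAction,
    SharedActionGroup,
)

__all__ = [
    "find_shared_groups",
    "apportion",
    "dissolve_member",
    "apportionment_map",
]


def find_shared_groups(
    actions: Sequence[ManagementAction],
    *,
    restrict_to: Iterable[str] | None = None,
) -> list[SharedActionGroup]:
    """Detect groups of actions eligible for cost sharing.

    Actions co-locate iff their ``(location_key, action_type)`` match exactly
    and their schedules overlap; one group is emitted per shared year, so an
    action belongs to at most one group per year.  ``restrict_to`` limits the
    search to actions of the given project ids (used during iterative budget
    selection, where removed projects no longer share).
    """
    keep = None if restrict_to is None else set(restrict_to)
    buckets: dict[tuple[str, str, int], list[ManagementAction]] = {}
    for a in actions:
        if keep is not None and a.project_id not in keep:
            continue
        for year in a.schedule:
            buckets.setdefault((a.location_key, a.action_type, year), []).append(a)

    groups: list[SharedActionGroup] = []
    for (loc, action_type, year), members in sorted(buckets.items()):
        if len({m.project_id for m in members}) < 2:
            continue
        groups.append(
            SharedActionGroup(
                location_key=loc,
                action_type=action_type,
                year=year,
                members=tuple(
                    (m.project_id, m.action_id, m.annual_cost)
                    for m in sorted(members, key=lambda m: (m.project_id, m.action_id))
                ),
            )
        )
    return groups


def apportion(group: SharedActionGroup) -> dict[str, float]:
    """Apportion the group's maximum proposed cost among its projects.

    share_j = max_cost * proposed_j / sum(proposed); with identical proposals
    this reduces to an equal split.  Shares conserve the maximum exactly.
    """
    by_project: dict[str, float] = {}
    for project_id, action_id, cost in group.members:
        if cost <= 0:
            raise DataValidationError(
                f"shared action {action_id}: proposed cost must be > 0 for apportionment"
            )
        by_project[project_id] = by_project.get(project_id, 0.0) + cost
    max_cost = max(by_project.values())
    total = sum(by_project.values())
    return {pid: max_cost * cost / total for pid, cost in by_project.items()}


def dissolve_member(
    group: SharedActionGroup, removed_project: str
) -> SharedActionGroup | None:
    """Drop one project from a sharing group.

    Returns the re-formed group over the survivors, or ``None`` when only one
    project remains (it then bears its own full proposed cost — dissolution).
    """
    if removed_project not in group.project_ids:
        raise DataValidationError(
            f"project {removed_project!r} is not a member of the group at "
            f"{group.location_key!r}/{group.action_type!r}/year {group.year}"
        )
    survivors = tuple(m for m in group.members if m[0] != removed_project)
    if len({m[0] for m in survivors}) < 2:
        return None
    return SharedActionGroup(
        location_key=group.location_key,
        action_type=group.action_type,
        year=group.year,
        members=survivors,
    )


def apportionment_map(
    actions: Sequence[ManagementAction],
    *,
    restrict_to: Iterable[str] | None = None,
) -> dict[str, dict[int, float]]:
    """Per-action, per-year apportioned annual costs for all shared groups.

    Returns ``{action_id: {year: apportioned_cost}}`` covering exactly the
    (action, year) pairs that are shared among the surviving projects; all
    other pairs keep the action's own annual cost.  A project proposing
    several actions in one group receives one project-level share, split over
    those actions in proportion to their proposals.
    """
    out: dict[str, dict[int, float]] = {}
    for group in find_shared_groups(actions, restrict_to=restrict_to):
        shares = apportion(group)
        proposed_by_project: dict[str, float] = {}
        for pid, _, cost in group.members:
            proposed_by_project[pid] = proposed_by_project.get(pid, 0.0) + cost
        for pid, action_id, cost in group.members:
            scale = shares[pid] / proposed_by_project[pid]
            out.setdefault(action_id, {})[group.year] = cost * scale
    return out
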