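"""Benefit, likelihood of success, discounted cost, and the priority score.

The cost-efficiency index ranking conservation projects is

    P = B * L / C

where ``B = P_w - P_n`` is the marginal gain in the species' probability of a
viable population in 100 years, ``L`` is the product over all project actions
of input x threat-outcome x species-outcome success, and ``C`` is the total
50-year net-present-value cost of the project's actions (after cost sharing),
discounted at a static annual rate (default 1%/yr):

    C = sum_{t=1..50} C_t / (1 + r)^t
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .model import (
    DEFAULT_P_WITH,
    HORIZON_YEARS,
    DataValidationError,
    IucnCategory,
    ManagementAction,
    SpeciesProject,
)

__all__ = [
    "DiscountSpec",
    "PN_ANCHORS",
    "anchor_pn",
    "compute_benefit",
    "compute_likelihood",
    "discount_cost",
    "project_cost",
    "priority_score",
]


@dataclass(frozen=True)
class DiscountSpec:
    """Net-present-value discounting of scheduled costs.

    ``rate`` is the static annual discount rate; year ``first_year_index`` is
    the first year to be discounted (year-1 costs are divided by (1+r)^1).
    """

    rate: float = 0.01
    horizon: int = HORIZON_YEARS
    first_year_index: int = 1

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise DataValidationError("discount rate must be >= 0")
        if self.horizon < 1:
            raise DataValidationError("horizon must be >= 1 year")

    def factor(self, year: int) -> float:
        """Present-value factor for a cost incurred in ``year``."""
        return (1.0 + self.rate) ** -(year - self.first_year_index + 1)


#: 100-year viability probability without management, anchored on the
#: cumulative extinction-risk curves for the three Red List categories.
PN_ANCHORS: dict[IucnCategory, float] = {
    IucnCategory.VULNERABLE: 0.9,
    IucnCategory.ENDANGERED: 0.3,
    IucnCategory.CRITICALLY_ENDANGERED: 0.05,
}


def anchor_pn(category: IucnCategory | str) -> float:
    """Anchoring value of P_n for a Red List category (V 0.9, E 0.3, CE 0.05)."""
    cat = IucnCategory.parse(category)
    if cat is None or cat not in PN_ANCHORS:
        raise DataValidationError(f"unknown IUCN category: {category!r}")
    return PN_ANCHORS[cat]


def compute_benefit(p_with: float, p_without: float) -> float:
    """B = P_w - P_n, the management-attributable gain in viability probability."""
    for name, v in (("p_with", p_with), ("p_without", p_without)):
        if not 0.0 <= v <= 1.0:
            raise DataValidationError(f"{name} must be in [0, 1], got {v}")
    if p_with < p_without:
        raise DataValidationError(
            f"p_with ({p_with}) < p_without ({p_without}); negative benefit is not modelled"
        )
    return p_with - p_without


def compute_likelihood(actions: Sequence[ManagementAction]) -> float:
    """L = prod_i (I_i * T_i * S_i) over the project's actions.

    The three success scores are elicited as independent probabilities, so the
    triple product is the probability the action meets its objective and the
    overall product the probability that every action does.
    """
    if not actions:
        raise DataValidationError("likelihood of success needs at least one action")
    l = 1.0
    for a in actions:
        l *= a.success_product
    return l


def discount_cost(
    annual_costs: Mapping[int, float],
    spec: DiscountSpec = DiscountSpec(),
) -> float:
    """Net present value of a year -> cost schedule under ``spec``."""
    total = 0.0
    for year, cost in annual_costs.items():
        if not (spec.first_year_index <= year <= spec.first_year_index + spec.horizon - 1):
            raise DataValidationError(
                f"year {year} outside horizon "
                f"{spec.first_year_index}..{spec.first_year_index + spec.horizon - 1}"
            )
        if cost < 0:
            raise DataValidationError(f"cost for year {year} is negative")
        total += cost * spec.factor(year)
    return total


def project_cost(
    project: SpeciesProject,
    apportionment: Mapping[str, Mapping[int, float]] | None = None,
    spec: DiscountSpec = DiscountSpec(),
    *,
    use_stored: bool = True,
) -> float:
    """Total discounted cost C of a project's actions.

    ``apportionment`` maps action_id -> {year -> apportioned annual cost} for
    actions whose cost is shared with co-located actions of other projects;
    unshared (action, year) pairs fall back to the action's own annual cost.
    If the dataset carries a pre-aggregated ``cost_total_npv`` (and
    ``use_stored`` is true) that stored value is returned unchanged.
    """
    if use_stored and project.cost_total_npv is not None:
        return project.cost_total_npv
    apportionment = apportionment or {}
    total = 0.0
    for action in project.actions:
        shares = apportionment.get(action.action_id, {})
        schedule = {y: shares.get(y, action.annual_cost) for y in action.schedule}
        total += discount_cost(schedule, spec)
    if total <= 0:
        raise DataValidationError(
            f"project {project.project_id}: total cost is 0; priority score undefined"
        )
    return total


def priority_score(benefit: float, likelihood: float, cost: float) -> float:
    """P = B * L / C (probability gain per currency unit)."""
    if not 0.0 <= benefit <= 1.0:
        raise DataValidationError(f"benefit must be in [0, 1], got {benefit}")
    if not 0.0 <= likelihood <= 1.0:
        raise DataValidationError(f"likelihood must be in [0, 1], got {likelihood}")
    if cost <= 0:
        raise DataValidationError(f"cost must be > 0, got {cost}")
    return benefit * likelihood / cost


def default_p_with() -> float:
    """The program objective for P_w (95% viability in 100 years)."""
    return DEFAULT_P_WITH
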