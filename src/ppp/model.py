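"""Domain types and dataset I/O for threatened-species project prioritization.

The prioritization works from two tables, mirroring the structure agencies use
for expert-elicited project data:

* a **species table** — one row per species project, carrying the probability of
  a viable population in 100 years without targeted management (``p_n``), with
  full successful implementation (``p_w``, default 0.95), a qualitative
  confidence grade on the benefit estimate, and optionally a pre-aggregated
  50-year net-present-value cost;
* an **actions table** — one row per management/monitoring action (many-to-one
  with projects), each with a schedule of years, an annual cost, and three
  success probabilities (input, threat-outcome, species-outcome) plus a
  confidence grade.

The canonical interchange format is a pair of CSV files; a best-effort reader
for the two-worksheet ``.xlsx`` layout is also provided.  Headers are matched
fuzzily (case/punctuation-insensitive, with a synonym table) and can be pinned
with an explicit override mapping.
"""

from __future__ import annotations

import dataclasses
import enum
import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "HORIZON_YEARS",
    "DEFAULT_P_WITH",
    "ConfidenceGrade",
    "IucnCategory",
    "TaxonGroup",
    "ManagementAction",
    "SpeciesProject",
    "SharedActionGroup",
    "PriorityRecord",
    "SimulationConfig",
    "SchemaError",
    "ReferentialIntegrityError",
    "DataValidationError",
    "read_dataset",
    "read_csv_pair",
    "read_workbook",
    "write_dataset",
    "write_results",
    "read_results",
    "projects_from_tables",
]

#: Planning horizon for costs, in years.
HORIZON_YEARS = 50

#: Program objective: probability of a viable population in 100 years with
#: full, successful implementation.  Projects default to this value of P_w.
DEFAULT_P_WITH = 0.95


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class ReferentialIntegrityError(ValueError):
    """Cross-table references are inconsistent (e.g. orphan actions)."""


class DataValidationError(ValueError):
    """A field value violates its domain constraints."""


class ConfidenceGrade(enum.Enum):
    """Qualitative confidence in an elicited estimate.

    Each grade maps to a symmetric interval half-width used when propagating
    elicitation uncertainty: very confident ±0.05, confident ±0.10,
    not confident ±0.20.
    """

    VERY_CONFIDENT = "very_confident"
    CONFIDENT = "confident"
    NOT_CONFIDENT = "not_confident"

    @property
    def half_width(self) -> float:
        return _HALF_WIDTHS[self]

    @classmethod
    def parse(cls, value: "str | ConfidenceGrade") -> "ConfidenceGrade":
        if isinstance(value, ConfidenceGrade):
            return value
        key = _norm(str(value))
        try:
            return _GRADE_ALIASES[key]
        except KeyError:
            raise DataValidationError(f"unknown confidence grade: {value!r}") from None


_HALF_WIDTHS = {
    ConfidenceGrade.VERY_CONFIDENT: 0.05,
    ConfidenceGrade.CONFIDENT: 0.10,
    ConfidenceGrade.NOT_CONFIDENT: 0.20,
}


class IucnCategory(enum.Enum):
    """Red List threat category used to anchor P_n estimates."""

    VULNERABLE = "vulnerable"
    ENDANGERED = "endangered"
    CRITICALLY_ENDANGERED = "critically_endangered"

    @classmethod
    def parse(cls, value: "str | IucnCategory | None") -> "IucnCategory | None":
        if value is None or isinstance(value, IucnCategory):
            return value
        if isinstance(value, float) and pd.isna(value):
            return None
        key = _norm(str(value))
        if not key:
            return None
        try:
            return _IUCN_ALIASES[key]
        except KeyError:
            raise DataValidationError(f"unknown IUCN category: {value!r}") from None


class TaxonGroup(enum.Enum):
    PLANT = "plant"
    ANIMAL = "animal"
    FUNGUS = "fungus"

    @classmethod
    def parse(cls, value: "str | TaxonGroup") -> "TaxonGroup":
        if isinstance(value, TaxonGroup):
            return value
        key = _norm(str(value))
        for member in cls:
            if key == member.value or key == member.value + "s":
                return member
        # common synonyms
        if key in {"flora"}:
            return cls.PLANT
        if key in {"fauna"}:
            return cls.ANIMAL
        if key in {"fungi"}:
            return cls.FUNGUS
        raise DataValidationError(f"unknown taxon group: {value!r}")


def _check_probability(name: str, value: float, row: "int | str | None" = None) -> float:
    value = float(value)
    if not (0.0 <= value <= 1.0):
        where = f" (row {row})" if row is not None else ""
        raise DataValidationError(f"{name} must be in [0, 1], got {value}{where}")
    return value


@dataclass(frozen=True)
class ManagementAction:
    """A costed, scheduled intervention at a site.

    ``input_success`` (I) is the probability the action can be implemented at
    all; ``threat_outcome_success`` (T) that it controls the threat;
    ``species_outcome_success`` (S) that the population responds.  Monitoring
    actions conventionally carry I = T = S = 1 so that they contribute cost but
    do not depress the project's likelihood of success.
    """

    action_id: str
    project_id: str
    site_id: str
    location_key: str
    action_type: str
    schedule: frozenset[int]
    annual_cost: float
    input_success: float = 1.0
    threat_outcome_success: float = 1.0
    species_outcome_success: float = 1.0
    confidence: ConfidenceGrade = ConfidenceGrade.CONFIDENT

    def __post_init__(self) -> None:
        object.__setattr__(self, "schedule", frozenset(int(y) for y in self.schedule))
        if not self.schedule:
            raise DataValidationError(f"action {self.action_id}: empty schedule")
        bad = [y for y in self.schedule if not (1 <= y <= HORIZON_YEARS)]
        if bad:
            raise DataValidationError(
                f"action {self.action_id}: schedule years {sorted(bad)} outside 1..{HORIZON_YEARS}"
            )
        if self.annual_cost < 0:
            raise DataValidationError(
                f"action {self.action_id}: annual_cost must be >= 0, got {self.annual_cost}"
            )
        for name in ("input_success", "threat_outcome_success", "species_outcome_success"):
            _check_probability(f"action {self.action_id}: {name}", getattr(self, name))
        object.__setattr__(self, "confidence", ConfidenceGrade.parse(self.confidence))

    @property
    def success_product(self) -> float:
        """I * T * S — this action's contribution to project likelihood."""
        return self.input_success * self.threat_outcome_success * self.species_outcome_success


@dataclass(frozen=True)
class SpeciesProject:
    """One prioritization asset: a species with its management prescription."""

    project_id: str
    species_name: str
    taxon_group: TaxonGroup
    p_without: float
    p_with: float = DEFAULT_P_WITH
    benefit_confidence: ConfidenceGrade = ConfidenceGrade.CONFIDENT
    iucn_category: IucnCategory | None = None
    recent_site_confirmation: bool = True
    actions: tuple[ManagementAction, ...] = ()
    cost_total_npv: float | None = None

    def __post_init__(self) -> None:
        _check_probability(f"project {self.project_id}: p_without", self.p_without)
        _check_probability(f"project {self.project_id}: p_with", self.p_with)
        if self.p_with < self.p_without:
            raise DataValidationError(
                f"project {self.project_id}: p_with ({self.p_with}) < p_without "
                f"({self.p_without}); negative benefit is not modelled"
            )
        object.__setattr__(self, "taxon_group", TaxonGroup.parse(self.taxon_group))
        object.__setattr__(
            self, "benefit_confidence", ConfidenceGrade.parse(self.benefit_confidence)
        )
        object.__setattr__(self, "iucn_category", IucnCategory.parse(self.iucn_category))
        object.__setattr__(self, "actions", tuple(self.actions))
        if self.cost_total_npv is not None and self.cost_total_npv <= 0:
            raise DataValidationError(
                f"project {self.project_id}: cost_total_npv must be > 0"
            )
        bad = [a.action_id for a in self.actions if a.project_id != self.project_id]
        if bad:
            raise ReferentialIntegrityError(
                f"project {self.project_id}: actions {bad} carry a different project_id"
            )

    @property
    def benefit(self) -> float:
        """Marginal gain in 100-year viability probability, B = P_w - P_n."""
        return self.p_with - self.p_without


@dataclass(frozen=True)
class SharedActionGroup:
    """Actions from distinct projects proposing the same work at the same
    location in the same year, eligible for cost apportionment."""

    location_key: str
    action_type: str
    year: int
    members: tuple[tuple[str, str, float], ...]  # (project_id, action_id, proposed_cost)

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", tuple(self.members))
        projects = {m[0] for m in self.members}
        if len(projects) < 2:
            raise DataValidationError(
                f"shared group at {self.location_key!r}/{self.action_type!r}/year "
                f"{self.year}: needs members from >= 2 distinct projects"
            )

    @property
    def project_ids(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for pid, _, _ in self.members:
            seen.setdefault(pid, None)
        return tuple(seen)


@dataclass
class PriorityRecord:
    """Per-project scoring result.

    ``score`` is B * L / C with C in currency units as given, so its natural
    magnitude is probability per dollar (tiny).  ``rank`` 1 is best.  The rank
    interval holds the 2.5 and 97.5 percentiles of simulated ranks; ``band`` is
    the five-level priority band (1 = highest priority).
    """

    project_id: str
    benefit: float
    likelihood: float
    cost: float
    score: float
    rank: int | None = None
    rank_interval: tuple[int, int] | None = None
    band: int | None = None

    def __post_init__(self) -> None:
        _check_probability(f"record {self.project_id}: benefit", self.benefit)
        _check_probability(f"record {self.project_id}: likelihood", self.likelihood)
        if self.cost <= 0:
            raise DataValidationError(f"record {self.project_id}: cost must be > 0")
        expected = self.benefit * self.likelihood / self.cost
        if abs(self.score - expected) > 1e-12 * max(1.0, abs(expected)):
            raise DataValidationError(
                f"record {self.project_id}: score {self.score} != B*L/C {expected}"
            )
        if self.rank_interval is not None:
            lo, hi = self.rank_interval
            if lo > hi:
                raise DataValidationError(
                    f"record {self.project_id}: rank interval lo {lo} > hi {hi}"
                )
        if self.band is not None and not (1 <= self.band <= 5):
            raise DataValidationError(f"record {self.project_id}: band must be 1..5")


@dataclass(frozen=True)
class SimulationConfig:
    """Monte Carlo settings for uncertainty propagation.

    ``cost_interval_symmetric`` is the relative half-width applied to cost for
    projects with recent site confirmation (±30%); ``cost_interval_stale`` the
    (up, down) relative bounds (+100%/−30%) for projects without it.
    ``l_floor`` truncates sampled likelihoods from below.  ``band_thresholds``
    are the rank-fraction cutoffs (top 30% / top 70%) used for banding.
    ``confidence_half_widths`` maps each qualitative grade to the half-width
    of its probability interval.
    """

    n_sims: int = 10_500
    seed: int = 0
    confidence_half_widths: Mapping[ConfidenceGrade, float] = field(
        default_factory=lambda: dict(_HALF_WIDTHS)
    )
    cost_interval_symmetric: float = 0.30
    cost_interval_stale: tuple[float, float] = (1.00, 0.30)
    l_floor: float = 0.1
    percentile_method: str = "nearest-rank"
    band_thresholds: tuple[float, float] = (0.30, 0.70)
    cutoff_rounding: str = "half-even"  # or "floor" / "ceil"
    band5_rule: str = "best-case"  # or "printed"

    def __post_init__(self) -> None:
        if self.n_sims < 1:
            raise DataValidationError("n_sims must be >= 1")
        widths = dict(self.confidence_half_widths)
        missing = [g for g in ConfidenceGrade if g not in widths]
        if missing or any(w < 0 for w in widths.values()):
            raise DataValidationError(
                "confidence_half_widths must give a non-negative width for every grade"
            )
        object.__setattr__(self, "confidence_half_widths", widths)
        lo, hi = self.band_thresholds
        if not (0.0 < lo < hi < 1.0):
            raise DataValidationError("band thresholds must be ordered and in (0, 1)")
        if self.percentile_method != "nearest-rank":
            raise DataValidationError("only the nearest-rank percentile method is supported")
        if self.cutoff_rounding not in {"half-even", "floor", "ceil"}:
            raise DataValidationError(f"unknown cutoff_rounding: {self.cutoff_rounding!r}")
        if self.band5_rule not in {"best-case", "printed"}:
            raise DataValidationError(f"unknown band5_rule: {self.band5_rule!r}")


# ---------------------------------------------------------------------------
# Header normalisation / fuzzy matching
# ---------------------------------------------------------------------------

def _norm(s: str) -> str:
    return re.sub(r"[^a-z0-9]", "", s.strip().lower())


_GRADE_ALIASES = {
    "veryconfident": ConfidenceGrade.VERY_CONFIDENT,
    "vc": ConfidenceGrade.VERY_CONFIDENT,
    "005": ConfidenceGrade.VERY_CONFIDENT,
    "confident": ConfidenceGrade.CONFIDENT,
    "c": ConfidenceGrade.CONFIDENT,
    "01": ConfidenceGrade.CONFIDENT,
    "notconfident": ConfidenceGrade.NOT_CONFIDENT,
    "nc": ConfidenceGrade.NOT_CONFIDENT,
    "02": ConfidenceGrade.NOT_CONFIDENT,
}
_GRADE_ALIASES.update({_norm(g.value): g for g in ConfidenceGrade})

_IUCN_ALIASES = {
    "vulnerable": IucnCategory.VULNERABLE,
    "v": IucnCategory.VULNERABLE,
    "vu": IucnCategory.VULNERABLE,
    "endangered": IucnCategory.ENDANGERED,
    "e": IucnCategory.ENDANGERED,
    "en": IucnCategory.ENDANGERED,
    "criticallyendangered": IucnCategory.CRITICALLY_ENDANGERED,
    "ce": IucnCategory.CRITICALLY_ENDANGERED,
    "cr": IucnCategory.CRITICALLY_ENDANGERED,
}

# canonical name -> accepted header spellings (normalised)
_SPECIES_SYNONYMS: dict[str, tuple[str, ...]] = {
    "project_id": ("projectid", "project", "id", "speciesid", "assetid"),
    "species_name": ("speciesname", "species", "scientificname", "name"),
    "taxon_group": ("taxongroup", "taxon", "group", "taxa"),
    "p_n": ("pn", "pwithout", "probwithout", "pnomanagement", "pnought"),
    "p_w": ("pw", "pwith", "probwith", "pmanaged"),
    "b": ("b", "benefit", "projectbenefit"),
    "benefit_confidence": (
        "benefitconfidence", "confidence", "bconfidence", "uncertaintybounding",
        "boundingvalue", "confidenceb",
    ),
    "iucn_category": ("iucncategory", "iucn", "threatcategory", "redlistcategory"),
    "recent_site_confirmation": (
        "recentsiteconfirmation", "siteconfirmed", "recentconfirmation", "sitesconfirmed",
    ),
    "cost_total_npv": (
        "costtotalnpv", "c", "cost", "totalcost", "projectcost", "costnpv", "totalcost50yr",
    ),
}

_ACTION_SYNONYMS: dict[str, tuple[str, ...]] = {
    "action_id": ("actionid", "action", "id"),
    "project_id": ("projectid", "project", "speciesid"),
    "site_id": ("siteid", "site"),
    "location_key": ("locationkey", "location", "locationid", "polygonid"),
    "action_type": ("actiontype", "type", "activity", "actionname"),
    "years": ("years", "schedule", "yearsscheduled", "scheduleyears"),
    "annual_cost": ("annualcost", "costperyear", "costyr", "cost"),
    "input_success": ("inputsuccess", "i", "input", "feasibility"),
    "threat_outcome_success": ("threatoutcomesuccess", "t", "threatoutcome", "output", "outputsuccess"),
    "species_outcome_success": ("speciesoutcomesuccess", "s", "speciesoutcome", "outcome", "outcomesuccess"),
    "confidence": ("confidence", "lconfidence", "uncertaintybounding", "boundingvalue"),
}

_SPECIES_REQUIRED = ("project_id", "species_name", "taxon_group", "p_n")
_ACTION_REQUIRED = (
    "action_id", "project_id", "annual_cost",
    "input_success", "threat_outcome_success", "species_outcome_success",
)


def _map_headers(
    columns: Iterable[str],
    synonyms: Mapping[str, tuple[str, ...]],
    required: Sequence[str],
    overrides: Mapping[str, str] | None,
    table: str,
) -> dict[str, str]:
    """Return canonical-name -> actual-column mapping, fuzzily matched."""
    overrides = {str(k): v for k, v in (overrides or {}).items()}
    lookup: dict[str, str] = {}
    for canonical, alts in synonyms.items():
        for alt in (canonical,) + alts:
            lookup.setdefault(_norm(alt), canonical)
    out: dict[str, str] = {}
    for col in columns:
        if col in overrides:
            out[overrides[col]] = col
            continue
        canonical = lookup.get(_norm(str(col)))
        if canonical is not None and canonical not in out:
            out[canonical] = col
    missing = [c for c in required if c not in out]
    if missing:
        raise SchemaError(f"{table} table is missing required column(s): {', '.join(missing)}")
    return out


def _parse_bool(value: object, default: bool = True) -> bool:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return default
    if isinstance(value, bool):
        return value
    key = _norm(str(value))
    if key in {"true", "t", "yes", "y", "1"}:
        return True
    if key in {"false", "f", "no", "n", "0"}:
        return False
    raise DataValidationError(f"cannot interpret boolean value {value!r}")


def _parse_years(value: object, row: int) -> frozenset[int]:
    if isinstance(value, (int, float)) and not pd.isna(value):
        return frozenset([int(value)])
    text = str(value).strip()
    if not text:
        raise DataValidationError(f"actions row {row}: empty schedule")
    years: set[int] = set()
    for part in re.split(r"[;,\s]+", text):
        if not part:
            continue
        if "-" in part and not part.startswith("-"):
            a, b = part.split("-", 1)
            years.update(range(int(a), int(b) + 1))
        else:
            years.add(int(float(part)))
    return frozenset(years)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def projects_from_tables(
    species: pd.DataFrame,
    actions: pd.DataFrame,
    *,
    species_overrides: Mapping[str, str] | None = None,
    action_overrides: Mapping[str, str] | None = None,
    benefit_tolerance: float = 1e-6,
) -> list[SpeciesProject]:
    """Validate and join the two tables into :class:`SpeciesProject` objects.

    Every action must reference an existing project and every project must own
    at least one action (the likelihood of success is undefined otherwise). A
    stored benefit column, if present, is reconciled against P_w − P_n; on
    mismatch beyond ``benefit_tolerance`` the recomputed value wins with a
    warning.
    """
    smap = _map_headers(species.columns, _SPECIES_SYNONYMS, _SPECIES_REQUIRED,
                        species_overrides, "species")
    amap = _map_headers(actions.columns, _ACTION_SYNONYMS, _ACTION_REQUIRED,
                        action_overrides, "actions")

    parsed_actions: dict[str, list[ManagementAction]] = {}
    for i, row in actions.reset_index(drop=True).iterrows():
        def av(name: str, default: object = None) -> object:
            col = amap.get(name)
            if col is None:
                return default
            val = row[col]
            if val is None or (isinstance(val, float) and pd.isna(val)):
                return default
            if isinstance(val, str) and not val.strip():
                return default
            return val

        try:
            action = ManagementAction(
                action_id=str(av("action_id")),
                project_id=str(av("project_id")),
                site_id=str(av("site_id", "")),
                location_key=str(av("location_key", f"__row{i}")),
                action_type=str(av("action_type", "")),
                schedule=_parse_years(av("years", 1), i),
                annual_cost=float(av("annual_cost")),
                input_success=float(av("input_success")),
                threat_outcome_success=float(av("threat_outcome_success")),
                species_outcome_success=float(av("species_outcome_success")),
                confidence=ConfidenceGrade.parse(av("confidence", "confident")),
            )
        except (TypeError, ValueError) as exc:
            if isinstance(exc, (DataValidationError, ReferentialIntegrityError)):
                raise type(exc)(f"actions row {i}: {exc}") from None
            raise DataValidationError(f"actions row {i}: {exc}") from None
        parsed_actions.setdefault(action.project_id, []).append(action)

    projects: list[SpeciesProject] = []
    seen_ids: set[str] = set()
    for i, row in species.reset_index(drop=True).iterrows():
        def sv(name: str, default: object = None) -> object:
            col = smap.get(name)
            if col is None:
                return default
            val = row[col]
            if val is None or (isinstance(val, float) and pd.isna(val)):
                return default
            if isinstance(val, str) and not val.strip():
                return default
            return val

        pid = str(sv("project_id"))
        if pid in seen_ids:
            raise ReferentialIntegrityError(f"duplicate project_id {pid!r} in species table")
        seen_ids.add(pid)
        own_actions = parsed_actions.pop(pid, None)
        if not own_actions:
            raise ReferentialIntegrityError(
                f"project {pid!r} has no actions; likelihood of success is undefined"
            )
        p_n = float(sv("p_n"))
        p_w = float(sv("p_w", DEFAULT_P_WITH))
        stored_b = sv("b")
        if stored_b is not None:
            recomputed = p_w - p_n
            if abs(float(stored_b) - recomputed) > benefit_tolerance:
                warnings.warn(
                    f"project {pid}: stored benefit {float(stored_b):.6f} != "
                    f"P_w - P_n = {recomputed:.6f}; using the recomputed value",
                    stacklevel=2,
                )
        cost = sv("cost_total_npv")
        try:
            projects.append(
                SpeciesProject(
                    project_id=pid,
                    species_name=str(sv("species_name")),
                    taxon_group=TaxonGroup.parse(sv("taxon_group")),
                    p_without=p_n,
                    p_with=p_w,
                    benefit_confidence=ConfidenceGrade.parse(sv("benefit_confidence", "confident")),
                    iucn_category=IucnCategory.parse(sv("iucn_category")),
                    recent_site_confirmation=_parse_bool(sv("recent_site_confirmation")),
                    actions=tuple(sorted(own_actions, key=lambda a: a.action_id)),
                    cost_total_npv=float(cost) if cost is not None else None,
                )
            )
        except (DataValidationError, ReferentialIntegrityError) as exc:
            raise type(exc)(f"species row {i}: {exc}") from None

    if parsed_actions:
        orphans = sorted(a.action_id for acts in parsed_actions.values() for a in acts)
        raise ReferentialIntegrityError(
            f"actions reference unknown project_id(s) {sorted(parsed_actions)}: "
            f"actions {orphans}"
        )
    return projects


def read_csv_pair(
    species_path: "str | Path",
    actions_path: "str | Path",
    **kwargs: object,
) -> list[SpeciesProject]:
    """Read the paired-CSV dialect (``species.csv`` + ``actions.csv``)."""
    species = pd.read_csv(species_path, float_precision="round_trip")
    actions = pd.read_csv(actions_path, float_precision="round_trip")
    return projects_from_tables(species, actions, **kwargs)


def read_workbook(path: "str | Path", **kwargs: object) -> list[SpeciesProject]:
    """Best-effort reader for the two-worksheet workbook layout
    (``PerSpeciesCostBenefit`` / ``PerActionLikelihoodOfSuccess``)."""
    sheets = pd.read_excel(path, sheet_name=None)
    species_df = actions_df = None
    for name, df in sheets.items():
        key = _norm(name)
        if "costbenefit" in key or "species" in key:
            species_df = df
        elif "likelihood" in key or "action" in key:
            actions_df = df
    if species_df is None or actions_df is None:
        raise SchemaError(
            "workbook must contain a per-species cost/benefit sheet and a "
            "per-action likelihood-of-success sheet"
        )
    return projects_from_tables(species_df, actions_df, **kwargs)


def read_dataset(
    path: "str | Path | tuple[str | Path, str | Path]",
    **kwargs: object,
) -> list[SpeciesProject]:
    """Read a dataset from a workbook, a (species, actions) path pair, or a
    directory containing ``species.csv`` and ``actions.csv``."""
    if isinstance(path, (tuple, list)):
        return read_csv_pair(path[0], path[1], **kwargs)
    p = Path(path)
    if p.is_dir():
        return read_csv_pair(p / "species.csv", p / "actions.csv", **kwargs)
    if p.suffix.lower() in {".xlsx", ".xlsm", ".xls"}:
        return read_workbook(p, **kwargs)
    raise SchemaError(
        f"cannot infer dataset layout from {path!r}; pass a workbook, a "
        "directory, or a (species_csv, actions_csv) pair"
    )


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

_SPECIES_COLUMNS = (
    "project_id", "species_name", "taxon_group", "p_n", "p_w", "benefit_confidence",
    "iucn_category", "recent_site_confirmation", "cost_total_npv",
)
_ACTION_COLUMNS = (
    "action_id", "project_id", "site_id", "location_key", "action_type", "years",
    "annual_cost", "input_success", "threat_outcome_success", "species_outcome_success",
    "confidence",
)


def dataset_tables(projects: Sequence[SpeciesProject]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flatten projects into the canonical (species, actions) DataFrames."""
    srows = []
    arows = []
    for p in projects:
        srows.append({
            "project_id": p.project_id,
            "species_name": p.species_name,
            "taxon_group": p.taxon_group.value,
            "p_n": p.p_without,
            "p_w": p.p_with,
            "benefit_confidence": p.benefit_confidence.value,
            "iucn_category": p.iucn_category.value if p.iucn_category else "",
            "recent_site_confirmation": p.recent_site_confirmation,
            "cost_total_npv": float("nan") if p.cost_total_npv is None else p.cost_total_npv,
        })
        for a in p.actions:
            arows.append({
                "action_id": a.action_id,
                "project_id": a.project_id,
                "site_id": a.site_id,
                "location_key": a.location_key,
                "action_type": a.action_type,
                "years": ";".join(str(y) for y in sorted(a.schedule)),
                "annual_cost": a.annual_cost,
                "input_success": a.input_success,
                "threat_outcome_success": a.threat_outcome_success,
                "species_outcome_success": a.species_outcome_success,
                "confidence": a.confidence.value,
            })
    return (
        pd.DataFrame(srows, columns=_SPECIES_COLUMNS),
        pd.DataFrame(arows, columns=_ACTION_COLUMNS),
    )


def write_csv(df: pd.DataFrame, path: "str | Path") -> None:
    """CSV writer preserving float values exactly (shortest round-trip repr)."""
    df.to_csv(path, index=False, float_format=lambda x: repr(float(x)))


def write_dataset(
    projects: Sequence[SpeciesProject],
    species_path: "str | Path",
    actions_path: "str | Path",
) -> None:
    """Write the paired-CSV dialect; round-trips through :func:`read_csv_pair`."""
    species, actions = dataset_tables(projects)
    write_csv(species, species_path)
    write_csv(actions, actions_path)


_RESULT_COLUMNS = (
    "project_id", "benefit", "likelihood", "cost", "score",
    "rank", "rank_lo", "rank_hi", "band",
)


def write_results(records: Sequence[PriorityRecord], path: "str | Path") -> None:
    """Write per-project priority results as CSV, one row per project."""
    if not records:
        raise DataValidationError("no records to write")
    rows = []
    for r in records:
        lo, hi = r.rank_interval if r.rank_interval is not None else (None, None)
        rows.append({
            "project_id": r.project_id,
            "benefit": r.benefit,
            "likelihood": r.likelihood,
            "cost": r.cost,
            "score": r.score,
            "rank": r.rank if r.rank is not None else "",
            "rank_lo": lo if lo is not None else "",
            "rank_hi": hi if hi is not None else "",
            "band": r.band if r.band is not None else "",
        })
    write_csv(pd.DataFrame(rows, columns=_RESULT_COLUMNS), path)


def read_results(path: "str | Path") -> list[PriorityRecord]:
    df = pd.read_csv(path)
    records = []
    for _, row in df.iterrows():
        def opt_int(name: str) -> int | None:
            v = row.get(name)
            return None if v is None or pd.isna(v) else int(v)

        lo, hi = opt_int("rank_lo"), opt_int("rank_hi")
        records.append(
            PriorityRecord(
                project_id=str(row["project_id"]),
                benefit=float(row["benefit"]),
                likelihood=float(row["likelihood"]),
                cost=float(row["cost"]),
                score=float(row["score"]),
                rank=opt_int("rank"),
                rank_interval=(lo, hi) if lo is not None and hi is not None else None,
                band=opt_int("band"),
            )
        )
    return records


def run_metadata(config: SimulationConfig | None = None, **extra: object) -> str:
    """JSON run-metadata blob (config echo + library versions)."""
    import numpy
    import scipy

    meta: dict[str, object] = {
        "versions": {
            "numpy": numpy.__version__,
            "pandas": pd.__version__,
            "scipy": scipy.__version__,
        },
    }
    if config is not None:
        cfg = dataclasses.asdict(config)
        cfg["confidence_half_widths"] = {
            g.value: w for g, w in config.confidence_half_widths.items()
        }
        meta["config"] = cfg
    meta.update(extra)
    return json.dumps(meta, indent=2, default=str)
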