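"""Threshold-based triage: allocate patients to hospital or video consultation.

A triage rule is a disjunction of per-item threshold criteria grouped under
two clinical criteria — "moderate or severe pain" and "using 2 crutches".
A patient whose 3-month responses cross *any* threshold is allocated to a
hospital consultation (the clinically conservative side); a patient observed
on at least one rule item who crosses none goes to video consultation.
Patients with every rule item missing are unallocatable and handled by an
explicit operational default.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
from scipy import stats

from .cohort_stats import percent_exact
from .instruments import (
    Cohort,
    Direction,
    Instrument,
    ItemDefinition,
    ItemKey,
    PatientRecord,
    ScoreRangeError,
    Timepoint,
    standard_items,
)

__all__ = [
    "Comparator",
    "CriterionGroup",
    "Allocation",
    "ThresholdCriterion",
    "TriageRule",
    "TriageOutcome",
    "AllocationSummary",
    "RateComparison",
    "item_crossed",
    "triage_patient",
    "triage_cohort",
    "compare_rates",
    "load_rule",
    "save_rule",
    "packaged_rule_names",
]


class Comparator(str, enum.Enum):
    GE = ">="
    LE = "<="


class CriterionGroup(str, enum.Enum):
    PAIN = "PAIN"
    CRUTCHES = "CRUTCHES"


class Allocation(str, enum.Enum):
    HOSPITAL = "HOSPITAL"
    VIDEO = "VIDEO"
    UNALLOCATABLE = "UNALLOCATABLE"


class TriagePolicy(str, enum.Enum):
    ANY_CROSSED = "ANY_CROSSED"


@dataclass(frozen=True)
class ThresholdCriterion:
    """One per-item threshold, phrased on the item's worse side."""

    item: ItemDefinition
    comparator: Comparator
    cutoff: int
    group: CriterionGroup

    def __post_init__(self) -> None:
        self.item.check(self.cutoff)
        worse_side = (Comparator.GE if self.item.direction is Direction.HIGHER_WORSE
                      else Comparator.LE)
        if self.comparator is not worse_side:
            raise ValueError(
                f"{self.item.item_id}: comparator {self.comparator.value} does "
                f"not point to the item's worse side"
            )

    def crosses(self, value: float) -> bool:
        if self.comparator is Comparator.GE:
            return value >= self.cutoff
        return value <= self.cutoff


@dataclass
class TriageRule:
    name: str
    criteria: tuple[ThresholdCriterion, ...]
    policy: TriagePolicy = TriagePolicy.ANY_CROSSED
    unallocatable_default: Allocation = Allocation.HOSPITAL

    def __post_init__(self) -> None:
        self.criteria = tuple(self.criteria)
        if not self.criteria:
            raise ValueError("a triage rule needs at least one criterion")
        keys = [c.item.key for c in self.criteria]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate items in triage rule")
        if self.unallocatable_default is Allocation.UNALLOCATABLE:
            raise ValueError("unallocatable_default must be HOSPITAL or VIDEO")

    @property
    def item_keys(self) -> list[ItemKey]:
        return [c.item.key for c in self.criteria]

    def without(self, item_id: str) -> "TriageRule":
        """A copy of the rule with one criterion removed."""
        kept = tuple(c for c in self.criteria if c.item.item_id != item_id)
        return TriageRule(f"{self.name}-{item_id}", kept, self.policy,
                          self.unallocatable_default)


def item_crossed(value: int | None, c: ThresholdCriterion) -> tuple[bool, bool]:
    """(crossed, missing) for one observed or absent item value."""
    if value is None:
        return False, True
    c.item.check(value)
    return c.crosses(value), False


@dataclass
class TriageOutcome:
    patient_id: str
    allocation: Allocation
    triggered: list[ThresholdCriterion] = field(default_factory=list)
    missing_items: list[ItemDefinition] = field(default_factory=list)


def triage_patient(record: PatientRecord, rule: TriageRule,
                   t: Timepoint) -> TriageOutcome:
    """Evaluate the rule's disjunction on one patient at one timepoint."""
    triggered: list[ThresholdCriterion] = []
    missing: list[ItemDefinition] = []
    n_observed = 0
    for c in rule.criteria:
        value = record.get(c.item.instrument, c.item.item_index, t)
        crossed, is_missing = item_crossed(value, c)
        if is_missing:
            missing.append(c.item)
        else:
            n_observed += 1
        if crossed:
            triggered.append(c)
    if n_observed == 0:
        return TriageOutcome(record.patient_id, Allocation.UNALLOCATABLE,
                             [], missing)
    allocation = Allocation.HOSPITAL if triggered else Allocation.VIDEO
    return TriageOutcome(record.patient_id, allocation, triggered, missing)


@dataclass
class AllocationSummary:
    """Counts of a cohort's triage outcomes.

    ``hospital_proportion`` is computed over allocated patients only;
    unallocatable patients are reported separately (operationally they are
    routed by the rule's ``unallocatable_default``, but they never enter the
    proportion).
    """

    n_allocated: int
    n_hospital: int
    n_video: int
    n_unallocatable: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.n_hospital + self.n_video != self.n_allocated:
            raise ValueError("n_hospital + n_video must equal n_allocated")

    @property
    def hospital_proportion(self) -> float:
        return self.n_hospital / self.n_allocated

    @property
    def hospital_percent(self) -> float:
        """One-decimal percentage, ties away from zero."""
        return percent_exact(self.n_hospital, self.n_allocated)


def triage_cohort(
    cohort: Cohort,
    rule: TriageRule,
    t: Timepoint,
) -> tuple[AllocationSummary, list[TriageOutcome]]:
    """Triage every respondent at ``t``; returns summary and outcomes.

    Only patients with a returned questionnaire at ``t`` are evaluated;
    among those, patients with at least one observed rule item are allocated.
    """
    if not cohort.records:
        raise ValueError("cannot triage an empty cohort")
    outcomes = [triage_patient(r, rule, t)
                for r in cohort.records if r.has_returned(t)]
    n_hospital = sum(o.allocation is Allocation.HOSPITAL for o in outcomes)
    n_video = sum(o.allocation is Allocation.VIDEO for o in outcomes)
    n_unalloc = sum(o.allocation is Allocation.UNALLOCATABLE for o in outcomes)
    if n_hospital + n_video == 0:
        raise ValueError(f"no allocatable patients at {t.value}")
    label = cohort.label.value if cohort.label else ""
    summary = AllocationSummary(n_hospital + n_video, n_hospital, n_video,
                                n_unalloc, label)
    return summary, outcomes


@dataclass
class RateComparison:
    """Hospital-vs-video 2x2 comparison between two cohorts."""

    table: np.ndarray
    method: str  # "CHI_SQUARE" | "FISHER"
    statistic: float
    p_value: float
    statistic_uncorrected: float = float("nan")
    p_uncorrected: float = float("nan")
    statistic_corrected: float = float("nan")
    p_corrected: float = float("nan")
    expected: np.ndarray | None = None


def compare_rates(a: AllocationSummary, b: AllocationSummary,
                  variant: str = "both") -> RateComparison:
    """Compare two allocation summaries on the hospital/video 2x2 table.

    Pearson's chi-square is used unless any expected cell count is below 5 or
    a margin is zero, in which case Fisher's exact test applies.  For the
    chi-square, both the uncorrected and the continuity-corrected (Yates)
    statistic are computed; the headline ``p_value`` is the corrected one
    (``variant="uncorrected"`` flips the headline).
    """
    if a.n_allocated == 0 or b.n_allocated == 0:
        raise ValueError("both summaries need allocated patients")
    table = np.array([[a.n_hospital, a.n_video],
                      [b.n_hospital, b.n_video]], dtype=float)
    zero_margin = (table.sum(axis=0) == 0).any()
    expected = None
    if not zero_margin:
        rows = table.sum(axis=1, keepdims=True)
        cols = table.sum(axis=0, keepdims=True)
        expected = rows * cols / table.sum()
    if zero_margin or (expected < 5).any():
        odds, p = stats.fisher_exact(table.astype(int))
        return RateComparison(table, "FISHER", float(odds), float(p),
                              expected=expected)
    chi2_u, p_u, _, _ = stats.chi2_contingency(table, correction=False)
    chi2_c, p_c, _, _ = stats.chi2_contingency(table, correction=True)
    headline = (chi2_u, p_u) if variant == "uncorrected" else (chi2_c, p_c)
    return RateComparison(table, "CHI_SQUARE", float(headline[0]),
                          float(headline[1]), float(chi2_u), float(p_u),
                          float(chi2_c), float(p_c), expected)


# ---------------------------------------------------------------------------
# Rule (de)serialisation


def _criterion_from_dict(d: dict, defs: dict[ItemKey, ItemDefinition]
                         ) -> ThresholdCriterion:
    key = (Instrument(d["instrument"]), int(d["item"]))
    if key not in defs:
        raise KeyError(f"unknown item {d['instrument']} #{d['item']}")
    return ThresholdCriterion(defs[key], Comparator(d["comparator"]),
                              int(d["cutoff"]), CriterionGroup(d["group"]))


def load_rule(name_or_path: str | Path,
              defs: dict[ItemKey, ItemDefinition] | None = None) -> TriageRule:
    """Load a rule from a packaged name (``candidate_9item``, ``final_6item``)
    or a JSON file path."""
    if defs is None:
        defs = standard_items()
    p = Path(name_or_path)
    if p.suffix == ".json" and p.exists():
        payload = json.loads(p.read_text(encoding="utf-8"))
    else:
        ref = resources.files("promtriage").joinpath(f"rules/{name_or_path}.json")
        try:
            payload = json.loads(ref.read_text(encoding="utf-8"))
        except FileNotFoundError as exc:
            raise FileNotFoundError(
                f"no packaged rule or file named {name_or_path!r}; packaged "
                f"rules: {', '.join(packaged_rule_names())}") from exc
    criteria = tuple(_criterion_from_dict(d, defs) for d in payload["criteria"])
    default = Allocation(payload.get("unallocatable_default", "HOSPITAL"))
    return TriageRule(payload["name"], criteria,
                      TriagePolicy(payload.get("policy", "ANY_CROSSED")), default)


def save_rule(rule: TriageRule, path: str | Path) -> None:
    payload = {
        "name": rule.name,
        "policy": rule.policy.value,
        "unallocatable_default": rule.unallocatable_default.value,
        "criteria": [
            {"instrument": c.item.instrument.value, "item": c.item.item_index,
             "comparator": c.comparator.value, "cutoff": c.cutoff,
             "group": c.group.value}
            for c in rule.criteria
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")


def packaged_rule_names() -> list[str]:
    folder = resources.files("promtriage").joinpath("rules")
    return sorted(f.name[:-5] for f in folder.iterdir() if f.name.endswith(".json"))
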