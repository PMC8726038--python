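"""PROM instruments: item definitions, patient records, scoring, and recoding.

The package models the questionnaire set routinely collected around total hip
arthroplasty (THA): two numeric rating scales (NRS) for pain at rest and during
activity, the EQ-5D-3L descriptive system plus EQ VAS, the Oxford Hip Score
(OHS), the HOOS Physical-function Shortform (HOOS-PS), and a 7-point anchor
question on functional improvement.  Items differ in direction: for NRS,
EQ-5D-3L dimensions, and the HOOS-PS total a *higher* score is worse, while for
OHS, EQ VAS, and the anchor a higher score is better.
:func:`recode_common_direction` reflects higher-worse items onto the
higher-better convention so that multi-item analyses (e.g. internal
consistency) operate on a common direction.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field


class Instrument(str, enum.Enum):
    NRS_REST = "NRS_REST"
    NRS_ACTIVITY = "NRS_ACTIVITY"
    EQ5D3L = "EQ5D3L"
    EQVAS = "EQVAS"
    OHS = "OHS"
    HOOSPS = "HOOSPS"
    ANCHOR = "ANCHOR"


class Direction(enum.Enum):
    HIGHER_WORSE = "HIGHER_WORSE"
    HIGHER_BETTER = "HIGHER_BETTER"


class Timepoint(str, enum.Enum):
    PRE = "PRE"
    M3 = "M3"
    M12 = "M12"


class CohortLabel(str, enum.Enum):
    TRAINING = "TRAINING"
    TEST = "TEST"


class ASA(str, enum.Enum):
    I = "I"
    II = "II"
    III = "III"
    IV = "IV"


class Charnley(str, enum.Enum):
    ONE_HIP = "ONE_HIP"
    BOTH_HIPS = "BOTH_HIPS"
    CONTRALATERAL_THA = "CONTRALATERAL_THA"
    MULTI_JOINT = "MULTI_JOINT"


#: (instrument, item_index); item_index is 1-based within multi-item
#: instruments and 0 for single-question instruments.
ItemKey = tuple[Instrument, int]

ResponseKey = tuple[Instrument, int, Timepoint]


class ScoreRangeError(ValueError):
    """A score lies outside its item's defined range."""


@dataclass(frozen=True)
class ItemDefinition:
    """One PROM question: its instrument, range, and direction."""

    instrument: Instrument
    item_index: int
    min_score: int
    max_score: int
    direction: Direction
    label: str = ""

    def __post_init__(self) -> None:
        if self.min_score >= self.max_score:
            raise ValueError(
                f"{self.instrument.value} item {self.item_index}: "
                f"min_score must be < max_score"
            )

    @property
    def key(self) -> ItemKey:
        return (self.instrument, self.item_index)

    @property
    def item_id(self) -> str:
        """Readable identifier, e.g. ``OHS_Q10`` or ``NRS_ACTIVITY``."""
        if self.item_index == 0:
            return self.instrument.value
        return f"{self.instrument.value}_Q{self.item_index}"

    @property
    def worst_score(self) -> int:
        return self.max_score if self.direction is Direction.HIGHER_WORSE else self.min_score

    @property
    def best_score(self) -> int:
        return self.min_score if self.direction is Direction.HIGHER_WORSE else self.max_score

    @property
    def n_categories(self) -> int:
        return self.max_score - self.min_score + 1

    def check(self, value: int) -> None:
        if not (self.min_score <= value <= self.max_score):
            raise ScoreRangeError(
                f"{self.item_id}: score {value} outside range "
                f"[{self.min_score}, {self.max_score}]"
            )


def standard_items() -> dict[ItemKey, ItemDefinition]:
    """The full study item set with their canonical ranges and directions."""
    items: list[ItemDefinition] = [
        ItemDefinition(Instrument.NRS_REST, 0, 0, 10, Direction.HIGHER_WORSE,
                       "NRS pain at rest"),
        ItemDefinition(Instrument.NRS_ACTIVITY, 0, 0, 10, Direction.HIGHER_WORSE,
                       "NRS pain during activity"),
        ItemDefinition(Instrument.EQVAS, 0, 0, 100, Direction.HIGHER_BETTER,
                       "EQ VAS self-rated health"),
        ItemDefinition(Instrument.ANCHOR, 0, 1, 7, Direction.HIGHER_BETTER,
                       "Anchor: functional improvement"),
    ]
    eq_labels = ["Mobility", "Self-care", "Usual activities",
                 "Pain/discomfort", "Anxiety/depression"]
    for i, lab in enumerate(eq_labels, start=1):
        items.append(ItemDefinition(Instrument.EQ5D3L, i, 1, 3,
                                    Direction.HIGHER_WORSE, f"EQ-5D-3L {lab}"))
    for i in range(1, 13):
        items.append(ItemDefinition(Instrument.OHS, i, 0, 4,
                                    Direction.HIGHER_BETTER, f"OHS question {i}"))
    for i in range(1, 6):
        items.append(ItemDefinition(Instrument.HOOSPS, i, 0, 4,
                                    Direction.HIGHER_WORSE, f"HOOS-PS item {i}"))
    return {d.key: d for d in items}


def cohort_label_for_year(year: int) -> CohortLabel:
    """Surgery-year split: 2016–2017 train the item selection, 2018 tests it."""
    if year in (2016, 2017):
        return CohortLabel.TRAINING
    if year == 2018:
        return CohortLabel.TEST
    raise ValueError(f"surgery year {year} outside the study window 2016-2018")


@dataclass
class PatientRecord:
    """One patient's characteristics and ordinal responses per timepoint."""

    patient_id: str
    surgery_year: int
    cohort_label: CohortLabel
    age_years: float
    gender: str  # "M" | "F"
    bmi_kg_m2: float
    asa: ASA
    charnley: Charnley
    deceased: bool = False
    returned: dict[Timepoint, bool] = field(default_factory=dict)
    responses: dict[ResponseKey, int] = field(default_factory=dict)

    def get(self, instrument: Instrument, item_index: int, t: Timepoint) -> int | None:
        return self.responses.get((instrument, item_index, t))

    def set(self, instrument: Instrument, item_index: int, t: Timepoint,
            value: int) -> None:
        self.responses[(instrument, item_index, t)] = int(value)

    def has_returned(self, t: Timepoint) -> bool:
        return bool(self.returned.get(t, False))


@dataclass(frozen=True)
class Violation:
    """One broken invariant, naming patient, item, timepoint, and rule."""

    patient_id: str
    rule: str
    message: str
    instrument: Instrument | None = None
    item_index: int | None = None
    timepoint: Timepoint | None = None


def validate_record(
    record: PatientRecord,
    defs: dict[ItemKey, ItemDefinition] | None = None,
) -> list[Violation]:
    """Report every invariant violation in ``record``; never raises.

    Checks that each stored score has a known item definition and lies within
    its range, and that no responses exist at a timepoint whose ``returned``
    flag is false.
    """
    if defs is None:
        defs = standard_items()
    violations: list[Violation] = []
    for (instrument, idx, t), value in record.responses.items():
        d = defs.get((instrument, idx))
        if d is None:
            violations.append(Violation(
                record.patient_id, "unknown item",
                f"no definition for {instrument.value} item {idx}",
                instrument, idx, t))
            continue
        if not (d.min_score <= value <= d.max_score):
            violations.append(Violation(
                record.patient_id, "score out of range",
                f"{d.item_id} at {t.value}: score {value} outside "
                f"[{d.min_score}, {d.max_score}]",
                instrument, idx, t))
        if not record.returned.get(t, False):
            violations.append(Violation(
                record.patient_id, "response without returned questionnaire",
                f"response for {d.item_id} at {t.value} but returned[{t.value}] "
                "is false",
                instrument, idx, t))
    return violations


@dataclass
class Cohort:
    """A labelled collection of patient records.

    ``n_thas`` may exceed the number of records when operations without a
    consenting record contribute to the response-rate denominator.
    """

    label: CohortLabel | None
    records: list[PatientRecord]
    n_thas: int = 0

    def __post_init__(self) -> None:
        if self.n_thas == 0:
            self.n_thas = len(self.records)
        if self.n_thas < len(self.records):
            raise ValueError("n_thas cannot be smaller than the number of records")
        ids = [r.patient_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate patient_id in cohort")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def n_deceased(self) -> int:
        return sum(r.deceased for r in self.records)

    def n_returned(self, t: Timepoint) -> int:
        return sum(r.has_returned(t) for r in self.records)


def score_ohs_total(
    record: PatientRecord,
    t: Timepoint,
    *,
    impute_missing: bool = False,
    max_missing: int = 2,
) -> int | None:
    """Oxford Hip Score total, 0 (most severe) to 48 (least symptoms).

    Complete-case by default: the total is absent if any of the 12 items is
    absent.  With ``impute_missing``, up to ``max_missing`` absent items are
    replaced by the mean of the answered items (the instrument's official
    rescue rule) and the total is rounded to the nearest integer.
    """
    values = [record.get(Instrument.OHS, i, t) for i in range(1, 13)]
    present = [v for v in values if v is not None]
    n_missing = 12 - len(present)
    if n_missing == 0:
        return sum(present)
    if impute_missing and 0 < n_missing <= max_missing and present:
        total = sum(present) * 12 / len(present)
        return int(total + 0.5)  # scores are nonnegative
    return None


def score_hoos_ps(
    record: PatientRecord,
    t: Timepoint,
    *,
    item_max: int = 4,
) -> float | None:
    """HOOS-PS summary, 0 (no difficulty) to 100 (extreme difficulty).

    Linear rescaling of the five-item sum; absent unless all five items are
    present.  ``item_max`` accommodates variant item scalings.
    """
    values = [record.get(Instrument.HOOSPS, i, t) for i in range(1, 6)]
    if any(v is None for v in values):
        return None
    return 100.0 * sum(values) / (5 * item_max)


def recode_common_direction(d: ItemDefinition, value: int) -> int:
    """Reflect higher-worse items so that higher always means better.

    Higher-worse values map to ``min + max - value`` (an involution on the
    item's range); higher-better values pass through unchanged.
    """
    d.check(value)
    if d.direction is Direction.HIGHER_WORSE:
        return d.min_score + d.max_score - value
    return value
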