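"""Screening and program-entry instruments.

The screening questionnaire collects demographics, smoking status, weekly
physical activity, three alcohol items and mobile-phone ownership; the
program-entry (baseline) assessment adds alcohol-related problems, the
motivation to reduce drinking, and the typical drinking day and time used
to schedule drinking-day SMS messages.

The three alcohol items are:

1. frequency of risky single-occasion drinking (RSOD) occasions in the last
   30 days, on an 8-level ordinal scale (``never`` .. ``>12``);
2. a 7-day typical-week drinking calendar (standard drinks per weekday),
   in the style of the Daily Drinking Questionnaire;
3. the maximum number of drinks consumed on a single occasion.

All categorical answers are stored as canonical lowercase tokens; file
readers can map localized labels through a user-supplied dictionary.
"""

from __future__ import annotations

import datetime
import json
import warnings
from dataclasses import dataclass, field, asdict
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

__all__ = [
    "GENDERS",
    "EDUCATION_LEVELS",
    "MIGRATION_LEVELS",
    "SMOKING_ITEMS",
    "RSOD_CATEGORIES",
    "IMPORTANCE_LEVELS",
    "READ_LEVELS",
    "VOLUME_PREFS",
    "EVALUATION_ITEMS",
    "WEEKDAYS",
    "N_PROBLEM_ITEMS",
    "PROBLEM_CATEGORIES",
    "RsodBand",
    "Violation",
    "ScreeningRecord",
    "ProgramBaseline",
    "FollowUpRecord",
    "validate_screening",
    "derive_smoker",
    "weekly_drinks_total",
    "map_rsod_band",
    "any_problem",
    "read_screening_csv",
    "write_screening_csv",
    "read_followup_csv",
    "write_followup_csv",
    "record_to_json",
    "record_from_json",
]

GENDERS = ("male", "female")
EDUCATION_LEVELS = ("none", "secondary", "extended_secondary", "technical_or_high")
MIGRATION_LEVELS = ("none", "one_parent", "both_parents")
SMOKING_ITEMS = ("daily", "occasional", "former", "never")
#: The 8 printed response categories of the RSOD-frequency item.
RSOD_CATEGORIES = ("never", "1-2", "3-4", "5-6", "7-8", "9-10", "11-12", ">12")
IMPORTANCE_LEVELS = (
    "very_unimportant",
    "rather_unimportant",
    "rather_important",
    "very_important",
)
READ_LEVELS = ("thorough", "short_look", "not_read")
VOLUME_PREFS = ("ok", "fewer", "more")
#: Follow-up evaluation items ("rather_yes" / "rather_no"), three about the
#: online feedback and three about the SMS messages.
EVALUATION_ITEMS = (
    "feedback_comprehensible",
    "feedback_interesting",
    "feedback_tailored",
    "sms_comprehensible",
    "sms_helpful",
    "sms_tailored",
)
WEEKDAYS = ("monday", "tuesday", "wednesday", "thursday", "friday", "saturday", "sunday")

N_PROBLEM_ITEMS = 10
#: Default grouping of the 10 positional problem items (p01..p10) into the
#: 4 instrument categories. The individual item texts are not modelled;
#: the grouping is configurable wherever it is consumed.
PROBLEM_CATEGORIES: Mapping[str, tuple[int, ...]] = {
    "individual": (0, 1, 2),
    "relational": (3, 4, 5),
    "sexual": (6, 7),
    "delinquency": (8, 9),
}

CALENDAR_COLUMNS = ("mon", "tue", "wed", "thu", "fri", "sat", "sun")
PROBLEM_COLUMNS = tuple(f"p{i + 1:02d}" for i in range(N_PROBLEM_ITEMS))


class RsodBand(Enum):
    """Coarse RSOD-frequency band used by the risk classification."""

    NONE = 0
    ONE_TO_TWO = 1
    MORE_THAN_TWO = 2

    def __lt__(self, other: "RsodBand") -> bool:
        return self.value < other.value


@dataclass(frozen=True)
class Violation:
    """One validation failure: which field broke which rule."""

    field: str
    rule: str
    message: str = ""


@dataclass(frozen=True)
class ScreeningRecord:
    person_id: str
    class_id: str
    gender: str
    age_years: int
    education: str
    migration: str
    smoking_item: str
    activity_hours_week: float
    rsod_category: str
    drinking_calendar: tuple[int, ...]
    max_drinks_occasion: int
    owns_mobile: bool

    def __post_init__(self) -> None:
        object.__setattr__(self, "drinking_calendar", tuple(self.drinking_calendar))
        if not 15 <= self.age_years <= 25:
            warnings.warn(
                f"age {self.age_years} outside the expected 15-25 range "
                f"for person {self.person_id}",
                stacklevel=3,
            )


@dataclass(frozen=True)
class ProgramBaseline:
    """Program-entry record: screening answers plus program-only items."""

    screening: ScreeningRecord
    problems: tuple[bool, ...]
    importance_reduce: str
    typical_drinking_day: str
    typical_drinking_time: datetime.time

    def __post_init__(self) -> None:
        object.__setattr__(self, "problems", tuple(self.problems))
        if len(self.problems) != N_PROBLEM_ITEMS:
            raise ValueError(
                f"problems must have exactly {N_PROBLEM_ITEMS} items, "
                f"got {len(self.problems)}"
            )
        if self.importance_reduce not in IMPORTANCE_LEVELS:
            raise ValueError(f"unknown importance level {self.importance_reduce!r}")
        if self.typical_drinking_day not in WEEKDAYS:
            raise ValueError(f"unknown weekday {self.typical_drinking_day!r}")


@dataclass(frozen=True)
class FollowUpRecord:
    """Follow-up answers; every item is individually optional (None = missing)."""

    person_id: str
    rsod_category: Optional[str] = None
    drinking_calendar: Optional[tuple[int, ...]] = None
    max_drinks_occasion: Optional[int] = None
    problems: Optional[tuple[Optional[bool], ...]] = None
    received_regularly: Optional[bool] = None
    read_level: Optional[str] = None
    timing_ok: Optional[bool] = None
    volume_pref: Optional[str] = None
    evaluations: Mapping[str, Optional[bool]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.drinking_calendar is not None:
            object.__setattr__(self, "drinking_calendar", tuple(self.drinking_calendar))
        if self.problems is not None:
            object.__setattr__(self, "problems", tuple(self.problems))
        if self.read_level is not None and self.read_level not in READ_LEVELS:
            raise ValueError(f"unknown read level {self.read_level!r}")
        if self.volume_pref is not None and self.volume_pref not in VOLUME_PREFS:
            raise ValueError(f"unknown volume preference {self.volume_pref!r}")
        for item in self.evaluations:
            if item not in EVALUATION_ITEMS:
                raise ValueError(f"unknown evaluation item {item!r}")


# ---------------------------------------------------------------------------
# derivations


def validate_screening(record: ScreeningRecord) -> list[Violation]:
    """Check a screening record against the instrument's invariants.

    Violations are data, not exceptions: the empty list means the record is
    well formed and every downstream classification accepts it.
    """
    out: list[Violation] = []
    if record.gender not in GENDERS:
        out.append(Violation("gender", "category", f"unknown gender {record.gender!r}"))
    if record.education not in EDUCATION_LEVELS:
        out.append(
            Violation("education", "category", f"unknown level {record.education!r}")
        )
    if record.migration not in MIGRATION_LEVELS:
        out.append(
            Violation("migration", "category", f"unknown level {record.migration!r}")
        )
    if record.smoking_item not in SMOKING_ITEMS:
        out.append(
            Violation(
                "smoking_item", "category", f"unknown answer {record.smoking_item!r}"
            )
        )
    if record.rsod_category not in RSOD_CATEGORIES:
        out.append(
            Violation(
                "rsod_category",
                "category",
                f"{record.rsod_category!r} is not one of the 8 response categories",
            )
        )
    cal = record.drinking_calendar
    if len(cal) != 7:
        out.append(
            Violation(
                "drinking_calendar", "length", f"expected 7 entries, got {len(cal)}"
            )
        )
    if any((not float(v).is_integer()) or v < 0 for v in cal):
        out.append(
            Violation("drinking_calendar", "non_negative", "entries must be ints >= 0")
        )
    if record.age_years < 15:
        out.append(Violation("age_years", "minimum", "age must be >= 15"))
    if record.activity_hours_week < 0:
        out.append(Violation("activity_hours_week", "non_negative", "hours >= 0"))
    if record.max_drinks_occasion < 0:
        out.append(Violation("max_drinks_occasion", "non_negative", "drinks >= 0"))
    return out


def derive_smoker(smoking_item: str) -> bool:
    """Current daily and occasional smokers count as smokers."""
    if smoking_item not in SMOKING_ITEMS:
        raise ValueError(f"unknown smoking answer {smoking_item!r}")
    return smoking_item in ("daily", "occasional")


def weekly_drinks_total(drinking_calendar: Sequence[int]) -> int:
    """Total standard drinks over the 7-day typical-week calendar."""
    if len(drinking_calendar) != 7:
        raise ValueError(f"calendar must have 7 entries, got {len(drinking_calendar)}")
    if any(v < 0 for v in drinking_calendar):
        raise ValueError("calendar entries must be non-negative")
    return int(sum(drinking_calendar))


def map_rsod_band(rsod_category: str) -> RsodBand:
    """Collapse the 8 RSOD-frequency categories into the 3 risk bands.

    ``never`` -> NONE, ``1-2`` -> ONE_TO_TWO, every category at or above
    ``3-4`` -> MORE_THAN_TWO (more than two occasions in the last 30 days).
    """
    if rsod_category not in RSOD_CATEGORIES:
        raise ValueError(f"unknown RSOD category {rsod_category!r}")
    if rsod_category == "never":
        return RsodBand.NONE
    if rsod_category == "1-2":
        return RsodBand.ONE_TO_TWO
    return RsodBand.MORE_THAN_TWO


def any_problem(problems: Iterable[Optional[bool]]) -> bool:
    """True iff at least one of the 10 problem items is endorsed.

    Missing items (None) count as "no problem", so the outcome is
    conservative under item non-response.
    """
    items = list(problems)
    if len(items) != N_PROBLEM_ITEMS:
        raise ValueError(f"expected {N_PROBLEM_ITEMS} problem items, got {len(items)}")
    return any(bool(v) for v in items if v is not None)


# ---------------------------------------------------------------------------
# file IO


def _map_label(value: str, label_map: Optional[Mapping[str, str]]) -> str:
    token = str(value).strip().lower()
    if label_map and token in label_map:
        return label_map[token]
    return token


def read_screening_csv(
    path, label_map: Optional[Mapping[str, str]] = None
) -> list[ScreeningRecord]:
    """Read screening records, one row per person.

    The calendar occupies columns ``mon..sun`` and booleans are 0/1 or
    true/false. Duplicate person_ids are a load error.
    """
    df = pd.read_csv(path, dtype={"person_id": str, "class_id": str})
    if df["person_id"].duplicated().any():
        dupes = df.loc[df["person_id"].duplicated(), "person_id"].tolist()
        raise ValueError(f"duplicate person_id(s) in {path}: {dupes}")
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        records.append(
            ScreeningRecord(
                person_id=str(d["person_id"]),
                class_id=str(d["class_id"]),
                gender=_map_label(d["gender"], label_map),
                age_years=int(d["age_years"]),
                education=_map_label(d["education"], label_map),
                migration=_map_label(d["migration"], label_map),
                smoking_item=_map_label(d["smoking_item"], label_map),
                activity_hours_week=float(d["activity_hours_week"]),
                rsod_category=_map_label(d["rsod_category"], label_map),
                drinking_calendar=tuple(int(d[c]) for c in CALENDAR_COLUMNS),
                max_drinks_occasion=int(d["max_drinks_occasion"]),
                owns_mobile=_to_bool(d["owns_mobile"]),
            )
        )
    return records


def write_screening_csv(records: Sequence[ScreeningRecord], path) -> None:
    rows = []
    for r in records:
        d = asdict(r)
        cal = d.pop("drinking_calendar")
        d.update(dict(zip(CALENDAR_COLUMNS, cal)))
        rows.append(d)
    cols = [
        "person_id",
        "class_id",
        "gender",
        "age_years",
        "education",
        "migration",
        "smoking_item",
        "activity_hours_week",
        "rsod_category",
        *CALENDAR_COLUMNS,
        "max_drinks_occasion",
        "owns_mobile",
    ]
    pd.DataFrame(rows)[cols].to_csv(path, index=False)


def read_followup_csv(path) -> list[FollowUpRecord]:
    df = pd.read_csv(path, dtype={"person_id": str})
    if df["person_id"].duplicated().any():
        raise ValueError(f"duplicate person_id(s) in {path}")
    out = []
    for row in df.itertuples(index=False):
        d = {k: (None if pd.isna(v) else v) for k, v in row._asdict().items()}
        cal = [d.get(c) for c in CALENDAR_COLUMNS]
        probs = [d.get(c) for c in PROBLEM_COLUMNS]
        out.append(
            FollowUpRecord(
                person_id=str(d["person_id"]),
                rsod_category=d.get("rsod_category"),
                drinking_calendar=(
                    None if any(v is None for v in cal) else tuple(int(v) for v in cal)
                ),
                max_drinks_occasion=(
                    None
                    if d.get("max_drinks_occasion") is None
                    else int(d["max_drinks_occasion"])
                ),
                problems=(
                    None
                    if all(v is None for v in probs)
                    else tuple(None if v is None else _to_bool(v) for v in probs)
                ),
                received_regularly=_opt_bool(d.get("received_regularly")),
                read_level=d.get("read_level"),
                timing_ok=_opt_bool(d.get("timing_ok")),
                volume_pref=d.get("volume_pref"),
                evaluations={
                    item: _opt_bool(d.get(item))
                    for item in EVALUATION_ITEMS
                    if d.get(item) is not None
                },
            )
        )
    return out


def write_followup_csv(records: Sequence[FollowUpRecord], path) -> None:
    rows = []
    for r in records:
        d: dict = {"person_id": r.person_id, "rsod_category": r.rsod_category}
        cal = r.drinking_calendar or (None,) * 7
        d.update(dict(zip(CALENDAR_COLUMNS, cal)))
        d["max_drinks_occasion"] = r.max_drinks_occasion
        probs = r.problems or (None,) * N_PROBLEM_ITEMS
        d.update(dict(zip(PROBLEM_COLUMNS, probs)))
        d["received_regularly"] = r.received_regularly
        d["read_level"] = r.read_level
        d["timing_ok"] = r.timing_ok
        d["volume_pref"] = r.volume_pref
        for item in EVALUATION_ITEMS:
            d[item] = r.evaluations.get(item)
        rows.append(d)
    pd.DataFrame(rows).to_csv(path, index=False)


def record_to_json(record: ScreeningRecord) -> str:
    return json.dumps(asdict(record), sort_keys=True)


def record_from_json(text: str) -> ScreeningRecord:
    d = json.loads(text)
    d["drinking_calendar"] = tuple(d["drinking_calendar"])
    return ScreeningRecord(**d)


def _to_bool(v) -> bool:
    if isinstance(v, str):
        return v.strip().lower() in ("1", "true", "yes", "y")
    return bool(v)


def _opt_bool(v) -> Optional[bool]:
    return None if v is None else _to_bool(v)
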