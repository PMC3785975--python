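"""Three-tier drinking-risk classification.

Two epidemiological indicators of problem drinking drive the rules:

- risky single-occasion drinking (RSOD, "binge drinking"): >= 5 standard
  drinks on one occasion for men, >= 4 for women;
- chronic risky volume: a daily average of >= 30 g pure alcohol for men,
  >= 20 g for women; with the weekly drinking calendar this corresponds to
  >= 18 (men) / >= 12 (women) standard drinks in a typical week at 12 g of
  ethanol per standard drink.

The classification partitions participants into three groups that determine
the SMS message dose and content pools:

- NON_RISK:  no RSOD occasion in the last 30 days and a weekly volume below
  the gender cutoff;
- LOW_RISK:  1-2 RSOD occasions, or no RSOD occasion but weekly volume at
  or above the cutoff;
- HIGH_RISK: more than 2 RSOD occasions in the last 30 days.

High weekly volume never escalates someone with 1-2 RSOD occasions to
HIGH_RISK: the band alone decides the top tier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from functools import total_ordering

import pandas as pd

from alkcheck.assessment import (
    RsodBand,
    ScreeningRecord,
    map_rsod_band,
    weekly_drinks_total,
)

__all__ = [
    "RiskGroup",
    "RiskThresholds",
    "DEFAULT_THRESHOLDS",
    "is_rsod_occasion",
    "classify_risk",
    "classify_record",
    "classify_frame",
    "volume_problem_drinking",
]


@total_ordering
class RiskGroup(Enum):
    NON_RISK = "non_risk"
    LOW_RISK = "low_risk"
    HIGH_RISK = "high_risk"

    @property
    def rank(self) -> int:
        return {"non_risk": 0, "low_risk": 1, "high_risk": 2}[self.value]

    def __lt__(self, other: "RiskGroup") -> bool:
        return self.rank < other.rank


@dataclass(frozen=True)
class RiskThresholds:
    """Gender-specific cutoffs behind the risk rules.

    ``grams_per_standard_drink`` defaults to 12 g ethanol; Swiss standard
    drinks range 10-12 g, so it is configurable.
    """

    rsod_min_drinks: dict = field(default_factory=lambda: {"male": 5, "female": 4})
    weekly_drinks_cutoff: dict = field(
        default_factory=lambda: {"male": 18, "female": 12}
    )
    daily_grams_cutoff: dict = field(default_factory=lambda: {"male": 30, "female": 20})
    grams_per_standard_drink: float = 12.0

    def __post_init__(self) -> None:
        for name in ("rsod_min_drinks", "weekly_drinks_cutoff", "daily_grams_cutoff"):
            pair = getattr(self, name)
            if pair["male"] <= 0 or pair["female"] <= 0:
                raise ValueError(f"{name} must be strictly positive")
            if pair["male"] < pair["female"]:
                raise ValueError(f"{name}: male threshold must be >= female")
        if self.grams_per_standard_drink <= 0:
            raise ValueError("grams_per_standard_drink must be positive")


DEFAULT_THRESHOLDS = RiskThresholds()


def is_rsod_occasion(
    drinks: int, gender: str, thresholds: RiskThresholds = DEFAULT_THRESHOLDS
) -> bool:
    """Whether one occasion's drink count is a risky single occasion."""
    if drinks < 0:
        raise ValueError("drinks must be non-negative")
    return drinks >= thresholds.rsod_min_drinks[gender]


def classify_risk(
    gender: str,
    rsod_band: RsodBand,
    weekly_drinks: int,
    thresholds: RiskThresholds = DEFAULT_THRESHOLDS,
) -> RiskGroup:
    """Assign the risk group from the RSOD band and weekly volume.

    Exhaustive and mutually exclusive over (band, weekly volume):
    MORE_THAN_TWO is always HIGH_RISK; NONE below the weekly cutoff is
    NON_RISK; everything else (1-2 occasions, or NONE at/above the cutoff)
    is LOW_RISK. Cutoff boundary: < 18 (men) / < 12 (women) is NON_RISK,
    the cutoff value itself is LOW_RISK.
    """
    if weekly_drinks < 0:
        raise ValueError("weekly_drinks must be non-negative")
    if rsod_band is RsodBand.MORE_THAN_TWO:
        return RiskGroup.HIGH_RISK
    if (
        rsod_band is RsodBand.NONE
        and weekly_drinks < thresholds.weekly_drinks_cutoff[gender]
    ):
        return RiskGroup.NON_RISK
    return RiskGroup.LOW_RISK


def classify_record(
    record: ScreeningRecord, thresholds: RiskThresholds = DEFAULT_THRESHOLDS
) -> RiskGroup:
    """Classify directly from a screening record."""
    return classify_risk(
        record.gender,
        map_rsod_band(record.rsod_category),
        weekly_drinks_total(record.drinking_calendar),
        thresholds,
    )


def classify_frame(
    df: pd.DataFrame, thresholds: RiskThresholds = DEFAULT_THRESHOLDS
) -> pd.DataFrame:
    """Append a ``risk_group`` column to a screening-records dataframe."""
    cal_cols = ["mon", "tue", "wed", "thu", "fri", "sat", "sun"]
    out = df.copy()
    out["risk_group"] = [
        classify_risk(
            row.gender,
            map_rsod_band(row.rsod_category),
            int(sum(getattr(row, c) for c in cal_cols)),
            thresholds,
        ).value
        for row in df.itertuples(index=False)
    ]
    return out


def volume_problem_drinking(
    gender: str,
    weekly_drinks: int,
    thresholds: RiskThresholds = DEFAULT_THRESHOLDS,
) -> bool:
    """Whether weekly volume reaches the chronic daily-grams indicator.

    Averages the weekly intake over 7 days and compares to the 30 g (men)
    / 20 g (women) daily cutoff.
    """
    if weekly_drinks < 0:
        raise ValueError("weekly_drinks must be non-negative")
    daily_grams = weekly_drinks * thresholds.grams_per_standard_drink / 7.0
    return daily_grams >= thresholds.daily_grams_cutoff[gender]
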