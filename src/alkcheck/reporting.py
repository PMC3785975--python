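"""Participant-flow accounting, program-use summaries and outcome tables.

Percentages are rounded half-up to one decimal, each with the denominator
the study reports them against:

- consent / present students;
- phone ownership / consented;
- registration / phone owners (the eligible);
- follow-up / phone owners (plus per arm: participants / registered and
  nonparticipants / eligible nonparticipants);
- unsubscription / registered.

Outcome tables use per-outcome complete-case denominators (persons with
the outcome observed at both assessments); program-use tables use per-item
denominators (non-missing answers), mirroring item-wise exclusion for
missing or inconsistent data.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Mapping, Optional, Sequence, Set

import numpy as np
import pandas as pd

from alkcheck.assessment import (
    EVALUATION_ITEMS,
    FollowUpRecord,
    ScreeningRecord,
)
from alkcheck.messaging import SmsLog

__all__ = [
    "FlowCounts",
    "round_half_up",
    "pct",
    "participant_flow",
    "outcome_table",
    "program_use_table",
]


def round_half_up(x: float, ndigits: int = 1) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def pct(numerator: int, denominator: int, ndigits: int = 1) -> float:
    """Percentage rounded half-up; 0.0 for an empty denominator."""
    if denominator == 0:
        return 0.0
    return round_half_up(100.0 * numerator / denominator, ndigits)


@dataclass(frozen=True)
class FlowCounts:
    present: int
    consented: int
    phone_owners: int
    registered: int
    unsubscribed: int
    followed_up: int
    followed_up_participants: int
    followed_up_nonparticipants: int
    consent_pct: float
    ownership_pct: float
    registration_pct: float
    followup_pct: float
    followup_participants_pct: float
    followup_nonparticipants_pct: float
    unsubscribed_pct: float

    def __post_init__(self) -> None:
        assert (
            self.present
            >= self.consented
            >= self.phone_owners
            >= self.registered
            >= self.registered - self.unsubscribed
            >= 0
        ), "flow counts must be monotone across stages"
        assert self.followed_up <= self.phone_owners


def participant_flow(
    n_present: int,
    screening: Sequence[ScreeningRecord],
    registered: Set[str],
    log: Optional[SmsLog],
    followed_up: Set[str],
) -> FlowCounts:
    """Stage counts and percentages of the participant flow.

    ``screening`` holds one record per consenting student; ``registered``
    and ``followed_up`` are person-id sets; unsubscriptions come from the
    SMS log. Ids appearing downstream but not upstream are a consistency
    error.
    """
    consented_ids = {r.person_id for r in screening}
    owner_ids = {r.person_id for r in screening if r.owns_mobile}
    if n_present < len(consented_ids):
        raise ValueError("more screening records than students present")
    if not registered <= owner_ids:
        raise ValueError(
            f"registered ids not among phone owners: {sorted(registered - owner_ids)[:5]}"
        )
    if not followed_up <= owner_ids:
        raise ValueError(
            f"followed-up ids not among the eligible: {sorted(followed_up - owner_ids)[:5]}"
        )
    unsub_ids = set(log.unsubscribed_at) if log is not None else set()
    if not unsub_ids <= registered:
        raise ValueError("unsubscribed ids must be registered participants")

    fu_part = followed_up & registered
    fu_nonpart = followed_up - registered
    nonpart = owner_ids - registered
    return FlowCounts(
        present=n_present,
        consented=len(consented_ids),
        phone_owners=len(owner_ids),
        registered=len(registered),
        unsubscribed=len(unsub_ids),
        followed_up=len(followed_up),
        followed_up_participants=len(fu_part),
        followed_up_nonparticipants=len(fu_nonpart),
        consent_pct=pct(len(consented_ids), n_present),
        ownership_pct=pct(len(owner_ids), len(consented_ids)),
        registration_pct=pct(len(registered), len(owner_ids)),
        followup_pct=pct(len(followed_up), len(owner_ids)),
        followup_participants_pct=pct(len(fu_part), len(registered)),
        followup_nonparticipants_pct=pct(len(fu_nonpart), len(nonpart)),
        unsubscribed_pct=pct(len(unsub_ids), len(registered)),
    )


#: outcome name -> reporting kind
OUTCOME_KINDS = {
    "any_rsod": "binary",
    "frequent_rsod": "binary",
    "weekly_drinks": "count",
    "max_drinks": "count",
    "any_problem": "binary",
}


def outcome_table(outcome_data: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Baseline/follow-up summary per outcome on its complete-case set.

    ``outcome_data`` maps the outcome name to a long dataframe
    (person_id, class_id, time, value) holding only persons observed at
    both times. Binary outcomes report n (%) at each time; counts report
    mean (SD) with one decimal.
    """
    rows = []
    for outcome, df in outcome_data.items():
        kind = OUTCOME_KINDS[outcome]
        wide = df.pivot(index="person_id", columns="time", values="value").dropna()
        n = len(wide)
        base, fu = wide[0].to_numpy(), wide[1].to_numpy()
        if kind == "binary":
            b_pos, f_pos = int(base.sum()), int(fu.sum())
            rows.append(
                {
                    "outcome": outcome,
                    "kind": kind,
                    "n": n,
                    "baseline_n": b_pos,
                    "baseline_pct": pct(b_pos, n),
                    "followup_n": f_pos,
                    "followup_pct": pct(f_pos, n),
                    "baseline_label": f"{b_pos}/{n} ({pct(b_pos, n)}%)",
                    "followup_label": f"{f_pos}/{n} ({pct(f_pos, n)}%)",
                }
            )
        else:
            bm, bs = round_half_up(base.mean()), round_half_up(base.std(ddof=1))
            fm, fs = round_half_up(fu.mean()), round_half_up(fu.std(ddof=1))
            rows.append(
                {
                    "outcome": outcome,
                    "kind": kind,
                    "n": n,
                    "baseline_mean": bm,
                    "baseline_sd": bs,
                    "followup_mean": fm,
                    "followup_sd": fs,
                    "baseline_label": f"{bm} (SD {bs})",
                    "followup_label": f"{fm} (SD {fs})",
                }
            )
    return pd.DataFrame(rows)


def program_use_table(followups: Iterable[FollowUpRecord]) -> pd.DataFrame:
    """Program-use and evaluation summary with per-item denominators.

    One row per (item, category): the count of valid answers for the item,
    the category count and its percentage of the valid answers. Items with
    no valid data are emitted with n_valid = 0 and flagged.
    """
    records = list(followups)
    rows = []

    def add(item: str, values, categories):
        valid = [v for v in values if v is not None]
        n_valid = len(valid)
        for cat in categories:
            count = sum(1 for v in valid if v == cat)
            rows.append(
                {
                    "item": item,
                    "category": str(cat),
                    "n_valid": n_valid,
                    "count": count,
                    "pct": pct(count, n_valid),
                    "no_data": n_valid == 0,
                }
            )

    add("received_regularly", [r.received_regularly for r in records], [True, False])
    add(
        "read_level",
        [r.read_level for r in records],
        ["thorough", "short_look", "not_read"],
    )
    add("timing_ok", [r.timing_ok for r in records], [True, False])
    add("volume_pref", [r.volume_pref for r in records], ["ok", "fewer", "more"])
    for item in EVALUATION_ITEMS:
        add(item, [r.evaluations.get(item) for r in records], [True, False])
    return pd.DataFrame(rows)
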