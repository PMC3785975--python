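"""Worked-example datasets reproducing the study's printed summary counts.

These builders construct, in code, datasets whose stage counts, outcome
prevalences and program-use tallies equal the published ones, so the
reporting and estimation pipeline can be exercised end to end and checked
against the printed percentages:

- participant flow: 490 present, 488 consented, 477 phone owners,
  364 registered, 23 unsubscribed, 367 followed up (280 participants,
  87 nonparticipants);
- complete-case outcomes: any RSOD 210/278 -> 188/278; frequent RSOD
  134/278 -> 114/278; any problem 57/280 -> 40/280; weekly drinks n=247
  mean 13.4 (SD 15.3) -> 11.3 (14.0); max drinks n=275 11.3 (10.3) ->
  10.5 (10.3);
- program use: 254/269 received regularly, 124/111/14 of 249 read levels,
  and the six evaluation items.

Individual-level joint distributions beyond these margins are synthetic:
binary pairs maximize baseline/follow-up concordance and count pairs are
comonotone, which leaves every marginal summary and every saturated-model
GEE estimate identical to what any other coupling would give.
"""

from __future__ import annotations

import datetime

import numpy as np
import pandas as pd

from alkcheck.assessment import FollowUpRecord, ScreeningRecord
from alkcheck.cohort_sim import zinb_from_moments, zinb_ppf
from alkcheck.messaging import SmsEvent, SmsLog, apply_incoming
from alkcheck.reporting import round_half_up

__all__ = [
    "N_CLASSES",
    "flow_fixture",
    "outcome_fixture",
    "program_use_fixture",
    "moment_matched_counts",
]

N_CLASSES = 36


def _class_id(i: int) -> str:
    return f"c{i % N_CLASSES:02d}"


def _screening_record(person_id: str, i: int, owns_mobile: bool) -> ScreeningRecord:
    return ScreeningRecord(
        person_id=person_id,
        class_id=_class_id(i),
        gender="male",
        age_years=17,
        education="secondary",
        migration="none",
        smoking_item="never",
        activity_hours_week=2.0,
        rsod_category="never",
        drinking_calendar=(0,) * 7,
        max_drinks_occasion=0,
        owns_mobile=owns_mobile,
    )


def flow_fixture() -> dict:
    """Participant flow with the printed stage counts.

    Returns n_present, the screening records, the registered and
    followed-up id sets and an SMS log with the unsubscribe messages.
    """
    n_present = 490
    n_consented = 488
    n_owners = 477
    n_registered = 364
    n_unsubscribed = 23
    n_fu_participants = 280
    n_fu_nonparticipants = 87

    ids = [f"f{i:04d}" for i in range(n_consented)]
    screening = [
        _screening_record(pid, i, owns_mobile=i < n_owners)
        for i, pid in enumerate(ids)
    ]
    owner_ids = ids[:n_owners]
    registered = set(owner_ids[:n_registered])
    nonparticipant_ids = owner_ids[n_registered:]

    log = SmsLog()
    t0 = datetime.datetime(2012, 9, 1, 12, 0)
    for k, pid in enumerate(owner_ids[:n_unsubscribed]):
        apply_incoming(
            log,
            SmsEvent(t0 + datetime.timedelta(days=7 + k), "in", pid, "STOP"),
        )
    followed_up = set(owner_ids[:n_fu_participants]) | set(
        nonparticipant_ids[:n_fu_nonparticipants]
    )
    return {
        "n_present": n_present,
        "screening": screening,
        "registered": registered,
        "log": log,
        "followed_up": followed_up,
    }


def _paired_binary(n: int, base_pos: int, fu_pos: int, prefix: str) -> pd.DataFrame:
    """Long binary outcome data with the given margins, maximal concordance."""
    both = min(base_pos, fu_pos)
    pairs = (
        [(1.0, 1.0)] * both
        + [(1.0, 0.0)] * (base_pos - both)
        + [(0.0, 1.0)] * (fu_pos - both)
    )
    pairs += [(0.0, 0.0)] * (n - len(pairs))
    rows = []
    for i, (b, f) in enumerate(pairs):
        pid = f"{prefix}{i:04d}"
        rows.append({"person_id": pid, "class_id": _class_id(i), "time": 0, "value": b})
        rows.append({"person_id": pid, "class_id": _class_id(i), "time": 1, "value": f})
    return pd.DataFrame(rows)


def moment_matched_counts(
    n: int, mean: float, sd: float, seed: int = 0
) -> np.ndarray:
    """Integer sample whose mean and SD round (half-up, 1 dp) to the targets.

    Starts from negative-binomial quantiles at the method-of-moments
    parameters, pins the sum, then runs a randomized local search over
    unit transfers between entries (sum-preserving) until the sample SD
    lands in the target's rounding window.
    """
    params = zinb_from_moments(mean, sd, 0.0)
    y = zinb_ppf((np.arange(n) + 0.5) / n, params).astype(int)

    target_sum = int(np.floor(mean * n + 0.5))
    order = np.argsort(np.abs(y - mean))
    j = 0
    while y.sum() != target_sum:
        idx = order[j % n]
        if y.sum() < target_sum:
            y[idx] += 1
        elif y[idx] > 0:
            y[idx] -= 1
        j += 1

    target_s2 = (n - 1) * sd**2 + target_sum**2 / n  # sum of squares target
    rng = np.random.default_rng(seed)
    for _ in range(200_000):
        cur_sd = y.std(ddof=1)
        if (
            round_half_up(y.mean()) == round_half_up(mean)
            and round_half_up(cur_sd) == round_half_up(sd)
        ):
            break
        i, k = rng.integers(0, n, size=2)
        if i == k or y[i] == 0:
            continue
        delta = 2 * (y[k] - y[i]) + 2  # change in sum of squares
        if abs((y**2).sum() + delta - target_s2) < abs((y**2).sum() - target_s2):
            y[i] -= 1
            y[k] += 1
    assert round_half_up(y.mean()) == round_half_up(mean)
    assert round_half_up(y.std(ddof=1)) == round_half_up(sd)
    assert (y >= 0).all()
    return y


def _paired_counts(
    n: int,
    base_mean: float,
    base_sd: float,
    fu_mean: float,
    fu_sd: float,
    prefix: str,
    seed: int,
) -> pd.DataFrame:
    base = np.sort(moment_matched_counts(n, base_mean, base_sd, seed))
    fu = np.sort(moment_matched_counts(n, fu_mean, fu_sd, seed + 1))
    rows = []
    for i in range(n):
        pid = f"{prefix}{i:04d}"
        rows.append(
            {"person_id": pid, "class_id": _class_id(i), "time": 0, "value": float(base[i])}
        )
        rows.append(
            {"person_id": pid, "class_id": _class_id(i), "time": 1, "value": float(fu[i])}
        )
    return pd.DataFrame(rows)


def outcome_fixture() -> dict[str, pd.DataFrame]:
    """Complete-case outcome data with the printed margins, long format."""
    return {
        "any_rsod": _paired_binary(278, 210, 188, "r"),
        "frequent_rsod": _paired_binary(278, 134, 114, "q"),
        "weekly_drinks": _paired_counts(247, 13.4, 15.3, 11.3, 14.0, "w", seed=11),
        "max_drinks": _paired_counts(275, 11.3, 10.3, 10.5, 10.3, "m", seed=13),
        "any_problem": _paired_binary(280, 57, 40, "p"),
    }


def program_use_fixture() -> list[FollowUpRecord]:
    """280 follow-up questionnaires with the printed program-use tallies."""
    n = 280

    def spread(yes: int, no: int):
        vals = [True] * yes + [False] * no
        vals += [None] * (n - len(vals))
        return vals

    def spread3(a: int, b: int, c: int, cats):
        vals = [cats[0]] * a + [cats[1]] * b + [cats[2]] * c
        vals += [None] * (n - len(vals))
        return vals

    received = spread(254, 15)
    read = spread3(124, 111, 14, ("thorough", "short_look", "not_read"))
    timing = spread(196, 64)
    volume = spread3(149, 92, 18, ("ok", "fewer", "more"))
    evals = {
        "feedback_comprehensible": spread(250, 15),
        "feedback_interesting": spread(182, 76),
        "feedback_tailored": spread(127, 130),
        "sms_comprehensible": spread(232, 8),
        "sms_helpful": spread(71, 164),
        "sms_tailored": spread(79, 155),
    }
    return [
        FollowUpRecord(
            person_id=f"u{i:04d}",
            received_regularly=received[i],
            read_level=read[i],
            timing_ok=timing[i],
            volume_pref=volume[i],
            evaluations={
                item: vals[i] for item, vals in evals.items() if vals[i] is not None
            },
        )
        for i in range(n)
    ]
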