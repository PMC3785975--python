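"""Tailored SMS planning, template rendering and log processing.

Every participant receives text messages for 12 weeks. The dose and the
content pool depend on the risk group:

- NON_RISK: one weekly message, categories {1, 2, 3, 4};
- LOW_RISK: one weekly message, categories {1, 2, 3, 5, 6, 7, 8, 9}, plus a
  biweekly message on the individually stated typical drinking day and time;
- HIGH_RISK: one weekly message, categories {1, 2, 3, 5, 6, 7, 8, 9, 10},
  plus the biweekly drinking-day message.

Biweekly is read as every second week (6 messages over 12 weeks), by
default in the odd weeks 1, 3, 5, 7, 9, 11. The drinking-day messages focus
on strategies to reduce drinking; they draw from a small motivational pool
(categories 5 and 9 by default).

Weekly categories rotate in a seeded round-robin without immediate repeats,
so every pool category appears at least once within 12 weeks. Participants
can unsubscribe at any time by texting a stop keyword; the log processor
marks them and cancels all later planned sends.
"""

from __future__ import annotations

import datetime
import json
import random
import string
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
import yaml

from alkcheck.assessment import WEEKDAYS, ProgramBaseline
from alkcheck.risk_engine import RiskGroup

__all__ = [
    "CONTENT_CATEGORIES",
    "CATEGORY_POOLS",
    "DRINKING_DAY_POOL",
    "PlanConfig",
    "Template",
    "TemplateBank",
    "DEFAULT_BANK",
    "PlanEntry",
    "MessagePlan",
    "SmsEvent",
    "SmsLog",
    "RenderError",
    "plan_messages",
    "render_message",
    "apply_incoming",
    "record_outgoing",
    "prune_plan",
    "attrition_rate",
    "load_template_bank",
    "plan_to_frame",
    "read_sms_log_jsonl",
    "write_sms_log_jsonl",
]

#: The ten SMS content categories.
CONTENT_CATEGORIES: Mapping[int, str] = {
    1: "drinking and body weight/fitness",
    2: "resisting peer pressure",
    3: "pros of sensible drinking",
    4: "motivation to maintain sensible drinking",
    5: "motivation for sensible drinking",
    6: "alcohol-related problems",
    7: "maximum number of drinks on a single occasion and related risks",
    8: "risks of binge drinking",
    9: "importance of reducing alcohol consumption",
    10: "local outpatient services for alcohol counseling",
}

#: Weekly-message content pools per risk group. Category 4 (maintaining
#: sensible drinking) is exclusive to NON_RISK; category 10 (counseling
#: services) exclusive to HIGH_RISK.
CATEGORY_POOLS: Mapping[RiskGroup, frozenset[int]] = {
    RiskGroup.NON_RISK: frozenset({1, 2, 3, 4}),
    RiskGroup.LOW_RISK: frozenset({1, 2, 3, 5, 6, 7, 8, 9}),
    RiskGroup.HIGH_RISK: frozenset({1, 2, 3, 5, 6, 7, 8, 9, 10}),
}

#: Motivational categories used for the biweekly drinking-day messages.
DRINKING_DAY_POOL: tuple[int, ...] = (5, 9)

N_WEEKS = 12


@dataclass(frozen=True)
class PlanConfig:
    weekly_weekday: str = "wednesday"
    weekly_time: datetime.time = datetime.time(17, 0)
    biweekly_phase: int = 0  # 0 -> weeks 1,3,5,...; 1 -> weeks 2,4,6,...
    sms_char_limit: int = 480
    stop_keywords: frozenset[str] = frozenset({"stop", "ende", "weg"})


DEFAULT_PLAN_CONFIG = PlanConfig()


@dataclass(frozen=True)
class Template:
    id: str
    category_id: int
    risk_groups: frozenset[RiskGroup]
    text: str


class TemplateBank:
    def __init__(self, templates: Iterable[Template]):
        templates = list(templates)
        self.templates = {t.id: t for t in templates}
        if len(self.templates) != len(templates):
            raise ValueError("duplicate template ids")

    def __getitem__(self, template_id: str) -> Template:
        if template_id not in self.templates:
            raise KeyError(f"unknown template {template_id!r}")
        return self.templates[template_id]

    def for_slot(self, category_id: int, risk_group: RiskGroup) -> list[Template]:
        return sorted(
            (
                t
                for t in self.templates.values()
                if t.category_id == category_id and risk_group in t.risk_groups
            ),
            key=lambda t: t.id,
        )


_ALL = frozenset(RiskGroup)
_DRINKER = frozenset({RiskGroup.LOW_RISK, RiskGroup.HIGH_RISK})

#: Built-in English template bank with the tailoring slots of the original
#: German messages ({name}, {max_drinks}, {bac_permille}, ...).
DEFAULT_BANK = TemplateBank(
    [
        Template(
            "cal-01",
            1,
            _ALL,
            "Hi {name}. Alcohol is rich in calories, slows down the body's "
            "burning of fat and increases your appetite. Drinking regularly "
            "makes you gain weight in the long term.",
        ),
        Template(
            "peer-01",
            2,
            _ALL,
            "Hi {name}. You are not just a follower who drinks to fit in. "
            "Only do what you think is right - that shows strength of "
            "character and can even impress others.",
        ),
        Template(
            "pros-01",
            3,
            _ALL,
            "Hey {name}. Even with a blood alcohol content of only 0.3 "
            "per-mille (1 to 2 beers) you have an increased risk of "
            "accidents. Without alcohol in your blood you are always safer "
            "on the road.",
        ),
        Template(
            "maintain-01",
            4,
            frozenset({RiskGroup.NON_RISK}),
            "Hi {name}. It's great that you keep your drinking sensible. "
            "Keep it up - your body and your wallet thank you!",
        ),
        Template(
            "motivate-01",
            5,
            _DRINKER,
            "Hi {name}. If you drink less alcohol you will feel better and "
            "have more energy the next day. Give it a try this week!",
        ),
        Template(
            "problems-01",
            6,
            _DRINKER,
            "Hello {name}. Alcohol can cause trouble with the people around "
            "you. Keep in mind that you can avoid these problems by "
            "drinking less or no alcohol at all.",
        ),
        Template(
            "maxdrinks-01",
            7,
            _DRINKER,
            "Hey {name}. You recently had {max_drinks} drinks on one "
            "occasion. Your blood alcohol concentration was about "
            "{bac_permille:.1f} per-mille that time. With that amount you "
            "risk unconsciousness and loss of memory. Watch out!",
        ),
        Template(
            "binge-01",
            8,
            _DRINKER,
            "Hi {name}. Heavy drinking occasions are hard on your body: "
            "blackouts, accidents and alcohol poisoning become much more "
            "likely. Pace yourself and drink water in between.",
        ),
        Template(
            "importance-01",
            9,
            _DRINKER,
            "Hi {name}. You would like to drink less alcohol. That's a "
            "smart decision! If you consume less alcohol, you will feel "
            "better and have more energy the next day.",
        ),
        Template(
            "services-01",
            10,
            frozenset({RiskGroup.HIGH_RISK}),
            "Hi {name}. Are you concerned about your own alcohol intake or "
            "that of a friend? Talking to someone about it can help. "
            "{counseling_contact} offers confidential support.",
        ),
    ]
)


@dataclass(frozen=True)
class PlanEntry:
    send_datetime: datetime.datetime
    slot: str  # "weekly" | "drinking_day"
    category_id: int
    template_id: str


@dataclass(frozen=True)
class MessagePlan:
    person_id: str
    risk_group: RiskGroup
    start: datetime.datetime
    entries: tuple[PlanEntry, ...]


@dataclass(frozen=True)
class SmsEvent:
    timestamp: datetime.datetime
    direction: str  # "in" | "out"
    person_id: str
    text: str
    unsubscribe_override: bool = False


@dataclass
class SmsLog:
    """Append-only record of all incoming and outgoing messages."""

    events: list[SmsEvent] = field(default_factory=list)
    unsubscribed_at: dict[str, datetime.datetime] = field(default_factory=dict)

    def last_timestamp(self, person_id: str) -> Optional[datetime.datetime]:
        stamps = [e.timestamp for e in self.events if e.person_id == person_id]
        return max(stamps) if stamps else None


class RenderError(ValueError):
    def __init__(self, placeholder: str):
        self.placeholder = placeholder
        super().__init__(f"missing value for placeholder {placeholder!r}")


def _first_occurrence(
    start: datetime.datetime, weekday: str, time: datetime.time
) -> datetime.datetime:
    """First datetime at/after ``start`` falling on weekday at the given time."""
    target = WEEKDAYS.index(weekday)
    candidate = datetime.datetime.combine(start.date(), time)
    candidate += datetime.timedelta(days=(target - candidate.weekday()) % 7)
    if candidate < start:
        candidate += datetime.timedelta(days=7)
    return candidate


def _category_sequence(pool: Sequence[int], n: int, rng: random.Random) -> list[int]:
    """Seeded round-robin: repeated shuffles of the pool, no immediate repeats."""
    pool = sorted(pool)
    if len(pool) == 1:
        return list(pool) * n
    seq: list[int] = []
    while len(seq) < n:
        block = pool[:]
        rng.shuffle(block)
        if seq and block[0] == seq[-1]:
            j = rng.randrange(1, len(block))
            block[0], block[j] = block[j], block[0]
        seq.extend(block)
    return seq[:n]


def plan_messages(
    risk_group: RiskGroup,
    baseline: ProgramBaseline,
    start_datetime: datetime.datetime,
    rng_seed: int,
    bank: TemplateBank = DEFAULT_BANK,
    config: PlanConfig = DEFAULT_PLAN_CONFIG,
) -> MessagePlan:
    """Build the dated 12-week message plan for one participant.

    Weekly messages go out at the configured fixed weekday/time; LOW/HIGH
    risk participants additionally get 6 biweekly messages on their stated
    typical drinking day and time. Deterministic for a given
    (group, baseline, start, seed).
    """
    rng = random.Random(rng_seed)
    pool = CATEGORY_POOLS[risk_group]
    entries: list[PlanEntry] = []

    first_weekly = _first_occurrence(
        start_datetime, config.weekly_weekday, config.weekly_time
    )
    for week, cat in enumerate(_category_sequence(pool, N_WEEKS, rng)):
        candidates = bank.for_slot(cat, risk_group)
        if not candidates:
            raise ValueError(
                f"no template for category {cat} and group {risk_group.value}"
            )
        entries.append(
            PlanEntry(
                first_weekly + datetime.timedelta(weeks=week),
                "weekly",
                cat,
                rng.choice(candidates).id,
            )
        )

    if risk_group is not RiskGroup.NON_RISK:
        day = baseline.typical_drinking_day
        time = baseline.typical_drinking_time
        if day is None or time is None:
            raise ValueError(
                "typical drinking day/time required for low/high risk plans"
            )
        first_dd = _first_occurrence(start_datetime, day, time)
        dd_weeks = range(config.biweekly_phase, N_WEEKS, 2)
        dd_cats = _category_sequence(DRINKING_DAY_POOL, len(list(dd_weeks)), rng)
        for cat, week in zip(dd_cats, dd_weeks):
            candidates = bank.for_slot(cat, risk_group)
            entries.append(
                PlanEntry(
                    first_dd + datetime.timedelta(weeks=week),
                    "drinking_day",
                    cat,
                    rng.choice(candidates).id,
                )
            )

    entries.sort(key=lambda e: (e.send_datetime, e.slot))
    end = start_datetime + datetime.timedelta(weeks=N_WEEKS)
    assert all(start_datetime <= e.send_datetime < end for e in entries)
    return MessagePlan(
        person_id=baseline.screening.person_id,
        risk_group=risk_group,
        start=start_datetime,
        entries=tuple(entries),
    )


class _StrictFormatter(string.Formatter):
    def get_value(self, key, args, kwargs):
        try:
            return kwargs[key] if isinstance(key, str) else args[key]
        except (KeyError, IndexError):
            raise RenderError(str(key)) from None


def render_message(
    template_id: str,
    tailoring_vars: Mapping[str, object],
    bank: TemplateBank = DEFAULT_BANK,
    char_limit: int = DEFAULT_PLAN_CONFIG.sms_char_limit,
) -> str:
    """Substitute every placeholder of a template; all-or-nothing.

    Raises :class:`RenderError` naming the first missing placeholder, and
    rejects rendered text over the SMS character limit.
    """
    template = bank[template_id]
    text = _StrictFormatter().vformat(template.text, (), dict(tailoring_vars))
    if len(text) > char_limit:
        raise ValueError(
            f"rendered message for {template_id!r} exceeds {char_limit} characters"
        )
    return text


def apply_incoming(
    log: SmsLog,
    event: SmsEvent,
    stop_keywords: frozenset[str] = DEFAULT_PLAN_CONFIG.stop_keywords,
) -> SmsLog:
    """Process one incoming SMS; stop keywords trigger unsubscription.

    Matching is case-insensitive on the stripped text; an explicit
    ``unsubscribe_override`` flag on the event forces unsubscription (manual
    review path for free-text withdrawal requests). A second stop message
    after unsubscription is an idempotent no-op.
    """
    if event.direction != "in":
        raise ValueError("apply_incoming only accepts incoming events")
    last = log.last_timestamp(event.person_id)
    if last is not None and event.timestamp < last:
        raise ValueError(
            f"event for {event.person_id} at {event.timestamp} predates the "
            f"last logged event at {last}"
        )
    is_stop = (
        event.text.strip().lower() in stop_keywords or event.unsubscribe_override
    )
    if is_stop and event.person_id in log.unsubscribed_at:
        return log
    log.events.append(event)
    if is_stop:
        log.unsubscribed_at[event.person_id] = event.timestamp
    return log


def record_outgoing(log: SmsLog, event: SmsEvent) -> SmsLog:
    """Append an outgoing send; refuses sends after unsubscription."""
    if event.direction != "out":
        raise ValueError("record_outgoing only accepts outgoing events")
    cut = log.unsubscribed_at.get(event.person_id)
    if cut is not None and event.timestamp >= cut:
        raise ValueError(
            f"{event.person_id} unsubscribed at {cut}; cannot send at "
            f"{event.timestamp}"
        )
    log.events.append(event)
    return log


def prune_plan(plan: MessagePlan, log: SmsLog) -> MessagePlan:
    """Cancel all planned sends at/after the participant's unsubscription."""
    cut = log.unsubscribed_at.get(plan.person_id)
    if cut is None:
        return plan
    return replace(
        plan, entries=tuple(e for e in plan.entries if e.send_datetime < cut)
    )


def attrition_rate(log: SmsLog, n_participants: int) -> float:
    """Fraction of program participants who unsubscribed."""
    if n_participants <= 0:
        raise ValueError("n_participants must be positive")
    return len(log.unsubscribed_at) / n_participants


# ---------------------------------------------------------------------------
# IO


def load_template_bank(path) -> TemplateBank:
    """Template bank from YAML: list of {id, category_id, risk_groups, text}."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return TemplateBank(
        [
            Template(
                id=t["id"],
                category_id=int(t["category_id"]),
                risk_groups=frozenset(RiskGroup(g) for g in t["risk_groups"]),
                text=t["text"],
            )
            for t in data
        ]
    )


def plan_to_frame(plan: MessagePlan) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "person_id": plan.person_id,
            "risk_group": plan.risk_group.value,
            "send_datetime": [e.send_datetime.isoformat() for e in plan.entries],
            "slot": [e.slot for e in plan.entries],
            "category_id": [e.category_id for e in plan.entries],
            "template_id": [e.template_id for e in plan.entries],
        }
    )


def read_sms_log_jsonl(path) -> SmsLog:
    log = SmsLog()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            d = json.loads(line)
            event = SmsEvent(
                timestamp=datetime.datetime.fromisoformat(d["timestamp"]),
                direction=d["direction"],
                person_id=str(d["person_id"]),
                text=d["text"],
                unsubscribe_override=bool(d.get("unsubscribe_override", False)),
            )
            if event.direction == "in":
                apply_incoming(log, event)
            else:
                record_outgoing(log, event)
    return log


def write_sms_log_jsonl(log: SmsLog, path) -> None:
    with open(path, "w") as fh:
        for e in log.events:
            fh.write(
                json.dumps(
                    {
                        "timestamp": e.timestamp.isoformat(),
                        "direction": e.direction,
                        "person_id": e.person_id,
                        "text": e.text,
                        "unsubscribe_override": e.unsubscribe_override,
                    }
                )
                + "\n"
            )
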