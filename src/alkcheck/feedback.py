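"""One-shot tailored social-norms feedback.

After the online assessment each participant receives a feedback report
tailored on exactly four baseline variables — gender, age, standard drinks
in a typical week, and RSOD frequency in the last 30 days — with four
sections, in this order:

1. drinks per week relative to the age- and gender-specific reference group
   (a percentile against the norm sample);
2. monthly financial cost of drinking;
3. calories consumed with alcoholic drinks per week;
4. number of heavy-drinking (RSOD) occasions relative to the reference group.

Norms come from a reference survey stored as a :class:`NormTable`: per
(gender, age-band) stratum, the reference sample of weekly-drinks values
and of RSOD-frequency categories. A Widmark blood-alcohol estimate is also
provided here because drinking-day SMS messages quote it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Mapping, Optional, Sequence

import yaml

from alkcheck.assessment import (
    RSOD_CATEGORIES,
    ProgramBaseline,
    map_rsod_band,
    weekly_drinks_total,
)

__all__ = [
    "DEFAULT_AGE_BANDS",
    "FeedbackConfig",
    "NormTable",
    "FeedbackReport",
    "percentile_rank",
    "drinking_cost",
    "weekly_calories",
    "estimate_bac_permille",
    "build_feedback",
    "load_norm_table",
    "synthetic_norm_table",
]

#: Default age bands for the norm strata; (21, 200) is the open-ended band.
DEFAULT_AGE_BANDS = ((15, 16), (17, 18), (19, 20), (21, 200))


@dataclass(frozen=True)
class FeedbackConfig:
    """Constants of the feedback computations (all configurable).

    - ``grams_per_drink``: ethanol per standard drink, g (default 12).
    - ``price_per_drink``: currency per standard drink (default 3.50 CHF).
    - ``kcal_per_gram``: energy density of ethanol, 7.1 kcal/g.
    - ``widmark_r``: Widmark distribution factor per gender.
    - ``body_weight_kg``: default body weight per gender used for the BAC
      estimate (the instruments do not collect weight).
    """

    grams_per_drink: float = 12.0
    price_per_drink: float = 3.50
    currency: str = "CHF"
    kcal_per_gram: float = 7.1
    widmark_r: Mapping[str, float] = field(
        default_factory=lambda: {"male": 0.68, "female": 0.55}
    )
    body_weight_kg: Mapping[str, float] = field(
        default_factory=lambda: {"male": 72.0, "female": 60.0}
    )


class NormTable:
    """Reference-group norms per (gender, age-band) stratum.

    Each stratum holds the raw reference sample of weekly-drinks values and
    of RSOD-frequency categories (as indices into the 8-level scale), from
    which percentiles are computed. Lookup uses the band containing the age;
    if the exact stratum is missing, the nearest band (by distance between
    band midpoint and age, ties toward the younger band) for the same gender
    is used as fallback.
    """

    def __init__(
        self,
        strata: Mapping[tuple[str, tuple[int, int]], dict],
        age_bands: Sequence[tuple[int, int]] = DEFAULT_AGE_BANDS,
    ):
        self.age_bands = tuple(tuple(b) for b in age_bands)
        self.strata = {}
        for (gender, band), data in strata.items():
            band = tuple(band)
            weekly = list(data["weekly_drinks"])
            rsod = list(data["rsod_category_index"])
            if not weekly or not rsod:
                raise ValueError(f"empty norm stratum {(gender, band)}")
            if any(not 0 <= i < len(RSOD_CATEGORIES) for i in rsod):
                raise ValueError(f"invalid RSOD category index in {(gender, band)}")
            self.strata[(gender, band)] = {
                "weekly_drinks": weekly,
                "rsod_category_index": rsod,
            }

    def band_for_age(self, age: int) -> tuple[int, int]:
        for lo, hi in self.age_bands:
            if lo <= age <= hi:
                return (lo, hi)
        # below the youngest band -> youngest; above the oldest -> oldest
        if age < self.age_bands[0][0]:
            return self.age_bands[0]
        return self.age_bands[-1]

    def lookup(self, gender: str, age: int) -> dict:
        band = self.band_for_age(age)
        if (gender, band) in self.strata:
            return self.strata[(gender, band)]
        candidates = [b for (g, b) in self.strata if g == gender]
        if not candidates:
            raise LookupError(f"no norm stratum for gender {gender!r}")
        mid = lambda b: (b[0] + min(b[1], b[0] + 4)) / 2.0
        best = min(candidates, key=lambda b: (abs(mid(b) - age), b[0]))
        return self.strata[(gender, best)]


@dataclass(frozen=True)
class FeedbackReport:
    person_id: str
    drinks_week: int
    percentile_vs_norm: float
    monthly_cost: float
    currency: str
    weekly_kcal: float
    rsod_band: str
    rsod_percentile: float
    section_texts: tuple[str, str, str, str]

    def to_json(self) -> str:
        d = {
            "person_id": self.person_id,
            "drinks_week": self.drinks_week,
            "percentile_vs_norm": self.percentile_vs_norm,
            "monthly_cost": self.monthly_cost,
            "currency": self.currency,
            "weekly_kcal": self.weekly_kcal,
            "rsod_band": self.rsod_band,
            "rsod_percentile": self.rsod_percentile,
            "section_texts": list(self.section_texts),
        }
        return json.dumps(d, sort_keys=True)

    def to_text(self) -> str:
        return "\n\n".join(self.section_texts)


def percentile_rank(value: float, reference_sample: Sequence[float]) -> float:
    """Mid-rank percentile of ``value`` within the reference sample.

    100 * (count strictly below + 0.5 * count equal) / n — so a value tied
    with the whole sample sits at 50 and percentiles of distinct sample
    values are evenly spread.
    """
    n = len(reference_sample)
    if n == 0:
        raise ValueError("reference sample must be non-empty")
    below = sum(1 for v in reference_sample if v < value)
    equal = sum(1 for v in reference_sample if v == value)
    return 100.0 * (below + 0.5 * equal) / n


def _round_half_up(x: float, ndigits: int) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def drinking_cost(weekly_drinks: int, price_per_drink: float) -> float:
    """Monthly cost of drinking: weekly drinks x price x 52/12 weeks/month."""
    if weekly_drinks < 0 or price_per_drink < 0:
        raise ValueError("inputs must be non-negative")
    return _round_half_up(weekly_drinks * price_per_drink * 52.0 / 12.0, 2)


def weekly_calories(
    weekly_drinks: int, grams_per_drink: float, kcal_per_gram: float
) -> float:
    """Energy from ethanol in a typical week (mixers not counted)."""
    if min(weekly_drinks, grams_per_drink, kcal_per_gram) < 0:
        raise ValueError("inputs must be non-negative")
    return weekly_drinks * grams_per_drink * kcal_per_gram


def estimate_bac_permille(
    n_drinks: float,
    grams_per_drink: float,
    body_weight_kg: float,
    widmark_r: float,
) -> float:
    """Widmark estimate of blood alcohol concentration, in per-mille (g/kg).

    BAC = ingested ethanol mass / (r x body weight). No elimination term is
    subtracted: the estimate describes the peak of a single occasion.
    """
    if body_weight_kg <= 0 or widmark_r <= 0:
        raise ValueError("body weight and Widmark r must be positive")
    if n_drinks < 0 or grams_per_drink < 0:
        raise ValueError("drinks and grams per drink must be non-negative")
    return (n_drinks * grams_per_drink) / (widmark_r * body_weight_kg)


_SECTION_TEMPLATES = (
    "In a typical week you drink {drinks_week} standard drinks. That is more "
    "than {percentile:.0f}% of {gender_label} your age.",
    "At {price:.2f} {currency} per drink, your drinking costs you about "
    "{monthly_cost:.2f} {currency} per month.",
    "The alcohol you drink in a typical week contains about {kcal:.0f} kcal.",
    "In the last 30 days you had {rsod_label} heavy drinking occasions "
    "(5 or more drinks for men, 4 or more for women). That is more than "
    "{rsod_percentile:.0f}% of {gender_label} your age.",
)

_RSOD_LABELS = {
    "never": "no",
    "1-2": "1-2",
    "3-4": "3-4",
    "5-6": "5-6",
    "7-8": "7-8",
    "9-10": "9-10",
    "11-12": "11-12",
    ">12": "more than 12",
}


def build_feedback(
    baseline: ProgramBaseline,
    norms: NormTable,
    config: FeedbackConfig = FeedbackConfig(),
) -> FeedbackReport:
    """Render the four-section normative feedback report.

    A pure function of (baseline, norms, config); tailoring uses only
    gender, age, weekly drinks and RSOD frequency.
    """
    scr = baseline.screening
    stratum = norms.lookup(scr.gender, scr.age_years)
    drinks_week = weekly_drinks_total(scr.drinking_calendar)
    pct = percentile_rank(drinks_week, stratum["weekly_drinks"])
    cost = drinking_cost(drinks_week, config.price_per_drink)
    kcal = weekly_calories(drinks_week, config.grams_per_drink, config.kcal_per_gram)
    rsod_idx = RSOD_CATEGORIES.index(scr.rsod_category)
    rsod_pct = percentile_rank(rsod_idx, stratum["rsod_category_index"])
    gender_label = {"male": "men", "female": "women"}[scr.gender]
    sections = (
        _SECTION_TEMPLATES[0].format(
            drinks_week=drinks_week, percentile=pct, gender_label=gender_label
        ),
        _SECTION_TEMPLATES[1].format(
            price=config.price_per_drink, currency=config.currency, monthly_cost=cost
        ),
        _SECTION_TEMPLATES[2].format(kcal=kcal),
        _SECTION_TEMPLATES[3].format(
            rsod_label=_RSOD_LABELS[scr.rsod_category],
            rsod_percentile=rsod_pct,
            gender_label=gender_label,
        ),
    )
    return FeedbackReport(
        person_id=scr.person_id,
        drinks_week=drinks_week,
        percentile_vs_norm=pct,
        monthly_cost=cost,
        currency=config.currency,
        weekly_kcal=kcal,
        rsod_band=map_rsod_band(scr.rsod_category).name,
        rsod_percentile=rsod_pct,
        section_texts=sections,
    )


def load_norm_table(path) -> NormTable:
    """Read a norm table from YAML/JSON.

    Expected layout::

        age_bands: [[15, 16], [17, 18], [19, 20], [21, 200]]
        strata:
          - gender: male
            age_band: [17, 18]
            weekly_drinks: [0, 2, 5, ...]
            rsod_category_index: [0, 0, 1, ...]
    """
    with open(path) as fh:
        data = yaml.safe_load(fh)
    age_bands = [tuple(b) for b in data.get("age_bands", DEFAULT_AGE_BANDS)]
    strata = {
        (s["gender"], tuple(s["age_band"])): {
            "weekly_drinks": s["weekly_drinks"],
            "rsod_category_index": s["rsod_category_index"],
        }
        for s in data["strata"]
    }
    return NormTable(strata, age_bands)


def synthetic_norm_table(
    seed: int = 0, n_per_stratum: int = 120, age_bands=DEFAULT_AGE_BANDS
) -> NormTable:
    """A synthetic stand-in for the unpublished reference-survey norms.

    Generates plausible per-stratum reference samples (males drink more than
    females, consumption rises with age) so the feedback pipeline is fully
    exercisable without the original reference data.
    """
    import numpy as np

    rng = np.random.default_rng(seed)
    strata = {}
    for gender in ("male", "female"):
        for bi, band in enumerate(age_bands):
            base = (10.0 if gender == "male" else 6.0) * (1.0 + 0.15 * bi)
            weekly = rng.negative_binomial(1.2, 1.2 / (1.2 + base), n_per_stratum)
            # RSOD frequency: mass concentrated on the low categories
            p_never = 0.40 if gender == "female" else 0.25
            probs = np.array([p_never, 0.28, 0.16, 0.08, 0.04, 0.02, 0.01, 0.01])
            probs[1:] *= (1 - p_never) / probs[1:].sum()
            rsod = rng.choice(8, size=n_per_stratum, p=probs)
            strata[(gender, tuple(band))] = {
                "weekly_drinks": weekly.astype(int).tolist(),
                "rsod_category_index": rsod.astype(int).tolist(),
            }
    return NormTable(strata, age_bands)
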