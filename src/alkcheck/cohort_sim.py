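"""Synthetic cohort generator with pre-post intervention effects.

Emulates the study flow of a school-based program evaluation: students are
present in school classes, nearly all consent to screening, mobile-phone
owners are eligible, a subset registers for the program (more likely with
lower education and higher maximum drinks), a few unsubscribe during the
12 weeks, and roughly three quarters complete the follow-up assessment
(smokers and frequent RSOD students drop out more).

Baseline alcohol measures are generated jointly: a per-class random
intercept plus a person-level drinking propensity feed a Gaussian copula
across the RSOD-frequency category, the weekly-drinks count and the
maximum-drinks count, so the three measures are positively correlated and
students within a class are more alike than students across classes
(the intra-class correlation that motivates the cluster-robust variance).

Weekly drinks follow a zero-inflated negative binomial whose parameters
are solved by method of moments from the target mean/SD; maximum drinks a
negative binomial. Default targets encode the participant profile of the
study cohort (weekly drinks mean 14.1, SD 16.1; max drinks 11.6, SD 10.8;
the 8-category RSOD distribution; demographic marginals).

The pre-post effect is a marginal shift with per-person dependence:

- binary outcomes: the follow-up prevalence implied by the configured odds
  ratio is reached through a stay/redraw transition — with probability
  ``binary_stay_prob`` the baseline value is kept, otherwise the value is
  redrawn with the rate that matches the target marginal;
- count outcomes: a Gaussian copula with correlation ``count_copula_rho``
  links each person's baseline and follow-up counts, the follow-up
  marginal being the baseline family with its mean scaled by the rate
  ratio.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field, asdict
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps
from scipy.special import expit, logit

from alkcheck.assessment import (
    EVALUATION_ITEMS,
    IMPORTANCE_LEVELS,
    N_PROBLEM_ITEMS,
    RSOD_CATEGORIES,
    FollowUpRecord,
    ProgramBaseline,
    ScreeningRecord,
    map_rsod_band,
    weekly_drinks_total,
)

__all__ = [
    "ZinbParams",
    "EffectParams",
    "SimConfig",
    "SimulatedStudy",
    "zinb_from_moments",
    "zinb_ppf",
    "simulate_cohort",
    "apply_effect_binary",
    "apply_effect_counts",
    "apply_effect",
    "long_outcomes",
]


@dataclass(frozen=True)
class ZinbParams:
    """Zero-inflated negative binomial: P(0) extra mass ``pi``, NB(k, mu)."""

    pi: float
    k: float
    mu: float

    @property
    def mean(self) -> float:
        return (1 - self.pi) * self.mu

    @property
    def sd(self) -> float:
        var_nb = self.mu + self.mu**2 / self.k
        second = (1 - self.pi) * (var_nb + self.mu**2)
        return float(np.sqrt(second - self.mean**2))


def zinb_from_moments(mean: float, sd: float, pi: float = 0.0) -> ZinbParams:
    """Solve ZINB parameters from target mean/SD at fixed zero inflation.

    Method of moments: the NB component mean is mean/(1-pi) and its
    variance follows from the target second moment; feasibility requires
    overdispersion (NB variance above its mean) after the split.
    """
    if not 0 <= pi < 1:
        raise ValueError("pi must be in [0, 1)")
    mu = mean / (1 - pi)
    second = sd**2 + mean**2
    var_nb = second / (1 - pi) - mu**2
    if var_nb <= mu:
        raise ValueError(
            f"targets mean={mean}, sd={sd}, pi={pi} need NB variance > mean "
            f"(got {var_nb:.2f} <= {mu:.2f}); lower pi or raise sd"
        )
    k = mu**2 / (var_nb - mu)
    return ZinbParams(pi=pi, k=k, mu=mu)


def zinb_ppf(u: np.ndarray, params: ZinbParams) -> np.ndarray:
    """Quantile function of the ZINB (vectorized over uniforms)."""
    u = np.asarray(u, dtype=float)
    p_nb = params.k / (params.k + params.mu)
    out = np.zeros(u.shape)
    tail = u > params.pi
    out[tail] = sps.nbinom.ppf(
        (u[tail] - params.pi) / (1 - params.pi), params.k, p_nb
    )
    return out


def _zinb_cdf(y: np.ndarray, params: ZinbParams) -> np.ndarray:
    p_nb = params.k / (params.k + params.mu)
    return params.pi + (1 - params.pi) * sps.nbinom.cdf(y, params.k, p_nb)


@dataclass(frozen=True)
class EffectParams:
    """Pre-post effect sizes (odds ratios for binaries, rate ratios for counts)."""

    or_any_rsod: float = 0.66
    or_frequent_rsod: float = 0.76
    rr_weekly_drinks: float = 0.83
    rr_max_drinks: float = 0.91
    or_any_problem: float = 0.60
    binary_stay_prob: float = 0.5
    count_copula_rho: float = 0.5


@dataclass(frozen=True)
class SimConfig:
    """Generator configuration; defaults encode the study-cohort profile."""

    seed: int
    n_present: int = 490
    p_consent: float = 488 / 490
    p_phone: float = 477 / 488
    n_classes: int = 36

    p_female: float = 0.245
    age_band_probs: Mapping[tuple[int, int], float] = field(
        default_factory=lambda: {
            (15, 16): 0.201,
            (17, 18): 0.533,
            (19, 20): 0.198,
            (21, 25): 0.068,
        }
    )
    education_probs: Mapping[str, float] = field(
        default_factory=lambda: {
            "none": 0.049,
            "secondary": 0.824,
            "extended_secondary": 0.108,
            "technical_or_high": 0.019,
        }
    )
    migration_probs: Mapping[str, float] = field(
        default_factory=lambda: {
            "none": 0.508,
            "one_parent": 0.190,
            "both_parents": 0.302,
        }
    )
    p_smoker: float = 0.53
    p_daily_given_smoker: float = 0.66
    p_never_given_nonsmoker: float = 0.75
    activity_mean: float = 4.5
    activity_sd: float = 4.6

    rsod_probs: tuple[float, ...] = (
        0.234,
        0.291,
        0.195,
        0.132,
        0.055,
        0.038,
        0.016,
        0.038,
    )
    weekly_mean: float = 14.1
    weekly_sd: float = 16.1
    weekly_zero_inflation: float = 0.15
    max_mean: float = 11.6
    max_sd: float = 10.8

    class_icc: float = 0.05  # share of drinking-propensity variance between classes
    alcohol_copula_rho: float = 0.6  # loading of each measure on the propensity

    participation_rate: float = 364 / 477
    beta_participation_low_edu: float = 0.5
    beta_participation_max_drinks: float = 0.3  # per SD of max drinks

    unsubscribe_rate: float = 23 / 364

    followup_rate: float = 367 / 477
    beta_dropout_smoker: float = 0.5
    beta_dropout_rsod: float = 0.15  # per RSOD category step

    p_any_problem: float = 0.22
    importance_probs: tuple[float, ...] = (0.451, 0.332, 0.132, 0.085)
    drinking_day_probs: Mapping[str, float] = field(
        default_factory=lambda: {
            "wednesday": 0.05,
            "thursday": 0.10,
            "friday": 0.45,
            "saturday": 0.35,
            "sunday": 0.05,
        }
    )

    effect: EffectParams = field(default_factory=EffectParams)
    #: probability that a followed-up person is missing each outcome item
    outcome_missingness: Mapping[str, float] = field(
        default_factory=lambda: {
            "any_rsod": 0.007,
            "frequent_rsod": 0.007,
            "weekly_drinks": 0.118,
            "max_drinks": 0.018,
            "any_problem": 0.0,
        }
    )
    program_use_missingness: float = 0.07

    def __post_init__(self) -> None:
        for name in (
            "age_band_probs",
            "education_probs",
            "migration_probs",
            "drinking_day_probs",
        ):
            probs = list(getattr(self, name).values())
            if any(p < 0 for p in probs) or abs(sum(probs) - 1) > 1e-6:
                raise ValueError(f"{name} must be non-negative and sum to 1")
        for name in ("rsod_probs", "importance_probs"):
            probs = getattr(self, name)
            if any(p < 0 for p in probs) or abs(sum(probs) - 1) > 2e-3:
                raise ValueError(f"{name} must be non-negative and sum to ~1")
        for name in (
            "p_consent",
            "p_phone",
            "p_female",
            "p_smoker",
            "participation_rate",
            "unsubscribe_rate",
            "followup_rate",
            "p_any_problem",
            "class_icc",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class SimulatedStudy:
    config: SimConfig
    n_present: int
    n_consented: int
    screening: list[ScreeningRecord]
    participates: dict[str, bool]  # phone owners only
    baselines: dict[str, ProgramBaseline]
    unsubscribed: set[str]
    followed_up: set[str]
    baseline_outcomes: pd.DataFrame
    followup_outcomes: pd.DataFrame
    followup_records: list[FollowUpRecord]
    truth: dict

    def screening_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.screening:
            d = asdict(r)
            cal = d.pop("drinking_calendar")
            d.update(dict(zip(("mon", "tue", "wed", "thu", "fri", "sat", "sun"), cal)))
            rows.append(d)
        return pd.DataFrame(rows)


def _calibrate_intercept(target: float, offsets: np.ndarray) -> float:
    """Intercept b0 such that mean(expit(b0 + offsets)) = target."""
    f = lambda b0: expit(b0 + offsets).mean() - target
    lo, hi = logit(target) - 10, logit(target) + 10
    return float(optimize.brentq(f, lo, hi))


def _categorical(rng, keys, probs, size):
    keys = list(keys)
    p = np.asarray(list(probs), dtype=float)
    p = p / p.sum()
    idx = rng.choice(len(keys), size=size, p=p)
    return [keys[i] for i in idx]


def simulate_cohort(config: SimConfig) -> SimulatedStudy:
    """Generate one full synthetic study, reproducibly from the config seed."""
    rng = np.random.default_rng(config.seed)
    n_present = config.n_present
    n_cons = int(rng.binomial(n_present, config.p_consent))
    n = n_cons  # screened persons

    person_ids = [f"s{i:04d}" for i in range(n)]
    class_ids = np.array([f"c{i % config.n_classes:02d}" for i in rng.permutation(n)])

    female = rng.random(n) < config.p_female
    gender = np.where(female, "female", "male")
    bands = _categorical(
        rng, config.age_band_probs.keys(), config.age_band_probs.values(), n
    )
    ages = np.array([rng.integers(lo, hi + 1) for lo, hi in bands])
    education = _categorical(
        rng, config.education_probs.keys(), config.education_probs.values(), n
    )
    migration = _categorical(
        rng, config.migration_probs.keys(), config.migration_probs.values(), n
    )
    smoker = rng.random(n) < config.p_smoker
    smoking_item = np.where(
        smoker,
        np.where(rng.random(n) < config.p_daily_given_smoker, "daily", "occasional"),
        np.where(rng.random(n) < config.p_never_given_nonsmoker, "never", "former"),
    )
    shape = (config.activity_mean / config.activity_sd) ** 2
    scale = config.activity_sd**2 / config.activity_mean
    activity = np.round(rng.gamma(shape, scale, n), 1)
    owns_mobile = rng.random(n) < config.p_phone

    # --- correlated alcohol measures via class intercept + Gaussian copula
    class_effects = {c: rng.normal() for c in sorted(set(class_ids))}
    b_class = np.array([class_effects[c] for c in class_ids])
    propensity = np.sqrt(config.class_icc) * b_class + np.sqrt(
        1 - config.class_icc
    ) * rng.normal(size=n)
    r = config.alcohol_copula_rho
    z = r * propensity[:, None] + np.sqrt(1 - r**2) * rng.normal(size=(n, 3))
    u = sps.norm.cdf(z)

    rsod_p = np.asarray(config.rsod_probs) / sum(config.rsod_probs)
    rsod_idx = np.searchsorted(np.cumsum(rsod_p), u[:, 0], side="right")
    rsod_idx = np.clip(rsod_idx, 0, len(RSOD_CATEGORIES) - 1)
    weekly_params = zinb_from_moments(
        config.weekly_mean, config.weekly_sd, config.weekly_zero_inflation
    )
    weekly = zinb_ppf(u[:, 1], weekly_params).astype(int)
    max_params = zinb_from_moments(config.max_mean, config.max_sd, 0.0)
    max_drinks = zinb_ppf(u[:, 2], max_params).astype(int)

    day_weights = np.array([0.06, 0.06, 0.08, 0.10, 0.25, 0.32, 0.13])
    calendars = rng.multinomial(weekly, day_weights)

    screening = [
        ScreeningRecord(
            person_id=person_ids[i],
            class_id=str(class_ids[i]),
            gender=str(gender[i]),
            age_years=int(ages[i]),
            education=education[i],
            migration=migration[i],
            smoking_item=str(smoking_item[i]),
            activity_hours_week=float(activity[i]),
            rsod_category=RSOD_CATEGORIES[rsod_idx[i]],
            drinking_calendar=tuple(int(v) for v in calendars[i]),
            max_drinks_occasion=int(max_drinks[i]),
            owns_mobile=bool(owns_mobile[i]),
        )
        for i in range(n)
    ]

    # --- participation among phone owners
    owners = np.flatnonzero(owns_mobile)
    low_edu = np.isin(np.array(education), ("none", "secondary")).astype(float)
    max_std = (max_drinks - max_drinks.mean()) / max(max_drinks.std(), 1e-9)
    part_offsets = (
        config.beta_participation_low_edu * low_edu[owners]
        + config.beta_participation_max_drinks * max_std[owners]
    )
    if config.participation_rate >= 1.0:
        p_part = np.ones(len(owners))
    elif config.participation_rate <= 0.0:
        p_part = np.zeros(len(owners))
    else:
        b0 = _calibrate_intercept(config.participation_rate, part_offsets)
        p_part = expit(b0 + part_offsets)
    part_draw = rng.random(len(owners)) < p_part
    participates = {person_ids[i]: bool(d) for i, d in zip(owners, part_draw)}
    participant_idx = [i for i, d in zip(owners, part_draw) if d]

    # --- program-entry records for participants
    p_item = 1 - (1 - config.p_any_problem) ** (1 / N_PROBLEM_ITEMS)
    baselines = {}
    any_problem_base = {}
    for i in participant_idx:
        problems = tuple(bool(v) for v in rng.random(N_PROBLEM_ITEMS) < p_item)
        any_problem_base[person_ids[i]] = any(problems)
        baselines[person_ids[i]] = ProgramBaseline(
            screening=screening[i],
            problems=problems,
            importance_reduce=_categorical(
                rng, IMPORTANCE_LEVELS, config.importance_probs, 1
            )[0],
            typical_drinking_day=_categorical(
                rng,
                config.drinking_day_probs.keys(),
                config.drinking_day_probs.values(),
                1,
            )[0],
            typical_drinking_time=datetime.time(int(rng.integers(19, 23)), 0),
        )

    # --- unsubscription (flat rate among participants)
    unsub_draw = rng.random(len(participant_idx)) < config.unsubscribe_rate
    unsubscribed = {person_ids[i] for i, d in zip(participant_idx, unsub_draw) if d}

    # --- loss to follow-up among eligible, worse for smokers / frequent RSOD
    drop_target = 1 - config.followup_rate
    drop_offsets = (
        config.beta_dropout_smoker * smoker[owners].astype(float)
        + config.beta_dropout_rsod * rsod_idx[owners]
    )
    if drop_target <= 0.0:
        p_drop = np.zeros(len(owners))
    else:
        b0 = _calibrate_intercept(drop_target, drop_offsets)
        p_drop = expit(b0 + drop_offsets)
    drop_draw = rng.random(len(owners)) < p_drop
    followed_up = {person_ids[i] for i, d in zip(owners, drop_draw) if not d}

    # --- outcomes at baseline (participants carry the problems item)
    base_rows = []
    for i in owners:
        pid = person_ids[i]
        band = map_rsod_band(RSOD_CATEGORIES[rsod_idx[i]])
        base_rows.append(
            {
                "person_id": pid,
                "class_id": str(class_ids[i]),
                "any_rsod": float(band.value >= 1),
                "frequent_rsod": float(band.value >= 2),
                "weekly_drinks": float(weekly[i]),
                "max_drinks": float(max_drinks[i]),
                "any_problem": (
                    float(any_problem_base[pid]) if pid in any_problem_base else np.nan
                ),
            }
        )
    baseline_outcomes = pd.DataFrame(base_rows)

    # --- follow-up outcomes: effect for participants, null for the rest
    is_part = baseline_outcomes["person_id"].map(
        lambda p: participates.get(p, False)
    )
    null_effect = EffectParams(
        or_any_rsod=1.0,
        or_frequent_rsod=1.0,
        rr_weekly_drinks=1.0,
        rr_max_drinks=1.0,
        or_any_problem=1.0,
        binary_stay_prob=config.effect.binary_stay_prob,
        count_copula_rho=config.effect.count_copula_rho,
    )
    fu_part = apply_effect(
        baseline_outcomes[is_part], config.effect, rng, weekly_params, max_params
    )
    fu_rest = apply_effect(
        baseline_outcomes[~is_part], null_effect, rng, weekly_params, max_params
    )
    followup_outcomes = (
        pd.concat([fu_part, fu_rest])
        .set_index("person_id")
        .loc[baseline_outcomes["person_id"]]
        .reset_index()
    )
    # only followed-up persons have follow-up data; item missingness on top
    followed_mask = followup_outcomes["person_id"].isin(followed_up)
    for col, miss in config.outcome_missingness.items():
        gone = ~followed_mask | (rng.random(len(followup_outcomes)) < miss)
        followup_outcomes.loc[gone, col] = np.nan

    followup_records = _followup_records(
        rng, config, followup_outcomes, followed_up, participates
    )

    truth = {
        "effect": asdict(config.effect),
        "weekly_params": asdict(weekly_params),
        "max_params": asdict(max_params),
        "n_owners": int(len(owners)),
        "n_participants": int(len(participant_idx)),
        "n_unsubscribed": int(len(unsubscribed)),
        "n_followed_up": int(len(followed_up)),
    }
    return SimulatedStudy(
        config=config,
        n_present=n_present,
        n_consented=n_cons,
        screening=screening,
        participates=participates,
        baselines=baselines,
        unsubscribed=unsubscribed,
        followed_up=followed_up,
        baseline_outcomes=baseline_outcomes,
        followup_outcomes=followup_outcomes,
        followup_records=followup_records,
        truth=truth,
    )


def apply_effect_binary(
    y1: np.ndarray,
    odds_ratio: float,
    stay_prob: float,
    rng,
    baseline_prevalence: Optional[float] = None,
) -> np.ndarray:
    """Follow-up binaries with target marginal odds(p2) = OR x odds(p1).

    Per person: keep the baseline value with probability ``stay_prob``,
    otherwise redraw Bernoulli(q) where q solves the marginal constraint.
    Feasibility requires stay_prob x p1 <= p2 <= stay_prob x p1 + 1 -
    stay_prob; q is clipped into [0, 1] otherwise. ``baseline_prevalence``
    fixes the p1 the odds ratio acts on (for calibration studies where the
    data-generating prevalence is known); by default the empirical
    baseline prevalence is used.
    """
    y1 = np.asarray(y1, dtype=float)
    if len(y1) == 0:
        return y1.copy()
    p1 = (
        float(np.nanmean(y1))
        if baseline_prevalence is None
        else float(baseline_prevalence)
    )
    return _binary_with_target(y1, _shift_odds(p1, odds_ratio), stay_prob, rng, p1=p1)


def _shift_odds(p1: float, odds_ratio: float) -> float:
    if odds_ratio == 0:
        return 0.0
    if p1 in (0.0, 1.0):
        return p1
    odds2 = odds_ratio * p1 / (1 - p1)
    return odds2 / (1 + odds2)


def _binary_with_target(
    y1: np.ndarray, p2: float, stay_prob: float, rng, p1: Optional[float] = None
) -> np.ndarray:
    """Stay/redraw transition hitting a target marginal prevalence."""
    n = len(y1)
    if n == 0 or stay_prob >= 1.0:
        return y1.copy()
    if p1 is None:
        p1 = float(np.nanmean(y1))
    q = np.clip((p2 - stay_prob * p1) / (1 - stay_prob), 0.0, 1.0)
    stay = rng.random(n) < stay_prob
    redraw = (rng.random(n) < q).astype(float)
    return np.where(stay, y1, redraw)


def apply_effect_counts(
    y1: np.ndarray,
    rate_ratio: float,
    dist: ZinbParams,
    copula_rho: float,
    rng,
) -> np.ndarray:
    """Follow-up counts via a Gaussian copula on randomized PIT uniforms.

    The baseline count is mapped to a latent normal through its randomized
    probability integral transform under ``dist``; the correlated latent
    is mapped back through the quantile function of the same family with
    mean scaled by the rate ratio.
    """
    y1 = np.asarray(y1, dtype=float)
    n = len(y1)
    if n == 0:
        return y1.copy()
    lo = _zinb_cdf(y1 - 1, dist)
    hi = _zinb_cdf(y1, dist)
    u1 = np.clip(lo + rng.random(n) * (hi - lo), 1e-12, 1 - 1e-12)
    z1 = sps.norm.ppf(u1)
    z2 = copula_rho * z1 + np.sqrt(1 - copula_rho**2) * rng.normal(size=n)
    target = ZinbParams(pi=dist.pi, k=dist.k, mu=dist.mu * rate_ratio)
    return zinb_ppf(sps.norm.cdf(z2), target)


def apply_effect(
    baseline_outcomes: pd.DataFrame,
    effect: EffectParams,
    rng,
    weekly_dist: Optional[ZinbParams] = None,
    max_dist: Optional[ZinbParams] = None,
) -> pd.DataFrame:
    """Generate the follow-up outcome table from the baseline one.

    Count distributions default to method-of-moments fits of the observed
    baseline columns. ``frequent_rsod`` is forced consistent with
    ``any_rsod`` (frequent implies any).
    """
    df = baseline_outcomes
    if weekly_dist is None:
        col = df["weekly_drinks"].dropna()
        weekly_dist = zinb_from_moments(col.mean(), col.std(), 0.1)
    if max_dist is None:
        col = df["max_drinks"].dropna()
        max_dist = zinb_from_moments(col.mean(), col.std(), 0.0)
    out = pd.DataFrame({"person_id": df["person_id"], "class_id": df["class_id"]})
    # frequent RSOD first, then any RSOD filled in among the non-frequent so
    # that nesting (frequent implies any) holds without bending either margin
    any1 = df["any_rsod"].to_numpy(dtype=float)
    freq1 = df["frequent_rsod"].to_numpy(dtype=float)
    freq2 = apply_effect_binary(
        freq1, effect.or_frequent_rsod, effect.binary_stay_prob, rng
    )
    any2 = np.ones(len(df))
    sub = freq2 == 0
    if sub.any() and len(df):
        p2_any = _shift_odds(float(any1.mean()), effect.or_any_rsod)
        p_sub = np.clip(
            (p2_any * len(df) - freq2.sum()) / sub.sum(), 0.0, 1.0
        )
        any2[sub] = _binary_with_target(
            any1[sub], p_sub, effect.binary_stay_prob, rng
        )
    out["any_rsod"] = any2
    out["frequent_rsod"] = freq2
    out["weekly_drinks"] = apply_effect_counts(
        df["weekly_drinks"].to_numpy(),
        effect.rr_weekly_drinks,
        weekly_dist,
        effect.count_copula_rho,
        rng,
    )
    out["max_drinks"] = apply_effect_counts(
        df["max_drinks"].to_numpy(),
        effect.rr_max_drinks,
        max_dist,
        effect.count_copula_rho,
        rng,
    )
    probs = df["any_problem"].to_numpy(dtype=float)
    present = ~np.isnan(probs)
    fu_prob = np.full(len(df), np.nan)
    fu_prob[present] = apply_effect_binary(
        probs[present], effect.or_any_problem, effect.binary_stay_prob, rng
    )
    out["any_problem"] = fu_prob
    return out


def _followup_records(
    rng, config: SimConfig, followup_outcomes, followed_up, participates
) -> list[FollowUpRecord]:
    """Follow-up questionnaires for followed-up program participants."""
    records = []
    miss = config.program_use_missingness

    def answer(p_categories, keys):
        if rng.random() < miss:
            return None
        return _categorical(rng, keys, p_categories, 1)[0]

    for row in followup_outcomes.itertuples(index=False):
        pid = row.person_id
        if pid not in followed_up or not participates.get(pid, False):
            continue
        rec = FollowUpRecord(
            person_id=pid,
            max_drinks_occasion=(
                None if np.isnan(row.max_drinks) else int(row.max_drinks)
            ),
            received_regularly=_opt(rng, miss, rng.random() < 0.944),
            read_level=answer((0.498, 0.446, 0.056), ("thorough", "short_look", "not_read")),
            timing_ok=_opt(rng, miss, rng.random() < 0.754),
            volume_pref=answer((0.575, 0.355, 0.070), ("ok", "fewer", "more")),
            evaluations={
                item: _opt(rng, miss, rng.random() < p)
                for item, p in zip(
                    EVALUATION_ITEMS, (0.943, 0.705, 0.494, 0.967, 0.302, 0.338)
                )
            },
        )
        records.append(rec)
    return records


def _opt(rng, miss, value):
    return None if rng.random() < miss else bool(value)


def paired_binary_study(
    n_persons: int,
    p1: float,
    odds_ratio: float,
    seed: int,
    n_classes: int = 36,
    icc: float = 0.05,
    stay_prob: float = 0.5,
) -> pd.DataFrame:
    """Complete paired binary data for estimator calibration studies.

    Persons sit in ``n_classes`` classes whose logit-scale random intercept
    carries a latent intra-class correlation ``icc``; the intercept is
    calibrated so the realized baseline prevalence targets ``p1``. The
    follow-up wave applies the stay/redraw effect transition. Returns the
    long format consumed by :func:`alkcheck.stats.gee_fit`.
    """
    rng = np.random.default_rng(seed)
    classes = np.arange(n_persons) % n_classes
    b_c = rng.normal(size=n_classes)[classes]
    sigma = np.sqrt(icc / (1 - icc) * np.pi**2 / 3)
    b0 = _calibrate_intercept(p1, sigma * b_c)
    y1 = (rng.random(n_persons) < expit(b0 + sigma * b_c)).astype(float)
    y2 = apply_effect_binary(y1, odds_ratio, stay_prob, rng, baseline_prevalence=p1)
    rows = []
    for t, y in ((0, y1), (1, y2)):
        for i in range(n_persons):
            rows.append(
                {
                    "person_id": f"p{i:04d}",
                    "class_id": f"c{classes[i]:02d}",
                    "time": t,
                    "value": y[i],
                }
            )
    return pd.DataFrame(rows)


def long_outcomes(study: SimulatedStudy, participants_only: bool = True) -> pd.DataFrame:
    """Stack baseline and follow-up outcomes into the long evaluation format."""
    base = study.baseline_outcomes.copy()
    base["time"] = 0
    fu = study.followup_outcomes.copy()
    fu["time"] = 1
    df = pd.concat([base, fu], ignore_index=True)
    if participants_only:
        df = df[df["person_id"].map(lambda p: study.participates.get(p, False))]
    cols = ["person_id", "class_id", "time"] + list(
        c for c in df.columns if c not in ("person_id", "class_id", "time")
    )
    return df[cols].reset_index(drop=True)
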