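# Methods

`alkcheck` re-implements the computational core of a combined web- and
SMS-based program to reduce problem drinking in vocational-school
students, together with a synthetic cohort generator and the pre-post
evaluation machinery. This note records the models, the defaults and the
reasoning behind the genuinely open design choices.

## Instruments and derivations

Screening collects demographics (gender, age, education, migration
background), smoking status, weekly physical activity, mobile-phone
ownership and three alcohol items: RSOD frequency in the last 30 days on
an 8-level ordinal scale (`never`, `1-2`, ..., `>12`), a 7-day
typical-week drinking calendar, and the maximum number of drinks on one
occasion. The program-entry assessment adds ten alcohol-related problem
items (grouped into individual / relational / sexual / delinquency
categories), the importance of reducing drinking, and the typical
drinking day and time.

Derivations are deliberately small and total: weekly volume is the
calendar sum; daily and occasional smokers count as smokers; the RSOD
scale collapses onto three bands (`never` → NONE, `1-2` → ONE_TO_TWO,
everything at or above `3-4` → MORE_THAN_TWO). Missing problem items
count as "no problem", making the any-problem outcome conservative under
item non-response. The problem-item texts are not modelled; items are
positional (p01..p10) with a configurable category grouping.

## Risk classification

Two indicators define problem drinking: risky single-occasion drinking
(≥ 5 standard drinks for men, ≥ 4 for women on one occasion) and chronic
volume (daily average ≥ 30 g / ≥ 20 g pure alcohol). With 12 g of ethanol
per standard drink the volume indicator corresponds to ≥ 18 / ≥ 12 drinks
per typical week, and the classification is:

- **NON_RISK** — RSOD band NONE and weekly drinks strictly below 18 (men)
  / 12 (women);
- **LOW_RISK** — band ONE_TO_TWO, or band NONE at/above the weekly cutoff;
- **HIGH_RISK** — band MORE_THAN_TWO.

The cutoff is inclusive for LOW_RISK, exclusive for NON_RISK, and a high
weekly volume never escalates a 1–2-occasion drinker to HIGH_RISK; the
boundary behaviour is pinned by tests. The standard-drink mass defaults to
12 g and is configurable (Swiss conventions range 10–12 g). Classification
uses the categorical band directly rather than an imputed occasion count,
because the instrument is categorical.

## Normative feedback

The one-shot feedback report is a pure function of gender, age, weekly
drinks and RSOD frequency — exactly the four tailoring variables of the
online feedback; all other baseline fields influence only SMS content. Its
four sections, in order: weekly drinks relative to the age/gender
reference group, monthly cost, weekly calories, RSOD occasions relative to
the reference group.

Percentiles use the mid-rank convention, 100·(#below + ½·#equal)/n,
against the raw reference sample of the person's (gender, age-band)
stratum. Age bands default to 15–16 / 17–18 / 19–20 / 21+; a missing
stratum falls back to the nearest band of the same gender (ties toward
the younger band). The reference norms of the original program came from
an unpublished prior survey; the package therefore ships a clearly
labelled synthetic norm-table generator (`synthetic_norm_table`) and
reads real tables from YAML/JSON.

Constants: cost uses 52/12 weeks per month and a configurable price per
drink (default 3.50 CHF — no printed figure exists); calories use
7.1 kcal per gram of ethanol, mixers excluded. The Widmark blood-alcohol
estimate is mass/(r·weight) in per-mille with r = 0.68 (men) / 0.55
(women) and no elimination term, since it describes the peak of a single
occasion; body weight is not collected by the instruments, so gender
defaults (72 / 60 kg) stand in. Under these defaults 14 drinks give
3.43 ‰ ≈ 0.34 in the per-cent (g/100 mL) convention.

## SMS planning

Everyone receives 12 weekly messages (default slot Wednesday 17:00,
configurable — only the drinking-day messages have an individually
specified time). LOW and HIGH risk participants additionally receive 6
biweekly messages on their stated typical drinking day and time.
"Biweekly" is read as every second week, by default the odd weeks
1, 3, ..., 11 (phase configurable).

Content pools: NON_RISK {1,2,3,4}, LOW_RISK {1,2,3,5,6,7,8,9}, HIGH_RISK
{1,2,3,5,6,7,8,9,10}; category 10 (counseling services) is exclusive to
HIGH_RISK and category 4 (maintaining sensible drinking) to NON_RISK.
The rotation across weeks is not specified anywhere, so the planner uses
a seeded round-robin: repeated shuffles of the pool without immediate
repeats, which guarantees every pool category appears within 12 weeks.
Drinking-day messages draw from the motivational categories {5, 9},
matching their stated focus on strategies toward sensible drinking.
Templates are English with flat `{placeholder}` slots; rendering is
all-or-nothing and names the first missing placeholder. Messages are
capped at 480 characters.

Unsubscription: any incoming SMS matching a stop keyword ({stop, ende,
weg}, case-insensitive, configurable) marks the sender unsubscribed and
cancels later planned sends; since the original rule was "any message
expressing the request", free-text withdrawals are supported through a
manual override flag on log events. The log refuses outgoing events after
unsubscription and out-of-order events per person.

## Cohort simulator

The generator emulates the study flow: 490 students present, consent
probability 488/490, phone ownership 477/488, 36 school classes of
near-equal size. Registration is a logistic model with positive weights
on lower education (0.5 on the log-odds) and standardized maximum drinks
(0.3), its intercept calibrated by root finding so the cohort-level rate
hits 364/477. Unsubscription is a flat 23/364. Loss to follow-up is a
second calibrated logistic model with positive weights on smoking (0.5)
and the RSOD category index (0.15 per step), so dropouts are more often
smokers and frequent bingers while the marginal follow-up rate stays at
367/477.

Baseline alcohol measures are drawn jointly: each person's drinking
propensity is a class random intercept (share `class_icc`, default 0.05,
of the latent variance — the real within-class correlation is unreported)
plus an individual term, and a Gaussian copula (loading 0.6) maps the
propensity to three correlated uniforms that feed the inverse CDFs of the
RSOD category distribution, a zero-inflated negative binomial for weekly
drinks (targets mean 14.1, SD 16.1; zero inflation 0.15; NB parameters
solved by method of moments) and a negative binomial for maximum drinks
(11.6, SD 10.8). Demographic marginals encode the participant profile
(24.5% female, age bands 20.1/53.3/19.8/6.9%, 53% smokers, education and
migration shares as published). The calendar spreads the weekly total
multinomially with weekend-heavy weights. The copula makes the three
alcohol measures positively correlated but does not force logical
consistency between the RSOD category and the maximum-drinks count; both
are noisy self-reports in the real instrument too.

The pre-post effect is marginal with per-person dependence. Binary
outcomes keep their baseline value with probability `binary_stay_prob`
(default 0.5 — within-person concordance is unreported) and are otherwise
redrawn at the rate that makes the follow-up marginal satisfy
odds(p₂) = OR·odds(p₁). Frequent RSOD is generated first and the
any-RSOD indicator is filled in among non-frequent persons, so nesting
holds without bending either margin. Counts go through a Gaussian copula
(ρ = 0.5) on randomized PIT uniforms, the follow-up marginal being the
baseline family with mean scaled by the rate ratio. Default effect sizes
are the published estimates (OR 0.66 / 0.76 / 0.60, IRR 0.83 / 0.91);
nonparticipants get a null effect.

Two calibration subtleties worth knowing:

- By default the redraw rate is calibrated against the *empirical*
  baseline prevalence, which pins a single dataset's margins (useful for
  demos) but couples the two waves across replicates and makes
  repeated-simulation calibration studies conservative. Estimator
  calibration therefore uses `paired_binary_study`, which fixes the
  theoretical prevalence (`apply_effect_binary(..., baseline_prevalence=)`).
- Differential dropout (smokers/bingers leave more) makes available-case
  marginal effect estimates slightly stronger than the generating target —
  a real feature of uncorrected pre-post designs, visible in the full
  cohort simulation.

## Estimation

The pre-post models are GEEs with an intercept and a time indicator,
independence working correlation, logit link for the three binary
outcomes (reported as OR) and log link with Poisson variance for the two
counts (reported as IRR). With a saturated two-point mean model the point
estimates equal link-transformed marginal means regardless of the working
correlation, so independence loses nothing; no dispersion parameter
affects the sandwich interval. The mean model is solved by IRLS
(Newton–Raphson for the canonical links), convergence at relative
coefficient change < 1e-8, at most 100 iterations; non-convergence (e.g.
separation) is flagged on the result, never silent.

Variance is the cluster-robust sandwich with scores aggregated at the
school-class level (students are sampled within classes); person-level
repeated measures are nested inside classes and absorbed by the
aggregation. A `cluster_by="person"` option exists for sensitivity, and a
G/(G−1) small-sample factor is optional (off by default, matching
large-sample software behaviour). Wald 95% CIs and two-sided p-values use
the normal reference. All available records enter each fit: persons
observed at one wave still contribute, since each observation carries its
own time indicator.

Calibration, measured by simulation with the paired generator (278
persons, baseline prevalence 0.755, concordance 0.5): the time-effect
Wald test at person-level clustering rejects a true null at 5.4% over
2,000 replicates; at the 36-class level it shows the well-known
small-sample inflation of cluster-robust tests (≈ 7.8%), which is exactly
why the person-level sensitivity option and the G/(G−1) factor exist.
Effect recovery at the published design size (mean estimate, CI coverage)
is asserted in the test suite at 300 replicates.

Baseline-difference and attrition analyses use a hand-computed Pearson
chi-square (upper-tail p from the χ² distribution) and a Mann–Whitney U
with mid-ranks: exact p by full enumeration of group labelings (valid
under ties) when the pooled sample has at most 12 observations, otherwise
the tie-corrected normal approximation with continuity correction. Both
match scipy's implementations to ~1e-8 on random inputs; they are written
out here so scipy can serve as an independent reference in the tests.

## Worked-example fixtures

`alkcheck.fixtures` reconstructs, in code, datasets whose summary
statistics equal the published ones: the participant-flow stage counts,
per-outcome complete-case margins (including integer count samples whose
mean/SD round to the printed 13.4 (15.3) → 11.3 (14.0) and 11.3 (10.3) →
10.5 (10.3), found by sum-preserving local search from negative-binomial
quantiles), and the item-wise program-use tallies. Joint structure beyond
the margins is synthetic — binary pairs maximize concordance, count pairs
are comonotone — which leaves every marginal summary and every
saturated-model GEE estimate unchanged relative to any other coupling.
The fitted complete-case odds ratios (e.g. 0.676 for any RSOD, 0.652 for
problems) differ slightly from the published available-case estimates
(0.66, 0.60) because partially observed persons entered the original
fits; the exact available-case composition is unrecoverable from the
printed tables.

## What passing tests do and do not show

The simulator reproduces the cohort's marginal structure, participation/
attrition selectivity and a plausible dependence structure, so green
tests demonstrate that the rules, schedules, reports and estimators are
implemented correctly and that the GEE machinery is well calibrated at
the study's size. They do not validate the behavioural content of the
messages, the unpublished reference norms (the shipped norm table is
synthetic), or the real within-person and within-class correlations,
which are unreported and enter only as configurable defaults.

## Problem sizes

Default runs keep everything light: the full cohort simulation (~490
students) takes well under a second; marginal checks use a 10,000-person
configuration; calibration studies use 300–2,000 replicates of the
278-pair design. The whole suite runs in about half a minute.
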