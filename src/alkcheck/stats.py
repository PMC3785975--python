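"""Estimation machinery for the pre-post evaluation.

The longitudinal course of each outcome over the two assessments is
analysed with a generalized estimating equation (GEE) model containing an
intercept and a time indicator (baseline = 0, follow-up = 1):

- logistic link for the binary outcomes (any RSOD occasion, frequent RSOD,
  any alcohol-related problem), reported as an odds ratio (OR);
- log link with Poisson variance for the count outcomes (standard drinks
  per typical week, maximum drinks on an occasion), reported as an
  incidence rate ratio (IRR).

The working correlation is independence. With a saturated two-time-point
mean model the point estimates equal the link-transformed marginal means
whatever the working correlation, so nothing is lost; what matters is the
variance, which uses the cluster-robust (sandwich) estimator with scores
aggregated at the school-class level to account for students being
sampled within classes. Wald 95% confidence intervals and two-sided
p-values use the normal reference distribution (alpha = 0.05).

All available data enter the fit: persons missing one assessment still
contribute their observed one (each observation carries its own time
indicator, so the estimating equations remain valid under missingness
that is unrelated to the outcome given time).

Baseline-difference and attrition analyses use Pearson chi-square tests
for categorical variables and Mann-Whitney U tests for ordinal/continuous
ones.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "LongRecord",
    "GEEResult",
    "gee_fit",
    "chi_square_test",
    "mann_whitney_u",
    "evaluate_outcomes",
    "OUTCOME_FAMILIES",
    "long_frame",
]

Family = Literal["binomial-logit", "poisson-log"]


@dataclass(frozen=True)
class LongRecord:
    person_id: str
    class_id: str
    time: int  # 0 = baseline, 1 = follow-up
    value: float


@dataclass(frozen=True)
class GEEResult:
    family: str
    intercept: float
    time_coef: float
    effect: float  # exp(time_coef): OR or IRR
    robust_se: float  # on the link scale
    ci_low: float  # exponentiated Wald bounds
    ci_high: float
    p_value: float
    n_persons: int
    n_obs: int
    n_clusters: int
    converged: bool
    n_iter: int

    def __post_init__(self) -> None:
        if self.converged:
            assert self.ci_low <= self.effect <= self.ci_high
            assert self.effect > 0


def _records_to_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = pd.DataFrame(
            {
                "person_id": [r.person_id for r in records],
                "class_id": [r.class_id for r in records],
                "time": [r.time for r in records],
                "value": [r.value for r in records],
            }
        )
    if df.duplicated(["person_id", "time"]).any():
        raise ValueError("at most one record per (person, time)")
    return df


def gee_fit(
    records,
    family: Family,
    cluster_by: str = "class",
    small_sample_correction: bool = False,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> GEEResult:
    """Fit the intercept + time GEE with independence working correlation.

    Parameters
    ----------
    records
        LongRecord sequence or a long dataframe with columns
        person_id, class_id, time, value.
    family
        "binomial-logit" or "poisson-log" (canonical links).
    cluster_by
        Sandwich aggregation level, "class" (default, the design's
        clustering) or "person" (sensitivity analysis).
    small_sample_correction
        Apply the G/(G-1) factor to the sandwich; off by default to match
        large-sample behavior.

    The mean model is solved by iteratively reweighted least squares
    (Fisher scoring, which for canonical links is Newton-Raphson on the
    independence estimating equations); convergence is relative coefficient
    change below ``tol``. Non-convergence is flagged on the result, not
    raised.
    """
    if family not in ("binomial-logit", "poisson-log"):
        raise ValueError(f"unknown family {family!r}")
    df = _records_to_frame(records)
    cluster_col = {"class": "class_id", "person": "person_id"}[cluster_by]
    clusters = df[cluster_col].to_numpy()
    if len(np.unique(clusters)) < 2:
        raise ValueError("need at least 2 clusters for the robust variance")

    y = df["value"].to_numpy(dtype=float)
    t = df["time"].to_numpy(dtype=float)
    X = np.column_stack([np.ones_like(t), t])

    if family == "binomial-logit" and not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("binomial outcomes must be 0/1")
    if (y < 0).any():
        raise ValueError("outcomes must be non-negative")

    beta = np.zeros(2)
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        eta = X @ beta
        if family == "binomial-logit":
            mu = 1.0 / (1.0 + np.exp(-eta))
            w = mu * (1.0 - mu)
        else:
            mu = np.exp(eta)
            w = mu
        # canonical link: score = X'(y - mu), information = X'WX
        score = X.T @ (y - mu)
        info = X.T @ (X * w[:, None])
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            break
        beta_new = beta + step
        denom = np.maximum(np.abs(beta_new), 1.0)
        if np.max(np.abs(step) / denom) < tol:
            beta = beta_new
            converged = True
            break
        beta = beta_new

    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta)) if family == "binomial-logit" else np.exp(eta)
    w = mu * (1.0 - mu) if family == "binomial-logit" else mu
    bread = np.linalg.pinv(X.T @ (X * w[:, None]))
    resid = y - mu
    meat = np.zeros((2, 2))
    uniq = np.unique(clusters)
    for g in uniq:
        s_g = X[clusters == g].T @ resid[clusters == g]
        meat += np.outer(s_g, s_g)
    if small_sample_correction:
        meat *= len(uniq) / (len(uniq) - 1)
    cov = bread @ meat @ bread
    se = math.sqrt(max(cov[1, 1], 0.0))

    z975 = sps.norm.ppf(0.975)
    z = beta[1] / se if se > 0 else math.inf * np.sign(beta[1] or 1)
    return GEEResult(
        family=family,
        intercept=float(beta[0]),
        time_coef=float(beta[1]),
        effect=float(np.exp(beta[1])),
        robust_se=float(se),
        ci_low=float(np.exp(beta[1] - z975 * se)),
        ci_high=float(np.exp(beta[1] + z975 * se)),
        p_value=float(2.0 * sps.norm.sf(abs(z))),
        n_persons=int(df["person_id"].nunique()),
        n_obs=int(len(df)),
        n_clusters=int(len(uniq)),
        converged=converged,
        n_iter=n_iter,
    )


def chi_square_test(table: Sequence[Sequence[float]]) -> tuple[float, int, float]:
    """Pearson chi-square test of independence on an r x c count table."""
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or (obs < 0).any():
        raise ValueError("table must be a 2-D array of non-negative counts")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if (row <= 0).any() or (col <= 0).any():
        raise ValueError("degenerate margins: every row and column sum must be > 0")
    expected = np.outer(row, col) / obs.sum()
    stat = float(((obs - expected) ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    return stat, df, float(sps.chi2.sf(stat, df))


def mann_whitney_u(
    x: Sequence[float],
    y: Sequence[float],
    exact_max_n: int = 12,
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test with mid-ranks for ties.

    Returns the classic statistic U = min(U_x, U_y). The p-value is exact
    (full enumeration of the C(n_x+n_y, n_x) group labelings, valid under
    ties) when the pooled size is at most ``exact_max_n``, and otherwise
    uses the tie-corrected normal approximation with continuity correction.
    """
    x = list(x)
    y = list(y)
    if not x or not y:
        raise ValueError("both samples must be non-empty")
    nx, ny = len(x), len(y)
    pooled = np.asarray(x + y, dtype=float)
    ranks = sps.rankdata(pooled)
    ux = float(ranks[:nx].sum() - nx * (nx + 1) / 2.0)
    uy = nx * ny - ux
    u = min(ux, uy)

    if nx + ny <= exact_max_n:
        # exact null distribution of U_x by enumerating group labelings
        mid = nx * ny / 2.0
        extreme = 0
        total = 0
        for idx in itertools.combinations(range(nx + ny), nx):
            r = ranks[list(idx)].sum() - nx * (nx + 1) / 2.0
            total += 1
            if abs(r - mid) >= abs(ux - mid) - 1e-12:
                extreme += 1
        return u, extreme / total

    n = nx + ny
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum()
    sigma2 = nx * ny / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if sigma2 <= 0:  # all values tied
        return u, 1.0
    mu = nx * ny / 2.0
    z = (abs(ux - mu) - 0.5) / math.sqrt(sigma2)
    return u, float(2.0 * sps.norm.sf(max(z, 0.0)))


#: Outcome name -> GEE family for the five effectiveness criteria.
OUTCOME_FAMILIES: dict[str, Family] = {
    "any_rsod": "binomial-logit",
    "frequent_rsod": "binomial-logit",
    "weekly_drinks": "poisson-log",
    "max_drinks": "poisson-log",
    "any_problem": "binomial-logit",
}


def long_frame(
    df: pd.DataFrame,
    outcome: str,
) -> pd.DataFrame:
    """Extract one outcome's available long records from a multi-outcome frame.

    ``df`` has columns person_id, class_id, time and one column per outcome;
    rows with a missing value for this outcome are dropped (all available
    data, not complete cases).
    """
    sub = df[["person_id", "class_id", "time", outcome]].dropna(subset=[outcome])
    return sub.rename(columns={outcome: "value"})


def evaluate_outcomes(
    df: pd.DataFrame,
    cluster_by: str = "class",
    outcomes: Optional[Sequence[str]] = None,
) -> dict[str, GEEResult]:
    """Fit the per-outcome GEE models on a long multi-outcome dataframe.

    Returns one result per outcome: ORs for the binary outcomes, IRRs for
    the counts, all clustered by school class by default.
    """
    results = {}
    for outcome in outcomes or OUTCOME_FAMILIES:
        family = OUTCOME_FAMILIES[outcome]
        results[outcome] = gee_fit(long_frame(df, outcome), family, cluster_by)
    return results
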