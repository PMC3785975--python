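"""GEE estimation and the nonparametric tests against independent oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from alkcheck.stats import (
    GEEResult,
    chi_square_test,
    evaluate_outcomes,
    gee_fit,
    long_frame,
    mann_whitney_u,
)


def paired_long(pairs, n_classes=6):
    """Long dataframe from (baseline, followup) pairs."""
    rows = []
    for i, (b, f) in enumerate(pairs):
        cid = f"c{i % n_classes}"
        if b is not None:
            rows.append({"person_id": f"p{i}", "class_id": cid, "time": 0, "value": b})
        if f is not None:
            rows.append({"person_id": f"p{i}", "class_id": cid, "time": 1, "value": f})
    return pd.DataFrame(rows)


class TestGeeClosedForms:
    def test_poisson_constant_outcome_recovers_the_mean(self):
        # value 2 at both waves: exp(intercept) = 2, IRR = 1
        df = paired_long([(2, 2)] * 8)
        res = gee_fit(df, "poisson-log")
        assert np.exp(res.intercept) == pytest.approx(2.0, abs=1e-7)
        assert res.effect == pytest.approx(1.0, abs=1e-7)

    def test_binomial_saturated_model_reproduces_marginal_odds_ratio(self):
        # balanced pairs: baseline 3/4 positive, follow-up 2/4 positive
        df = paired_long([(1, 1), (1, 1), (1, 0), (0, 0)])
        res = gee_fit(df, "binomial-logit")
        assert res.effect == pytest.approx((2 / 2) / (3 / 1), abs=1e-8)

    def test_fixture_odds_ratio_equals_marginal_oracle(self, outcome_data):
        res = gee_fit(outcome_data["any_rsod"], "binomial-logit")
        assert res.effect == pytest.approx((188 * 68) / (210 * 90), abs=1e-8)
        assert res.converged

    def test_effect_is_exactly_exp_of_time_coefficient(self, outcome_data):
        for outcome, family in [
            ("any_rsod", "binomial-logit"),
            ("weekly_drinks", "poisson-log"),
        ]:
            res = gee_fit(outcome_data[outcome], family)
            assert res.effect == np.exp(res.time_coef)

    def test_available_case_records_enter_the_fit(self):
        # persons observed at only one wave still contribute
        df = paired_long([(1, 1), (1, 0), (0, None), (None, 1), (1, None)])
        res = gee_fit(df, "binomial-logit")
        assert res.n_obs == 7
        assert res.n_persons == 5


class TestSandwich:
    def hand_sandwich(self, df, family):
        """Independent hand-coded sandwich on a fitted mean model."""
        res = gee_fit(df, family)
        X = np.column_stack([np.ones(len(df)), df["time"].to_numpy(float)])
        eta = X @ np.array([res.intercept, res.time_coef])
        mu = 1 / (1 + np.exp(-eta)) if family == "binomial-logit" else np.exp(eta)
        w = mu * (1 - mu) if family == "binomial-logit" else mu
        bread = np.linalg.inv(X.T @ (X * w[:, None]))
        return res, X, df["value"].to_numpy(float) - mu, bread

    def test_one_obs_per_cluster_equals_hc0(self):
        df = pd.DataFrame(
            {
                "person_id": [f"p{i}" for i in range(6)],
                "class_id": [f"c{i}" for i in range(6)],  # one obs per cluster
                "time": [0, 0, 0, 1, 1, 1],
                "value": [3.0, 1.0, 2.0, 1.0, 0.0, 2.0],
            }
        )
        res, X, resid, bread = self.hand_sandwich(df, "poisson-log")
        meat = (X * resid[:, None]).T @ (X * resid[:, None])  # HC0
        hc0_se = np.sqrt((bread @ meat @ bread)[1, 1])
        assert res.robust_se == pytest.approx(hc0_se, abs=1e-10)

    def test_invariant_to_cluster_relabeling(self, outcome_data):
        df = outcome_data["frequent_rsod"].copy()
        ref = gee_fit(df, "binomial-logit")
        relabel = {c: f"z{i}" for i, c in enumerate(sorted(set(df["class_id"]))[::-1])}
        df["class_id"] = df["class_id"].map(relabel)
        assert gee_fit(df, "binomial-logit").robust_se == pytest.approx(
            ref.robust_se, abs=1e-12
        )

    def test_cluster_replication_halves_the_variance(self, outcome_data):
        df = outcome_data["any_problem"]
        ref = gee_fit(df, "binomial-logit")
        doubled = pd.concat(
            [df, df.assign(person_id=df.person_id + "x", class_id=df.class_id + "x")]
        )
        res = gee_fit(doubled, "binomial-logit")
        assert res.robust_se**2 == pytest.approx(ref.robust_se**2 / 2, rel=1e-9)

    def test_single_cluster_is_an_error(self):
        df = paired_long([(1, 0), (0, 1)], n_classes=1)
        with pytest.raises(ValueError, match="2 clusters"):
            gee_fit(df, "binomial-logit")

    def test_separation_flags_nonconvergence(self):
        df = paired_long([(1, 0)] * 12)  # all positive -> all negative
        res = gee_fit(df, "binomial-logit")
        assert not res.converged

    def test_agreement_with_reference_gee_implementation(self):
        """Coefficients and robust SEs match statsmodels GEE (independence
        working correlation, robust covariance) on simulated datasets."""
        import statsmodels.api as sm
        from alkcheck.cohort_sim import paired_binary_study

        for rep in range(50):
            df = paired_binary_study(60, 0.6, 0.7, seed=400 + rep, n_classes=12)
            mine = gee_fit(df, "binomial-logit")
            ref = sm.GEE(
                df["value"],
                sm.add_constant(df["time"].astype(float)),
                groups=df["class_id"],
                family=sm.families.Binomial(),
                cov_struct=sm.cov_struct.Independence(),
            ).fit()
            assert mine.intercept == pytest.approx(ref.params.iloc[0], abs=1e-6)
            assert mine.time_coef == pytest.approx(ref.params.iloc[1], abs=1e-6)
            assert mine.robust_se == pytest.approx(ref.bse.iloc[1], abs=1e-6)


class TestChiSquare:
    def test_perfect_independence(self):
        stat, df, p = chi_square_test([[5, 5], [5, 5]])
        assert stat == 0.0 and p == 1.0

    def test_diagonal_table_hand_computation(self):
        stat, df, p = chi_square_test([[10, 0], [0, 10]])
        assert stat == pytest.approx(20.0)  # sum (O-E)^2/E with E=5
        assert df == 1

    def test_degrees_of_freedom_for_2x3(self):
        _, df, _ = chi_square_test([[3, 4, 5], [6, 2, 1]])
        assert df == 2

    def test_degenerate_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            chi_square_test([[0, 0], [5, 5]])

    def test_matches_scipy_on_random_tables(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            shape = rng.integers(2, 5, size=2)
            table = rng.integers(1, 40, size=shape)
            stat, df, p = chi_square_test(table)
            ref = sps.chi2_contingency(table, correction=False)
            assert stat == pytest.approx(ref.statistic, abs=1e-8)
            assert p == pytest.approx(ref.pvalue, abs=1e-8)


class TestMannWhitney:
    def test_complete_separation_gives_zero(self):
        u, _ = mann_whitney_u([1, 2], [3, 4])
        assert u == 0.0

    def test_direct_pair_counting(self):
        u, _ = mann_whitney_u([1, 3], [2, 4])
        assert u == 1.0

    def test_exact_p_equals_permutation_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            nx, ny = rng.integers(2, 6, size=2)
            x = rng.integers(0, 6, nx).astype(float)
            y = rng.integers(0, 6, ny).astype(float)
            u_obs, p = mann_whitney_u(x, y)
            # oracle: enumerate every C(nx+ny, nx) labeling of the pooled data
            pooled = np.concatenate([x, y])
            ranks = sps.rankdata(pooled)
            mid = nx * ny / 2
            obs_ux = ranks[:nx].sum() - nx * (nx + 1) / 2
            hits = total = 0
            for idx in itertools.combinations(range(nx + ny), nx):
                ux = ranks[list(idx)].sum() - nx * (nx + 1) / 2
                total += 1
                hits += abs(ux - mid) >= abs(obs_ux - mid) - 1e-12
            assert p == pytest.approx(hits / total, abs=1e-12)

    def test_matches_scipy_asymptotic_with_ties(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            nx, ny = rng.integers(8, 30, size=2)
            x = rng.integers(0, 8, nx).astype(float)
            y = rng.integers(0, 10, ny).astype(float)
            _, p = mann_whitney_u(x, y)
            ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
            assert p == pytest.approx(ref.pvalue, abs=1e-8)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1])


class TestEvaluateOutcomes:
    def test_five_models_with_expected_families(self, outcome_data):
        # build a single long frame with one column per outcome
        long = None
        for name, df in outcome_data.items():
            part = df.rename(columns={"value": name})
            long = part if long is None else long.merge(
                part, on=["person_id", "class_id", "time"], how="outer"
            )
        results = evaluate_outcomes(long)
        assert set(results) == {
            "any_rsod", "frequent_rsod", "weekly_drinks", "max_drinks", "any_problem",
        }
        assert results["any_rsod"].family == "binomial-logit"
        assert results["weekly_drinks"].family == "poisson-log"
        assert all(r.n_clusters == 36 for r in results.values())
        # decreasing outcomes give effects below 1
        assert all(r.effect < 1 for r in results.values())
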