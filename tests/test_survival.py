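"""Survival machinery: product-limit arithmetic, log-rank behaviour, the
Cox fit against a brute-force partial-likelihood oracle, concordance
against pair enumeration, bootstrap CIs and mean-hazard dichotomisation."""

import numpy as np
import pandas as pd
import pytest
from lifelines.utils import concordance_index as lifelines_cindex

from pelscore.survival import (
    bootstrap_cindex,
    concordance_index,
    cox_fit,
    dichotomize_by_mean_hazard,
    km_estimate,
    logrank_test,
    multivariate_table,
    univariate_table,
)


class TestKaplanMeier:
    def test_all_events_no_censoring(self):
        km = km_estimate([1, 2, 3, 4], [1, 1, 1, 1]).set_index("time")
        assert km.loc[2.0, "survival"] == pytest.approx(0.5)

    def test_all_censored_survival_stays_one(self):
        km = km_estimate([1, 2, 3], [0, 0, 0])
        assert (km["survival"] == 1.0).all()

    def test_hand_product_limit_six_subjects(self):
        # times 1,2*,3,4,5*,6 (star = censored)
        km = km_estimate([1, 2, 3, 4, 5, 6], [1, 0, 1, 1, 0, 1]).set_index("time")
        # S(1)=5/6; S(3)=5/6*3/4; S(4)=...*2/3; S(6)=...*0
        assert km.loc[1.0, "survival"] == pytest.approx(5 / 6)
        assert km.loc[3.0, "survival"] == pytest.approx(5 / 6 * 3 / 4)
        assert km.loc[4.0, "survival"] == pytest.approx(5 / 6 * 3 / 4 * 2 / 3)
        assert km.loc[6.0, "survival"] == pytest.approx(0.0)

    def test_no_censoring_equals_empirical_survival(self, rng):
        t = rng.exponential(2.0, 50)
        km = km_estimate(t, np.ones(50, dtype=int))
        for time, s in zip(km["time"], km["survival"]):
            assert s == pytest.approx((t > time).mean())

    def test_nonincreasing_and_starts_at_one(self, rng):
        t = rng.exponential(2.0, 40)
        e = rng.integers(0, 2, 40)
        e[0] = 1
        km = km_estimate(t, e)
        assert (np.diff(km["survival"]) <= 1e-12).all()
        assert km["survival"].iloc[0] <= 1.0


class TestLogRank:
    def test_identical_groups_statistic_zero(self):
        t = [1.0, 2.0, 3.0, 4.0] * 2
        e = [1, 1, 0, 1] * 2
        g = [0] * 4 + [1] * 4
        chi2, p = logrank_test(t, e, g)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_power_under_rate_ratio_three(self, rng):
        hits = 0
        for _ in range(40):
            t = np.concatenate([rng.exponential(1.0, 200), rng.exponential(3.0, 200)])
            e = np.ones(400, dtype=int)
            g = np.repeat([0, 1], 200)
            _, p = logrank_test(t, e, g)
            hits += p < 0.01
        assert hits >= 38  # >= 95% power

    def test_empty_group_and_no_events_rejected(self):
        with pytest.raises(ValueError, match="two groups"):
            logrank_test([1, 2], [1, 1], [0, 0])
        with pytest.raises(ValueError, match="event"):
            logrank_test([1, 2], [0, 0], [0, 1])


def brute_force_cox_beta(df, grid=None):
    """1-D grid maximisation of the Breslow partial likelihood (no ties in
    the fixtures, so Efron and Breslow coincide)."""
    t = df["time"].to_numpy()
    e = df["event"].to_numpy()
    x = df["x"].to_numpy()

    def log_pl(beta):
        ll = 0.0
        for i in np.flatnonzero(e == 1):
            risk = t >= t[i]
            ll += beta * x[i] - np.log(np.exp(beta * x[risk]).sum())
        return ll

    grid = np.linspace(-4, 4, 8001) if grid is None else grid
    vals = [log_pl(b) for b in grid]
    return grid[int(np.argmax(vals))]


class TestCoxFit:
    def _binary_eight(self):
        return pd.DataFrame(
            {
                "time": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0],
                "event": [1, 1, 1, 0, 1, 1, 0, 1],
                "x": [1, 1, 0, 1, 0, 1, 0, 0],
            }
        )

    def test_matches_brute_force_partial_likelihood(self):
        df = self._binary_eight()
        fit = cox_fit(df, ["x"], standardize=False)
        assert fit.converged
        beta_oracle = brute_force_cox_beta(df)
        assert fit.summary["beta"].iloc[0] == pytest.approx(beta_oracle, abs=1e-3)

    def test_sign_matches_logrank_observed_minus_expected(self, rng):
        """With a binary covariate and no ties, sign(beta) follows the
        direction of the group contrast."""
        t = np.concatenate([rng.exponential(1.0, 30), rng.exponential(3.0, 30)])
        df = pd.DataFrame(
            {"time": t, "event": 1, "x": np.repeat([1, 0], 30)}
        )
        fit = cox_fit(df, ["x"], standardize=False)
        assert fit.summary["beta"].iloc[0] > 0  # x=1 group dies faster

    def test_null_covariate_beta_small_p_uniform(self, rng):
        ps = []
        for _ in range(40):
            df = pd.DataFrame(
                {
                    "time": rng.exponential(5.0, 120),
                    "event": rng.integers(0, 2, 120),
                    "x": rng.normal(size=120),
                }
            )
            fit = cox_fit(df, ["x"])
            ps.append(fit.summary["p"].iloc[0])
        assert 0.2 < np.mean(np.asarray(ps) < 0.5) < 0.8  # roughly uniform
        assert np.mean(np.asarray(ps) < 0.05) <= 0.2

    def test_hr_and_ci_consistent_with_beta(self):
        df = self._binary_eight()
        fit = cox_fit(df, ["x"], standardize=False)
        row = fit.summary.iloc[0]
        assert row["hr"] == pytest.approx(np.exp(row["beta"]))
        assert row["ci_lower"] <= row["hr"] <= row["ci_upper"]

    def test_too_few_events_rejected(self):
        df = pd.DataFrame({"time": [1.0, 2.0], "event": [1, 0], "x": [0.0, 1.0]})
        with pytest.raises(ValueError, match="events"):
            cox_fit(df, ["x"])

    def test_perfect_separation_flagged_not_silent(self):
        # covariate orders survival perfectly -> monotone likelihood
        df = pd.DataFrame(
            {
                "time": np.arange(1.0, 13.0),
                "event": 1,
                "x": -np.arange(12.0),
            }
        )
        fit = cox_fit(df, ["x"])
        # either flagged non-converged or finite with a huge SE; never a
        # silently confident estimate
        if fit.converged:
            assert fit.summary["se"].iloc[0] > 1.0


class TestConcordance:
    def test_perfect_and_constant_risk(self):
        t = np.array([5.0, 4.0, 3.0, 2.0, 1.0])
        e = np.ones(5, dtype=int)
        assert concordance_index(-t, t, e) == 1.0
        assert concordance_index(np.zeros(5), t, e) == 0.5

    def test_matches_pair_enumeration(self, rng):
        for _ in range(20):
            n = 25
            t = rng.exponential(1.0, n)
            e = rng.integers(0, 2, n)
            r = rng.normal(size=n)
            if not ((t[:, None] < t[None, :]) & (e[:, None] == 1)).any():
                continue
            num = den = 0.0
            for i in range(n):
                for j in range(n):
                    if t[i] < t[j] and e[i] == 1:
                        den += 1
                        num += 1.0 if r[i] > r[j] else (0.5 if r[i] == r[j] else 0.0)
            assert concordance_index(r, t, e) == pytest.approx(num / den)

    def test_agrees_with_lifelines_when_no_tied_times(self, rng):
        t = rng.exponential(1.0, 60)  # continuous -> no ties
        e = rng.integers(0, 2, 60)
        e[:5] = 1
        r = rng.normal(size=60)
        mine = concordance_index(r, t, e)
        ref = lifelines_cindex(t, -r, e)
        assert mine == pytest.approx(ref)

    def test_invariant_under_monotone_transform(self, rng):
        t = rng.exponential(1.0, 40)
        e = rng.integers(0, 2, 40)
        e[0] = 1
        r = rng.normal(size=40)
        assert concordance_index(r, t, e) == concordance_index(np.exp(3 * r), t, e)

    def test_no_comparable_pairs_flagged(self):
        with pytest.raises(ValueError, match="comparable"):
            concordance_index([1.0, 2.0], [3.0, 3.0], [0, 0])


@pytest.fixture(scope="module")
def coupled_data():
    rng = np.random.default_rng(12)
    n = 80
    x = rng.normal(size=n)
    t = rng.exponential(np.exp(-0.9 * x))
    c = np.full(n, 2.0)
    return pd.DataFrame(
        {
            "time": np.minimum(t, c),
            "event": (t <= c).astype(int),
            "x": x,
            "noise": rng.normal(size=n),
        }
    )


class TestBootstrapCindex:
    def test_fixed_seed_reproducible(self, coupled_data):
        a = bootstrap_cindex(coupled_data, ["x"], n_bootstrap=150, seed=3)
        b = bootstrap_cindex(coupled_data, ["x"], n_bootstrap=150, seed=3)
        assert a == b

    def test_perfect_predictor_upper_ci_one(self):
        df = pd.DataFrame(
            {"time": np.arange(1.0, 31.0), "event": 1, "x": -np.arange(30.0)}
        )
        # risk = -time exactly reverses survival order on every resample;
        # fit may or may not converge, so score the feature directly
        c = concordance_index(df["x"].to_numpy(), df["time"], df["event"])
        assert c == 1.0

    def test_ci_brackets_point_estimate(self, coupled_data):
        c, (lo, hi) = bootstrap_cindex(coupled_data, ["x"], n_bootstrap=200, seed=1)
        assert lo <= c <= hi
        assert 0.5 < c <= 1.0

    def test_too_few_resamples_rejected(self, coupled_data):
        with pytest.raises(ValueError, match="n_bootstrap"):
            bootstrap_cindex(coupled_data, ["x"], n_bootstrap=50, seed=0)


class TestDichotomize:
    def test_two_two_split_on_hand_scores(self):
        # engineer linear predictors giving hazard {e^0,e^0,e^1,e^1}:
        # cutoff between the two levels -> 2/2 split
        rng = np.random.default_rng(5)
        x = np.repeat([0.0, 1.0], 20)
        t = rng.exponential(np.exp(-1.5 * x))
        df = pd.DataFrame({"time": t, "event": 1, "x": x})
        fit = cox_fit(df, ["x"], standardize=False)
        res = dichotomize_by_mean_hazard(fit, df, ["x"], standardize=False)
        assert res["n_high"] == 20 and res["n_low"] == 20
        assert res["logrank_p"] < 0.05

    def test_constant_scores_degenerate_flagged(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame(
            {"time": rng.exponential(1, 30), "event": 1, "x": rng.normal(size=30)}
        )
        fit = cox_fit(df, ["x"])
        df2 = df.assign(x=0.0)
        res = dichotomize_by_mean_hazard(fit, df2, ["x"])
        assert res["degenerate"]
        assert np.isnan(res["logrank_p"])

    def test_strong_effect_separates_km_curves(self, coupled_data):
        fit = cox_fit(coupled_data, ["x"])
        res = dichotomize_by_mean_hazard(fit, coupled_data, ["x"])
        assert not res["degenerate"]
        sub = coupled_data.dropna()
        km_hi = km_estimate(
            sub["time"][res["high_risk"]], sub["event"][res["high_risk"]]
        )
        km_lo = km_estimate(
            sub["time"][~res["high_risk"]], sub["event"][~res["high_risk"]]
        )
        # high-risk curve lies below at the median follow-up
        tmid = sub["time"].median()
        s_hi = km_hi[km_hi["time"] <= tmid]["survival"].min()
        s_lo = km_lo[km_lo["time"] <= tmid]["survival"].min()
        assert s_hi < s_lo


class TestTables:
    def test_univariate_table_shape_and_flags(self, coupled_data):
        out = univariate_table(coupled_data, ["x", "noise"], n_bootstrap=120, seed=0)
        assert list(out["feature"]) == ["x", "noise"]
        assert out["testable"].all()
        x_row = out.set_index("feature").loc["x"]
        assert x_row["ci_lower"] <= x_row["cindex"] <= x_row["ci_upper"]
        assert x_row["cindex"] > out.set_index("feature").loc["noise", "cindex"]

    def test_multivariate_returns_hr_rows_with_cis(self, coupled_data):
        out = multivariate_table(coupled_data, ["x", "noise"], n_bootstrap=120, seed=0)
        assert len(out["summary"]) == 2
        assert (out["summary"]["ci_lower"] <= out["summary"]["hr"]).all()
        assert (out["summary"]["hr"] <= out["summary"]["ci_upper"]).all()
        assert 0 <= out["cindex"] <= 1

    def test_adding_noise_feature_barely_moves_model_c(self, coupled_data):
        solo = multivariate_table(coupled_data, ["x"], n_bootstrap=120, seed=0)
        both = multivariate_table(coupled_data, ["x", "noise"], n_bootstrap=120, seed=0)
        assert abs(solo["cindex"] - both["cindex"]) < 0.03
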