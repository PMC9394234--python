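"""Kaplan–Meier, Cox and maximally-selected-rank cutpoint behaviour."""

import numpy as np
import pandas as pd
import pytest

from clonefish import corr_marker_vs_feature, cox_fit, km_rfs, max_rank_cutoff


def surv_df(times, events, groups=None, **extra):
    df = pd.DataFrame({"time_years": times, "event": events})
    if groups is not None:
        df["group"] = groups
    for k, v in extra.items():
        df[k] = v
    return df


def product_limit(times, events, t):
    """Hand product-limit oracle for small fixtures."""
    s = 1.0
    order = np.argsort(times)
    at_risk = len(times)
    for i in order:
        if times[i] > t:
            break
        if events[i]:
            s *= 1 - 1 / at_risk
        at_risk -= 1
    return s


class TestKaplanMeier:
    def test_no_events_survival_stays_one(self):
        out = km_rfs(surv_df([1, 2, 3], [0, 0, 0], ["g"] * 3))
        assert out["rfs_at"]["g"][5.0] == 100.0
        assert out["degenerate"]

    def test_hand_product_limit_fixture(self):
        # censored at 1, events at 2 and 3: S(2) = 1/2, S(3) = 0
        out = km_rfs(
            surv_df([1, 2, 3], [0, 1, 1], ["g"] * 3), horizons=(2.0, 3.0)
        )
        assert out["rfs_at"]["g"][2.0] == pytest.approx(50.0)
        assert out["rfs_at"]["g"][3.0] == pytest.approx(0.0)

    @pytest.mark.parametrize("n", [4, 5, 6])
    def test_estimator_matches_oracle_on_small_fixtures(self, n, rng):
        times = rng.uniform(0.5, 10, n).round(2)
        events = rng.integers(0, 2, n)
        if events.sum() == 0:
            events[0] = 1
        out = km_rfs(surv_df(times, events, ["g"] * n), horizons=(4.0, 8.0))
        for t in (4.0, 8.0):
            assert out["rfs_at"]["g"][t] == pytest.approx(
                100 * product_limit(times, events, t)
            )

    def test_strong_hazard_ratio_detected_by_logrank(self, rng):
        hits = 0
        for seed in range(40):
            # ~40% censoring overall at these rates and follow-up window
            r = np.random.default_rng(seed)
            t_fav = r.exponential(1 / 0.05, 33)
            t_unf = r.exponential(1 / (0.05 * 11), 17)
            cens = r.uniform(0, 30, 50)
            times = np.concatenate([t_fav, t_unf])
            events = (times <= cens).astype(int)
            times = np.minimum(times, cens)
            out = km_rfs(surv_df(times, events, ["fav"] * 33 + ["unf"] * 17))
            hits += out["logrank_p"] < 0.001
        assert hits / 40 >= 0.95

    def test_logrank_invariant_to_time_rescaling(self, rng):
        times = rng.exponential(5, 40)
        events = rng.integers(0, 2, 40)
        groups = ["a"] * 20 + ["b"] * 20
        p_years = km_rfs(surv_df(times, events, groups))["logrank_p"]
        p_days = km_rfs(surv_df(times * 365.25, events, groups))["logrank_p"]
        assert p_years == pytest.approx(p_days, rel=1e-9)


class TestCox:
    def test_independent_covariate_hr_near_one(self, rng):
        n = 300
        df = surv_df(
            rng.exponential(5, n), rng.integers(0, 2, n), x=rng.normal(size=n)
        )
        res = cox_fit(df, ["x"], mode="univariate")
        row = res.table.iloc[0]
        assert row.ci_low < 1 < row.ci_high

    def test_planted_hr_recovered(self, rng):
        n = 500
        x = rng.integers(0, 2, n)
        lam = 0.1 * np.exp(np.log(3) * x)
        times = rng.exponential(1 / lam)
        cens = rng.uniform(0, 30, n)
        df = surv_df(np.minimum(times, cens), (times <= cens).astype(int), x=x)
        res = cox_fit(df, ["x"])
        row = res.table.iloc[0]
        assert row.ci_low <= 3.0 <= row.ci_high
        assert res.hr("x") == pytest.approx(3.0, rel=0.35)

    def test_age_entered_per_five_years(self, rng):
        n = 400
        age = rng.uniform(1, 15, n)
        lam = 0.05 * np.exp(0.1 * age)  # log-HR 0.1 per year = 0.5 per 5 years
        times = rng.exponential(1 / lam)
        df = surv_df(times, np.ones(n, dtype=int), age=age)
        res = cox_fit(df, ["age"])
        assert res.table.covariate.iloc[0] == "age_per5y"
        assert np.log(res.hr("age_per5y")) == pytest.approx(0.5, abs=0.15)

    def test_protocol_reference_excluded(self, rng):
        n = 200
        df = surv_df(
            rng.exponential(5, n),
            rng.integers(0, 2, n),
            protocol=rng.choice(["PETHEMA", "SHOP", "UKALL2003"], n),
        )
        res = cox_fit(df, ["protocol"])
        assert "protocol_PETHEMA" not in set(res.table.covariate)
        assert {"protocol_SHOP", "protocol_UKALL2003"} <= set(res.table.covariate)

    def test_zero_events_explicit_failure(self):
        df = surv_df([1, 2, 3, 4], [0, 0, 0, 0], x=[0, 1, 0, 1])
        with pytest.raises(ValueError, match="no events"):
            cox_fit(df, ["x"])

    def test_consistency_with_growing_n(self):
        biases = []
        for n in (100, 500, 2000):
            errs = []
            for seed in range(10):
                r = np.random.default_rng(seed)
                x = r.integers(0, 2, n)
                times = r.exponential(1 / (0.1 * np.exp(np.log(3) * x)))
                df = surv_df(times, np.ones(n, dtype=int), x=x)
                errs.append(np.log(cox_fit(df, ["x"]).hr("x")) - np.log(3))
            biases.append(abs(np.mean(errs)))
        assert biases[2] < biases[0] + 0.02  # bias shrinks (allow MC slack)


class TestMaxRankCutoff:
    def _planted(self, rng, n=200, cut=50.0):
        marker = rng.uniform(0, 100, n)
        lam = np.where(marker > cut, 0.4, 0.05)
        times = rng.exponential(1 / lam)
        cens = rng.uniform(5, 15, n)
        df = surv_df(np.minimum(times, cens), (times <= cens).astype(int))
        return marker, df

    def test_planted_changepoint_recovered(self, rng):
        marker, df = self._planted(rng)
        out = max_rank_cutoff(marker, df)
        assert abs(out["cutpoint"] - 50.0) < 5.0
        assert not out["unstable"]

    def test_independent_marker_flagged_unstable(self, rng):
        n = 100
        df = surv_df(rng.exponential(5, n), rng.integers(0, 2, n))
        # maximally selected statistics overfit; use held-out-style threshold
        out = max_rank_cutoff(rng.uniform(0, 100, n), df)
        assert out["statistic"] < 3.5  # well below any planted-effect scale

    def test_cutpoints_restricted_to_inner_quantiles(self, rng):
        marker, df = self._planted(rng)
        out = max_rank_cutoff(marker, df)
        lo, hi = np.quantile(marker, [0.10, 0.90])
        assert (out["profile"].cutpoint >= lo).all()
        assert (out["profile"].cutpoint <= hi).all()

    def test_grid_outside_data_range_rejected(self, rng):
        marker, df = self._planted(rng, n=50)
        with pytest.raises(ValueError):
            max_rank_cutoff(marker, df, candidates=[-10.0, 50.0])


class TestCorrelation:
    def test_perfect_antimonotone_rank_minus_one(self):
        x = [1, 2, 3, 4, 5]
        y = [10, 8, 7, 3, 1]
        r, _ = corr_marker_vs_feature(x, y)
        assert r == pytest.approx(-1.0)

    def test_independent_pairs_p_uniform_under_permutation(self, rng):
        # permutation oracle: the observed |rho| should not be extreme
        x = rng.normal(size=40)
        y = rng.normal(size=40)
        r_obs, p = corr_marker_vs_feature(x, y)
        perm = [
            corr_marker_vs_feature(x, rng.permutation(y))[0] for _ in range(200)
        ]
        frac_larger = np.mean([abs(r) >= abs(r_obs) for r in perm])
        assert abs(frac_larger - p) < 0.15

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            corr_marker_vs_feature([1, 1, 1], [1, 2, 3])
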