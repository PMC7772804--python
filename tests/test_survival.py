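import numpy as np
import pandas as pd
import pytest

from coxis import ClinicalTable, CoxisError
from coxis.survival import (
    cox_fit,
    km_estimate,
    logrank_test,
    optimal_cutoff,
    stratify,
)
from oracles import hand_km, logrank_chi2, permutation_logrank


def _clinical(times, events, **cols):
    idx = [f"s{i}" for i in range(len(times))]
    return ClinicalTable(data=pd.DataFrame(
        {"os_time": times, "os_event": events, **cols}, index=idx))


class TestStratify:
    def test_median_split(self):
        s = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        res = stratify(s, mode="median")
        assert list(res.labels) == ["low", "low", "high", "high"]
        assert res.group_sizes == {"low": 2, "high": 2}

    def test_ties_at_cutoff_go_low(self):
        s = pd.Series([1.0, 1.0, 1.0, 2.0], index=list("abcd"))
        res = stratify(s, mode="median")  # median = 1
        assert list(res.labels) == ["low", "low", "low", "high"]

    def test_q25_q75(self):
        s = pd.Series(np.arange(1.0, 9.0))
        assert (stratify(s, mode="q25").labels == "high").sum() == 6
        assert (stratify(s, mode="q75").labels == "high").sum() == 2

    def test_quantile_groups_near_equal(self, rng):
        s = pd.Series(rng.uniform(size=103))
        res = stratify(s, k_quantiles=4)
        sizes = sorted(res.group_sizes.values())
        assert max(sizes) - min(sizes) <= 1
        assert sum(sizes) == 103

    def test_quantile_groups_ordered_by_score(self, rng):
        s = pd.Series(rng.normal(size=40))
        res = stratify(s, k_quantiles=4)
        assert s[res.labels == "q1"].max() <= s[res.labels == "q4"].min()

    def test_insufficient_n(self):
        with pytest.raises(CoxisError):
            stratify(pd.Series([1.0, 2.0, 3.0]), mode="median")
        with pytest.raises(CoxisError):
            stratify(pd.Series(np.arange(5.0)), k_quantiles=3)


class TestKaplanMeier:
    def test_no_events(self):
        curve = km_estimate([1.0, 2.0, 3.0], [0, 0, 0])
        assert np.all(curve.survival == 1.0)
        assert np.isnan(curve.median)

    def test_single_event_of_four(self):
        curve = km_estimate([5.0, 2.0, 3.0, 4.0], [0, 1, 0, 0])
        assert curve.at(2.0) == pytest.approx(0.75)
        assert curve.at(1.5) == pytest.approx(1.0)

    def test_mixed_censoring_matches_hand_product_limit(self):
        """6 observations with an event and a censoring at the same time:
        S = 5/6 (t=1), 2/3 (t=2), 4/9 (t=3), 0 (t=5); median at t=3."""
        times = [1.0, 2.0, 2.0, 3.0, 4.0, 5.0]
        events = [1, 0, 1, 1, 0, 1]
        curve = km_estimate(times, events)
        ht, hs = hand_km(times, events)
        np.testing.assert_allclose(hs, [5 / 6, 2 / 3, 4 / 9, 0.0], atol=1e-15)
        for tk, sk in zip(ht, hs):
            assert curve.at(tk) == pytest.approx(sk, abs=1e-12)
        assert curve.median == pytest.approx(3.0)

    def test_curve_monotone_in_unit_interval(self, rng):
        t = rng.exponential(2.0, 50)
        e = (rng.uniform(size=50) < 0.7).astype(int)
        curve = km_estimate(t, e)
        assert curve.survival[0] == 1.0 or curve.times[0] == 0.0
        assert np.all(np.diff(curve.survival) <= 1e-12)
        assert np.all((curve.survival >= 0) & (curve.survival <= 1))

    def test_empty_rejected(self):
        with pytest.raises(CoxisError):
            km_estimate([], [])


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        t = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        e = [1, 1, 0, 1, 1, 0]
        g = [0, 0, 0, 1, 1, 1]
        res = logrank_test(t, e, g)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_statistic_matches_hand_summation(self, rng):
        t = rng.exponential(2.0, 30)
        e = (rng.uniform(size=30) < 0.8).astype(int)
        g = rng.integers(0, 2, 30)
        res = logrank_test(t, e, g)
        assert res.statistic == pytest.approx(logrank_chi2(t, e, g == 1), abs=1e-9)

    def test_label_swap_invariance(self, rng):
        t = rng.exponential(2.0, 24)
        e = (rng.uniform(size=24) < 0.8).astype(int)
        g = rng.integers(0, 2, 24)
        a = logrank_test(t, e, g)
        b = logrank_test(t, e, 1 - g)
        assert a.statistic == pytest.approx(b.statistic, abs=1e-10)

    def test_time_unit_invariance(self, rng):
        t = rng.exponential(2.0, 24)
        e = (rng.uniform(size=24) < 0.8).astype(int)
        g = rng.integers(0, 2, 24)
        a = logrank_test(t, e, g)
        b = logrank_test(t * 365.25, e, g)
        assert a.p_value == pytest.approx(b.p_value, abs=1e-12)

    def test_agreement_with_permutation_reference(self, rng):
        """The analytic statistic must equal the permutation oracle's exactly;
        the chi-square p tracks the exact permutation p to within the
        asymptotic approximation's small-sample accuracy (~0.05 at n<=14)."""
        for _ in range(5):
            n = int(rng.integers(10, 15))
            t = rng.exponential(2.0, n) + 0.01
            e = (rng.uniform(size=n) < 0.8).astype(int)
            if e.sum() == 0:
                e[0] = 1
            g = np.zeros(n, dtype=int)
            g[rng.permutation(n)[: n // 2]] = 1
            res = logrank_test(t, e, g)
            obs, p_perm = permutation_logrank(t, e, g, 20_000, rng)
            assert res.statistic == pytest.approx(obs, abs=1e-10)
            assert abs(res.p_value - p_perm) < 0.05

    def test_k_group_power_on_planted_effect(self, rng):
        """Hazard multiplying by 1.5 per quantile step, n=400: the 4-group
        log-rank test should be decisive."""
        n = 400
        score = rng.normal(size=n)
        s = pd.Series(score, index=[f"s{i}" for i in range(n)])
        res = stratify(s, k_quantiles=4)
        grp_idx = res.labels.str.lstrip("q").astype(int).to_numpy()
        hazard = 0.2 * 1.5 ** (grp_idx - 1)
        t = rng.exponential(1.0 / hazard)
        e = np.ones(n, dtype=int)
        lr = logrank_test(t, e, res.labels.to_numpy())
        assert lr.df == 3
        assert lr.p_value < 0.001

    def test_single_group_rejected(self):
        with pytest.raises(CoxisError):
            logrank_test([1.0, 2.0], [1, 1], [0, 0])


class TestOptimalCutoff:
    def test_reported_minimum_matches_table(self, rng):
        n = 120
        s = pd.Series(rng.normal(size=n), index=[f"s{i}" for i in range(n)])
        t = rng.exponential(2.0, n)
        e = (rng.uniform(size=n) < 0.7).astype(int)
        cl = _clinical(t, e)
        res = optimal_cutoff(s, cl)
        assert res.candidate_pvalues is not None
        chosen_p = res.candidate_pvalues[{"q25": 0.25, "median": 0.50, "q75": 0.75}[res.cutoff_type]]
        assert chosen_p == min(res.candidate_pvalues.values())

    def test_planted_median_step_selects_median(self, rng):
        """Hazard steps by 2x exactly at the score median: the median split
        should win the log-rank comparison in nearly all cohorts."""
        wins = 0
        n_cohorts = 50
        for _ in range(n_cohorts):
            n = 300
            s = pd.Series(rng.normal(size=n), index=[f"s{i}" for i in range(n)])
            above = (s > s.median()).to_numpy()
            hazard = np.where(above, 0.4, 0.2)
            t = rng.exponential(1.0 / hazard)
            e = np.ones(n, dtype=int)
            res = optimal_cutoff(s, _clinical(t, e))
            wins += res.cutoff_type == "median"
        assert wins >= int(0.9 * n_cohorts)

    def test_null_survival_returns_minimum_anyway(self):
        n = 40
        s = pd.Series(np.arange(n, dtype=float), index=[f"s{i}" for i in range(n)])
        t = np.full(n, 5.0)
        t[::2] = 4.0  # two distinct times, identical in both arms by symmetry
        e = np.ones(n, dtype=int)
        res = optimal_cutoff(s, _clinical(t, e))
        assert res.candidate_pvalues
        assert min(res.candidate_pvalues.values()) > 0.2


class TestCoxFit:
    def test_duplicated_score_column_is_error(self, rng):
        n = 60
        t = rng.exponential(2.0, n)
        e = (rng.uniform(size=n) < 0.8).astype(int)
        score = rng.normal(size=n)
        cl = _clinical(t, e, twin=score)
        s = pd.Series(score, index=cl.data.index)
        with pytest.raises(CoxisError, match="collinear|rank"):
            cox_fit(cl, scores=s, score_name="score", covariates=("twin",))

    def test_hr_equals_exp_coef(self, rng):
        n = 150
        score = rng.normal(size=n)
        t = rng.exponential(1.0 / (0.2 * np.exp(0.7 * score)))
        e = np.ones(n, dtype=int)
        cl = _clinical(t, e)
        fit = cox_fit(cl, scores=pd.Series(score, index=cl.data.index),
                      score_name="score")
        row = fit.table.loc["score"]
        assert row["hr"] == pytest.approx(np.exp(row["coef"]), rel=1e-10)
        assert row["hr_low"] <= row["hr"] <= row["hr_high"]

    def test_univariate_hr_ranking_preserves_effect_order(self, rng):
        """Two planted effects (log-HR 0.3 vs 0.9) on disjoint scores: the
        stronger one should be estimated larger in nearly all replicates."""
        ok = 0
        reps = 20
        for _ in range(reps):
            n = 300
            s1 = rng.normal(size=n)
            s2 = rng.normal(size=n)
            t = rng.exponential(1.0 / (0.2 * np.exp(0.3 * s1 + 0.9 * s2)))
            e = np.ones(n, dtype=int)
            cl = _clinical(t, e)
            f1 = cox_fit(cl, scores=pd.Series(s1, index=cl.data.index), score_name="s")
            f2 = cox_fit(cl, scores=pd.Series(s2, index=cl.data.index), score_name="s")
            ok += f2.hr("s") > f1.hr("s")
        assert ok >= int(0.95 * reps)

    def test_missing_covariate_rows_dropped_and_counted(self, rng):
        n = 80
        t = rng.exponential(2.0, n)
        e = (rng.uniform(size=n) < 0.8).astype(int)
        age = rng.normal(60, 10, n)
        age[:5] = np.nan
        cl = _clinical(t, e, age=age)
        s = pd.Series(rng.normal(size=n), index=cl.data.index)
        fit = cox_fit(cl, scores=s, score_name="score", covariates=("age",))
        assert fit.n == n - 5
        assert fit.n_dropped_missing == 5

    def test_few_events_warns(self, rng):
        n = 40
        t = rng.exponential(2.0, n)
        e = np.zeros(n, dtype=int)
        e[:3] = 1
        cl = _clinical(t, e)
        s = pd.Series(rng.normal(size=n), index=cl.data.index)
        with pytest.warns(UserWarning, match="events"):
            cox_fit(cl, scores=s, score_name="score")
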