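import numpy as np
import pandas as pd
import pytest
from scipy import stats

from coxis import CoxisError, ResponseTable
from coxis.icb import (
    deviance_explained,
    logistic_fit,
    nested_model_test,
    pd_vs_cr_subset,
    pool_responses,
    roc_auc,
    signature_benchmark,
)
from coxis.scoring import ScoreTable
from oracles import allpairs_auc


def _resp(categories, **cols):
    idx = [f"s{i}" for i in range(len(categories))]
    return ResponseTable(data=pd.DataFrame({"category": categories, **cols}, index=idx))


class TestPoolResponses:
    @pytest.mark.parametrize("convention,sd_value", [("sd_nonresponder", 0),
                                                     ("sd_responder", 1)])
    def test_sd_pooling(self, convention, sd_value):
        r = _resp(["SD", "PD", "PR", "CR"])
        out = pool_responses(r, convention=convention)
        assert out.responder.loc["s0"] == sd_value
        assert out.responder.loc["s1"] == 0
        assert out.responder.loc["s2"] == 1
        assert out.responder.loc["s3"] == 1

    def test_ne_dropped_and_counted(self):
        r = _resp(["NE", "CR", "PD", "NE"])
        out = pool_responses(r)
        assert out.n_ne_dropped == 2
        assert len(out.responder) == 2

    def test_deterministic_pure_function(self):
        r = _resp(["SD", "PD", "PR", "CR", "NE"])
        a = pool_responses(r, "sd_responder").responder
        b = pool_responses(r, "sd_responder").responder
        pd.testing.assert_series_equal(a, b)

    def test_unknown_convention(self):
        with pytest.raises(CoxisError, match="convention"):
            pool_responses(_resp(["CR"]), convention="whatever")


class TestRocAuc:
    def test_perfect_separation_low_positive(self):
        scores = np.array([1.0, 2.0, 8.0, 9.0])
        labels = np.array([1, 1, 0, 0])
        assert roc_auc(scores, labels, low_score_is_positive=True) == 1.0
        assert roc_auc(scores, labels, low_score_is_positive=False) == 0.0

    def test_null_scores_near_half(self, rng):
        n = 4000
        scores = rng.normal(size=n)
        labels = rng.integers(0, 2, n)
        assert roc_auc(scores, labels) == pytest.approx(0.5, abs=0.05)

    def test_equals_allpairs_oracle(self, rng):
        """AUC must equal the brute-force all-pairs U/(n1*n0) statistic,
        including tied scores counting one half."""
        for _ in range(50):
            n = int(rng.integers(6, 50))
            scores = rng.integers(0, 8, n).astype(float)  # many ties
            labels = np.zeros(n, dtype=int)
            labels[rng.permutation(n)[: int(rng.integers(2, n - 1))]] = 1
            if labels.sum() in (0, n):
                continue
            assert roc_auc(scores, labels) == pytest.approx(
                allpairs_auc(scores, labels), abs=1e-12)

    def test_flip_complement_when_no_ties(self, rng):
        scores = rng.permutation(np.arange(20, dtype=float))
        labels = np.array([0, 1] * 10)
        a = roc_auc(scores, labels, low_score_is_positive=False)
        b = roc_auc(scores, labels, low_score_is_positive=True)
        assert a + b == pytest.approx(1.0, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(CoxisError):
            roc_auc(np.array([1.0, 2.0]), np.array([1, 1]))


class TestPdVsCr:
    def test_subset_and_counts(self):
        r = _resp(["PD"] * 3 + ["CR"] * 2 + ["SD"] * 4)
        sub, counts = pd_vs_cr_subset(r)
        assert len(sub.data) == 5
        assert counts == {"PD": 3, "CR": 2, "dropped": 4}

    def test_missing_class_rejected(self):
        with pytest.raises(CoxisError):
            pd_vs_cr_subset(_resp(["PD", "SD"]))


class TestLogisticFit:
    def test_intercept_only_residual_equals_null(self, rng):
        y = pd.Series(rng.integers(0, 2, 50).astype(float))
        fit = logistic_fit(y, None)
        assert fit.deviance == pytest.approx(fit.null_deviance, rel=1e-10)
        assert deviance_explained(fit) == pytest.approx(0.0, abs=1e-10)

    def test_constant_column_rejected_as_collinear(self, rng):
        y = pd.Series(rng.integers(0, 2, 50).astype(float))
        X = pd.DataFrame({"const_col": np.ones(50)})
        with pytest.raises(CoxisError, match="collinear"):
            logistic_fit(y, X)

    def test_parameter_recovery(self, rng):
        """Planted logistic coefficient 1.0 on a standardized score at n=400:
        the mean estimate over 20 replicates is close to truth."""
        estimates = []
        for _ in range(20):
            x = rng.normal(size=400)
            p = 1 / (1 + np.exp(-(-0.5 + 1.0 * x)))
            y = pd.Series(rng.binomial(1, p).astype(float))
            fit = logistic_fit(y, pd.DataFrame({"x": x}))
            estimates.append(fit.params["x"])
        assert np.mean(estimates) == pytest.approx(1.0, abs=0.2)

    def test_separation_is_error(self):
        x = np.concatenate([np.zeros(20), np.ones(20)])
        y = pd.Series(x.copy())
        with pytest.raises(CoxisError):
            logistic_fit(y, pd.DataFrame({"x": x}))

    def test_categorical_expansion(self, rng):
        y = pd.Series(rng.integers(0, 2, 90).astype(float))
        X = pd.DataFrame({"ic": rng.choice(["IC0", "IC1", "IC2+"], 90)})
        fit = logistic_fit(y, X)
        assert len(fit.design_columns) == 2  # drop-first indicators


class TestNestedModelTest:
    def _fit_pair(self, rng, n=200, true_coef=0.0):
        x = rng.normal(size=n)
        noise = rng.normal(size=n)
        p = 1 / (1 + np.exp(-(-0.3 + true_coef * x)))
        y = pd.Series(rng.binomial(1, p).astype(float))
        small = logistic_fit(y, pd.DataFrame({"x": x}))
        large = logistic_fit(y, pd.DataFrame({"x": x, "noise": noise}))
        return small, large

    def test_same_model_stat_zero_p_one(self, rng):
        small, _ = self._fit_pair(rng)
        stat, df, p = nested_model_test(small, small)
        assert stat == 0.0 and df == 0 and p == 1.0

    def test_statistic_nonnegative(self, rng):
        for _ in range(5):
            small, large = self._fit_pair(rng)
            stat, df, p = nested_model_test(small, large)
            assert stat >= 0.0 and df == 1 and 0.0 <= p <= 1.0

    def test_null_pvalues_uniform(self, rng):
        """Adding a pure-noise predictor: the chi-square p is U(0,1)."""
        pvals = []
        for _ in range(300):
            small, large = self._fit_pair(rng)
            pvals.append(nested_model_test(small, large)[2])
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_power_on_true_predictor(self, rng):
        """The added predictor actually drives the response at n=400:
        the nested test should detect it in nearly every replicate."""
        hits = 0
        reps = 25
        for _ in range(reps):
            n = 400
            x = rng.normal(size=n)
            p = 1 / (1 + np.exp(-(-0.3 + 0.8 * x)))
            y = pd.Series(rng.binomial(1, p).astype(float))
            small = logistic_fit(y, None)
            large = logistic_fit(y, pd.DataFrame({"x": x}))
            hits += nested_model_test(small, large)[2] < 0.01
        assert hits >= int(0.9 * reps)

    def test_non_nested_rejected(self, rng):
        n = 100
        y = pd.Series(rng.integers(0, 2, n).astype(float))
        a = logistic_fit(y, pd.DataFrame({"x": rng.normal(size=n)}))
        b = logistic_fit(y, pd.DataFrame({"z": rng.normal(size=n)}))
        with pytest.raises(CoxisError, match="nested"):
            nested_model_test(a, b)


class TestDevianceExplained:
    def test_matches_recomputation(self, rng):
        x = rng.normal(size=120)
        p = 1 / (1 + np.exp(-(0.2 + 1.5 * x)))
        y = pd.Series(rng.binomial(1, p).astype(float))
        fit = logistic_fit(y, pd.DataFrame({"x": x}))
        assert deviance_explained(fit) == pytest.approx(
            1 - fit.deviance / fit.null_deviance)
        assert 0.0 <= deviance_explained(fit) <= 1.0


class TestSignatureBenchmark:
    def _table(self, rng, n=80):
        idx = [f"s{i}" for i in range(n)]
        coxis = rng.uniform(0.5, 2.0, n)
        scores = pd.DataFrame({"COX-IS": coxis, "TWIN": coxis, "OTHER": rng.normal(size=n)},
                              index=idx)
        return ScoreTable(scores=scores), pd.Series(rng.integers(0, 2, n), index=idx)

    def test_duplicate_signature_identical_rows(self, rng):
        table, y = self._table(rng)
        bench = signature_benchmark(table, y,
                                    low_favorable={"COX-IS": True, "TWIN": True})
        assert bench.loc["COX-IS", "p"] == bench.loc["TWIN", "p"]
        assert bench.loc["COX-IS", "auc"] == bench.loc["TWIN", "auc"]

    def test_neglog10_consistent(self, rng):
        table, y = self._table(rng)
        bench = signature_benchmark(table, y)
        np.testing.assert_allclose(bench["neg_log10_p"],
                                   -np.log10(bench["p"]), atol=1e-12)

    def test_orientation_flips_auc(self, rng):
        table, y = self._table(rng)
        a = signature_benchmark(table, y, signatures=["OTHER"],
                                low_favorable={"OTHER": False})
        b = signature_benchmark(table, y, signatures=["OTHER"],
                                low_favorable={"OTHER": True})
        assert a.loc["OTHER", "auc"] + b.loc["OTHER", "auc"] == pytest.approx(1.0, abs=1e-9)
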