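import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from vrdot.prediction import (
    DegenerateDesignError,
    DomainError,
    backward_stepwise,
    classify,
    fit_logistic,
    nagelkerke_r2,
)


def _binary_2x2(n11=10, n10=5, n01=4, n00=20):
    """x=1: n11 events / n10 non-events; x=0: n01 / n00."""
    x = np.array([1.0] * (n11 + n10) + [0.0] * (n01 + n00))
    y = np.array([1.0] * n11 + [0.0] * n10 + [1.0] * n01 + [0.0] * n00)
    return pd.DataFrame({"x": x}), y


class TestFitLogistic:
    def test_intercept_only_recovers_prevalence(self):
        y = np.array([1.0] * 3 + [0.0] * 7)
        X = pd.DataFrame(index=range(10))
        fit = fit_logistic(X, y)
        assert expit(fit.params["const"]) == pytest.approx(0.3, abs=1e-8)

    def test_binary_predictor_or_equals_cross_product(self):
        X, y = _binary_2x2(10, 5, 4, 20)
        fit = fit_logistic(X, y)
        assert fit.odds_ratios["x"] == pytest.approx((10 * 20) / (5 * 4), rel=1e-6)

    def test_coefficient_recovery_within_2se(self):
        rng = np.random.default_rng(13)
        n = 500
        x = rng.normal(size=n)
        p = expit(-1.0 + 0.8 * x)
        y = (rng.random(n) < p).astype(float)
        fit = fit_logistic(pd.DataFrame({"x": x}), y)
        assert abs(fit.params["const"] - (-1.0)) < 2 * fit.bse["const"]
        assert abs(fit.params["x"] - 0.8) < 2 * fit.bse["x"]

    def test_both_classes_required(self):
        with pytest.raises(DomainError):
            fit_logistic(pd.DataFrame({"x": [1.0, 2.0, 3.0]}), np.ones(3))

    def test_rank_deficiency_rejected(self):
        X = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [2.0, 4, 6, 8]})
        with pytest.raises(DegenerateDesignError):
            fit_logistic(X, np.array([0.0, 1, 0, 1]))

    def test_perfect_separation_flagged_not_raised(self):
        X = pd.DataFrame({"x": [-2.0, -1.0, 1.0, 2.0]})
        y = np.array([0.0, 0.0, 1.0, 1.0])
        fit = fit_logistic(X, y)
        assert fit.separation

    def test_firth_penalty_finite_under_separation(self):
        X = pd.DataFrame({"x": [-2.0, -1.0, 1.0, 2.0, -1.5, 1.5]})
        y = np.array([0.0, 0.0, 1.0, 1.0, 0.0, 1.0])
        fit = fit_logistic(X, y, penalty="firth")
        assert np.isfinite(fit.params["x"]) and abs(fit.params["x"]) < 20

    def test_deviance_never_increases_with_predictor(self):
        rng = np.random.default_rng(21)
        for seed in range(5):
            r = np.random.default_rng(seed)
            n = 80
            X = pd.DataFrame({"a": r.normal(size=n), "b": r.normal(size=n)})
            y = (r.random(n) < expit(0.5 * X.a)).astype(float)
            f1 = fit_logistic(X[["a"]], y)
            f2 = fit_logistic(X, y)
            assert f2.llf >= f1.llf - 1e-8


class TestNagelkerke:
    def test_null_model_zero(self):
        y = np.array([1.0] * 4 + [0.0] * 6)
        fit = fit_logistic(pd.DataFrame(index=range(10)), y)
        assert nagelkerke_r2(fit) == pytest.approx(0.0, abs=1e-10)

    def test_matches_direct_likelihood_evaluation(self):
        X, y = _binary_2x2(10, 5, 4, 20)
        fit = fit_logistic(X, y)
        # independent evaluation from the 2x2 closed-form fitted cells
        p1, p0 = 10 / 15, 4 / 24
        l1 = 10 * np.log(p1) + 5 * np.log(1 - p1) + 4 * np.log(p0) + 20 * np.log(1 - p0)
        prev = 14 / 39
        l0 = 39 * (prev * np.log(prev) + (1 - prev) * np.log(1 - prev))
        n = 39
        expected = (1 - np.exp(2 * (l0 - l1) / n)) / (1 - np.exp(2 * l0 / n))
        assert nagelkerke_r2(fit) == pytest.approx(expected, rel=1e-6)

    def test_invariant_to_predictor_rescaling(self):
        rng = np.random.default_rng(31)
        n = 120
        x = rng.normal(size=n)
        y = (rng.random(n) < expit(x)).astype(float)
        f1 = fit_logistic(pd.DataFrame({"x": x}), y)
        f2 = fit_logistic(pd.DataFrame({"x": 100 * x}), y)
        assert nagelkerke_r2(f1) == pytest.approx(nagelkerke_r2(f2), abs=1e-8)

    def test_near_perfect_fit_approaches_one(self):
        X = pd.DataFrame({"x": np.r_[np.zeros(20), np.ones(20)]})
        y = np.r_[np.zeros(20), np.ones(20)]
        fit = fit_logistic(X, y, penalty="firth")
        assert nagelkerke_r2(fit) > 0.9


class TestClassify:
    def test_intercept_only_majority_class(self):
        y = np.array([1.0] * 3 + [0.0] * 7)
        fit = fit_logistic(pd.DataFrame(index=range(10)), y)
        labels, pct = classify(fit, pd.DataFrame(index=range(10)), y)
        assert labels.sum() == 0
        assert pct == pytest.approx(70.0)

    def test_threshold_one_predicts_all_negative(self):
        X, y = _binary_2x2()
        fit = fit_logistic(X, y)
        labels, _ = classify(fit, X, y, threshold=1.0)
        assert labels.sum() == 0

    def test_separable_data_fully_classified(self):
        X = pd.DataFrame({"x": [-2.0, -1.0, 1.0, 2.0, -1.5, 1.5]})
        y = np.array([0.0, 0.0, 1.0, 1.0, 0.0, 1.0])
        fit = fit_logistic(X, y, penalty="firth")
        _, pct = classify(fit, X, y)
        assert pct == 100.0


class TestBackwardStepwise:
    @staticmethod
    def _sim(seed, n=400, beta=1.5, noise_cols=3):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame({"signal": rng.normal(size=n)})
        for j in range(noise_cols):
            X[f"noise{j}"] = rng.normal(size=n)
        y = (rng.random(n) < expit(-0.5 + beta * X.signal)).astype(float)
        return X, y

    def test_noise_predictors_mostly_removed(self):
        kept_signal, kept_noise = 0, 0
        reps = 40
        for seed in range(reps):
            X, y = self._sim(seed + 17)
            retained, _ = backward_stepwise(X, y, p_keep=0.10)
            kept_signal += "signal" in retained
            kept_noise += sum(1 for r in retained if r.startswith("noise"))
        assert kept_signal == reps
        # each of 3 noise cols retained with prob ~0.1 -> far fewer than 1/rep
        assert kept_noise / (3 * reps) < 0.3

    def test_pure_noise_collapses_to_intercept(self):
        collapsed = 0
        for seed in range(30):
            rng = np.random.default_rng(seed + 53)
            X = pd.DataFrame(rng.normal(size=(200, 3)), columns=["a", "b", "c"])
            y = rng.integers(0, 2, size=200).astype(float)
            retained, _ = backward_stepwise(X, y, p_keep=0.10)
            collapsed += len(retained) == 0
        assert collapsed > 15

    def test_single_strong_predictor_retained(self):
        X, y = self._sim(99, noise_cols=0)
        retained, fit = backward_stepwise(X, y)
        assert retained == ("signal",)
        assert fit.pvalues["signal"] < 0.10

    def test_forced_in_covariate_survives(self):
        rng = np.random.default_rng(7)
        X = pd.DataFrame({"age": rng.normal(size=300), "noise": rng.normal(size=300)})
        y = rng.integers(0, 2, size=300).astype(float)
        retained, _ = backward_stepwise(X, y, forced_in=("age",))
        assert "age" in retained
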