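import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vrdot.discrimination import (
    DomainError,
    UndefinedCorrelationError,
    auc_ci,
    confusion_metrics,
    optimal_cutoff,
    partial_spearman,
    roc_curve,
    spearman_rho,
)
from conftest import brute_force_auc


class TestSpearman:
    def test_monotone_extremes(self):
        assert spearman_rho([1, 2, 3], [10, 20, 30]).rho == pytest.approx(1.0)
        assert spearman_rho([1, 2, 3], [30, 20, 10]).rho == pytest.approx(-1.0)

    def test_tied_ranks_hand_value(self):
        # ranks y = 1.5,1.5,3,4 -> product-moment 4.5/sqrt(22.5)
        r = spearman_rho([1, 2, 3, 4], [1, 1, 2, 3])
        assert r.rho == pytest.approx(4.5 / np.sqrt(22.5), abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            spearman_rho([1, 2, 3], [5, 5, 5])

    def test_short_input_rejected(self):
        with pytest.raises(DomainError):
            spearman_rho([1, 2], [3, 4])


class TestPartialSpearman:
    def test_constant_covariate_equals_plain(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=30), rng.normal(size=30)
        plain = spearman_rho(x, y)
        part = partial_spearman(x, y, np.zeros(30))
        assert part.rho == pytest.approx(plain.rho, abs=1e-12)

    def test_exact_affine_relation_degenerate(self):
        z = np.arange(20.0)
        y = 2.0 * z + 1.0  # rank-identical to the covariate
        x = np.random.default_rng(1).normal(size=20)
        with pytest.raises(UndefinedCorrelationError):
            partial_spearman(x, y, z)

    def test_independent_covariate_close_to_plain(self):
        rng = np.random.default_rng(3)
        n = 200
        x = rng.normal(size=n)
        y = 0.6 * x + rng.normal(size=n)
        z = rng.normal(size=n)  # independent of both
        plain = spearman_rho(x, y).rho
        part = partial_spearman(x, y, z).rho
        assert abs(part - plain) < 0.1

    def test_shared_covariate_attenuates(self):
        rng = np.random.default_rng(5)
        n = 300
        z = rng.normal(size=n)
        x = z + 0.4 * rng.normal(size=n)
        y = z + 0.4 * rng.normal(size=n)
        assert spearman_rho(x, y).rho > 0.7
        assert abs(partial_spearman(x, y, z).rho) < 0.3

    def test_matches_pingouin_oracle(self):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(7)
        n = 60
        df = pd.DataFrame(
            {"x": rng.normal(size=n), "y": rng.normal(size=n), "z": rng.normal(size=n)}
        )
        df["y"] += 0.5 * df["x"] + 0.3 * df["z"]
        ours = partial_spearman(df.x, df.y, df[["z"]])
        ref = pingouin.partial_corr(df, x="x", y="y", covar="z", method="spearman")
        assert ours.rho == pytest.approx(float(ref["r"].iloc[0]), abs=1e-6)


class TestROC:
    def test_four_point_example(self):
        scores = [3, 5, 1, 4]
        labels = [1, 1, 0, 0]
        roc = roc_curve(scores, labels, positive_label=1, direction="higher-is-positive")
        assert roc.auc == pytest.approx(0.75)

    def test_perfect_separation(self):
        roc = roc_curve([1, 2, 8, 9], [0, 0, 1, 1], 1, "higher-is-positive")
        assert roc.auc == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(DomainError):
            roc_curve([1, 2, 3], [1, 1, 1], 1, "higher-is-positive")

    def test_direction_antisymmetry_without_ties(self):
        rng = np.random.default_rng(2)
        s = rng.normal(size=40)
        y = rng.integers(0, 2, size=40)
        y[0], y[1] = 0, 1
        a1 = roc_curve(s, y, 1, "higher-is-positive").auc
        a2 = roc_curve(s, y, 1, "lower-is-positive").auc
        assert a1 + a2 == pytest.approx(1.0)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(4)
        s = rng.normal(size=50)
        y = (s + rng.normal(size=50) > 0).astype(int)
        a1 = roc_curve(s, y, 1, "higher-is-positive").auc
        a2 = roc_curve(np.exp(s), y, 1, "higher-is-positive").auc
        assert a1 == pytest.approx(a2)

    @given(st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_auc_equals_brute_force_pairwise(self, seed):
        rng = np.random.default_rng(seed)
        n1, n0 = rng.integers(2, 15, size=2)
        # integer scores force ties
        pos = rng.integers(0, 8, size=n1).astype(float)
        neg = rng.integers(0, 8, size=n0).astype(float)
        scores = np.concatenate([pos, neg])
        labels = np.array([1] * n1 + [0] * n0)
        roc = roc_curve(scores, labels, 1, "higher-is-positive")
        assert roc.auc == pytest.approx(brute_force_auc(pos, neg), abs=1e-12)

    def test_matches_sklearn_auc(self):
        sk = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(11)
        s = rng.integers(0, 10, size=60).astype(float)
        y = rng.integers(0, 2, size=60)
        y[:2] = [0, 1]
        ours = roc_curve(s, y, 1, "higher-is-positive").auc
        assert ours == pytest.approx(sk.roc_auc_score(y, s))


class TestBootstrapCI:
    def test_same_seed_reproducible(self):
        rng = np.random.default_rng(6)
        s = rng.normal(size=60)
        y = np.array([1] * 30 + [0] * 30)
        roc = roc_curve(s, y, 1, "higher-is-positive")
        ci1 = auc_ci(roc, n_boot=200, seed=5)
        ci2 = auc_ci(roc, n_boot=200, seed=5)
        assert ci1 == ci2

    def test_null_ci_covers_half(self):
        rng = np.random.default_rng(5)
        s = np.concatenate([rng.normal(size=50), rng.normal(size=50)])
        y = np.array([1] * 50 + [0] * 50)
        roc = roc_curve(s, y, 1, "higher-is-positive")
        lo, hi = auc_ci(roc, n_boot=500, seed=5)
        assert lo <= 0.5 <= hi

    def test_perfect_separation_ci_degenerate(self):
        s = np.concatenate([np.arange(20) + 100.0, np.arange(20.0)])
        y = np.array([1] * 20 + [0] * 20)
        roc = roc_curve(s, y, 1, "higher-is-positive")
        assert auc_ci(roc, n_boot=100, seed=1) == (1.0, 1.0)


class TestCutoffs:
    def test_four_point_youden_tie_breaks_to_specificity(self):
        roc = roc_curve([3, 5, 1, 4], [1, 1, 0, 0], 1, "higher-is-positive")
        rep = optimal_cutoff(roc)
        assert (rep.sensitivity, rep.specificity) == (0.5, 1.0)
        assert rep.youden_j == pytest.approx(0.5)

    def test_perfect_separation_j_one(self):
        roc = roc_curve([1, 2, 8, 9], [0, 0, 1, 1], 1, "higher-is-positive")
        assert optimal_cutoff(roc).youden_j == pytest.approx(1.0)

    def test_identical_scores_j_zero(self):
        roc = roc_curve([5, 5, 5, 5], [1, 1, 0, 0], 1, "higher-is-positive")
        assert optimal_cutoff(roc).youden_j == pytest.approx(0.0)

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_youden_maximal_over_all_thresholds(self, seed):
        rng = np.random.default_rng(seed)
        s = rng.integers(0, 10, size=20).astype(float)
        y = rng.integers(0, 2, size=20)
        y[:2] = [0, 1]
        roc = roc_curve(s, y, 1, "higher-is-positive")
        best = optimal_cutoff(roc).youden_j
        for t in np.unique(s):
            rep = confusion_metrics(s, y, t, "higher-is-positive", positive_label=1)
            assert rep.youden_j <= best + 1e-12

    def test_confusion_table_arithmetic(self):
        # TP=10, FN=0, FP=2, TN=8
        scores = np.array([1.0] * 12 + [0.0] * 8)
        labels = np.array([1] * 10 + [0] * 10)
        rep = confusion_metrics(scores, labels, 1.0, "higher-is-positive", positive_label=1)
        assert rep.sensitivity == 1.0
        assert rep.specificity == pytest.approx(0.8)
        assert rep.ppv == pytest.approx(10 / 12)
        assert rep.npv == 1.0

    def test_extreme_cutoffs(self):
        s = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([0, 1, 0, 1])
        low = confusion_metrics(s, y, 0.0, "higher-is-positive", 1)
        assert (low.sensitivity, low.specificity) == (1.0, 0.0)
        high = confusion_metrics(s, y, 9.0, "higher-is-positive", 1)
        assert (high.sensitivity, high.specificity) == (0.0, 1.0)
        assert np.isnan(high.ppv)
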