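import numpy as np
import pytest

from hope.evaluate import (
    accuracy,
    macro_f1,
    micro_f1,
    per_class_table,
    roc_auc,
    support_performance_regression,
)


def brute_confusion(pred, truth):
    """Independent per-class confusion counting by explicit loops."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    n, c = pred.shape
    tp = np.zeros(c)
    fp = np.zeros(c)
    fn = np.zeros(c)
    for i in range(n):
        for j in range(c):
            if pred[i, j] and truth[i, j]:
                tp[j] += 1
            elif pred[i, j] and not truth[i, j]:
                fp[j] += 1
            elif not pred[i, j] and truth[i, j]:
                fn[j] += 1
    return tp, fp, fn


def brute_micro_f1(pred, truth):
    tp, fp, fn = brute_confusion(pred, truth)
    TP, FP, FN = tp.sum(), fp.sum(), fn.sum()
    p = TP / (TP + FP) if TP + FP else 0.0
    r = TP / (TP + FN) if TP + FN else 0.0
    return 2 * p * r / (p + r) if p + r else 0.0


def brute_macro_f1(pred, truth):
    tp, fp, fn = brute_confusion(pred, truth)
    precs = [tp[j] / (tp[j] + fp[j]) if tp[j] + fp[j] else 0.0
             for j in range(len(tp))]
    recs = [tp[j] / (tp[j] + fn[j]) if tp[j] + fn[j] else 0.0
            for j in range(len(tp))]
    P, R = np.mean(precs), np.mean(recs)
    return 2 * P * R / (P + R) if P + R else 0.0


def brute_auc(scores, truth):
    s = np.asarray(scores, dtype=float).ravel()
    t = np.asarray(truth).astype(bool).ravel()
    pos, neg = s[t], s[~t]
    wins = 0.0
    for a in pos:
        for b in neg:
            wins += 1.0 if a > b else (0.5 if a == b else 0.0)
    return wins / (len(pos) * len(neg))


class TestMicroF1:
    def test_pooled_counts_example(self):
        # class 1: TP=1, FP=1; class 2: FN=1
        truth = np.array([[1, 0], [0, 0], [0, 1]])
        pred = np.array([[1, 0], [1, 0], [0, 0]])
        assert micro_f1(pred, truth) == pytest.approx(0.5)

    def test_perfect_prediction(self):
        t = np.array([[1, 0], [0, 1]])
        assert micro_f1(t, t) == 1.0

    def test_complement_prediction_zero(self):
        t = np.array([[1, 0], [0, 1]])
        assert micro_f1(1 - t, t) == 0.0

    def test_degenerate_flagged_nan(self):
        z = np.zeros((3, 2), dtype=int)
        assert np.isnan(micro_f1(z, z))


class TestMacroF1:
    def test_harmonic_of_means_example(self):
        # class 1: P=0.5, R=1; class 2: P=0, R=0
        truth = np.array([[1, 1], [0, 0]])
        pred = np.array([[1, 0], [1, 1]])
        assert macro_f1(pred, truth) == pytest.approx(1 / 3)

    def test_perfect_prediction(self):
        t = np.array([[1, 0], [0, 1]])
        assert macro_f1(t, t) == 1.0

    def test_single_class_macro_equals_micro(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            pred = rng.integers(0, 2, size=(15, 1))
            truth = rng.integers(0, 2, size=(15, 1))
            if truth.sum() == 0 and pred.sum() == 0:
                continue
            assert macro_f1(pred, truth) == pytest.approx(
                micro_f1(pred, truth), abs=1e-12
            )

    def test_mean_of_f1_variant_differs_when_classes_unbalanced(self):
        truth = np.array([[1, 1], [0, 0]])
        pred = np.array([[1, 0], [1, 1]])
        # per-class F1: 2/3 and 0 -> mean 1/3 happens to agree here; use a
        # case with three classes where the two formulas separate
        truth = np.array([[1, 1, 0], [0, 1, 1], [1, 0, 0]])
        pred = np.array([[1, 0, 0], [0, 1, 1], [0, 0, 1]])
        a = macro_f1(pred, truth, "harmonic-of-means")
        b = macro_f1(pred, truth, "mean-of-f1")
        assert a != pytest.approx(b)


class TestAccuracy:
    def test_cell_fraction_example(self):
        truth = np.array([[1, 0], [0, 1]])
        pred = np.array([[1, 1], [0, 1]])
        assert accuracy(pred, truth) == pytest.approx(0.75)

    def test_subset_variant(self):
        truth = np.array([[1, 0], [0, 1]])
        pred = np.array([[1, 1], [0, 1]])
        assert accuracy(pred, truth, "subset") == pytest.approx(0.5)

    def test_matches_counting_oracle(self):
        rng = np.random.default_rng(4)
        pred = rng.integers(0, 2, size=(12, 7))
        truth = rng.integers(0, 2, size=(12, 7))
        expected = sum(
            int(pred[i, j] == truth[i, j])
            for i in range(12) for j in range(7)
        ) / (12 * 7)
        assert accuracy(pred, truth) == pytest.approx(expected, abs=1e-12)


class TestRocAuc:
    def test_pair_counting_example(self):
        assert roc_auc([0.9, 0.8, 0.3], [1, 0, 1]) == pytest.approx(0.5)

    def test_separated_scores(self):
        assert roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0
        assert roc_auc([0.9, 0.8, 0.2, 0.1], [0, 0, 1, 1]) == 0.0

    def test_ties_count_half(self):
        assert roc_auc([0.5, 0.5], [1, 0]) == pytest.approx(0.5)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(5)
        s = rng.random(40)
        t = rng.integers(0, 2, size=40)
        a = roc_auc(s, t)
        assert roc_auc(np.exp(3 * s) + 7, t) == pytest.approx(a, abs=1e-12)

    def test_degenerate_truth_flagged(self):
        assert np.isnan(roc_auc([0.1, 0.9], [1, 1]))


class TestOracleEquivalence:
    def test_matches_brute_force_on_random_matrices(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            pred = rng.integers(0, 2, size=(20, 8))
            truth = rng.integers(0, 2, size=(20, 8))
            scores = rng.random((20, 8))
            assert micro_f1(pred, truth) == pytest.approx(
                brute_micro_f1(pred, truth), abs=1e-10
            )
            assert macro_f1(pred, truth) == pytest.approx(
                brute_macro_f1(pred, truth), abs=1e-10
            )
            assert roc_auc(scores, truth) == pytest.approx(
                brute_auc(scores, truth), abs=1e-10
            )

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(1)
        pred = rng.integers(0, 2, size=(25, 6))
        truth = rng.integers(0, 2, size=(25, 6))
        scores = rng.random((25, 6))
        perm = rng.permutation(25)
        assert micro_f1(pred, truth) == micro_f1(pred[perm], truth[perm])
        assert macro_f1(pred, truth) == macro_f1(pred[perm], truth[perm])
        assert accuracy(pred, truth) == accuracy(pred[perm], truth[perm])
        assert roc_auc(scores, truth) == pytest.approx(
            roc_auc(scores[perm], truth[perm]), abs=1e-12
        )


class TestSupportRegression:
    def make_table(self, support, f1):
        import pandas as pd

        return pd.DataFrame({
            "ko": [f"K{i}" for i in range(len(support))],
            "support": support,
            "precision": f1,
            "recall": f1,
            "f1": f1,
        })

    def test_exact_line(self):
        tab = self.make_table([1, 2, 3], [0.1, 0.2, 0.3])
        slope, intercept, p = support_performance_regression(tab)
        assert slope == pytest.approx(0.1)
        assert intercept == pytest.approx(0.0, abs=1e-12)
        assert p < 0.05

    def test_constant_scores_zero_slope(self):
        tab = self.make_table([1, 2, 3, 4], [0.5, 0.5, 0.5, 0.5])
        slope, _, p = support_performance_regression(tab)
        assert slope == 0.0
        assert p == 1.0

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            support_performance_regression(self.make_table([1, 2], [0.1, 0.2]))


def test_per_class_table_contents():
    truth = np.array([[1, 0], [1, 1], [0, 0]])
    pred = np.array([[1, 0], [0, 1], [0, 1]])
    tab = per_class_table(pred, truth, ["K1", "K2"])
    assert list(tab["ko"]) == ["K1", "K2"]
    assert list(tab["support"]) == [2, 1]
    assert tab["precision"].iloc[0] == pytest.approx(1.0)
    assert tab["recall"].iloc[0] == pytest.approx(0.5)
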