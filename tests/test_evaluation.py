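import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import (matthews_corrcoef, precision_recall_fscore_support,
                             roc_auc_score)

from gppi.errors import MetricError
from gppi.evaluation import (ConfusionCounts, confusion_at, evaluation_report,
                             mcc, optimal_threshold, roc_auc, threshold_curve)


def pairwise_auc(scores, labels):
    """O(P*N) Mann-Whitney oracle: ties count 1/2."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestConfusion:
    def test_basic_counts(self):
        c = confusion_at([0.9, 0.1], [1, 0], 0.85)
        assert (c.tp, c.fp, c.tn, c.fn) == (1, 0, 1, 0)

    def test_score_equal_to_threshold_is_positive(self):
        c = confusion_at([0.85], [1], 0.85)
        assert c.tp == 1 and c.fn == 0

    def test_threshold_zero_predicts_everything_positive(self):
        c = confusion_at([0.2, 0.8, 0.5], [1, 0, 0], 0.0)
        assert c.fp == 2 and c.tn == 0 and c.tp == 1

    def test_length_mismatch_rejected(self):
        with pytest.raises(MetricError):
            confusion_at([0.5], [1, 0], 0.5)


class TestMCC:
    def test_perfect_classifier(self):
        assert mcc(ConfusionCounts(tp=10, fp=0, tn=12, fn=0)) == 1.0

    def test_single_class_prediction_is_zero(self):
        assert mcc(ConfusionCounts(tp=10, fp=10, tn=0, fn=0)) == 0.0

    def test_arithmetic_example(self):
        c = ConfusionCounts(tp=40, fp=10, tn=35, fn=15)
        expected = (40 * 35 - 10 * 15) / np.sqrt(50 * 55 * 45 * 50)
        assert abs(mcc(c) - expected) < 1e-12

    @given(st.tuples(*[st.integers(0, 200)] * 4))
    @settings(max_examples=100, deadline=None)
    def test_class_swap_symmetry(self, counts):
        tp, fp, tn, fn = counts
        if tp + fp + tn + fn == 0:
            return
        assert mcc(ConfusionCounts(tp, fp, tn, fn)) == pytest.approx(
            mcc(ConfusionCounts(tn, fn, tp, fp)), abs=1e-12)

    def test_agrees_with_sklearn_on_random_predictions(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, size=200)
        pred = rng.integers(0, 2, size=200)
        c = ConfusionCounts(tp=int(np.sum((pred == 1) & (y == 1))),
                            fp=int(np.sum((pred == 1) & (y == 0))),
                            tn=int(np.sum((pred == 0) & (y == 0))),
                            fn=int(np.sum((pred == 0) & (y == 1))))
        assert mcc(c) == pytest.approx(matthews_corrcoef(y, pred), abs=1e-12)


class TestAUC:
    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_all_ties_is_half(self):
        assert roc_auc([0.5, 0.5, 0.5, 0.5], [1, 0, 1, 0]) == pytest.approx(0.5)

    def test_single_class_undefined(self):
        with pytest.raises(MetricError):
            roc_auc([0.5, 0.6], [1, 1])

    def test_trapezoid_equals_pairwise_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            n = int(rng.integers(10, 60))
            scores = np.round(rng.random(n), 2)  # rounding induces ties
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                continue
            assert roc_auc(scores, labels) == pytest.approx(
                pairwise_auc(scores, labels), abs=1e-9)
            assert roc_auc(scores, labels) == pytest.approx(
                roc_auc_score(labels, scores), abs=1e-12)


class TestThresholdCurve:
    def test_extreme_thresholds(self):
        scores = np.array([0.2, 0.4, 0.6, 0.8])
        labels = np.array([0, 1, 0, 1])
        curve = threshold_curve(scores, labels, [0.0, 0.9])
        assert curve.sensitivity[0] == 1.0
        assert curve.sensitivity[-1] == 0.0
        assert curve.precision_undefined[-1]
        assert curve.precision[-1] == 1.0

    def test_sensitivity_non_increasing(self):
        rng = np.random.default_rng(5)
        scores = rng.random(100)
        labels = rng.integers(0, 2, size=100)
        curve = threshold_curve(scores, labels, np.linspace(0, 1, 21))
        assert (np.diff(curve.sensitivity) <= 1e-12).all()


class TestOptimalThreshold:
    def test_separable_scores_reach_full_precision(self):
        scores = np.array([0.95, 0.92, 0.9, 0.3, 0.2, 0.1])
        labels = np.array([1, 1, 1, 0, 0, 0])
        t = optimal_threshold(scores, labels, min_sensitivity=0.96)
        c = confusion_at(scores, labels, t)
        assert c.fp == 0 and c.fn == 0
        assert t == 0.9

    def test_full_sensitivity_floor_bounds_threshold(self):
        scores = np.array([0.4, 0.6, 0.7, 0.1])
        labels = np.array([1, 1, 0, 0])
        t = optimal_threshold(scores, labels, min_sensitivity=1.0)
        assert t <= 0.4

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(2)
        scores = np.round(rng.random(500), 3)
        labels = rng.integers(0, 2, size=500)
        got = optimal_threshold(scores, labels, 0.8)
        # independent exhaustive scan over every candidate threshold
        best = None
        for t in np.unique(np.append(scores, 0.0)):
            pred = scores >= t
            tp = np.sum(pred & (labels == 1))
            sens = tp / np.sum(labels == 1)
            prec = tp / pred.sum() if pred.sum() else 1.0
            if sens >= 0.8 and (best is None or (prec, t) >= best[:2]):
                best = (prec, t)
        assert got == pytest.approx(best[1], abs=0)

    def test_result_satisfies_floor(self):
        rng = np.random.default_rng(3)
        scores = rng.random(200)
        labels = rng.integers(0, 2, size=200)
        t = optimal_threshold(scores, labels, 0.9)
        c = confusion_at(scores, labels, t)
        assert c.tp / (c.tp + c.fn) >= 0.9

    def test_invalid_floor_rejected(self):
        with pytest.raises(MetricError):
            optimal_threshold([0.5, 0.6], [0, 1], min_sensitivity=1.5)


class TestReport:
    def test_balanced_macro_equals_weighted(self):
        scores = np.array([0.9, 0.8, 0.3, 0.2])
        labels = np.array([1, 1, 0, 0])
        rep = evaluation_report(scores, labels, 0.5)
        for k in ("precision", "recall", "f1"):
            assert rep.macro_avg[k] == pytest.approx(rep.weighted_avg[k])

    def test_f1_of_equal_precision_recall(self):
        # class 1: precision = recall = 2/3 -> F1 = 2/3
        scores = np.array([0.9, 0.9, 0.9, 0.1, 0.1, 0.1])
        labels = np.array([1, 1, 0, 1, 0, 0])
        rep = evaluation_report(scores, labels, 0.5)
        m = rep.per_class["1"]
        assert m["precision"] == m["recall"] == pytest.approx(2 / 3)
        assert m["f1"] == pytest.approx(2 / 3)

    def test_agrees_with_sklearn_per_class_metrics(self):
        rng = np.random.default_rng(7)
        scores = rng.random(300)
        labels = rng.integers(0, 2, size=300)
        rep = evaluation_report(scores, labels, 0.6)
        pred = (scores >= 0.6).astype(int)
        p, r, f, s = precision_recall_fscore_support(labels, pred,
                                                     zero_division=0)
        for cls in (0, 1):
            m = rep.per_class[str(cls)]
            assert m["precision"] == pytest.approx(p[cls], abs=1e-12)
            assert m["recall"] == pytest.approx(r[cls], abs=1e-12)
            assert m["f1"] == pytest.approx(f[cls], abs=1e-12)
            assert m["support"] == s[cls]

    def test_full_report_on_arithmetic_example(self):
        # 40/10/35/15 counts rebuilt from explicit scores
        scores = np.concatenate([
            np.full(40, 0.9), np.full(15, 0.1),   # positives
            np.full(10, 0.9), np.full(35, 0.1),   # negatives
        ])
        labels = np.concatenate([np.ones(55), np.zeros(45)]).astype(int)
        rep = evaluation_report(scores, labels, 0.5)
        assert (rep.counts.tp, rep.counts.fp, rep.counts.tn, rep.counts.fn) == \
            (40, 10, 35, 15)
        assert rep.accuracy == pytest.approx(0.75)
        assert rep.per_class["1"]["precision"] == pytest.approx(40 / 50)
        assert rep.per_class["1"]["recall"] == pytest.approx(40 / 55)
        assert rep.mcc == pytest.approx(
            (40 * 35 - 10 * 15) / np.sqrt(50 * 55 * 45 * 50))
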