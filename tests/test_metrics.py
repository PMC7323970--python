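"""Evaluation metrics against brute-force oracles and closed forms."""

import numpy as np
import pandas as pd
import pytest

from agrisuit.metrics import (
    ConfusionMatrix, confusion, evaluate, kappa, multiclass_auc,
    overall_accuracy, per_class_metrics,
)


def brute_force_per_class(counts, classes):
    """One-vs-rest tally by explicit enumeration of label pairs."""
    # rebuild the label vectors the matrix came from
    ref, pred = [], []
    for i, r in enumerate(classes):
        for j, p in enumerate(classes):
            ref += [r] * counts[i][j]
            pred += [p] * counts[i][j]
    ref, pred = np.array(ref), np.array(pred)
    n = len(ref)
    rows = {}
    for c in classes:
        tp = int(((ref == c) & (pred == c)).sum())
        fn = int(((ref == c) & (pred != c)).sum())
        fp = int(((ref != c) & (pred == c)).sum())
        tn = n - tp - fn - fp
        div = lambda a, b: a / b if b > 0 else np.nan
        sens, spec, ppv = div(tp, tp + fn), div(tn, tn + fp), div(tp, tp + fp)
        rows[c] = dict(sensitivity=sens, specificity=spec, ppv=ppv,
                       npv=div(tn, tn + fn), precision=ppv, recall=sens,
                       f1=div(2 * ppv * sens, ppv + sens) if np.isfinite(ppv) and np.isfinite(sens) else np.nan,
                       prevalence=(tp + fn) / n, detection_rate=tp / n,
                       detection_prevalence=(tp + fp) / n,
                       balanced_accuracy=(sens + spec) / 2)
    return rows


def brute_force_auc(ref, scores, classes):
    """Exhaustive pair counting over all sample pairs, per class pair."""
    from itertools import combinations
    pair_vals = []
    for ki, kj in combinations(range(len(classes)), 2):
        aucs = []
        for kpos, kneg in ((ki, kj), (kj, ki)):
            pos = scores[ref == classes[kpos], kpos]
            neg = scores[ref == classes[kneg], kpos]
            wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
            aucs.append(wins / (len(pos) * len(neg)))
        pair_vals.append(sum(aucs) / 2)
    return float(np.mean(pair_vals))


class TestConfusion:
    def test_perfect_prediction_diagonal(self):
        cm = confusion([1, 2, 3, 4], [1, 2, 3, 4])
        np.testing.assert_array_equal(cm.counts, np.eye(4, dtype=int))

    def test_enumeration_example(self):
        cm = confusion(["A", "B", "B"], ["A", "A", "B"])
        np.testing.assert_array_equal(cm.counts, [[1, 0], [1, 1]])

    def test_order_invariance(self):
        a = confusion([1, 2, 2, 3], [1, 2, 3, 3])
        b = confusion([2, 1, 3, 2], [2, 1, 3, 3])
        np.testing.assert_array_equal(a.counts, b.counts)

    def test_label_outside_class_set_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            confusion([1, 5], [1, 1], classes=[1, 2])

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ConfusionMatrix(np.zeros((2, 2), dtype=int), (1, 2))


class TestOverallAccuracyAndKappa:
    def test_oa_examples(self):
        assert overall_accuracy(confusion([1, 2, 3, 4], [1, 2, 3, 4])) == 1.0
        assert overall_accuracy(confusion(["A", "B", "B"], ["A", "A", "B"])) == pytest.approx(2 / 3)
        assert overall_accuracy(ConfusionMatrix(np.array([[0, 3], [2, 0]]), (1, 2))) == 0.0

    def test_kappa_perfect(self):
        assert kappa(confusion([1, 2, 3], [1, 2, 3])) == 1.0

    def test_kappa_chance_level(self):
        assert kappa(ConfusionMatrix(np.array([[1, 1], [1, 1]]), (1, 2))) == pytest.approx(0.0)

    def test_kappa_perfect_disagreement(self):
        # p_o = 0, p_e = 0.5 -> (0 - 0.5) / (1 - 0.5) = -1
        assert kappa(ConfusionMatrix(np.array([[0, 2], [2, 0]]), (1, 2))) == pytest.approx(-1.0)

    def test_kappa_degenerate_chance_one(self):
        # p_e = 1 forces every count into one diagonal cell, so p_o = 1 too
        assert kappa(ConfusionMatrix(np.array([[5]]), (1,))) == 1.0
        assert kappa(ConfusionMatrix(np.array([[7, 0], [0, 0]]), (1, 2))) == 1.0

    def test_kappa_le_oa(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            counts = rng.integers(0, 20, (4, 4))
            if counts.sum() == 0 or np.trace(counts) == counts.sum():
                continue
            cm = ConfusionMatrix(counts, (1, 2, 3, 4))
            assert kappa(cm) <= overall_accuracy(cm) + 1e-12


class TestPerClassMetrics:
    def test_perfect_diagonal_all_ones(self):
        cm = confusion([1, 2, 3, 4] * 3, [1, 2, 3, 4] * 3)
        df = per_class_metrics(cm)
        for col in ("sensitivity", "specificity", "f1", "balanced_accuracy"):
            assert np.allclose(df[col], 1.0)

    def test_absent_prediction_ppv_nan(self):
        cm = confusion([1, 1, 2, 2], [2, 2, 2, 2])
        with pytest.warns(UserWarning, match="undefined"):
            df = per_class_metrics(cm)
        assert np.isnan(df.loc[1, "ppv"])
        assert df.loc[1, "sensitivity"] == 0.0

    def test_against_brute_force_tally(self):
        rng = np.random.default_rng(3)
        classes = (1, 2, 3, 4)
        for _ in range(50):
            counts = rng.integers(0, 15, (4, 4))
            if counts.sum() == 0:
                continue
            cm = ConfusionMatrix(counts, classes)
            import warnings
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                df = per_class_metrics(cm)
            oracle = brute_force_per_class(counts.tolist(), classes)
            for c in classes:
                for k, v in oracle[c].items():
                    got = df.loc[c, k]
                    assert (np.isnan(v) and np.isnan(got)) or got == pytest.approx(v)

    def test_oa_is_prevalence_weighted_sensitivity(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            counts = rng.integers(1, 15, (4, 4))
            cm = ConfusionMatrix(counts, (1, 2, 3, 4))
            df = per_class_metrics(cm)
            assert overall_accuracy(cm) == pytest.approx(
                float((df["prevalence"] * df["sensitivity"]).sum()))


class TestMulticlassAUC:
    def test_perfectly_ordered_scores(self):
        ref = np.array([1, 1, 2, 2, 3, 3])
        scores = np.eye(3)[ref - 1] * 0.8 + 0.1
        assert multiclass_auc(ref, scores, classes=[1, 2, 3]) == 1.0

    def test_constant_scores(self):
        ref = np.array([1, 1, 2, 2, 3, 3])
        scores = np.full((6, 3), 1 / 3)
        assert multiclass_auc(ref, scores, classes=[1, 2, 3]) == pytest.approx(0.5)

    def test_against_exhaustive_pair_counting(self):
        rng = np.random.default_rng(11)
        classes = np.array([1, 2, 3])
        for _ in range(50):
            n = int(rng.integers(6, 20))
            ref = rng.choice(classes, size=n)
            while len(np.unique(ref)) < 3:
                ref = rng.choice(classes, size=n)
            scores = rng.random((n, 3))
            got = multiclass_auc(ref, scores, classes=classes)
            assert got == pytest.approx(brute_force_auc(ref, scores, list(classes)))

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(13)
        ref = rng.choice([1, 2, 3], size=30)
        ref[:3] = [1, 2, 3]
        scores = rng.random((30, 3))
        a = multiclass_auc(ref, scores, classes=[1, 2, 3])
        b = multiclass_auc(ref, np.exp(5 * scores), classes=[1, 2, 3])
        assert a == pytest.approx(b)

    def test_agrees_with_sklearn_hand_till(self):
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(17)
        ref = rng.choice([0, 1, 2, 3], size=200)
        raw = rng.random((200, 4)) + 0.5 * np.eye(4)[ref]
        proba = raw / raw.sum(axis=1, keepdims=True)
        got = multiclass_auc(ref, proba, classes=[0, 1, 2, 3])
        expect = roc_auc_score(ref, proba, multi_class="ovo", average="macro")
        assert got == pytest.approx(expect, abs=1e-9)

    def test_missing_class_pair_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            multiclass_auc([1, 1], np.random.rand(2, 3), classes=[1, 2, 3])


class TestRandomPredictionCalibration:
    def test_uniform_random_predictions_near_chance(self):
        rng = np.random.default_rng(23)
        n = 10_000
        ref = rng.choice([1, 2, 3, 4], size=n)
        pred = rng.choice([1, 2, 3, 4], size=n)
        raw = rng.random((n, 4))
        scores = raw / raw.sum(axis=1, keepdims=True)
        rep = evaluate(ref, pred, scores, classes=[1, 2, 3, 4])
        assert abs(rep.kappa) < 0.03
        assert abs(rep.auc - 0.5) < 0.02
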