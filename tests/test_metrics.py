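"""Confusion algebra and ROC against the published tables and brute oracles."""

import numpy as np
import pytest

import _tables as T
from rrnet import (CLASSES, ConfusionMatrix, binary_metrics, class_metrics,
                   collapse_binary, confusion, metrics_table, pool, roc)
from rrnet.metrics import round2


class TestConfusion:
    def test_all_correct_diagonal(self):
        y = np.repeat(CLASSES, 10)
        cm = confusion(y, y)
        assert np.array_equal(cm.counts, 10 * np.eye(3, dtype=int))

    def test_hand_tally(self):
        true_ = ["AFIB", "AFIB", "AFL", "NSR", "NSR", "NSR"]
        pred = ["AFIB", "AFL", "AFL", "NSR", "AFIB", "NSR"]
        cm = confusion(true_, pred)
        assert np.array_equal(cm.counts,
                              [[1, 1, 0], [0, 1, 0], [1, 0, 2]])

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            confusion(["AFIB"], ["VT"])


class TestPool:
    def test_published_folds_sum_to_overall(self):
        cms = [ConfusionMatrix(m) for m in T.FOLD_MATRICES]
        pooled = pool(cms)
        assert np.array_equal(pooled.counts, T.ALL_MATRIX)
        assert pooled.counts[0, 1] == 1411

    def test_single_matrix_identity(self):
        cm = ConfusionMatrix(T.FOLD_MATRICES[0])
        assert np.array_equal(pool([cm]).counts, cm.counts)

    def test_commutative(self):
        a = ConfusionMatrix(T.FOLD_MATRICES[0])
        b = ConfusionMatrix(T.FOLD_MATRICES[1])
        assert np.array_equal(pool([a, b]).counts, pool([b, a]).counts)

    def test_class_order_mismatch_rejected(self):
        a = ConfusionMatrix(np.eye(2, dtype=int), ("x", "y"))
        b = ConfusionMatrix(np.eye(2, dtype=int), ("y", "x"))
        with pytest.raises(ValueError):
            pool([a, b])


class TestClassMetrics:
    @pytest.mark.parametrize("cls", CLASSES)
    def test_overall_matrix_reproduces_printed_metrics(self, cls):
        m = class_metrics(ConfusionMatrix(T.ALL_MATRIX), cls)
        assert (m.ACC, m.SEN, m.SPE) == T.ALL_METRICS[cls]

    @pytest.mark.parametrize("fold", range(1, 11))
    @pytest.mark.parametrize("cls", CLASSES)
    def test_every_published_fold_metric(self, fold, cls):
        cm = ConfusionMatrix(T.FOLD_MATRICES[fold - 1])
        m = class_metrics(cm, cls)
        assert (m.ACC, m.SEN, m.SPE) == T.FOLD_METRICS[(fold, cls)]

    @pytest.mark.parametrize("fold", range(11))
    def test_tn_conventions_differ_by_other_class_confusions(self, fold):
        """Standard TN exceeds the diagonal-sum TN by exactly the
        confusions among the *other* classes, so the two coincide iff
        those cross-confusions are zero."""
        mat = T.ALL_MATRIX if fold == 10 else T.FOLD_MATRICES[fold]
        cm = ConfusionMatrix(mat)
        for cls in CLASSES:
            i = cm.classes.index(cls)
            others = [j for j in range(3) if j != i]
            cross = sum(int(cm.counts[a, b]) for a in others for b in others
                        if a != b)
            m = class_metrics(cm, cls)
            assert m.TN_standard - m.TN == cross
            if cross == 0:
                assert m.TN == m.TN_standard

    def test_published_tables_follow_diagonal_tn_convention(self):
        """Fold 9's NSR accuracy prints 99.86; the standard TN would give
        99.87, so the published algebra uses the diagonal-sum TN."""
        m = class_metrics(ConfusionMatrix(T.FOLD_MATRICES[8]), "NSR")
        assert m.ACC == 99.86
        acc_std = round2(100 * (m.TP + m.TN_standard)
                         / (m.TP + m.TN_standard + m.FP + m.FN))
        assert acc_std == 99.87

    def test_perfect_diagonal_all_hundred(self):
        m = metrics_table(ConfusionMatrix(np.diag([5, 6, 7])))
        for cls in CLASSES:
            assert (m[cls].ACC, m[cls].SEN, m[cls].SPE) == (100.0, 100.0, 100.0)

    def test_zero_denominator_is_nan_not_zero(self):
        cm = ConfusionMatrix(np.array([[0, 0, 0], [0, 3, 0], [0, 0, 4]]))
        m = class_metrics(cm, "AFIB")
        assert np.isnan(m.SEN)
        assert not np.isnan(m.SPE)

    def test_rounding_half_away_from_zero(self):
        assert round2(93.755) == 93.76
        assert round2(99.98499) == 99.98


class TestBinaryCollapse:
    def test_overall_matrix_collapses_to_published_binary(self):
        cm2 = collapse_binary(ConfusionMatrix(T.ALL_MATRIX))
        assert np.array_equal(cm2.counts, T.BINARY_MATRIX)

    def test_totals_conserved(self):
        cm = ConfusionMatrix(T.FOLD_MATRICES[0])
        assert collapse_binary(cm).total == cm.total

    def test_zero_matrix(self):
        out = collapse_binary(ConfusionMatrix(np.zeros((3, 3), dtype=int)))
        assert np.array_equal(out.counts, np.zeros((2, 2), dtype=int))

    def test_published_binary_metrics_both_orientations(self):
        b = binary_metrics(ConfusionMatrix(T.BINARY_MATRIX,
                                           ("Arrhythmia", "Non-Arrhythmia")))
        assert b["ACC"] == T.BINARY_ACC
        assert b["sensitivity_arrhythmia"] == T.BINARY_SEN_ARRHYTHMIA
        assert b["specificity_arrhythmia"] == T.BINARY_SPE_ARRHYTHMIA
        assert b["swapped_SEN"] == T.BINARY_SPE_ARRHYTHMIA
        assert b["swapped_SPE"] == T.BINARY_SEN_ARRHYTHMIA

    def test_identity_matrix_all_hundred(self):
        b = binary_metrics(ConfusionMatrix(np.eye(2, dtype=int),
                                           ("Arrhythmia", "Non-Arrhythmia")))
        assert b["ACC"] == b["sensitivity_arrhythmia"] == 100.0


def brute_roc(pos: np.ndarray, score: np.ndarray):
    """Enumerate every threshold; return (fpr, tpr) pairs, high to low."""
    pts = [(0.0, 0.0)]
    for th in sorted(set(score), reverse=True):
        pred = score >= th
        tpr = (pred & pos).sum() / pos.sum()
        fpr = (pred & ~pos).sum() / (~pos).sum()
        pts.append((fpr, tpr))
    return pts


class TestRoc:
    def test_perfect_separation_auc_one(self):
        y = np.array(["AFIB"] * 5 + ["AFL"] * 5 + ["NSR"] * 5, dtype=object)
        scores = np.eye(3)[np.repeat([0, 1, 2], 5)] * 0.8 + 0.1
        res = roc(scores, y)
        for cls in CLASSES:
            assert res.per_class[cls][2] == 1.0
        assert res.micro[2] == 1.0
        assert res.macro[2] >= 0.999

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_random_scores_chance_auc(self, seed):
        rng = np.random.default_rng(seed)
        n = 10_000
        y = np.asarray(CLASSES, dtype=object)[rng.integers(3, size=n)]
        s = rng.uniform(size=(n, 3))
        s /= s.sum(axis=1, keepdims=True)
        res = roc(s, y)
        for cls in CLASSES:
            assert abs(res.per_class[cls][2] - 0.5) < 0.02

    def test_four_point_sweep_matches_brute_enumeration(self):
        y = np.array(["AFIB", "AFIB", "NSR", "NSR"], dtype=object)
        s = np.array([[0.9, 0.05, 0.05],
                      [0.4, 0.30, 0.30],
                      [0.6, 0.20, 0.20],
                      [0.1, 0.45, 0.45]])
        res = roc(s, y)
        fpr, tpr, auc_val = res.per_class["AFIB"]
        expected = brute_roc(y == "AFIB", s[:, 0])
        got = list(zip(fpr.tolist(), tpr.tolist()))
        for p in expected:
            assert p in [(round(a, 12), round(b, 12)) for a, b in got]
        # hand integration: thresholds 0.9,0.6,0.4,0.1 ->
        # (0,.5) (.5,.5) (.5,1) (1,1): area = .5*.5 + .5*1 = 0.75
        assert auc_val == pytest.approx(0.75)

    def test_absent_class_flagged(self):
        y = np.array(["AFIB", "AFIB", "AFL"], dtype=object)
        s = np.full((3, 3), 1 / 3)
        res = roc(s, y)
        assert res.absent_classes == ("NSR",)
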