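"""Metric equations against brute-force and reference oracles, plus the
y-randomization machinery."""

import math
from fractions import Fraction

import numpy as np
import pytest

from blendsense import (
    ClassMetrics,
    ConfusionCounts,
    class_metrics,
    classification_report,
    confusion_counts,
    crp_squared,
    fit_lda,
    predict_lda,
    r0_squared,
    r_squared,
    rm_squared,
    rmse,
    y_randomization,
)


def brute_force_metrics(tp, tn, fp, fn):
    """Evaluate the six metrics by exact rational arithmetic on an
    explicitly enumerated prediction list (independent of the package)."""
    y_true = [1] * tp + [0] * tn + [0] * fp + [1] * fn
    y_pred = [1] * tp + [0] * tn + [1] * fp + [0] * fn
    n = len(y_true)
    TP = sum(1 for t, p in zip(y_true, y_pred) if t == 1 and p == 1)
    TN = sum(1 for t, p in zip(y_true, y_pred) if t == 0 and p == 0)
    FP = sum(1 for t, p in zip(y_true, y_pred) if t == 0 and p == 1)
    FN = sum(1 for t, p in zip(y_true, y_pred) if t == 1 and p == 0)
    pre = 100 * Fraction(TP, TP + FP) if TP + FP else Fraction(0)
    rec = 100 * Fraction(TP, TP + FN) if TP + FN else Fraction(0)
    acu = 100 * Fraction(TP + TN, n)
    err = 100 - acu
    f1 = Fraction(2 * TP, 2 * TP + FP + FN) if 2 * TP + FP + FN else Fraction(0)
    denom = (TP + FN) * (TP + FP) * (TN + FN) * (TN + FP)
    mcc = (TP * TN - FN * FP) / math.sqrt(denom) if denom else 0.0
    return (float(pre), float(rec), float(acu), float(err), float(f1), float(mcc))


class TestConfusionCounts:
    def test_all_correct(self):
        c = confusion_counts([1] * 41 + [0] * 9, [1] * 41 + [0] * 9, 1)
        assert (c.TP, c.TN, c.FP, c.FN) == (41, 9, 0, 0)

    def test_all_predicted_positive(self):
        c = confusion_counts([1] * 41 + [0] * 9, [1] * 50, 1)
        assert (c.TP, c.TN, c.FP, c.FN) == (41, 0, 9, 0)

    def test_empty_and_mismatched_inputs_rejected(self):
        with pytest.raises(ValueError):
            confusion_counts([], [], 1)
        with pytest.raises(ValueError):
            confusion_counts([1, 0], [1], 1)


class TestClassMetrics:
    def test_degenerate_all_positive_prediction(self):
        """A classifier answering 'positive' for everything on an 82/18
        split: high accuracy, F1 0.90, but MCC 0 — learned nothing."""
        m = class_metrics(ConfusionCounts(41, 0, 9, 0))
        assert m.PRE == pytest.approx(82.0)
        assert m.REC == 100.0
        assert m.ACU == pytest.approx(82.0)
        assert m.ERR == pytest.approx(18.0)
        assert m.F1S == pytest.approx(0.90, abs=0.005)
        assert m.MCC == 0.0

    def test_perfect_prediction(self):
        m = class_metrics(ConfusionCounts(41, 9, 0, 0))
        assert (m.PRE, m.REC, m.ACU, m.ERR) == (100.0, 100.0, 100.0, 0.0)
        assert (m.F1S, m.MCC) == (1.0, 1.0)

    def test_brute_force_oracle_all_matrices_up_to_12(self):
        """Exhaustive agreement with rational-arithmetic enumeration over
        every confusion matrix with total <= 12, degenerate cells included."""
        total_checked = 0
        for n in range(1, 13):
            for tp in range(n + 1):
                for tn in range(n - tp + 1):
                    for fp in range(n - tp - tn + 1):
                        fn = n - tp - tn - fp
                        m = class_metrics(ConfusionCounts(tp, tn, fp, fn))
                        expect = brute_force_metrics(tp, tn, fp, fn)
                        got = (m.PRE, m.REC, m.ACU, m.ERR, m.F1S, m.MCC)
                        np.testing.assert_allclose(got, expect, rtol=0, atol=1e-12)
                        total_checked += 1
        assert total_checked == 1819  # C(16,4) - 1 matrices

    def test_against_reference_library_on_random_matrices(self):
        metrics = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(0)
        for _ in range(40):
            tp, tn, fp, fn = rng.integers(0, 20, size=4)
            if tp + tn + fp + fn == 0:
                continue
            y_true = [1] * tp + [0] * tn + [0] * fp + [1] * fn
            y_pred = [1] * tp + [0] * tn + [1] * fp + [0] * fn
            m = class_metrics(ConfusionCounts(int(tp), int(tn), int(fp), int(fn)))
            assert m.PRE == pytest.approx(
                100 * metrics.precision_score(y_true, y_pred, zero_division=0)
            )
            assert m.REC == pytest.approx(
                100 * metrics.recall_score(y_true, y_pred, zero_division=0)
            )
            assert m.F1S == pytest.approx(
                metrics.f1_score(y_true, y_pred, zero_division=0)
            )
            if len(set(y_true)) > 1 and len(set(y_pred)) > 1:
                assert m.MCC == pytest.approx(metrics.matthews_corrcoef(y_true, y_pred))

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            class_metrics(ConfusionCounts(0, 0, 0, 0))


class TestClassificationReport:
    def test_degenerate_binary_macro_averages(self):
        y_true = ["blended"] * 41 + ["pure"] * 9
        y_pred = ["blended"] * 50
        rep = classification_report(y_true, y_pred, ["pure", "blended"])
        assert rep.overall.PRE == pytest.approx(41.0)
        assert rep.overall.REC == pytest.approx(50.0)
        assert rep.per_class["blended"].F1S == pytest.approx(0.90, abs=0.005)
        assert rep.overall.MCC == 0.0

    def test_binary_acu_err_mcc_identical_across_classes(self):
        rng = np.random.default_rng(3)
        y_true = rng.choice(["a", "b"], 40).tolist()
        y_pred = rng.choice(["a", "b"], 40).tolist()
        rep = classification_report(y_true, y_pred, ["a", "b"])
        a, b = rep.per_class["a"], rep.per_class["b"]
        assert a.ACU == pytest.approx(b.ACU)
        assert a.ERR == pytest.approx(b.ERR)
        assert a.MCC == pytest.approx(b.MCC)

    def test_perfect_multiclass(self):
        y = ["a", "b", "c"] * 4
        rep = classification_report(y, y, ["a", "b", "c"])
        assert rep.overall.ACU == 100.0 and rep.overall.MCC == 1.0

    def test_overall_is_unweighted_mean(self):
        rng = np.random.default_rng(9)
        y_true = rng.choice(["a", "b", "c"], 60).tolist()
        y_pred = rng.choice(["a", "b", "c"], 60).tolist()
        rep = classification_report(y_true, y_pred, ["a", "b", "c"])
        for f in ("PRE", "REC", "ACU", "ERR", "F1S", "MCC"):
            mean = np.mean([getattr(m, f) for m in rep.per_class.values()])
            assert getattr(rep.overall, f) == pytest.approx(mean)

    def test_unseen_predicted_label_rejected(self):
        with pytest.raises(ValueError):
            classification_report(["a"], ["z"], ["a", "b"])


class TestRegressionStatistics:
    def test_perfect_prediction(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        assert rmse(a, a) == 0.0
        assert r_squared(a, a) == pytest.approx(1.0)
        assert r0_squared(a, a) == pytest.approx(1.0)

    def test_constant_prediction(self):
        a = np.array([1.0, 2.0, 3.0])
        p = np.full(3, 2.0)
        assert rmse(a, p) == pytest.approx(np.sqrt(np.mean((a - 2.0) ** 2)))
        with pytest.raises(ValueError):
            r_squared(a, p)

    def test_textbook_formulas_on_random_vectors(self, rng):
        a, p = rng.normal(size=30), rng.normal(size=30)
        assert rmse(a, p) == pytest.approx(float(np.sqrt(np.mean((a - p) ** 2))))
        assert r_squared(a, p) == pytest.approx(float(np.corrcoef(a, p)[0, 1] ** 2))

    def test_proportional_prediction_has_unit_r0(self, rng):
        a = rng.uniform(1, 10, 25)
        assert r0_squared(a, 2.0 * a) == pytest.approx(1.0)

    def test_large_intercept_depresses_r0_below_r2(self, rng):
        a = rng.uniform(0, 50, 40)
        p = a + 30.0 + rng.normal(0, 0.5, 40)
        assert r0_squared(a, p) < r_squared(a, p)

    @pytest.mark.parametrize(
        "R2,R02,expect",
        [
            (0.9, 0.9, 0.9),
            (1.0, 1.0, 1.0),
            (0.97, 0.95, 0.97 * (1 - math.sqrt(0.02))),
        ],
    )
    def test_rm_squared_values(self, R2, R02, expect):
        assert rm_squared(R2, R02) == pytest.approx(expect)

    def test_rm_equals_r2_when_fits_coincide(self, rng):
        a = rng.uniform(0, 50, 30)
        p = 1.3 * a  # through-origin and free fits coincide
        R2, R02 = r_squared(a, p), r0_squared(a, p)
        # sqrt amplifies float error in the gap: 1e-16 becomes 1e-8
        assert rm_squared(R2, R02) == pytest.approx(R2, abs=1e-7)

    @pytest.mark.parametrize(
        "rcal,rrand,expect",
        [(0.99, 0.64, 0.59), (0.96, 0.06, 0.93), (0.81, 0.0, 0.81)],
    )
    def test_crp_squared_values(self, rcal, rrand, expect):
        assert round(crp_squared(rcal, rrand), 2) == expect

    def test_crp_squared_clamps_negative_radicand(self):
        with pytest.warns(UserWarning):
            assert crp_squared(0.3, 0.6) == 0.0


class TestYRandomization:
    @staticmethod
    def _lda_accuracy(X, y):
        pred = predict_lda(fit_lda(X, y), X)
        return {"accuracy": float(np.mean(np.asarray(pred) == np.asarray(y)))}

    def test_identity_hook_reproduces_original_scores(self, rng):
        X = np.vstack([rng.normal(0, 1, (20, 2)), rng.normal(5, 1, (20, 2))])
        y = np.array(["a"] * 20 + ["b"] * 20)
        res = y_randomization(self._lda_accuracy, X, y, n_permutations=1, identity=True)
        assert res.per_permutation_scores[0] == self._lda_accuracy(X, y)

    def test_noise_labels_give_majority_share_accuracy(self, rng):
        # pure-noise features, 80/20 labels: permuted LDA accuracy should
        # hover at the majority share (the binomial null)
        X = rng.normal(size=(100, 3))
        y = np.array(["maj"] * 80 + ["min"] * 20)
        res = y_randomization(self._lda_accuracy, X, y, n_permutations=30, seed=5)
        assert res.mean_scores["accuracy"] == pytest.approx(0.8, abs=0.05)

    def test_same_seed_same_scores(self, rng):
        X = rng.normal(size=(30, 3))
        y = np.array(["a", "b"] * 15)
        r1 = y_randomization(self._lda_accuracy, X, y, n_permutations=5, seed=11)
        r2 = y_randomization(self._lda_accuracy, X, y, n_permutations=5, seed=11)
        assert r1.per_permutation_scores == r2.per_permutation_scores

    def test_permutations_preserve_label_multiset(self, rng):
        X = rng.normal(size=(40, 2))
        y = np.array(["a"] * 30 + ["b"] * 10)
        seen = []

        def spy(Xp, yp):
            seen.append(sorted(yp.tolist()))
            return {"s": 0.0}

        y_randomization(spy, X, y, n_permutations=4, seed=0)
        assert all(s == sorted(y.tolist()) for s in seen)

    def test_fit_failures_are_counted_and_skipped(self, rng):
        X = rng.normal(size=(10, 2))
        y = np.arange(10)
        calls = {"n": 0}

        def flaky(Xp, yp):
            calls["n"] += 1
            if calls["n"] % 2:
                raise RuntimeError("boom")
            return {"s": 1.0}

        res = y_randomization(flaky, X, y, n_permutations=6, seed=0)
        assert res.n_failures == 3
        assert len(res.per_permutation_scores) == 3
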