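"""Confusion-matrix metrics and repeated stratified cross-validation."""

import numpy as np
import pytest

from hsin.evaluation import (
    ConfusionMatrix,
    confusion_matrix,
    f_score,
    kappa,
    metrics_report,
    overall_accuracy,
    per_class_accuracy,
    repeated_stratified_cv,
)
from hsin.exceptions import InvalidInputError

CM = ConfusionMatrix(np.array([[40, 10], [20, 30]]), ["a", "b"])


class TestConfusionMatrix:
    def test_perfect_prediction_is_diagonal(self):
        cm = confusion_matrix(["a", "b", "a"], ["a", "b", "a"])
        np.testing.assert_array_equal(cm.counts, [[2, 0], [0, 1]])

    def test_enumeration_example(self):
        cm = confusion_matrix(["A", "A", "B", "B"], ["A", "B", "B", "B"])
        np.testing.assert_array_equal(cm.counts, [[1, 1], [0, 2]])

    def test_empty_input_rejected(self):
        with pytest.raises(InvalidInputError):
            confusion_matrix([], [])

    def test_unknown_label_rejected(self):
        with pytest.raises(InvalidInputError):
            confusion_matrix(["a"], ["c"], class_names=["a", "b"])

    def test_agrees_with_sklearn(self, rng):
        """Cross-check against the scikit-learn confusion matrix."""
        from sklearn.metrics import confusion_matrix as sk

        y1 = rng.choice(list("abcd"), 200)
        y2 = rng.choice(list("abcd"), 200)
        cm = confusion_matrix(y1, y2, class_names=list("abcd"))
        np.testing.assert_array_equal(cm.counts, sk(y1, y2, labels=list("abcd")))


class TestMetrics:
    def test_overall_accuracy(self):
        assert overall_accuracy(CM) == pytest.approx(0.70)
        diag = ConfusionMatrix(np.diag([5, 7]), ["a", "b"])
        assert overall_accuracy(diag) == 1.0
        off = ConfusionMatrix(np.array([[0, 3], [4, 0]]), ["a", "b"])
        assert overall_accuracy(off) == 0.0

    def test_f_score_hand_arithmetic(self):
        """Class a: P=40/60, R=40/50 -> F=8/11; class b: P=30/40, R=30/50
        -> F = 2*(0.75*0.6)/1.35 = 2/3; macro mean."""
        assert f_score(CM) == pytest.approx((8 / 11 + 2 / 3) / 2)
        diag = ConfusionMatrix(np.diag([5, 7]), ["a", "b"])
        assert f_score(diag) == 1.0

    def test_f_score_degenerate_class_warns(self):
        cm = ConfusionMatrix(np.array([[3, 0], [2, 0]]), ["a", "b"])
        with pytest.warns(UserWarning):
            f = f_score(cm)
        assert 0.0 <= f < 1.0

    def test_kappa_hand_arithmetic(self):
        """P_o = 0.7, P_c = 0.5 -> kappa = 0.4."""
        assert kappa(CM) == pytest.approx(0.4)
        diag = ConfusionMatrix(np.diag([5, 7]), ["a", "b"])
        assert kappa(diag) == 1.0

    def test_kappa_near_zero_for_independent_predictions(self, rng):
        y = rng.choice(["a", "b"], 4000)
        pred = rng.choice(["a", "b"], 4000)
        assert abs(kappa(confusion_matrix(y, pred))) < 0.05

    def test_kappa_agrees_with_sklearn(self, rng):
        from sklearn.metrics import cohen_kappa_score

        y1 = rng.choice(list("abc"), 300)
        y2 = np.where(rng.random(300) < 0.7, y1, rng.choice(list("abc"), 300))
        cm = confusion_matrix(y1, y2, class_names=list("abc"))
        assert kappa(cm) == pytest.approx(cohen_kappa_score(y1, y2))

    def test_per_class_accuracy(self):
        assert per_class_accuracy(CM) == {"a": 0.8, "b": 0.6}
        diag = ConfusionMatrix(np.diag([5, 7]), ["a", "b"])
        assert per_class_accuracy(diag) == {"a": 1.0, "b": 1.0}

    def test_per_class_accuracy_empty_row_flagged(self):
        cm = ConfusionMatrix(np.array([[3, 1], [0, 0]]), ["a", "b"])
        with pytest.warns(UserWarning):
            out = per_class_accuracy(cm)
        assert np.isnan(out["b"])


class TestMetricProperties:
    def test_kappa_not_above_overall_accuracy(self, rng):
        """For any matrix with positive chance agreement, kappa <= OA."""
        for _ in range(50):
            counts = rng.integers(0, 30, (3, 3))
            if counts.sum() == 0 or counts.sum(1).min() == 0:
                continue
            cm = ConfusionMatrix(counts, ["a", "b", "c"])
            assert kappa(cm) <= overall_accuracy(cm) + 1e-12

    def test_macro_f_invariant_to_relabeling(self, rng):
        counts = rng.integers(1, 30, (4, 4))
        cm = ConfusionMatrix(counts, list("abcd"))
        perm = rng.permutation(4)
        cm_p = ConfusionMatrix(counts[np.ix_(perm, perm)],
                               [list("abcd")[i] for i in perm])
        assert f_score(cm) == pytest.approx(f_score(cm_p))

    def test_transpose_swaps_precision_and_recall(self, rng):
        counts = rng.integers(1, 30, (3, 3))
        cm = ConfusionMatrix(counts, list("abc"))
        cm_t = ConfusionMatrix(counts.T, list("abc"))
        c = counts.astype(float)
        recall = np.diag(c) / c.sum(axis=1)
        precision_t = np.diag(c.T) / c.T.sum(axis=0)
        np.testing.assert_allclose(recall, precision_t)
        # F is symmetric in P and R, hence transpose-invariant
        assert f_score(cm) == pytest.approx(f_score(cm_t))


class TestRepeatedCV:
    def _patchset(self, n_per_class=12, noiseless=True):
        from hsin.patches import PatchSet

        rng = np.random.default_rng(0)
        protos = rng.normal(0, 1, (3, 5, 5, 4)).astype(np.float32)
        data, labels = [], []
        for k, c in enumerate("abc"):
            block = np.repeat(protos[None, k], n_per_class, axis=0)
            if not noiseless:
                block = block + rng.normal(0, 0.05, block.shape).astype(np.float32)
            data.append(block)
            labels += [c] * n_per_class
        return PatchSet(np.concatenate(data), np.array(labels))

    def _builder(self, input_shape, n_classes):
        from hsin.models import LayerSpec, ModelSpec

        return ModelSpec(
            "toy", tuple(input_shape),
            [
                LayerSpec("flatten", "flatten"),
                LayerSpec("dense", "dense", units=8, activation="relu"),
                LayerSpec("dense", "out", units=n_classes, activation="softmax"),
            ],
            n_classes,
        )

    def test_fold_structure(self):
        from hsin.models import TrainConfig

        ps = self._patchset()
        reports, summary = repeated_stratified_cv(
            ps, self._builder, TrainConfig(epochs=1, seed=0), folds=3, repeats=2,
        )
        assert len(reports) == 6
        sizes = [r.n_samples for r in reports]
        assert max(sizes) - min(sizes) <= 3  # one per class
        assert sum(sizes) == 2 * len(ps)  # every sample tested once per repeat

    def test_memorizing_model_achieves_perfect_cv_accuracy(self):
        from hsin.models import TrainConfig

        ps = self._patchset(noiseless=True)
        reports, summary = repeated_stratified_cv(
            ps, self._builder, TrainConfig(epochs=30, seed=0), folds=3, repeats=1,
        )
        assert summary["overall_accuracy"][0] == pytest.approx(1.0)

    def test_class_smaller_than_folds_rejected(self):
        from hsin.models import TrainConfig

        ps = self._patchset(n_per_class=4)
        with pytest.raises(InvalidInputError, match="folds"):
            repeated_stratified_cv(ps, self._builder, TrainConfig(epochs=1),
                                   folds=10)
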