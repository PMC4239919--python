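"""RBF-SVM vigilance classifier: level merging, kernel, pruning, metrics."""

import numpy as np
import pandas as pd
import pytest

from sleeponset import (
    alarm,
    evaluate,
    merge_levels,
    predict,
    prune_support_vectors,
    rbf_kernel,
    train_classifier,
)
from sleeponset.classification import VigilanceModel
from sleeponset.errors import ValidationError


def blobs(n_per_class, centers, spread, seed):
    rng = np.random.default_rng(seed)
    xs, ys = [], []
    for label, c in centers.items():
        xs.append(rng.normal(c, spread, size=(n_per_class, len(c))))
        ys.append(np.full(n_per_class, label))
    return np.vstack(xs), np.concatenate(ys)


CENTERS_4 = {6: (0.0, 0.0), 5: (6.0, 0.0), 4: (0.0, 6.0), 3: (6.0, 6.0)}


class TestMergeLevels:
    def test_mapping(self):
        np.testing.assert_array_equal(merge_levels([6, 5, 4, 3, 2, 1]), [6, 5, 4, 3, 3, 3])

    @pytest.mark.parametrize("bad", [0, 7, -1])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValidationError):
            merge_levels([6, bad])


class TestRbfKernel:
    def test_zero_distance_is_one(self):
        x = np.array([1.0, 2.0, 3.0])
        assert rbf_kernel(x, x, sigma=2.0) == pytest.approx(1.0)

    def test_characteristic_distance(self):
        sigma = 1.5
        x = np.zeros(4)
        xi = np.full(4, np.sqrt(2.0 * sigma**2 / 4.0))  # ||x-xi||^2 = 2 sigma^2
        assert rbf_kernel(x, xi, sigma) == pytest.approx(np.exp(-1.0))

    def test_monotone_decay_to_zero(self):
        x = np.zeros(2)
        vals = [rbf_kernel(x, np.array([d, 0.0]), 1.0) for d in (1, 2, 5, 20)]
        assert all(a > b for a, b in zip(vals, vals[1:]))
        assert vals[-1] < 1e-8

    def test_invalid_sigma_and_dimension(self):
        with pytest.raises(ValidationError):
            rbf_kernel(np.zeros(2), np.zeros(2), 0.0)
        with pytest.raises(ValidationError):
            rbf_kernel(np.zeros(2), np.zeros(3), 1.0)


class TestTrainPredict:
    def test_separable_blobs_perfect_cv(self):
        x, y = blobs(30, CENTERS_4, 0.3, seed=0)
        model = train_classifier(x, y, folds=5, seed=0)
        assert model.cv_accuracy == pytest.approx(1.0)
        np.testing.assert_array_equal(predict(model, x), merge_levels(y))

    def test_shuffled_labels_near_chance(self):
        x, y = blobs(40, CENTERS_4, 0.3, seed=1)
        rng = np.random.default_rng(1)
        model = train_classifier(x, rng.permutation(y), folds=5, seed=1)
        majority = 0.25
        assert model.cv_accuracy < majority + 0.15

    def test_duplicated_training_set_same_predictions(self):
        x, y = blobs(25, CENTERS_4, 0.5, seed=2)
        grid = np.random.default_rng(3).uniform(-2, 8, size=(100, 2))
        m1 = train_classifier(x, y, sigma_grid=(2.0,), c_grid=(10.0,), seed=0)
        m2 = train_classifier(
            np.vstack([x, x]), np.concatenate([y, y]), sigma_grid=(2.0,), c_grid=(10.0,), seed=0
        )
        np.testing.assert_array_equal(predict(m1, grid), predict(m2, grid))

    def test_determinism(self):
        x, y = blobs(25, CENTERS_4, 0.8, seed=4)
        m1 = train_classifier(x, y, seed=7)
        m2 = train_classifier(x, y, seed=7)
        assert m1.sigma == m2.sigma and m1.C == m2.C
        grid = np.random.default_rng(5).uniform(-2, 8, size=(50, 2))
        np.testing.assert_array_equal(predict(m1, grid), predict(m2, grid))

    def test_degenerate_class_rejected(self):
        x = np.random.default_rng(0).normal(size=(20, 2))
        with pytest.raises(ValidationError):
            train_classifier(x, np.full(20, 6))

    def test_missing_feature_and_nan_rejected(self):
        x, y = blobs(20, {6: (0.0,), 5: (4.0,)}, 0.3, seed=5)
        model = train_classifier(x, y, folds=5, seed=0)
        with pytest.raises(ValidationError):
            predict(model, pd.DataFrame({"other": [1.0]}))
        with pytest.raises(ValidationError):
            predict(model, np.array([[np.nan]]))

    def test_model_round_trips_through_file(self, tmp_path):
        x, y = blobs(20, CENTERS_4, 0.5, seed=6)
        model = train_classifier(x, y, sigma_grid=(2.0,), c_grid=(10.0,), seed=0)
        path = tmp_path / "model.pkl"
        model.save(path)
        back = VigilanceModel.load(path)
        grid = np.random.default_rng(7).uniform(-2, 8, size=(50, 2))
        np.testing.assert_array_equal(predict(model, grid), predict(back, grid))


class TestPruning:
    def test_full_fraction_is_identity(self):
        x, y = blobs(30, CENTERS_4, 1.0, seed=8)
        model = train_classifier(x, y, sigma_grid=(2.0,), c_grid=(10.0,), seed=0)
        pruned = prune_support_vectors(model, 1.0)
        assert pruned.n_support_vectors == model.n_support_vectors
        grid = np.random.default_rng(9).uniform(-2, 8, size=(200, 2))
        np.testing.assert_array_equal(predict(model, grid), predict(pruned, grid))

    def test_thirty_percent_on_separable_problem(self):
        x, y = blobs(60, CENTERS_4, 0.6, seed=10)
        x_test, y_test = blobs(40, CENTERS_4, 0.6, seed=11)
        model = train_classifier(x, y, seed=0)
        pruned = prune_support_vectors(model, 0.30)
        truth = merge_levels(y_test)
        acc = 100.0 * np.mean(predict(model, x_test) == truth)
        acc_pruned = 100.0 * np.mean(predict(pruned, x_test) == truth)
        assert pruned.n_support_vectors < model.n_support_vectors
        assert abs(acc - acc_pruned) <= 1.0

    @pytest.mark.parametrize("fraction", [0.0, -0.1, 1.5])
    def test_invalid_fraction_rejected(self, fraction):
        x, y = blobs(20, CENTERS_4, 0.5, seed=12)
        model = train_classifier(x, y, sigma_grid=(2.0,), c_grid=(10.0,), seed=0)
        with pytest.raises(ValidationError):
            prune_support_vectors(model, fraction)


class TestEvaluate:
    def test_perfect_predictions(self):
        y = np.array([6, 5, 4, 3] * 5)
        rep = evaluate(y, y)
        assert rep.accuracy == 100.0 and rep.sensitivity == 100.0 and rep.specificity == 100.0

    def test_all_one_class_on_balanced_truth(self):
        truth = np.repeat([6, 5, 4, 3], 10)
        pred = np.full(40, 6)
        rep = evaluate(pred, truth)
        assert rep.accuracy == pytest.approx(25.0)
        assert rep.specificity == pytest.approx(75.0)  # (0 + 1 + 1 + 1) / 4

    def test_two_class_confusion_arithmetic(self):
        # confusion matrix [[8, 2], [1, 9]] -> accuracy 17/20
        truth = np.array([6] * 10 + [3] * 10)
        pred = np.array([6] * 8 + [3] * 2 + [3] * 9 + [6] * 1)
        rep = evaluate(pred, truth)
        assert rep.accuracy == pytest.approx(85.0)
        assert rep.confusion.loc[6, 6] == 8 and rep.confusion.loc[3, 6] == 1
        assert rep.confusion.to_numpy().sum() == rep.n_test == 20

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            evaluate(np.array([]), np.array([]))


class TestAlarm:
    def test_threshold_semantics(self):
        assert not alarm(6)  # awake, default threshold = moderately drowsy
        assert not alarm(5)
        assert alarm(4)
        assert alarm(3)

    def test_threshold_awake_always_fires(self):
        assert all(alarm(c, threshold_class=6) for c in (6, 5, 4, 3))

    def test_invalid_class_rejected(self):
        with pytest.raises(ValidationError):
            alarm(2)
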