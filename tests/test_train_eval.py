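"""Tests for the fold protocol, augmentation, training loop and metrics."""

from dataclasses import replace

import numpy as np
import pytest
from scipy.stats import friedmanchisquare
from sklearn.metrics import precision_score, recall_score, roc_auc_score

from aplscreen.compact_net import CANONICAL_CONFIG
from aplscreen.synthetic_smear import generate_cell_dataset
from aplscreen.train_eval import (
    ConfusionMatrix,
    TrainConfig,
    augment,
    confusion,
    friedman_test,
    lr_at_epoch,
    metrics_from_confusion,
    nemenyi_cd,
    oversample_minority,
    roc_auc,
    stratified_kfold,
    train_model,
)
# class sizes of the clinical single-cell dataset
CLINICAL_CLASS_SIZES = (953, 1063, 976, 912, 628, 2282)


class TestStratifiedKFold:
    def test_five_by_five_exact(self):
        labels = np.repeat(np.arange(5), 5)
        split = stratified_kfold(labels, 5, seed=0)
        for f in range(5):
            counts = np.bincount(labels[split.fold_of_sample == f], minlength=5)
            assert np.all(counts == 1)

    def test_clinical_class_sizes_within_one(self):
        labels = np.repeat(np.arange(6), CLINICAL_CLASS_SIZES)
        split = stratified_kfold(labels, 5, seed=7)
        for f in range(5):
            counts = np.bincount(labels[split.fold_of_sample == f], minlength=6)
            for c, size in enumerate(CLINICAL_CLASS_SIZES):
                assert abs(counts[c] - size / 5) <= 1

    def test_partition(self):
        labels = np.repeat(np.arange(6), 13)
        split = stratified_kfold(labels, 5, seed=1)
        assert np.all(split.fold_of_sample >= 0)
        assert np.all(split.fold_of_sample < 5)
        union = np.concatenate([np.flatnonzero(split.fold_of_sample == f)
                                for f in range(5)])
        assert sorted(union.tolist()) == list(range(len(labels)))

    def test_rounds_rotate_distinct_test_folds(self):
        labels = np.repeat(np.arange(6), 10)
        split = stratified_kfold(labels, 5, seed=2)
        tests = [roles["test"] for roles in split.round_roles]
        assert sorted(tests) == [0, 1, 2, 3, 4]
        for roles in split.round_roles:
            assert len(roles["train"]) == 3
            assert set(roles["train"]) | {roles["val"], roles["test"]} == set(range(5))

    def test_deterministic_given_seed(self):
        labels = np.repeat(np.arange(6), 11)
        a = stratified_kfold(labels, 5, seed=9).fold_of_sample
        b = stratified_kfold(labels, 5, seed=9).fold_of_sample
        assert np.array_equal(a, b)

    def test_small_class_rejected_by_name(self):
        labels = ["a"] * 10 + ["b"] * 3
        with pytest.raises(ValueError, match="b"):
            stratified_kfold(labels, 5, seed=0)


class TestAugment:
    def _dihedral_variants(self, crop):
        out = []
        for flip_h in (False, True):
            base = crop[:, ::-1] if flip_h else crop
            for flip_v in (False, True):
                b2 = base[::-1, :] if flip_v else base
                for k in range(4):
                    out.append(np.rot90(b2, k))
        return out

    def test_output_is_dihedral_transform(self):
        rng = np.random.default_rng(0)
        crop = rng.integers(0, 256, (8, 8, 3), dtype=np.uint8)
        for _ in range(20):
            aug = augment(crop, rng)
            assert any(np.array_equal(aug, v) for v in self._dihedral_variants(crop))

    def test_shape_preserved(self):
        rng = np.random.default_rng(1)
        crop = np.zeros((16, 16, 3), dtype=np.uint8)
        assert augment(crop, rng).shape == crop.shape

    def test_reproducible_given_seed(self):
        crop = np.random.default_rng(2).integers(0, 256, (8, 8, 3), dtype=np.uint8)
        seq_a = [augment(crop, np.random.default_rng(5)) for _ in range(1)]
        seq_b = [augment(crop, np.random.default_rng(5)) for _ in range(1)]
        for a, b in zip(seq_a, seq_b):
            assert np.array_equal(a, b)


class TestOversample:
    def test_balanced_input_is_permutation(self):
        labels = np.repeat(np.arange(3), 4)
        idx = oversample_minority(labels, np.random.default_rng(0))
        assert sorted(idx.tolist()) == list(range(12))

    def test_two_class_imbalance(self):
        labels = np.array([0] * 10 + [1] * 5)
        idx = oversample_minority(labels, np.random.default_rng(1))
        assert len(idx) == 20
        assert (labels[idx] == 0).sum() == 10
        assert (labels[idx] == 1).sum() == 10

    def test_singleton_class_repeated(self):
        labels = np.array([0] * 7 + [1])
        idx = oversample_minority(labels, np.random.default_rng(2))
        assert (labels[idx] == 1).sum() == 7


class TestTraining:
    def test_lr_schedule(self):
        tc = TrainConfig()
        assert lr_at_epoch(tc, 0) == pytest.approx(5e-3)
        assert lr_at_epoch(tc, 9) == pytest.approx(5e-3)
        assert lr_at_epoch(tc, 10) == pytest.approx(1e-3)
        assert lr_at_epoch(tc, 20) == pytest.approx(2e-4)

    def test_small_scale_training_learns(self):
        # reduced-resolution twin of the full training run
        cfg = replace(CANONICAL_CONFIG, block_channels=(8, 16),
                      block_strides=(1, 1), se_ratio=4, fc_hidden=32,
                      input_size=56)
        crops, labels = generate_cell_dataset(12, seed=3, crop_size=56)
        rng = np.random.default_rng(0)
        order = rng.permutation(len(labels))
        split = int(0.8 * len(order))
        tr, va = order[:split], order[split:]
        tc = TrainConfig(seed=0, epochs=6, batch_size=8,
                         early_stop_val_acc=0.99)
        model, log = train_model(cfg, tc, crops[tr], labels[tr],
                                 crops[va], labels[va])
        assert log[0]["lr"] == pytest.approx(5e-3)
        assert {"epoch", "lr", "train_loss", "val_acc"} <= set(log[0])
        assert log[-1]["train_loss"] < log[0]["train_loss"]
        assert max(e["val_acc"] for e in log) >= 0.5

    def test_input_stats_frozen_from_training_data(self):
        cfg = replace(CANONICAL_CONFIG, block_channels=(4,), block_strides=(1,),
                      use_se=False, fc_hidden=8, input_size=32)
        crops, labels = generate_cell_dataset(2, seed=1, crop_size=32)
        tc = TrainConfig(seed=0, epochs=1, batch_size=4)
        model, _ = train_model(cfg, tc, crops, labels)
        expected = (crops.astype(np.float32) / 255.0).mean(axis=(0, 1, 2))
        np.testing.assert_allclose(model.input_mean, expected, atol=1e-5)


class TestCrossValidate:
    def test_full_protocol_at_reduced_scale(self):
        """Five rounds of the fold rotation run end to end and report five
        confusion matrices plus mean +/- sd summaries."""
        from aplscreen.train_eval import cross_validate
        cfg = replace(CANONICAL_CONFIG, block_channels=(8, 16),
                      block_strides=(1, 1), se_ratio=4, fc_hidden=16,
                      input_size=48)
        crops, labels = generate_cell_dataset(10, seed=5, crop_size=48)
        tc = TrainConfig(seed=1, epochs=2, batch_size=8)
        result = cross_validate(crops, labels, cfg, tc)
        assert len(result["rounds"]) == 5
        test_folds = set()
        for rd in result["rounds"]:
            assert rd["confusion"].total == 12  # one fold of 60 samples
            test_folds.add(rd["round"])
        assert test_folds == {0, 1, 2, 3, 4}
        for key in ("tpr", "tnr", "precision", "fbeta", "auc"):
            assert {"mean", "sd"} <= set(result["summary"][key])
            assert np.isfinite(result["summary"][key]["mean"])

    def test_roc_curve_points_integrate_to_auc(self):
        from aplscreen.train_eval import roc_curve_points
        rng = np.random.default_rng(11)
        y = rng.integers(0, 6, 200)
        scores = rng.random((200, 6))
        pts = roc_curve_points(scores, y, class_idx=2)
        assert list(pts.columns) == ["fpr", "tpr", "threshold"]
        area = np.trapezoid(pts["tpr"], pts["fpr"])
        aucs, _ = roc_auc(scores, y)
        assert area == pytest.approx(aucs[2], abs=1e-12)


class TestConfusion:
    def test_perfect_predictions_diagonal(self):
        y = np.array([0, 1, 2, 3, 4, 5, 5])
        cm = confusion(y, y)
        assert cm.n_misclassified == 0
        assert np.array_equal(np.diag(cm.counts), np.bincount(y, minlength=6))

    def test_clinical_matrix_totals(self, clinical_confusion):
        cm = ConfusionMatrix(clinical_confusion)
        assert cm.total == 1361
        assert cm.n_misclassified == 11

    def test_matches_brute_force_tally(self):
        rng = np.random.default_rng(0)
        y_true = rng.integers(0, 6, 200)
        y_pred = rng.integers(0, 6, 200)
        cm = confusion(y_true, y_pred)
        for i in range(6):
            for j in range(6):
                assert cm.counts[i, j] == int(np.sum((y_true == i) & (y_pred == j)))

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            confusion(["promyelocyte"], ["blast"])

    def test_accepts_class_names(self):
        cm = confusion(["promyelocyte", "basophil"], ["promyelocyte", "basophil"])
        assert cm.counts[4, 4] == 1 and cm.counts[0, 0] == 1


class TestMetrics:
    def test_identity_matrix_is_perfect(self):
        ms = metrics_from_confusion(ConfusionMatrix(np.eye(6, dtype=int) * 10))
        for key in ("tpr", "tnr", "precision", "fbeta"):
            assert ms.weighted[key] == pytest.approx(1.0)
        assert ms.weighted["fpr"] == pytest.approx(0.0)
        assert ms.weighted["fnr"] == pytest.approx(0.0)

    def test_complement_identities_hold_exactly(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            counts = rng.integers(0, 30, (6, 6))
            counts[rng.integers(0, 6)] += 5  # ensure non-empty
            ms = metrics_from_confusion(ConfusionMatrix(counts))
            tpr, fnr = ms.per_class["tpr"], ms.per_class["fnr"]
            tnr, fpr = ms.per_class["tnr"], ms.per_class["fpr"]
            ok = ~np.isnan(tpr)
            np.testing.assert_allclose(tpr[ok] + fnr[ok], 1.0, atol=1e-12)
            ok = ~np.isnan(tnr)
            np.testing.assert_allclose(tnr[ok] + fpr[ok], 1.0, atol=1e-12)

    def test_weighted_tpr_equals_accuracy(self):
        rng = np.random.default_rng(2)
        counts = rng.integers(1, 40, (6, 6))
        cm = ConfusionMatrix(counts)
        ms = metrics_from_confusion(cm)
        assert ms.weighted["tpr"] == pytest.approx(np.trace(counts) / counts.sum())

    def test_agrees_with_sklearn_on_random_labels(self):
        rng = np.random.default_rng(3)
        y_true = rng.integers(0, 6, 400)
        y_pred = rng.integers(0, 6, 400)
        ms = metrics_from_confusion(confusion(y_true, y_pred))
        np.testing.assert_allclose(
            ms.per_class["tpr"], recall_score(y_true, y_pred, average=None,
                                              labels=range(6)), atol=1e-12)
        np.testing.assert_allclose(
            ms.per_class["precision"],
            precision_score(y_true, y_pred, average=None, labels=range(6),
                            zero_division=np.nan), atol=1e-12)
        assert ms.weighted["tpr"] == pytest.approx(
            recall_score(y_true, y_pred, average="weighted"))

    def test_zero_denominator_is_nan_with_warning(self):
        counts = np.zeros((6, 6), dtype=int)
        counts[0, 0] = 5  # only class 0 present; others have no support
        with pytest.warns(UserWarning, match="undefined"):
            ms = metrics_from_confusion(ConfusionMatrix(counts))
        assert np.isnan(ms.per_class["tpr"][1])
        assert ms.weighted["tpr"] == pytest.approx(1.0)


class TestRocAuc:
    def test_perfect_separation(self):
        y = np.array([0] * 5 + [1] * 5)
        scores = np.zeros((10, 6))
        scores[:5, 0] = 0.9
        scores[5:, 1] = 0.9
        aucs, _ = roc_auc(scores, y)
        assert aucs[0] == pytest.approx(1.0)
        assert aucs[1] == pytest.approx(1.0)

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(4)
        y = rng.integers(0, 6, 3000)
        scores = rng.random((3000, 6))
        scores /= scores.sum(axis=1, keepdims=True)
        aucs, weighted = roc_auc(scores, y)
        assert np.all(np.abs(aucs - 0.5) < 0.05)
        assert abs(weighted - 0.5) < 0.05

    def test_four_point_toy_matches_rank_count(self):
        # positives score 0.8 and 0.4; negatives 0.6 and 0.2
        # pairs won: (0.8 > 0.6, 0.8 > 0.2, 0.4 < 0.6, 0.4 > 0.2) = 3/4
        y = np.array([1, 1, 0, 0])
        scores = np.zeros((4, 6))
        scores[:, 1] = [0.8, 0.4, 0.6, 0.2]
        aucs, _ = roc_auc(scores, y)
        assert aucs[1] == pytest.approx(3 / 4)

    def test_matches_sklearn(self):
        rng = np.random.default_rng(5)
        y = rng.integers(0, 6, 300)
        scores = rng.random((300, 6))
        aucs, _ = roc_auc(scores, y)
        for c in range(6):
            assert aucs[c] == pytest.approx(
                roc_auc_score((y == c).astype(int), scores[:, c]))

    def test_absent_class_is_nan(self):
        y = np.zeros(10, dtype=int)
        scores = np.random.default_rng(6).random((10, 6))
        aucs, _ = roc_auc(scores, y)
        assert np.isnan(aucs[3])


class TestFriedmanNemenyi:
    def test_identical_models_give_zero_statistic(self):
        res = friedman_test(np.ones((3, 5)))
        assert res.friedman_statistic == 0.0
        assert res.p_value == 1.0

    def test_hand_ranked_three_by_three(self):
        m = np.array([[0.9, 0.8, 0.7],
                      [0.8, 0.7, 0.9],
                      [0.1, 0.2, 0.3]])
        res = friedman_test(m)
        # ranks per column: (1,2,3), (1,2,3), (2,1,3) -> averages 4/3, 5/3, 3
        np.testing.assert_allclose(res.average_ranks, [4 / 3, 5 / 3, 3])
        expected = 12 * 3 / (3 * 4) * ((4 / 3 - 2) ** 2 + (5 / 3 - 2) ** 2 + 1.0)
        assert res.friedman_statistic == pytest.approx(expected)

    def test_ranks_sum_to_conservation_constant(self):
        rng = np.random.default_rng(7)
        m = rng.random((4, 6))
        res = friedman_test(m)
        assert res.average_ranks.sum() * 6 == pytest.approx(4 * 5 / 2 * 6)

    def test_matches_scipy_without_ties(self):
        rng = np.random.default_rng(8)
        m = rng.random((4, 10))
        res = friedman_test(m)
        stat, p = friedmanchisquare(*m)
        assert res.friedman_statistic == pytest.approx(stat)
        assert res.p_value == pytest.approx(p)

    def test_single_measurement_rejected(self):
        with pytest.raises(ValueError, match="measurement"):
            friedman_test(np.ones((3, 1)))

    def test_nemenyi_reference_values(self):
        assert nemenyi_cd(4, 6, 0.05) == pytest.approx(1.915, abs=5e-4)
        assert nemenyi_cd(2, 1, 0.05) == pytest.approx(1.960, abs=1e-6)

    def test_nemenyi_decreases_with_more_measurements(self):
        cds = [nemenyi_cd(4, n) for n in (2, 5, 10, 50)]
        assert all(a > b for a, b in zip(cds, cds[1:]))

    def test_untabulated_parameters_rejected(self):
        with pytest.raises(ValueError):
            nemenyi_cd(11, 5, 0.05)
        with pytest.raises(ValueError):
            nemenyi_cd(4, 5, 0.01)
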