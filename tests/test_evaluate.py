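"""Evaluation protocol: splits, confusion, static features, baselines."""

import numpy as np
import pytest

from aeronose.evaluate import (
    ExperimentConfig,
    confusion_matrix,
    extract_static_features,
    holdout_split,
    run_baselines,
    run_experiment,
    snn_cross_validate,
    stratified_kfold,
)
from aeronose.recording import ConditionedRecording
from aeronose.snn import NetworkParams
from aeronose.synthetic import ClassProfile, SimulationConfig, generate_dataset


class TestStratifiedKfold:
    def test_folds_partition_and_stratify(self):
        labels = np.repeat([f"c{i}" for i in range(8)], 9)
        folds = stratified_kfold(labels, 5, seed=0)
        assert len(folds) == 5
        all_test = np.concatenate([t for _, t in folds])
        assert sorted(all_test) == list(range(72))
        for train, test in folds:
            assert set(train) | set(test) == set(range(72))
            assert not set(train) & set(test)
            counts = np.unique(labels[test], return_counts=True)[1]
            assert set(counts) <= {1, 2}  # 9 = 5 folds of 1 or 2 per class

    def test_leave_one_out_on_single_class(self):
        folds = stratified_kfold(["x"] * 4, 4, seed=1)
        assert all(len(test) == 1 for _, test in folds)

    def test_undersized_class_rejected(self):
        with pytest.raises(ValueError):
            stratified_kfold(["a"] * 2 + ["b"] * 9, 5, seed=0)


class TestHoldoutSplit:
    def test_nine_replicates_split_six_three(self):
        labels = np.repeat(["a", "b"], 9)
        train, test = holdout_split(labels, 0.7, seed=0)
        for c in ("a", "b"):
            assert np.sum(labels[train] == c) == 6
            assert np.sum(labels[test] == c) == 3

    def test_half_split_on_pairs(self):
        train, test = holdout_split(["a", "a", "b", "b"], 0.5, seed=0)
        assert len(train) == len(test) == 2

    def test_deterministic(self):
        labels = np.repeat(["a", "b", "c"], 6)
        a = holdout_split(labels, 0.7, seed=9)
        b = holdout_split(labels, 0.7, seed=9)
        np.testing.assert_array_equal(a[0], b[0])

    def test_empty_side_rejected(self):
        with pytest.raises(ValueError):
            holdout_split(["a", "a"], 0.3, seed=0)  # would leave no train sample


class TestConfusionMatrix:
    def test_perfect_predictions_are_diagonal(self):
        y = ["a", "b", "c", "a"]
        m = confusion_matrix(y, y, ["a", "b", "c"])
        assert np.all(m == np.diag([2, 1, 1]))

    def test_collapsed_predictions_fill_one_column(self):
        m = confusion_matrix(["a", "b", "c"], ["a", "a", "a"], ["a", "b", "c"])
        assert m[:, 0].sum() == 3 and m.sum() == 3

    def test_two_errors_in_24_gives_91_66_percent(self):
        """The hold-out structure: 8 classes x 3 replicates with two
        misclassifications -> 22/24 accuracy."""
        classes = [f"c{i}" for i in range(8)]
        true = np.repeat(classes, 3)
        pred = true.copy()
        pred[0], pred[10] = "c5", "c2"
        m = confusion_matrix(true, pred, classes)
        assert m.sum() == 24 and np.trace(m) == 22
        assert np.trace(m) / m.sum() == pytest.approx(22 / 24)
        assert m.sum(axis=1).tolist() == [3] * 8  # row sums = per-class counts

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="class_order"):
            confusion_matrix(["a"], ["z"], ["a", "b"])


def pulse_recording(height=1.0):
    """Unit-height rectangle spanning the whole 50 s sniffing phase."""
    values = np.zeros((90, 2))
    values[15:65, :] = height
    return ConditionedRecording(
        sensor_ids=[1, 2], values=values, mode="local",
        phase_boundaries=(0, 15, 65, 70, 90),
    )


class TestStaticFeatures:
    def test_flat_zero_signal(self):
        cond = ConditionedRecording(
            sensor_ids=[1], values=np.zeros((90, 1)), mode="local",
            phase_boundaries=(0, 15, 65, 70, 90),
        )
        f = extract_static_features(cond)
        assert f.max_delta[0] == 0 and f.auc[0] == 0 and f.slope[0] == 0

    def test_rectangular_pulse_hand_values(self):
        f = extract_static_features(pulse_recording())
        np.testing.assert_allclose(f.max_delta, 1.0)
        np.testing.assert_allclose(f.auc, 50.0)  # 50 samples x 1.0 x dt=1 s
        np.testing.assert_allclose(f.slope, 1.0)  # onset jump of 1 over dt=1

    def test_invariant_to_purge_content(self):
        a = pulse_recording()
        b = pulse_recording()
        b.values[70:, :] = 0.9  # perturb purge only
        fa, fb = extract_static_features(a), extract_static_features(b)
        np.testing.assert_array_equal(fa.as_vector(), fb.as_vector())

    def test_vector_length_is_three_per_sensor(self):
        assert extract_static_features(pulse_recording()).as_vector().shape == (6,)

    def test_missing_sniffing_phase_rejected(self):
        cond = ConditionedRecording(
            sensor_ids=[1], values=np.zeros((4, 1)), mode="local",
            phase_boundaries=(0, 4, 4, 4, 4),
        )
        with pytest.raises(ValueError, match="sniffing"):
            extract_static_features(cond)


class TestBaselines:
    def blobs(self, seed=0, sep=8.0):
        rng = np.random.default_rng(seed)
        X = np.vstack(
            [rng.normal(sep * c, 1.0, size=(10, 6)) for c in range(3)]
        )
        y = np.repeat(["a", "b", "c"], 10)
        return X, y

    def test_separable_blobs_score_near_one(self):
        X, y = self.blobs()
        table = run_baselines(X, y, k=5, seed=0)
        assert set(table["method"]) == {"LDA", "SVM", "KNN"}
        assert (table["accuracy"] > 0.95).all()

    def test_pca_reduces_to_three_components(self):
        from aeronose.evaluate import baseline_pipelines

        X, y = self.blobs()
        pipe = baseline_pipelines()["LDA"]
        pipe.fit(X, y)
        assert pipe.named_steps["pca"].n_components_ == 3

    def test_permuted_labels_score_near_chance(self):
        X, y = self.blobs(seed=1)
        rng = np.random.default_rng(0)
        accs = []
        for _ in range(5):
            table = run_baselines(X, rng.permutation(y), k=5, seed=0)
            accs.append(table["accuracy"].mean())
        assert np.mean(accs) < 0.55  # chance is 1/3

    def test_degenerate_features_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            run_baselines(np.ones((12, 4)), ["a", "b"] * 6, k=2)


SMALL_EXPERIMENT = ExperimentConfig(
    simulation=SimulationConfig(
        n_classes=3, n_sensors=12, replicates_per_class=5,
        excluded_sensor_ids=(5, 6), seed=3,
    ),
    excluded_sensor_ids=(5, 6),
    params=NetworkParams(neurons_per_class=4, weights_per_neuron=400),
    k_folds=3,
    seed=3,
)


class TestRunExperiment:
    def test_smoke_report_contents(self):
        report = run_experiment(SMALL_EXPERIMENT)
        assert len(report.fold_accuracies) == 3
        assert list(report.methods["method"]) == ["SNN", "LDA", "SVM", "KNN"]
        assert report.confusion.shape == (3, 3)
        assert report.confusion.sum() == 15  # every sample tested once in CV
        assert report.holdout_confusion.sum() == 6  # 2 held out per class
        assert 0 <= report.holdout_accuracy <= 1
        assert "CV accuracy" in report.to_text()

    def test_cv_confusion_consistent_with_fold_means(self):
        report = run_experiment(SMALL_EXPERIMENT)
        acc_from_confusion = np.trace(report.confusion) / report.confusion.sum()
        assert acc_from_confusion == pytest.approx(report.mean_accuracy)

    def test_deterministic_given_master_seed(self):
        a = run_experiment(SMALL_EXPERIMENT)
        b = run_experiment(SMALL_EXPERIMENT)
        assert a.fold_accuracies == b.fold_accuracies
        np.testing.assert_array_equal(a.confusion, b.confusion)
        assert a.holdout_accuracy == b.holdout_accuracy


class TestNormalizationEffect:
    def test_global_beats_local_on_amplitude_coded_classes(self):
        """When classes differ mainly in absolute response amplitude, local
        per-sample scaling erases the distinction and global min-max keeps
        it (direction-of-effect property, averaged over seeds)."""
        deltas_by_seed = {"global": [], "local": []}
        pattern = None
        for seed in range(3):
            rng = np.random.default_rng(seed)
            cfg = SimulationConfig(
                n_classes=3, n_sensors=10, replicates_per_class=5,
                excluded_sensor_ids=(), noise_sd=0.002, seed=seed,
            )
            pattern = rng.uniform(0.05, 0.2, size=10)
            profiles = [
                ClassProfile(f"class_{i}", amp * pattern, 7.0, 12.0)
                for i, amp in enumerate((0.5, 1.0, 2.0))
            ]
            recs, manifest = generate_dataset(cfg, profiles)
            labels = np.array(manifest["label"])
            for mode in ("global", "local"):
                exp = ExperimentConfig(
                    simulation=cfg, excluded_sensor_ids=(),
                    normalization=mode, k_folds=3,
                    params=NetworkParams(neurons_per_class=3,
                                         weights_per_neuron=400),
                    seed=seed,
                )
                accs, _, _ = snn_cross_validate(recs, labels, exp)
                deltas_by_seed[mode].append(np.mean(accs))
        assert np.mean(deltas_by_seed["global"]) >= np.mean(deltas_by_seed["local"])


class TestAccuracyDegradesWithSeparation:
    def test_monotone_degradation_toward_zero_separation(self):
        """Seed-averaged CV accuracy does not improve as the classes
        collapse onto each other."""
        def mean_acc(sep):
            accs = []
            for seed in range(3):
                cfg = SimulationConfig(
                    n_classes=3, n_sensors=10, replicates_per_class=5,
                    excluded_sensor_ids=(), class_separation=sep,
                    overlap_pairs=(), seed=seed,
                )
                recs, manifest = generate_dataset(cfg)
                exp = ExperimentConfig(
                    simulation=cfg, excluded_sensor_ids=(), k_folds=3,
                    params=NetworkParams(neurons_per_class=3,
                                         weights_per_neuron=400),
                    seed=seed,
                )
                a, _, _ = snn_cross_validate(
                    recs, np.array(manifest["label"]), exp
                )
                accs.append(np.mean(a))
            return np.mean(accs)

        assert mean_acc(0.0) <= mean_acc(1.0) + 1e-9
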