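"""Evaluation protocol: stratified CV, hold-out inference, baselines.

The spiking classifier is scored by stratified k-fold cross-validation and
by inference on a per-class hold-out split.  For comparison, the temporal
data is also reduced to three static per-sensor features — maximum
normalized resistance change, area under the response curve during the
sniffing phase, and maximal response slope — then standardized, projected
onto 3 principal components, and classified with linear discriminant
analysis, an RBF support-vector machine, and distance-weighted k-nearest
neighbours.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .aero import AeroEncoder
from .preprocessing import (
    DEFAULT_EXCLUDED,
    DEFAULT_WINDOW,
    ChannelExcluder,
    GlobalNormalizer,
    LocalNormalizer,
    RollingMean,
)
from .recording import SNIFFING_PHASE, ConditionedRecording
from .snn import NetworkParams, SnnClassifier
from .synthetic import SimulationConfig, generate_dataset


def stratified_kfold(labels, k: int, seed: int = 0):
    """Deterministic stratified folds as (train_indices, test_indices) pairs."""
    labels = np.asarray(labels)
    _, counts = np.unique(labels, return_counts=True)
    if k < 2:
        raise ValueError("k must be >= 2")
    if counts.min() < k:
        raise ValueError(f"every class needs >= {k} samples for {k}-fold CV")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(len(labels)), labels))


def holdout_split(labels, train_fraction: float, seed: int = 0):
    """Per-class hold-out split; with 9 replicates at 0.7 this gives 6 train
    and 3 test per class (floor rounding on the training side)."""
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must lie in (0, 1)")
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    train, test = [], []
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        rng.shuffle(idx)
        n_train = int(np.floor(train_fraction * len(idx)))
        if n_train == 0 or n_train == len(idx):
            raise ValueError(
                f"class {c!r}: split {train_fraction} leaves an empty side"
            )
        train.extend(idx[:n_train])
        test.extend(idx[n_train:])
    return np.array(sorted(train)), np.array(sorted(test))


def confusion_matrix(true_labels, predicted_labels, class_order) -> np.ndarray:
    """Count matrix with entry (i, j) = true class i predicted as class j."""
    true_labels = np.asarray(true_labels)
    predicted_labels = np.asarray(predicted_labels)
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label sequences differ in length")
    known = set(class_order)
    unknown = [l for l in list(true_labels) + list(predicted_labels) if l not in known]
    if unknown:
        raise ValueError(f"labels not in class_order: {sorted(set(map(str, unknown)))}")
    return _sk_confusion(true_labels, predicted_labels, labels=list(class_order))


# ---------------------------------------------------------------------------
# Static features and baselines


@dataclass
class StaticFeatureVector:
    """Three per-sensor summaries of the sniffing-phase response."""

    max_delta: np.ndarray  # maximum normalized change, dimensionless
    auc: np.ndarray  # area under the curve, dimensionless * s
    slope: np.ndarray  # maximal forward first-difference, 1/s

    def as_vector(self) -> np.ndarray:
        return np.concatenate([self.max_delta, self.auc, self.slope])


def extract_static_features(cond: ConditionedRecording) -> StaticFeatureVector:
    """Reduce a conditioned recording to per-sensor static features over the
    sniffing (sample draw-in) phase.

    The slope includes the transition into the phase (the first difference
    from the last pre-phase sample), so a response that jumps at onset has
    slope ``1/dt``.  AUC is the rectangle-rule integral ``sum * dt``.
    """
    start, stop = cond.phase_range(SNIFFING_PHASE)
    if stop <= start:
        raise ValueError("recording has no sniffing phase")
    dt = 1.0 / cond.sampling_rate
    phase = cond.values[start:stop]
    lead = cond.values[max(start - 1, 0): stop]
    slopes = np.diff(lead, axis=0) / dt if lead.shape[0] > 1 else np.zeros(
        (1, cond.n_sensors)
    )
    return StaticFeatureVector(
        max_delta=phase.max(axis=0),
        auc=phase.sum(axis=0) * dt,
        slope=slopes.max(axis=0),
    )


def baseline_pipelines(
    svm_c: float = 1.0, knn_k: int = 5, n_components: int = 3
) -> dict[str, Pipeline]:
    """Standardize -> PCA(3) -> classifier, per baseline method."""
    def make(clf):
        return Pipeline(
            [
                ("scale", StandardScaler()),
                ("pca", PCA(n_components=n_components)),
                ("clf", clf),
            ]
        )

    return {
        "LDA": make(LinearDiscriminantAnalysis()),
        "SVM": make(SVC(kernel="rbf", C=svm_c)),
        "KNN": make(KNeighborsClassifier(n_neighbors=knn_k, weights="distance")),
    }


def run_baselines(
    features: np.ndarray, labels, k: int = 5, seed: int = 0, **pipe_kwargs
) -> pd.DataFrame:
    """Stratified k-fold accuracy of each statistical baseline.

    Returns a table with columns ``method, accuracy, wall_time_s``.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2:
        raise ValueError("features must be a 2-D samples x features matrix")
    if np.allclose(X.std(axis=0), 0):
        raise ValueError("degenerate features: zero variance everywhere")
    labels = np.asarray(labels)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    rows = []
    for name, pipe in baseline_pipelines(**pipe_kwargs).items():
        t0 = time.perf_counter()
        scores = cross_val_score(pipe, X, labels, cv=skf)
        rows.append(
            {
                "method": name,
                "accuracy": float(scores.mean()),
                "wall_time_s": time.perf_counter() - t0,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# End-to-end experiment


@dataclass
class ExperimentConfig:
    """Everything needed to run the evaluation protocol on synthetic data."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    excluded_sensor_ids: tuple[int, ...] = DEFAULT_EXCLUDED
    smoothing_window: int = DEFAULT_WINDOW
    normalization: str = "global"  # "local" or "global"
    n_bits: int = 4
    params: NetworkParams = field(default_factory=NetworkParams)
    k_folds: int = 5
    train_fraction: float = 0.7
    holdout_replicates: int = 3
    seed: int = 0


@dataclass
class EvalReport:
    fold_accuracies: list[float]
    mean_accuracy: float
    accuracy_std: float
    confusion: np.ndarray
    class_order: list[str]
    holdout_accuracy: Optional[float]
    holdout_confusion: Optional[np.ndarray]
    methods: pd.DataFrame  # method, accuracy, wall_time_s

    def to_text(self) -> str:
        lines = [
            f"5-fold CV accuracy: {100 * self.mean_accuracy:.2f}% "
            f"(+/- {100 * self.accuracy_std:.2f}%)",
            "fold accuracies: "
            + ", ".join(f"{100 * a:.1f}%" for a in self.fold_accuracies),
        ]
        if self.holdout_accuracy is not None:
            lines.append(
                f"hold-out (unseen replicates) accuracy: "
                f"{100 * self.holdout_accuracy:.2f}%"
            )
        lines.append("method comparison:")
        for _, row in self.methods.iterrows():
            lines.append(
                f"  {row['method']:<4} accuracy {100 * row['accuracy']:6.2f}%  "
                f"({row['wall_time_s']:.2f} s)"
            )
        return "\n".join(lines)


def _condition_pipeline(config: ExperimentConfig):
    steps = [
        ("exclude", ChannelExcluder(config.excluded_sensor_ids)),
        ("smooth", RollingMean(config.smoothing_window)),
    ]
    if config.normalization == "local":
        steps.append(("norm", LocalNormalizer()))
    elif config.normalization == "global":
        steps.append(("norm", GlobalNormalizer()))
    else:
        raise ValueError(f"unknown normalization {config.normalization!r}")
    steps.append(("encode", AeroEncoder(config.n_bits)))
    return Pipeline(steps)


def snn_cross_validate(
    recordings, labels, config: ExperimentConfig
) -> tuple[list[float], np.ndarray, list[str]]:
    """Per-fold conditioning + one-shot training + scoring.

    The global normalization scale (when used) is fitted on the training
    fold only, so held-out samples never leak into the per-sensor extremes.
    """
    labels = np.asarray(labels)
    class_order = sorted(set(str(l) for l in labels))
    folds = stratified_kfold(labels, config.k_folds, config.seed)
    accs, confusions = [], []
    for train_idx, test_idx in folds:
        pipe = _condition_pipeline(config)
        train_recs = [recordings[i] for i in train_idx]
        test_recs = [recordings[i] for i in test_idx]
        X_train = pipe.fit_transform(train_recs)
        X_test = pipe.transform(test_recs)
        clf = SnnClassifier(
            **{
                name: getattr(config.params, name)
                for name in (
                    "neurons_per_class", "weights_per_neuron",
                    "initial_plasticity", "learning_competition",
                    "min_plasticity", "plastic_decay",
                )
            },
            random_state=config.seed,
        )
        clf.fit(X_train, labels[train_idx])
        pred = clf.predict(X_test)
        accs.append(float(np.mean(pred == labels[test_idx])))
        confusions.append(
            confusion_matrix(labels[test_idx], pred, class_order)
        )
    return accs, np.sum(confusions, axis=0), class_order


def run_experiment(config: Optional[ExperimentConfig] = None) -> EvalReport:
    """Run the full protocol on a synthetic dataset.

    Generates the dataset, cross-validates the spiking classifier, trains
    on a per-class split and scores the held-out replicates, and runs the
    PCA + LDA/SVM/KNN baselines on static features.  Deterministic given
    the config's seeds.
    """
    config = config or ExperimentConfig()
    recordings, manifest = generate_dataset(config.simulation)
    labels = np.array(manifest["label"])

    t_snn = time.perf_counter()
    fold_accs, confusion, class_order = snn_cross_validate(
        recordings, labels, config
    )
    snn_wall = time.perf_counter() - t_snn

    # hold-out inference on unseen replicates
    train_idx, test_idx = holdout_split(labels, config.train_fraction, config.seed)
    pipe = _condition_pipeline(config)
    X_train = pipe.fit_transform([recordings[i] for i in train_idx])
    X_test = pipe.transform([recordings[i] for i in test_idx])
    clf = SnnClassifier(random_state=config.seed)
    clf.set_params(
        **{
            name: getattr(config.params, name)
            for name in (
                "neurons_per_class", "weights_per_neuron", "initial_plasticity",
                "learning_competition", "min_plasticity", "plastic_decay",
            )
        }
    )
    clf.fit(X_train, labels[train_idx])
    holdout_pred = clf.predict(X_test)
    holdout_acc = float(np.mean(holdout_pred == labels[test_idx]))
    holdout_conf = confusion_matrix(labels[test_idx], holdout_pred, class_order)

    # baselines on static features of the conditioned recordings
    cond_pipe = _condition_pipeline(config)
    cond_steps = Pipeline(cond_pipe.steps[:-1])  # drop the encoder
    conditioned = cond_steps.fit_transform(recordings)
    features = np.stack(
        [extract_static_features(c).as_vector() for c in conditioned]
    )
    methods = run_baselines(features, labels, k=config.k_folds, seed=config.seed)
    snn_row = pd.DataFrame(
        [
            {
                "method": "SNN",
                "accuracy": float(np.mean(fold_accs)),
                "wall_time_s": snn_wall,
            }
        ]
    )
    methods = pd.concat([snn_row, methods], ignore_index=True)

    return EvalReport(
        fold_accuracies=fold_accs,
        mean_accuracy=float(np.mean(fold_accs)),
        accuracy_std=float(np.std(fold_accs)),
        confusion=confusion,
        class_order=class_order,
        holdout_accuracy=holdout_acc,
        holdout_confusion=holdout_conf,
        methods=methods,
    )
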