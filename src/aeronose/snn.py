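"""Binary-weight one-shot spiking classifier with winner-takes-all readout.

The network is a two-layer feed-forward model: an input layer the size of
the activation-bin space (sensor x timepoint x amplitude-level) and a fully
connected layer of integrate-and-fire neurons grouped into per-class pools.
Weights are binary — each neuron owns a *set* of at most ``W`` bin indices —
so the membrane potential for a sample is simply the count of active input
bins coinciding with the neuron's synapses.

Learning is one-shot and STDP-like: each training sample is presented once.
Within the sample's class pool, the best-matching already-used neuron either
*reinforces* (swaps a plasticity-limited number of non-matching synapses for
unclaimed active bins, then decays its plasticity multiplicatively toward a
floor) or, if its match ratio falls below the ``learning_competition``
threshold, a fresh neuron is *recruited* and wired to a random subset of the
sample's bins.  Classification reads out the class label of the maximally
activated neuron (ties broken by lowest neuron index, for reproducibility).

An optional fully-unsupervised mode lets all neurons compete for every
sample and assigns class labels post hoc by majority over the samples each
neuron learned.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .aero import BIN_LAYOUT_VERSION, ActivationBins, EncodingConfig, max_weight_bound

logger = logging.getLogger(__name__)

MODEL_FORMAT = "aeronose-snn-v1"


@dataclass(frozen=True)
class NetworkParams:
    """The six scalars governing pool size, connectivity and plasticity.

    Defaults are the optimized operating point for a 90-timepoint, 4-bit
    encoded 8-class problem; see :class:`aeronose.optimize.ParamBounds` for
    the search ranges.
    """

    neurons_per_class: int = 10
    weights_per_neuron: int = 1795
    initial_plasticity: float = 0.84
    learning_competition: float = 0.48
    min_plasticity: float = 0.21
    plastic_decay: float = 0.27

    def __post_init__(self) -> None:
        if self.neurons_per_class < 1 or self.weights_per_neuron < 1:
            raise ValueError("neurons_per_class and weights_per_neuron must be >= 1")
        for name in ("initial_plasticity", "learning_competition",
                     "min_plasticity", "plastic_decay"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.min_plasticity > self.initial_plasticity:
            raise ValueError("min_plasticity must not exceed initial_plasticity")


@dataclass
class NeuronState:
    class_label: Optional[str]
    weights: set = field(default_factory=set)
    plasticity: float = 1.0
    times_learned: int = 0
    label_votes: dict = field(default_factory=dict)  # unsupervised bookkeeping


@dataclass
class SnnModel:
    params: NetworkParams
    encoding: EncodingConfig
    neurons: list[NeuronState]
    class_labels: list[str]
    seed: int
    n_learn_events: int = 0
    supervised: bool = True


class LearningRecord(NamedTuple):
    neuron_index: int
    action: str  # "recruit" or "reinforce"
    swap_count: int


class Prediction(NamedTuple):
    label: str
    potentials: np.ndarray
    winner_index: int


def init_model(
    params: NetworkParams,
    encoding: EncodingConfig,
    class_labels: Sequence[str],
    seed: int = 0,
    supervised: bool = True,
) -> SnnModel:
    """Allocate ``neurons_per_class`` neurons per class, all unused and at
    full plasticity."""
    labels = list(class_labels)
    if len(set(labels)) != len(labels) or not labels:
        raise ValueError("class_labels must be non-empty and unique")
    bound = max_weight_bound(encoding.timepoints, encoding.levels)
    if params.weights_per_neuron > bound:
        logger.warning(
            "weights_per_neuron=%d exceeds the bound 2*T*levels=%d",
            params.weights_per_neuron, bound,
        )
    neurons = [
        NeuronState(
            class_label=lab if supervised else None,
            plasticity=params.initial_plasticity,
        )
        for lab in labels
        for _ in range(params.neurons_per_class)
    ]
    return SnnModel(
        params=params,
        encoding=encoding,
        neurons=neurons,
        class_labels=labels,
        seed=int(seed),
        supervised=supervised,
    )


def potential(neuron: NeuronState, bins: ActivationBins) -> int:
    """Membrane potential: the binary-weight dot product
    ``|weights ∩ active bins|``."""
    return len(neuron.weights & bins.bins)


def _pool_indices(model: SnnModel, label: str) -> list[int]:
    if model.supervised:
        return [
            i for i, n in enumerate(model.neurons) if n.class_label == label
        ]
    return list(range(len(model.neurons)))


def learn_sample(
    model: SnnModel, bins: ActivationBins, label: str
) -> Optional[LearningRecord]:
    """Present one sample to its class pool (or to every neuron in
    unsupervised mode).

    The best-matching used neuron reinforces if its match ratio
    ``potential / min(W, |bins|)`` reaches ``learning_competition``;
    otherwise a fresh neuron is recruited with a seeded random subset of the
    sample's bins.  Reinforcement never evicts synapses that match the
    current sample, and each learning event decays the neuron's plasticity
    by ``(1 - plastic_decay)`` down to ``min_plasticity``.
    """
    if label not in model.class_labels:
        raise ValueError(f"unknown label {label!r}")
    if len(bins) == 0:
        logger.warning("sample with no active bins skipped during learning")
        return None

    p = model.params
    W = p.weights_per_neuron
    denom = min(W, len(bins))
    pool = _pool_indices(model, label)
    used = [i for i in pool if model.neurons[i].times_learned > 0]
    unused = [i for i in pool if model.neurons[i].times_learned == 0]

    rng = np.random.default_rng(
        np.random.SeedSequence([model.seed & 0x7FFFFFFF, model.n_learn_events])
    )
    model.n_learn_events += 1

    best_used = None
    if used:
        pots = [potential(model.neurons[i], bins) for i in used]
        best_pos = int(np.argmax(pots))  # argmax takes the lowest index on ties
        best_used = used[best_pos]
        best_match = pots[best_pos] / denom

    if best_used is not None and best_match >= p.learning_competition:
        target, action = best_used, "reinforce"
    elif unused:
        target, action = unused[0], "recruit"
    elif best_used is not None:
        target, action = best_used, "reinforce"
    else:  # pool exists but nothing used and nothing free: cannot happen
        raise RuntimeError("empty neuron pool")

    neuron = model.neurons[target]
    if action == "recruit":
        k = min(W, len(bins))
        chosen = rng.choice(sorted(bins.bins), size=k, replace=False)
        neuron.weights = set(int(b) for b in chosen)
        swaps = 0
    else:
        budget = math.ceil(neuron.plasticity * W)
        removable = sorted(neuron.weights - bins.bins)
        addable = sorted(bins.bins - neuron.weights)
        n_remove = min(budget, len(removable), len(addable))
        if n_remove:
            drop = rng.choice(removable, size=n_remove, replace=False)
            neuron.weights -= set(int(b) for b in drop)
        free = W - len(neuron.weights)
        n_add = min(free, len(addable))
        if n_add:
            add = rng.choice(addable, size=n_add, replace=False)
            neuron.weights |= set(int(b) for b in add)
        swaps = n_add
        neuron.plasticity = max(
            p.min_plasticity, neuron.plasticity * (1.0 - p.plastic_decay)
        )
    neuron.times_learned += 1
    neuron.label_votes[label] = neuron.label_votes.get(label, 0) + 1
    return LearningRecord(target, action, swaps)


def train_one_shot(
    model: SnnModel, dataset: Sequence[tuple[ActivationBins, str]]
) -> tuple[SnnModel, list[Optional[LearningRecord]]]:
    """Single feed-forward pass over the dataset, in the given order."""
    if len(dataset) == 0:
        raise ValueError("cannot train on an empty dataset")
    log = [learn_sample(model, bins, label) for bins, label in dataset]
    if not model.supervised:
        assign_labels_by_majority(model)
    return model, log


def assign_labels_by_majority(model: SnnModel) -> None:
    """Post-hoc labelling for the unsupervised mode: each used neuron takes
    the majority label of the samples it learned; unused neurons take the
    first class label (they can only win all-zero ties)."""
    for n in model.neurons:
        if n.label_votes:
            n.class_label = max(sorted(n.label_votes), key=n.label_votes.get)
        elif n.class_label is None:
            n.class_label = model.class_labels[0]


def predict_bins(
    model: SnnModel, bins: ActivationBins, firing_threshold: Optional[int] = None
) -> Prediction:
    """Winner-takes-all readout over all neurons.

    Ties (including the all-zero untrained case) go to the lowest neuron
    index.  With ``firing_threshold`` set, potentials below the threshold
    are floored to zero before the argmax.
    """
    pots = np.array([potential(n, bins) for n in model.neurons], dtype=int)
    if firing_threshold is not None:
        pots = np.where(pots >= firing_threshold, pots, 0)
    winner = int(np.argmax(pots))
    label = model.neurons[winner].class_label
    return Prediction(label=label, potentials=pots, winner_index=winner)


# ---------------------------------------------------------------------------
# Serialisation


def save_model(model: SnnModel, path) -> None:
    doc = {
        "format": MODEL_FORMAT,
        "bin_layout": BIN_LAYOUT_VERSION,
        "params": {
            "neurons_per_class": model.params.neurons_per_class,
            "weights_per_neuron": model.params.weights_per_neuron,
            "initial_plasticity": model.params.initial_plasticity,
            "learning_competition": model.params.learning_competition,
            "min_plasticity": model.params.min_plasticity,
            "plastic_decay": model.params.plastic_decay,
        },
        "encoding": {
            "n_bits": model.encoding.n_bits,
            "timepoints": model.encoding.timepoints,
            "sensor_ids": list(model.encoding.sensor_ids),
        },
        "class_labels": model.class_labels,
        "seed": model.seed,
        "n_learn_events": model.n_learn_events,
        "supervised": model.supervised,
        "neurons": [
            {
                "class_label": n.class_label,
                "weights": sorted(n.weights),
                "plasticity": n.plasticity,
                "times_learned": n.times_learned,
                "label_votes": n.label_votes,
            }
            for n in model.neurons
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_model(path) -> SnnModel:
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ValueError(f"{path}: truncated or corrupt model file ({exc})") from None
    if doc.get("format") != MODEL_FORMAT:
        raise ValueError(
            f"{path}: unsupported model format {doc.get('format')!r}"
        )
    if doc.get("bin_layout") != BIN_LAYOUT_VERSION:
        raise ValueError(
            f"{path}: incompatible bin layout {doc.get('bin_layout')!r}"
        )
    params = NetworkParams(**doc["params"])
    enc = doc["encoding"]
    encoding = EncodingConfig(
        n_bits=enc["n_bits"],
        timepoints=enc["timepoints"],
        sensor_ids=tuple(enc["sensor_ids"]),
    )
    neurons = [
        NeuronState(
            class_label=n["class_label"],
            weights=set(n["weights"]),
            plasticity=n["plasticity"],
            times_learned=n["times_learned"],
            label_votes=dict(n.get("label_votes", {})),
        )
        for n in doc["neurons"]
    ]
    return SnnModel(
        params=params,
        encoding=encoding,
        neurons=neurons,
        class_labels=list(doc["class_labels"]),
        seed=int(doc["seed"]),
        n_learn_events=int(doc.get("n_learn_events", 0)),
        supervised=bool(doc.get("supervised", True)),
    )


# ---------------------------------------------------------------------------
# sklearn-style estimator


class SnnClassifier(BaseEstimator, ClassifierMixin):
    """One-shot spiking classifier over activation-bin sets.

    Parameters mirror :class:`NetworkParams`; ``X`` is a sequence of
    :class:`~aeronose.aero.ActivationBins` (as produced by
    :class:`~aeronose.aero.AeroEncoder`), so the estimator composes with
    sklearn pipelines and model selection.

    Attributes
    ----------
    classes_ : ndarray of unique labels seen during fit
    model_ : the trained :class:`SnnModel`
    """

    def __init__(
        self,
        neurons_per_class: int = 10,
        weights_per_neuron: int = 1795,
        initial_plasticity: float = 0.84,
        learning_competition: float = 0.48,
        min_plasticity: float = 0.21,
        plastic_decay: float = 0.27,
        supervised: bool = True,
        firing_threshold: Optional[int] = None,
        random_state: int = 0,
    ):
        self.neurons_per_class = neurons_per_class
        self.weights_per_neuron = weights_per_neuron
        self.initial_plasticity = initial_plasticity
        self.learning_competition = learning_competition
        self.min_plasticity = min_plasticity
        self.plastic_decay = plastic_decay
        self.supervised = supervised
        self.firing_threshold = firing_threshold
        self.random_state = random_state

    def _params(self) -> NetworkParams:
        return NetworkParams(
            neurons_per_class=self.neurons_per_class,
            weights_per_neuron=self.weights_per_neuron,
            initial_plasticity=self.initial_plasticity,
            learning_competition=self.learning_competition,
            min_plasticity=self.min_plasticity,
            plastic_decay=self.plastic_decay,
        )

    def fit(self, X: Sequence[ActivationBins], y):
        y = np.asarray(y)
        if len(X) != len(y):
            raise ValueError("X and y must have the same length")
        if len(X) == 0:
            raise ValueError("cannot fit on an empty dataset")
        self.classes_ = np.unique(y)
        self.model_ = init_model(
            self._params(),
            X[0].config,
            [str(c) for c in self.classes_],
            seed=self.random_state,
            supervised=self.supervised,
        )
        _, self.learning_log_ = train_one_shot(
            self.model_, [(b, str(lab)) for b, lab in zip(X, y)]
        )
        return self

    def decision_function(self, X) -> np.ndarray:
        """Per-class maximal neuron potential for each sample."""
        check_is_fitted(self, "model_")
        out = np.zeros((len(X), len(self.classes_)), dtype=int)
        for i, bins in enumerate(X):
            pred = predict_bins(self.model_, bins, self.firing_threshold)
            for j, c in enumerate(self.classes_):
                pool = [
                    pred.potentials[k]
                    for k, n in enumerate(self.model_.neurons)
                    if n.class_label == str(c)
                ]
                out[i, j] = max(pool) if pool else 0
        return out

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        labels = [
            predict_bins(self.model_, bins, self.firing_threshold).label
            for bins in X
        ]
        # map back onto the dtype of classes_
        lut = {str(c): c for c in self.classes_}
        return np.array([lut[lab] for lab in labels])
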