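"""Hyperparameter search over the network parameters.

Fitness is stratified k-fold cross-validated accuracy of the one-shot
classifier ("stable" accuracy: the fold mean, optionally penalized by a
configurable multiple of the fold standard deviation).  The search itself
is classic differential evolution (rand/1/bin): integer-valued parameters
are rounded after mutation, every candidate is clipped to its bounds, and
the best individual ever evaluated is returned.  A small grid-search entry
point is provided as an alternative for low-dimensional sweeps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, NamedTuple, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .aero import ActivationBins
from .snn import NetworkParams, init_model, predict_bins, train_one_shot

#: Parameter order used for the search vector.
PARAM_NAMES = (
    "neurons_per_class",
    "weights_per_neuron",
    "initial_plasticity",
    "learning_competition",
    "min_plasticity",
    "plastic_decay",
)

INTEGER_PARAMS = frozenset({"neurons_per_class", "weights_per_neuron"})


def _default_bounds() -> dict:
    return {
        "neurons_per_class": (1, 30),
        "weights_per_neuron": (1, 2880),
        "initial_plasticity": (0.75, 1.00),
        "learning_competition": (0.1, 0.75),
        "min_plasticity": (0.1, 0.50),
        "plastic_decay": (0.1, 0.50),
    }


@dataclass
class ParamBounds:
    """Per-parameter (low, high) search box.

    The defaults are the standard optimization ranges for this network:
    1–30 neurons per class, 1–2880 weights per neuron (the input-space
    bound for a 90-timepoint 4-bit encoding), initial plasticity 0.75–1.0,
    learning competition 0.1–0.75, minimum plasticity 0.1–0.5 and plastic
    decay 0.1–0.5.
    """

    bounds: dict = field(default_factory=_default_bounds)

    def __post_init__(self) -> None:
        missing = set(PARAM_NAMES) - set(self.bounds)
        if missing:
            raise ValueError(f"missing bounds for {sorted(missing)}")
        for name, (lo, hi) in self.bounds.items():
            if lo > hi:
                raise ValueError(f"bounds for {name} are inverted: ({lo}, {hi})")

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.array([self.bounds[n][0] for n in PARAM_NAMES], dtype=float)
        hi = np.array([self.bounds[n][1] for n in PARAM_NAMES], dtype=float)
        return lo, hi

    def clip_round(self, x: np.ndarray) -> np.ndarray:
        lo, hi = self.arrays()
        x = np.clip(np.asarray(x, dtype=float), lo, hi)
        for i, name in enumerate(PARAM_NAMES):
            if name in INTEGER_PARAMS:
                x[i] = round(x[i])
        return x

    def to_params(self, x: np.ndarray) -> NetworkParams:
        x = self.clip_round(x)
        kwargs = {}
        for i, name in enumerate(PARAM_NAMES):
            kwargs[name] = int(x[i]) if name in INTEGER_PARAMS else float(x[i])
        # keep the plasticity ordering constraint inside the box
        if kwargs["min_plasticity"] > kwargs["initial_plasticity"]:
            kwargs["min_plasticity"] = kwargs["initial_plasticity"]
        return NetworkParams(**kwargs)


@dataclass
class DEConfig:
    population_size: int = 15
    generations: int = 25
    mutation_factor: float = 0.6
    crossover_rate: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 4:
            raise ValueError("population_size must be >= 4")
        if not 0 < self.mutation_factor <= 2:
            raise ValueError("mutation_factor must lie in (0, 2]")
        if not 0 <= self.crossover_rate <= 1:
            raise ValueError("crossover_rate must lie in [0, 1]")


class FitnessRecord(NamedTuple):
    generation: int
    best_params: NetworkParams
    best_fitness: float
    population_mean_fitness: float


def cv_fitness(
    params: NetworkParams,
    encoded_dataset: Sequence[tuple[ActivationBins, str]],
    k: int = 5,
    seed: int = 0,
    stability_penalty: float = 0.0,
) -> float:
    """Stratified k-fold CV accuracy of the one-shot classifier.

    Returns mean fold accuracy minus ``stability_penalty`` times the fold
    standard deviation.  Deterministic given (params, dataset, seed).
    """
    if k < 2:
        raise ValueError("k must be >= 2 for stratified cross-validation")
    labels = np.array([lab for _, lab in encoded_dataset])
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        raise ValueError(f"every class needs >= {k} samples for {k}-fold CV")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    accs = []
    for train_idx, test_idx in skf.split(np.zeros(len(labels)), labels):
        model = init_model(
            params, encoded_dataset[0][0].config,
            sorted(set(labels)), seed=seed,
        )
        train_one_shot(model, [encoded_dataset[i] for i in train_idx])
        correct = sum(
            predict_bins(model, encoded_dataset[i][0]).label == labels[i]
            for i in test_idx
        )
        accs.append(correct / len(test_idx))
    accs = np.array(accs)
    return float(accs.mean() - stability_penalty * accs.std())


def de_optimize(
    fitness: Callable[[NetworkParams], float],
    bounds: ParamBounds | None = None,
    config: DEConfig | None = None,
) -> tuple[NetworkParams, list[FitnessRecord]]:
    """Maximize ``fitness`` with classic rand/1/bin differential evolution.

    Candidates are clipped to the bounds (integer parameters rounded after
    mutation); greedy selection keeps the better of target and trial; the
    returned parameters are the best individual ever evaluated.  The
    per-generation records carry the running best and population mean, so
    ``best_fitness`` is non-decreasing by construction.
    """
    bounds = bounds or ParamBounds()
    config = config or DEConfig()
    rng = np.random.default_rng(config.seed)
    lo, hi = bounds.arrays()
    dim = len(PARAM_NAMES)
    np_size = config.population_size

    pop = np.array(
        [bounds.clip_round(rng.uniform(lo, hi)) for _ in range(np_size)]
    )
    fit = np.array([fitness(bounds.to_params(x)) for x in pop])
    best_i = int(np.argmax(fit))
    best_x, best_f = pop[best_i].copy(), float(fit[best_i])
    records = [FitnessRecord(0, bounds.to_params(best_x), best_f, float(fit.mean()))]

    for gen in range(1, config.generations + 1):
        for i in range(np_size):
            choices = [j for j in range(np_size) if j != i]
            r1, r2, r3 = rng.choice(choices, size=3, replace=False)
            mutant = pop[r1] + config.mutation_factor * (pop[r2] - pop[r3])
            mutant = bounds.clip_round(mutant)
            cross = rng.random(dim) < config.crossover_rate
            cross[rng.integers(dim)] = True  # guarantee >= 1 mutant gene
            trial = bounds.clip_round(np.where(cross, mutant, pop[i]))
            f_trial = fitness(bounds.to_params(trial))
            if f_trial >= fit[i]:
                pop[i], fit[i] = trial, f_trial
            if f_trial > best_f:
                best_x, best_f = trial.copy(), float(f_trial)
        records.append(
            FitnessRecord(gen, bounds.to_params(best_x), best_f, float(fit.mean()))
        )
    return bounds.to_params(best_x), records


def grid_optimize(
    fitness: Callable[[NetworkParams], float],
    grid: dict[str, Sequence],
    base: NetworkParams | None = None,
) -> tuple[NetworkParams, float]:
    """Exhaustive search over the cartesian product of ``grid`` values,
    holding the remaining parameters at ``base``.  Deterministic; intended
    for small low-dimensional sweeps."""
    import itertools

    base = base or NetworkParams()
    names = list(grid)
    best_p, best_f = None, -math.inf
    for combo in itertools.product(*(grid[n] for n in names)):
        kwargs = {n: getattr(base, n) for n in PARAM_NAMES}
        kwargs.update(dict(zip(names, combo)))
        p = NetworkParams(**kwargs)
        f = fitness(p)
        if f > best_f:
            best_p, best_f = p, f
    return best_p, best_f
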