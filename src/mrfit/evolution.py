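"""Differential-evolution estimator with maximum-likelihood fitness (MLP-IE).

Classic DE/rand/1/bin specialized to the drying-model regression: a
population of candidate coefficient vectors is initialized uniformly, then
evolved for a fixed number of generations through difference-vector mutation,
binomial crossover and greedy one-to-one survivor selection, with the mean
squared moisture-ratio residual (the maximum-likelihood fitness, MLF) as the
objective.  The loop always runs exactly ``generations`` sweeps — there is no
early stopping — and all randomness flows from a single seeded generator, so
identical inputs give bitwise-identical results.

Individuals and partner indices are 0-based here; the population state each
sweep's mutation partners refer to is the frozen parent generation, while
survivors accumulate in the next generation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence
import warnings

import numpy as np

from .dataset import DryingDataset
from .metrics import FitMetrics, adjusted_r_squared, r_squared
from .model import PolynomialModel, mlf, predict

__all__ = [
    "EvolutionConfig",
    "Population",
    "FitResult",
    "init_population",
    "mutate_rand1",
    "crossover_binomial",
    "select_greedy",
    "best_individual",
    "run_mlp_ie",
]


@dataclass(frozen=True)
class EvolutionConfig:
    """Hyperparameters of the classic estimator.

    ``scaling_factor`` (F) multiplies the mutation difference vector and
    ``crossover_rate`` (CR) is the per-element probability of inheriting from
    the mutant.  Initialization draws uniformly on
    ``[init_low, init_high)``; the search is unbounded afterwards.
    """

    population_size: int = 30
    generations: int = 20
    scaling_factor: float = 0.5
    crossover_rate: float = 0.9
    init_low: float = 0.0
    init_high: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 4:
            raise ValueError("population size must be at least 4 (mutation needs 3 partners)")
        if self.generations < 1:
            raise ValueError("generations must be at least 1")
        if self.scaling_factor <= 0:
            raise ValueError("scaling factor must be positive")
        if not 0.0 <= self.crossover_rate <= 1.0:
            raise ValueError("crossover rate must lie in [0, 1]")
        if not self.init_low < self.init_high:
            raise ValueError("init_low must be below init_high")


@dataclass
class Population:
    """P x Q matrix of candidate coefficient vectors at one generation."""

    individuals: np.ndarray
    generation: int = 0

    def __post_init__(self) -> None:
        arr = np.asarray(self.individuals, dtype=float)
        if arr.ndim != 2:
            raise ValueError("individuals must be a 2-D (P x Q) array")
        if not np.all(np.isfinite(arr)):
            raise ValueError("individuals must be finite")
        self.individuals = arr

    @property
    def size(self) -> int:
        return self.individuals.shape[0]

    @property
    def dimension(self) -> int:
        return self.individuals.shape[1]


@dataclass(frozen=True)
class FitResult:
    """Outcome of one evolutionary fit."""

    model: PolynomialModel
    best_mlf_trajectory: np.ndarray
    metrics: FitMetrics
    config: object
    scaling_schedule: np.ndarray | None = None
    crossover_schedule: np.ndarray | None = None

    @property
    def order(self) -> int:
        return self.model.order

    @property
    def best_gamma(self) -> np.ndarray:
        return self.model.gamma

    @property
    def best_mlf(self) -> float:
        return float(self.best_mlf_trajectory[-1])

    def to_dict(self) -> dict:
        from dataclasses import asdict

        d = {
            "order": self.order,
            "gamma": self.best_gamma.tolist(),
            "best_mlf": self.best_mlf,
            "trajectory": self.best_mlf_trajectory.tolist(),
            "metrics": {
                "r2": self.metrics.r2,
                "adj_r2": self.metrics.adj_r2,
                "rmse": self.metrics.rmse,
            },
            "config": asdict(self.config),
        }
        if self.scaling_schedule is not None:
            d["scaling_schedule"] = self.scaling_schedule.tolist()
        if self.crossover_schedule is not None:
            d["crossover_schedule"] = self.crossover_schedule.tolist()
        return d


def init_population(config, dimension: int, rng: np.random.Generator) -> Population:
    """Uniform random initial population on ``[init_low, init_high)``."""
    if dimension < 1:
        raise ValueError("dimension must be at least 1")
    draws = rng.uniform(config.init_low, config.init_high, size=(config.population_size, dimension))
    return Population(individuals=draws, generation=0)


def _draw_partners(pop_size: int, p: int, rng: np.random.Generator, count: int = 3) -> np.ndarray:
    candidates = np.delete(np.arange(pop_size), p)
    return rng.choice(candidates, size=count, replace=False)


def mutate_rand1(
    pop: Population,
    p: int,
    scaling_factor: float,
    rng: np.random.Generator,
    partners: Sequence[int] | None = None,
) -> np.ndarray:
    """DE/rand/1 mutant: ``gamma_k1 + F * (gamma_k2 - gamma_k3)``.

    The three partner indices are drawn without replacement from the
    population excluding ``p`` (or supplied explicitly for testing).
    """
    if pop.size < 4:
        raise ValueError("mutation needs a population of at least 4")
    if not 0 <= p < pop.size:
        raise ValueError(f"individual index {p} out of range")
    if partners is None:
        partners = _draw_partners(pop.size, p, rng)
    k1, k2, k3 = partners
    g = pop.individuals
    return g[k1] + scaling_factor * (g[k2] - g[k3])


def crossover_binomial(
    mutant: np.ndarray,
    parent: np.ndarray,
    crossover_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Binomial (uniform) crossover with a forced mutant element.

    Element ``q`` comes from the mutant when an independent uniform draw falls
    below CR or when ``q`` equals a random forced position, guaranteeing the
    trial vector inherits at least one mutant element.
    """
    mutant = np.asarray(mutant, dtype=float)
    parent = np.asarray(parent, dtype=float)
    if mutant.shape != parent.shape or mutant.ndim != 1:
        raise ValueError("mutant and parent must be 1-D vectors of equal length")
    q_forced = rng.integers(mutant.size)
    take_mutant = rng.random(mutant.size) < crossover_rate
    take_mutant[q_forced] = True
    return np.where(take_mutant, mutant, parent)


def select_greedy(trial: np.ndarray, parent: np.ndarray, dataset: DryingDataset) -> np.ndarray:
    """Greedy one-to-one selection: the trial survives only on a strict MLF
    improvement; ties keep the parent."""
    if np.asarray(trial).shape != np.asarray(parent).shape:
        raise ValueError("trial and parent must have equal length")
    return trial if mlf(trial, dataset) < mlf(parent, dataset) else parent


def best_individual(pop: Population, dataset: DryingDataset) -> tuple[int, np.ndarray, float]:
    """Index, coefficient vector and MLF of the fittest individual.

    Ties are broken by the lowest index.
    """
    if pop.size < 1:
        raise ValueError("population is empty")
    X = dataset.design_matrix(pop.dimension - 1)
    resid = dataset.moisture_ratio[None, :] - pop.individuals @ X.T
    fitness = np.mean(resid * resid, axis=1)
    idx = int(np.argmin(fitness))  # argmin returns the first minimum
    return idx, pop.individuals[idx].copy(), float(fitness[idx])


def _population_fitness(individuals: np.ndarray, X: np.ndarray, y: np.ndarray) -> np.ndarray:
    resid = y[None, :] - individuals @ X.T
    return np.mean(resid * resid, axis=1)


def _finalize(dataset, order, pop, fitness, trajectory, config, f_sched=None, cr_sched=None):
    idx = int(np.argmin(fitness))
    model = PolynomialModel(order=order, gamma=pop[idx].copy())
    pred = predict(model, dataset.shrinkage)
    r2 = r_squared(pred, dataset.moisture_ratio)
    adj = (
        adjusted_r_squared(r2, dataset.kmax, order)
        if dataset.kmax > order + 1
        else float("nan")
    )
    metrics = FitMetrics(
        r2=r2,
        adj_r2=adj,
        rmse=float(np.sqrt(fitness[idx])),
        order=order,
        kmax=dataset.kmax,
    )
    return FitResult(
        model=model,
        best_mlf_trajectory=np.asarray(trajectory),
        metrics=metrics,
        config=config,
        scaling_schedule=None if f_sched is None else np.asarray(f_sched),
        crossover_schedule=None if cr_sched is None else np.asarray(cr_sched),
    )


def _check_design(dataset: DryingDataset, order: int) -> None:
    if dataset.kmax < order + 1:
        raise ValueError(f"kmax={dataset.kmax} < order+1={order + 1}: model unidentifiable")
    if order >= 1 and np.unique(dataset.shrinkage).size < order + 1:
        warnings.warn(
            "shrinkage values do not span the model order; the fit is not unique",
            stacklevel=3,
        )


def run_mlp_ie(dataset: DryingDataset, order: int, config: EvolutionConfig) -> FitResult:
    """Run the classic estimator for exactly ``config.generations`` sweeps.

    Each sweep mutates, crosses over and greedily selects every individual
    against the frozen parent generation, then records the best MLF.  Returns
    the best individual of the final generation with its trajectory and
    goodness-of-fit metrics.
    """
    _check_design(dataset, order)
    rng = np.random.default_rng(config.seed)
    Q = order + 1
    X = dataset.design_matrix(order)
    y = dataset.moisture_ratio

    pop = init_population(config, Q, rng).individuals
    fitness = _population_fitness(pop, X, y)
    trajectory = []
    for _ in range(config.generations):
        new_pop = pop.copy()
        new_fitness = fitness.copy()
        for p in range(config.population_size):
            mutant = mutate_rand1(Population(pop), p, config.scaling_factor, rng)
            trial = crossover_binomial(mutant, pop[p], config.crossover_rate, rng)
            trial_fit = float(np.mean((y - X @ trial) ** 2))
            if trial_fit < fitness[p]:
                new_pop[p] = trial
                new_fitness[p] = trial_fit
        pop, fitness = new_pop, new_fitness
        trajectory.append(float(fitness.min()))
    return _finalize(dataset, order, pop, fitness, trajectory, config)
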