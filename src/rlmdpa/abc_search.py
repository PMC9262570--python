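"""Artificial bee colony (ABC) search over flat network weight vectors.

The optimizer maintains a population of "food sources" (candidate weight
vectors).  Each cycle runs three phases:

* employed bees perturb one coordinate of their source toward a random
  partner and keep the candidate only if its fitness improves (greedy);
* onlooker bees repeat the same move on sources chosen by roulette-wheel
  selection with probability proportional to fitness;
* at most one scout per cycle abandons a source whose trial counter
  exceeded the limit and re-draws it uniformly inside the bounds.

Fitness of a weight vector is 1 / (1 + SSE) where SSE is the squared
error between true and predicted hard labels -- for binary labels simply
1 / (1 + number of misclassified samples) -- so fitness lies in (0, 1]
and equals 1 exactly on a perfect classification.

The global best position is tracked separately (elitism): the reported
best-fitness history is non-decreasing regardless of scout resets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .env import LabeledImageSet
from .exceptions import ConfigurationError, DimensionMismatchError
from .network import NetworkArchitecture, QNetwork

__all__ = [
    "FoodSource",
    "ABCConfig",
    "FitnessContext",
    "ABCResult",
    "init_population",
    "neighbor_solution",
    "mutate_coordinate",
    "selection_probabilities",
    "roulette_select",
    "employed_phase",
    "onlooker_phase",
    "scout_phase",
    "run_abc",
    "sphere_fitness",
]


@dataclass
class FoodSource:
    """A candidate solution with its fitness and no-improvement counter."""

    position: np.ndarray
    fitness: float
    trial: int = 0


@dataclass
class ABCConfig:
    """Colony parameters.

    ``colony_size`` food sources; the employed and onlooker bee counts are
    each half the colony, one scout at most per cycle.  ``limit`` defaults
    to n_employed x D.  The budget is counted in fitness evaluations
    (25,000 by default, colony 100).  ``phi_interval`` is the range of the
    perturbation factor in the neighbor move; candidates leaving the
    bounds are clipped.
    """

    colony_size: int = 100
    limit: Optional[int] = None
    max_evaluations: int = 25_000
    bounds: tuple[float, float] = (-1.0, 1.0)
    phi_interval: tuple[float, float] = (0.0, 1.0)
    n_scouts: int = 1

    @property
    def n_employed(self) -> int:
        return max(1, self.colony_size // 2)

    @property
    def n_onlookers(self) -> int:
        return max(1, self.colony_size // 2)

    def resolved_limit(self, dim: int) -> int:
        return self.limit if self.limit is not None else self.n_employed * dim

    def validate(self) -> None:
        if self.colony_size < 2:
            raise ConfigurationError("colony_size must be >= 2")
        if self.limit is not None and self.limit < 1:
            raise ConfigurationError("limit must be >= 1")
        lo, hi = self.bounds
        if lo > hi:
            raise ConfigurationError(f"bounds must satisfy min <= max, got {self.bounds}")
        if self.max_evaluations < self.colony_size:
            raise ConfigurationError(
                "max_evaluations smaller than colony_size: cannot initialize"
            )


class FitnessContext:
    """Classification fitness 1/(1 + misclassification count) on a dataset.

    A seeded subsample of the data may be used to keep per-candidate
    evaluation cheap; by default the full set is scored.
    """

    def __init__(self, data: LabeledImageSet, arch: NetworkArchitecture,
                 subsample: Optional[int] = None, seed: int = 0):
        if len(data) < 1:
            raise ConfigurationError("fitness dataset must be non-empty")
        arch.validate()
        self.arch = arch
        if subsample is not None and subsample < len(data):
            rng = np.random.default_rng(seed)
            idx = rng.choice(len(data), size=subsample, replace=False)
            data = data.subset(np.sort(idx))
        self.data = data
        self.dimension = arch.n_parameters

    def __call__(self, position: np.ndarray) -> float:
        position = np.asarray(position, dtype=np.float64).ravel()
        if position.size != self.dimension:
            raise DimensionMismatchError(
                f"expected vector of length {self.dimension}, got {position.size}"
            )
        net = QNetwork.from_vector(position, self.arch)
        q = net.forward(self.data.images, training=False)
        predicted = np.argmax(q, axis=1)
        sse = float(np.sum((self.data.labels - predicted) ** 2))
        return 1.0 / (1.0 + sse)


def sphere_fitness(position: np.ndarray) -> float:
    """1/(1 + ||x||^2): a smooth stub with optimum 1 at the origin."""
    position = np.asarray(position, dtype=np.float64)
    return 1.0 / (1.0 + float(position @ position))


# ---------------------------------------------------------------------------
# phases


def init_population(cfg: ABCConfig, dim: int, rng: np.random.Generator,
                    fitness: Callable[[np.ndarray], float]) -> list[FoodSource]:
    """Uniform draws in the bounds, fitness evaluated, trials zeroed."""
    lo, hi = cfg.bounds
    pop = []
    for _ in range(cfg.colony_size):
        position = lo + rng.random(dim) * (hi - lo)
        pop.append(FoodSource(position=position, fitness=fitness(position), trial=0))
    return pop


def mutate_coordinate(position: np.ndarray, partner: np.ndarray, j: int,
                      phi: float, bounds: tuple[float, float]) -> np.ndarray:
    """v_j = s_j + phi (s_j - partner_j), other coordinates untouched."""
    v = position.copy()
    v[j] = position[j] + phi * (position[j] - partner[j])
    lo, hi = bounds
    v[j] = min(max(v[j], lo), hi)
    return v


def neighbor_solution(pop: Sequence[FoodSource], i: int, rng: np.random.Generator,
                      cfg: ABCConfig) -> np.ndarray:
    """Candidate differing from source i in exactly one coordinate."""
    if len(pop) < 2:
        raise ConfigurationError("neighbor search needs at least two food sources")
    k = int(rng.integers(len(pop) - 1))
    if k >= i:
        k += 1
    j = int(rng.integers(pop[i].position.size))
    lo_phi, hi_phi = cfg.phi_interval
    phi = lo_phi + rng.random() * (hi_phi - lo_phi)
    return mutate_coordinate(pop[i].position, pop[k].position, j, phi, cfg.bounds)


def _greedy_try(pop, i, rng, cfg, fitness) -> int:
    """One neighbor search with greedy replacement; returns evals used (1)."""
    candidate = neighbor_solution(pop, i, rng, cfg)
    f = fitness(candidate)
    if f > pop[i].fitness:
        pop[i] = FoodSource(position=candidate, fitness=f, trial=0)
    else:
        pop[i].trial += 1
    return 1


def employed_phase(pop, rng, cfg, fitness) -> int:
    """Neighbor search on each employed source; returns evaluations used."""
    evals = 0
    for i in range(min(cfg.n_employed, len(pop))):
        evals += _greedy_try(pop, i, rng, cfg, fitness)
    return evals


def selection_probabilities(pop: Sequence[FoodSource]) -> np.ndarray:
    """p_i proportional to fitness, normalized to sum exactly to 1."""
    fit = np.array([s.fitness for s in pop], dtype=np.float64)
    return fit / fit.sum()


def roulette_select(pop: Sequence[FoodSource], rng: np.random.Generator) -> int:
    p = selection_probabilities(pop)
    return int(rng.choice(len(pop), p=p))


def onlooker_phase(pop, rng, cfg, fitness) -> int:
    """n_onlooker roulette-selected neighbor searches; returns evals used."""
    evals = 0
    for _ in range(cfg.n_onlookers):
        i = roulette_select(pop, rng)
        evals += _greedy_try(pop, i, rng, cfg, fitness)
    return evals


def scout_phase(pop, rng, cfg, fitness, dim: int) -> int:
    """Re-draw up to n_scouts exhausted sources uniformly in the bounds."""
    limit = cfg.resolved_limit(dim)
    over = [i for i in range(len(pop)) if pop[i].trial > limit]
    over.sort(key=lambda i: pop[i].trial, reverse=True)
    evals = 0
    lo, hi = cfg.bounds
    for i in over[: cfg.n_scouts]:
        position = lo + rng.random(dim) * (hi - lo)
        pop[i] = FoodSource(position=position, fitness=fitness(position), trial=0)
        evals += 1
    return evals


# ---------------------------------------------------------------------------
# driver


@dataclass
class ABCResult:
    best_position: np.ndarray
    best_fitness: float
    history: np.ndarray  # best-so-far fitness after each cycle
    n_evaluations: int
    n_iterations: int


def run_abc(cfg: ABCConfig, fitness: Callable[[np.ndarray], float],
            dim: Optional[int] = None, seed: int = 0) -> ABCResult:
    """Run employed -> onlooker -> scout cycles until the budget is spent.

    ``fitness`` may be a :class:`FitnessContext` (its ``dimension`` is then
    used) or any callable on weight vectors with ``dim`` given explicitly.
    """
    cfg.validate()
    if dim is None:
        dim = getattr(fitness, "dimension", None)
        if dim is None:
            raise ConfigurationError("dim required when fitness has no .dimension")
    rng = np.random.default_rng(seed)

    pop = init_population(cfg, dim, rng, fitness)
    evals = len(pop)
    best_i = int(np.argmax([s.fitness for s in pop]))
    best = FoodSource(pop[best_i].position.copy(), pop[best_i].fitness)

    history = []
    iterations = 0
    while evals < cfg.max_evaluations:
        evals += employed_phase(pop, rng, cfg, fitness)
        evals += onlooker_phase(pop, rng, cfg, fitness)
        evals += scout_phase(pop, rng, cfg, fitness, dim)
        iterations += 1
        cycle_best = max(pop, key=lambda s: s.fitness)
        if cycle_best.fitness > best.fitness:
            best = FoodSource(cycle_best.position.copy(), cycle_best.fitness)
        history.append(best.fitness)

    return ABCResult(
        best_position=best.position,
        best_fitness=best.fitness,
        history=np.asarray(history),
        n_evaluations=evals,
        n_iterations=iterations,
    )
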