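"""NSGA-II search over individuals with three maximised objectives.

Fast non-dominated sorting and crowding distance follow Deb et al.'s
formulation; parent selection is binary tournament on (rank, crowding);
environmental selection is the standard (mu + lambda) truncation keeping the
best 100 of parents and offspring.  The post-run Decision Maker keeps
non-dominated individuals whose sample sensitivity and specificity both
reach 0.9, relaxing to 0.8 and finally to the single max-min individual so
the pipeline always yields a deployable model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .genotype import Individual, mutate, random_individual, recombine


class UnevaluatedError(ValueError):
    pass


@dataclass
class Front:
    rank: int
    members: list[Individual]


@dataclass
class EvolutionHistory:
    """Per-generation log: fitness array of each generation's population."""

    generations: list[np.ndarray] = field(default_factory=list)

    def best_per_objective(self):
        return np.array([g.max(axis=0) for g in self.generations])

    def median_per_objective(self):
        return np.array([np.median(g, axis=0) for g in self.generations])


def dominates(f1, f2) -> bool:
    """True iff f1 >= f2 in every objective and > in at least one
    (all objectives maximised)."""
    if f1 is None or f2 is None:
        raise UnevaluatedError("cannot compare unevaluated fitness")
    ge = all(a >= b for a, b in zip(f1, f2))
    gt = any(a > b for a, b in zip(f1, f2))
    return ge and gt


def non_dominated_sort(population: Sequence[Individual]) -> list[Front]:
    """Fast non-dominated sorting; fronts partition the population and
    annotate each individual's ``rank``."""
    n = len(population)
    fits = [ind.fitness for ind in population]
    if any(f is None for f in fits):
        raise UnevaluatedError("all individuals must be evaluated")
    S = [[] for _ in range(n)]
    n_dom = np.zeros(n, dtype=int)
    for p in range(n):
        for q in range(n):
            if p == q:
                continue
            if dominates(fits[p], fits[q]):
                S[p].append(q)
            elif dominates(fits[q], fits[p]):
                n_dom[p] += 1
    fronts: list[Front] = []
    current = [p for p in range(n) if n_dom[p] == 0]
    rank = 0
    while current:
        for p in current:
            population[p].rank = rank
        fronts.append(Front(rank, [population[p] for p in current]))
        nxt = []
        for p in current:
            for q in S[p]:
                n_dom[q] -= 1
                if n_dom[q] == 0:
                    nxt.append(q)
        current = nxt
        rank += 1
    return fronts


def crowding_distance(front: Sequence[Individual]) -> np.ndarray:
    """Crowding distances of a front; boundary members get +inf, interior
    members the sum of normalised neighbour gaps per objective (objectives
    with zero range contribute 0).  Annotates ``crowding``."""
    m = len(front)
    if m == 0:
        raise ValueError("empty front")
    fits = np.array([ind.fitness for ind in front], dtype=float)
    dist = np.zeros(m)
    for j in range(fits.shape[1]):
        order = np.argsort(fits[:, j], kind="stable")
        lo, hi = fits[order[0], j], fits[order[-1], j]
        dist[order[0]] = dist[order[-1]] = np.inf
        rng = hi - lo
        if rng <= 0:
            continue
        for k in range(1, m - 1):
            dist[order[k]] += (fits[order[k + 1], j]
                               - fits[order[k - 1], j]) / rng
    for ind, d in zip(front, dist):
        ind.crowding = float(d)
    return dist


def tournament_winner(a: Individual, b: Individual,
                      rng: np.random.Generator) -> Individual:
    """Winner of one comparison: lower rank, then larger crowding, then a
    fair coin."""
    if a.rank is None or b.rank is None:
        raise UnevaluatedError("tournament requires ranked individuals")
    if a.rank != b.rank:
        return a if a.rank < b.rank else b
    if a.crowding != b.crowding:
        return a if a.crowding > b.crowding else b
    return a if rng.random() < 0.5 else b


def binary_tournament(population: Sequence[Individual],
                      rng: np.random.Generator) -> Individual:
    """Draw two individuals uniformly (with replacement) and return the
    tournament winner."""
    i, j = rng.integers(len(population), size=2)
    return tournament_winner(population[i], population[j], rng)


def _rank_population(population: list[Individual]) -> list[Front]:
    fronts = non_dominated_sort(population)
    for fr in fronts:
        crowding_distance(fr.members)
    return fronts


def _evaluate(population, fitness_fn):
    worst = (0.0, 0.0, 0.0)
    for ind in population:
        if ind.fitness is None:
            try:
                ind.fitness = tuple(fitness_fn(ind))
            except Exception:
                ind.fitness = worst


def evolve(fitness_fn: Callable[[Individual], tuple],
           rng: np.random.Generator,
           population_size: int = 100,
           generations: int = 50,
           recombination_rate: float = 0.90,
           mutation_rate: float = 0.015,
           initial_population: Sequence[Individual] | None = None):
    """Run the generational NSGA-II loop.

    Per generation: evaluate, rank, produce ``population_size`` offspring by
    binary tournament + recombination (0.90) + mutation (0.015), then keep
    the best ``population_size`` of parents and offspring by
    (rank, crowding).  Individuals whose evaluation raises are assigned the
    worst fitness.  Returns ``(population, history)``.
    """
    if initial_population is not None:
        population = [ind.copy() for ind in initial_population]
    else:
        population = [random_individual(rng) for _ in range(population_size)]
    _evaluate(population, fitness_fn)
    _rank_population(population)
    history = EvolutionHistory()
    history.generations.append(
        np.array([ind.fitness for ind in population], dtype=float))

    for _ in range(generations):
        offspring = []
        while len(offspring) < population_size:
            p1 = binary_tournament(population, rng)
            p2 = binary_tournament(population, rng)
            child = recombine(p1, p2, rng, rate=recombination_rate)
            child = mutate(child, rng, rate=mutation_rate)
            offspring.append(child)
        _evaluate(offspring, fitness_fn)
        combined = population + offspring
        fronts = _rank_population(combined)
        survivors: list[Individual] = []
        for fr in fronts:
            if len(survivors) + len(fr.members) <= population_size:
                survivors.extend(fr.members)
            else:
                room = population_size - len(survivors)
                by_crowd = sorted(fr.members, key=lambda m: -m.crowding)
                survivors.extend(by_crowd[:room])
                break
        population = survivors
        _rank_population(population)
        history.generations.append(
            np.array([ind.fitness for ind in population], dtype=float))
    return population, history


def decision_maker(final_front: Sequence[Individual],
                   thresholds=(0.9, 0.8)) -> tuple[list[Individual], bool]:
    """Select deployable individuals from the final non-dominated front.

    Keeps members with Sss and Ssp both >= 0.9; if none, relaxes both to
    0.8; if still none, returns the single individual maximising
    min(Sss, Ssp), flagged below-threshold.  Returns
    ``(selected, below_threshold_flag)``.  No comfort threshold is applied.
    The returned selection is a set of *distinct* genotypes: NSGA-II
    populations accumulate clones of good lineages, and a Pareto-optimal
    solution set contains each solution once.
    """
    if not final_front:
        raise ValueError("empty front")
    unique, seen = [], set()
    for ind in final_front:
        key = ind.to_json()
        if key not in seen:
            seen.add(key)
            unique.append(ind)
    for thr in thresholds:
        sel = [ind for ind in unique
               if ind.fitness[0] >= thr and ind.fitness[1] >= thr]
        if sel:
            return sel, False
    best = max(unique, key=lambda i: min(i.fitness[0], i.fitness[1]))
    return [best], True


def pareto_front(population: Sequence[Individual]) -> list[Individual]:
    """Rank-0 members of a population."""
    return non_dominated_sort(population)[0].members
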