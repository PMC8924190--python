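import numpy as np
import pytest

from evoseizure.genotype import Individual, random_individual
from evoseizure.nsga2 import (
    UnevaluatedError, binary_tournament, crowding_distance, decision_maker,
    dominates, evolve, non_dominated_sort, pareto_front, tournament_winner,
)


def make_pop(fitnesses, rng=None):
    rng = rng or np.random.default_rng(0)
    pop = []
    for f in fitnesses:
        ind = random_individual(rng)
        ind.fitness = tuple(f)
        pop.append(ind)
    return pop


def brute_force_fronts(fits):
    """Reference: peel non-dominated layers by exhaustive pairwise checks."""
    remaining = list(range(len(fits)))
    fronts = []
    while remaining:
        nd = [p for p in remaining
              if not any(dominates(fits[q], fits[p])
                         for q in remaining if q != p)]
        fronts.append(sorted(nd))
        remaining = [p for p in remaining if p not in nd]
    return fronts


def test_dominance_relation():
    assert dominates((0.9, 0.9, 0.9), (0.8, 0.8, 0.8))
    assert not dominates((0.9, 0.5, 0.9), (0.5, 0.9, 0.9))
    assert not dominates((0.5, 0.9, 0.9), (0.9, 0.5, 0.9))
    f = (0.3, 0.3, 0.3)
    assert not dominates(f, f)
    with pytest.raises(UnevaluatedError):
        dominates(None, f)


def test_sort_matches_brute_force_oracle():
    rng = np.random.default_rng(1)
    fits = [tuple(v) for v in rng.random((200, 3))]
    pop = make_pop(fits)
    fronts = non_dominated_sort(pop)
    idx = {id(ind): i for i, ind in enumerate(pop)}
    got = [sorted(idx[id(m)] for m in fr.members) for fr in fronts]
    assert got == brute_force_fronts(fits)


def test_sort_degenerate_shapes():
    same = make_pop([(0.5, 0.5, 0.5)] * 7)
    assert len(non_dominated_sort(same)) == 1
    chain = make_pop([(i, i, i) for i in range(5)])
    fronts = non_dominated_sort(chain)
    assert [len(f.members) for f in fronts] == [1] * 5
    assert fronts[0].members[0].fitness == (4, 4, 4)


def test_crowding_boundary_and_interior():
    two = make_pop([(0.1, 0.5, 0.5), (0.9, 0.5, 0.5)])
    assert np.isinf(crowding_distance(two)).all()
    # 3 collinear equispaced points varying in one objective
    three = make_pop([(0.0, 0.5, 0.5), (0.5, 0.5, 0.5), (1.0, 0.5, 0.5)])
    d = crowding_distance(three)
    assert np.isinf(d[0]) and np.isinf(d[2])
    assert d[1] == pytest.approx(1.0)


def test_crowding_duplicate_fitness_no_division_by_zero():
    d = crowding_distance(make_pop([(0.5, 0.5, 0.5)] * 4))
    assert np.isfinite(d).sum() >= 2 and (d[np.isfinite(d)] >= 0).all()


def test_tournament_rank_then_crowding():
    rng = np.random.default_rng(2)
    a, b = make_pop([(1, 1, 1), (0, 0, 0)])
    a.rank, b.rank = 0, 1
    a.crowding = b.crowding = 0.5
    assert all(tournament_winner(a, b, rng) is a for _ in range(50))
    assert all(tournament_winner(b, a, rng) is a for _ in range(50))
    b.rank = 0
    a.crowding, b.crowding = np.inf, 0.2
    assert all(tournament_winner(a, b, rng) is a for _ in range(50))


def test_tournament_fair_on_full_ties():
    rng = np.random.default_rng(3)
    a, b = make_pop([(1, 1, 1), (1, 1, 1)])
    a.rank = b.rank = 0
    a.crowding = b.crowding = 1.0
    wins = sum(tournament_winner(a, b, rng) is a for _ in range(10_000))
    assert abs(wins / 10_000 - 0.5) < 3 * np.sqrt(0.25 / 10_000)
    # the population-level draw must return members of the population
    assert binary_tournament([a, b], rng) in (a, b)


# ---------------------------------------------------------------------------
# generational loop

def c3_share_fitness(ind: Individual):
    """Synthetic problem: all three objectives reward C3 usage."""
    share = sum(hf.electrode == "C3" for hf in ind.hyperfeatures) / 5.0
    return (share, share, share)


def time_share_fitness(ind: Individual):
    """All objectives reward the time-branch allele; the all-time genotype
    is strictly optimal in every objective."""
    share = sum(hf.active_group == "time" for hf in ind.hyperfeatures) / 5.0
    return (share, share, share)


def test_evolve_fixates_strictly_optimal_genotype():
    hits = 0
    for seed in range(10):
        pop, _ = evolve(time_share_fitness, np.random.default_rng(seed),
                        population_size=20, generations=10)
        best = max(ind.fitness[0] for ind in pareto_front(pop))
        hits += best == 1.0
    assert hits >= 9


def test_evolve_elitism_and_population_size():
    pop, history = evolve(c3_share_fitness, np.random.default_rng(4),
                          population_size=20, generations=8)
    assert len(pop) == 20
    best = history.best_per_objective()
    assert (np.diff(best[:, 0]) >= 0).all()  # per-objective max never drops


def test_evolve_deterministic_under_seed():
    r1 = evolve(c3_share_fitness, np.random.default_rng(9),
                population_size=10, generations=5)
    r2 = evolve(c3_share_fitness, np.random.default_rng(9),
                population_size=10, generations=5)
    assert [i.to_dict() for i in r1[0]] == [i.to_dict() for i in r2[0]]
    for g1, g2 in zip(r1[1].generations, r2[1].generations):
        np.testing.assert_array_equal(g1, g2)


def test_evolve_failing_fitness_becomes_worst():
    def sometimes_broken(ind):
        if ind.hyperfeatures[0].electrode == "Cz":
            raise RuntimeError("boom")
        return c3_share_fitness(ind)

    pop, _ = evolve(sometimes_broken, np.random.default_rng(5),
                    population_size=10, generations=2)
    assert all(ind.fitness is not None for ind in pop)


# ---------------------------------------------------------------------------
# decision maker

def test_decision_maker_threshold_ladder():
    front = make_pop([(0.95, 0.92, 0.5), (0.5, 0.99, 1.0)])
    sel, below = decision_maker(front)
    assert [s.fitness for s in sel] == [(0.95, 0.92, 0.5)] and not below

    relaxed = make_pop([(0.85, 0.85, 0.2), (0.99, 0.5, 1.0)])
    sel, below = decision_maker(relaxed)
    assert [s.fitness for s in sel] == [(0.85, 0.85, 0.2)] and not below

    poor = make_pop([(0.5, 0.5, 1.0), (0.7, 0.2, 1.0)])
    sel, below = decision_maker(poor)
    assert below and len(sel) == 1
    assert sel[0].fitness == (0.5, 0.5, 1.0)  # max-min individual

    with pytest.raises(ValueError):
        decision_maker([])


def test_decision_maker_deduplicates_clones():
    rng = np.random.default_rng(6)
    ind = random_individual(rng)
    ind.fitness = (0.95, 0.95, 1.0)
    clones = [ind.copy() for _ in range(5)]
    for c in clones:
        c.fitness = ind.fitness
    sel, _ = decision_maker(clones)
    assert len(sel) == 1
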