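import itertools

import numpy as np
import pytest

from evoseizure.genotype import (
    GENE_DOMAINS, GENE_NAMES, GENES_PER_INDIVIDUAL, Individual,
    PREICTAL_DOMAIN, decode, gene_neighbours, hyperfeature_similarity,
    mutate, pair_hyperfeatures, random_individual, recombine,
)
from evoseizure.features import FEATURE_IDS
from evoseizure.montage import ADJACENCY


def test_individual_structure():
    ind = random_individual(np.random.default_rng(0))
    assert len(ind.hyperfeatures) == 5
    assert len(GENE_NAMES) == 13
    assert GENES_PER_INDIVIDUAL == 66
    assert ind.preictal_min in PREICTAL_DOMAIN
    assert PREICTAL_DOMAIN == tuple(range(30, 80, 5))


def test_random_individual_deterministic_and_uniform():
    a = random_individual(np.random.default_rng(5))
    b = random_individual(np.random.default_rng(5))
    assert a == b
    rng = np.random.default_rng(1)
    draws = [random_individual(rng) for _ in range(2000)]
    counts = {}
    for ind in draws:
        for hf in ind.hyperfeatures:
            counts[hf.electrode] = counts.get(hf.electrode, 0) + 1
    n = 2000 * 5
    p = 1 / 19
    se = np.sqrt(p * (1 - p) / n)
    for e in ADJACENCY:
        assert abs(counts.get(e, 0) / n - p) < 3 * se
    assert all(ind.preictal_min in PREICTAL_DOMAIN for ind in draws)


def test_decode_tree_examples(rng):
    hf = random_individual(rng).hyperfeatures[0]
    assert decode(hf.replace(active_group="frequency",
                             active_frequency_feature="sef",
                             sef=75)).feature_id == "sef75"
    assert decode(hf.replace(active_group="time",
                             active_time_feature="hjorth",
                             hjorth="activity")).feature_id == "variance"
    assert decode(hf.replace(active_group="frequency",
                             active_frequency_feature="band_power",
                             active_band_feature="relative_power",
                             band="low_gamma")).feature_id == \
        "rel_power_low_gamma"


def test_silent_gene_changes_do_not_alter_phenotype(rng):
    hf = random_individual(rng).hyperfeatures[0].replace(active_group="time")
    for w in GENE_DOMAINS["wavelet"]:
        assert decode(hf.replace(wavelet=w)) == decode(hf)


def test_decode_is_total_and_covers_all_24_features(rng):
    base = random_individual(rng).hyperfeatures[0]
    active = ("active_group", "active_time_feature",
              "active_frequency_feature", "active_band_feature",
              "moment", "hjorth", "band", "wavelet", "sef")
    seen = set()
    for combo in itertools.product(*(GENE_DOMAINS[n] for n in active)):
        spec = decode(base.replace(**dict(zip(active, combo))))
        seen.add(spec.feature_id)
    assert seen == set(FEATURE_IDS)
    assert len(seen) == 24


def test_gene_neighbourhoods():
    assert gene_neighbours("preictal", 30) == (35,)
    assert gene_neighbours("preictal", 75) == (70,)
    assert set(gene_neighbours("preictal", 50)) == {45, 55}
    assert gene_neighbours("electrode", "C3") == ADJACENCY["C3"]
    assert gene_neighbours("active_group", "time") == ("frequency",)
    # symmetry over every gene value
    for name, domain in GENE_DOMAINS.items():
        for v in domain:
            nbrs = gene_neighbours(name, v)
            assert len(nbrs) >= 1
            for n in nbrs:
                assert v in gene_neighbours(name, n)


def test_mutation_zero_rate_identity_and_boundary_step(rng):
    ind = random_individual(rng)
    assert mutate(ind, rng, rate=0.0) == ind
    ind30 = Individual([hf.replace() for hf in ind.hyperfeatures], 30)
    assert mutate(ind30, rng, rate=1.0).preictal_min == 35


def test_mutation_rate_monte_carlo(rng):
    n_ind = 2000
    changed = total = 0
    for _ in range(n_ind):
        a = random_individual(rng)
        b = mutate(a, rng, rate=0.015)
        for ha, hb in zip(a.hyperfeatures, b.hyperfeatures):
            for ga, gb in zip(ha.genes(), hb.genes()):
                total += 1
                changed += ga != gb
        total += 1
        changed += a.preictal_min != b.preictal_min
    p = 0.015
    se = np.sqrt(p * (1 - p) / total)
    assert abs(changed / total - p) < 3 * se


def test_pairing_identity_and_greedy_order(rng):
    a = random_individual(rng)
    assert pair_hyperfeatures(a, a) == [(i, i) for i in range(5)]

    b = random_individual(rng)
    # force a near-identical pair at (2, 3): 13 shared genes
    b.hyperfeatures[3] = a.hyperfeatures[2].replace()
    pairs = pair_hyperfeatures(a, b)
    assert (2, 3) in pairs


def test_pairing_similarity_symmetric(rng):
    a, b = random_individual(rng), random_individual(rng)
    sims_ab = sorted(
        hyperfeature_similarity(a.hyperfeatures[i], b.hyperfeatures[j])
        for i, j in pair_hyperfeatures(a, b))
    sims_ba = sorted(
        hyperfeature_similarity(b.hyperfeatures[i], a.hyperfeatures[j])
        for i, j in pair_hyperfeatures(b, a))
    assert sims_ab == sims_ba


def test_recombination_closure_and_gene_containment(rng):
    for _ in range(200):
        a, b = random_individual(rng), random_individual(rng)
        child = recombine(a, b, rng, rate=1.0)
        child.validate()
        pairs = pair_hyperfeatures(a, b)
        for i, j in pairs:
            for name in GENE_NAMES:
                v = getattr(child.hyperfeatures[i], name)
                assert v in (getattr(a.hyperfeatures[i], name),
                             getattr(b.hyperfeatures[j], name))
        assert child.preictal_min in (a.preictal_min, b.preictal_min)


def test_recombination_identity_cases(rng):
    a = random_individual(rng)
    assert recombine(a, a, rng, rate=1.0) == a
    b = random_individual(rng)
    assert recombine(a, b, rng, rate=0.0) in (a, b)


def test_variation_operator_fuzz(rng):
    """Closure: long chains of mutate/recombine keep individuals valid."""
    pop = [random_individual(rng) for _ in range(10)]
    for _ in range(2000):
        i, j = rng.integers(10, size=2)
        child = recombine(pop[i], pop[j], rng)
        child = mutate(child, rng, rate=0.1)
        child.validate()
        pop[rng.integers(10)] = child


def test_individual_json_roundtrip(rng):
    ind = random_individual(rng)
    ind.fitness = (0.5, 0.6, 0.75)
    back = Individual.from_dict(ind.to_dict())
    assert back == ind and back.fitness == ind.fitness
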