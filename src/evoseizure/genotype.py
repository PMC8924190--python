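"""Genotype encoding of prediction models and the variation operators.

An individual is five hyper-feature genotypes plus one pre-ictal-period
gene (66 genes total).  Each hyper-feature carries 13 genes: nine select the
first-level feature through a hierarchical decode tree (inactive branches
stay populated but silent), and four set delay, electrode, reducing operator
and window length.  Mutation is a unitary step to a neighbouring gene value
— ordered domains step +/-1 with reflecting boundaries, the electrode gene
steps along physical scalp adjacency.  Recombination pairs the two parents'
hyper-features by genotypic similarity and mixes genes uniformly within each
pair.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .montage import ADJACENCY, ELECTRODES

#: Ordered domains of the 13 hyper-feature genes.
GENE_DOMAINS: dict[str, tuple] = {
    "active_group": ("time", "frequency"),
    "active_time_feature": ("moment", "hjorth"),
    "active_frequency_feature": ("band_power", "wavelet", "sef"),
    "active_band_feature": ("relative_power", "wavelet_energy"),
    "moment": ("mean", "variance", "skewness", "kurtosis"),
    "hjorth": ("activity", "mobility", "complexity"),
    "band": ("delta", "theta", "alpha", "beta", "low_gamma", "high_gamma"),
    "wavelet": ("d1", "d2", "d3", "d4", "d5", "d6", "d7", "d8", "a8"),
    "sef": (50, 75, 90),
    "delay": (0, 5, 10, 15, 20, 25, 30),            # minutes
    "electrode": ELECTRODES,
    "operator": ("mean", "median", "variance", "max", "min"),
    "window_length": (5, 10, 15, 20, 25, 30),       # minutes
}
GENE_NAMES = tuple(GENE_DOMAINS)
PREICTAL_DOMAIN = tuple(range(30, 80, 5))           # 30 ... 75 min
N_HYPERFEATURES = 5
GENES_PER_INDIVIDUAL = N_HYPERFEATURES * len(GENE_NAMES) + 1  # 66


def gene_neighbours(name: str, value):
    """Neighbouring values of a gene under the unitary-step topology."""
    if name == "electrode":
        return ADJACENCY[value]
    domain = GENE_DOMAINS[name] if name != "preictal" else PREICTAL_DOMAIN
    i = domain.index(value)
    nbrs = []
    if i > 0:
        nbrs.append(domain[i - 1])
    if i < len(domain) - 1:
        nbrs.append(domain[i + 1])
    return tuple(nbrs)


@dataclass(frozen=True)
class HyperFeatureSpec:
    """Decoded phenotype of one hyper-feature."""

    feature_id: str
    electrode: str
    delay_min: int
    operator: str
    window_min: int


@dataclass
class HyperFeatureGenotype:
    """13-gene encoding of one hyper-feature (all genes always populated)."""

    active_group: str
    active_time_feature: str
    active_frequency_feature: str
    active_band_feature: str
    moment: str
    hjorth: str
    band: str
    wavelet: str
    sef: int
    delay: int
    electrode: str
    operator: str
    window_length: int

    def genes(self) -> tuple:
        return tuple(getattr(self, n) for n in GENE_NAMES)

    def replace(self, **kw) -> "HyperFeatureGenotype":
        d = {n: getattr(self, n) for n in GENE_NAMES}
        d.update(kw)
        return HyperFeatureGenotype(**d)

    def validate(self) -> None:
        for n in GENE_NAMES:
            if getattr(self, n) not in GENE_DOMAINS[n]:
                raise ValueError(f"gene {n} has invalid value {getattr(self, n)!r}")


@dataclass
class Individual:
    """Five hyper-feature genotypes + a pre-ictal-period gene.

    ``fitness`` is the (Sss, Ssp, Pcf) triple once evaluated; ``rank`` and
    ``crowding`` are NSGA-II annotations.  Equality compares genes only.
    """

    hyperfeatures: list[HyperFeatureGenotype]
    preictal_min: int
    fitness: tuple | None = field(default=None, compare=False)
    rank: int | None = field(default=None, compare=False)
    crowding: float | None = field(default=None, compare=False)

    def __post_init__(self):
        if len(self.hyperfeatures) != N_HYPERFEATURES:
            raise ValueError(f"need exactly {N_HYPERFEATURES} hyper-features")
        if self.preictal_min not in PREICTAL_DOMAIN:
            raise ValueError(f"preictal_min {self.preictal_min} not in "
                             f"{PREICTAL_DOMAIN}")

    def validate(self) -> None:
        for hf in self.hyperfeatures:
            hf.validate()
        if self.preictal_min not in PREICTAL_DOMAIN:
            raise ValueError("invalid preictal_min")

    def specs(self) -> list[HyperFeatureSpec]:
        return [decode(hf) for hf in self.hyperfeatures]

    def electrodes(self) -> set[str]:
        return {s.electrode for s in self.specs()}

    def copy(self) -> "Individual":
        return Individual(
            [hf.replace() for hf in self.hyperfeatures], self.preictal_min,
            fitness=self.fitness, rank=self.rank, crowding=self.crowding,
        )

    def to_dict(self) -> dict:
        return {
            "hyperfeatures": [
                {n: getattr(hf, n) for n in GENE_NAMES}
                for hf in self.hyperfeatures
            ],
            "preictal_min": self.preictal_min,
            "fitness": list(self.fitness) if self.fitness else None,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Individual":
        hfs = [HyperFeatureGenotype(**h) for h in d["hyperfeatures"]]
        fit = tuple(d["fitness"]) if d.get("fitness") else None
        return cls(hfs, d["preictal_min"], fitness=fit)

    def to_json(self) -> str:
        return json.dumps(self.to_dict())


# ---------------------------------------------------------------------------
# decode

def decode(hf: HyperFeatureGenotype) -> HyperFeatureSpec:
    """Hierarchical genotype -> phenotype decode (total and deterministic).

    ``active_group`` picks the time or frequency branch; within time the
    moment or Hjorth gene is read (Hjorth *activity* decodes to the variance
    feature, its duplicate); within frequency ``active_frequency_feature``
    picks band power (then relative power vs wavelet energy), wavelet, or
    spectral edge.  Genes on inactive branches are ignored.
    """
    if hf.active_group == "time":
        if hf.active_time_feature == "moment":
            feature_id = hf.moment
        else:  # hjorth
            feature_id = {
                "activity": "variance",
                "mobility": "hjorth_mobility",
                "complexity": "hjorth_complexity",
            }[hf.hjorth]
    else:  # frequency
        if hf.active_frequency_feature == "sef":
            feature_id = f"sef{hf.sef}"
        elif hf.active_frequency_feature == "wavelet":
            feature_id = f"wavelet_{hf.wavelet}"
        else:  # band_power: relative power vs absolute wavelet energy
            if hf.active_band_feature == "relative_power":
                feature_id = f"rel_power_{hf.band}"
            else:
                feature_id = f"wavelet_{hf.wavelet}"
    return HyperFeatureSpec(
        feature_id=feature_id,
        electrode=hf.electrode,
        delay_min=hf.delay,
        operator=hf.operator,
        window_min=hf.window_length,
    )


# ---------------------------------------------------------------------------
# initialisation and variation

def random_hyperfeature(rng: np.random.Generator) -> HyperFeatureGenotype:
    return HyperFeatureGenotype(
        **{n: dom[rng.integers(len(dom))] for n, dom in GENE_DOMAINS.items()}
    )


def random_individual(rng: np.random.Generator) -> Individual:
    """Uniform draw of every gene from its domain."""
    return Individual(
        [random_hyperfeature(rng) for _ in range(N_HYPERFEATURES)],
        preictal_min=PREICTAL_DOMAIN[rng.integers(len(PREICTAL_DOMAIN))],
    )


def mutate(ind: Individual, rng: np.random.Generator,
           rate: float = 0.015) -> Individual:
    """Independent per-gene mutation: with probability ``rate`` a gene takes
    a uniformly chosen neighbouring value (unitary step)."""
    hfs = []
    for hf in ind.hyperfeatures:
        changes = {}
        for n in GENE_NAMES:
            if rng.random() < rate:
                nbrs = gene_neighbours(n, getattr(hf, n))
                changes[n] = nbrs[rng.integers(len(nbrs))]
        hfs.append(hf.replace(**changes) if changes else hf.replace())
    pre = ind.preictal_min
    if rng.random() < rate:
        nbrs = gene_neighbours("preictal", pre)
        pre = nbrs[rng.integers(len(nbrs))]
    return Individual(hfs, pre)


def hyperfeature_similarity(a: HyperFeatureGenotype,
                            b: HyperFeatureGenotype) -> int:
    """Number of equal gene values (0..13)."""
    return sum(x == y for x, y in zip(a.genes(), b.genes()))


def pair_hyperfeatures(a: Individual, b: Individual) -> list[tuple[int, int]]:
    """Greedy maximum-similarity bipartite pairing of the 5x5 hyper-features.

    Ties break on the lowest (a-index, b-index) in row-major order.  Returns
    pairs ``(i, j)`` meaning a.hyperfeatures[i] <-> b.hyperfeatures[j].
    """
    sim = np.array([
        [hyperfeature_similarity(ha, hb) for hb in b.hyperfeatures]
        for ha in a.hyperfeatures
    ])
    pairs = []
    free_a = list(range(N_HYPERFEATURES))
    free_b = list(range(N_HYPERFEATURES))
    while free_a:
        best = None
        for i in free_a:
            for j in free_b:
                if best is None or sim[i, j] > sim[best]:
                    best = (i, j)
        pairs.append(best)
        free_a.remove(best[0])
        free_b.remove(best[1])
    return sorted(pairs)


def recombine(a: Individual, b: Individual, rng: np.random.Generator,
              rate: float = 0.90) -> Individual:
    """With probability ``rate``, gene-wise uniform crossover of similarity-
    paired hyper-features and of the pre-ictal gene; otherwise a copy of one
    parent chosen uniformly."""
    if rng.random() >= rate:
        return (a if rng.random() < 0.5 else b).copy()
    pairs = pair_hyperfeatures(a, b)
    hfs: list[HyperFeatureGenotype | None] = [None] * N_HYPERFEATURES
    for i, j in pairs:
        ha, hb = a.hyperfeatures[i], b.hyperfeatures[j]
        genes = {
            n: (getattr(ha, n) if rng.random() < 0.5 else getattr(hb, n))
            for n in GENE_NAMES
        }
        hfs[i] = HyperFeatureGenotype(**genes)
    pre = a.preictal_min if rng.random() < 0.5 else b.preictal_min
    return Individual(hfs, pre)
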