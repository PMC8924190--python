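"""Phenotype mining over Decision-Maker-selected individuals.

Each selected individual becomes one transaction of canonical items: the
active-branch gene values of its five hyper-features (decoded feature id,
electrode, operator, window length, delay), plus its pre-ictal period.
Gene presence is the fraction of transactions containing an item; gene
interaction comes from apriori association rules (level-wise frequent
itemsets, then rules filtered on support / confidence / lift), with pairwise
interaction strength obtained by summing rule lifts and normalising to
[0, 1].  Electrode-to-electrode rules with lift > 1 are exported as a
connectivity edge list.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import chain, combinations

import pandas as pd

from .genotype import Individual

MIN_SUPPORT = 0.07
MIN_CONFIDENCE = 0.10
MIN_LIFT = 1.00


@dataclass(frozen=True)
class AssociationRule:
    antecedent: frozenset
    consequent: frozenset
    support: float
    confidence: float
    lift: float

    @property
    def items(self) -> frozenset:
        return self.antecedent | self.consequent


def transaction_from_individual(ind: Individual) -> frozenset:
    """Canonical item set of one individual (active-branch values only)."""
    items = {f"preictal:{ind.preictal_min}"}
    for spec in ind.specs():
        items.add(f"feature:{spec.feature_id}")
        items.add(f"electrode:{spec.electrode}")
        items.add(f"operator:{spec.operator}")
        items.add(f"window:{spec.window_min}")
        items.add(f"delay:{spec.delay_min}")
    return frozenset(items)


def transactions_from_individuals(individuals) -> list[frozenset]:
    return [transaction_from_individual(ind) for ind in individuals]


def gene_presence(selected_individuals) -> dict[str, float]:
    """Ratio of transactions containing each item."""
    tx = _as_transactions(selected_individuals)
    if not tx:
        raise ValueError("need at least one individual")
    counts: dict[str, int] = {}
    for t in tx:
        for item in t:
            counts[item] = counts.get(item, 0) + 1
    n = len(tx)
    return {item: c / n for item, c in sorted(counts.items())}


def _as_transactions(seq) -> list[frozenset]:
    seq = list(seq)
    if seq and isinstance(seq[0], Individual):
        return transactions_from_individuals(seq)
    return [frozenset(t) for t in seq]


# ---------------------------------------------------------------------------
# apriori

def frequent_itemsets(transactions, min_support: float = MIN_SUPPORT,
                      max_len: int | None = None) -> dict[frozenset, float]:
    """Level-wise apriori frequent-itemset mining.

    Returns a mapping itemset -> support.  Candidate (k+1)-itemsets are
    joined from frequent k-itemsets and pruned by downward closure before
    counting.  ``max_len`` caps the itemset size: with duplicated
    transactions every subset of a shared transaction is frequent, so
    unbounded mining is exponential in the transaction length.
    """
    tx = _as_transactions(transactions)
    n = len(tx)
    if n == 0:
        raise ValueError("need at least one transaction")

    def support(s: frozenset) -> float:
        return sum(s <= t for t in tx) / n

    items = sorted(set(chain.from_iterable(tx)))
    level = {frozenset([i]) for i in items}
    freq: dict[frozenset, float] = {}
    size = 1
    while level and (max_len is None or size <= max_len):
        size += 1
        counted = {s: support(s) for s in level}
        kept = {s: v for s, v in counted.items() if v >= min_support}
        freq.update(kept)
        prev = set(kept)
        candidates = set()
        for a in prev:
            for b in prev:
                u = a | b
                if len(u) == len(a) + 1:
                    if all(frozenset(c) in prev
                           for c in combinations(u, len(a))):
                        candidates.add(u)
        level = candidates
    return freq


def apriori_rules(transactions, min_support: float = MIN_SUPPORT,
                  min_confidence: float = MIN_CONFIDENCE,
                  min_lift: float = MIN_LIFT,
                  max_len: int | None = 2) -> list[AssociationRule]:
    """Association rules from frequent itemsets, filtered by all three
    thresholds.  Lift = support(A u B) / (support(A) support(B)).

    The default ``max_len=2`` mines pairwise rules — the granularity at
    which interaction strengths and connectivity are aggregated; pass
    ``max_len=None`` for exhaustive mining on small item universes.
    """
    tx = _as_transactions(transactions)
    n = len(tx)
    freq = frequent_itemsets(tx, min_support=min_support, max_len=max_len)

    def support(s: frozenset) -> float:
        if s in freq:
            return freq[s]
        return sum(s <= t for t in tx) / n

    rules = []
    for itemset, supp in freq.items():
        if len(itemset) < 2:
            continue
        for r in range(1, len(itemset)):
            for ante in combinations(sorted(itemset), r):
                A = frozenset(ante)
                B = itemset - A
                sA, sB = support(A), support(B)
                if sA == 0 or sB == 0:
                    continue
                conf = supp / sA
                lift = supp / (sA * sB)
                if conf >= min_confidence and lift >= min_lift:
                    rules.append(AssociationRule(A, B, supp, conf, lift))
    return rules


# ---------------------------------------------------------------------------
# aggregation

def interaction_matrix(rules, items=None) -> pd.DataFrame:
    """Pairwise interaction strengths in [0, 1].

    For each rule, every antecedent-consequent item pair accumulates the
    rule's lift; pair sums are divided by the maximum pair sum.  ``items``
    optionally restricts the matrix to a subset of items.
    """
    sums: dict[tuple[str, str], float] = {}
    universe = set(items) if items is not None else None
    for rule in rules:
        for a in rule.antecedent:
            for b in rule.consequent:
                if universe is not None and (a not in universe
                                             or b not in universe):
                    continue
                key = tuple(sorted((a, b)))
                sums[key] = sums.get(key, 0.0) + rule.lift
    labels = sorted(set(chain.from_iterable(sums)) if items is None
                    else universe)
    mat = pd.DataFrame(0.0, index=labels, columns=labels)
    peak = max(sums.values(), default=0.0)
    for (a, b), v in sums.items():
        w = v / peak if peak > 0 else 0.0
        mat.loc[a, b] = w
        mat.loc[b, a] = w
    return mat


def electrode_connectivity(rules, transactions=None) -> pd.DataFrame:
    """Electrode-to-electrode edges from association rules with lift > 1.

    Returns an edge-list table (electrode_a, electrode_b, lift) summing lifts
    per unordered pair; with ``transactions`` given, a ``presence`` column
    table of node weights is attached as ``df.attrs['node_weights']``.
    """
    sums: dict[tuple[str, str], float] = {}
    for rule in rules:
        if rule.lift <= 1.0:
            continue
        for a in rule.antecedent:
            for b in rule.consequent:
                if a.startswith("electrode:") and b.startswith("electrode:"):
                    key = tuple(sorted((a, b)))
                    sums[key] = sums.get(key, 0.0) + rule.lift
    rows = [
        {"electrode_a": a.split(":", 1)[1],
         "electrode_b": b.split(":", 1)[1],
         "lift": v}
        for (a, b), v in sorted(sums.items())
    ]
    df = pd.DataFrame(rows, columns=["electrode_a", "electrode_b", "lift"])
    if transactions is not None:
        presence = gene_presence(transactions)
        df.attrs["node_weights"] = {
            k.split(":", 1)[1]: v for k, v in presence.items()
            if k.startswith("electrode:")
        }
    return df
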