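"""Weighted association-rule mining on the post-discretized matrix.

Items are the signed gene states g+ / g-; transactions are samples.  The
weighted measures follow the rank-weighting convention

    wsupp(X)    = sup(X)    * mean weight of X's items,
    wconf(A=>C) = conf(A=>C) * mean weight of (A u C)'s items,

where a signed item inherits its base gene's rank weight.  Since every weight
is <= 1, wsupp <= sup, so a level-wise frequent-itemset search on plain
support at the weighted threshold is a lossless superset of the weighted
result; the weighted filter is applied afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .preprocess import base_gene

__all__ = [
    "WeightedRule",
    "MiningConfig",
    "rule_key",
    "weighted_support",
    "weighted_confidence",
    "mine_rules",
    "rank_rules",
    "dynamic_select_rules",
    "select_top_rules",
]


@dataclass(frozen=True)
class WeightedRule:
    """An association rule A => C over signed items with its four scores."""

    antecedent: frozenset[str]
    consequent: frozenset[str]
    support: float
    wsupp: float
    confidence: float
    wconf: float

    def __post_init__(self) -> None:
        if not self.antecedent or not self.consequent:
            raise ValueError("both rule sides must be nonempty")
        if self.antecedent & self.consequent:
            raise ValueError("antecedent and consequent must be disjoint")

    @property
    def items(self) -> frozenset[str]:
        return self.antecedent | self.consequent

    def key(self) -> str:
        return (
            ";".join(sorted(self.antecedent))
            + "=>"
            + ";".join(sorted(self.consequent))
        )


def rule_key(rule: WeightedRule) -> str:
    return rule.key()


@dataclass(frozen=True)
class MiningConfig:
    min_wsupp: float = 0.5
    min_wconf: float = 0.7
    max_itemset_size: int = 4
    number_erules: int = 100

    def __post_init__(self) -> None:
        if not 0.0 < self.min_wsupp <= 1.0 or not 0.0 < self.min_wconf <= 1.0:
            raise ValueError("thresholds must lie in (0, 1]")
        if self.max_itemset_size < 2:
            raise ValueError("max_itemset_size must be >= 2")
        if self.number_erules < 1:
            raise ValueError("number_erules must be >= 1")


def _support(itemset: Iterable[str], transactions: pd.DataFrame) -> float:
    cols = list(itemset)
    missing = [c for c in cols if c not in transactions.columns]
    if missing:
        raise KeyError(f"unknown item(s): {missing}")
    return float(transactions[cols].all(axis=1).mean())


def _mean_weight(itemset: Iterable[str], weights: Mapping[str, float]) -> float:
    items = list(itemset)
    try:
        return sum(weights[i] for i in items) / len(items)
    except KeyError as exc:
        raise KeyError(f"no weight for item {exc.args[0]!r}") from exc


def weighted_support(
    itemset: Iterable[str],
    transactions: pd.DataFrame,
    weights: Mapping[str, float],
) -> float:
    """sup(X) scaled by the mean item weight; equals sup when all weights 1."""
    items = list(itemset)
    if not items:
        raise ValueError("empty itemset")
    return _support(items, transactions) * _mean_weight(items, weights)


def weighted_confidence(
    antecedent: Iterable[str],
    consequent: Iterable[str],
    transactions: pd.DataFrame,
    weights: Mapping[str, float],
) -> float:
    """conf(A=>C) scaled by the mean weight of A u C."""
    a = set(antecedent)
    c = set(consequent)
    if not a or not c:
        raise ValueError("both rule sides must be nonempty")
    sup_a = _support(a, transactions)
    if sup_a == 0.0:
        raise ValueError("antecedent never occurs; confidence undefined")
    conf = _support(a | c, transactions) / sup_a
    return conf * _mean_weight(a | c, weights)


def _gene_of(item: str) -> str:
    """Base gene of a signed item; plain (unsigned) items are their own gene."""
    try:
        return base_gene(item)
    except ValueError:
        return item


def _self_contradictory(itemset: frozenset[str]) -> bool:
    """True when both signed states of one gene appear (support must be 0)."""
    genes = [_gene_of(i) for i in itemset]
    return len(set(genes)) < len(genes)


def _frequent_itemsets(
    transactions: pd.DataFrame, min_support: float, max_size: int
) -> dict[frozenset[str], float]:
    """Level-wise (Apriori) search on plain support."""
    mat = transactions.to_numpy(dtype=bool)
    n = mat.shape[0]
    cols = list(transactions.columns)
    col_idx = {c: j for j, c in enumerate(cols)}

    freq: dict[frozenset[str], float] = {}
    # Track the transaction cover of each frequent itemset for fast extension.
    covers: dict[frozenset[str], np.ndarray] = {}
    level: list[frozenset[str]] = []
    for c in cols:
        cover = mat[:, col_idx[c]]
        sup = cover.sum() / n
        s = frozenset([c])
        if sup >= min_support:
            freq[s] = sup
            covers[s] = cover
            level.append(s)

    size = 1
    while level and size < max_size:
        candidates: set[frozenset[str]] = set()
        level_set = set(level)
        ordered = sorted(level, key=lambda s: sorted(s))
        for i, a in enumerate(ordered):
            for b in ordered[i + 1 :]:
                cand = a | b
                if len(cand) != size + 1:
                    continue
                if _self_contradictory(cand):
                    continue
                # Apriori pruning: all size-k subsets must be frequent.
                if all(
                    frozenset(sub) in level_set for sub in combinations(cand, size)
                ):
                    candidates.add(cand)
        next_level = []
        for cand in candidates:
            items = sorted(cand)
            cover = covers[frozenset(items[:1])].copy()
            for it in items[1:]:
                cover &= mat[:, col_idx[it]]
            sup = cover.sum() / n
            if sup >= min_support:
                freq[cand] = sup
                covers[cand] = cover
                next_level.append(cand)
        level = next_level
        size += 1
    return freq


def mine_rules(
    transactions: pd.DataFrame,
    weights: Mapping[str, float],
    config: MiningConfig,
) -> list[WeightedRule]:
    """All rules with wsupp >= min_wsupp and wconf >= min_wconf.

    Frequent itemsets are found on plain support at threshold ``min_wsupp``
    (lossless because wsupp <= sup), rules are generated over every
    antecedent/consequent bipartition, and the weighted thresholds are applied
    last.  Itemsets pairing g+ with g- of the same gene are discarded as
    contradictory.
    """
    if transactions.empty:
        raise ValueError("empty transaction matrix")
    freq = _frequent_itemsets(
        transactions, config.min_wsupp, config.max_itemset_size
    )
    rules: list[WeightedRule] = []
    for itemset, sup in freq.items():
        if len(itemset) < 2:
            continue
        mean_w = _mean_weight(itemset, weights)
        wsupp = sup * mean_w
        if wsupp < config.min_wsupp:
            continue
        items = sorted(itemset)
        for r in range(1, len(items)):
            for ante in combinations(items, r):
                a = frozenset(ante)
                c = itemset - a
                sup_a = freq.get(a)
                if sup_a is None:
                    sup_a = _support(a, transactions)
                if sup_a == 0.0:
                    continue
                conf = sup / sup_a
                wconf = conf * mean_w
                if wconf < config.min_wconf:
                    continue
                rules.append(
                    WeightedRule(
                        antecedent=a,
                        consequent=c,
                        support=sup,
                        wsupp=wsupp,
                        confidence=conf,
                        wconf=wconf,
                    )
                )
    return rules


def rank_rules(rules: list[WeightedRule]) -> list[WeightedRule]:
    """Descending wconf, ties by descending wsupp, then the serialized key."""
    return sorted(rules, key=lambda r: (-r.wconf, -r.wsupp, r.key()))


def dynamic_select_rules(
    rules: list[WeightedRule], z_offset: float = 0.0
) -> list[WeightedRule]:
    """Retain rules scoring at or above mean + z_offset * sd on both measures.

    The mean and (population) standard deviation are taken over the input
    rule set, giving each rule its own data-driven support/confidence floor.
    """
    if not rules:
        raise ValueError("empty rule list")
    ws = np.array([r.wsupp for r in rules])
    wc = np.array([r.wconf for r in rules])
    eps = 1e-12  # guard against accumulation error when all scores are equal
    t_ws = ws.mean() + z_offset * ws.std() - eps
    t_wc = wc.mean() + z_offset * wc.std() - eps
    return [r for r in rules if r.wsupp >= t_ws and r.wconf >= t_wc]


def select_top_rules(ranked: list[WeightedRule], number_erules: int) -> list[WeightedRule]:
    if number_erules < 1:
        raise ValueError("number_erules must be >= 1")
    return ranked[:number_erules]


def rules_to_frame(rules: list[WeightedRule]) -> pd.DataFrame:
    """Tabular view used by the rules.tsv writer."""
    rows = [
        {
            "antecedent": ";".join(sorted(r.antecedent)),
            "consequent": ";".join(sorted(r.consequent)),
            "support": r.support,
            "wsupp": r.wsupp,
            "confidence": r.confidence,
            "wconf": r.wconf,
            "rank": i + 1,
        }
        for i, r in enumerate(rules)
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "antecedent",
            "consequent",
            "support",
            "wsupp",
            "confidence",
            "wconf",
            "rank",
        ],
    )
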