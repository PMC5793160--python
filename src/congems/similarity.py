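"""Weighted rank-based similarity between association rules.

Two measures are defined over a pair of rules r1 = (r1a => r1c) and
r2 = (r2a => r2c), each item carrying its gene's rank weight:

* Weighted Jaccard: the weighted sum of items shared on the same side
  (LHS/LHS, RHS/RHS) or on opposite sides (LHS/RHS, RHS/LHS), divided by the
  weighted sum over the four corresponding unions.  A rule against itself
  scores exactly 1/3 (the two cross-unions each duplicate the whole rule).

* Weighted cosine: the cosine of the two rule vectors of length 2n over an
  ordered item universe of size n - antecedent weights in the first half,
  consequent weights in the second - so a shared item only contributes when
  it sits on the same side of both rules.  A rule against itself scores 1.

The two scores are blended as e1 * WJaccard + e2 * WCos (defaults 0.5/0.5)
and turned into the dissimilarity 1 - blend that the clustering consumes.
Matching is over signed items: g+ and g- are distinct states of gene g.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .mining import WeightedRule

__all__ = [
    "rule_item_universe",
    "build_rule_vector",
    "weighted_jaccard",
    "weighted_cosine",
    "integrated_similarity",
    "compute_dissimilarity_matrix",
]


def rule_item_universe(rules: Sequence[WeightedRule]) -> list[str]:
    """Deterministic (sorted) universe of the signed items used by ``rules``."""
    universe: set[str] = set()
    for r in rules:
        universe |= r.items
    return sorted(universe)


def build_rule_vector(
    rule: WeightedRule,
    item_universe: Sequence[str],
    weights: Mapping[str, float],
) -> np.ndarray:
    """Length-2n vector: antecedent weights first, consequent weights second."""
    index = {item: i for i, item in enumerate(item_universe)}
    unknown = rule.items - index.keys()
    if unknown:
        raise KeyError(f"rule items outside universe: {sorted(unknown)}")
    n = len(item_universe)
    vec = np.zeros(2 * n)
    for item in rule.antecedent:
        vec[index[item]] = weights[item]
    for item in rule.consequent:
        vec[n + index[item]] = weights[item]
    return vec


def _wsum(items: frozenset[str] | set[str], weights: Mapping[str, float]) -> float:
    return sum(weights[i] for i in items)


def weighted_jaccard(
    r1: WeightedRule, r2: WeightedRule, weights: Mapping[str, float]
) -> float:
    """Weighted Jaccard over the four side combinations; 0/0 defined as 0."""
    num = (
        _wsum(r1.antecedent & r2.antecedent, weights)
        + _wsum(r1.consequent & r2.consequent, weights)
        + _wsum(r1.antecedent & r2.consequent, weights)
        + _wsum(r1.consequent & r2.antecedent, weights)
    )
    den = (
        _wsum(r1.antecedent | r2.antecedent, weights)
        + _wsum(r1.consequent | r2.consequent, weights)
        + _wsum(r1.antecedent | r2.consequent, weights)
        + _wsum(r1.consequent | r2.antecedent, weights)
    )
    if den == 0.0:
        return 0.0
    return num / den


def weighted_cosine(
    r1: WeightedRule,
    r2: WeightedRule,
    weights: Mapping[str, float],
    item_universe: Sequence[str] | None = None,
) -> float:
    """Cosine of the two 2n rule vectors; 0 when either norm vanishes."""
    if item_universe is None:
        item_universe = rule_item_universe([r1, r2])
    u = build_rule_vector(r1, item_universe, weights)
    v = build_rule_vector(r2, item_universe, weights)
    nu = float(np.linalg.norm(u))
    nv = float(np.linalg.norm(v))
    if nu == 0.0 or nv == 0.0:
        return 0.0
    return float(u @ v) / (nu * nv)


def integrated_similarity(
    r1: WeightedRule,
    r2: WeightedRule,
    weights: Mapping[str, float],
    e1: float = 0.5,
    e2: float = 0.5,
    item_universe: Sequence[str] | None = None,
) -> float:
    _check_blend(e1, e2)
    return e1 * weighted_jaccard(r1, r2, weights) + e2 * weighted_cosine(
        r1, r2, weights, item_universe
    )


def _check_blend(e1: float, e2: float) -> None:
    if e1 < 0 or e2 < 0 or e1 + e2 > 1.0 + 1e-12:
        raise ValueError("need e1, e2 >= 0 and e1 + e2 <= 1")


def compute_dissimilarity_matrix(
    rules: Sequence[WeightedRule],
    weights: Mapping[str, float],
    e1: float = 0.5,
    e2: float = 0.5,
    return_similarity: bool = False,
) -> pd.DataFrame | tuple[pd.DataFrame, pd.DataFrame]:
    """Symmetric rule-by-rule dissimilarity 1 - (e1*WJ + e2*WCos).

    The diagonal is forced to 0 (the linkage input contract) even though the
    off-diagonal formula would give 1 - e1/3 - e2 for a rule paired with its
    own copy.  With ``return_similarity`` the blended similarity matrix
    (diagonal 1) is returned as well; it feeds the network-concept indices.
    """
    _check_blend(e1, e2)
    if len(rules) < 2:
        raise ValueError("need at least 2 rules")
    universe = rule_item_universe(rules)
    vectors = np.stack(
        [build_rule_vector(r, universe, weights) for r in rules]
    )
    norms = np.linalg.norm(vectors, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cos = (vectors @ vectors.T) / np.outer(norms, norms)
    cos = np.nan_to_num(cos, nan=0.0)

    n = len(rules)
    jac = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            jac[i, j] = jac[j, i] = weighted_jaccard(rules[i], rules[j], weights)

    sim = e1 * jac + e2 * cos
    dissim = 1.0 - sim
    np.fill_diagonal(dissim, 0.0)
    np.fill_diagonal(sim, 1.0)

    keys = [r.key() for r in rules]
    d = pd.DataFrame(dissim, index=keys, columns=keys)
    if return_similarity:
        return d, pd.DataFrame(sim, index=keys, columns=keys)
    return d


def similarity_long_format(
    rules: Sequence[WeightedRule],
    weights: Mapping[str, float],
    e1: float = 0.5,
    e2: float = 0.5,
) -> pd.DataFrame:
    """Long-format pair table: rule_i, rule_j, WJaccard, WCos, Int, dissim."""
    universe = rule_item_universe(rules)
    rows = []
    for i, r1 in enumerate(rules):
        for j in range(i + 1, len(rules)):
            r2 = rules[j]
            wj = weighted_jaccard(r1, r2, weights)
            wc = weighted_cosine(r1, r2, weights, universe)
            integ = e1 * wj + e2 * wc
            rows.append(
                {
                    "rule_i": r1.key(),
                    "rule_j": r2.key(),
                    "Wzeta": wj,
                    "WCos": wc,
                    "Int": integ,
                    "dissim": 1.0 - integ,
                }
            )
    return pd.DataFrame(
        rows, columns=["rule_i", "rule_j", "Wzeta", "WCos", "Int", "dissim"]
    )
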