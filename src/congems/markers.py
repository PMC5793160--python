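"""Condensed gene-expression markers from rule-modules.

Within each module the antecedent genesets and consequent genesets of the
member rules are counted; the most frequent geneset per (module, side) is a
marker candidate.  Candidates overlapping in genes are then pruned by two
geneset-equivalence regulations: with equal frequencies the geneset covering
all participating genes survives, with unequal frequencies the most frequent
one survives.  Survivors are ranked globally by frequency.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections import Counter

import pandas as pd

from .clustering import ModulePartition, UNASSIGNED
from .mining import WeightedRule

__all__ = [
    "GenesetFrequency",
    "CondensedMarker",
    "side_geneset_frequencies",
    "most_frequent_genesets",
    "prune_equivalent_genesets",
    "rank_condensed_markers",
]


@dataclass(frozen=True)
class GenesetFrequency:
    geneset: frozenset[str]
    side: str          # "antecedent" or "consequent"
    module: str
    frequency: int

    def __post_init__(self) -> None:
        if not self.geneset:
            raise ValueError("empty geneset")
        if self.frequency < 1:
            raise ValueError("frequency must be >= 1")

    def sorted_items(self) -> tuple[str, ...]:
        return tuple(sorted(self.geneset))


@dataclass(frozen=True)
class CondensedMarker:
    geneset: frozenset[str]
    module: str
    side: str
    frequency: int
    rank: int

    def label(self) -> str:
        return ";".join(sorted(self.geneset))


def side_geneset_frequencies(
    partition: ModulePartition, rules: list[WeightedRule]
) -> list[GenesetFrequency]:
    """Multiset counts of antecedent/consequent genesets per module.

    Rules labeled grey are excluded; every rule must carry a label.
    """
    counts: Counter[tuple[str, str, frozenset[str]]] = Counter()
    for rule in rules:
        key = rule.key()
        if key not in partition.labels.index:
            raise KeyError(f"rule without module label: {key}")
        module = partition.labels[key]
        if module == UNASSIGNED:
            continue
        counts[(module, "antecedent", rule.antecedent)] += 1
        counts[(module, "consequent", rule.consequent)] += 1
    return [
        GenesetFrequency(geneset=gs, side=side, module=mod, frequency=c)
        for (mod, side, gs), c in sorted(
            counts.items(), key=lambda kv: (kv[0][0], kv[0][1], sorted(kv[0][2]))
        )
    ]


def most_frequent_genesets(
    freqs: list[GenesetFrequency],
) -> list[GenesetFrequency]:
    """Argmax-frequency geneset per (module, side).

    Ties go to the larger geneset, then to the lexicographically smallest.
    """
    best: dict[tuple[str, str], GenesetFrequency] = {}
    for f in freqs:
        key = (f.module, f.side)
        cur = best.get(key)
        if cur is None:
            best[key] = f
            continue
        cand = (f.frequency, len(f.geneset))
        incumbent = (cur.frequency, len(cur.geneset))
        if cand > incumbent or (
            cand == incumbent and f.sorted_items() < cur.sorted_items()
        ):
            best[key] = f
    return [best[k] for k in sorted(best)]


def _overlap_components(
    candidates: list[GenesetFrequency],
) -> list[list[int]]:
    """Connected components of the share-an-item graph over candidates."""
    parent = list(range(len(candidates)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    by_item: dict[str, int] = {}
    for i, cand in enumerate(candidates):
        for item in cand.geneset:
            if item in by_item:
                union(by_item[item], i)
            else:
                by_item[item] = i
    comps: dict[int, list[int]] = {}
    for i in range(len(candidates)):
        comps.setdefault(find(i), []).append(i)
    return list(comps.values())


def _covering_member(members: list[GenesetFrequency]) -> GenesetFrequency | None:
    """A member whose geneset is a superset of every other member's, if any."""
    for m in members:
        if all(other.geneset <= m.geneset for other in members):
            return m
    return None


def _maximal_members(members: list[GenesetFrequency]) -> list[GenesetFrequency]:
    out = []
    for m in members:
        if not any(
            m.geneset < other.geneset for other in members if other is not m
        ):
            out.append(m)
    return out


def prune_equivalent_genesets(
    candidates: list[GenesetFrequency],
) -> list[GenesetFrequency]:
    """Apply the two geneset-equivalence pruning regulations.

    Within each overlap component: equal frequencies keep only the member
    covering all participating genes (when one exists, else all maximal
    members); unequal frequencies keep the maximum-frequency member(s), with
    residual ties resolved by the covering rule again.  Frequencies are
    carried through unchanged, never merged.  The operation is idempotent and
    leaves genesets disjoint from all others untouched.
    """
    kept: list[GenesetFrequency] = []
    for comp in _overlap_components(candidates):
        members = [candidates[i] for i in comp]
        if len(members) == 1:
            kept.extend(members)
            continue
        freqs = {m.frequency for m in members}
        if len(freqs) > 1:
            top = max(freqs)
            members = [m for m in members if m.frequency == top]
        if len(members) == 1:
            kept.extend(members)
            continue
        cover = _covering_member(members)
        if cover is not None:
            kept.append(cover)
        else:
            kept.extend(_maximal_members(members))
    kept.sort(key=lambda m: (m.module, m.side, m.sorted_items()))
    return kept


def rank_condensed_markers(
    pruned: list[GenesetFrequency], top_k: int | None = None
) -> list[CondensedMarker]:
    """Global ranking by descending frequency.

    Ties prefer the smaller geneset, then lexicographic order; module and
    side are carried through.
    """
    if top_k is not None and top_k < 1:
        raise ValueError("top_k must be >= 1")
    ordered = sorted(
        pruned,
        key=lambda m: (-m.frequency, len(m.geneset), m.sorted_items(), m.module, m.side),
    )
    if top_k is not None:
        ordered = ordered[:top_k]
    return [
        CondensedMarker(
            geneset=m.geneset,
            module=m.module,
            side=m.side,
            frequency=m.frequency,
            rank=i + 1,
        )
        for i, m in enumerate(ordered)
    ]


def markers_to_frame(markers: list[CondensedMarker]) -> pd.DataFrame:
    rows = [
        {
            "rank": m.rank,
            "geneset": m.label(),
            "module_color": m.module,
            "side": m.side,
            "frequency": m.frequency,
            "status": "unannotated",
        }
        for m in markers
    ]
    return pd.DataFrame(
        rows, columns=["rank", "geneset", "module_color", "side", "frequency", "status"]
    )
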