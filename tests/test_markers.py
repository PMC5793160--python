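"""Geneset frequencies, pruning regulations, and marker ranking."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_rule
from congems.clustering import ModulePartition
from congems.markers import (
    GenesetFrequency,
    most_frequent_genesets,
    prune_equivalent_genesets,
    rank_condensed_markers,
    side_geneset_frequencies,
)


def gf(items, freq, side="antecedent", module="blue"):
    return GenesetFrequency(
        geneset=frozenset(items), side=side, module=module, frequency=freq
    )


def partition_for(rules, color="blue"):
    labels = pd.Series({r.key(): color for r in rules}, name="module_color")
    return ModulePartition(labels=labels)


class TestSideFrequencies:
    def test_counting_example(self):
        rules = [
            make_rule(["A", "B"], ["C"]),
            make_rule(["A", "B"], ["D"]),
            make_rule(["A"], ["C"]),
        ]
        freqs = side_geneset_frequencies(partition_for(rules), rules)
        table = {(f.side, f.sorted_items()): f.frequency for f in freqs}
        assert table[("antecedent", ("A", "B"))] == 2
        assert table[("antecedent", ("A",))] == 1
        assert table[("consequent", ("C",))] == 2
        assert table[("consequent", ("D",))] == 1

    def test_single_rule_module(self):
        rules = [make_rule(["X"], ["Y"])]
        freqs = side_geneset_frequencies(partition_for(rules), rules)
        assert sorted((f.side, f.frequency) for f in freqs) == [
            ("antecedent", 1),
            ("consequent", 1),
        ]

    def test_grey_rules_excluded(self):
        rules = [make_rule(["A"], ["B"]), make_rule(["C"], ["D"])]
        labels = pd.Series(
            {rules[0].key(): "blue", rules[1].key(): "grey"}, name="module_color"
        )
        freqs = side_geneset_frequencies(ModulePartition(labels=labels), rules)
        genes = {i for f in freqs for i in f.geneset}
        assert genes == {"A", "B"}

    def test_unlabeled_rule_rejected(self):
        rules = [make_rule(["A"], ["B"])]
        empty = ModulePartition(labels=pd.Series(dtype=object))
        with pytest.raises(KeyError):
            side_geneset_frequencies(empty, rules)


class TestMostFrequent:
    def test_argmax_per_side(self):
        freqs = [
            gf(["A", "B"], 2),
            gf(["A"], 1),
            gf(["C"], 2, side="consequent"),
            gf(["D"], 1, side="consequent"),
        ]
        winners = {(w.side): w for w in most_frequent_genesets(freqs)}
        assert winners["antecedent"].geneset == {"A", "B"}
        assert winners["consequent"].geneset == {"C"}

    def test_frequency_tie_prefers_larger_geneset(self):
        freqs = [gf(["A"], 3), gf(["B", "C"], 3)]
        (winner,) = most_frequent_genesets(freqs)
        assert winner.geneset == {"B", "C"}

    def test_full_tie_prefers_lexicographic(self):
        freqs = [gf(["B"], 2), gf(["A"], 2)]
        (winner,) = most_frequent_genesets(freqs)
        assert winner.geneset == {"A"}


class TestPruning:
    def test_equal_frequency_keeps_covering_geneset(self):
        out = prune_equivalent_genesets([gf(["a"], 2), gf(["a", "b"], 2)])
        assert [set(m.geneset) for m in out] == [{"a", "b"}]

    def test_unequal_frequency_keeps_most_frequent(self):
        out = prune_equivalent_genesets([gf(["a"], 3), gf(["a", "b"], 2)])
        assert [set(m.geneset) for m in out] == [{"a"}]
        assert out[0].frequency == 3

    def test_disjoint_genesets_both_kept(self):
        out = prune_equivalent_genesets([gf(["a"], 2), gf(["b"], 2)])
        assert len(out) == 2

    def test_no_covering_member_keeps_maximal(self):
        out = prune_equivalent_genesets(
            [gf(["a", "b"], 2), gf(["b", "c"], 2), gf(["b"], 2)]
        )
        assert sorted(m.sorted_items() for m in out) == [("a", "b"), ("b", "c")]

    @given(
        st.lists(
            st.tuples(
                st.sets(st.sampled_from("abcdefg"), min_size=1, max_size=4),
                st.integers(1, 5),
            ),
            min_size=1,
            max_size=10,
            unique_by=lambda t: frozenset(t[0]),
        )
    )
    @settings(max_examples=100, derandomize=True)
    def test_pruning_idempotent_and_monotone(self, raw):
        candidates = [gf(items, freq) for items, freq in raw]
        once = prune_equivalent_genesets(candidates)
        twice = prune_equivalent_genesets(once)
        assert {(m.sorted_items(), m.frequency) for m in once} == {
            (m.sorted_items(), m.frequency) for m in twice
        }
        assert len(once) <= len(candidates)
        # A geneset disjoint from every other always survives, with its
        # original frequency untouched.
        inputs = {m.sorted_items(): m.frequency for m in candidates}
        survivors = {m.sorted_items(): m.frequency for m in once}
        for cand in candidates:
            others = [c for c in candidates if c is not cand]
            if all(not (cand.geneset & o.geneset) for o in others):
                assert survivors[cand.sorted_items()] == inputs[cand.sorted_items()]


class TestRanking:
    def test_global_frequency_ranking_with_tie_rule(self):
        pruned = [
            gf(["a"], 5),
            gf(["b", "c"], 3),
            gf(["d"], 3),
            gf(["e"], 1),
        ]
        markers = rank_condensed_markers(pruned, top_k=2)
        assert [m.rank for m in markers] == [1, 2]
        assert set(markers[0].geneset) == {"a"}
        assert set(markers[1].geneset) == {"d"}  # smaller geneset wins the tie

    def test_top_k_larger_than_list(self):
        markers = rank_condensed_markers([gf(["a"], 2)], top_k=10)
        assert len(markers) == 1
        assert markers[0].rank == 1

    def test_empty_input_empty_output(self):
        assert rank_condensed_markers([]) == []

    def test_invalid_top_k_rejected(self):
        with pytest.raises(ValueError):
            rank_condensed_markers([gf(["a"], 1)], top_k=0)
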