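"""Weighted rule mining: scores, search completeness, ranking, selection."""

import numpy as np
import pandas as pd
import pytest

from _oracles import brute_force_weighted_rules
from congems.mining import (
    MiningConfig,
    WeightedRule,
    dynamic_select_rules,
    mine_rules,
    rank_rules,
    select_top_rules,
    weighted_confidence,
    weighted_support,
)


def scored_rule(a, c, wconf, wsupp=0.5):
    return WeightedRule(
        antecedent=frozenset(a), consequent=frozenset(c), support=1.0,
        wsupp=wsupp, confidence=1.0, wconf=wconf,
    )


class TestScores:
    def test_weighted_support_hand_example(self, mining_example):
        transactions, weights = mining_example
        # sup({A,B}) = 3/4, mean weight = (1 + 2/3)/2 = 5/6
        assert weighted_support(["A", "B"], transactions, weights) == pytest.approx(
            0.625
        )

    def test_unit_weights_reduce_to_support(self, mining_example):
        transactions, _ = mining_example
        ones = {"A": 1.0, "B": 1.0, "C": 1.0}
        assert weighted_support(["A", "C"], transactions, ones) == pytest.approx(
            2 / 4
        )

    def test_absent_item_scores_zero(self, mining_example):
        transactions, weights = mining_example
        transactions = transactions.copy()
        transactions["D"] = False
        assert weighted_support(["D"], transactions, {**weights, "D": 1.0}) == 0.0

    def test_empty_itemset_rejected(self, mining_example):
        transactions, weights = mining_example
        with pytest.raises(ValueError):
            weighted_support([], transactions, weights)

    def test_weighted_confidence_hand_example(self, mining_example):
        transactions, weights = mining_example
        # conf(B=>A) = 1, mean weight of {A,B} = 5/6
        assert weighted_confidence(
            ["B"], ["A"], transactions, weights
        ) == pytest.approx(5 / 6)

    def test_never_occurring_antecedent_rejected(self, mining_example):
        transactions, weights = mining_example
        transactions = transactions.copy()
        transactions["D"] = False
        with pytest.raises(ValueError, match="never occurs"):
            weighted_confidence(["D"], ["A"], transactions, {**weights, "D": 1.0})

    def test_scores_scale_linearly_with_weights(self, mining_example):
        transactions, weights = mining_example
        c = 0.37
        scaled = {k: c * v for k, v in weights.items()}
        assert weighted_support(
            ["A", "B"], transactions, scaled
        ) == pytest.approx(c * weighted_support(["A", "B"], transactions, weights))
        assert weighted_confidence(
            ["B"], ["A"], transactions, scaled
        ) == pytest.approx(
            c * weighted_confidence(["B"], ["A"], transactions, weights)
        )


class TestMineRules:
    def test_worked_example_yields_exactly_one_rule(self, mining_example):
        transactions, weights = mining_example
        rules = mine_rules(
            transactions, weights, MiningConfig(min_wsupp=0.5, min_wconf=0.7)
        )
        assert len(rules) == 1
        (rule,) = rules
        assert rule.antecedent == frozenset({"B"})
        assert rule.consequent == frozenset({"A"})
        assert rule.wsupp == pytest.approx(0.625)
        assert rule.wconf == pytest.approx(5 / 6)

    def test_permissive_thresholds_return_both_directions(self):
        transactions = pd.DataFrame(
            [[1, 1], [1, 1], [1, 1]], columns=["A", "B"]
        ).astype(bool)
        rules = mine_rules(
            transactions,
            {"A": 1.0, "B": 1.0},
            MiningConfig(min_wsupp=1e-9, min_wconf=1e-9),
        )
        assert {r.key() for r in rules} == {"A=>B", "B=>A"}

    def test_unreachable_thresholds_return_empty(self, mining_example):
        transactions, weights = mining_example
        assert (
            mine_rules(
                transactions, weights, MiningConfig(min_wsupp=0.99, min_wconf=0.99)
            )
            == []
        )

    def test_contradictory_signed_itemsets_excluded(self):
        # g1+ and g1- co-occur in no sample by construction; even a
        # fabricated co-occurrence must not produce a g1+ => g1- rule.
        transactions = pd.DataFrame(
            [[1, 1], [1, 1]], columns=["g1+", "g1-"]
        ).astype(bool)
        rules = mine_rules(
            transactions,
            {"g1+": 1.0, "g1-": 1.0},
            MiningConfig(min_wsupp=0.1, min_wconf=0.1),
        )
        assert rules == []

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n_items = int(rng.integers(4, 9))
        n_txn = int(rng.integers(8, 25))
        columns = [f"i{k}" for k in range(n_items)]
        transactions = pd.DataFrame(
            rng.random((n_txn, n_items)) < 0.45, columns=columns
        )
        weights = {c: float(rng.uniform(0.2, 1.0)) for c in columns}
        config = MiningConfig(min_wsupp=0.1, min_wconf=0.4, max_itemset_size=3)
        mined = {
            (r.antecedent, r.consequent): (r.support, r.wsupp, r.confidence, r.wconf)
            for r in mine_rules(transactions, weights, config)
        }
        expected = brute_force_weighted_rules(
            transactions.to_numpy(), columns, weights, 0.1, 0.4, 3
        )
        assert mined.keys() == expected.keys()
        for key, scores in expected.items():
            assert np.allclose(mined[key], scores, atol=1e-12)


class TestRankingAndSelection:
    def test_rank_by_wconf_then_wsupp(self):
        r1 = scored_rule(["a"], ["b"], wconf=0.9, wsupp=0.5)
        r2 = scored_rule(["a"], ["c"], wconf=0.9, wsupp=0.6)
        r3 = scored_rule(["b"], ["c"], wconf=0.8, wsupp=0.7)
        assert rank_rules([r1, r3, r2]) == [r2, r1, r3]

    def test_full_tie_falls_back_to_lexicographic_key(self):
        r1 = scored_rule(["b"], ["c"], wconf=0.9)
        r2 = scored_rule(["a"], ["c"], wconf=0.9)
        assert rank_rules([r1, r2]) == [r2, r1]

    def test_rank_empty_is_empty(self):
        assert rank_rules([]) == []

    def test_dynamic_selection_keeps_above_mean(self):
        low = scored_rule(["a"], ["b"], wconf=0.7)
        high = scored_rule(["a"], ["c"], wconf=0.9)
        assert dynamic_select_rules([low, high]) == [high]

    def test_dynamic_selection_identical_scores_keep_all(self):
        rules = [scored_rule(["a"], [f"b{i}"], wconf=0.8) for i in range(3)]
        assert dynamic_select_rules(rules) == rules

    def test_dynamic_selection_very_negative_offset_keeps_all(self):
        rules = [
            scored_rule(["a"], ["b"], wconf=0.7),
            scored_rule(["a"], ["c"], wconf=0.9),
        ]
        assert dynamic_select_rules(rules, z_offset=-100.0) == rules

    def test_dynamic_selection_empty_rejected(self):
        with pytest.raises(ValueError):
            dynamic_select_rules([])

    def test_top_n_truncation(self):
        rules = [scored_rule(["a"], [f"b{i}"], wconf=0.9 - 0.1 * i) for i in range(5)]
        assert select_top_rules(rules, 3) == rules[:3]
        assert select_top_rules(rules, 10) == rules
        with pytest.raises(ValueError):
            select_top_rules(rules, 0)
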