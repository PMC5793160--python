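import numpy as np
import pandas as pd
import pytest

from congems.mining import WeightedRule


def make_rule(antecedent, consequent):
    """Rule skeleton for similarity tests; scores are irrelevant there."""
    return WeightedRule(
        antecedent=frozenset(antecedent),
        consequent=frozenset(consequent),
        support=1.0,
        wsupp=1.0,
        confidence=1.0,
        wconf=1.0,
    )


def random_rule(rng, universe, weights=None, max_side=3):
    """Random valid rule: disjoint nonempty sides drawn from the universe."""
    k = rng.integers(2, min(len(universe), 2 * max_side) + 1)
    items = list(rng.choice(universe, size=k, replace=False))
    split = rng.integers(1, k)
    return make_rule(items[:split], items[split:])


@pytest.fixture
def worked_weights():
    """Weights of the three-gene worked similarity example."""
    return {"g1+": 1.0, "g2+": 0.9, "g3+": 0.8}


@pytest.fixture
def worked_pair():
    return make_rule(["g1+"], ["g2+"]), make_rule(["g1+"], ["g3+"])


@pytest.fixture
def mining_example():
    """Four transactions over items A, B, C with rank-style weights."""
    transactions = pd.DataFrame(
        [[1, 1, 0], [1, 1, 0], [1, 1, 1], [1, 0, 1]],
        columns=["A", "B", "C"],
        index=["t1", "t2", "t3", "t4"],
    ).astype(bool)
    weights = {"A": 1.0, "B": 2 / 3, "C": 1 / 3}
    return transactions, weights


@pytest.fixture
def two_block_dissim():
    """Two well-separated planted blocks (within 0.05, between 0.9)."""
    n = 8
    arr = np.full((n, n), 0.9)
    for block in (range(4), range(4, 8)):
        for i in block:
            for j in block:
                arr[i, j] = 0.05
    np.fill_diagonal(arr, 0.0)
    return pd.DataFrame(
        arr, index=[f"r{i}" for i in range(n)], columns=[f"r{i}" for i in range(n)]
    )
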