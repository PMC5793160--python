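"""Seeded generators for two-group expression data and boolean transaction data.

Every downstream stage of the rule-module pipeline is testable against these
generators without external downloads: expression matrices carry planted
differentially expressed (DE) genes and planted correlated gene blocks, and
transaction matrices carry planted co-occurring itemsets.  The planted truth
is returned alongside the data so recovery can be scored.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SyntheticExpressionSpec",
    "SyntheticTruth",
    "simulate_expression",
    "simulate_transactions",
    "write_expression_tsv",
    "write_groups_tsv",
    "write_truth_json",
]


@dataclass(frozen=True)
class SyntheticExpressionSpec:
    """Parameters of a planted two-group expression experiment.

    Genes are drawn i.i.d. Normal(0, noise_sd^2) unless they belong to a
    correlated block (one shared latent factor per block per sample, pairwise
    correlation ``rho``) and/or to the planted DE set (group-mean shift
    ``delta`` added to case samples, sign alternating gene by gene so both
    up- and down-regulated paths are exercised).  Block membership and DE
    status may overlap: the first ``n_de`` genes are DE and the first
    ``n_blocks * block_size`` genes are tiled into blocks.
    """

    n_genes: int
    n_case: int
    n_control: int
    n_de: int = 0
    delta: float = 0.0
    n_blocks: int = 0
    block_size: int = 0
    rho: float = 0.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_case < 1 or self.n_control < 1:
            raise ValueError("n_genes, n_case and n_control must be positive")
        if not 0 <= self.n_de <= self.n_genes:
            raise ValueError("n_de must satisfy 0 <= n_de <= n_genes")
        if self.n_blocks * self.block_size > self.n_genes:
            raise ValueError("n_blocks * block_size exceeds n_genes")
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted structure: DE genes with their shift sign, block membership."""

    de_genes: dict[str, int]           # gene id -> +1 (up in cases) or -1
    block_assignment: dict[str, int]   # gene id -> block index (0-based)

    def block_of(self, gene: str) -> int | None:
        return self.block_assignment.get(gene)


def gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(n)]


def sample_ids(n_case: int, n_control: int) -> tuple[list[str], pd.Series]:
    ids = [f"case{i:03d}" for i in range(n_case)] + [
        f"ctrl{i:03d}" for i in range(n_control)
    ]
    groups = pd.Series(
        ["case"] * n_case + ["control"] * n_control, index=ids, name="group"
    )
    return ids, groups


def simulate_expression(
    spec: SyntheticExpressionSpec,
) -> tuple[pd.DataFrame, pd.Series, SyntheticTruth]:
    """Draw a genes x samples matrix with planted DE genes and blocks.

    Returns ``(values, groups, truth)`` where ``values`` is a genes x samples
    DataFrame, ``groups`` maps sample id to ``case``/``control`` and ``truth``
    records the planted structure.  Identical spec (including seed) yields
    bit-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    m = spec.n_case + spec.n_control
    genes = gene_ids(spec.n_genes)
    samples, groups = sample_ids(spec.n_case, spec.n_control)

    values = rng.normal(0.0, spec.noise_sd, size=(spec.n_genes, m))

    # Correlated blocks: x = sqrt(rho) * f_block + sqrt(1 - rho) * eps,
    # one latent factor per block per sample; marginal sd stays noise_sd.
    block_assignment: dict[str, int] = {}
    for b in range(spec.n_blocks):
        factor = rng.normal(0.0, spec.noise_sd, size=m)
        lo, hi = b * spec.block_size, (b + 1) * spec.block_size
        values[lo:hi, :] = (
            np.sqrt(spec.rho) * factor[None, :]
            + np.sqrt(1.0 - spec.rho) * values[lo:hi, :]
        )
        for g in genes[lo:hi]:
            block_assignment[g] = b

    # DE shift on case samples, alternating up/down.
    de_genes: dict[str, int] = {}
    for i in range(spec.n_de):
        sign = 1 if i % 2 == 0 else -1
        values[i, : spec.n_case] += sign * spec.delta
        de_genes[genes[i]] = sign

    df = pd.DataFrame(values, index=genes, columns=samples)
    return df, groups, SyntheticTruth(de_genes, block_assignment)


def simulate_transactions(
    n_items: int,
    n_transactions: int,
    patterns: list[tuple[set[str] | frozenset[str], float]] = (),
    item_noise_prob: float = 0.0,
    seed: int = 0,
    item_prefix: str = "I",
) -> pd.DataFrame:
    """Boolean transactions x items matrix with planted co-occurring itemsets.

    Each pattern ``(itemset, embed_prob)`` is inserted independently into each
    transaction with probability ``embed_prob``; background items fire with
    ``item_noise_prob``.  Items are named ``I0 .. I{n_items-1}`` unless a
    different prefix is given; pattern items must belong to that universe.
    """
    if not 0.0 <= item_noise_prob <= 1.0:
        raise ValueError("item_noise_prob must lie in [0, 1]")
    items = [f"{item_prefix}{i}" for i in range(n_items)]
    universe = set(items)
    for itemset, p in patterns:
        missing = set(itemset) - universe
        if missing:
            raise ValueError(f"pattern items outside universe: {sorted(missing)}")
        if not 0.0 <= p <= 1.0:
            raise ValueError("embed_prob must lie in [0, 1]")

    rng = np.random.default_rng(seed)
    mat = rng.random((n_transactions, n_items)) < item_noise_prob
    col = {it: j for j, it in enumerate(items)}
    for itemset, p in patterns:
        hit = rng.random(n_transactions) < p
        for it in itemset:
            mat[hit, col[it]] = True
    return pd.DataFrame(
        mat, index=[f"t{k}" for k in range(n_transactions)], columns=items
    )


# --- plain-text writers -----------------------------------------------------

def write_expression_tsv(values: pd.DataFrame, path: str | Path) -> None:
    """First column is the gene id, header row holds the sample ids."""
    values.to_csv(path, sep="\t", index_label="gene")


def write_groups_tsv(groups: pd.Series, path: str | Path) -> None:
    groups.rename_axis("sample_id").to_frame().to_csv(path, sep="\t")


def write_truth_json(truth: SyntheticTruth, path: str | Path) -> None:
    payload = {
        "de_genes": truth.de_genes,
        "block_assignment": truth.block_assignment,
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))
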