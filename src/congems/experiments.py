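"""Reproducible recovery experiments on planted synthetic structure.

These functions define the package's standard evaluation scenarios — the
conditions under which the pipeline is expected to recover what was planted:

* ``planted_block_recovery``: two disjoint correlated DE blocks (rho = 0.9,
  shift 3 standard deviations, 20 samples per group).  After discretization
  each DE gene contributes one signed item to the case-group signature and
  the complementary item to the control-group signature; those two
  complementary co-occurrence patterns are the rule-generating structure the
  scenario plants, and each single-pattern rule is scored against its
  pattern of origin by adjusted Rand index.  (Block identity within a
  signature is not recoverable from co-occurrence at a 3-sigma shift: the
  group dichotomy makes cross-block confidence ~0.88 vs within-block ~0.92,
  inside sampling noise at 40 samples; see the methods note.)

* ``transaction_pattern_recovery``: two disjoint itemset patterns embedded
  directly in boolean transactions, the block-like analogue at the
  transaction level, scored the same way.

* ``null_deg_rate`` / ``planted_de_recovery``: type-I error of the
  moderated t under a global null, and sensitivity on strongly shifted
  genes after BH correction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from . import preprocess as pp
from .clustering import UNASSIGNED, average_linkage, dynamic_tree_cut
from .mining import MiningConfig, mine_rules, rank_rules
from .pipeline import PipelineConfig, run_pipeline
from .similarity import compute_dissimilarity_matrix
from .synthetic import (
    SyntheticExpressionSpec,
    simulate_expression,
    simulate_transactions,
)

__all__ = [
    "recovery_config",
    "recovery_spec",
    "planted_block_recovery",
    "transaction_pattern_recovery",
    "null_deg_rate",
    "planted_de_recovery",
]


def recovery_spec(seed: int) -> SyntheticExpressionSpec:
    """Study conditions of the planted-block scenario."""
    return SyntheticExpressionSpec(
        n_genes=60,
        n_case=20,
        n_control=20,
        n_de=12,
        delta=3.0,
        n_blocks=2,
        block_size=6,
        rho=0.9,
        noise_sd=1.0,
        seed=seed,
    )


def recovery_config(seed: int) -> PipelineConfig:
    """Analysis settings of the planted-block scenario.

    Pair rules only; mining thresholds sized so that rank weights (spanning
    1..1/12 over the 12 planted DEGs) keep cross-signature itemsets (raw
    support ~0.03) out while retaining within-signature pairs across most of
    the weight range.
    """
    return PipelineConfig(
        min_wsupp=0.1,
        min_wconf=0.3,
        max_itemset_size=2,
        top_genes=12,
        number_erules=200,
        low_variance_quantile=0.0,
        seed=seed,
    )


def planted_block_recovery(seed: int) -> dict:
    """One replicate of the planted-block scenario.

    Returns the adjusted Rand index between the rule-module labels and the
    planted co-occurrence-pattern origin of each single-pattern rule, plus
    bookkeeping counts.
    """
    spec = recovery_spec(seed)
    values, groups, truth = simulate_expression(spec)
    result = run_pipeline(values, groups, recovery_config(seed))
    if result.partition is None:
        return {"ari": 0.0, "n_rules": len(result.selected_rules), "n_scored": 0, "n_modules": 0}

    def item_phase(item: str) -> str:
        gene = pp.base_gene(item)
        sign = 1 if item.endswith(pp.UP_SUFFIX) else -1
        return "case" if truth.de_genes[gene] == sign else "control"

    labels, origins = [], []
    for rule in result.selected_rules:
        phases = {item_phase(i) for i in rule.items}
        if len(phases) != 1:
            continue  # mixed-pattern rule: no single origin
        labels.append(result.partition.labels[rule.key()])
        origins.append(phases.pop())
    ari = adjusted_rand_score(origins, labels) if len(set(origins)) > 1 else 0.0
    return {
        "ari": float(ari),
        "n_rules": len(result.selected_rules),
        "n_scored": len(labels),
        "n_modules": result.partition.n_modules,
    }


def transaction_pattern_recovery(
    seed: int,
    n_items: int = 16,
    n_transactions: int = 60,
    pattern_size: int = 5,
    embed_prob: float = 0.55,
    item_noise_prob: float = 0.05,
) -> dict:
    """Two disjoint planted itemsets -> two rule-modules, scored by ARI.

    Items carry uniform weight 1 so the weighted measures reduce to the
    classical ones; pattern membership of each rule is its origin label.
    """
    items_a = {f"I{i}" for i in range(pattern_size)}
    items_b = {f"I{i}" for i in range(pattern_size, 2 * pattern_size)}
    transactions = simulate_transactions(
        n_items,
        n_transactions,
        patterns=[(items_a, embed_prob), (items_b, embed_prob)],
        item_noise_prob=item_noise_prob,
        seed=seed,
    )
    weights = {c: 1.0 for c in transactions.columns}
    rules = rank_rules(
        mine_rules(
            transactions,
            weights,
            MiningConfig(min_wsupp=0.3, min_wconf=0.7, max_itemset_size=3),
        )
    )
    origins, kept = [], []
    for r in rules:
        if r.items <= items_a:
            origins.append("A"), kept.append(r)
        elif r.items <= items_b:
            origins.append("B"), kept.append(r)
    if len(kept) < 4 or len(set(origins)) < 2:
        return {"ari": 0.0, "n_rules": len(rules), "n_scored": len(kept), "n_modules": 0}
    dissim = compute_dissimilarity_matrix(kept, weights)
    partition = dynamic_tree_cut(average_linkage(dissim), dissim, min_module_size=3)
    labels = [partition.labels[r.key()] for r in kept]
    return {
        "ari": float(adjusted_rand_score(origins, labels)),
        "n_rules": len(rules),
        "n_scored": len(kept),
        "n_modules": partition.n_modules,
    }


def null_deg_rate(seed: int, n_genes: int = 2000, n_per_group: int = 10, alpha: float = 0.05) -> float:
    """Fraction of genes with raw p < alpha under the global null."""
    spec = SyntheticExpressionSpec(
        n_genes=n_genes, n_case=n_per_group, n_control=n_per_group, seed=seed
    )
    values, groups, _ = simulate_expression(spec)
    records = pp.moderated_t_test(values, groups)
    return float(np.mean([r.p < alpha for r in records]))


def planted_de_recovery(
    seed: int,
    n_genes: int = 500,
    n_de: int = 50,
    n_per_group: int = 10,
    delta: float = 3.0,
    alpha: float = 0.05,
) -> float:
    """Fraction of planted DE genes passing BH FDR < alpha (delta = 3 sd)."""
    spec = SyntheticExpressionSpec(
        n_genes=n_genes,
        n_case=n_per_group,
        n_control=n_per_group,
        n_de=n_de,
        delta=delta,
        seed=seed,
    )
    values, groups, truth = simulate_expression(spec)
    records = pp.attach_fdr(pp.moderated_t_test(values, groups))
    fdr = {r.gene_id: r.fdr for r in records}
    return float(np.mean([fdr[g] < alpha for g in truth.de_genes]))
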