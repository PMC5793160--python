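"""End-to-end rule-module discovery pipeline and its file I/O.

Wires the full chain: normalize -> moderated t + BH -> DEG selection ->
rank/weight (with a top-genes cap) -> discretize/post-discretize -> weighted
rule mining -> rank + dynamic selection + top-N -> integrated similarity ->
average linkage -> dynamic tree cut -> condensed markers -> validity report
against PAM reference labels.  All artifacts are plain TSV; the run is fully
deterministic for a given configuration and seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import preprocess as pp
from .clustering import average_linkage, dynamic_tree_cut, pam_reference_labels
from .markers import (
    markers_to_frame,
    most_frequent_genesets,
    prune_equivalent_genesets,
    rank_condensed_markers,
    side_geneset_frequencies,
)
from .mining import (
    MiningConfig,
    dynamic_select_rules,
    mine_rules,
    rank_rules,
    rules_to_frame,
    select_top_rules,
)
from .similarity import compute_dissimilarity_matrix
from .validity import reports_to_frame, validity_report

logger = logging.getLogger("congems")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "read_expression_tsv", "read_groups_tsv"]


@dataclass
class PipelineConfig:
    """All user-facing knobs of the rule-module pipeline."""

    pvalue_threshold: float = 0.05
    fc_up: float = 1.4
    fc_down: float = 0.7
    top_genes: int = 100
    low_variance_quantile: float = 0.30
    log2_input: bool = True
    min_wsupp: float = 0.5
    min_wconf: float = 0.7
    max_itemset_size: int = 4
    number_erules: int = 100
    dynamic_z_offset: float = 0.0
    use_dynamic_thresholds: bool = True
    e1: float = 0.5
    e2: float = 0.5
    min_module_size: int = 3
    deep_split: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.pvalue_threshold < 1:
            raise ValueError("pvalue_threshold must lie in (0, 1)")
        if not self.fc_down < 1 < self.fc_up:
            raise ValueError("need fc_down < 1 < fc_up")
        if self.e1 < 0 or self.e2 < 0 or self.e1 + self.e2 > 1 + 1e-12:
            raise ValueError("need e1, e2 >= 0 and e1 + e2 <= 1")
        if self.top_genes < 1:
            raise ValueError("top_genes must be >= 1")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Flat key = value config file (JSON also accepted)."""
        text = Path(path).read_text()
        try:
            raw = json.loads(text)
        except json.JSONDecodeError:
            raw = {}
            for line in text.splitlines():
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                key, _, value = line.partition("=")
                raw[key.strip()] = value.strip()
        fields = {f: t for f, t in cls.__annotations__.items()}
        kwargs = {}
        for key, value in raw.items():
            if key not in fields:
                raise KeyError(f"unknown config key {key!r}")
            target = cls.__dataclass_fields__[key].type
            if isinstance(value, str):
                if target == "bool":
                    value = value.lower() in ("1", "true", "yes")
                elif target == "int":
                    value = int(value)
                elif target == "float":
                    value = float(value)
            kwargs[key] = value
        kwargs.update(overrides)
        return cls(**kwargs)


@dataclass
class PipelineResult:
    config: PipelineConfig
    degs: pd.DataFrame
    weights: "pp.GeneWeightTable"
    transactions: pd.DataFrame
    rules: list
    selected_rules: list
    dissim: pd.DataFrame | None = None
    similarity: pd.DataFrame | None = None
    partition: object | None = None
    pam_labels: pd.Series | None = None
    markers: pd.DataFrame | None = None
    validity: pd.DataFrame | None = None
    dendrogram: object | None = None
    stage_counts: dict = field(default_factory=dict)


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        raise ValueError(f"missing values in expression matrix {path}")
    return df


def read_groups_tsv(path: str | Path) -> pd.Series:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"groups file not found: {path}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    groups = df.iloc[:, 0].astype(str)
    bad = set(groups) - {"case", "control"}
    if bad:
        raise ValueError(f"groups must be case/control, found {sorted(bad)}")
    return groups


def _write(df: pd.DataFrame, outdir: Path | None, name: str, **kwargs) -> None:
    if outdir is not None:
        df.to_csv(outdir / name, sep="\t", float_format="%.10g", **kwargs)


def run_pipeline(
    expr: pd.DataFrame,
    groups: pd.Series,
    config: PipelineConfig | None = None,
    outdir: str | Path | None = None,
    probe_to_gene: dict[str, str] | None = None,
) -> PipelineResult:
    """Run the full rule-module discovery chain on a two-group matrix.

    ``expr`` is genes x samples; every sample must appear in ``groups`` with
    label case or control.  When ``outdir`` is given the stage artifacts
    (degs.tsv, rules.tsv, dissim.tsv, modules.tsv, markers.tsv, validity.tsv
    and run_log.json) are written there.  An empty rule set stops the run
    gracefully after rules.tsv.
    """
    config = config or PipelineConfig()
    missing = [s for s in expr.columns if s not in groups.index]
    if missing:
        raise ValueError(f"samples without group label: {missing[:5]}")

    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {"genes_input": expr.shape[0], "samples": expr.shape[1]}

    # 1-2: variance filter, normalization, moderated t, BH.
    filtered = pp.filter_low_variance(expr, config.low_variance_quantile)
    counts["genes_after_variance_filter"] = filtered.shape[0]
    normalized = pp.zero_mean_normalize(filtered)
    records = pp.moderated_t_test(
        normalized, groups, fc_values=filtered, log2_input=config.log2_input
    )
    pp.attach_fdr(records)

    # 3-4: DEG selection, ranking, weighting, top-genes cap.
    degs = pp.select_degs(
        records,
        p_cut=config.pvalue_threshold,
        fc_up=config.fc_up,
        fc_down=config.fc_down,
        probe_to_gene=probe_to_gene,
    )
    counts["degs"] = len(degs)
    weight_table = pp.rank_and_weight(degs)
    if config.top_genes < weight_table.re_n:
        weight_table = pp.GeneWeightTable(
            weight_table.table.iloc[: config.top_genes].copy()
        )
    counts["genes_mined"] = weight_table.re_n
    _write(weight_table.table, outdir, "degs.tsv", index=False)

    # 5-7: transpose, discretize, post-discretize.
    di = pp.discretize(normalized.loc[weight_table.genes].T)
    transactions = pp.post_discretize(di)
    counts["transactions"] = transactions.shape[0]
    counts["items"] = transactions.shape[1]

    # 8: weighted rule mining, ranking, dynamic selection, top-N cap.
    item_weights = weight_table.item_weights()
    mining = MiningConfig(
        min_wsupp=config.min_wsupp,
        min_wconf=config.min_wconf,
        max_itemset_size=config.max_itemset_size,
        number_erules=config.number_erules,
    )
    rules = rank_rules(mine_rules(transactions, item_weights, mining))
    counts["rules_mined"] = len(rules)
    _write(rules_to_frame(rules), outdir, "rules.tsv", index=False)

    result = PipelineResult(
        config=config,
        degs=weight_table.table,
        weights=weight_table,
        transactions=transactions,
        rules=rules,
        selected_rules=[],
        stage_counts=counts,
    )
    if len(rules) < 2:
        logger.warning(
            "rule mining produced %d rule(s); stopping after rules.tsv", len(rules)
        )
        _finalize_log(outdir, config, counts)
        return result

    selected = rules
    if config.use_dynamic_thresholds:
        selected = dynamic_select_rules(selected, config.dynamic_z_offset)
    selected = select_top_rules(rank_rules(selected), config.number_erules)
    counts["rules_selected"] = len(selected)
    result.selected_rules = selected
    if len(selected) < 2:
        logger.warning("fewer than 2 rules after selection; stopping")
        _finalize_log(outdir, config, counts)
        return result

    # 9-10: integrated similarity and dissimilarity.
    dissim, similarity = compute_dissimilarity_matrix(
        selected, item_weights, config.e1, config.e2, return_similarity=True
    )
    result.dissim, result.similarity = dissim, similarity
    _write(dissim, outdir, "dissim.tsv", index_label="rule")

    # 11-12: average linkage and dynamic tree cut.
    dendro = average_linkage(dissim)
    partition = dynamic_tree_cut(
        dendro,
        dissim,
        min_module_size=config.min_module_size,
        deep_split=config.deep_split,
    )
    result.dendrogram = dendro
    result.partition = partition
    counts["modules"] = partition.n_modules
    _write(partition.to_frame("rule_id"), outdir, "modules.tsv", index=False)

    # 13-14: geneset frequencies, winners, pruning, marker ranking.
    freqs = side_geneset_frequencies(partition, selected)
    winners = most_frequent_genesets(freqs)
    pruned = prune_equivalent_genesets(winners)
    markers = rank_condensed_markers(pruned)
    counts["condensed_markers"] = len(markers)
    marker_frame = markers_to_frame(markers)
    result.markers = marker_frame
    _write(marker_frame, outdir, "markers.tsv", index=False)

    # 16: validity indices against PAM reference labels.
    if partition.n_modules >= 1:
        k = max(partition.n_modules, 1)
        pam = pam_reference_labels(dissim, k=k, seed=config.seed)
        result.pam_labels = pam
        report = validity_report(
            dissim, similarity, partition.labels, pam, method="proposed"
        )
        validity = reports_to_frame([report])
        result.validity = validity
        _write(validity, outdir, "validity.tsv", index_label="index")

    _finalize_log(outdir, config, counts)
    return result


def _finalize_log(outdir: Path | None, config: PipelineConfig, counts: dict) -> None:
    for stage, value in counts.items():
        logger.info("%s: %s", stage, value)
    if outdir is not None:
        payload = {"config": asdict(config), "stage_counts": counts}
        (outdir / "run_log.json").write_text(json.dumps(payload, indent=2))
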