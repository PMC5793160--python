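"""Differential-expression preprocessing for rule mining.

The chain implemented here turns a two-group expression (or methylation)
matrix into the boolean transaction matrix mined downstream:

1. gene-wise zero-mean normalization,
2. empirical-Bayes moderated two-group t test with BH FDR correction,
3. DEG selection by FDR and fold-change gates (with probe collapse),
4. rank-based gene weights w_i = (rank_max - (rank_i - 1)) / rank_max,
5. discretization of the transposed normalized matrix at 0 (DI),
6. post-discretization doubling the columns into signed items g+ / g- (PDI).

The per-sample PDI rows are the transactions; the signed-item columns are the
items, each inheriting its base gene's weight.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DEStatRecord",
    "GeneWeightTable",
    "zero_mean_normalize",
    "filter_low_variance",
    "moderated_t_test",
    "bh_fdr",
    "select_degs",
    "rank_and_weight",
    "discretize",
    "post_discretize",
    "UP_SUFFIX",
    "DOWN_SUFFIX",
    "signed_item",
    "base_gene",
]

UP_SUFFIX = "+"
DOWN_SUFFIX = "-"


def signed_item(gene: str, up: bool) -> str:
    return gene + (UP_SUFFIX if up else DOWN_SUFFIX)


def base_gene(item: str) -> str:
    """Strip the +/- direction suffix from a signed item."""
    if not item or item[-1] not in (UP_SUFFIX, DOWN_SUFFIX):
        raise ValueError(f"{item!r} is not a signed item")
    return item[:-1]


@dataclass
class DEStatRecord:
    """Per-gene differential-expression statistics."""

    gene_id: str
    t_moderated: float
    p: float
    fdr: float = math.nan
    fold_change: float = math.nan
    direction: str = ""


@dataclass
class GeneWeightTable:
    """Retained DEGs ordered by rank with their rank-based weights.

    ``table`` has columns gene, rank, weight with ranks 1..re_n; the top gene
    gets weight 1 and the last gene weight 1/rank_max, equally spaced.
    """

    table: pd.DataFrame

    @property
    def re_n(self) -> int:
        return len(self.table)

    @property
    def rank_max(self) -> int:
        return int(self.table["rank"].max())

    @property
    def genes(self) -> list[str]:
        return self.table["gene"].tolist()

    def gene_weights(self) -> dict[str, float]:
        return dict(zip(self.table["gene"], self.table["weight"]))

    def item_weights(self) -> dict[str, float]:
        """Weights for the signed items; g+ and g- inherit gene g's weight."""
        out: dict[str, float] = {}
        for gene, w in self.gene_weights().items():
            out[signed_item(gene, True)] = w
            out[signed_item(gene, False)] = w
        return out


def filter_low_variance(values: pd.DataFrame, quantile: float = 0.30) -> pd.DataFrame:
    """Drop the genes in the lowest variance quantile (default 30%)."""
    if not 0.0 <= quantile < 1.0:
        raise ValueError("quantile must lie in [0, 1)")
    if quantile == 0.0:
        return values
    var = values.var(axis=1, ddof=1)
    cut = var.quantile(quantile)
    out = values.loc[var > cut]
    if out.empty:
        raise ValueError("variance filter removed every gene")
    return out


def zero_mean_normalize(values: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    """Scale each gene row to mean 0 and unit (sample, m-1) standard deviation.

    Raises on constant genes; callers drop low-variance genes first.
    """
    mu = values.mean(axis=1)
    sd = values.std(axis=1, ddof=ddof)
    zero = sd[sd == 0]
    if len(zero):
        raise ValueError(
            f"zero-variance gene(s) cannot be normalized: {list(zero.index[:5])}"
        )
    return values.sub(mu, axis=0).div(sd, axis=0)


def _trigamma_inverse(x: float, tol: float = 1e-10, max_iter: int = 80) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        return math.inf
    y = 0.5 + 1.0 / x
    for _ in range(max_iter):
        tri = special.polygamma(1, y)
        step = (tri - x) / special.polygamma(2, y)
        y_new = y - step
        if y_new <= 0:
            y_new = y / 2.0
        if abs(y_new - y) < tol * y:
            return float(y_new)
        y = y_new
    return float(y)


def _fit_f_dist(s2: np.ndarray, df_resid: int) -> tuple[float, float]:
    """Method-of-moments fit of the scaled-F prior (s0^2, d0) on residual
    variances, via the moments of log s^2 (digamma/trigamma identities)."""
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    z = np.log(s2[ok])
    half = df_resid / 2.0
    e = z - special.digamma(half) + math.log(half)
    e_mean = float(np.mean(e))
    n = len(e)
    if n < 2:
        return float(np.exp(e_mean)), math.inf
    e_var = float(np.mean((e - e_mean) ** 2) * n / (n - 1)) - float(
        special.polygamma(1, half)
    )
    if e_var <= 0:
        # Variances tighter than chi^2 sampling noise: shrink fully.
        return float(np.exp(e_mean)), math.inf
    d0 = 2.0 * _trigamma_inverse(e_var)
    s0_2 = float(np.exp(e_mean + special.digamma(d0 / 2.0) - math.log(d0 / 2.0)))
    return s0_2, d0


def _fold_changes(
    values: pd.DataFrame, case: list[str], control: list[str], log2_input: bool
) -> pd.Series:
    mean_case = values[case].mean(axis=1)
    mean_control = values[control].mean(axis=1)
    if log2_input:
        return np.exp2(mean_case - mean_control)
    return mean_case / mean_control


def moderated_t_test(
    values: pd.DataFrame,
    groups: pd.Series,
    fc_values: pd.DataFrame | None = None,
    log2_input: bool = True,
    shrink: bool = True,
) -> list[DEStatRecord]:
    """Empirical-Bayes moderated two-group t test, gene by gene.

    The pooled residual variance of each gene is shrunk toward a prior
    variance s0^2 with prior degrees of freedom d0, both estimated by method
    of moments from the observed variance distribution (Smyth-style).  With
    ``shrink=False`` (d0 forced to 0) the statistic reduces to the ordinary
    pooled two-sample t.  Fold changes are computed on ``fc_values`` (default:
    the test matrix itself), as 2^(mean difference) when ``log2_input`` else
    as the ratio of group means.
    """
    case = [s for s in values.columns if groups[s] == "case"]
    control = [s for s in values.columns if groups[s] == "control"]
    n1, n2 = len(case), len(control)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 samples")

    x1 = values[case].to_numpy(dtype=float)
    x2 = values[control].to_numpy(dtype=float)
    mean_diff = x1.mean(axis=1) - x2.mean(axis=1)
    df_resid = n1 + n2 - 2
    ss = ((x1 - x1.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (x2 - x2.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    s2 = ss / df_resid

    if shrink:
        s0_2, d0 = _fit_f_dist(s2, df_resid)
    else:
        s0_2, d0 = 0.0, 0.0
    if math.isinf(d0):
        s2_tilde = np.full_like(s2, s0_2)
        df_total = math.inf
    else:
        s2_tilde = (d0 * s0_2 + df_resid * s2) / (d0 + df_resid)
        df_total = d0 + df_resid

    se = np.sqrt(s2_tilde * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, mean_diff / se, 0.0)
    t = np.where((se == 0) & (mean_diff == 0), 0.0, t)
    if math.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df=df_total)

    fc_src = values if fc_values is None else fc_values
    fc = _fold_changes(fc_src, case, control, log2_input)

    records = []
    for i, gene in enumerate(values.index):
        f = float(fc.loc[gene])
        records.append(
            DEStatRecord(
                gene_id=str(gene),
                t_moderated=float(t[i]),
                p=float(min(p[i], 1.0)),
                fold_change=f,
                direction="up" if f >= 1.0 else "down",
            )
        )
    return records


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up corrected p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def attach_fdr(records: list[DEStatRecord]) -> list[DEStatRecord]:
    q = bh_fdr([r.p for r in records])
    for r, qi in zip(records, q):
        r.fdr = float(qi)
    return records


def collapse_probes(
    records: list[DEStatRecord], probe_to_gene: dict[str, str]
) -> list[DEStatRecord]:
    """Keep, for each gene, only the probe with the lowest raw p-value.

    Applied before any filtering; the surviving record is renamed to the gene.
    """
    best: dict[str, DEStatRecord] = {}
    for r in records:
        gene = probe_to_gene.get(r.gene_id, r.gene_id)
        cur = best.get(gene)
        if cur is None or r.p < cur.p:
            best[gene] = r
    out = []
    for gene, r in best.items():
        r.gene_id = gene
        out.append(r)
    return out


def select_degs(
    records: list[DEStatRecord],
    p_cut: float = 0.05,
    fc_up: float = 1.4,
    fc_down: float = 0.7,
    probe_to_gene: dict[str, str] | None = None,
) -> list[DEStatRecord]:
    """DEGs: FDR < p_cut and fold change outside the (fc_down, fc_up) gate."""
    if not 0.0 < p_cut < 1.0:
        raise ValueError("p_cut must lie in (0, 1)")
    if not fc_down < 1.0 < fc_up:
        raise ValueError("need fc_down < 1 < fc_up")
    if probe_to_gene is not None:
        records = collapse_probes(records, probe_to_gene)
    kept = [
        r
        for r in records
        if r.fdr < p_cut and (r.fold_change >= fc_up or r.fold_change <= fc_down)
    ]
    if not kept:
        raise ValueError("no DEGs at given thresholds")
    return kept


def rank_and_weight(degs: list[DEStatRecord]) -> GeneWeightTable:
    """Rank DEGs by ascending FDR (ties: raw p, then input order) and assign
    w_i = (rank_max - (rank_i - 1)) / rank_max."""
    if not degs:
        raise ValueError("empty DEG list")
    order = sorted(range(len(degs)), key=lambda i: (degs[i].fdr, degs[i].p, i))
    rank_max = len(degs)
    rows = []
    for rank, i in enumerate(order, start=1):
        w = (rank_max - (rank - 1)) / rank_max
        rows.append(
            {
                "gene": degs[i].gene_id,
                "p": degs[i].p,
                "fdr": degs[i].fdr,
                "fold_change": degs[i].fold_change,
                "direction": degs[i].direction,
                "rank": rank,
                "weight": w,
            }
        )
    return GeneWeightTable(pd.DataFrame(rows))


def discretize(transposed_normalized: pd.DataFrame) -> pd.DataFrame:
    """DI(i,k) = 1 iff the normalized value is >= 0 (samples x genes input).

    Zero is mapped to 1 so every entry is defined.
    """
    arr = transposed_normalized.to_numpy(dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite value in matrix to discretize")
    return pd.DataFrame(
        arr >= 0.0,
        index=transposed_normalized.index,
        columns=transposed_normalized.columns,
    )


def post_discretize(di: pd.DataFrame) -> pd.DataFrame:
    """Double the columns into signed items: PDI = [DI | 1 - DI].

    Column k keeps gene_k's up state (gene+), column re_n + k its complement
    (gene-); each gene is exactly one of above/below its mean per sample.
    """
    up = di.copy()
    up.columns = [signed_item(str(g), True) for g in di.columns]
    down = ~di
    down.columns = [signed_item(str(g), False) for g in di.columns]
    return pd.concat([up, down], axis=1)
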