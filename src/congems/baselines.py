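"""Topological-overlap gene-module baselines.

The comparator detectors build a correlation network over genes (Pearson or
Spearman, soft-thresholded to a weighted adjacency), score node similarity
with TOM / weighted TOM / generalized TOM of degree m, and hand
1 - similarity to the same average-linkage + dynamic tree cut pipeline the
rule-modules use.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .clustering import ModulePartition, average_linkage, dynamic_tree_cut

__all__ = [
    "soft_threshold_adjacency",
    "pick_soft_threshold",
    "tom_matrix",
    "gtom_matrix",
    "baseline_gene_modules",
]


def _correlation(expr: pd.DataFrame, method: str) -> np.ndarray:
    values = expr.to_numpy(dtype=float)
    sd = values.std(axis=1)
    if np.any(sd == 0):
        bad = [str(g) for g, s in zip(expr.index, sd) if s == 0][:5]
        raise ValueError(f"constant gene(s) have undefined correlation: {bad}")
    if method == "pearson":
        return np.corrcoef(values)
    if method == "spearman":
        ranks = stats.rankdata(values, axis=1)
        return np.corrcoef(ranks)
    raise ValueError("method must be 'pearson' or 'spearman'")


def soft_threshold_adjacency(
    expr: pd.DataFrame, method: str = "pearson", beta: float = 6.0
) -> pd.DataFrame:
    """A_ij = |cor(i, j)|^beta with zero diagonal."""
    if beta < 1:
        raise ValueError("beta must be >= 1")
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    a = np.abs(_correlation(expr, method)) ** beta
    np.fill_diagonal(a, 0.0)
    return pd.DataFrame(a, index=expr.index, columns=expr.index)


def pick_soft_threshold(
    expr: pd.DataFrame,
    method: str = "pearson",
    betas: range = range(1, 21),
    r2_target: float = 0.8,
    n_bins: int = 10,
) -> int:
    """Smallest power whose degree distribution fits a scale-free law.

    For each candidate beta the connectivity k_i is binned and log10 p(k) is
    regressed on log10 k; the first beta reaching the target R^2 wins, else
    the best-fitting beta overall.
    """
    best_beta, best_r2 = None, -np.inf
    for beta in betas:
        a = soft_threshold_adjacency(expr, method, float(beta)).to_numpy()
        k = a.sum(axis=1)
        k = k[k > 0]
        if len(k) < n_bins:
            continue
        edges = np.quantile(k, np.linspace(0, 1, n_bins + 1))
        edges = np.unique(edges)
        if len(edges) < 3:
            continue
        which = np.clip(np.digitize(k, edges[1:-1]), 0, len(edges) - 2)
        centers, probs = [], []
        for b in range(len(edges) - 1):
            mask = which == b
            if mask.sum() == 0:
                continue
            centers.append(k[mask].mean())
            probs.append(mask.mean())
        if len(centers) < 3:
            continue
        x = np.log10(np.asarray(centers))
        y = np.log10(np.asarray(probs))
        slope, intercept, r, _, _ = stats.linregress(x, y)
        r2 = r * r
        if r2 >= r2_target:
            return int(beta)
        if r2 > best_r2:
            best_beta, best_r2 = int(beta), r2
    if best_beta is None:
        raise ValueError("no candidate beta produced a fit")
    return best_beta


def tom_matrix(adjacency: pd.DataFrame | np.ndarray) -> pd.DataFrame:
    """Topological overlap: shared-neighbor weight relative to the smaller
    connectivity, valid for binary and weighted adjacencies; unit diagonal."""
    a = np.asarray(adjacency, dtype=float)
    if not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    a = (a + a.T) / 2.0
    np.fill_diagonal(a, 0.0)
    l = a @ a
    k = a.sum(axis=1)
    num = l + a
    den = np.minimum.outer(k, k) - a + 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(den > 0, num / den, 0.0)
    np.fill_diagonal(t, 1.0)
    if isinstance(adjacency, pd.DataFrame):
        return pd.DataFrame(t, index=adjacency.index, columns=adjacency.columns)
    return pd.DataFrame(t)


def gtom_matrix(
    adjacency: pd.DataFrame | np.ndarray, m: int = 1, tau: float = 0.5
) -> pd.DataFrame:
    """Generalized topological overlap of degree m on a binary graph.

    Weighted inputs are binarized at ``tau`` first.  Degree 0 returns the
    adjacency itself (unit diagonal); degree m >= 1 compares the m-step
    neighborhoods N_m(i) = {u != i : dist(u, i) <= m}:

        (|N_m(i) & N_m(j)| + X_ij) / (min(|N_m(i)|, |N_m(j)|) + 1 - X_ij).

    Degree 1 coincides with TOM on binary graphs.
    """
    if m < 0:
        raise ValueError("degree m must be >= 0")
    x = np.asarray(adjacency, dtype=float)
    if not np.allclose(x, x.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    binary = (x >= tau) if not np.array_equal(x, x.astype(bool)) else x.astype(bool)
    binary = np.asarray(binary, dtype=bool)
    np.fill_diagonal(binary, False)

    index = (
        adjacency.index
        if isinstance(adjacency, pd.DataFrame)
        else pd.RangeIndex(x.shape[0])
    )
    xb = binary.astype(float)
    if m == 0:
        out = xb.copy()
        np.fill_diagonal(out, 1.0)
        return pd.DataFrame(out, index=index, columns=index)

    reach = binary.copy()
    for _ in range(m - 1):
        reach = reach | ((reach.astype(int) @ binary.astype(int)) > 0)
        np.fill_diagonal(reach, False)
    nbr = reach.astype(float)
    shared = nbr @ nbr.T
    sizes = nbr.sum(axis=1)
    num = shared + xb
    den = np.minimum.outer(sizes, sizes) + 1.0 - xb
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(den > 0, num / den, 0.0)
    np.fill_diagonal(t, 1.0)
    return pd.DataFrame(t, index=index, columns=index)


def baseline_similarity(
    expr: pd.DataFrame,
    measure: str = "wTOM",
    method: str = "pearson",
    beta: float = 6.0,
    tau: float = 0.5,
) -> pd.DataFrame:
    """Similarity matrix for one baseline: wTOM or GTOM0..GTOM3."""
    adjacency = soft_threshold_adjacency(expr, method, beta)
    if measure == "wTOM":
        return tom_matrix(adjacency)
    if measure.startswith("GTOM"):
        degree = int(measure[4:])
        return gtom_matrix(adjacency, m=degree, tau=tau)
    raise ValueError(f"unknown measure {measure!r}")


def baseline_gene_modules(
    expr: pd.DataFrame,
    measure: str = "wTOM",
    method: str = "pearson",
    beta: float = 6.0,
    tau: float = 0.5,
    min_module_size: int = 3,
    deep_split: int = 2,
) -> tuple[ModulePartition, pd.DataFrame]:
    """Color-labeled gene modules from one TOM-family similarity measure.

    Returns the partition together with the similarity matrix it was derived
    from (the input to the network-concept validity indices).
    """
    sim = baseline_similarity(expr, measure, method, beta, tau)
    dissim = 1.0 - sim
    np.fill_diagonal(dissim.values, 0.0)
    dendro = average_linkage(dissim)
    partition = dynamic_tree_cut(
        dendro, dissim, min_module_size=min_module_size, deep_split=deep_split
    )
    return partition, sim
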