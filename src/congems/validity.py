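"""Cluster-validity indices and win-draw-loss method comparison.

Nine indices are computed per partition: Dunn index and average silhouette
width on the dissimilarity; average scaled connectivity, average clustering
coefficient, average maximum adjacency ratio, density and centralization on
the similarity (fundamental network concepts, averaged per module and then
across non-grey modules); Rand and adjusted Rand against a reference
labeling.  Indices that are undefined for a partition are reported as
invalid (the "-" convention) and an infinite Dunn index (all-singleton
diameters) is kept as Inf.  In pairwise comparison a finite value beats both
Inf and invalid; only average scaled connectivity is lower-better.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import (
    adjusted_rand_score,
    rand_score,
    silhouette_samples,
)

from .clustering import UNASSIGNED

__all__ = [
    "INDEX_ORDER",
    "LOWER_BETTER",
    "ValidityReport",
    "dunn_index",
    "avg_silhouette_width",
    "network_concepts",
    "rand_scores",
    "validity_report",
    "win_draw_loss",
]

INDEX_ORDER = (
    "avgDI",
    "avgSW",
    "avgSC",
    "avgCC",
    "avgMAR",
    "density",
    "centralization",
    "rand",
    "adjusted_rand",
)
LOWER_BETTER = frozenset({"avgSC"})

INVALID = None  # the tables' "-" marker


@dataclass
class ValidityReport:
    """index name -> value; None marks an undefined ("-") entry."""

    values: dict[str, float | None] = field(default_factory=dict)
    method: str = ""

    def __post_init__(self) -> None:
        for key in self.values:
            if key not in INDEX_ORDER:
                raise KeyError(f"unknown validity index {key!r}")

    def get(self, index: str) -> float | None:
        return self.values.get(index, INVALID)

    def as_series(self) -> pd.Series:
        def fmt(v):
            if v is None:
                return "NA"
            if math.isinf(v):
                return "Inf"
            return v

        return pd.Series(
            {k: fmt(self.get(k)) for k in INDEX_ORDER}, name=self.method
        )


def _split_clusters(labels: pd.Series | np.ndarray) -> dict[str, np.ndarray]:
    lab = np.asarray(labels, dtype=object)
    out: dict[str, np.ndarray] = {}
    for value in pd.unique(lab):
        if value == UNASSIGNED:
            continue
        out[str(value)] = np.flatnonzero(lab == value)
    return out


def dunn_index(
    dissim: pd.DataFrame | np.ndarray, labels: pd.Series | np.ndarray
) -> float | None:
    """min inter-cluster distance / max intra-cluster diameter.

    All-singleton clusters give diameter 0 and hence Inf; fewer than two
    clusters make the index undefined.
    """
    arr = np.asarray(dissim, dtype=float)
    clusters = _split_clusters(labels)
    if len(clusters) < 2:
        return INVALID
    names = list(clusters)
    max_diam = 0.0
    for idx in clusters.values():
        if len(idx) > 1:
            sub = arr[np.ix_(idx, idx)]
            max_diam = max(max_diam, float(sub.max()))
    min_inter = math.inf
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            min_inter = min(
                min_inter, float(arr[np.ix_(clusters[a], clusters[b])].min())
            )
    if max_diam == 0.0:
        return math.inf
    return min_inter / max_diam


def avg_silhouette_width(
    dissim: pd.DataFrame | np.ndarray, labels: pd.Series | np.ndarray
) -> float | None:
    """Mean silhouette width over clustered (non-grey) objects."""
    arr = np.asarray(dissim, dtype=float)
    lab = np.asarray(labels, dtype=object)
    mask = lab != UNASSIGNED
    lab = lab[mask]
    if len(set(lab)) < 2:
        return INVALID
    sub = arr[np.ix_(np.flatnonzero(mask), np.flatnonzero(mask))]
    codes = pd.factorize(lab)[0]
    widths = silhouette_samples(sub, codes, metric="precomputed")
    return float(widths.mean())


def _module_concepts(a: np.ndarray) -> dict[str, float | None]:
    """Fundamental network concepts for one module's similarity submatrix."""
    n = a.shape[0]
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    out: dict[str, float | None] = {}

    out["density"] = float(a.sum() / (n * (n - 1))) if n >= 2 else INVALID

    kmax = k.max() if n else 0.0
    out["avgSC"] = float((k / kmax).mean()) if kmax > 0 else INVALID

    sum_sq = (a**2).sum(axis=1)
    if np.all(k > 0):
        out["avgMAR"] = float((sum_sq / k).mean())
    else:
        out["avgMAR"] = INVALID

    if n >= 3:
        tri = np.einsum("ij,jq,qi->i", a, a, a)
        den = k**2 - sum_sq
        if np.all(den > 0):
            out["avgCC"] = float((tri / den).mean())
        else:
            out["avgCC"] = INVALID
        dens = out["density"]
        if dens is None:
            out["centralization"] = INVALID
        else:
            out["centralization"] = float(n / (n - 2) * (kmax / (n - 1) - dens))
    else:
        out["avgCC"] = INVALID
        out["centralization"] = INVALID
    return out


def network_concepts(
    similarity: pd.DataFrame | np.ndarray, labels: pd.Series | np.ndarray
) -> dict[str, float | None]:
    """Per-module network concepts, averaged unweighted across modules.

    Modules where an index is undefined are skipped for that index; the
    index is invalid when no module defines it.
    """
    arr = np.asarray(similarity, dtype=float)
    clusters = _split_clusters(labels)
    per_index: dict[str, list[float]] = {
        key: [] for key in ("avgSC", "avgCC", "avgMAR", "density", "centralization")
    }
    for idx in clusters.values():
        sub = arr[np.ix_(idx, idx)]
        concepts = _module_concepts(sub)
        for key, vals in per_index.items():
            if concepts[key] is not None:
                vals.append(concepts[key])
    return {
        key: (float(np.mean(vals)) if vals else INVALID)
        for key, vals in per_index.items()
    }


def rand_scores(
    labels_a: pd.Series | np.ndarray, labels_b: pd.Series | np.ndarray
) -> dict[str, float]:
    """Rand index (pair-agreement fraction) and adjusted Rand index."""
    a = pd.factorize(np.asarray(labels_a, dtype=object))[0]
    b = pd.factorize(np.asarray(labels_b, dtype=object))[0]
    if len(a) != len(b):
        raise ValueError("label vectors differ in length")
    if len(a) < 2:
        raise ValueError("need at least 2 objects")
    return {
        "rand": float(rand_score(a, b)),
        "adjusted_rand": float(adjusted_rand_score(a, b)),
    }


def validity_report(
    dissim: pd.DataFrame | np.ndarray,
    similarity: pd.DataFrame | np.ndarray,
    labels: pd.Series | np.ndarray,
    reference_labels: pd.Series | np.ndarray | None = None,
    method: str = "",
) -> ValidityReport:
    """All nine indices for one partition.

    ``similarity`` is the matrix the method clusters (integrated rule
    similarity for rule partitions, TOM-family similarity for gene
    partitions); ``reference_labels`` (typically PAM at k = module count)
    feed the two external indices.
    """
    values: dict[str, float | None] = {}
    values["avgDI"] = dunn_index(dissim, labels)
    values["avgSW"] = avg_silhouette_width(dissim, labels)
    values.update(network_concepts(similarity, labels))
    if reference_labels is not None and len(set(np.asarray(labels, dtype=object))) > 1:
        values.update(rand_scores(labels, reference_labels))
    else:
        values["rand"] = INVALID
        values["adjusted_rand"] = INVALID
    return ValidityReport(values=values, method=method)


def _is_invalid(v: float | None) -> bool:
    return v is None or (isinstance(v, float) and math.isinf(v))


def win_draw_loss(
    report_a: ValidityReport, report_b: ValidityReport
) -> tuple[int, int, int]:
    """Per-index comparison of two methods' validity reports.

    Both entries invalid (or Inf) draw; a finite value beats an invalid/Inf
    one; otherwise the index orientation decides, with equal values drawing.
    Returns (wins, draws, losses) for ``report_a``.
    """
    wins = draws = losses = 0
    for index in INDEX_ORDER:
        va, vb = report_a.get(index), report_b.get(index)
        bad_a, bad_b = _is_invalid(va), _is_invalid(vb)
        if bad_a and bad_b:
            draws += 1
        elif bad_b:
            wins += 1
        elif bad_a:
            losses += 1
        elif va == vb:
            draws += 1
        else:
            better_a = (va < vb) if index in LOWER_BETTER else (va > vb)
            wins += 1 if better_a else 0
            losses += 0 if better_a else 1
    return wins, draws, losses


def reports_to_frame(reports: list[ValidityReport]) -> pd.DataFrame:
    """validity.tsv layout: one row per index, one column per method."""
    return pd.DataFrame({r.method: r.as_series() for r in reports})
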