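"""Independent brute-force reference implementations used only by tests."""

from itertools import combinations

import numpy as np


def brute_force_weighted_rules(
    matrix, columns, weights, min_wsupp, min_wconf, max_size
):
    """Enumerate every itemset and bipartition directly from the boolean
    matrix; returns {(antecedent, consequent): (sup, wsupp, conf, wconf)}."""
    mat = np.asarray(matrix, dtype=bool)
    n = mat.shape[0]

    def sup(items):
        cover = np.ones(n, dtype=bool)
        for it in items:
            cover &= mat[:, columns.index(it)]
        return cover.sum() / n

    out = {}
    for size in range(2, max_size + 1):
        for itemset in combinations(columns, size):
            s = sup(itemset)
            mean_w = sum(weights[i] for i in itemset) / size
            wsupp = s * mean_w
            if wsupp < min_wsupp:
                continue
            for r in range(1, size):
                for ante in combinations(itemset, r):
                    cons = tuple(i for i in itemset if i not in ante)
                    sa = sup(ante)
                    if sa == 0:
                        continue
                    conf = s / sa
                    wconf = conf * mean_w
                    if wconf >= min_wconf:
                        out[(frozenset(ante), frozenset(cons))] = (
                            s,
                            wsupp,
                            conf,
                            wconf,
                        )
    return out


def brute_force_tom(a):
    """Triple-loop topological overlap."""
    a = np.asarray(a, dtype=float).copy()
    np.fill_diagonal(a, 0.0)
    n = a.shape[0]
    t = np.eye(n)
    k = a.sum(axis=1)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            num = sum(a[i, u] * a[j, u] for u in range(n) if u not in (i, j))
            num += a[i, j]
            den = min(k[i], k[j]) - a[i, j] + 1.0
            t[i, j] = num / den if den > 0 else 0.0
    return t


def brute_force_cosine(u, v):
    """Explicit elementwise evaluation of the rule-vector cosine."""
    dot = sum(ui * vi for ui, vi in zip(u, v))
    nu = sum(ui * ui for ui in u) ** 0.5
    nv = sum(vi * vi for vi in v) ** 0.5
    if nu == 0 or nv == 0:
        return 0.0
    return dot / (nu * nv)


def exhaustive_pam_cost(dissim, k):
    """Optimal medoid cost by trying every k-subset."""
    arr = np.asarray(dissim, dtype=float)
    n = arr.shape[0]
    best = np.inf
    for medoids in combinations(range(n), k):
        cost = arr[:, list(medoids)].min(axis=1).sum()
        best = min(best, cost)
    return best


def pam_cost(dissim, labels):
    """Cost of a PAM labeling: for each cluster use its best medoid."""
    arr = np.asarray(dissim, dtype=float)
    labels = np.asarray(labels)
    total = 0.0
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        sub = arr[np.ix_(idx, idx)]
        total += sub.sum(axis=0).min()
    return total
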