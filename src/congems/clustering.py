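"""Average-linkage clustering, dynamic tree cut and PAM reference labels.

The dissimilarity matrix between rules (or genes, for the network baselines)
is clustered with UPGMA, the dendrogram is cut with a dynamic hybrid branch
detector into color-labeled modules, and partitioning-around-medoids labels
with k equal to the module count serve as an external reference partition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

__all__ = [
    "Dendrogram",
    "ModulePartition",
    "MODULE_COLORS",
    "average_linkage",
    "dynamic_tree_cut",
    "pam_reference_labels",
]

# WGCNA-style fixed palette, assigned to modules by decreasing size.
MODULE_COLORS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
    "paleturquoise", "violet", "darkolivegreen", "darkmagenta",
]
UNASSIGNED = "grey"


@dataclass(frozen=True)
class Dendrogram:
    """UPGMA merge history.

    ``merges`` has one row per merge: (left id, right id, height, new size)
    with leaves numbered 0..n-1 and internal nodes n, n+1, ... in merge
    order, matching the scipy linkage-matrix layout.
    """

    merges: np.ndarray
    leaf_ids: tuple[str, ...]

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    def leaves_under(self, node: int) -> list[int]:
        n = self.n_leaves
        stack, out = [node], []
        while stack:
            v = stack.pop()
            if v < n:
                out.append(v)
            else:
                row = self.merges[v - n]
                stack.extend((int(row[0]), int(row[1])))
        return out

    def to_newick(self) -> str:
        """Newick string with branch lengths from the merge heights."""
        n = self.n_leaves
        heights = {i: 0.0 for i in range(n)}
        for k, (a, b, h, _) in enumerate(self.merges):
            heights[n + k] = float(h)

        def render(node: int) -> str:
            if node < n:
                return self.leaf_ids[node]
            a, b, h, _ = self.merges[node - n]
            parts = []
            for child in (int(a), int(b)):
                bl = float(h) - heights[child]
                parts.append(f"{render(child)}:{bl:.6g}")
            return "(" + ",".join(parts) + ")"

        return render(2 * n - 2) + ";"


def _check_square(dissim: pd.DataFrame | np.ndarray) -> np.ndarray:
    arr = np.asarray(dissim, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError("dissimilarity must be square")
    if not np.all(np.isfinite(arr)):
        raise ValueError("dissimilarity contains non-finite values")
    if not np.allclose(arr, arr.T, atol=1e-10):
        raise ValueError("dissimilarity must be symmetric")
    return (arr + arr.T) / 2.0


def average_linkage(dissim: pd.DataFrame | np.ndarray) -> Dendrogram:
    """UPGMA: inter-cluster distance is the unweighted mean over cross pairs.

    Ties are broken deterministically by the smallest (creation-order) index
    pair.  Naive O(n^3); rule sets at desk scale stay in the hundreds.
    """
    arr = _check_square(dissim)
    n = arr.shape[0]
    if n < 2:
        raise ValueError("need at least 2 objects")
    if isinstance(dissim, pd.DataFrame):
        labels = tuple(str(c) for c in dissim.columns)
    else:
        labels = tuple(str(i) for i in range(n))

    # active clusters: node id -> (creation order, member leaf indices)
    active: dict[int, list[int]] = {i: [i] for i in range(n)}
    order: dict[int, int] = {i: i for i in range(n)}
    dist: dict[tuple[int, int], float] = {}
    for i, j in combinations(range(n), 2):
        dist[(i, j)] = arr[i, j]

    merges = np.zeros((n - 1, 4))
    next_id = n
    for step in range(n - 1):
        best = None
        for a, b in combinations(sorted(active, key=order.get), 2):
            key = (a, b) if order[a] < order[b] else (b, a)
            d = dist[(min(a, b), max(a, b))]
            cand = (d, order[key[0]], order[key[1]])
            if best is None or cand < best[0]:
                best = (cand, key)
        (d, _, _), (a, b) = best
        sa, sb = active[a], active[b]
        merged = sa + sb
        for c in active:
            if c in (a, b):
                continue
            pa = (min(a, c), max(a, c))
            pb = (min(b, c), max(b, c))
            d_new = (len(sa) * dist[pa] + len(sb) * dist[pb]) / len(merged)
            dist[(min(c, next_id), max(c, next_id))] = d_new
        del active[a], active[b]
        active[next_id] = merged
        order[next_id] = next_id
        merges[step] = (min(a, b), max(a, b), d, len(merged))
        next_id += 1
    return Dendrogram(merges=merges, leaf_ids=labels)


@dataclass
class ModulePartition:
    """Object -> module-color labels plus the input they were cut from."""

    labels: pd.Series
    dissim: pd.DataFrame | None = None

    @property
    def module_colors(self) -> list[str]:
        sizes = self.labels[self.labels != UNASSIGNED].value_counts()
        return list(sizes.index)

    @property
    def n_modules(self) -> int:
        return len(set(self.labels) - {UNASSIGNED})

    def module_sizes(self) -> dict[str, int]:
        return self.labels[self.labels != UNASSIGNED].value_counts().to_dict()

    def to_frame(self, id_column: str = "object_id") -> pd.DataFrame:
        return self.labels.rename("module_color").rename_axis(id_column).reset_index()


def _branch_clusters(
    dendro: Dendrogram,
    heights: np.ndarray,
    node: int,
    min_size: int,
    gap_frac: float,
    clusters: list[list[int]],
) -> None:
    """Recursive variable-height branch detection.

    A node splits into its two children when both would be large enough and
    the merge height stands clear of the children's internal heights by at
    least ``gap_frac`` of its own height; otherwise the subtree is emitted as
    one candidate cluster.
    """
    n = dendro.n_leaves
    if node < n:
        clusters.append([node])
        return
    a, b, h, _ = dendro.merges[node - n]
    a, b = int(a), int(b)

    def internal_height(v: int) -> float:
        return 0.0 if v < n else float(dendro.merges[v - n][2])

    child_h = max(internal_height(a), internal_height(b))
    size_a = 1 if a < n else int(dendro.merges[a - n][3])
    size_b = 1 if b < n else int(dendro.merges[b - n][3])
    splittable = (
        size_a >= min_size
        and size_b >= min_size
        and h > 0
        and (h - child_h) >= gap_frac * h
    )
    if splittable:
        _branch_clusters(dendro, heights, a, min_size, gap_frac, clusters)
        _branch_clusters(dendro, heights, b, min_size, gap_frac, clusters)
    else:
        clusters.append(dendro.leaves_under(node))


def dynamic_tree_cut(
    dendro: Dendrogram,
    dissim: pd.DataFrame | np.ndarray,
    min_module_size: int = 3,
    deep_split: int = 2,
    cut_height: float | None = None,
) -> ModulePartition:
    """Dynamic hybrid tree cut into color-labeled modules.

    Stage 1 cuts the tree statically at ``cut_height`` (default 99% of the
    top merge height).  Stage 2 recursively splits each branch where the
    joining height stands clear of the sub-branch heights; ``deep_split``
    (0..4) controls the required clearance, higher values splitting more
    aggressively.  Branches below ``min_module_size`` are dissolved and their
    members reassigned PAM-style to the closest module when they are at least
    as close to it as the module's own radius; everything else stays grey.
    Colors are drawn from the fixed palette by decreasing module size.
    """
    if min_module_size < 1:
        raise ValueError("min_module_size must be >= 1")
    if not 0 <= deep_split <= 4:
        raise ValueError("deep_split must lie in 0..4")
    arr = _check_square(dissim)
    n = dendro.n_leaves
    if arr.shape[0] != n:
        raise ValueError("dendrogram and dissimilarity disagree on size")

    heights = dendro.merges[:, 2]
    max_h = float(heights.max()) if len(heights) else 0.0
    if cut_height is None:
        cut_height = 0.99 * max_h
    gap_frac = (1.0 - deep_split / 4.0) * 0.5

    # Stage 1: maximal subtrees merged at or below cut_height.
    roots: list[int] = []
    top = 2 * n - 2
    stack = [top]
    while stack:
        v = stack.pop()
        if v < n or dendro.merges[v - n][2] <= cut_height:
            roots.append(v)
        else:
            row = dendro.merges[v - n]
            stack.extend((int(row[0]), int(row[1])))

    # Stage 2: adaptive splitting inside each static branch.
    clusters: list[list[int]] = []
    for r in roots:
        _branch_clusters(dendro, heights, r, min_module_size, gap_frac, clusters)

    kept = [sorted(c) for c in clusters if len(c) >= min_module_size]
    grey = sorted(
        set(range(n)) - {i for c in kept for i in c}
    )

    # Stage 3 (PAM-like): pull stragglers into the nearest module when close.
    if kept and grey:
        radii = []
        for c in kept:
            sub = arr[np.ix_(c, c)]
            radii.append(float(sub.mean(axis=1).max()) if len(c) > 1 else 0.0)
        for g in grey[:]:
            avg = [float(arr[g, c].mean()) for c in kept]
            best = int(np.argmin(avg))
            if avg[best] <= max(radii[best], 1e-12):
                kept[best].append(g)
                grey.remove(g)
        kept = [sorted(c) for c in kept]

    labels = np.array([UNASSIGNED] * n, dtype=object)
    # Palette order by decreasing size, ties by smallest member index.
    for color_idx, c in enumerate(
        sorted(kept, key=lambda c: (-len(c), c[0] if c else n))
    ):
        color = (
            MODULE_COLORS[color_idx]
            if color_idx < len(MODULE_COLORS)
            else f"module{color_idx + 1}"
        )
        for i in c:
            labels[i] = color

    series = pd.Series(labels, index=list(dendro.leaf_ids), name="module_color")
    d = (
        dissim
        if isinstance(dissim, pd.DataFrame)
        else pd.DataFrame(arr, index=list(dendro.leaf_ids), columns=list(dendro.leaf_ids))
    )
    return ModulePartition(labels=series, dissim=d)


def pam_reference_labels(
    dissim: pd.DataFrame | np.ndarray,
    k: int,
    seed: int = 0,
    n_restarts: int = 10,
) -> pd.Series:
    """Partitioning around medoids on a precomputed dissimilarity.

    Deterministic BUILD initialization followed by SWAP until no improving
    medoid exchange exists, plus ``n_restarts`` seeded random restarts to
    escape the local optima single-swap descent can hit.  Deterministic for
    a given seed.  Labels are 0..k-1 in order of the sorted medoid indices.
    """
    arr = _check_square(dissim)
    n = arr.shape[0]
    if not 1 <= k <= n:
        raise ValueError("need 1 <= k <= n")
    index = (
        list(dissim.index) if isinstance(dissim, pd.DataFrame) else list(range(n))
    )

    def total_cost(medoids: list[int]) -> float:
        return float(arr[:, medoids].min(axis=1).sum())

    def build() -> list[int]:
        medoids = [int(np.argmin(arr.sum(axis=1)))]
        while len(medoids) < k:
            current = arr[:, medoids].min(axis=1)
            gains = np.maximum(current[None, :] - arr, 0.0).sum(axis=1)
            gains[medoids] = -np.inf
            medoids.append(int(np.argmax(gains)))
        return medoids

    def swap(medoids: list[int]) -> list[int]:
        medoids = list(medoids)
        improved = True
        while improved:
            improved = False
            best_cost = total_cost(medoids)
            best_pair = None
            for mi, m in enumerate(medoids):
                for h in range(n):
                    if h in medoids:
                        continue
                    trial = medoids[:mi] + [h] + medoids[mi + 1 :]
                    c = total_cost(trial)
                    if c < best_cost - 1e-12:
                        best_cost, best_pair = c, (mi, h)
            if best_pair is not None:
                mi, h = best_pair
                medoids[mi] = h
                improved = True
        return medoids

    best = swap(build())
    if n_restarts > 0:
        rng = np.random.default_rng(seed)
        for _ in range(n_restarts):
            start = list(rng.choice(n, size=k, replace=False))
            cand = swap(start)
            if total_cost(cand) < total_cost(best) - 1e-12:
                best = cand
    medoids = sorted(best)
    assign = np.argmin(arr[:, medoids], axis=1)
    return pd.Series(assign, index=index, name="pam_label")
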