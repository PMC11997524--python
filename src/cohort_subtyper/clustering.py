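"""Ward-linkage agglomerative clustering with silhouette-based model selection.

Ward's criterion merges, at every step, the pair of clusters whose union
minimally increases the within-cluster sum of squares; merge heights follow
the Lance–Williams recurrence in Euclidean geometry.  The number of clusters
is chosen by cutting the same dendrogram at each candidate k and keeping the
cut with the highest mean silhouette score, with ties broken toward the
smaller k.  Within-cluster sum of squares per k is emitted alongside as an
elbow diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.typing import ArrayLike, NDArray
from scipy.cluster import hierarchy
from sklearn.metrics import silhouette_score

__all__ = [
    "Dendrogram",
    "ClusterAssignment",
    "ward_linkage",
    "cut_tree",
    "silhouette",
    "select_k",
]


@dataclass
class Dendrogram:
    """Ward merge tree in scipy linkage-matrix form.

    ``linkage`` rows are (cluster_a, cluster_b, height, new_size); heights
    are nondecreasing (Ward is monotone) and there are exactly
    ``n_leaves - 1`` merges.
    """

    linkage: NDArray[np.float64]
    n_leaves: int

    def __post_init__(self) -> None:
        if self.linkage.shape != (self.n_leaves - 1, 4):
            raise ValueError("linkage must have n_leaves - 1 rows of 4")

    @property
    def heights(self) -> NDArray[np.float64]:
        return self.linkage[:, 2]


@dataclass
class ClusterAssignment:
    """Flat cluster labels, renumbered by decreasing cluster size."""

    labels: NDArray[np.int64]
    k: int
    mean_silhouette: float | None = None

    def sizes(self) -> NDArray[np.int64]:
        return np.bincount(self.labels, minlength=self.k)


def _canonical_labels(raw: NDArray[np.integer]) -> NDArray[np.int64]:
    """Renumber labels by decreasing size; ties by smallest member index."""
    raw = np.asarray(raw)
    uniq = np.unique(raw)
    first_member = {u: int(np.argmax(raw == u)) for u in uniq}
    order = sorted(uniq, key=lambda u: (-int(np.sum(raw == u)), first_member[u]))
    remap = {u: i for i, u in enumerate(order)}
    return np.array([remap[v] for v in raw], dtype=np.int64)


def ward_linkage(X: ArrayLike) -> Dendrogram:
    """Euclidean Ward agglomeration of the rows of ``X``."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] < 2:
        raise ValueError("need at least 2 points to cluster")
    if not np.all(np.isfinite(X)):
        raise ValueError("input contains non-finite values")
    Z = hierarchy.linkage(X, method="ward")
    return Dendrogram(linkage=Z, n_leaves=X.shape[0])


def cut_tree(dendrogram: Dendrogram, k: int) -> ClusterAssignment:
    """Cut to exactly ``k`` flat clusters by undoing the last k-1 merges."""
    if not 1 <= k <= dendrogram.n_leaves:
        raise ValueError(f"k={k} out of range [1, {dendrogram.n_leaves}]")
    raw = hierarchy.fcluster(dendrogram.linkage, t=k, criterion="maxclust")
    return ClusterAssignment(labels=_canonical_labels(raw), k=k)


def silhouette(X: ArrayLike, labels: ArrayLike) -> float:
    """Mean silhouette score ((b - a) / max(a, b)); singletons score 0."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    labels = np.asarray(labels)
    k = len(np.unique(labels))
    n = X.shape[0]
    if k < 2 or k > n:
        raise ValueError(f"silhouette needs 2 <= k <= n; got k={k}, n={n}")
    if k == n:  # every cluster a singleton: each contributes 0 by convention
        return 0.0
    return float(silhouette_score(X, labels, metric="euclidean"))


def _wcss(X: NDArray[np.float64], labels: NDArray[np.integer]) -> float:
    total = 0.0
    for lab in np.unique(labels):
        pts = X[labels == lab]
        total += float(((pts - pts.mean(axis=0)) ** 2).sum())
    return total


def select_k(
    X: ArrayLike, k_min: int = 2, k_max: int = 10
) -> tuple[ClusterAssignment, dict[int, dict[str, float]]]:
    """Choose k in [k_min, k_max] by maximal mean silhouette on Ward cuts.

    Returns the winning assignment together with per-k diagnostics
    (silhouette and within-cluster sum of squares for elbow inspection).
    Ties on silhouette break toward smaller k.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = X.shape[0]
    if n <= k_max:
        raise ValueError(f"need more points ({n}) than k_max ({k_max})")
    dend = ward_linkage(X)
    diagnostics: dict[int, dict[str, float]] = {}
    best: ClusterAssignment | None = None
    for k in range(k_min, k_max + 1):
        assign = cut_tree(dend, k)
        score = silhouette(X, assign.labels)
        assign.mean_silhouette = score
        diagnostics[k] = {"silhouette": score, "wcss": _wcss(X, assign.labels)}
        if best is None or score > best.mean_silhouette + 1e-12:
            best = assign
    assert best is not None
    return best, diagnostics
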