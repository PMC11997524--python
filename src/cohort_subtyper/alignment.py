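"""Provider batch-effect removal by optimal transport in 2-D.

Clinical-note embeddings carry provider-specific structure (the authoring
clinician's style) on top of patient phenotype.  To remove it, patient note
vectors are first reduced to 2-D (UMAP by default, PCA as an exact and fast
fallback), then each provider's point cloud is mapped onto a reference
provider's cloud: the exact earth-mover (Monge–Kantorovich) plan between the
two empirical distributions is solved as a linear program with uniform
weights and squared-Euclidean cost, and each source point is moved to the
barycenter of its transported mass over the target points.  The reference
cloud itself is left untouched.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from numpy.typing import ArrayLike, NDArray
from scipy import sparse
from scipy.optimize import linprog
from scipy.spatial.distance import cdist

__all__ = [
    "ReducedEmbedding",
    "TransportPlan",
    "AlignedEmbedding",
    "reduce_2d",
    "emd_plan",
    "barycentric_map",
    "align_providers",
]

logger = logging.getLogger(__name__)


@dataclass
class ReducedEmbedding:
    points: NDArray[np.float64]  # patients x 2
    patient_index: list[str]
    provider_of: dict[str, str]
    reducer_params: dict = field(default_factory=dict)


@dataclass
class TransportPlan:
    plan: NDArray[np.float64]
    source_weights: NDArray[np.float64]
    target_weights: NDArray[np.float64]
    cost: float


@dataclass
class AlignedEmbedding:
    points: NDArray[np.float64]
    patient_index: list[str]
    provider_of: dict[str, str]
    reference_provider: str


def reduce_2d(
    X: ArrayLike,
    patient_index: list[str],
    provider_of: dict[str, str],
    backend: str = "umap",
    seed: int = 0,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
) -> ReducedEmbedding:
    """Reduce patient vectors to 2-D with a pluggable backend.

    ``umap`` runs a neighbor-embedding projection (deterministic given the
    seed, single-threaded); ``pca`` projects onto the top two principal
    components, which is exact, fast, and preserves linear offsets such as
    an additive provider shift.  The neighbor count auto-shrinks with a
    warning when there are too few points.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 patients to reduce")
    if X.shape[0] != len(patient_index):
        raise ValueError("patient_index length must match rows of X")
    params: dict = {"backend": backend, "seed": seed}
    if backend == "pca":
        from sklearn.decomposition import PCA

        pts = PCA(n_components=2, random_state=seed).fit_transform(X)
    elif backend == "umap":
        import umap  # deferred: numba compilation is expensive

        if n_neighbors >= X.shape[0]:
            new = max(2, X.shape[0] - 1)
            logger.warning("n_neighbors=%d >= n points; shrinking to %d", n_neighbors, new)
            n_neighbors = new
        params.update({"n_neighbors": n_neighbors, "min_dist": min_dist})
        reducer = umap.UMAP(
            n_components=2,
            n_neighbors=n_neighbors,
            min_dist=min_dist,
            random_state=seed,
            n_jobs=1,
        )
        pts = np.asarray(reducer.fit_transform(X), dtype=float)
    else:
        raise ValueError(f"unknown reducer backend {backend!r}")
    return ReducedEmbedding(
        points=pts,
        patient_index=list(patient_index),
        provider_of=dict(provider_of),
        reducer_params=params,
    )


def emd_plan(source: ArrayLike, target: ArrayLike) -> TransportPlan:
    """Exact EMD plan between two point clouds, uniform weights.

    Solves the discrete Monge–Kantorovich transportation problem with
    squared-Euclidean cost via linear programming (HiGHS).  Marginal
    constraints hold to solver precision; the optimal objective is reported
    as ``cost``.
    """
    src = np.atleast_2d(np.asarray(source, dtype=float))
    tgt = np.atleast_2d(np.asarray(target, dtype=float))
    if src.shape[0] == 0 or tgt.shape[0] == 0:
        raise ValueError("both point clouds must be non-empty")
    n, m = src.shape[0], tgt.shape[0]
    a = np.full(n, 1.0 / n)
    b = np.full(m, 1.0 / m)
    C = cdist(src, tgt, metric="sqeuclidean")

    # Equality constraints: row sums = a, column sums = b. One constraint is
    # redundant (both sum to 1); dropping the last column constraint keeps
    # the system full-rank for the LP solver.
    rows = []
    cols = []
    data = []
    for i in range(n):
        rows.extend([i] * m)
        cols.extend(range(i * m, (i + 1) * m))
        data.extend([1.0] * m)
    for j in range(m - 1):
        rows.extend([n + j] * n)
        cols.extend(j + m * np.arange(n))
        data.extend([1.0] * n)
    A_eq = sparse.csr_matrix((data, (rows, cols)), shape=(n + m - 1, n * m))
    b_eq = np.concatenate([a, b[:-1]])
    res = linprog(C.ravel(), A_eq=A_eq, b_eq=b_eq, bounds=(0, None), method="highs")
    if not res.success:
        raise RuntimeError(f"transport LP failed: {res.message}")
    plan = res.x.reshape(n, m)
    return TransportPlan(plan=plan, source_weights=a, target_weights=b, cost=float(res.fun))


def barycentric_map(plan: TransportPlan, target: ArrayLike) -> NDArray[np.float64]:
    """Map each source point to the barycenter of its transported mass."""
    tgt = np.atleast_2d(np.asarray(target, dtype=float))
    row_mass = plan.plan.sum(axis=1)
    if np.any(row_mass <= 0):
        raise ValueError("transport plan has an empty source row")
    return (plan.plan @ tgt) / row_mass[:, None]


def align_providers(
    reduced: ReducedEmbedding, reference: str | None = None
) -> AlignedEmbedding:
    """Align every provider's 2-D cloud onto the reference provider's cloud.

    ``reference=None`` selects the provider with the most patients (ties
    broken lexicographically).  Non-reference providers are processed in
    sorted order; the reference cloud is returned bit-for-bit unchanged.
    """
    providers = sorted({reduced.provider_of[p] for p in reduced.patient_index})
    counts = {
        prov: sum(1 for p in reduced.patient_index if reduced.provider_of[p] == prov)
        for prov in providers
    }
    if reference is None:
        reference = min(providers, key=lambda pr: (-counts[pr], pr))
    elif reference not in providers:
        raise ValueError(f"unknown reference provider {reference!r}; have {providers}")
    prov_arr = np.array([reduced.provider_of[p] for p in reduced.patient_index])
    out = reduced.points.copy()
    ref_cloud = reduced.points[prov_arr == reference]
    for prov in providers:
        if prov == reference:
            continue
        mask = prov_arr == prov
        plan = emd_plan(reduced.points[mask], ref_cloud)
        out[mask] = barycentric_map(plan, ref_cloud)
    return AlignedEmbedding(
        points=out,
        patient_index=list(reduced.patient_index),
        provider_of=dict(reduced.provider_of),
        reference_provider=reference,
    )
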