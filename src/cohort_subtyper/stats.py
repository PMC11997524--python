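"""Cluster characterization statistics.

Contingency-table and rank-based statistics used to phenotype clusters:

* 2x2 chi-square with Yates continuity correction plus the prevalence ratio
  (PR), for feature enrichment of one cluster against the rest;
* uncorrected Pearson chi-square for r x c tables, with Cramér V and
  *adjusted* standardized residuals
  ``(O - E) / sqrt(E (1 - row share)(1 - col share))`` for per-cell
  post hoc inspection;
* Kruskal–Wallis with the rank-based eta-squared effect size
  ``(H - k + 1) / (N - k)`` and Dunn's pairwise post hoc z tests;
* Bonferroni and Benjamini–Hochberg multiplicity control.

The PR of a feature in a cluster is its prevalence inside the cluster
divided by its prevalence in all other clusters; a feature present only
inside the cluster is flagged EXCLUSIVE rather than given an infinite ratio.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.typing import ArrayLike, NDArray
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "EXCLUSIVE",
    "ContingencyTable",
    "EnrichmentResult",
    "KWResult",
    "CrossTabReport",
    "chi2_2x2_yates",
    "chi2_rxc",
    "prevalence_ratio",
    "adjust_p",
    "code_enrichment",
    "select_top_codes",
    "kruskal_wallis_eta2",
    "eta_squared_from_h",
    "dunn_posthoc",
    "cramers_v",
    "adjusted_residuals",
    "cross_tabulate",
    "table_from_adjusted_residuals",
]

logger = logging.getLogger(__name__)

#: Sentinel for a feature whose prevalence outside the cluster is zero.
EXCLUSIVE = "EXCLUSIVE"


@dataclass
class ContingencyTable:
    observed: NDArray[np.int64]
    row_labels: list[str] | None = None
    col_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.observed = np.asarray(self.observed, dtype=np.int64)
        if self.observed.ndim != 2:
            raise ValueError("contingency table must be 2-D")
        if np.any(self.observed < 0):
            raise ValueError("counts must be nonnegative")
        if self.observed.sum() == 0:
            raise ValueError("table total must be positive")

    @property
    def n(self) -> int:
        return int(self.observed.sum())


@dataclass
class EnrichmentResult:
    feature: str
    cluster: int
    chi2: float
    df: int
    p_raw: float
    p_adjusted: float
    prevalence_ratio: float | str
    counts: tuple[int, int, int, int]  # a, b, c, d

    @property
    def significant(self) -> bool:
        return self.p_adjusted < 0.05


@dataclass
class KWResult:
    H: float
    df: int
    p: float
    eta_squared: float


@dataclass
class CrossTabReport:
    table: ContingencyTable
    chi2: float
    df: int
    p: float
    cramers_v: float
    adjusted_residuals: NDArray[np.float64]
    residual_p_adjusted: NDArray[np.float64]


def _check_margins(t: ContingencyTable) -> None:
    if np.any(t.observed.sum(axis=0) == 0) or np.any(t.observed.sum(axis=1) == 0):
        raise ValueError("contingency table has a zero margin")


def chi2_2x2_yates(table: ContingencyTable | ArrayLike) -> tuple[float, float]:
    """Yates-corrected chi-square for a 2x2 table; returns (chi2, p).

    The correction term |O - E| - 0.5 is floored at zero.
    """
    t = table if isinstance(table, ContingencyTable) else ContingencyTable(np.asarray(table))
    if t.observed.shape != (2, 2):
        raise ValueError("chi2_2x2_yates requires a 2x2 table")
    _check_margins(t)
    chi2, p, _, _ = sps.chi2_contingency(t.observed, correction=True)
    return float(chi2), float(p)


def chi2_rxc(table: ContingencyTable | ArrayLike) -> tuple[float, int, float]:
    """Uncorrected Pearson chi-square for an r x c table: (chi2, df, p)."""
    t = table if isinstance(table, ContingencyTable) else ContingencyTable(np.asarray(table))
    if min(t.observed.shape) < 2:
        raise ValueError("need at least a 2x2 table")
    _check_margins(t)
    chi2, p, df, _ = sps.chi2_contingency(t.observed, correction=False)
    return float(chi2), int(df), float(p)


def prevalence_ratio(table: ContingencyTable | ArrayLike) -> float | str:
    """Prevalence ratio from a 2x2 table with rows (in-cluster, rest).

    Rows are (has-feature, lacks-feature) counts for the cluster and for all
    other clusters; PR = (a/(a+b)) / (c/(c+d)).  Returns the EXCLUSIVE
    sentinel when the feature never occurs outside the cluster, and 0.0 when
    it occurs only outside.
    """
    t = table if isinstance(table, ContingencyTable) else ContingencyTable(np.asarray(table))
    if t.observed.shape != (2, 2):
        raise ValueError("prevalence ratio requires a 2x2 table")
    (a, b), (c, d) = t.observed
    if a + b == 0:
        raise ValueError("in-cluster size is zero")
    if a == 0 and c == 0:
        raise ValueError("feature absent everywhere; prevalence ratio undefined")
    if c == 0:
        return EXCLUSIVE
    return float((a / (a + b)) / (c / (c + d)))


def adjust_p(p_values: ArrayLike, method: str = "bonferroni") -> NDArray[np.float64]:
    """Multiple-testing adjustment (``bonferroni`` or ``bh``), input order kept."""
    ps = np.asarray(p_values, dtype=float)
    if ps.size == 0:
        return ps
    if np.any((ps < 0) | (ps > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    key = {"bonferroni": "bonferroni", "bh": "fdr_bh"}.get(method)
    if key is None:
        raise ValueError(f"unknown correction method {method!r}")
    return multipletests(ps, method=key)[1]


def code_enrichment(
    presence: pd.DataFrame,
    labels: ArrayLike,
    correction: str = "bonferroni",
) -> list[EnrichmentResult]:
    """One Yates 2x2 enrichment test per (cluster, feature).

    ``presence`` is a patients x features binary table; ``labels`` assigns
    each patient (row) a cluster.  The multiplicity family is all features
    within one cluster's analysis.  Features absent everywhere are skipped
    with a warning.  Results are sorted by (cluster, adjusted p, -PR).
    """
    labels = np.asarray(labels)
    if len(labels) != presence.shape[0]:
        raise ValueError("labels length must match presence rows")
    pres = presence.to_numpy() > 0
    results: list[EnrichmentResult] = []
    for cluster in np.unique(labels):
        in_cl = labels == cluster
        cluster_res: list[EnrichmentResult] = []
        for j, feature in enumerate(presence.columns):
            a = int(np.sum(pres[in_cl, j]))
            b = int(np.sum(in_cl)) - a
            c = int(np.sum(pres[~in_cl, j]))
            d = int(np.sum(~in_cl)) - c
            if a + c == 0:
                logger.warning("feature %r absent everywhere; skipped", feature)
                continue
            table = ContingencyTable(np.array([[a, b], [c, d]]))
            if a + c == a + b + c + d or min(table.observed.sum(0)) == 0:
                # feature present in everyone: degenerate margin, skip
                logger.warning("feature %r present in every patient; skipped", feature)
                continue
            chi2, p = chi2_2x2_yates(table)
            pr = prevalence_ratio(table)
            cluster_res.append(
                EnrichmentResult(
                    feature=str(feature),
                    cluster=int(cluster),
                    chi2=chi2,
                    df=1,
                    p_raw=p,
                    p_adjusted=np.nan,
                    prevalence_ratio=pr,
                    counts=(a, b, c, d),
                )
            )
        adj = adjust_p([r.p_raw for r in cluster_res], method=correction)
        for r, pa in zip(cluster_res, adj):
            r.p_adjusted = float(pa)
        cluster_res.sort(
            key=lambda r: (
                r.p_adjusted,
                -np.inf if r.prevalence_ratio == EXCLUSIVE else -r.prevalence_ratio,
            )
        )
        results.extend(cluster_res)
    return results


def _pr_sort_key(r: EnrichmentResult) -> float:
    return np.inf if r.prevalence_ratio == EXCLUSIVE else float(r.prevalence_ratio)


def select_top_codes(
    results: list[EnrichmentResult], n: int = 10, alpha: float = 0.05
) -> list[EnrichmentResult]:
    """Top-n enriched features of one cluster.

    If any result is significant after correction, return the (at most n)
    significant ones with the highest PR; otherwise fall back to the
    highest-PR nonsignificant results (callers can see the nonsignificance
    from ``p_adjusted``).  EXCLUSIVE ranks above any finite PR.
    """
    if not results:
        return []
    clusters = {r.cluster for r in results}
    if len(clusters) != 1:
        raise ValueError("select_top_codes expects results from a single cluster")
    significant = [r for r in results if r.p_adjusted < alpha]
    pool = significant if significant else list(results)
    pool.sort(key=lambda r: (-_pr_sort_key(r), r.p_adjusted, r.feature))
    return pool[:n]


def eta_squared_from_h(H: float, k: int, n: int) -> float:
    """Rank eta-squared effect size: (H - k + 1) / (N - k)."""
    if k < 2 or n <= k:
        raise ValueError("need k >= 2 groups and N > k observations")
    return (H - k + 1) / (n - k)


def kruskal_wallis_eta2(values: ArrayLike, groups: ArrayLike) -> KWResult:
    """Kruskal–Wallis H (midranks, tie-corrected) with rank eta-squared.

    eta^2 = (H - k + 1) / (N - k); for k groups H is chi-square distributed
    with k - 1 degrees of freedom under the null.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    k = len(uniq)
    if k < 2:
        raise ValueError("need at least 2 groups")
    samples = [values[groups == g] for g in uniq]
    if any(len(s) == 0 for s in samples):
        raise ValueError("every group needs at least one value")
    N = len(values)
    if np.all(values == values[0]):
        logger.warning("all values identical; H = 0")
        return KWResult(H=0.0, df=k - 1, p=1.0, eta_squared=eta_squared_from_h(0.0, k, N))
    H, p = sps.kruskal(*samples)
    return KWResult(H=float(H), df=k - 1, p=float(p), eta_squared=eta_squared_from_h(float(H), k, N))


def dunn_posthoc(values: ArrayLike, groups: ArrayLike) -> pd.DataFrame:
    """Dunn's pairwise rank post hoc test with BH-adjusted two-sided p.

    For groups i, j with sizes n_i, n_j and mean ranks Rbar_i, Rbar_j over
    the pooled midranks,

        z_ij = (Rbar_i - Rbar_j) /
               sqrt((N(N+1)/12 - sum(T)/(12(N-1))) (1/n_i + 1/n_j))

    where sum(T) = sum over tie groups of t^3 - t.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    uniq = list(np.unique(groups))
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    N = len(values)
    ranks = sps.rankdata(values)
    _, tie_counts = np.unique(values, return_counts=True)
    tie_sum = float(np.sum(tie_counts**3 - tie_counts))
    var_term = N * (N + 1) / 12.0 - tie_sum / (12.0 * (N - 1))
    rows = []
    for i in range(len(uniq)):
        for j in range(i + 1, len(uniq)):
            gi, gj = uniq[i], uniq[j]
            ri = ranks[groups == gi]
            rj = ranks[groups == gj]
            se = np.sqrt(var_term * (1.0 / len(ri) + 1.0 / len(rj)))
            z = 0.0 if se == 0 else float((ri.mean() - rj.mean()) / se)
            p = float(2 * sps.norm.sf(abs(z)))
            rows.append({"group_a": gi, "group_b": gj, "z": z, "p_raw": p})
    out = pd.DataFrame(rows)
    out["p_adjusted"] = adjust_p(out["p_raw"].to_numpy(), method="bh")
    return out


def cramers_v(chi2: float, n: int, shape: tuple[int, int]) -> float:
    """Cramér V = sqrt(chi2 / (N * (min(r, c) - 1)))."""
    r, c = shape
    if min(r, c) < 2:
        raise ValueError("Cramér V needs at least a 2x2 table")
    return float(np.sqrt(chi2 / (n * (min(r, c) - 1))))


def adjusted_residuals(observed: ArrayLike) -> NDArray[np.float64]:
    """Adjusted standardized residuals of an r x c table.

    r_ij = (O - E) / sqrt(E (1 - rowN_i/N)(1 - colN_j/N)); approximately
    standard normal per cell under independence.
    """
    O = np.asarray(observed, dtype=float)
    N = O.sum()
    row = O.sum(axis=1)
    col = O.sum(axis=0)
    E = np.outer(row, col) / N
    denom = np.sqrt(E * np.outer(1 - row / N, 1 - col / N))
    return (O - E) / denom


def cross_tabulate(
    labels_a: ArrayLike,
    labels_b: ArrayLike,
    names: tuple[str, str] = ("a", "b"),
) -> CrossTabReport:
    """Cross-tabulate two cluster solutions over the same patients.

    Reports the Pearson chi-square, Cramér V, per-cell adjusted standardized
    residuals, and BH-adjusted two-sided normal p-values for the residuals.
    """
    labels_a = np.asarray(labels_a)
    labels_b = np.asarray(labels_b)
    if len(labels_a) != len(labels_b):
        raise ValueError("label vectors must cover the same patients")
    ct = pd.crosstab(labels_a, labels_b)
    table = ContingencyTable(
        ct.to_numpy(),
        row_labels=[f"{names[0]}{v}" for v in ct.index],
        col_labels=[f"{names[1]}{v}" for v in ct.columns],
    )
    chi2, df, p = chi2_rxc(table)
    resid = adjusted_residuals(table.observed)
    cell_p = 2 * sps.norm.sf(np.abs(resid))
    adj = adjust_p(cell_p.ravel(), method="bh").reshape(cell_p.shape)
    return CrossTabReport(
        table=table,
        chi2=chi2,
        df=df,
        p=p,
        cramers_v=cramers_v(chi2, table.n, table.observed.shape),
        adjusted_residuals=resid,
        residual_p_adjusted=adj,
    )


def table_from_adjusted_residuals(
    row_totals: ArrayLike,
    col_totals: ArrayLike,
    residuals: dict[tuple[int, int], float],
) -> NDArray[np.int64]:
    """Reconstruct an integer contingency table from marginals and residuals.

    Inverts the adjusted-residual formula, ``O = E + r * sd``, for every
    cell whose residual is given, then repeatedly completes rows or columns
    that have exactly one unknown cell from the marginal totals.  Raises if
    the given residuals underdetermine the table or the rounded result is
    inconsistent with the marginals.
    """
    row = np.asarray(row_totals, dtype=float)
    col = np.asarray(col_totals, dtype=float)
    if row.sum() != col.sum():
        raise ValueError("row and column totals disagree")
    N = row.sum()
    E = np.outer(row, col) / N
    sd = np.sqrt(E * np.outer(1 - row / N, 1 - col / N))
    O = np.full((len(row), len(col)), np.nan)
    for (i, j), r in residuals.items():
        O[i, j] = E[i, j] + r * sd[i, j]
    changed = True
    while changed and np.isnan(O).any():
        changed = False
        for i in range(len(row)):
            missing = np.flatnonzero(np.isnan(O[i]))
            if len(missing) == 1:
                O[i, missing[0]] = row[i] - np.nansum(O[i])
                changed = True
        for j in range(len(col)):
            missing = np.flatnonzero(np.isnan(O[:, j]))
            if len(missing) == 1:
                O[missing[0], j] = col[j] - np.nansum(O[:, j])
                changed = True
    if np.isnan(O).any():
        raise ValueError("residuals underdetermine the table")
    out = np.round(O).astype(np.int64)
    if np.any(out < 0):
        raise ValueError("reconstruction produced negative counts")
    if not (np.array_equal(out.sum(axis=1), row.astype(int)) and np.array_equal(out.sum(axis=0), col.astype(int))):
        raise ValueError("rounded reconstruction violates the marginals")
    return out
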