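"""Representative terms per note cluster via class-based TF-IDF.

All notes belonging to one cluster are treated as a single class document.
After stop-word removal and a maximum-document-frequency cap, each term t in
cluster c scores

    W(t, c) = (count(t, c) / tokens_in_c) * log(1 + A / f_t)

with A the mean token count per cluster and f_t the total count of t over
all clusters — the canonical class-based TF-IDF.  Term prevalence ratios
(patient-level presence inside vs outside the cluster) accompany the
scores; a term that only ever occurs inside one cluster is flagged
EXCLUSIVE.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.typing import ArrayLike, NDArray
from sklearn.feature_extraction.text import CountVectorizer

from .stats import EXCLUSIVE

__all__ = ["TermCountsByCluster", "TermScore", "vectorize", "ctfidf", "term_prevalence_ratio", "top_terms"]


@dataclass
class TermCountsByCluster:
    counts: pd.DataFrame  # term x cluster total counts
    doc_frequency: pd.DataFrame  # term x cluster patient-presence counts
    docs_per_cluster: dict[int, int]

    @property
    def vocabulary(self) -> list[str]:
        return list(self.counts.index)


@dataclass
class TermScore:
    term: str
    cluster: int
    ctfidf: float
    prevalence_ratio: float | str


def vectorize(
    notes: dict[str, str],
    labels: dict[str, int],
    stop_words: str | list[str] | None = "english",
    max_df: float = 0.8,
) -> TermCountsByCluster:
    """Count lowercased unigrams per cluster after stop-word/max-df filtering.

    ``max_df`` drops terms appearing in more than that fraction of notes
    (the "too frequent across most notes" cap).
    """
    missing = [p for p in notes if p not in labels]
    if missing:
        raise ValueError(f"patients without cluster label: {missing[:5]}")
    pids = sorted(notes)
    try:
        vec = CountVectorizer(lowercase=True, stop_words=stop_words, max_df=max_df)
        M = vec.fit_transform([notes[p] for p in pids])
    except ValueError as exc:
        raise ValueError(
            f"empty vocabulary after filtering (try a lower max_df): {exc}"
        ) from exc
    terms = vec.get_feature_names_out()
    lab = np.array([labels[p] for p in pids])
    clusters = sorted(np.unique(lab))
    counts = pd.DataFrame(0, index=terms, columns=clusters, dtype=int)
    docfreq = pd.DataFrame(0, index=terms, columns=clusters, dtype=int)
    dense = M.toarray()
    for c in clusters:
        rows = dense[lab == c]
        counts[c] = rows.sum(axis=0)
        docfreq[c] = (rows > 0).sum(axis=0)
    docs = {int(c): int(np.sum(lab == c)) for c in clusters}
    return TermCountsByCluster(counts=counts, doc_frequency=docfreq, docs_per_cluster=docs)


def term_prevalence_ratio(tc: TermCountsByCluster, term: str, cluster: int) -> float | str:
    """Patient-presence prevalence of ``term`` in ``cluster`` vs the rest."""
    if term not in tc.doc_frequency.index:
        raise ValueError(f"term {term!r} not in vocabulary")
    df_row = tc.doc_frequency.loc[term]
    if df_row.sum() == 0:
        raise ValueError(f"term {term!r} absent everywhere")
    in_count = df_row[cluster]
    in_docs = tc.docs_per_cluster[cluster]
    rest_count = df_row.sum() - in_count
    rest_docs = sum(v for c, v in tc.docs_per_cluster.items() if c != cluster)
    if rest_count == 0:
        return EXCLUSIVE
    return float((in_count / in_docs) / (rest_count / rest_docs))


def ctfidf(tc: TermCountsByCluster) -> list[TermScore]:
    """Class-based TF-IDF score for every (term, cluster) pair."""
    if tc.counts.shape[1] < 2:
        raise ValueError("class-based TF-IDF needs at least 2 clusters")
    tokens_per_cluster = tc.counts.sum(axis=0)
    A = float(tokens_per_cluster.mean())
    f = tc.counts.sum(axis=1)  # total count of each term over clusters
    scores: list[TermScore] = []
    for term in tc.counts.index:
        if f[term] == 0:
            continue
        idf = np.log(1.0 + A / f[term])
        for c in tc.counts.columns:
            tf = tc.counts.at[term, c] / tokens_per_cluster[c]
            scores.append(
                TermScore(
                    term=str(term),
                    cluster=int(c),
                    ctfidf=float(tf * idf),
                    prevalence_ratio=term_prevalence_ratio(tc, term, c),
                )
            )
    return scores


def top_terms(scores: list[TermScore], per_cluster_n: int = 10) -> dict[int, list[TermScore]]:
    """Per cluster, terms ranked by descending c-TF-IDF (ties lexicographic)."""
    out: dict[int, list[TermScore]] = {}
    clusters = sorted({s.cluster for s in scores})
    for c in clusters:
        ranked = sorted(
            (s for s in scores if s.cluster == c), key=lambda s: (-s.ctfidf, s.term)
        )
        out[c] = ranked[:per_cluster_n]
    return out
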