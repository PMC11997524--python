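"""Patient design matrix from diagnosis-code counts and code embeddings.

The structured arm represents each patient as the count-weighted sum of
pretrained code embeddings over their record: with ``P`` the patients x codes
count matrix and ``E`` the codes x d embedding table, the design matrix is
``X = P @ E``.  Counts are used as-is (not binarized), so a code appearing
ten times contributes ten times its embedding.  Codes for the condition of
interest are excluded from ``P`` up front so that clustering reflects
comorbidity structure rather than the index diagnosis itself.

Enrichment statistics downstream use patient-level *presence* (binary),
which is also derived here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.typing import NDArray

__all__ = [
    "CodeCountMatrix",
    "CodeEmbeddingMatrix",
    "DesignMatrix",
    "build_count_matrix",
    "compose_design",
]

logger = logging.getLogger(__name__)


@dataclass
class CodeCountMatrix:
    """Nonnegative integer counts, patients x codes."""

    values: NDArray[np.int64]
    patient_index: list[str]
    code_index: list[str]

    def presence(self) -> pd.DataFrame:
        """Binary patient-level presence indicator (count >= 1)."""
        return pd.DataFrame(
            (self.values > 0).astype(int),
            index=self.patient_index,
            columns=self.code_index,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.patient_index, columns=self.code_index)


@dataclass
class CodeEmbeddingMatrix:
    """Real-valued embedding per code, codes x d."""

    values: NDArray[np.float64]
    code_index: list[str]

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CodeEmbeddingMatrix":
        return cls(frame.to_numpy(dtype=float), list(frame.index))


@dataclass
class DesignMatrix:
    """Patient-level embedding sums, patients x d."""

    values: NDArray[np.float64]
    patient_index: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.patient_index)


def build_count_matrix(
    records: pd.DataFrame, exclusion_codes: set[str] | frozenset[str] = frozenset()
) -> CodeCountMatrix:
    """Pivot long-format (patient_id, code, count) records into a count matrix.

    Codes in ``exclusion_codes`` are dropped, and patients whose records
    contain *only* excluded codes are removed (and reported via logging),
    mirroring a cohort filter that requires at least one comorbidity code.

    Raises
    ------
    ValueError
        If records are empty, counts are negative/non-integer, or no patient
        survives the exclusion.
    """
    required = {"patient_id", "code", "count"}
    if not required.issubset(records.columns):
        raise ValueError(f"records must have columns {sorted(required)}")
    if len(records) == 0:
        raise ValueError("records are empty")
    counts = pd.to_numeric(records["count"], errors="raise")
    if (counts < 0).any():
        raise ValueError("counts must be nonnegative")
    if not np.allclose(counts, counts.astype(int)):
        raise ValueError("counts must be integers")

    all_patients = records["patient_id"].astype(str).unique().tolist()
    kept = records[~records["code"].astype(str).isin(exclusion_codes)]
    if len(kept) == 0:
        raise ValueError("no records survive code exclusion")
    pivot = (
        kept.assign(
            patient_id=kept["patient_id"].astype(str),
            code=kept["code"].astype(str),
        )
        .pivot_table(
            index="patient_id", columns="code", values="count", aggfunc="sum", fill_value=0
        )
        .astype(np.int64)
    )
    # drop patients with no nonzero entries left
    nonzero = pivot.sum(axis=1) > 0
    dropped = sorted(set(all_patients) - set(pivot.index[nonzero]))
    if dropped:
        logger.warning(
            "%d patient(s) removed: only excluded codes in record: %s",
            len(dropped),
            dropped[:10],
        )
    pivot = pivot.loc[nonzero]
    if pivot.shape[0] == 0:
        raise ValueError("no patients survive code exclusion")
    return CodeCountMatrix(
        values=pivot.to_numpy(), patient_index=list(pivot.index), code_index=list(pivot.columns)
    )


def compose_design(P: CodeCountMatrix, E: CodeEmbeddingMatrix, normalize: bool = False) -> DesignMatrix:
    """Compute ``X = P @ E`` after aligning code indices.

    Codes present in the count matrix but missing from the embedding table
    are dropped with a warning (zero-imputation would silently bias the
    sums).  With ``normalize=True`` rows of ``X`` are L2-normalized, offered
    as a sensitivity analysis; the default leaves raw embedding sums.
    """
    emb_pos = {c: i for i, c in enumerate(E.code_index)}
    keep = [c for c in P.code_index if c in emb_pos]
    missing = [c for c in P.code_index if c not in emb_pos]
    if missing:
        logger.warning("%d code(s) lack embeddings and are dropped: %s", len(missing), missing[:10])
    if not keep:
        raise ValueError("no overlap between count-matrix codes and embedding table")
    cols = [P.code_index.index(c) for c in keep]
    rows = [emb_pos[c] for c in keep]
    X = P.values[:, cols].astype(float) @ E.values[rows, :]
    if normalize:
        norms = np.linalg.norm(X, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        X = X / norms
    return DesignMatrix(values=X, patient_index=list(P.patient_index))
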