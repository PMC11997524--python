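"""Attention-entropy-weighted pooling of transformer token embeddings.

A clinical note is encoded (upstream, e.g. by Clinical BERT) as a token
embedding matrix ``E`` of shape ``(d_tok, n)`` together with the final-layer
self-attention matrix ``A`` of shape ``(n, n)``, already averaged over
attention heads so each row is a probability distribution over tokens.

To collapse the token dimension into a single note vector we weight each
token by the differential entropy of its attention row: rows with diffuse
(high-entropy) attention distributions receive higher weight after a softmax
over the per-row entropies.  The entropy of an attention row is estimated
nonparametrically from order-statistic spacings (the Ebrahimi variant of the
Vasicek estimator), since the attention values are samples from an unknown
density.  Per-note vectors from multiple chunks of the same patient are
averaged into the patient-level representation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from numpy.typing import ArrayLike, NDArray

__all__ = [
    "ChunkEncoding",
    "NoteVector",
    "chunk_text",
    "spacing_entropy",
    "row_entropies",
    "entropy_softmax_weights",
    "pool_chunk",
    "patient_vector",
]

logger = logging.getLogger(__name__)

#: Minimum row length for the spacing entropy estimator.
MIN_SAMPLE_SIZE = 4


@dataclass
class ChunkEncoding:
    """Token embeddings and head-averaged attention for one note chunk.

    Parameters
    ----------
    token_embeddings : ndarray, shape (d_tok, n)
        One contextual embedding column per token.
    attention : ndarray, shape (n, n)
        Row-stochastic self-attention matrix (rows sum to 1).
    """

    token_embeddings: NDArray[np.floating]
    attention: NDArray[np.floating]

    def __post_init__(self) -> None:
        self.token_embeddings = np.asarray(self.token_embeddings, dtype=float)
        self.attention = np.asarray(self.attention, dtype=float)
        if self.token_embeddings.ndim != 2:
            raise ValueError("token_embeddings must be 2-D (d_tok, n)")
        n = self.token_embeddings.shape[1]
        if n < 1:
            raise ValueError("chunk must contain at least one token")
        if self.attention.shape != (n, n):
            raise ValueError(
                f"attention shape {self.attention.shape} does not match "
                f"token count {n}"
            )
        if np.any(self.attention < 0):
            raise ValueError("attention entries must be nonnegative")
        rowsum = self.attention.sum(axis=1)
        if not np.allclose(rowsum, 1.0, atol=1e-6):
            raise ValueError("attention rows must sum to 1 (tolerance 1e-6)")

    @property
    def n_tokens(self) -> int:
        return self.token_embeddings.shape[1]

    @property
    def dim(self) -> int:
        return self.token_embeddings.shape[0]


@dataclass
class NoteVector:
    """Pooled vector for a note (or a patient after chunk averaging)."""

    values: NDArray[np.floating]
    patient_id: str | None = None
    chunk_count: int = 1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


def chunk_text(text: str, max_chars: int = 1024) -> list[str]:
    """Split ``text`` into contiguous chunks of at most ``max_chars``.

    Split points prefer the last whitespace inside each window so words are
    kept intact; a hard split at ``max_chars`` is used only when the window
    contains no whitespace.  The concatenation of the returned chunks equals
    the input exactly.
    """
    if max_chars < 1:
        raise ValueError("max_chars must be >= 1")
    if not text:
        raise ValueError("cannot chunk an empty note")
    chunks: list[str] = []
    pos = 0
    while pos < len(text):
        if len(text) - pos <= max_chars:
            chunks.append(text[pos:])
            break
        window = text[pos : pos + max_chars]
        # rfind over the window proper; split after the last whitespace
        cut = -1
        for i in range(len(window) - 1, -1, -1):
            if window[i].isspace():
                cut = i + 1
                break
        if cut <= 0:
            cut = max_chars
        chunks.append(text[pos : pos + cut])
        pos += cut
    return chunks


def spacing_entropy(sample: ArrayLike, window: int | None = None) -> float:
    """Differential entropy of a 1-D sample via order-statistic spacings.

    Implements the Ebrahimi–Pflughoeft–Soofi estimator: with order
    statistics ``x_(1..n)``, window ``m`` (default ``floor(sqrt(n) + 0.5)``)
    and boundary convention ``x_(j) = x_(1)`` for ``j < 1`` and ``x_(n)`` for
    ``j > n``,

        H = (1/n) * sum_i log( n * (x_(i+m) - x_(i-m)) / (c_i * m) )

    with boundary-corrected coefficients ``c_i = 1 + (i-1)/m`` for
    ``i <= m``, ``2`` for ``m < i <= n-m`` and ``1 + (n-i)/m`` for
    ``i > n-m``.  Zero spacings (tied values) are clamped at machine epsilon
    so the estimate stays finite; heavily tied samples are therefore pushed
    toward a large negative value rather than ``-inf``.
    """
    x = np.sort(np.asarray(sample, dtype=float))
    n = x.size
    if n < MIN_SAMPLE_SIZE:
        raise ValueError(f"spacing entropy needs n >= {MIN_SAMPLE_SIZE}, got {n}")
    if not np.all(np.isfinite(x)):
        raise ValueError("sample contains non-finite values")
    m = int(math.sqrt(n) + 0.5) if window is None else int(window)
    if m < 1 or m >= n:
        raise ValueError(f"window m={m} out of range for n={n}")
    i = np.arange(1, n + 1)
    upper = np.minimum(i + m, n) - 1
    lower = np.maximum(i - m, 1) - 1
    spacings = x[upper] - x[lower]
    spacings = np.maximum(spacings, np.finfo(float).eps)
    c = np.full(n, 2.0)
    head = i <= m
    tail = i > n - m
    c[head] = 1.0 + (i[head] - 1) / m
    c[tail] = 1.0 + (n - i[tail]) / m
    return float(np.mean(np.log(n * spacings / (c * m))))


def row_entropies(attention: ArrayLike) -> NDArray[np.float64]:
    """Spacing-estimator entropy of every attention row."""
    A = np.asarray(attention, dtype=float)
    if A.ndim != 2:
        raise ValueError("attention must be a 2-D matrix")
    out = np.empty(A.shape[0])
    for idx, row in enumerate(A):
        try:
            out[idx] = spacing_entropy(row)
        except ValueError as exc:
            raise ValueError(f"attention row {idx}: {exc}") from exc
    return out


def entropy_softmax_weights(entropies: ArrayLike) -> NDArray[np.float64]:
    """Softmax of per-row entropies; higher entropy -> higher weight."""
    h = np.asarray(entropies, dtype=float)
    if not np.all(np.isfinite(h)):
        raise ValueError("entropies must be finite")
    z = np.exp(h - h.max())
    return z / z.sum()


def pool_chunk(chunk: ChunkEncoding, mode: str = "entropy_weighted") -> NoteVector:
    """Collapse one chunk's token embeddings into a single note vector.

    ``entropy_weighted`` computes ``N = E @ w`` with ``w`` the softmaxed
    per-row attention entropies; ``simple_mean`` is the arithmetic mean over
    tokens.  Chunks too short for the spacing estimator (< 4 tokens) fall
    back to the simple mean with a logged warning.
    """
    if mode not in ("entropy_weighted", "simple_mean"):
        raise ValueError(f"unknown pooling mode {mode!r}")
    E = chunk.token_embeddings
    if mode == "entropy_weighted" and chunk.n_tokens < MIN_SAMPLE_SIZE:
        logger.warning(
            "chunk has %d tokens (< %d); falling back to simple mean",
            chunk.n_tokens,
            MIN_SAMPLE_SIZE,
        )
        mode = "simple_mean"
    if mode == "simple_mean":
        return NoteVector(E.mean(axis=1))
    w = entropy_softmax_weights(row_entropies(chunk.attention))
    return NoteVector(E @ w)


def patient_vector(chunks: list[NoteVector], patient_id: str | None = None) -> NoteVector:
    """Arithmetic mean of per-chunk note vectors for one patient."""
    if not chunks:
        raise ValueError("patient has no pooled chunks")
    dims = {c.values.shape for c in chunks}
    if len(dims) != 1:
        raise ValueError(f"inconsistent chunk dimensions: {sorted(dims)}")
    stacked = np.stack([c.values for c in chunks])
    return NoteVector(stacked.mean(axis=0), patient_id=patient_id, chunk_count=len(chunks))
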