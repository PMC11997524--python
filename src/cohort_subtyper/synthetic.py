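"""Synthetic EHR cohort with planted subtype and provider structure.

Emulates the three inputs of the subtyping pipeline so every stage is
testable without access to protected health data:

1. long-format diagnosis records (patient, code, count) drawn per subtype
   from a planted Dirichlet code profile, plus a pretrained-style code
   embedding table in which each subtype's marker codes point along a
   subtype-specific direction;
2. per-note-chunk token-embedding matrices with head-averaged, row-stochastic
   attention matrices whose rows have heterogeneous entropies (softmax of
   Gaussian logits at a per-row log-uniform temperature), with an additive
   provider offset in token-embedding space emulating clinician style;
3. per-patient demographics (sex, age of onset, diagnosis category) drawn
   per subtype.

The true subtype labels never enter any pipeline input file; they are kept
out-of-band (a separate truth file) for evaluation only.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .note_pooling import ChunkEncoding

__all__ = ["CohortConfig", "SyntheticCohort", "generate_cohort", "write_cohort", "read_cohort"]

#: Diagnosis categories used for the planted dx-category distributions.
DX_CATEGORIES = ["AD", "dementia_unspecified", "FTD", "LBD", "VCI", "other"]


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort.

    Scales are in the units of the corresponding embedding space; ages are
    in years.  ``subtype_separation`` is the distance between subtype mean
    directions in embedding space, ``provider_shift_scale`` the magnitude of
    the additive per-provider offset on token embeddings.
    """

    n_patients: int = 300
    n_subtypes: int = 3
    n_codes: int = 120
    n_excluded_codes: int = 6
    embed_dim_codes: int = 300
    embed_dim_tokens: int = 768
    tokens_per_chunk: tuple[int, int] = (12, 32)
    chunks_per_patient: tuple[int, int] = (1, 2)
    n_providers: int = 4
    provider_shift_scale: float = 1.0
    subtype_separation: float = 4.0
    code_concentration: float = 1.0
    marker_boost: float = 10.0
    mean_codes_per_patient: int = 30
    token_noise_scale: float = 1.0
    sex_prob_by_subtype: tuple[float, ...] | None = None
    age_mean_by_subtype: tuple[float, ...] | None = None
    age_sd_by_subtype: tuple[float, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        K = self.n_subtypes
        for name in ("n_patients", "n_subtypes", "n_codes", "n_excluded_codes",
                     "embed_dim_codes", "embed_dim_tokens", "n_providers",
                     "mean_codes_per_patient"):
            if getattr(self, name) < 1:
                raise ValueError(f"invalid config: {name} must be a positive integer")
        if K < 2:
            raise ValueError("invalid config: n_subtypes must be >= 2")
        if self.n_excluded_codes >= self.n_codes:
            raise ValueError("invalid config: n_excluded_codes must leave non-excluded codes")
        for name in ("provider_shift_scale", "subtype_separation", "token_noise_scale"):
            if getattr(self, name) < 0:
                raise ValueError(f"invalid config: {name} must be nonnegative")
        if self.code_concentration <= 0 or self.marker_boost <= 0:
            raise ValueError("invalid config: code_concentration and marker_boost must be positive")
        for name in ("tokens_per_chunk", "chunks_per_patient"):
            lo, hi = getattr(self, name)
            if lo < 1 or hi < lo:
                raise ValueError(f"invalid config: {name} must be a positive (lo, hi) range")
        # per-subtype demographic defaults: sex skew, early/late onset spread
        if self.sex_prob_by_subtype is None:
            base = [0.47, 0.40, 0.62, 0.55, 0.35]
            self.sex_prob_by_subtype = tuple(base[k % len(base)] for k in range(K))
        if self.age_mean_by_subtype is None:
            base = [73.6, 69.8, 75.5, 71.0, 74.0]
            self.age_mean_by_subtype = tuple(base[k % len(base)] for k in range(K))
        if self.age_sd_by_subtype is None:
            base = [9.1, 9.6, 8.1, 9.0, 8.5]
            self.age_sd_by_subtype = tuple(base[k % len(base)] for k in range(K))
        for name in ("sex_prob_by_subtype", "age_mean_by_subtype", "age_sd_by_subtype"):
            if len(getattr(self, name)) != K:
                raise ValueError(f"invalid config: {name} must have length n_subtypes")
        if any(not 0 <= p <= 1 for p in self.sex_prob_by_subtype):
            raise ValueError("invalid config: sex_prob_by_subtype entries must lie in [0, 1]")
        if any(s < 0 for s in self.age_sd_by_subtype):
            raise ValueError("invalid config: age_sd_by_subtype entries must be nonnegative")


@dataclass
class SyntheticCohort:
    """Generated cohort; ``true_subtype`` is evaluation-only ground truth."""

    records: pd.DataFrame  # patient_id, code, count
    code_embeddings: pd.DataFrame  # index code, columns e0..e{d-1}
    chunk_encodings: dict[str, list[ChunkEncoding]]
    provider_of: dict[str, str]
    sex_of: dict[str, str]
    age_of: dict[str, float]
    dx_category_of: dict[str, str]
    excluded_codes: list[str]
    true_subtype: dict[str, int] | None = None
    code_profiles: np.ndarray | None = None  # K x n_nonexcluded planted profiles
    nonexcluded_codes: list[str] | None = None

    @property
    def patient_ids(self) -> list[str]:
        return sorted(self.provider_of)

    def demographics_frame(self) -> pd.DataFrame:
        pids = self.patient_ids
        return pd.DataFrame(
            {
                "patient_id": pids,
                "provider_id": [self.provider_of[p] for p in pids],
                "sex": [self.sex_of[p] for p in pids],
                "age_of_onset": [self.age_of[p] for p in pids],
                "dx_category": [self.dx_category_of[p] for p in pids],
            }
        )


def _orthonormal_directions(rng: np.random.Generator, k: int, dim: int) -> np.ndarray:
    """k mutually orthogonal unit vectors in R^dim."""
    if k > dim:
        raise ValueError("cannot place more orthogonal directions than dimensions")
    M = rng.normal(size=(dim, k))
    Q, _ = np.linalg.qr(M)
    return Q.T[:k]


def _dx_probs(rng: np.random.Generator, K: int) -> np.ndarray:
    """Subtype-tilted diagnosis-category distributions."""
    base = np.array([0.38, 0.32, 0.055, 0.076, 0.028, 0.141])
    base = base / base.sum()
    probs = np.empty((K, len(base)))
    for k in range(K):
        tilt = np.ones(len(base))
        tilt[(2 + k) % len(base)] = 3.0  # each subtype over-represents one category
        p = base * tilt
        probs[k] = p / p.sum()
    return probs


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Draw a full cohort deterministically from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    K = config.n_subtypes
    n_ex = config.n_excluded_codes
    excluded = [f"DXI{j:03d}" for j in range(n_ex)]  # condition-of-interest codes
    regular = [f"C{j:03d}" for j in range(config.n_codes - n_ex)]
    n_reg = len(regular)

    # planted Dirichlet code profile per subtype: each subtype boosts one
    # contiguous marker block of the regular vocabulary
    block = max(1, n_reg // (2 * K))
    alphas = np.full((K, n_reg), config.code_concentration)
    marker_slices = []
    for k in range(K):
        sl = slice(k * block, (k + 1) * block)
        alphas[k, sl] *= config.marker_boost
        marker_slices.append(sl)
    profiles = np.vstack([rng.dirichlet(alphas[k]) for k in range(K)])

    # code embeddings: isotropic base + marker-block shift along a
    # subtype-specific orthogonal direction so count-weighted sums separate
    d_code = config.embed_dim_codes
    code_dirs = _orthonormal_directions(rng, K, d_code)
    emb = rng.normal(scale=1.0 / np.sqrt(d_code), size=(n_reg + n_ex, d_code))
    for k in range(K):
        emb[marker_slices[k], :] += config.subtype_separation * code_dirs[k]
    all_codes = regular + excluded
    code_embeddings = pd.DataFrame(
        emb, index=all_codes, columns=[f"e{i}" for i in range(d_code)]
    )
    code_embeddings.index.name = "code"

    # patients
    pids = [f"P{i:04d}" for i in range(config.n_patients)]
    subtype = rng.integers(0, K, size=config.n_patients)
    providers = [f"prov{j}" for j in range(config.n_providers)]
    provider_idx = rng.integers(0, config.n_providers, size=config.n_patients)

    rec_rows: list[tuple[str, str, int]] = []
    for i, pid in enumerate(pids):
        k = subtype[i]
        total = max(5, int(rng.poisson(config.mean_codes_per_patient)))
        counts = rng.multinomial(total, profiles[k])
        for j in np.flatnonzero(counts):
            rec_rows.append((pid, regular[j], int(counts[j])))
        # every patient also carries 1-2 condition-of-interest codes
        for j in rng.choice(n_ex, size=int(rng.integers(1, 3)), replace=False):
            rec_rows.append((pid, excluded[j], int(rng.integers(1, 6))))
    records = pd.DataFrame(rec_rows, columns=["patient_id", "code", "count"])

    # note chunks: token columns = subtype mean + provider offset + noise;
    # attention rows = softmax of Gaussian logits at log-uniform temperature
    d_tok = config.embed_dim_tokens
    tok_dirs = _orthonormal_directions(rng, K, d_tok)
    subtype_means = config.subtype_separation * tok_dirs
    prov_vecs = rng.normal(size=(config.n_providers, d_tok))
    prov_vecs /= np.linalg.norm(prov_vecs, axis=1, keepdims=True)
    prov_offsets = config.provider_shift_scale * prov_vecs

    lo_c, hi_c = config.chunks_per_patient
    lo_t, hi_t = config.tokens_per_chunk
    chunk_encodings: dict[str, list[ChunkEncoding]] = {}
    for i, pid in enumerate(pids):
        k = subtype[i]
        p = provider_idx[i]
        n_chunks = int(rng.integers(lo_c, hi_c + 1))
        chunks = []
        for _ in range(n_chunks):
            n_tok = int(rng.integers(lo_t, hi_t + 1))
            E = (
                subtype_means[k][:, None]
                + prov_offsets[p][:, None]
                + config.token_noise_scale * rng.normal(size=(d_tok, n_tok))
            )
            temps = np.exp(rng.uniform(np.log(0.05), np.log(5.0), size=n_tok))
            logits = rng.normal(size=(n_tok, n_tok))
            A = np.exp(logits / temps[:, None])
            A /= A.sum(axis=1, keepdims=True)
            chunks.append(ChunkEncoding(token_embeddings=E, attention=A))
        chunk_encodings[pid] = chunks

    # demographics
    sex_p = np.asarray(config.sex_prob_by_subtype)
    dxp = _dx_probs(rng, K)
    sex_of, age_of, dx_of, prov_of, truth = {}, {}, {}, {}, {}
    for i, pid in enumerate(pids):
        k = subtype[i]
        sex_of[pid] = "F" if rng.random() < sex_p[k] else "M"
        age_of[pid] = float(
            rng.normal(config.age_mean_by_subtype[k], config.age_sd_by_subtype[k])
        )
        dx_of[pid] = DX_CATEGORIES[rng.choice(len(DX_CATEGORIES), p=dxp[k])]
        prov_of[pid] = providers[provider_idx[i]]
        truth[pid] = int(k)

    return SyntheticCohort(
        records=records,
        code_embeddings=code_embeddings,
        chunk_encodings=chunk_encodings,
        provider_of=prov_of,
        sex_of=sex_of,
        age_of=age_of,
        dx_category_of=dx_of,
        excluded_codes=excluded,
        true_subtype=truth,
        code_profiles=profiles,
        nonexcluded_codes=regular,
    )


def write_cohort(cohort: SyntheticCohort, directory: str | Path) -> None:
    """Write the cohort's pipeline inputs; truth labels go to a separate file."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    cohort.records.to_csv(d / "records.csv", index=False)
    cohort.code_embeddings.to_csv(d / "code_embeddings.tsv", sep="\t")
    cohort.demographics_frame().to_csv(d / "demographics.csv", index=False)
    (d / "excluded_codes.txt").write_text("\n".join(cohort.excluded_codes) + "\n")
    arrays: dict[str, np.ndarray] = {}
    for pid, chunks in cohort.chunk_encodings.items():
        for ci, ch in enumerate(chunks):
            arrays[f"{pid}__{ci}__emb"] = ch.token_embeddings
            arrays[f"{pid}__{ci}__att"] = ch.attention
    np.savez_compressed(d / "chunks.npz", **arrays)
    if cohort.true_subtype is not None:
        pids = cohort.patient_ids
        pd.DataFrame(
            {"patient_id": pids, "subtype": [cohort.true_subtype[p] for p in pids]}
        ).to_csv(d / "truth.csv", index=False)


def _read_records(path: Path) -> pd.DataFrame:
    rows = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if header != ["patient_id", "code", "count"]:
            raise ValueError(f"{path}:1: expected header patient_id,code,count")
        for lineno, row in enumerate(reader, start=2):
            if len(row) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 fields, got {len(row)}")
            try:
                count = int(row[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: count is not an integer: {row[2]!r}") from exc
            if count < 0:
                raise ValueError(f"{path}:{lineno}: negative count {count}")
            rows.append((row[0], row[1], count))
    return pd.DataFrame(rows, columns=["patient_id", "code", "count"])


def read_cohort(directory: str | Path) -> SyntheticCohort:
    """Load a cohort written by :func:`write_cohort`.

    The truth file is optional: without it the cohort loads with
    ``true_subtype`` unset.
    """
    d = Path(directory)
    records = _read_records(d / "records.csv")
    code_embeddings = pd.read_csv(d / "code_embeddings.tsv", sep="\t", index_col="code")
    demo = pd.read_csv(d / "demographics.csv", dtype={"patient_id": str})
    excluded = [
        line for line in (d / "excluded_codes.txt").read_text().splitlines() if line
    ]
    chunk_encodings: dict[str, list[ChunkEncoding]] = {}
    with np.load(d / "chunks.npz") as npz:
        per_patient: dict[str, dict[int, dict[str, np.ndarray]]] = {}
        for key in npz.files:
            pid, ci, kind = key.rsplit("__", 2)
            per_patient.setdefault(pid, {}).setdefault(int(ci), {})[kind] = npz[key]
        for pid, by_chunk in per_patient.items():
            chunk_encodings[pid] = [
                ChunkEncoding(
                    token_embeddings=by_chunk[ci]["emb"], attention=by_chunk[ci]["att"]
                )
                for ci in sorted(by_chunk)
            ]
    truth = None
    truth_path = d / "truth.csv"
    if truth_path.exists():
        tf = pd.read_csv(truth_path, dtype={"patient_id": str})
        truth = dict(zip(tf["patient_id"], tf["subtype"].astype(int)))
    return SyntheticCohort(
        records=records,
        code_embeddings=code_embeddings,
        chunk_encodings=chunk_encodings,
        provider_of=dict(zip(demo["patient_id"], demo["provider_id"])),
        sex_of=dict(zip(demo["patient_id"], demo["sex"])),
        age_of=dict(zip(demo["patient_id"], demo["age_of_onset"].astype(float))),
        dx_category_of=dict(zip(demo["patient_id"], demo["dx_category"])),
        excluded_codes=excluded,
        true_subtype=truth,
    )
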