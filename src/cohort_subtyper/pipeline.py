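"""End-to-end orchestration of the two subtyping arms.

The ICD arm clusters the full count-weighted code-embedding design matrix;
the note arm pools chunk encodings per patient, reduces to 2-D, removes the
provider batch effect by optimal transport, and clusters the aligned 2-D
points.  Both arms end with the same demographic characterization (sex
chi-square, Kruskal–Wallis age of onset with Dunn post hoc, diagnosis-
category enrichment), and the two labelings are cross-tabulated to check
cross-modality correspondence.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import alignment, clustering, icd_design, note_pooling, stats, topics
from .synthetic import SyntheticCohort, read_cohort

__all__ = ["RunConfig", "ArmResult", "run_icd_arm", "run_note_arm", "compare_arms", "run"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Run parameters; every analysis choice the method leaves open is here."""

    input_dir: str = "."
    output_dir: str = "out"
    arm: str = "both"  # icd | note | both
    seed: int = 0
    pooling_mode: str = "entropy_weighted"
    reducer_backend: str = "umap"
    reducer_n_neighbors: int = 15
    reducer_min_dist: float = 0.1
    align_reference: str | None = None  # None -> largest provider
    k_min: int = 2
    k_max: int = 10
    enrichment_correction: str = "bonferroni"
    characterization_correction: str = "bh"
    alpha: float = 0.05
    top_n: int = 10
    max_df: float = 0.8
    normalize_design: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class ArmResult:
    labels: pd.Series  # patient_id -> cluster
    assignment: clustering.ClusterAssignment
    diagnostics: dict
    enrichment: list[stats.EnrichmentResult] = field(default_factory=list)
    top_codes: dict[int, list[stats.EnrichmentResult]] = field(default_factory=dict)
    demographics: dict = field(default_factory=dict)


def _stage(name: str):
    logger.info("stage %s", name)


def _characterize_demographics(
    cohort: SyntheticCohort, labels: pd.Series, config: RunConfig
) -> dict:
    """Sex chi-square + PR, age-of-onset KW/eta2 + Dunn, dx-category enrichment."""
    pids = list(labels.index)
    lab = labels.to_numpy()
    out: dict = {}
    # sex: one Yates 2x2 per cluster (female in cluster vs rest)
    sex = np.array([cohort.sex_of[p] == "F" for p in pids])
    sex_rows = []
    for c in np.unique(lab):
        in_c = lab == c
        a, b = int(np.sum(sex & in_c)), int(np.sum(~sex & in_c))
        cc, d = int(np.sum(sex & ~in_c)), int(np.sum(~sex & ~in_c))
        t = stats.ContingencyTable(np.array([[a, b], [cc, d]]))
        chi2, p = stats.chi2_2x2_yates(t)
        sex_rows.append(
            {"cluster": int(c), "chi2": chi2, "p_raw": p,
             "pr_female": stats.prevalence_ratio(t)}
        )
    padj = stats.adjust_p([r["p_raw"] for r in sex_rows], config.characterization_correction)
    for r, pa in zip(sex_rows, padj):
        r["p_adjusted"] = float(pa)
    out["sex"] = sex_rows
    # age of onset
    ages = np.array([cohort.age_of[p] for p in pids])
    kw = stats.kruskal_wallis_eta2(ages, lab)
    out["age_of_onset"] = {
        "H": kw.H, "df": kw.df, "p": kw.p, "eta_squared": kw.eta_squared,
        "dunn": stats.dunn_posthoc(ages, lab).to_dict(orient="records"),
    }
    # diagnosis-category enrichment (binary per category)
    cats = sorted({cohort.dx_category_of[p] for p in pids})
    presence = pd.DataFrame(
        {cat: [int(cohort.dx_category_of[p] == cat) for p in pids] for cat in cats},
        index=pids,
    )
    out["dx_category"] = stats.code_enrichment(
        presence, lab, correction=config.characterization_correction
    )
    return out


def run_icd_arm(cohort: SyntheticCohort, config: RunConfig) -> ArmResult:
    """Count matrix -> design matrix -> Ward/silhouette -> code enrichment."""
    _stage("build_count_matrix")
    P = icd_design.build_count_matrix(cohort.records, set(cohort.excluded_codes))
    _stage("compose_design")
    E = icd_design.CodeEmbeddingMatrix.from_frame(cohort.code_embeddings)
    X = icd_design.compose_design(P, E, normalize=config.normalize_design)
    _stage("select_k")
    assignment, diagnostics = clustering.select_k(X.values, config.k_min, config.k_max)
    labels = pd.Series(assignment.labels, index=X.patient_index, name="cluster")
    _stage("code_enrichment")
    presence = P.presence().loc[X.patient_index]
    enrichment = stats.code_enrichment(
        presence, labels.to_numpy(), correction=config.enrichment_correction
    )
    top = {
        c: stats.select_top_codes(
            [r for r in enrichment if r.cluster == c], n=config.top_n, alpha=config.alpha
        )
        for c in range(assignment.k)
    }
    demo = _characterize_demographics(cohort, labels, config)
    return ArmResult(
        labels=labels,
        assignment=assignment,
        diagnostics=diagnostics,
        enrichment=enrichment,
        top_codes=top,
        demographics=demo,
    )


def run_note_arm(cohort: SyntheticCohort, config: RunConfig) -> ArmResult:
    """Pool chunks -> 2-D reduction -> provider alignment -> Ward/silhouette."""
    _stage("pool_chunks")
    pids = cohort.patient_ids
    vectors = []
    for pid in pids:
        chunks = cohort.chunk_encodings.get(pid)
        if not chunks:
            raise ValueError(f"patient {pid} has no note chunks")
        pooled = [note_pooling.pool_chunk(ch, mode=config.pooling_mode) for ch in chunks]
        vectors.append(note_pooling.patient_vector(pooled, patient_id=pid).values)
    V = np.vstack(vectors)
    _stage("reduce_2d")
    reduced = alignment.reduce_2d(
        V,
        pids,
        cohort.provider_of,
        backend=config.reducer_backend,
        seed=config.seed,
        n_neighbors=config.reducer_n_neighbors,
        min_dist=config.reducer_min_dist,
    )
    _stage("align_providers")
    aligned = alignment.align_providers(reduced, reference=config.align_reference)
    _stage("select_k")
    assignment, diagnostics = clustering.select_k(aligned.points, config.k_min, config.k_max)
    labels = pd.Series(assignment.labels, index=pids, name="cluster")
    demo = _characterize_demographics(cohort, labels, config)
    return ArmResult(
        labels=labels,
        assignment=assignment,
        diagnostics={**diagnostics, "reference_provider": aligned.reference_provider},
        demographics=demo,
    )


def compare_arms(labels_icd: pd.Series, labels_note: pd.Series) -> stats.CrossTabReport:
    """Cross-tabulate the two cluster solutions on their common patients."""
    common = labels_icd.index.intersection(labels_note.index)
    if len(common) == 0:
        raise ValueError("no overlapping patients between arms")
    return stats.cross_tabulate(
        labels_note.loc[common].to_numpy(),
        labels_icd.loc[common].to_numpy(),
        names=("note", "icd"),
    )


def _enrichment_frame(results: list[stats.EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cluster": r.cluster,
                "feature": r.feature,
                "chi2": r.chi2,
                "df": r.df,
                "p_raw": r.p_raw,
                "p_adjusted": r.p_adjusted,
                "prevalence_ratio": r.prevalence_ratio,
                "a": r.counts[0], "b": r.counts[1], "c": r.counts[2], "d": r.counts[3],
            }
            for r in results
        ]
    )


def run(config: RunConfig) -> dict:
    """Run the configured arm(s) on the cohort in ``config.input_dir``.

    Writes labels, enrichment tables, diagnostics, and (for arm=both) the
    cross-modality report into ``config.output_dir``; returns the in-memory
    results keyed by arm.
    """
    cohort = read_cohort(config.input_dir)
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    if config.arm in ("icd", "both"):
        res = run_icd_arm(cohort, config)
        results["icd"] = res
        res.labels.rename_axis("patient_id").to_csv(out_dir / "icd_labels.csv")
        _enrichment_frame(res.enrichment).to_csv(out_dir / "icd_enrichment.tsv", sep="\t", index=False)
    if config.arm in ("note", "both"):
        res = run_note_arm(cohort, config)
        results["note"] = res
        res.labels.rename_axis("patient_id").to_csv(out_dir / "note_labels.csv")
    if config.arm == "both":
        report = compare_arms(results["icd"].labels, results["note"].labels)
        results["comparison"] = report
        payload = {
            "seed": config.seed,
            "observed": report.table.observed.tolist(),
            "row_labels": report.table.row_labels,
            "col_labels": report.table.col_labels,
            "chi2": report.chi2,
            "df": report.df,
            "p": report.p,
            "cramers_v": report.cramers_v,
            "adjusted_residuals": report.adjusted_residuals.tolist(),
            "residual_p_adjusted": report.residual_p_adjusted.tolist(),
        }
        (out_dir / "cross_tab.json").write_text(json.dumps(payload, indent=2))
    return results
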