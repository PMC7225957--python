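"""End-to-end orchestration of the subtyping analysis.

Stages, in order: preprocess (zero filter, standardize, assemble) ->
autoencoder -> univariate Cox screening of bottleneck features -> cluster
number selection -> K-means -> risk orientation (Kaplan-Meier / log-rank)
-> ANOVA ranking on the training split -> classifier sweep and comparison
grids -> differential expression -> preranked GSEA (when gene sets are
given) -> covariate association tables. Every random stage draws a child
seed derived deterministically from the global seed and the stage name, so
a pipeline run is reproducible from its config alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .autoencoder import AEConfig, encode, train_autoencoder
from .cohort import CohortConfig, SyntheticCohort, simulate_cohort
from .enrich import GeneSetCollection, preranked_gsea
from .matrix import ExpressionMatrix, MIRNA, RNA, read_clinical_tsv
from .preprocess import PreprocessConfig, preprocess_cohort
from .rankclassify import (ClassifierSpec, SplitSpec, anova_rank,
                           hyperparameter_grid, stratified_split,
                           sweep_feature_counts, train_eval)
from .diffexpr import differential_expression, top_k
from .subtype import choose_k, evaluate_k_range, kmeans_cluster, orient_risk_labels
from .survstats import records_from_clinical, select_survival_features
from .assoc import covariate_table, fisher_exact

logger = logging.getLogger(__name__)


def child_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


@dataclass
class PipelineConfig:
    # either synthetic generation ...
    cohort: CohortConfig | None = None
    # ... or paths to real TSV inputs
    rna_path: str | None = None
    mirna_path: str | None = None
    clinical_path: str | None = None
    gene_sets_path: str | None = None

    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    autoencoder: AEConfig = field(default_factory=AEConfig)
    screening_alpha: float = 0.05
    k_min: int = 1
    k_max: int = 10
    kmeans_restarts: int = 50
    split: SplitSpec = field(default_factory=SplitSpec)
    classifier: ClassifierSpec = field(default_factory=lambda: ClassifierSpec("svm"))
    top_m_mirna: int = 20
    top_n_rna: int = 25
    comparison_families: tuple = ("knn", "rf", "lr")
    gsea_n_perm: int = 200
    de_top_k: int = 25
    outdir: str | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.cohort is None and (self.rna_path is None or self.mirna_path is None
                                    or self.clinical_path is None):
            raise ValueError("provide either a synthetic cohort config or "
                             "rna/mirna/clinical paths")


@dataclass
class PipelineResult:
    matrix: ExpressionMatrix
    latent: pd.DataFrame
    selected_features: list
    cox_table: pd.DataFrame
    k_choice: object
    cluster_labels: pd.Series
    risk_labels: pd.Series
    logrank_p: float
    ranking: pd.DataFrame
    sweep: pd.DataFrame
    primary_eval: object
    comparison_grids: dict
    de_table: pd.DataFrame
    de_top: pd.DataFrame
    enrichment: pd.DataFrame | None
    associations: pd.DataFrame
    summary: dict


def _load_inputs(config: PipelineConfig):
    if config.cohort is not None:
        cohort = simulate_cohort(config.cohort)
        return cohort.rna, cohort.mirna, cohort.clinical, cohort
    rna = ExpressionMatrix.from_tsv(config.rna_path, feature_class=RNA)
    mirna = ExpressionMatrix.from_tsv(config.mirna_path, feature_class=MIRNA)
    clinical = read_clinical_tsv(config.clinical_path)
    return rna, mirna, clinical, None


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    config.validate()
    rna_raw, mirna_raw, clinical, cohort = _load_inputs(config)

    logger.info("stage: preprocess")
    matrix, prep_report = preprocess_cohort(rna_raw, mirna_raw, config.preprocess)
    clinical = clinical.loc[matrix.patients]
    records = records_from_clinical(clinical)

    logger.info("stage: autoencoder")
    ae_cfg = dataclasses.replace(config.autoencoder,
                                 seed=child_seed(config.seed, "autoencoder"))
    model = train_autoencoder(matrix, ae_cfg)
    latent = encode(model, matrix)

    logger.info("stage: cox screening")
    selected, cox_table = select_survival_features(latent, records,
                                                   config.screening_alpha)
    Z = latent[selected]

    logger.info("stage: cluster-number selection")
    evals = evaluate_k_range(Z, config.k_min, config.k_max,
                             restarts=config.kmeans_restarts,
                             seed=child_seed(config.seed, "evaluate_k"))
    kc = choose_k(evals)

    logger.info("stage: k-means (k=%d)", kc.k)
    clusters = kmeans_cluster(Z, kc.k, restarts=config.kmeans_restarts,
                              seed=child_seed(config.seed, "kmeans"))
    orientation = orient_risk_labels(clusters, records)
    risk = orientation.risk_labels

    logger.info("stage: ANOVA ranking + classifiers")
    split_spec = dataclasses.replace(config.split,
                                     seed=child_seed(config.seed, "split"))
    train_ids, test_ids = stratified_split(matrix.patients, risk, split_spec)
    ranking = anova_rank(matrix.subset_patients(train_ids), risk.loc[train_ids])
    clf_seed = child_seed(config.seed, "classifier")
    sweep = sweep_feature_counts(matrix, risk, train_ids, test_ids, ranking,
                                 spec=config.classifier, seed=clf_seed)
    primary = train_eval(matrix, risk, train_ids, test_ids, ranking,
                         config.top_m_mirna, config.top_n_rna,
                         config.classifier, seed=clf_seed)
    grids = {}
    for family in config.comparison_families:
        grids[family] = hyperparameter_grid(
            matrix, risk, train_ids, test_ids, ranking, family,
            config.top_m_mirna, config.top_n_rna, seed=clf_seed)

    logger.info("stage: differential expression")
    rna_for_de = rna_raw.subset_patients(matrix.patients)
    de = differential_expression(rna_for_de, risk)
    de_top = top_k(de, config.de_top_k)

    enrichment = None
    if config.gene_sets_path is not None:
        logger.info("stage: preranked GSEA")
        sets = GeneSetCollection.from_gmt(config.gene_sets_path)
        stat = de.set_index("feature")["t"]
        enrichment = preranked_gsea(stat, sets, n_perm=config.gsea_n_perm,
                                    seed=child_seed(config.seed, "gsea"))

    logger.info("stage: covariate associations")
    assoc_rows = []
    for col in clinical.columns:
        if col in ("time_days", "event"):
            continue
        vals = clinical[col].dropna().unique()
        if set(vals) <= {0, 1}:
            tab = covariate_table(clinical[col], risk)
            odds, p = fisher_exact(tab)
            assoc_rows.append({"covariate": col, "rate_high": tab.rate_high,
                               "rate_low": tab.rate_low, "odds_ratio": odds,
                               "fisher_p": p})
    associations = pd.DataFrame(assoc_rows)

    summary = {
        "version": __version__,
        "seed": config.seed,
        "n_patients": matrix.n_patients,
        "n_features": matrix.n_features,
        "preprocess": {k: {kk: vv for kk, vv in v.items()
                           if not kk.startswith("dropped")} if isinstance(v, dict) else v
                       for k, v in prep_report.items()},
        "n_selected_latent": len(selected),
        "chosen_k": kc.k,
        "k_conflict": kc.conflict,
        "logrank_p": orientation.logrank_p,
        "n_high_risk": int((risk == "high-risk").sum()),
        "n_low_risk": int((risk == "low-risk").sum()),
        "svm_test_accuracy": primary.test_accuracy,
        "svm_train_accuracy": primary.train_accuracy,
        "confusion": {"tp": primary.tp, "fn": primary.fn,
                      "fp": primary.fp, "tn": primary.tn},
        "best_comparison_accuracy": {
            fam: float(g["test_accuracy"].max()) for fam, g in grids.items()},
    }
    if cohort is not None:
        from sklearn.metrics import adjusted_rand_score
        ari = adjusted_rand_score(cohort.true_labels.loc[risk.index], risk)
        summary["true_label_ari"] = float(ari)

    result = PipelineResult(
        matrix=matrix, latent=latent, selected_features=selected,
        cox_table=cox_table, k_choice=kc, cluster_labels=clusters,
        risk_labels=risk, logrank_p=orientation.logrank_p, ranking=ranking,
        sweep=sweep, primary_eval=primary, comparison_grids=grids,
        de_table=de, de_top=de_top, enrichment=enrichment,
        associations=associations, summary=summary)

    if config.outdir is not None:
        _write_bundle(result, Path(config.outdir))
    return result


def _write_bundle(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"cluster": result.cluster_labels,
                  "risk_label": result.risk_labels}).to_csv(
        outdir / "labels.tsv", sep="\t", index_label="patient_id")
    result.cox_table.to_csv(outdir / "cox_screen.tsv", sep="\t")
    result.sweep.to_csv(outdir / "feature_sweep.tsv", sep="\t", index=False)
    for fam, grid in result.comparison_grids.items():
        grid.to_csv(outdir / f"grid_{fam}.tsv", sep="\t", index=False)
    result.de_table.to_csv(outdir / "differential_expression.tsv", sep="\t",
                           index=False)
    result.de_top.to_csv(outdir / "de_top.tsv", sep="\t", index=False)
    if result.enrichment is not None:
        result.enrichment.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
    result.associations.to_csv(outdir / "associations.tsv", sep="\t", index=False)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(result.summary, fh, indent=1, sort_keys=True)
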