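"""Preprocessing: zero-fraction filtering, per-feature standardization, and
assembly of the paired RNA + miRNA matrices into one multi-omics matrix.

Zero handling drops features whose zero fraction exceeds a threshold, then
patients whose zero fraction over the surviving features exceeds a second
threshold (both default 20%). Standardization is per feature across
patients (z-score with sample standard deviation), so that downstream
Cox screening and K-means see comparable feature scales. Remaining zeros
are kept as 0 — no imputation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class PreprocessConfig:
    feature_zero_frac_max: float = 0.20
    sample_zero_frac_max: float = 0.20
    standardize: bool = True

    def validate(self) -> None:
        for name in ("feature_zero_frac_max", "sample_zero_frac_max"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass
class FilterReport:
    """Provenance of the zero filter: which ids were dropped and why."""
    dropped_features: list
    dropped_patients: list

    def to_dict(self) -> dict:
        return {"n_dropped_features": len(self.dropped_features),
                "n_dropped_patients": len(self.dropped_patients),
                "dropped_features": list(map(str, self.dropped_features)),
                "dropped_patients": list(map(str, self.dropped_patients))}


def filter_zero_features(matrix: ExpressionMatrix,
                         config: PreprocessConfig | None = None
                         ) -> tuple[ExpressionMatrix, FilterReport]:
    """Drop zero-heavy features, then zero-heavy patients.

    Features with zero fraction > ``feature_zero_frac_max`` are removed
    first; patient zero fractions are then recomputed over the surviving
    features and patients above ``sample_zero_frac_max`` removed.
    """
    config = config or PreprocessConfig()
    config.validate()
    vals = matrix.values
    if (vals.to_numpy() < 0).any():
        raise ValueError("expression matrix contains negative values")

    feat_zero_frac = (vals == 0).mean(axis=0)
    keep_feat = feat_zero_frac[feat_zero_frac <= config.feature_zero_frac_max].index
    dropped_feat = [f for f in vals.columns if f not in set(keep_feat)]
    if len(keep_feat) == 0:
        raise ValueError("all features filtered: every feature exceeds the "
                         f"zero-fraction threshold {config.feature_zero_frac_max}")
    surv = vals[keep_feat]

    pat_zero_frac = (surv == 0).mean(axis=1)
    keep_pat = pat_zero_frac[pat_zero_frac <= config.sample_zero_frac_max].index
    dropped_pat = [p for p in surv.index if p not in set(keep_pat)]
    if len(keep_pat) == 0:
        raise ValueError("all patients filtered by the sample zero-fraction rule")

    out = ExpressionMatrix(surv.loc[keep_pat].copy(),
                           matrix.feature_class.loc[keep_feat].copy())
    return out, FilterReport(dropped_feat, dropped_pat)


def standardize_features(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """z-score every feature across patients (mean 0, sample sd 1)."""
    vals = matrix.values
    sd = vals.std(axis=0, ddof=1)
    zero_var = sd[(sd == 0) | sd.isna()].index
    if len(zero_var) > 0:
        raise ValueError("zero-variance features cannot be standardized: "
                         f"{list(zero_var)[:5]}")
    z = (vals - vals.mean(axis=0)) / sd
    return ExpressionMatrix(z, matrix.feature_class.copy())


def assemble_multiomics(rna: ExpressionMatrix, mirna: ExpressionMatrix
                        ) -> ExpressionMatrix:
    """Column-concatenate RNA and miRNA matrices on their common patients.

    Patient order follows the RNA matrix; patients missing from either
    matrix are dropped with a warning. Feature ids get a class prefix
    (``RNA:`` / ``miRNA:``) so the combined ids stay unique.
    """
    common = [p for p in rna.patients if p in set(mirna.patients)]
    if not common:
        raise ValueError(
            "disjoint patient sets: rna-only "
            f"{list(rna.patients[:5])}, mirna-only {list(mirna.patients[:5])}")
    only_rna = [p for p in rna.patients if p not in set(mirna.patients)]
    only_mirna = [p for p in mirna.patients if p not in set(rna.patients)]
    if only_rna or only_mirna:
        logger.warning("dropping patients absent from one matrix: %d rna-only, "
                       "%d mirna-only", len(only_rna), len(only_mirna))

    r = rna.values.loc[common].add_prefix("RNA:")
    m = mirna.values.loc[common].add_prefix("miRNA:")
    combined = pd.concat([r, m], axis=1)
    classes = pd.concat([
        pd.Series(rna.feature_class.values, index=r.columns),
        pd.Series(mirna.feature_class.values, index=m.columns),
    ])
    return ExpressionMatrix(combined, classes)


def _drop_constant_features(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Remove zero-variance features (unstandardizable) with a warning."""
    sd = matrix.values.std(axis=0, ddof=1)
    keep = sd[(sd > 0) & sd.notna()].index
    n_drop = matrix.n_features - len(keep)
    if n_drop:
        logger.warning("dropping %d constant features before standardization", n_drop)
        return matrix.subset_features(keep)
    return matrix


def preprocess_cohort(rna: ExpressionMatrix, mirna: ExpressionMatrix,
                      config: PreprocessConfig | None = None
                      ) -> tuple[ExpressionMatrix, dict]:
    """filter -> standardize -> assemble, returning the matrix and a report."""
    config = config or PreprocessConfig()
    rna_f, rep_rna = filter_zero_features(rna, config)
    mirna_f, rep_mirna = filter_zero_features(mirna, config)
    rna_f = _drop_constant_features(rna_f)
    mirna_f = _drop_constant_features(mirna_f)
    if config.standardize:
        rna_f = standardize_features(rna_f)
        mirna_f = standardize_features(mirna_f)
    combined = assemble_multiomics(rna_f, mirna_f)
    report = {"rna": rep_rna.to_dict(), "mirna": rep_mirna.to_dict(),
              "n_patients": combined.n_patients, "n_features": combined.n_features}
    return combined, report
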