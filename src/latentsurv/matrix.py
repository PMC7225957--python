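"""Core containers: patient-by-feature expression matrices and clinical tables.

An :class:`ExpressionMatrix` is a thin wrapper around a pandas DataFrame
(rows = patients, columns = features) that additionally tracks the omics
class of every feature (``"RNA"`` or ``"miRNA"``) so that downstream stages
can rank and select RNAs and miRNAs separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

RNA = "RNA"
MIRNA = "miRNA"
VALID_CLASSES = (RNA, MIRNA)


@dataclass
class ExpressionMatrix:
    """Patients x features expression values with per-feature class tags.

    Parameters
    ----------
    values
        DataFrame indexed by patient id, one column per feature.
    feature_class
        Series mapping feature id -> ``"RNA"`` | ``"miRNA"``. If omitted,
        every feature is tagged ``"RNA"``.
    """

    values: pd.DataFrame
    feature_class: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.feature_class is None:
            self.feature_class = pd.Series(RNA, index=self.values.columns)
        self.feature_class = self.feature_class.reindex(self.values.columns)
        if self.feature_class.isna().any():
            missing = list(self.feature_class.index[self.feature_class.isna()])
            raise ValueError(f"features without a class tag: {missing[:5]}")
        bad = set(self.feature_class.unique()) - set(VALID_CLASSES)
        if bad:
            raise ValueError(f"unknown feature classes: {sorted(bad)}")
        if self.values.columns.duplicated().any():
            dups = list(self.values.columns[self.values.columns.duplicated()])
            raise ValueError(f"duplicate feature ids: {dups[:5]}")
        if self.values.index.duplicated().any():
            dups = list(self.values.index[self.values.index.duplicated()])
            raise ValueError(f"duplicate patient ids: {dups[:5]}")

    # -- basic accessors -------------------------------------------------
    @property
    def patients(self) -> pd.Index:
        return self.values.index

    @property
    def features(self) -> pd.Index:
        return self.values.columns

    @property
    def n_patients(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def class_features(self, cls: str) -> pd.Index:
        """Feature ids belonging to one omics class."""
        if cls not in VALID_CLASSES:
            raise ValueError(f"unknown feature class {cls!r}")
        return self.features[self.feature_class.values == cls]

    def subset_features(self, features) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values[list(features)].copy(),
                                self.feature_class.loc[list(features)].copy())

    def subset_patients(self, patients) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(patients)].copy(),
                                self.feature_class.copy())

    def to_numpy(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    # -- I/O -------------------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        """Write values as TSV (patients as rows, header = feature ids)."""
        self.values.to_csv(path, sep="\t", index_label="patient_id")

    @classmethod
    def from_tsv(cls, path: str | Path, feature_class: str = RNA) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col="patient_id")
        return cls(df, pd.Series(feature_class, index=df.columns))


def read_clinical_tsv(path: str | Path) -> pd.DataFrame:
    """Read a clinical table (patient_id, time_days, event, covariates...)."""
    df = pd.read_csv(path, sep="\t", index_col="patient_id")
    for col in ("time_days", "event"):
        if col not in df.columns:
            raise ValueError(f"clinical table missing required column {col!r}")
    return df


def write_clinical_tsv(clinical: pd.DataFrame, path: str | Path) -> None:
    clinical.to_csv(path, sep="\t", index_label="patient_id")
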