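"""ANOVA feature ranking and the subtype classifier sweep.

The inferred high-/low-risk labels act as training targets. Features are
ranked on the 60% training split only (one-way ANOVA F between the two
label groups, RNAs and miRNAs ranked separately), then classifiers are fit
on the top-m miRNA + top-n RNA combinations: an RBF-kernel SVM as the
primary model and KNN / random-forest / logistic-regression comparison
grids. Test data never enter the ranking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .matrix import ExpressionMatrix, RNA, MIRNA

#: feature-count grids of the systematic sweep
MIRNA_COUNTS = (5, 10, 15, 20)
RNA_COUNTS = (5, 10, 15, 20, 25, 30)
#: showcased (miRNA, RNA) combinations reported as the headline table
SHOWCASE_COMBINATIONS = ((5, 5), (10, 10), (15, 15), (20, 20), (20, 25), (20, 30))


@dataclass
class SplitSpec:
    train_fraction: float = 0.6
    stratified: bool = True
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")


@dataclass
class ClassifierSpec:
    family: str = "svm"     # svm | knn | rf | lr
    hyperparameters: dict = field(default_factory=dict)

    def build(self, seed: int = 0):
        hp = dict(self.hyperparameters)
        if self.family == "svm":
            return SVC(kernel=hp.get("kernel", "rbf"), C=hp.get("C", 1.0),
                       gamma=hp.get("gamma", "scale"), random_state=seed)
        if self.family == "knn":
            metric = hp.get("metric", "euclidean")
            if metric not in ("manhattan", "euclidean"):
                raise ValueError(f"unsupported KNN metric {metric!r}")
            return KNeighborsClassifier(n_neighbors=hp.get("k", 5), metric=metric)
        if self.family == "rf":
            criterion = hp.get("criterion", "gini")
            if criterion not in ("entropy", "gini"):
                raise ValueError(f"unsupported RF criterion {criterion!r}")
            return RandomForestClassifier(n_estimators=hp.get("n_trees", 10),
                                          criterion=criterion, random_state=seed)
        if self.family == "lr":
            penalty = hp.get("penalty", "l2")
            if penalty not in ("l1", "l2"):
                raise ValueError(f"unsupported LR penalty {penalty!r}")
            return LogisticRegression(l1_ratio=1.0 if penalty == "l1" else 0.0,
                                      C=hp.get("C", 1.0),
                                      solver="liblinear", random_state=seed)
        raise ValueError(f"unknown classifier family {self.family!r}")


@dataclass
class EvalResult:
    family: str
    n_mirna: int
    n_rna: int
    train_accuracy: float
    test_accuracy: float
    tp: int
    fn: int
    fp: int
    tn: int

    @property
    def accuracy_from_confusion(self) -> float:
        return (self.tp + self.tn) / (self.tp + self.fn + self.fp + self.tn)


def anova_rank(X_train: ExpressionMatrix, labels_train: pd.Series
               ) -> pd.DataFrame:
    """Per-feature one-way ANOVA F between the two label groups.

    Returns a table with F, p, feature class, and rank (descending F,
    computed separately within the RNA and miRNA classes).
    """
    groups = pd.unique(labels_train)
    if len(groups) < 2:
        raise ValueError("training labels contain a single class")
    arr = X_train.to_numpy()
    masks = [(labels_train == g).to_numpy() for g in groups]
    f_stat, p_val = stats.f_oneway(*[arr[m] for m in masks], axis=0)
    f_stat = np.nan_to_num(np.asarray(f_stat, dtype=float), nan=0.0)
    p_val = np.nan_to_num(np.asarray(p_val, dtype=float), nan=1.0)
    table = pd.DataFrame({"F": f_stat, "p_value": p_val,
                          "feature_class": X_train.feature_class.values},
                         index=X_train.features)
    table["rank"] = (table.groupby("feature_class")["F"]
                     .rank(ascending=False, method="first").astype(int))
    return table.sort_values(["feature_class", "rank"])


def stratified_split(patients, labels: pd.Series, spec: SplitSpec
                     ) -> tuple[list, list]:
    """Disjoint, covering train/test patient-id split, seed-deterministic."""
    spec.validate()
    patients = list(patients)
    y = labels.loc[patients]
    counts = y.value_counts()
    if (counts < 2).any():
        raise ValueError(f"class too small to split: {counts.to_dict()}")
    train, test = train_test_split(
        patients, train_size=spec.train_fraction, random_state=spec.seed,
        stratify=y if spec.stratified else None, shuffle=True)
    return list(train), list(test)


def _top_features(ranking: pd.DataFrame, top_m_mirna: int, top_n_rna: int) -> list:
    feats = []
    for cls, count in ((MIRNA, top_m_mirna), (RNA, top_n_rna)):
        sub = ranking[ranking["feature_class"] == cls]
        if count > len(sub):
            raise ValueError(f"requested top {count} {cls} features, only "
                             f"{len(sub)} available")
        feats.extend(sub.sort_values("rank").index[:count])
    return feats


def train_eval(X: ExpressionMatrix, labels: pd.Series, train_ids: list,
               test_ids: list, ranking: pd.DataFrame, top_m_mirna: int,
               top_n_rna: int, spec: ClassifierSpec | None = None,
               seed: int = 0, positive_label: str = "high-risk") -> EvalResult:
    """Fit on the training split with top-ranked features; evaluate on test.

    Confusion matrix uses the high-risk subtype as the positive class.
    """
    spec = spec or ClassifierSpec("svm")
    feats = _top_features(ranking, top_m_mirna, top_n_rna)
    Xtr = X.values.loc[train_ids, feats].to_numpy()
    Xte = X.values.loc[test_ids, feats].to_numpy()
    ytr = labels.loc[train_ids].to_numpy()
    yte = labels.loc[test_ids].to_numpy()
    clf = spec.build(seed=seed)
    clf.fit(Xtr, ytr)
    pred_tr = clf.predict(Xtr)
    pred_te = clf.predict(Xte)
    pos = positive_label
    tp = int(((yte == pos) & (pred_te == pos)).sum())
    fn = int(((yte == pos) & (pred_te != pos)).sum())
    fp = int(((yte != pos) & (pred_te == pos)).sum())
    tn = int(((yte != pos) & (pred_te != pos)).sum())
    return EvalResult(family=spec.family, n_mirna=top_m_mirna, n_rna=top_n_rna,
                      train_accuracy=float((pred_tr == ytr).mean()),
                      test_accuracy=float((pred_te == yte).mean()),
                      tp=tp, fn=fn, fp=fp, tn=tn)


def sweep_feature_counts(X: ExpressionMatrix, labels: pd.Series,
                         train_ids: list, test_ids: list,
                         ranking: pd.DataFrame,
                         mirna_counts=MIRNA_COUNTS, rna_counts=RNA_COUNTS,
                         spec: ClassifierSpec | None = None,
                         seed: int = 0) -> pd.DataFrame:
    """Systematic (m, n) grid plus the six showcased combinations.

    Returns one row per evaluation; showcase rows are tagged in the
    ``showcase`` column and ordered by total feature count.
    """
    spec = spec or ClassifierSpec("svm")
    rows = []
    for m in mirna_counts:
        for n in rna_counts:
            res = train_eval(X, labels, train_ids, test_ids, ranking, m, n,
                             spec, seed=seed)
            rows.append({"n_mirna": m, "n_rna": n,
                         "n_features": m + n, "showcase": False,
                         "train_accuracy": res.train_accuracy,
                         "test_accuracy": res.test_accuracy})
    for m, n in SHOWCASE_COMBINATIONS:
        res = train_eval(X, labels, train_ids, test_ids, ranking, m, n,
                         spec, seed=seed)
        rows.append({"n_mirna": m, "n_rna": n, "n_features": m + n,
                     "showcase": True,
                     "train_accuracy": res.train_accuracy,
                     "test_accuracy": res.test_accuracy})
    return pd.DataFrame(rows)


#: comparison-grid definitions: family -> (hyperparameter name, values, variants)
_GRIDS = {
    "knn": ("k", list(range(1, 11)), ("manhattan", "euclidean"), "metric"),
    "rf": ("n_trees", list(range(1, 11)), ("entropy", "gini"), "criterion"),
    "lr": ("C", [1, 5, 10, 50, 100, 500, 1000], ("l1", "l2"), "penalty"),
}


def hyperparameter_grid(X: ExpressionMatrix, labels: pd.Series,
                        train_ids: list, test_ids: list,
                        ranking: pd.DataFrame, family: str,
                        top_m_mirna: int = 20, top_n_rna: int = 25,
                        seed: int = 0) -> pd.DataFrame:
    """Comparison grids: KNN k=1..10 x metric, RF trees=1..10 x criterion,
    LR C grid x penalty. One row per cell with test accuracy; the best cell
    carries ``best = True``."""
    if family not in _GRIDS:
        raise ValueError(f"unknown family {family!r}; choose from {sorted(_GRIDS)}")
    pname, values, variants, vname = _GRIDS[family]
    rows = []
    for v in values:
        for var in variants:
            spec = ClassifierSpec(family, {pname: v, vname: var})
            res = train_eval(X, labels, train_ids, test_ids, ranking,
                             top_m_mirna, top_n_rna, spec, seed=seed)
            rows.append({pname: v, vname: var,
                         "train_accuracy": res.train_accuracy,
                         "test_accuracy": res.test_accuracy})
    table = pd.DataFrame(rows)
    table["best"] = False
    table.loc[table["test_accuracy"].idxmax(), "best"] = True
    return table
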