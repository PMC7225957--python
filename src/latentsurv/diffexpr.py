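"""Two-group differential expression between subtypes and the quartile
expression-survival screen.

The differential test is deliberately simple and explicitly labeled as
such: a per-feature Welch t test on log2(x + 1)-transformed normalized
expression, with the log2 fold change defined as the difference of group
means on that scale (high-risk minus low-risk) and Benjamini-Hochberg
adjustment across all tested features. The stage is swappable — any
external differential-expression table in the same schema can be fed to
downstream ranking and enrichment.

The quartile screen compares survival between the top-25% and bottom-25%
expression groups of a single gene, excluding the middle half.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import HIGH_RISK, LOW_RISK
from .matrix import ExpressionMatrix
from .survstats import SurvivalRecord, bh_adjust, logrank_test


def differential_expression(X: ExpressionMatrix, labels: pd.Series,
                            group_a: str = HIGH_RISK, group_b: str = LOW_RISK
                            ) -> pd.DataFrame:
    """Welch t on log2(x+1) per feature; lfc = mean(group_a) - mean(group_b).

    Features constant in both groups get p = 1 and lfc = 0. Returns a table
    sorted by p ascending with columns feature, log2_fold_change, t,
    p_value, adjusted_p, rank.
    """
    labels = labels.loc[X.patients]
    mask_a = (labels == group_a).to_numpy()
    mask_b = (labels == group_b).to_numpy()
    if mask_a.sum() < 2 or mask_b.sum() < 2:
        raise ValueError("each group needs at least 2 patients")
    log = np.log2(X.to_numpy() + 1.0)
    a, b = log[mask_a], log[mask_b]
    lfc = a.mean(axis=0) - b.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t_stat, p_val = stats.ttest_ind(a, b, axis=0, equal_var=False)
    t_stat = np.asarray(t_stat, dtype=float)
    p_val = np.asarray(p_val, dtype=float)
    constant = (a.std(axis=0) == 0) & (b.std(axis=0) == 0)
    t_stat[constant] = 0.0
    p_val[constant] = 1.0
    lfc = np.where(constant, 0.0, lfc)
    p_val = np.nan_to_num(p_val, nan=1.0)
    t_stat = np.nan_to_num(t_stat, nan=0.0)

    table = pd.DataFrame({"feature": X.features, "log2_fold_change": lfc,
                          "t": t_stat, "p_value": p_val})
    table["adjusted_p"] = bh_adjust(table["p_value"].to_numpy())
    table = table.sort_values(
        ["p_value", "feature"], kind="stable").reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return table


def top_k(results: pd.DataFrame, k: int = 25) -> pd.DataFrame:
    """First k rows by adjusted p (ties: |lfc| descending, then feature id)."""
    if k < 0:
        raise ValueError("k must be >= 0")
    ordered = results.assign(_abs_lfc=results["log2_fold_change"].abs())
    ordered = ordered.sort_values(["adjusted_p", "_abs_lfc", "feature"],
                                  ascending=[True, False, True], kind="stable")
    ordered = ordered.drop(columns="_abs_lfc")
    if k > len(results):
        import warnings
        warnings.warn(f"requested top {k} of {len(results)} results; returning all")
        k = len(results)
    return ordered.head(k).reset_index(drop=True)


def quartile_survival_screen(expr: pd.Series, records: list[SurvivalRecord],
                             quantile: float = 0.25
                             ) -> tuple[int, int, float]:
    """Log-rank test between extreme expression groups of one feature.

    The top ``floor(q*n)`` and bottom ``floor(q*n)`` patients by expression
    form the two groups; the middle patients are excluded. Ties at the
    quantile boundary are resolved by a stable sort on patient id, so group
    membership is deterministic. Returns (n_high, n_low, logrank_p).
    """
    n = len(expr)
    if n < 8:
        raise ValueError("need at least 8 patients for the quartile screen")
    if expr.nunique() == 1:
        raise ValueError("all expression values identical: no ordering")
    g = int(np.floor(quantile * n))
    if g < 1:
        raise ValueError(f"quantile {quantile} too small for n={n}")
    ordered = expr.sort_index(kind="stable").sort_values(kind="stable")
    low_ids = list(ordered.index[:g])
    high_ids = list(ordered.index[-g:])
    by_pid = {r.patient_id: r for r in records}
    high = [by_pid[str(p)] for p in high_ids]
    low = [by_pid[str(p)] for p in low_ids]
    _, _, p = logrank_test([high, low])
    return len(high), len(low), float(p)
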