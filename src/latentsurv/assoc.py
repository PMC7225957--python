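"""Subtype-association statistics: Fisher exact tests on clinical and
mutation contingency tables, per-chromosome Mann-Whitney copy-number
comparison, and seed-gene co-expression screening.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import HIGH_RISK, LOW_RISK
from .matrix import ExpressionMatrix
from .survstats import bh_adjust

logger = logging.getLogger(__name__)


@dataclass
class ContingencyTable2x2:
    """Counts with rows = subtype (high-risk, low-risk) and columns =
    trait present / absent."""
    a: int  # high-risk, trait present
    b: int  # high-risk, trait absent
    c: int  # low-risk, trait present
    d: int  # low-risk, trait absent

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("empty table")

    @property
    def rate_high(self) -> float:
        return self.a / (self.a + self.b)

    @property
    def rate_low(self) -> float:
        return self.c / (self.c + self.d)


def fisher_exact(table: ContingencyTable2x2) -> tuple[float, float]:
    """Two-sided Fisher exact test.

    p sums the hypergeometric probabilities of all tables with the observed
    margins whose probability does not exceed the observed one. The sample
    odds ratio is reported, with a 0.5 continuity correction when a cell
    is zero.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        raise ValueError("a margin of the table is zero")
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    odds = (a * d) / (b * c)
    return float(odds), float(p)


def covariate_table(flags: pd.Series, labels: pd.Series) -> ContingencyTable2x2:
    """2x2 table of a binary covariate against the two risk subtypes."""
    flags = flags.loc[labels.index].astype(bool)
    hi = labels == HIGH_RISK
    return ContingencyTable2x2(
        a=int((hi & flags).sum()), b=int((hi & ~flags).sum()),
        c=int((~hi & flags).sum()), d=int((~hi & ~flags).sum()))


def mutation_table(mutation_flags: pd.DataFrame, labels: pd.Series,
                   genes: list[str] | None = None) -> pd.DataFrame:
    """Per-gene mutated-patient counts by subtype with Fisher tests.

    ``mutation_flags`` is a patient x gene boolean table (a patient is
    mutated or not — patient counts, not mutation-event counts). Genes
    absent from the table are skipped with a warning.
    """
    if set(pd.unique(labels)) - {HIGH_RISK, LOW_RISK}:
        raise ValueError("labels must be binary high-risk/low-risk")
    genes = list(genes) if genes is not None else list(mutation_flags.columns)
    rows = []
    for gene in genes:
        if gene not in mutation_flags.columns:
            logger.warning("gene %r absent from mutation flags; skipped", gene)
            continue
        tab = covariate_table(mutation_flags[gene], labels)
        if tab.a + tab.c == 0 or tab.b + tab.d == 0:
            p = 1.0   # trait constant across the cohort: no association testable
        else:
            _, p = fisher_exact(tab)
        rows.append({"gene": gene, "n_high_mut": tab.a, "n_high": tab.a + tab.b,
                     "n_low_mut": tab.c, "n_low": tab.c + tab.d,
                     "rate_high": tab.rate_high, "rate_low": tab.rate_low,
                     "fisher_p": p})
    return pd.DataFrame(rows).set_index("gene")


def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U with midrank ties.

    Exact enumeration when both groups have <= 8 observations and no ties;
    otherwise the tie-corrected normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < pooled.size
    small = x.size <= 8 and y.size <= 8
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def chromosome_cnv_compare(cnv: pd.DataFrame, labels: pd.Series,
                           alpha: float = 0.05) -> pd.DataFrame:
    """Per-chromosome Mann-Whitney comparison of mean log2 copy values.

    ``cnv`` is patient x chromosome. BH adjustment runs across chromosomes;
    ``flagged`` marks adjusted p < alpha. Chromosomes observed in a single
    subtype are skipped.
    """
    labels = labels.loc[cnv.index]
    hi = (labels == HIGH_RISK).to_numpy()
    rows = []
    for chrom in cnv.columns:
        v = cnv[chrom].to_numpy(dtype=float)
        ok = np.isfinite(v)
        x, y = v[ok & hi], v[ok & ~hi]
        if x.size == 0 or y.size == 0:
            logger.warning("chromosome %s has a single subtype represented; "
                           "skipped", chrom)
            continue
        u, p = mann_whitney(x, y)
        rows.append({"chromosome": chrom, "U": u, "p_value": p,
                     "median_high": float(np.median(x)),
                     "median_low": float(np.median(y))})
    table = pd.DataFrame(rows).set_index("chromosome")
    if len(table):
        table["adjusted_p"] = bh_adjust(table["p_value"].to_numpy())
        table["flagged"] = table["adjusted_p"] < alpha
    return table


def coexpression_screen(seed_feature: str, X: ExpressionMatrix) -> pd.DataFrame:
    """Pearson correlation of one seed feature against every other feature.

    p-values come from the t transform t = r sqrt((n-2)/(1-r^2)); BH FDR is
    applied over all tested features. Zero-variance targets are excluded
    with a warning; the seed itself is never in the output. Sorted by |r|
    descending.
    """
    if seed_feature not in set(X.features):
        raise ValueError(f"seed feature {seed_feature!r} not in matrix")
    if X.n_patients < 3:
        raise ValueError("need at least 3 patients")
    seed = X.values[seed_feature].to_numpy(dtype=float)
    if seed.std() == 0:
        raise ValueError("seed feature has zero variance")
    rows = []
    n_excluded = 0
    for feat in X.features:
        if feat == seed_feature:
            continue
        v = X.values[feat].to_numpy(dtype=float)
        if v.std() == 0:
            n_excluded += 1
            continue
        r, p = stats.pearsonr(seed, v)
        rows.append({"target": feat, "pearson_r": float(r), "p_value": float(p)})
    if n_excluded:
        logger.warning("excluded %d zero-variance targets", n_excluded)
    table = pd.DataFrame(rows).set_index("target")
    table["fdr"] = bh_adjust(table["p_value"].to_numpy())
    return table.reindex(table["pearson_r"].abs().sort_values(ascending=False).index)
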