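"""Preranked gene-set enrichment (GSEA) and over-representation analysis.

Preranked GSEA: features are ordered by a signed ranking statistic
(by default the differential-expression t value); the enrichment score of
a set is the maximum deviation of a running sum that steps up by
|stat|^weight (normalized over set members) at set hits and down by
1/(N - |S|) at misses. Significance comes from a gene-set permutation
null — random same-size sets drawn from the universe — with the normalized
enrichment score NES = ES / mean(|null ES| of the matching sign) and BH
adjustment across sets.

Over-representation is the classic one-sided hypergeometric upper-tail
test on the 2x2 overlap table between a selected feature list and a set
within a universe.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .survstats import bh_adjust


@dataclass
class GeneSetCollection:
    """Named feature-id sets. Members and names are unique."""

    sets: dict[str, list[str]]

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if len(set(members)) != len(members):
                raise ValueError(f"duplicate members in set {name!r}")

    def __len__(self) -> int:
        return len(self.sets)

    # -- GMT I/O (tab-separated: name, description, members) -------------
    def to_gmt(self, path: str | Path, description: str = "na") -> None:
        with open(path, "w") as fh:
            for name, members in self.sets.items():
                fh.write("\t".join([name, description, *members]) + "\n")

    @classmethod
    def from_gmt(cls, path: str | Path) -> "GeneSetCollection":
        sets: dict[str, list[str]] = {}
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3:
                    continue
                name, _desc, *members = parts
                if name in sets:
                    raise ValueError(f"duplicate set name {name!r} in GMT")
                sets[name] = [m for m in members if m]
        return cls(sets)


def _enrichment_score(hit_mask: np.ndarray, weights: np.ndarray) -> float:
    """Signed maximum deviation of the running sum over the ranked list."""
    n = hit_mask.size
    n_hits = int(hit_mask.sum())
    hit_w = np.where(hit_mask, weights, 0.0)
    total = hit_w.sum()
    if total == 0:   # all-zero statistic in the set: treat hits uniformly
        hit_w = hit_mask.astype(float)
        total = hit_w.sum()
    miss_pen = 1.0 / (n - n_hits)
    steps = hit_w / total - np.where(hit_mask, 0.0, miss_pen)
    running = np.cumsum(steps)
    return float(running[np.argmax(np.abs(running))])


def preranked_gsea(ranking: pd.Series, sets: GeneSetCollection,
                   weight: float = 1.0, n_perm: int = 1000,
                   seed: int = 0) -> pd.DataFrame:
    """Enrichment of each set in a feature -> statistic ranking.

    ``ranking`` maps every feature of the universe to a real statistic
    (larger = more associated with the first subtype). Sets with fewer than
    2 members in the universe are skipped with a warning.
    """
    ranking = ranking.sort_values(ascending=False, kind="stable")
    universe = list(ranking.index)
    pos = {f: i for i, f in enumerate(universe)}
    n = len(universe)
    stat = np.abs(ranking.to_numpy(dtype=float)) ** weight
    rng = np.random.default_rng(seed)

    rows = []
    for name, members in sets.sets.items():
        idx = [pos[m] for m in members if m in pos]
        if len(idx) < 2:
            warnings.warn(f"set {name!r} has <2 members in the universe; skipped")
            continue
        mask = np.zeros(n, dtype=bool)
        mask[idx] = True
        es = _enrichment_score(mask, stat)

        size = len(idx)
        null_es = np.empty(n_perm)
        for b in range(n_perm):
            null_mask = np.zeros(n, dtype=bool)
            null_mask[rng.choice(n, size, replace=False)] = True
            null_es[b] = _enrichment_score(null_mask, stat)
        same_sign = null_es >= 0 if es >= 0 else null_es < 0
        n_same = int(same_sign.sum())
        if n_same == 0:
            p = 1.0 / (n_perm + 1)
            nes = 0.0
        else:
            p = (1 + int((np.abs(null_es[same_sign]) >= abs(es)).sum())) / (1 + n_same)
            denom = float(np.abs(null_es[same_sign]).mean())
            nes = es / denom if denom > 0 else 0.0
        rows.append({"set": name, "size": size, "ES": es, "NES": nes,
                     "p_value": p})
    table = pd.DataFrame(rows)
    if len(table):
        table["adjusted_p"] = bh_adjust(table["p_value"].to_numpy())
        table = table.sort_values("p_value", kind="stable").reset_index(drop=True)
    return table


def ora_test(selected, gene_set, universe) -> tuple[float, float]:
    """One-sided hypergeometric over-representation test.

    Returns (odds_ratio, p_value) for the overlap between ``selected`` and
    ``gene_set`` within ``universe``; the odds ratio uses a 0.5 continuity
    correction when any 2x2 cell is zero.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    selected = set(selected) & universe
    gene_set = set(gene_set) & universe
    N = len(universe)
    K = len(gene_set)
    n = len(selected)
    k = len(selected & gene_set)
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    a = k
    b = n - k
    c = K - k
    d = N - K - n + k
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    odds = (a * d) / (b * c)
    return float(odds), min(p, 1.0)
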