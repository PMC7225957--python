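"""Cluster-number selection and K-means subtype inference on the selected
latent features, plus orientation of the two clusters into high-/low-risk
survival subtypes.

K-means (Lloyd, best of restarts), the Silhouette index and the
Calinski-Harabasz criterion come from scikit-learn; the elbow curve (WCSS
against k) is reported descriptively and never decides k on its own. The
consensus rule is: k maximizing the Silhouette index, with a flagged
conflict when the Calinski-Harabasz argmax disagrees.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import calinski_harabasz_score, silhouette_score

from .cohort import HIGH_RISK, LOW_RISK
from .survstats import SurvivalRecord, kaplan_meier, logrank_test

logger = logging.getLogger(__name__)


@dataclass
class ClusterEval:
    k: int
    wcss: float
    silhouette: float | None        # undefined at k = 1
    calinski_harabasz: float | None


def _fit_kmeans(X: np.ndarray, k: int, restarts: int, seed: int) -> KMeans:
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed,
                tol=1e-12, max_iter=500)
    km.fit(X)
    return km


def evaluate_k_range(X: pd.DataFrame | np.ndarray, k_min: int = 1,
                     k_max: int = 10, restarts: int = 50,
                     seed: int = 0) -> list[ClusterEval]:
    """Score best-of-restarts K-means for each k in [k_min, k_max]."""
    arr = np.asarray(X, dtype=float)
    n = arr.shape[0]
    if k_max >= n:
        raise ValueError(f"k_max ({k_max}) must be below n patients ({n})")
    if np.allclose(arr, arr[0]):
        raise ValueError("degenerate input: all points identical")
    evals = []
    for k in range(k_min, k_max + 1):
        km = _fit_kmeans(arr, k, restarts, seed)
        sil = ch = None
        if k >= 2 and len(np.unique(km.labels_)) >= 2:
            sil = float(silhouette_score(arr, km.labels_))
            ch = float(calinski_harabasz_score(arr, km.labels_))
        evals.append(ClusterEval(k=k, wcss=float(km.inertia_),
                                 silhouette=sil, calinski_harabasz=ch))
    return evals


@dataclass
class KChoice:
    k: int
    silhouette_argmax: int
    calinski_argmax: int
    conflict: bool


def choose_k(evals: list[ClusterEval]) -> KChoice:
    """Consensus cluster number: Silhouette argmax, conflict-flagged vs CH."""
    scored = [ev for ev in evals if ev.silhouette is not None]
    if not scored:
        raise ValueError("need evaluations with k >= 2")
    sil_k = max(scored, key=lambda ev: ev.silhouette).k
    ch_k = max(scored, key=lambda ev: ev.calinski_harabasz).k
    conflict = sil_k != ch_k
    if conflict:
        logger.warning("cluster-number conflict: silhouette -> %d, "
                       "Calinski-Harabasz -> %d; using silhouette", sil_k, ch_k)
    return KChoice(k=sil_k, silhouette_argmax=sil_k, calinski_argmax=ch_k,
                   conflict=conflict)


def kmeans_cluster(X: pd.DataFrame | np.ndarray, k: int, restarts: int = 50,
                   seed: int = 0) -> pd.Series | np.ndarray:
    """Best-of-restarts K-means labels (arbitrary integers), seed-deterministic."""
    if k < 2:
        raise ValueError("k must be >= 2")
    arr = np.asarray(X, dtype=float)
    km = _fit_kmeans(arr, k, restarts, seed)
    if isinstance(X, pd.DataFrame):
        return pd.Series(km.labels_, index=X.index, name="cluster")
    return km.labels_


@dataclass
class RiskOrientation:
    risk_labels: pd.Series          # patient -> "high-risk"/"low-risk"
    logrank_chi2: float
    logrank_p: float
    tie_broken: bool


def orient_risk_labels(labels: pd.Series, records: list[SurvivalRecord]
                       ) -> RiskOrientation:
    """Name the cluster with worse Kaplan-Meier survival "high-risk".

    Survival is compared at the median follow-up time; an exact tie is
    broken by declaring the smaller cluster high-risk (with a warning).
    Only defined for exactly two clusters.
    """
    uniq = sorted(pd.unique(labels))
    if len(uniq) != 2:
        raise ValueError(f"risk orientation requires exactly 2 clusters, got {len(uniq)}")
    by_pid = {r.patient_id: r for r in records}
    groups = {u: [by_pid[str(p)] for p in labels.index[labels == u]] for u in uniq}
    t_all = np.array([r.time for g in groups.values() for r in g])
    t_med = float(np.median(t_all))
    surv_at_med = {u: kaplan_meier(g).probability_at(t_med) for u, g in groups.items()}

    tie = False
    s0, s1 = surv_at_med[uniq[0]], surv_at_med[uniq[1]]
    if s0 == s1:
        tie = True
        logger.warning("identical survival at median follow-up; smaller "
                       "cluster named high-risk")
        sizes = {u: (labels == u).sum() for u in uniq}
        high = min(uniq, key=lambda u: (sizes[u], u))
    else:
        high = uniq[0] if s0 < s1 else uniq[1]
    risk = labels.map(lambda u: HIGH_RISK if u == high else LOW_RISK)
    risk.name = "risk_label"
    chi2, _, p = logrank_test([groups[uniq[0]], groups[uniq[1]]])
    return RiskOrientation(risk_labels=risk, logrank_chi2=float(chi2),
                           logrank_p=float(p), tie_broken=tie)
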