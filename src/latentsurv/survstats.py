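"""Survival statistics: univariate Cox proportional-hazards screening,
Kaplan-Meier estimation, log-rank testing and Benjamini-Hochberg adjustment.

The Cox model here is univariate by design: each latent feature from the
autoencoder bottleneck is screened one at a time, and features whose score
test (the log-rank-type test at beta = 0) falls below alpha are kept. For a
binary covariate the Cox score test is algebraically identical to the
two-group log-rank statistic, which is asserted in the test suite.

Ties are handled with the Efron approximation throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class SurvivalRecord:
    patient_id: str
    time: float   # days, > 0
    event: int    # 1 = death observed, 0 = censored

    def __post_init__(self) -> None:
        if not np.isfinite(self.time) or self.time <= 0:
            raise ValueError(f"time must be finite and positive, got {self.time}")
        if self.event not in (0, 1):
            raise ValueError(f"event must be 0 or 1, got {self.event}")


def records_from_clinical(clinical: pd.DataFrame) -> list[SurvivalRecord]:
    """Build records from a clinical table with time_days/event columns."""
    return [SurvivalRecord(str(pid), float(row["time_days"]), int(row["event"]))
            for pid, row in clinical.iterrows()]


def _arrays(records: list[SurvivalRecord]):
    t = np.array([r.time for r in records], dtype=float)
    e = np.array([r.event for r in records], dtype=int)
    return t, e


@dataclass
class CoxFit:
    beta: float
    se: float
    p_value: float        # score (log-rank-type) test at beta = 0
    wald_p: float
    converged: bool
    n_events: int
    score_chi2: float


def _cox_derivatives(beta: float, x: np.ndarray, t: np.ndarray, e: np.ndarray):
    """Log partial likelihood, score and information under Efron ties."""
    order = np.argsort(t, kind="stable")
    x, t, e = x[order], t[order], e[order]
    n = len(t)
    eta = beta * x
    w = np.exp(eta)
    loglik = grad = info = 0.0
    i = 0
    # suffix sums over the risk set {j : t_j >= t_i}
    S0 = np.cumsum(w[::-1])[::-1]
    S1 = np.cumsum((w * x)[::-1])[::-1]
    S2 = np.cumsum((w * x * x)[::-1])[::-1]
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        d_idx = [k for k in range(i, j) if e[k] == 1]
        d = len(d_idx)
        if d > 0:
            s0, s1, s2 = S0[i], S1[i], S2[i]
            wd = w[d_idx]
            xd = x[d_idx]
            ds0, ds1, ds2 = wd.sum(), (wd * xd).sum(), (wd * xd * xd).sum()
            loglik += eta[d_idx].sum()
            for l in range(d):
                f = l / d
                a0 = s0 - f * ds0
                a1 = s1 - f * ds1
                a2 = s2 - f * ds2
                loglik -= np.log(a0)
                grad_term = a1 / a0
                grad += 0.0 - grad_term  # event-x part added once below
                info += a2 / a0 - grad_term ** 2
            grad += xd.sum()
        i = j
    return loglik, grad, info


def fit_univariate_cox(x, records: list[SurvivalRecord],
                       max_iter: int = 100, tol: float = 1e-8) -> CoxFit:
    """Maximize the univariate Cox partial likelihood by Newton-Raphson.

    ``p_value`` is from the score test at beta = 0, matching log-rank for a
    binary covariate; the Wald p is reported alongside.
    """
    x = np.asarray(x, dtype=float)
    t, e = _arrays(records)
    if len(x) != len(records):
        raise ValueError("covariate length does not match records")
    n_events = int(e.sum())
    if n_events < 2:
        raise ValueError("need at least 2 events to fit a Cox model")
    if np.ptp(x) == 0:
        raise ValueError("non-identifiable covariate: x is constant")
    # standardize internally for numerical stability, rescale beta afterwards
    scale = x.std()
    xs = (x - x.mean()) / scale

    _, score0, info0 = _cox_derivatives(0.0, xs, t, e)
    score_chi2 = score0 ** 2 / info0 if info0 > 0 else 0.0
    score_p = float(stats.chi2.sf(score_chi2, df=1))

    beta = 0.0
    converged = False
    loglik_prev = -np.inf
    for _ in range(max_iter):
        loglik, grad, info = _cox_derivatives(beta, xs, t, e)
        if info <= 0 or not np.isfinite(loglik):
            break
        delta = grad / info
        # step-halving if the step does not improve the likelihood
        for _h in range(30):
            cand = beta + delta
            ll_new, _, _ = _cox_derivatives(cand, xs, t, e)
            if ll_new >= loglik - 1e-12:
                break
            delta /= 2.0
        beta = beta + delta
        if abs(delta) < tol:
            converged = True
            break
        if abs(beta) > 50:   # monotone likelihood / complete separation
            break
        loglik_prev = loglik

    _, _, info_hat = _cox_derivatives(beta, xs, t, e)
    se_s = 1.0 / np.sqrt(info_hat) if info_hat > 0 else np.inf
    beta_out = beta / scale
    se_out = se_s / scale
    wald_p = float(stats.chi2.sf((beta / se_s) ** 2, df=1)) if np.isfinite(se_s) else 1.0
    return CoxFit(beta=float(beta_out), se=float(se_out), p_value=score_p,
                  wald_p=wald_p, converged=converged, n_events=n_events,
                  score_chi2=float(score_chi2))


def select_survival_features(Z: pd.DataFrame, records: list[SurvivalRecord],
                             alpha: float = 0.05
                             ) -> tuple[list[str], pd.DataFrame]:
    """Screen latent features with univariate Cox fits; keep p < alpha.

    Returns the selected feature names and the full per-feature fit table.
    Raises if nothing passes, mirroring a pipeline that can only proceed
    with significant features.
    """
    if len(Z) != len(records):
        raise ValueError("Z rows do not align with survival records")
    rows = []
    for col in Z.columns:
        x = Z[col].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            rows.append({"feature": col, "beta": np.nan, "se": np.nan,
                         "p_value": 1.0, "wald_p": 1.0, "converged": False})
            continue
        fit = fit_univariate_cox(x, records)
        rows.append({"feature": col, "beta": fit.beta, "se": fit.se,
                     "p_value": fit.p_value, "wald_p": fit.wald_p,
                     "converged": fit.converged})
    table = pd.DataFrame(rows).set_index("feature")
    selected = list(table.index[table["p_value"] < alpha])
    if not selected:
        raise EmptySelectionError(
            f"no latent feature reached p < {alpha}; cannot proceed to clustering")
    return selected, table


class EmptySelectionError(RuntimeError):
    """Raised when Cox screening selects no feature."""


@dataclass
class SurvivalCurve:
    times: np.ndarray            # ordered distinct event times
    survival: np.ndarray         # S(t) just after each event time
    at_risk: np.ndarray
    n_events: np.ndarray

    def probability_at(self, t: float) -> float:
        """S(t): product-limit estimate at time t (right-continuous)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def kaplan_meier(records: list[SurvivalRecord]) -> SurvivalCurve:
    """Product-limit estimator. Censored times do not step the curve."""
    if not records:
        raise ValueError("empty record list")
    t, e = _arrays(records)
    event_times = np.unique(t[e == 1])
    surv = []
    at_risk = []
    n_ev = []
    s = 1.0
    for et in event_times:
        n = int((t >= et).sum())
        d = int(((t == et) & (e == 1)).sum())
        s *= (n - d) / n
        surv.append(s)
        at_risk.append(n)
        n_ev.append(d)
    return SurvivalCurve(times=event_times, survival=np.array(surv),
                         at_risk=np.array(at_risk), n_events=np.array(n_ev))


def logrank_test(groups: list[list[SurvivalRecord]]
                 ) -> tuple[float, int, float]:
    """k-group log-rank test: observed minus expected events with the
    hypergeometric variance. Returns (chi_square, df, p_value)."""
    k = len(groups)
    if k < 2:
        raise ValueError("need at least 2 groups")
    for gi, g in enumerate(groups):
        if not g:
            raise ValueError(f"group {gi} is empty")
    times = []
    events = []
    gidx = []
    for gi, g in enumerate(groups):
        t, e = _arrays(g)
        times.append(t)
        events.append(e)
        gidx.append(np.full(len(g), gi))
    t = np.concatenate(times)
    e = np.concatenate(events)
    g = np.concatenate(gidx)
    if e.sum() == 0:
        raise ValueError("no events in any group")

    event_times = np.unique(t[e == 1])
    O = np.zeros(k)
    E = np.zeros(k)
    V = np.zeros((k, k))
    for et in event_times:
        at_risk = t >= et
        n_j = at_risk.sum()
        d_j = int(((t == et) & (e == 1)).sum())
        n_i = np.array([(at_risk & (g == gi)).sum() for gi in range(k)], dtype=float)
        d_i = np.array([(((t == et) & (e == 1)) & (g == gi)).sum() for gi in range(k)],
                       dtype=float)
        O += d_i
        E += d_j * n_i / n_j
        if n_j > 1:
            frac = n_i / n_j
            c = d_j * (n_j - d_j) / (n_j - 1)
            V += c * (np.diag(frac) - np.outer(frac, frac))
    diff = (O - E)[:-1]
    Vsub = V[:-1, :-1]
    try:
        chi2 = float(diff @ np.linalg.solve(Vsub, diff))
    except np.linalg.LinAlgError:
        chi2 = float(diff @ np.linalg.pinv(Vsub) @ diff)
    df = k - 1
    p = float(stats.chi2.sf(chi2, df=df))
    return chi2, df, p


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out
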