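"""Survival analysis: Cox proportional hazards, Kaplan-Meier / log-rank,
and time-dependent ROC at a fixed horizon.

The Cox model maximizes the Breslow-ties partial likelihood by
Newton-Raphson with step-halving (the log partial likelihood never
decreases across iterations). Covariates are standardized internally and
coefficients reported on the original scale; standard errors come from the
observed information. The same Breslow machinery powers the penalized
phenotype-linkage selector.

The time-dependent ROC uses the Kaplan-Meier (cumulative/dynamic)
estimator of Heagerty, Lumley and Pepe: at horizon t, for a marker cutoff
c, ``TPR = (1 - S_c(t)) P(M > c) / (1 - S(t))`` and
``FPR = S_c(t) P(M > c) / S(t)`` with S the overall and S_c the
above-cutoff Kaplan-Meier curve; the AUC is the trapezoid area. With no
censoring this reduces exactly to the empirical AUC of the binary
event-by-horizon outcome.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test

from .io import ClinicalTable


# ---------------------------------------------------------------------------
# Breslow partial likelihood
# ---------------------------------------------------------------------------

def _sort_by_time(time: np.ndarray, event: np.ndarray, X: np.ndarray):
    order = np.argsort(-time, kind="stable")         # descending: risk sets by cumsum
    return time[order], event[order], X[order], order


def breslow_loglik(beta: np.ndarray, time: np.ndarray, event: np.ndarray,
                   X: np.ndarray) -> float:
    """Breslow-ties log partial likelihood."""
    t, d, Xs, _ = _sort_by_time(time, event, X)
    eta = Xs @ beta
    # guard against overflow in degenerate fits
    eta = np.clip(eta, -500, 500)
    exp_eta = np.exp(eta)
    cum = np.cumsum(exp_eta)                          # sum over {j: t_j >= t_i}
    # ties: the risk-set sum at a tied time is the cumsum at the LAST tied index
    last = np.empty(len(t), dtype=int)
    i = 0
    while i < len(t):
        j = i
        while j + 1 < len(t) and t[j + 1] == t[i]:
            j += 1
        last[i:j + 1] = j
        i = j + 1
    risk_sum = cum[last]
    mask = d == 1
    return float(np.sum(eta[mask]) - np.sum(np.log(risk_sum[mask])))


def breslow_gradient(beta: np.ndarray, time: np.ndarray, event: np.ndarray,
                     X: np.ndarray) -> np.ndarray:
    """Gradient of the Breslow log partial likelihood (no Hessian — linear
    cost in the number of covariates, used by the penalized selector)."""
    t, d, Xs, _ = _sort_by_time(time, event, X)
    n = len(t)
    eta = np.clip(Xs @ beta, -500, 500)
    w = np.exp(eta)
    S0 = np.cumsum(w)
    S1 = np.cumsum(w[:, None] * Xs, axis=0)
    last = np.empty(n, dtype=int)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and t[j + 1] == t[i]:
            j += 1
        last[i:j + 1] = j
        i = j + 1
    mask = d == 1
    s0 = S0[last[mask]]
    s1 = S1[last[mask]]
    return Xs[mask].sum(axis=0) - (s1 / s0[:, None]).sum(axis=0)


def breslow_grad_hess(beta: np.ndarray, time: np.ndarray, event: np.ndarray,
                      X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Gradient and (negative-definite) Hessian of the Breslow log partial
    likelihood."""
    t, d, Xs, _ = _sort_by_time(time, event, X)
    n, p = Xs.shape
    eta = np.clip(Xs @ beta, -500, 500)
    w = np.exp(eta)
    S0 = np.cumsum(w)
    S1 = np.cumsum(w[:, None] * Xs, axis=0)
    last = np.empty(n, dtype=int)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and t[j + 1] == t[i]:
            j += 1
        last[i:j + 1] = j
        i = j + 1
    mask = d == 1
    s0 = S0[last[mask]]
    s1 = S1[last[mask]]
    xbar = s1 / s0[:, None]
    grad = Xs[mask].sum(axis=0) - xbar.sum(axis=0)
    # Hessian needs S2 = cumsum of w * x x^T
    S2 = np.cumsum(w[:, None, None] * (Xs[:, :, None] * Xs[:, None, :]), axis=0)
    s2 = S2[last[mask]]
    hess = -(s2 / s0[:, None, None] - xbar[:, :, None] * xbar[:, None, :]).sum(axis=0)
    return grad, hess


def breslow_neg_loglik_and_grad(beta: np.ndarray, time: np.ndarray,
                                event: np.ndarray, X: np.ndarray
                                ) -> tuple[float, np.ndarray]:
    ll = breslow_loglik(beta, time, event, X)
    grad, _ = breslow_grad_hess(beta, time, event, X)
    return -ll, -grad


@dataclass
class CoxFit:
    """Fitted multivariate Cox model (Breslow ties)."""

    coef: pd.Series
    se: pd.Series
    z: pd.Series
    p: pd.Series
    log_partial_likelihood: float
    n_events: int
    converged: bool
    n_iter: int


def fit_cox(clinical: ClinicalTable, covariates: pd.DataFrame,
            tol: float = 1e-8, max_iter: int = 50) -> CoxFit:
    """Newton-Raphson Cox fit with step-halving.

    Covariates are standardized internally; results are reported on the
    original covariate scale. Non-convergence and diverging coefficients
    (a symptom of complete separation) are reported, never silent.
    """
    df = clinical.table.set_index("sample_id").loc[covariates.index]
    time = df["time"].to_numpy(dtype=float)
    event = df["event"].to_numpy(dtype=float)
    if event.sum() < 1:
        raise ValueError("no events in the data")
    X = covariates.to_numpy(dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    if np.any(sd == 0):
        bad = list(covariates.columns[sd == 0])
        raise ValueError(f"constant covariate(s): {bad}")
    Xs = (X - mu) / sd

    beta = np.zeros(Xs.shape[1])
    ll = breslow_loglik(beta, time, event, Xs)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        grad, hess = breslow_grad_hess(beta, time, event, Xs)
        if np.linalg.norm(grad) < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(hess, -grad)
        except np.linalg.LinAlgError:
            step = grad * 1e-3
        # step-halving: never decrease the log partial likelihood
        alpha = 1.0
        for _ in range(30):
            cand = beta + alpha * step
            ll_new = breslow_loglik(cand, time, event, Xs)
            if ll_new >= ll - 1e-12:
                break
            alpha /= 2.0
        beta = beta + alpha * step
        ll = breslow_loglik(beta, time, event, Xs)
        if np.any(np.abs(beta) > 50):
            raise ValueError("diverging coefficients (possible complete separation)")
    else:
        it = max_iter
    grad, hess = breslow_grad_hess(beta, time, event, Xs)
    if np.linalg.norm(grad) < max(tol, 1e-6):
        converged = True
    info = -hess
    cov = np.linalg.inv(info)
    se_std = np.sqrt(np.diag(cov))
    coef = beta / sd
    se = se_std / sd
    z = coef / se
    p = 2.0 * scipy.stats.norm.sf(np.abs(z))
    cols = covariates.columns
    return CoxFit(
        coef=pd.Series(coef, index=cols),
        se=pd.Series(se, index=cols),
        z=pd.Series(z, index=cols),
        p=pd.Series(np.clip(p, np.finfo(float).tiny, 1.0), index=cols),
        log_partial_likelihood=float(ll),
        n_events=int(event.sum()),
        converged=converged,
        n_iter=it,
    )


# ---------------------------------------------------------------------------
# Kaplan-Meier and log-rank
# ---------------------------------------------------------------------------

@dataclass
class SurvivalCurvePair:
    """Per-group Kaplan-Meier step functions with the two-group log-rank
    test (NaN when undefined, e.g. no events)."""

    curves: dict[str, pd.DataFrame]   # columns: time, at_risk, events, survival
    logrank_chi2: float
    logrank_p: float


def km_curve(time: np.ndarray, event: np.ndarray) -> pd.DataFrame:
    """Product-limit estimate as a step table starting at S=1."""
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event)
    tab = kmf.event_table
    surv = kmf.survival_function_.iloc[:, 0]
    return pd.DataFrame({
        "time": tab.index.to_numpy(dtype=float),
        "at_risk": tab["at_risk"].to_numpy(dtype=float),
        "events": tab["observed"].to_numpy(dtype=float),
        "survival": surv.reindex(tab.index).to_numpy(dtype=float),
    })


def km_logrank(clinical: ClinicalTable, groups: pd.Series) -> SurvivalCurvePair:
    """Kaplan-Meier curves per group and the two-group log-rank test."""
    df = clinical.table.set_index("sample_id")
    groups = groups.reindex(df.index).dropna()
    names = sorted(groups.unique())
    if len(names) != 2:
        raise ValueError(f"expected exactly 2 groups, got {names}")
    curves = {}
    args = []
    for name in names:
        ids = groups.index[groups == name]
        if len(ids) == 0:
            raise ValueError(f"group {name!r} is empty")
        t = df.loc[ids, "time"].to_numpy(dtype=float)
        e = df.loc[ids, "event"].to_numpy(dtype=float)
        curves[name] = km_curve(t, e)
        args.append((t, e))
    total_events = sum(a[1].sum() for a in args)
    if total_events == 0:
        return SurvivalCurvePair(curves, float("nan"), float("nan"))
    res = logrank_test(args[0][0], args[1][0],
                       event_observed_A=args[0][1], event_observed_B=args[1][1])
    return SurvivalCurvePair(curves, float(res.test_statistic), float(res.p_value))


# ---------------------------------------------------------------------------
# Time-dependent ROC
# ---------------------------------------------------------------------------

def _km_at(time: np.ndarray, event: np.ndarray, horizon: float) -> float:
    """Kaplan-Meier survival probability at the horizon (product-limit)."""
    order = np.argsort(time, kind="stable")
    t, e = time[order], event[order]
    n = len(t)
    s = 1.0
    i = 0
    while i < n and t[i] <= horizon:
        j = i
        d = 0.0
        while j < n and t[j] == t[i]:
            d += e[j]
            j += 1
        at_risk = n - i
        if d > 0:
            s *= 1.0 - d / at_risk
        i = j
    return s


def time_dependent_roc(risk_scores: pd.Series, clinical: ClinicalTable,
                       horizon: float) -> dict:
    """Cumulative/dynamic ROC at ``horizon`` with the Kaplan-Meier
    estimator; AUC by trapezoid over the cutoff-swept curve."""
    df = clinical.table.set_index("sample_id").loc[risk_scores.index]
    time = df["time"].to_numpy(dtype=float)
    event = df["event"].to_numpy(dtype=float)
    m = risk_scores.to_numpy(dtype=float)
    if horizon <= 0 or horizon > time.max():
        raise ValueError("horizon outside the observed time range")
    s_all = _km_at(time, event, horizon)
    if s_all >= 1.0:
        raise ValueError("no events by the horizon")
    if np.all((event == 0) & (time < horizon)):
        raise ValueError("all subjects censored before the horizon")
    cuts = np.unique(m)
    fpr = [1.0]
    tpr = [1.0]
    n = len(m)
    for c in cuts:
        sel = m > c
        p_c = sel.mean()
        if p_c == 0:
            s_c = 1.0
        else:
            s_c = _km_at(time[sel], event[sel], horizon)
        tp = (1.0 - s_c) * p_c / (1.0 - s_all)
        fp = s_c * p_c / s_all if s_all > 0 else 0.0
        tpr.append(min(max(tp, 0.0), 1.0))
        fpr.append(min(max(fp, 0.0), 1.0))
    fpr.append(0.0)
    tpr.append(0.0)
    # round away 1-ulp noise before ordering the staircase vertices
    fpr_arr = np.round(np.array(fpr)[::-1], 12)
    tpr_arr = np.round(np.array(tpr)[::-1], 12)
    order = np.lexsort((tpr_arr, fpr_arr))
    fpr_arr, tpr_arr = fpr_arr[order], tpr_arr[order]
    auc = float(np.trapezoid(tpr_arr, fpr_arr))
    return {"fpr": fpr_arr, "tpr": tpr_arr, "auc": auc,
            "horizon": horizon, "km_survival_at_horizon": s_all}
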