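"""Cox proportional-hazards risk stratification and survival statistics.

The Cox model h(t|X) = h0(t) exp(beta' X) is fitted by Newton-Raphson
maximization of the partial likelihood (Efron tie handling by default,
Breslow available), with step-halving on overshoot and a ridge fallback
when the likelihood is monotone (perfect separation). Standard errors come
from the inverse observed information; 95% CIs are beta +/- 1.96 se.

Downstream: risk scores RS_i = beta' X_i, a median high/low split (ties go
to low risk), the Kaplan-Meier product-limit estimator, the log-rank test,
Harrell's C, cumulative-case/dynamic-control time-dependent AUC, and a
Schoenfeld-residual check of the proportional-hazards assumption with a
stratified refit as the fallback.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist
from scipy.stats import pearsonr, norm
from sklearn.base import BaseEstimator

__all__ = [
    "CoxFit",
    "fit_cox",
    "CoxPH",
    "risk_scores",
    "median_split",
    "kaplan_meier",
    "log_rank",
    "c_index",
    "td_auc",
    "schoenfeld_check",
]


@dataclass
class CoxFit:
    beta: np.ndarray
    se: np.ndarray
    hr: np.ndarray
    hr_ci: np.ndarray  # (p, 2) lower/upper on the hazard-ratio scale
    loglik_trace: list[float]
    converged: bool
    ridge_used: bool
    c_index: float
    feature_names: list[str]
    ties_rule: str
    covariance: np.ndarray | None = None

    def as_dict(self) -> dict:
        return {
            "beta": self.beta.tolist(),
            "se": self.se.tolist(),
            "hr": self.hr.tolist(),
            "hr_ci": self.hr_ci.tolist(),
            "c_index": self.c_index,
            "converged": self.converged,
            "ridge_used": self.ridge_used,
            "ties_rule": self.ties_rule,
            "feature_names": self.feature_names,
        }


def _split_records(records: pd.DataFrame):
    cov_cols = [c for c in records.columns if c not in {"sample_id", "time", "event", "stratum"}]
    X = records[cov_cols].to_numpy(dtype=float)
    t = records["time"].to_numpy(dtype=float)
    d = records["event"].to_numpy(dtype=int)
    if (t <= 0).any():
        raise ValueError("times must be positive")
    if not np.isfinite(X).all():
        raise ValueError("covariates must be finite")
    return X, t, d, cov_cols


def _loglik_grad_hess(beta, X, t, d, ties: str, ridge: float = 0.0):
    """Partial log-likelihood, gradient, and Hessian in one descending-time
    sweep; Efron or Breslow handling of tied event times."""
    n, p = X.shape
    eta = X @ beta
    w = np.exp(eta)
    order = np.argsort(-t, kind="stable")
    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    S0, S1, S2 = 0.0, np.zeros(p), np.zeros((p, p))
    i = 0
    while i < n:
        j = i
        ti = t[order[i]]
        while j < n and t[order[j]] == ti:
            j += 1
        block = order[i:j]
        wb = w[block]
        Xb = X[block]
        S0 += wb.sum()
        S1 += wb @ Xb
        S2 += (Xb * wb[:, None]).T @ Xb
        ev = block[d[block] == 1]
        dk = len(ev)
        if dk:
            we = w[ev]
            Xe = X[ev]
            ll += eta[ev].sum()
            grad += Xe.sum(axis=0)
            if ties == "efron":
                S0d = we.sum()
                S1d = we @ Xe
                S2d = (Xe * we[:, None]).T @ Xe
                for l in range(dk):
                    f = l / dk
                    phi = S0 - f * S0d
                    s1 = S1 - f * S1d
                    s2 = S2 - f * S2d
                    ll -= np.log(phi)
                    grad -= s1 / phi
                    hess -= s2 / phi - np.outer(s1, s1) / phi**2
            else:  # breslow
                ll -= dk * np.log(S0)
                grad -= dk * S1 / S0
                hess -= dk * (S2 / S0 - np.outer(S1, S1) / S0**2)
        i = j
    if ridge > 0:
        ll -= 0.5 * ridge * beta @ beta
        grad -= ridge * beta
        hess -= ridge * np.eye(p)
    return ll, grad, hess


def _newton(X, t, d, ties, ridge, max_iter=100, tol=1e-9):
    p = X.shape[1]
    beta = np.zeros(p)
    ll, grad, hess = _loglik_grad_hess(beta, X, t, d, ties, ridge)
    trace = [ll]
    converged = False
    for _ in range(max_iter):
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError:
            return beta, trace, False, hess
        new_beta = beta + step
        new_ll, new_grad, new_hess = _loglik_grad_hess(new_beta, X, t, d, ties, ridge)
        halvings = 0
        while (not np.isfinite(new_ll) or new_ll < ll) and halvings < 30:
            step *= 0.5
            new_beta = beta + step
            new_ll, new_grad, new_hess = _loglik_grad_hess(new_beta, X, t, d, ties, ridge)
            halvings += 1
        beta, grad, hess = new_beta, new_grad, new_hess
        trace.append(new_ll)
        if abs(new_ll - ll) < tol * (abs(ll) + 1.0):
            converged = True
            ll = new_ll
            break
        ll = new_ll
    return beta, trace, converged, hess


def fit_cox(records: pd.DataFrame, ties_rule: str = "efron", ridge: float = 0.0,
            alpha: float = 0.05) -> CoxFit:
    """Fit the proportional-hazards model on a records frame with columns
    ``time``, ``event`` and one column per covariate.

    Monotone likelihood (runaway coefficients or a singular information
    matrix) triggers an automatic ridge refit, flagged in the result.
    """
    if ties_rule not in {"efron", "breslow"}:
        raise ValueError("ties_rule must be efron or breslow")
    X, t, d, names = _split_records(records)
    if d.sum() == 0:
        raise ValueError("no events")
    beta, trace, converged, hess = _newton(X, t, d, ties_rule, ridge)
    ridge_used = ridge > 0
    scale = X.std(axis=0)
    # monotone likelihood / separation: per-sd log-hazard beyond e^10 is a
    # runaway coefficient, not a finite maximizer
    if not converged or np.abs(beta * np.where(scale > 0, scale, 1.0)).max() > 10:
        ridge_used = True
        beta, trace, converged, hess = _newton(X, t, d, ties_rule, ridge=0.1)
    info = -hess
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.full((len(beta), len(beta)), np.nan)
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    z = norm.ppf(1 - alpha / 2)
    ci = np.exp(np.column_stack([beta - z * se, beta + z * se]))
    rs = X @ beta
    cidx = c_index(records, rs)
    return CoxFit(
        beta=beta,
        se=se,
        hr=np.exp(beta),
        hr_ci=ci,
        loglik_trace=trace,
        converged=converged,
        ridge_used=ridge_used,
        c_index=cidx,
        feature_names=names,
        ties_rule=ties_rule,
        covariance=cov,
    )


class CoxPH(BaseEstimator):
    """sklearn-style wrapper: ``fit(X, y)`` with y a (time, event) 2-column
    array or structured array; ``predict(X)`` returns risk scores."""

    def __init__(self, ties_rule: str = "efron", ridge: float = 0.0):
        self.ties_rule = ties_rule
        self.ridge = ridge

    @staticmethod
    def _coerce_y(y):
        y = np.asarray(y)
        if y.dtype.names:
            fields = y.dtype.names
            return y[fields[-1]].astype(float), y[fields[0]].astype(int)
        y = np.atleast_2d(y.astype(float))
        return y[:, 0], y[:, 1].astype(int)

    def fit(self, X, y):
        if isinstance(X, pd.DataFrame):
            names = [str(c) for c in X.columns]
            Xa = X.to_numpy(dtype=float)
        else:
            Xa = np.asarray(X, dtype=float)
            names = [f"x{i}" for i in range(Xa.shape[1])]
        t, d = self._coerce_y(y)
        records = pd.DataFrame(Xa, columns=names)
        records["time"] = t
        records["event"] = d
        fit = fit_cox(records, ties_rule=self.ties_rule, ridge=self.ridge)
        self.fit_ = fit
        self.coef_ = fit.beta
        self.se_ = fit.se
        self.feature_names_in_ = np.array(names)
        return self

    def predict(self, X):
        Xa = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
        return Xa @ self.coef_


def risk_scores(fit: CoxFit, X) -> np.ndarray:
    """RS_i = beta_hat' X_i (no centering)."""
    Xa = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    if Xa.shape[1] != len(fit.beta):
        raise ValueError("covariate dimension mismatch")
    return Xa @ fit.beta


def median_split(rs) -> np.ndarray:
    """'high' where RS > median, 'low' otherwise (ties at the median are
    conservative: low risk)."""
    rs = np.asarray(rs, dtype=float)
    if len(rs) < 2:
        raise ValueError("need at least 2 samples")
    med = np.median(rs)
    return np.where(rs > med, "high", "low")


def kaplan_meier(records: pd.DataFrame) -> pd.DataFrame:
    """Product-limit estimator; one row per distinct event time with the
    at-risk count, events, and the survival value after the drop."""
    t = records["time"].to_numpy(dtype=float)
    d = records["event"].to_numpy(dtype=int)
    order = np.argsort(t, kind="stable")
    t, d = t[order], d[order]
    rows = []
    s = 1.0
    n = len(t)
    i = 0
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        at_risk = n - i
        events = int(d[i:j].sum())
        if events:
            s *= 1.0 - events / at_risk
            rows.append({"time": t[i], "n_risk": at_risk, "n_event": events, "survival": s})
        i = j
    return pd.DataFrame(rows, columns=["time", "n_risk", "n_event", "survival"])


def km_at(km: pd.DataFrame, t: float) -> float:
    """Evaluate the right-continuous KM step function at time t."""
    past = km[km["time"] <= t]
    return 1.0 if past.empty else float(past["survival"].iloc[-1])


def log_rank(records: pd.DataFrame, groups) -> tuple[float, float]:
    """Two-group log-rank test: (chi-square, p) from the observed-minus-
    expected events with hypergeometric variance at each event time."""
    groups = np.asarray(groups)
    levels = np.unique(groups)
    if len(levels) != 2:
        raise ValueError("log-rank here compares exactly two groups")
    t = records["time"].to_numpy(dtype=float)
    d = records["event"].to_numpy(dtype=int)
    g1 = groups == levels[0]
    event_times = np.unique(t[d == 1])
    if len(event_times) == 0:
        raise ValueError("no events")
    o_minus_e = 0.0
    var = 0.0
    for et in event_times:
        at_risk = t >= et
        n = at_risk.sum()
        n1 = (at_risk & g1).sum()
        if n1 == 0 and not (at_risk & ~g1).any():
            raise ValueError("empty risk set")
        dt = int(((t == et) & (d == 1)).sum())
        d1 = int(((t == et) & (d == 1) & g1).sum())
        e1 = dt * n1 / n
        o_minus_e += d1 - e1
        if n > 1:
            var += dt * (n1 / n) * (1 - n1 / n) * (n - dt) / (n - 1)
    if var == 0:
        return 0.0, 1.0
    chi2 = o_minus_e**2 / var
    return float(chi2), float(chi2_dist.sf(chi2, 1))


def c_index(records: pd.DataFrame, rs) -> float:
    """Harrell's concordance over usable pairs; tied risk scores count 0.5.

    A pair (i, j) is comparable when t_i < t_j and subject i had the event.
    """
    t = records["time"].to_numpy(dtype=float)
    d = records["event"].to_numpy(dtype=int)
    rs = np.asarray(rs, dtype=float)
    earlier = (t[:, None] < t[None, :]) & (d[:, None] == 1)
    if not earlier.any():
        raise ValueError("no comparable pairs")
    higher = rs[:, None] > rs[None, :]
    tied = rs[:, None] == rs[None, :]
    concordant = (earlier & higher).sum() + 0.5 * (earlier & tied).sum()
    return float(concordant / earlier.sum())


def td_auc(records: pd.DataFrame, rs, horizons=(1.0, 3.0, 5.0)) -> pd.DataFrame:
    """Cumulative-case/dynamic-control AUC at each horizon h.

    Cases: event by h; controls: still at risk past h; censored subjects
    with time <= h are excluded. Degenerate horizons (no cases or no
    controls) are flagged invalid rather than raised.
    """
    t = records["time"].to_numpy(dtype=float)
    d = records["event"].to_numpy(dtype=int)
    rs = np.asarray(rs, dtype=float)
    rows = []
    for h in horizons:
        cases = (t <= h) & (d == 1)
        controls = t > h
        if cases.sum() == 0 or controls.sum() == 0:
            rows.append({"horizon": h, "auc": np.nan, "n_cases": int(cases.sum()),
                         "n_controls": int(controls.sum()), "valid": False})
            continue
        a, b = rs[cases], rs[controls]
        wins = (a[:, None] > b[None, :]).sum() + 0.5 * (a[:, None] == b[None, :]).sum()
        rows.append({
            "horizon": h,
            "auc": float(wins / (len(a) * len(b))),
            "n_cases": int(cases.sum()),
            "n_controls": int(controls.sum()),
            "valid": True,
        })
    return pd.DataFrame(rows)


def schoenfeld_check(fit: CoxFit, records: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Scaled Schoenfeld residuals against event rank-time.

    Per covariate: Pearson correlation of the scaled residual with the rank
    of the event time and its test p; p < alpha flags a proportional-
    hazards violation.
    """
    X, t, d, names = _split_records(records)
    ev = np.flatnonzero(d == 1)
    if len(ev) < 3:
        raise ValueError("need at least 3 events")
    eta = X @ fit.beta
    w = np.exp(eta)
    resid = np.zeros((len(ev), len(fit.beta)))
    order = np.argsort(t[ev], kind="stable")
    ev = ev[order]
    for k, i in enumerate(ev):
        at_risk = t >= t[i]
        ww = w[at_risk]
        xbar = (ww[:, None] * X[at_risk]).sum(axis=0) / ww.sum()
        resid[k] = X[i] - xbar
    cov = fit.covariance if fit.covariance is not None else np.eye(len(fit.beta))
    scaled = len(ev) * resid @ cov
    ranks = np.arange(1, len(ev) + 1, dtype=float)
    rows = []
    for j, name in enumerate(names):
        col = scaled[:, j]
        if np.std(col) == 0:
            r, p = 0.0, 1.0
        else:
            r, p = pearsonr(col, ranks)
        rows.append({"covariate": name, "corr": float(r), "p": float(p),
                     "violation": bool(p < alpha)})
    return pd.DataFrame(rows)


def fit_cox_stratified(records: pd.DataFrame, strata, ties_rule: str = "efron",
                       ridge: float = 0.0) -> CoxFit:
    """Stratified Cox fit: the partial likelihood is summed over strata
    (each with its own baseline hazard); the fallback when the PH check
    flags a covariate."""
    strata = np.asarray(strata)
    X, t, d, names = _split_records(records)
    if d.sum() == 0:
        raise ValueError("no events")
    levels = np.unique(strata)

    def lgh(beta, rdg):
        ll, g, h = 0.0, np.zeros(X.shape[1]), np.zeros((X.shape[1], X.shape[1]))
        for lev in levels:
            m = strata == lev
            if d[m].sum() == 0:
                continue
            li, gi, hi = _loglik_grad_hess(beta, X[m], t[m], d[m], ties_rule, 0.0)
            ll += li
            g += gi
            h += hi
        if rdg > 0:
            ll -= 0.5 * rdg * beta @ beta
            g -= rdg * beta
            h -= rdg * np.eye(X.shape[1])
        return ll, g, h

    beta = np.zeros(X.shape[1])
    ll, g, h = lgh(beta, ridge)
    trace = [ll]
    converged = False
    for _ in range(100):
        try:
            step = np.linalg.solve(-h, g)
        except np.linalg.LinAlgError:
            break
        nb = beta + step
        nll, ng, nh = lgh(nb, ridge)
        halv = 0
        while (not np.isfinite(nll) or nll < ll) and halv < 30:
            step *= 0.5
            nb = beta + step
            nll, ng, nh = lgh(nb, ridge)
            halv += 1
        beta, g, h = nb, ng, nh
        trace.append(nll)
        if abs(nll - ll) < 1e-9 * (abs(ll) + 1):
            converged = True
            break
        ll = nll
    try:
        cov = np.linalg.inv(-h)
    except np.linalg.LinAlgError:
        cov = np.full((len(beta), len(beta)), np.nan)
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    ci = np.exp(np.column_stack([beta - 1.96 * se, beta + 1.96 * se]))
    rs = X @ beta
    return CoxFit(
        beta=beta, se=se, hr=np.exp(beta), hr_ci=ci, loglik_trace=trace,
        converged=converged, ridge_used=ridge > 0, c_index=c_index(records, rs),
        feature_names=names, ties_rule=ties_rule, covariance=cov,
    )
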