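"""Survival machinery: Cox regression, concordance, time-dependent ROC, KM.

Everything here is implemented natively so the whole prognosis chain is one
auditable code path: a Newton-Raphson Cox partial-likelihood maximiser with
Breslow tie handling, Harrell's C-index with percentile-bootstrap confidence
intervals and a one-sided permutation comparison between two risk scores,
cumulative-case / dynamic-control time-dependent ROC curves, and the
Kaplan-Meier product-limit estimator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


# --------------------------------------------------------------------------
# Cox proportional hazards
# --------------------------------------------------------------------------

@dataclass
class CoxFit:
    """Cox model fit summary (Breslow ties, Wald inference)."""
    names: list[str]
    beta: np.ndarray
    se: np.ndarray
    loglik: float
    converged: bool
    n_iter: int
    n: int
    n_events: int

    @property
    def hr(self) -> np.ndarray:
        return np.exp(self.beta)

    @property
    def ci(self) -> np.ndarray:
        """95% HR confidence intervals, rows (lower, upper)."""
        lo = np.exp(self.beta - 1.959963984540054 * self.se)
        hi = np.exp(self.beta + 1.959963984540054 * self.se)
        return np.vstack([lo, hi])

    @property
    def p_values(self) -> np.ndarray:
        z = self.beta / self.se
        return 2.0 * stats.norm.sf(np.abs(z))

    def summary_dict(self) -> dict:
        ci = self.ci
        return {name: {"beta": float(b), "hr": float(np.exp(b)),
                       "ci_low": float(ci[0, k]), "ci_high": float(ci[1, k]),
                       "p": float(p), "se": float(s)}
                for k, (name, b, s, p) in enumerate(
                    zip(self.names, self.beta, self.se, self.p_values))}


def _cox_loglik_grad_hess(X: np.ndarray, time: np.ndarray, event: np.ndarray,
                          beta: np.ndarray):
    """Breslow log partial likelihood with analytic gradient and Hessian.

    Subjects are pre-sorted by descending time so risk-set sums are cumsums.
    """
    eta = X @ beta
    eta = np.clip(eta, -500, 500)
    theta = np.exp(eta)
    s0 = np.cumsum(theta)
    s1 = np.cumsum(theta[:, None] * X, axis=0)
    # group tied times: the risk set at a time t is everyone with time >= t
    # -> use the *last* index among the tie group in the descending order
    n = time.size
    last_of_tie = np.empty(n, dtype=np.int64)
    idx = 0
    while idx < n:
        j = idx
        while j + 1 < n and time[j + 1] == time[idx]:
            j += 1
        last_of_tie[idx:j + 1] = j
        idx = j + 1

    ev = np.flatnonzero(event > 0)
    rs = last_of_tie[ev]
    S0 = s0[rs]
    S1 = s1[rs]
    ll = float(eta[ev].sum() - np.log(S0).sum())
    grad = X[ev].sum(axis=0) - (S1 / S0[:, None]).sum(axis=0)

    p = X.shape[1]
    hess = np.zeros((p, p))
    # S2 risk-set sums via cumulative outer products
    xx = X[:, :, None] * X[:, None, :]
    s2 = np.cumsum(theta[:, None, None] * xx, axis=0)
    S2 = s2[rs]
    m = S1 / S0[:, None]
    hess = -(S2 / S0[:, None, None]).sum(axis=0) \
        + np.einsum("ki,kj->ij", m, m)
    return ll, grad, hess


def cox_fit(X: np.ndarray, time: np.ndarray, event: np.ndarray,
            names: list[str] | None = None, tol: float = 1e-9,
            max_iter: int = 100) -> CoxFit:
    """Maximise the Breslow partial likelihood by Newton-Raphson with
    step-halving; standard errors from the inverse observed information.

    Raises on degenerate input (no events, constant covariate) and flags
    non-convergence / likelihood monotonicity instead of returning silently
    wrong estimates.
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    if X.shape[0] == 1 and X.shape[1] > 1 and np.asarray(time).size > 1:
        X = X.T
    time = np.asarray(time, dtype=np.float64)
    event = np.asarray(event, dtype=np.float64)
    n, p = X.shape
    if names is None:
        names = [f"x{i}" for i in range(p)]
    if event.sum() < 1:
        raise ValueError("need at least one event")
    if np.any(X.std(axis=0) == 0):
        raise ValueError("constant covariate in Cox design")

    order = np.argsort(-time, kind="stable")
    Xs, ts, es = X[order], time[order], event[order]

    beta = np.zeros(p)
    ll, grad, hess = _cox_loglik_grad_hess(Xs, ts, es, beta)
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError as exc:
            raise ValueError("singular information matrix "
                             "(possible separation)") from exc
        # step-halving: never decrease the likelihood
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            ll_new, grad_new, hess_new = _cox_loglik_grad_hess(Xs, ts, es, cand)
            if ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        beta, ll, grad, hess = cand, ll_new, grad_new, hess_new
        if np.abs(scale * step).max() < tol:
            converged = True
            break
    if not converged:
        raise ValueError("Cox Newton-Raphson did not converge "
                         "(monotone likelihood / separation?)")
    if np.abs(beta).max() > 50:
        raise ValueError("divergent coefficients: perfect separation")
    cov = np.linalg.inv(-hess)
    se = np.sqrt(np.diag(cov))
    return CoxFit(list(names), beta, se, ll, converged, n_iter,
                  n=n, n_events=int(es.sum()))


def cox_score_at_null(X: np.ndarray, time: np.ndarray,
                      event: np.ndarray) -> np.ndarray:
    """Score vector (gradient of log partial likelihood) at beta = 0."""
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    if X.shape[0] == 1:
        X = X.T
    order = np.argsort(-np.asarray(time, float), kind="stable")
    _, grad, _ = _cox_loglik_grad_hess(
        X[order], np.asarray(time, float)[order],
        np.asarray(event, float)[order], np.zeros(X.shape[1]))
    return grad


# --------------------------------------------------------------------------
# concordance
# --------------------------------------------------------------------------

def concordance_index(score: np.ndarray, time: np.ndarray,
                      event: np.ndarray) -> float:
    """Harrell's C: among pairs whose ordering is determinable under
    censoring (the shorter observed time ended in an event), the fraction
    where the higher score accompanies the shorter survival; score ties
    count 1/2."""
    s = np.asarray(score, dtype=np.float64)
    t = np.asarray(time, dtype=np.float64)
    e = np.asarray(event, dtype=bool)
    # comparable pairs: t_i < t_j with e_i = 1
    ti = t[e][:, None]
    si = s[e][:, None]
    comp = ti < t[None, :]
    n_comp = comp.sum()
    if n_comp == 0:
        raise ValueError("no comparable pairs")
    higher = (si > s[None, :]) & comp
    tied = (si == s[None, :]) & comp
    return float((higher.sum() + 0.5 * tied.sum()) / n_comp)


def c_index_ci(score: np.ndarray, time: np.ndarray, event: np.ndarray,
               n_boot: int = 1000, seed: int = 0) -> tuple[float, float]:
    """Percentile 95% bootstrap CI (subject-level resampling) of the C-index."""
    s = np.asarray(score, float)
    t = np.asarray(time, float)
    e = np.asarray(event, bool)
    n = s.size
    rng = np.random.default_rng(seed)
    vals = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            vals[b] = concordance_index(s[idx], t[idx], e[idx])
        except ValueError:
            vals[b] = np.nan
    vals = vals[np.isfinite(vals)]
    lo, hi = np.percentile(vals, [2.5, 97.5])
    return float(lo), float(hi)


def compare_models_permutation(score_a: np.ndarray, score_b: np.ndarray,
                               time: np.ndarray, event: np.ndarray,
                               n_perm: int = 1000, seed: int = 0) -> float:
    """One-sided permutation p-value for C(A) > C(B).

    Null draws swap, independently per subject with probability 1/2, which
    model's score the subject contributes to each group; p uses the add-one
    rule so it is never below 1/(n_perm+1).
    """
    a = np.asarray(score_a, float)
    b = np.asarray(score_b, float)
    if a.shape != b.shape:
        raise ValueError("score vectors must have equal length")
    t = np.asarray(time, float)
    e = np.asarray(event, bool)
    obs = concordance_index(a, t, e) - concordance_index(b, t, e)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        swap = rng.random(a.size) < 0.5
        pa = np.where(swap, b, a)
        pb = np.where(swap, a, b)
        null = concordance_index(pa, t, e) - concordance_index(pb, t, e)
        if null >= obs:
            count += 1
    return (1 + count) / (n_perm + 1)


# --------------------------------------------------------------------------
# time-dependent ROC
# --------------------------------------------------------------------------

def mann_whitney_auc(case_scores: np.ndarray, control_scores: np.ndarray) -> float:
    """AUC via the Mann-Whitney U statistic with tie correction."""
    n1 = case_scores.size
    n0 = control_scores.size
    if n1 == 0 or n0 == 0:
        raise ValueError("need at least one case and one control")
    allscores = np.concatenate([case_scores, control_scores])
    ranks = stats.rankdata(allscores)
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def td_roc(score: np.ndarray, time: np.ndarray, event: np.ndarray,
           horizon_months: float) -> tuple[np.ndarray, float, dict]:
    """Cumulative-case / dynamic-control ROC at a horizon.

    Cases: event with time <= t.  Controls: observed time > t.  Subjects
    censored at or before t without an event are excluded (their status at
    t is unknown); the exclusion count is reported alongside the curve.
    Returns (roc_points [n,2] as (FPR, TPR), AUC, info).
    """
    s = np.asarray(score, float)
    t = np.asarray(time, float)
    e = np.asarray(event, bool)
    case = e & (t <= horizon_months)
    control = t > horizon_months
    excluded = ~case & ~control
    if case.sum() == 0 or control.sum() == 0:
        raise ValueError(f"no cases or no controls at {horizon_months} months")
    auc = mann_whitney_auc(s[case], s[control])
    thresholds = np.r_[np.inf, np.sort(np.unique(s))[::-1]]
    tpr = [(s[case] >= th).mean() for th in thresholds]
    fpr = [(s[control] >= th).mean() for th in thresholds]
    roc = np.column_stack([fpr, tpr])
    info = {"n_cases": int(case.sum()), "n_controls": int(control.sum()),
            "n_excluded_censored": int(excluded.sum())}
    return roc, auc, info


def td_auc(score, time, event, horizon_months) -> float:
    return td_roc(score, time, event, horizon_months)[1]


# --------------------------------------------------------------------------
# Kaplan-Meier
# --------------------------------------------------------------------------

@dataclass
class KMCurve:
    """Product-limit survival curve for one group."""
    times: np.ndarray        # unique event times, ascending
    survival: np.ndarray     # S(t) just after each event time
    at_risk: np.ndarray      # risk-set size just before each event time
    n_events: np.ndarray

    def at(self, t: float) -> float:
        """S(t) with S(0) = 1 and right-continuous steps."""
        k = np.searchsorted(self.times, t, side="right")
        return 1.0 if k == 0 else float(self.survival[k - 1])


def km_estimate(time: np.ndarray, event: np.ndarray,
                group_labels: np.ndarray | None = None) -> dict[object, KMCurve]:
    """Kaplan-Meier curves per group (one group if labels are None)."""
    t = np.asarray(time, float)
    e = np.asarray(event, bool)
    if group_labels is None:
        group_labels = np.zeros(t.size, dtype=int)
    groups = np.asarray(group_labels)
    out: dict[object, KMCurve] = {}
    for g in np.unique(groups):
        sel = groups == g
        if not sel.any():
            raise ValueError(f"empty group {g!r}")
        tg, eg = t[sel], e[sel]
        order = np.argsort(tg, kind="stable")
        tg, eg = tg[order], eg[order]
        ev_times = np.unique(tg[eg])
        surv = []
        atrisk = []
        nev = []
        s = 1.0
        for et in ev_times:
            n_at = int((tg >= et).sum())
            d = int((eg & (tg == et)).sum())
            s *= 1.0 - d / n_at
            surv.append(s)
            atrisk.append(n_at)
            nev.append(d)
        out[g] = KMCurve(ev_times, np.asarray(surv), np.asarray(atrisk),
                         np.asarray(nev))
    return out
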