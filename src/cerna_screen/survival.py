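"""From-scratch survival and association statistics for the cohort screens.

Kaplan-Meier product-limit estimation, the two-group log-rank test, Cox
proportional-hazards regression (Efron tie handling, damped Newton), Spearman
rank correlation with average-rank ties, and expression dichotomization.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import stats

__all__ = [
    "SubjectRecord",
    "KmCurve",
    "LogRankResult",
    "CoxResult",
    "km_estimate",
    "survival_at",
    "logrank_test",
    "cox_fit",
    "spearman_rho",
    "dichotomize",
]


@dataclass
class SubjectRecord:
    """One patient: follow-up time (months), event flag, gene expression."""

    id: str
    time: float
    event: int  # 1 = death, 0 = censored
    expr: Dict[str, float] = field(default_factory=dict)
    group: Optional[str] = None  # "low" | "high"

    def __post_init__(self) -> None:
        if not (math.isfinite(self.time) and self.time > 0):
            raise ValueError(f"subject {self.id!r}: time must be finite and > 0")
        if self.event not in (0, 1):
            raise ValueError(f"subject {self.id!r}: event must be 0 or 1")


@dataclass
class KmCurve:
    times: np.ndarray  # distinct event times, ascending
    survival: np.ndarray  # S(t) at each event time
    at_risk: np.ndarray
    events: np.ndarray


@dataclass
class LogRankResult:
    chi_square: float
    p_value: float
    observed: Tuple[float, float]
    expected: Tuple[float, float]


@dataclass
class CoxResult:
    covariates: List[str]
    beta: np.ndarray
    se: np.ndarray
    converged: bool
    n_events: int

    @property
    def hr(self) -> np.ndarray:
        return np.exp(self.beta)

    @property
    def ci95(self) -> Tuple[np.ndarray, np.ndarray]:
        z = 1.959963984540054  # Phi^-1(0.975)
        return np.exp(self.beta - z * self.se), np.exp(self.beta + z * self.se)

    @property
    def p_value(self) -> np.ndarray:
        z = np.divide(self.beta, self.se, out=np.zeros_like(self.beta),
                      where=self.se > 0)
        return 2.0 * stats.norm.sf(np.abs(z))


def km_estimate(records: Sequence[SubjectRecord]) -> KmCurve:
    """Product-limit estimator; censored subjects leave the risk set after
    their time (ties: deaths at t are counted before censorings at t)."""
    if not records:
        raise ValueError("empty cohort")
    times = np.array([r.time for r in records], dtype=float)
    events = np.array([r.event for r in records], dtype=int)
    event_times = np.unique(times[events == 1])
    surv, n_risk, n_events = [], [], []
    s = 1.0
    for t in event_times:
        n = int(np.sum(times >= t))
        d = int(np.sum((times == t) & (events == 1)))
        s *= 1.0 - d / n
        surv.append(s)
        n_risk.append(n)
        n_events.append(d)
    return KmCurve(
        times=event_times,
        survival=np.array(surv),
        at_risk=np.array(n_risk),
        events=np.array(n_events),
    )


def survival_at(curve: KmCurve, t: float) -> float:
    """Right-continuous step-function evaluation of S(t); S(0) = 1."""
    if t < 0:
        raise ValueError("t must be >= 0")
    idx = np.searchsorted(curve.times, t, side="right") - 1
    if idx < 0:
        return 1.0
    return float(curve.survival[idx])


def logrank_test(
    a: Sequence[SubjectRecord], b: Sequence[SubjectRecord]
) -> LogRankResult:
    """Two-group log-rank test with the hypergeometric variance."""
    if not a or not b:
        raise ValueError("both groups must be non-empty")
    times = np.array([r.time for r in list(a) + list(b)], dtype=float)
    events = np.array([r.event for r in list(a) + list(b)], dtype=int)
    grp = np.array([0] * len(a) + [1] * len(b))
    if events.sum() == 0:
        raise ValueError("no events in either group")
    o_a = e_a = v = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = at_risk.sum()
        n_a = (at_risk & (grp == 0)).sum()
        dying = (times == t) & (events == 1)
        d = dying.sum()
        d_a = (dying & (grp == 0)).sum()
        o_a += d_a
        e_a += d * n_a / n
        if n > 1:
            v += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    total_events = float(events.sum())
    if v <= 0:
        chi = 0.0
    else:
        chi = (o_a - e_a) ** 2 / v
    p = float(stats.chi2.sf(chi, df=1)) if chi > 0 else 1.0
    return LogRankResult(
        chi_square=float(chi),
        p_value=p,
        observed=(float(o_a), total_events - float(o_a)),
        expected=(float(e_a), total_events - float(e_a)),
    )


def _cox_loglik(beta, X, times, events):
    """Efron partial log-likelihood with gradient and Hessian."""
    eta = X @ beta
    # clip for numerical safety; separation is flagged by the caller
    w = np.exp(np.clip(eta, -500, 500))
    p = X.shape[1]
    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    for t in np.unique(times[events == 1]):
        risk = times >= t
        dying = (times == t) & (events == 1)
        d = int(dying.sum())
        s_r = w[risk].sum()
        u_r = w[risk] @ X[risk]
        m_r = (w[risk][:, None] * X[risk]).T @ X[risk]
        s_d = w[dying].sum()
        u_d = w[dying] @ X[dying]
        m_d = (w[dying][:, None] * X[dying]).T @ X[dying]
        ll += eta[dying].sum()
        for l in range(d):
            f = l / d
            phi = s_r - f * s_d
            mu = (u_r - f * u_d) / phi
            ll -= math.log(phi)
            grad_term = mu
            grad -= grad_term
            hess -= (m_r - f * m_d) / phi - np.outer(mu, mu)
        grad += X[dying].sum(axis=0)
    return ll, grad, hess


def cox_fit(
    records: Sequence[SubjectRecord],
    covariates: Sequence[str],
    max_iter: int = 50,
    tol: float = 1e-8,
) -> CoxResult:
    """Cox proportional-hazards fit maximizing the Efron partial likelihood.

    ``covariates`` are gene-expression keys, or the literal "group" to use
    each record's low/high label (high = 1).  Newton iterations with step
    halving; 95% CI from the inverse observed information.
    """
    covariates = list(covariates)
    n = len(records)
    X = np.empty((n, len(covariates)))
    for j, cov in enumerate(covariates):
        if cov == "group":
            col = [1.0 if r.group == "high" else 0.0 for r in records]
        else:
            try:
                col = [r.expr[cov] for r in records]
            except KeyError:
                raise KeyError(f"covariate {cov!r} missing from cohort expression")
        X[:, j] = col
    times = np.array([r.time for r in records], dtype=float)
    events = np.array([r.event for r in records], dtype=int)
    if events.sum() < 1:
        raise ValueError("no events in cohort")
    for j, cov in enumerate(covariates):
        if np.unique(X[:, j]).size < 2:
            raise ValueError(f"covariate {cov!r} is constant")

    beta = np.zeros(len(covariates))
    ll, grad, hess = _cox_loglik(beta, X, times, events)
    converged = False
    for _ in range(max_iter):
        if np.linalg.norm(grad) < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError:
            break
        # damped Newton: halve until the partial likelihood improves
        alpha = 1.0
        for _ in range(30):
            ll_new, grad_new, hess_new = _cox_loglik(
                beta + alpha * step, X, times, events
            )
            # tolerance scaled to |ll|: near the optimum the difference is
            # below float precision and the full Newton step must be accepted
            if ll_new >= ll - 1e-10 * (1.0 + abs(ll)):
                break
            alpha /= 2.0
        beta = beta + alpha * step
        ll, grad, hess = ll_new, grad_new, hess_new
    else:
        if np.linalg.norm(grad) < tol:
            converged = True
    if np.max(np.abs(beta)) > 20:
        warnings.warn("possible separation: |beta| > 20", RuntimeWarning)
    try:
        cov_mat = np.linalg.inv(-hess)
        se = np.sqrt(np.clip(np.diag(cov_mat), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(len(covariates), np.nan)
        converged = False
    return CoxResult(
        covariates=covariates,
        beta=beta,
        se=se,
        converged=converged,
        n_events=int(events.sum()),
    )


def _average_ranks(x: np.ndarray) -> np.ndarray:
    """Ranks 1..n with ties sharing their average rank."""
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(len(x), dtype=float)
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and x[order[j + 1]] == x[order[i]]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def spearman_rho(
    x: Sequence[float], y: Sequence[float]
) -> Tuple[float, float]:
    """Spearman correlation (average-rank ties) with the t-approximation p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    rx, ry = _average_ranks(x), _average_ranks(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float(rx @ rx) * float(ry @ ry))
    if denom == 0:
        raise ValueError("constant input: rho undefined")
    rho = float(rx @ ry) / denom
    rho = max(-1.0, min(1.0, rho))
    if abs(rho) == 1.0:
        p = 0.0
    else:
        t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
        p = 2.0 * float(stats.t.sf(abs(t), df=n - 2))
    return rho, p


def dichotomize(
    values: Sequence[float],
    method: Union[str, float] = "median",
    outcomes: Optional[Sequence[int]] = None,
) -> List[str]:
    """Split subjects into "low"/"high" groups.

    method: "median" (high iff value > sample median; ties at the median go
    low), a numeric cutoff c (high iff value > c), or "youden" (requires
    binary ``outcomes``; high iff value >= the Youden-optimal cutoff).
    """
    vals = np.asarray(values, dtype=float)
    if len(vals) < 2:
        raise ValueError("need at least 2 subjects")
    if np.unique(vals).size < 2:
        raise ValueError("all values identical: cannot dichotomize")
    if method == "median":
        thr = float(np.median(vals))
        return ["high" if v > thr else "low" for v in vals]
    if method == "youden":
        if outcomes is None:
            raise ValueError("youden method requires outcomes")
        from .ish import youden_cutoff

        cut, _ = youden_cutoff(vals, outcomes, candidates=sorted(set(vals)))
        return ["high" if v >= cut else "low" for v in vals]
    thr = float(method)
    return ["high" if v > thr else "low" for v in vals]
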