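"""Low-level Cox proportional-hazards primitives.

A screening run fits thousands of single-covariate Cox models (one per
candidate gene pair), so the univariate fitter here is vectorised across
covariates: one Newton iteration updates every model simultaneously.
Ties in event times are handled by Efron's approximation, which reduces
to the exact partial likelihood when event times are distinct.
Correctness is cross-checked against ``lifelines`` in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "UnivariateCoxResult",
    "fit_univariate_cox",
    "cox_partial_loglik",
    "breslow_baseline_hazard",
]

# |beta| beyond this signals monotone likelihood (complete separation);
# the Wald statistic is meaningless there, so the fit is flagged.
_BETA_BOUND = 15.0


@dataclass(frozen=True)
class UnivariateCoxResult:
    """Per-covariate results of independent single-covariate Cox fits."""

    coef: np.ndarray
    se: np.ndarray
    z: np.ndarray
    p: np.ndarray
    converged: np.ndarray  # False for constant covariates or separation

    def __len__(self) -> int:
        return self.coef.size


def _event_groups(time_sorted: np.ndarray, event_sorted: np.ndarray):
    """Indices of tied event-time groups, in increasing time order.

    Yields (first_at_risk_index, event_index_array) pairs where
    ``first_at_risk_index`` is the position of the first subject whose
    time is >= the group's event time (risk set = suffix from there).
    """
    ev_idx = np.flatnonzero(event_sorted == 1)
    if ev_idx.size == 0:
        return
    ev_times = time_sorted[ev_idx]
    # boundaries of runs of equal event times
    starts = np.flatnonzero(np.r_[True, np.diff(ev_times) > 0])
    bounds = np.r_[starts, ev_times.size]
    for k in range(starts.size):
        members = ev_idx[bounds[k] : bounds[k + 1]]
        t = time_sorted[members[0]]
        first = np.searchsorted(time_sorted, t, side="left")
        yield first, members


def fit_univariate_cox(
    X: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    max_iter: int = 50,
    tol: float = 1e-9,
) -> UnivariateCoxResult:
    """Fit one single-covariate Cox PH model per row of ``X``.

    Parameters
    ----------
    X : array, shape (p, n) or (n,)
        Covariate values; each row is fitted independently.
    time, event : arrays, shape (n,)
        Right-censored follow-up times and event indicators in {0, 1}.

    Returns
    -------
    UnivariateCoxResult with Wald statistics per covariate. Covariates
    that are constant, or whose likelihood is monotone (separation),
    come back with ``converged=False`` and NaN statistics.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    p, n = X.shape
    if time.shape != (n,) or event.shape != (n,):
        raise ValueError("time/event length must match number of samples")
    if int(event.sum()) < 2:
        raise ValueError("need at least two events to fit Cox models")

    order = np.argsort(time, kind="stable")
    ts, es, Xs = time[order], event[order], X[:, order]

    groups = list(_event_groups(ts, es))
    fittable = np.ptp(Xs, axis=1) > 0

    beta = np.zeros(p)
    active = fittable.copy()
    for _ in range(max_iter):
        if not active.any():
            break
        grad, hess = _gradient_hessian(beta, Xs, groups)
        step = np.zeros(p)
        ok = active & (hess < 0)
        step[ok] = -grad[ok] / hess[ok]
        np.clip(step, -2.0, 2.0, out=step)  # damp early overshoot
        beta = np.where(active, beta + step, beta)
        diverged = np.abs(beta) > _BETA_BOUND
        fittable &= ~diverged
        active &= ~diverged
        active &= np.abs(step) > tol

    _, hess = _gradient_hessian(beta, Xs, groups)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(-1.0 / hess)
    coef = np.where(fittable, beta, np.nan)
    se = np.where(fittable, se, np.nan)
    z = coef / se
    pval = 2.0 * stats.norm.sf(np.abs(z))
    return UnivariateCoxResult(coef=coef, se=se, z=z, p=pval, converged=fittable)


def _gradient_hessian(beta, Xs, groups):
    """Efron score and observed information for every covariate row."""
    eta = beta[:, None] * Xs
    eta -= eta.max(axis=1, keepdims=True)  # guard overflow; risk sets are ratios
    w = np.exp(eta)
    wx = w * Xs
    wxx = wx * Xs
    # suffix sums: risk set at sorted index i is i..n-1
    S0 = np.cumsum(w[:, ::-1], axis=1)[:, ::-1]
    S1 = np.cumsum(wx[:, ::-1], axis=1)[:, ::-1]
    S2 = np.cumsum(wxx[:, ::-1], axis=1)[:, ::-1]

    grad = np.zeros(beta.size)
    hess = np.zeros(beta.size)
    for first, members, in groups:
        d = members.size
        s0, s1, s2 = S0[:, first], S1[:, first], S2[:, first]
        grad += Xs[:, members].sum(axis=1)
        if d == 1:
            r1 = s1 / s0
            grad -= r1
            hess -= s2 / s0 - r1 * r1
        else:
            t0 = w[:, members].sum(axis=1)
            t1 = wx[:, members].sum(axis=1)
            t2 = wxx[:, members].sum(axis=1)
            for ell in range(d):
                f = ell / d
                a0 = s0 - f * t0
                r1 = (s1 - f * t1) / a0
                grad -= r1
                hess -= (s2 - f * t2) / a0 - r1 * r1
    return grad, hess


def cox_partial_loglik(lp: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Breslow log partial likelihood of fixed linear predictors ``lp``.

    Used to score held-out folds during penalised-Cox cross-validation.
    """
    lp = np.asarray(lp, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    order = np.argsort(time, kind="stable")
    ts, es, lps = time[order], event[order], lp[order]
    m = lps.max()
    w = np.exp(lps - m)
    S0 = np.cumsum(w[::-1])[::-1]
    ev = es == 1
    first = np.searchsorted(ts, ts[ev], side="left")
    return float(np.sum(lps[ev] - (np.log(S0[first]) + m)))


def breslow_baseline_hazard(
    lp: np.ndarray, time: np.ndarray, event: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Breslow estimate of the baseline cumulative hazard H0(t).

    ``lp`` are linear predictors on the scale where covariates equal to
    zero give hazard ``h0(t)`` exactly. Returns (event_times, H0) as a
    right-continuous step function evaluated at the distinct event times.
    """
    lp = np.asarray(lp, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    order = np.argsort(time, kind="stable")
    ts, es = time[order], event[order]
    w = np.exp(lp[order])
    S0 = np.cumsum(w[::-1])[::-1]

    uniq_times = []
    increments = []
    for first, members in _event_groups(ts, es):
        uniq_times.append(ts[members[0]])
        increments.append(members.size / S0[first])
    return np.asarray(uniq_times), np.cumsum(increments)
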