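"""Cox proportional-hazards machinery shared by the association and
combination modules: a small Newton fitter for the partial likelihood with
Breslow tie handling, plus the closed-form score (log-rank-type) test at
beta = 0."""

from __future__ import annotations

import numpy as np
from scipy import stats

_ETA_CLIP = 30.0  # guards exp overflow; hazard ratios beyond e^30 are pathological


def _sorted_groups(time: np.ndarray, event: np.ndarray):
    """Sort ascending by time and locate tie groups containing events.

    Returns (order, group_starts, group_death_masks) where each group is a
    run of equal times and the mask flags its events within sorted order.
    """
    order = np.argsort(time, kind="stable")
    t = time[order]
    starts = np.flatnonzero(np.r_[True, t[1:] != t[:-1]])
    ends = np.r_[starts[1:], len(t)]
    return order, starts, ends


def cox_loglik_grad_hess(beta: np.ndarray, design: np.ndarray, time: np.ndarray, event: np.ndarray):
    """Breslow partial log-likelihood, gradient and information at ``beta``.

    ``design`` is n x p; risk sets use all samples with time >= the event
    time (ties enter the same risk set).
    """
    order, starts, ends = _sorted_groups(time, event)
    D = design[order]
    ev = np.asarray(event, dtype=bool)[order]
    eta = np.clip(D @ beta, -_ETA_CLIP, _ETA_CLIP)
    w = np.exp(eta)

    # suffix (risk-set) sums: S0 scalar, S1 p-vector, S2 p x p per position
    s0 = np.cumsum(w[::-1])[::-1]
    s1 = np.cumsum((w[:, None] * D)[::-1], axis=0)[::-1]
    dd = np.einsum("ni,nj->nij", D, D)
    s2 = np.cumsum((w[:, None, None] * dd)[::-1], axis=0)[::-1]

    p = design.shape[1]
    loglik = 0.0
    grad = np.zeros(p)
    info = np.zeros((p, p))
    for f, e in zip(starts, ends):
        deaths = ev[f:e]
        d = int(deaths.sum())
        if d == 0:
            continue
        m = s1[f] / s0[f]
        loglik += eta[f:e][deaths].sum() - d * np.log(s0[f])
        grad += D[f:e][deaths].sum(axis=0) - d * m
        info += d * (s2[f] / s0[f] - np.outer(m, m))
    return loglik, grad, info


def cox_fit(design: np.ndarray, time: np.ndarray, event: np.ndarray,
            max_iter: int = 25, tol: float = 1e-8):
    """Newton-Raphson fit of a Cox model.

    Returns ``(beta, cov, converged)``; ``cov`` is the inverse observed
    information at the optimum.  Step-halving keeps the partial likelihood
    monotone; non-convergence is signalled, not raised.
    """
    design = np.asarray(design, dtype=float)
    if np.asarray(event).sum() == 0:
        raise ValueError("Cox model requires at least one event")
    p = design.shape[1]
    beta = np.zeros(p)
    ll, grad, info = cox_loglik_grad_hess(beta, design, time, event)
    converged = False
    for _ in range(max_iter):
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            return beta, np.full((p, p), np.nan), False
        # step halving
        factor = 1.0
        for _ in range(20):
            cand = beta + factor * step
            ll_new, grad_new, info_new = cox_loglik_grad_hess(cand, design, time, event)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            factor *= 0.5
        else:
            return beta, np.full((p, p), np.nan), False
        beta, ll, grad, info = cand, ll_new, grad_new, info_new
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.nan)
    return beta, cov, converged


def cox_wald_z(x: np.ndarray, time: np.ndarray, event: np.ndarray,
               covariates: np.ndarray | None = None) -> float:
    """Wald z for the coefficient of ``x`` in a Cox model with covariates."""
    cols = [np.asarray(x, dtype=float)[:, None]]
    if covariates is not None and covariates.size:
        cols.append(np.asarray(covariates, dtype=float))
    design = np.hstack(cols)
    beta, cov, converged = cox_fit(design, time, event)
    if not converged or not np.isfinite(cov[0, 0]) or cov[0, 0] <= 0:
        return np.nan
    return float(beta[0] / np.sqrt(cov[0, 0]))


def cox_score_test(x: np.ndarray, time: np.ndarray, event: np.ndarray) -> tuple[float, float]:
    """Univariate partial-likelihood score test of ``x`` at beta = 0.

    Equivalent to a log-rank-type test of the continuous covariate; returns
    ``(z, two_sided_p)``.
    """
    x = np.asarray(x, dtype=float)
    order, starts, ends = _sorted_groups(time, event)
    xs = x[order]
    ev = np.asarray(event, dtype=bool)[order]
    n = len(xs)
    s0 = np.arange(n, 0, -1, dtype=float)        # risk-set sizes (w = 1)
    s1 = np.cumsum(xs[::-1])[::-1]
    s2 = np.cumsum((xs**2)[::-1])[::-1]
    u = 0.0
    i_info = 0.0
    for f, e in zip(starts, ends):
        deaths = ev[f:e]
        d = int(deaths.sum())
        if d == 0:
            continue
        m = s1[f] / s0[f]
        u += xs[f:e][deaths].sum() - d * m
        i_info += d * (s2[f] / s0[f] - m**2)
    if i_info <= 0:
        return np.nan, np.nan
    z = u / np.sqrt(i_info)
    return float(z), float(2.0 * stats.norm.sf(abs(z)))
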