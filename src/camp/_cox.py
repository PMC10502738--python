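"""Newton-Raphson engine for the Cox partial likelihood with one
linearly age-varying covariate.

The model for individual ``i`` at age ``t`` is

    lambda_i(t) = lambda_0(t) * exp( x_i * (b0 + b1*(t - t0)) + C_i @ gamma )

where ``x_i`` is the tested marker dosage and ``C_i`` collects the static
columns (the marker itself, an optional polygenic offset and covariates).
At every event age the marker therefore contributes two partial-likelihood
covariates: ``x`` and ``x*(t - t0)``.

Because ``x`` is a standardized hard-call dosage it takes only a handful of
distinct values, which makes the risk-set sums separable:

    sum_{i in R(t)} exp(a_i + b_i*(t-t0))
        = sum_g exp(x_g*b1*(t-t0)) * sum_{i in R(t), x_i = x_g} exp(a_i)

so each Newton iteration costs O(n * G * q^2) with G distinct dosage levels
rather than O(n * #events).  A dense chunked path covers continuous dosages.
All exponentials are computed with a per-event shift so that trial steps far
from the optimum cannot overflow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_MAX_GROUPS = 32  # above this, fall back to the dense path
_DENSE_CHUNK = 512


@dataclass
class CoxTVData:
    """Pre-sorted design for one marker fit (age-ascending order)."""

    age: np.ndarray          # (n,)
    event: np.ndarray        # (n,) bool
    statics: np.ndarray      # (n, q); column 0 is the marker dosage
    t0: float
    include_tv: bool
    ties: str                # "efron" | "breslow"
    ut: np.ndarray           # (E,) distinct event ages, ascending
    d: np.ndarray            # (E,) tied-event counts
    risk_start: np.ndarray   # (E,) first sorted row in the risk set
    death_idx: np.ndarray    # (#events,) sorted rows of events, grouped by age
    death_off: np.ndarray    # (E,) CSR offsets into death_idx
    pairprod: np.ndarray     # (n, q*(q+1)//2) upper-triangular column products
    iu: tuple                # triu indices of the q x q block
    ms: np.ndarray           # (p,) static column feeding each full column
    tf: np.ndarray           # (p,) 0/1: power of (t - t0) on each full column
    spos: np.ndarray         # (q,) position in theta of each static column
    ginv: np.ndarray | None  # (n,) dosage-level index, or None (dense path)
    gvals: np.ndarray | None # (G,) distinct dosage values

    @property
    def p(self) -> int:
        return self.ms.size

    @property
    def n(self) -> int:
        return self.age.size


def prepare(age, event, statics, t0, include_tv=True, ties="efron"):
    """Sort and index the data for repeated likelihood evaluations."""
    age = np.asarray(age, dtype=float)
    event = np.asarray(event).astype(bool)
    statics = np.asarray(statics, dtype=float)
    if statics.ndim == 1:
        statics = statics[:, None]
    order = np.argsort(age, kind="stable")
    age_s, event_s, stat_s = age[order], event[order], statics[order]

    death_rows = np.flatnonzero(event_s)
    ev_ages = age_s[death_rows]
    ut, counts = np.unique(ev_ages, return_counts=True)
    death_off = np.concatenate([[0], np.cumsum(counts)[:-1]]).astype(np.intp)
    risk_start = np.searchsorted(age_s, ut, side="left")

    q = stat_s.shape[1]
    iu = np.triu_indices(q)
    pairprod = stat_s[:, iu[0]] * stat_s[:, iu[1]]

    if include_tv:
        ms = np.concatenate([[0, 0], np.arange(1, q)]).astype(np.intp)
        tf = np.concatenate([[0, 1], np.zeros(q - 1)]).astype(np.intp)
        spos = np.concatenate([[0], np.arange(2, q + 1)]).astype(np.intp)
    else:
        ms = np.arange(q, dtype=np.intp)
        tf = np.zeros(q, dtype=np.intp)
        spos = np.arange(q, dtype=np.intp)

    x_s = stat_s[:, 0]
    gvals = np.unique(x_s)
    if gvals.size <= _MAX_GROUPS:
        ginv = np.searchsorted(gvals, x_s).astype(np.intp)
    else:
        ginv, gvals = None, None

    return CoxTVData(
        age=age_s, event=event_s, statics=stat_s, t0=float(t0),
        include_tv=include_tv, ties=ties, ut=ut, d=counts.astype(np.intp),
        risk_start=risk_start.astype(np.intp), death_idx=death_rows.astype(np.intp),
        death_off=death_off, pairprod=pairprod, iu=iu, ms=ms, tf=tf,
        spos=spos, ginv=ginv, gvals=gvals,
    )


def _suffix(v):
    """suffix[i] = sum of v[i:], with a trailing zero row."""
    out = np.zeros((v.shape[0] + 1,) + v.shape[1:], dtype=float)
    out[:-1] = np.cumsum(v[::-1], axis=0)[::-1]
    return out


def _risk_moments(data: CoxTVData, a, beta1, b, A, c, m):
    """Scaled risk-set sums S0 (E,), S1 (E,q), S2p (E,npair).

    The true sums equal the returned ones times exp(A + m_e).
    """
    E = c.size
    q = data.statics.shape[1]
    npair = data.pairprod.shape[1]
    z = np.exp(a - A)
    S0 = np.zeros(E)
    S1 = np.zeros((E, q))
    S2p = np.zeros((E, npair))
    r = data.risk_start
    if data.ginv is not None:
        for g in range(data.gvals.size):
            zg = np.where(data.ginv == g, z, 0.0)
            Fg = np.exp(data.gvals[g] * beta1 * c - m)
            suf0 = _suffix(zg)
            suf1 = _suffix(zg[:, None] * data.statics)
            suf2 = _suffix(zg[:, None] * data.pairprod)
            S0 += Fg * suf0[r]
            S1 += Fg[:, None] * suf1[r]
            S2p += Fg[:, None] * suf2[r]
    else:
        n = data.n
        for e0 in range(0, E, _DENSE_CHUNK):
            e1 = min(e0 + _DENSE_CHUNK, E)
            ce, me = c[e0:e1], m[e0:e1]
            r0 = r[e0]
            rows = slice(r0, n)
            W = np.exp(a[rows, None] - A + b[rows, None] * ce[None, :] - me[None, :])
            mask = np.arange(r0, n)[:, None] >= r[e0:e1][None, :]
            W = np.where(mask, W, 0.0)
            S0[e0:e1] = W.sum(axis=0)
            S1[e0:e1] = W.T @ data.statics[rows]
            S2p[e0:e1] = W.T @ data.pairprod[rows]
    return S0, S1, S2p


def _expand(data: CoxTVData, c, S1, S2p):
    """Lift static moments to the full design (marker, marker*(t-t0), ...)."""
    E = c.size
    q = data.statics.shape[1]
    Fmat = np.power(c[:, None], data.tf[None, :])
    S1f = S1[:, data.ms] * Fmat
    S2 = np.empty((E, q, q))
    S2[:, data.iu[0], data.iu[1]] = S2p
    S2[:, data.iu[1], data.iu[0]] = S2p
    S2f = S2[:, data.ms][:, :, data.ms] * (Fmat[:, :, None] * Fmat[:, None, :])
    return S1f, S2f


def loglik_grad_hess(theta, data: CoxTVData):
    """Log partial likelihood with analytic gradient and Hessian."""
    theta = np.asarray(theta, dtype=float)
    p = data.p
    a = data.statics @ theta[data.spos]
    beta1 = theta[1] if data.include_tv else 0.0
    b = data.statics[:, 0] * beta1
    A = a.max() if a.size else 0.0
    c = data.ut - data.t0
    bmax, bmin = (b.max(), b.min()) if b.size else (0.0, 0.0)
    m = np.maximum(c * bmax, c * bmin)

    S0, S1, S2p = _risk_moments(data, a, beta1, b, A, c, m)
    S1f, S2f = _expand(data, c, S1, S2p)

    # death-set sums (scaled identically to the risk-set sums)
    di, off = data.death_idx, data.death_off
    cflat = np.repeat(c, data.d)
    mflat = np.repeat(m, data.d)
    wd = np.exp(a[di] - A + b[di] * cflat - mflat)
    S0D = np.add.reduceat(wd, off)
    S1D = np.add.reduceat(wd[:, None] * data.statics[di], off, axis=0)
    S2Dp = np.add.reduceat(wd[:, None] * data.pairprod[di], off, axis=0)
    S1Df, S2Df = _expand(data, c, S1D, S2Dp)
    etaD = np.add.reduceat(a[di] + b[di] * cflat, off)
    Fflat = np.power(cflat[:, None], data.tf[None, :])
    UD = np.add.reduceat(data.statics[di][:, data.ms] * Fflat, off, axis=0)

    dd = data.d.astype(float)
    ll = etaD.sum() - float(dd @ (A + m))
    grad = UD.sum(axis=0)
    H = np.zeros((p, p))

    if data.ties == "breslow":
        denom = S0
        ll -= float(dd @ np.log(denom))
        r1 = S1f / denom[:, None]
        grad -= dd @ r1
        H -= np.einsum("e,ejk->jk", dd / denom, S2f)
        H += np.einsum("e,ej,ek->jk", dd, r1, r1)
    else:
        for l in range(int(data.d.max())):
            act = data.d > l
            frac = l / dd[act]
            denom = S0[act] - frac * S0D[act]
            ll -= float(np.log(denom).sum())
            s1 = S1f[act] - frac[:, None] * S1Df[act]
            r1 = s1 / denom[:, None]
            grad -= r1.sum(axis=0)
            s2 = S2f[act] - frac[:, None, None] * S2Df[act]
            H -= np.einsum("e,ejk->jk", 1.0 / denom, s2)
            H += r1.T @ r1
    return ll, grad, H


def newton_maximize(data: CoxTVData, tol=1e-8, max_iter=50,
                    divergence_bound=50.0, n_refine=2):
    """Maximize the partial likelihood; step-halving keeps it non-decreasing.

    Returns (theta, ll, hessian, converged, iterations, monotone_flag).
    """
    p = data.p
    theta = np.zeros(p)
    ll, grad, H = loglik_grad_hess(theta, data)
    converged = False
    monotone = False
    it = 0
    beta_slice = slice(0, 2 if data.include_tv else 1)

    for it in range(1, max_iter + 1):
        step = _solve_step(H, grad)
        accepted = False
        for h in range(11):
            cand = theta + step / (2.0 ** h)
            ll_new, grad_new, H_new = loglik_grad_hess(cand, data)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                accepted = True
                break
        if not accepted:
            if np.max(np.abs(theta[beta_slice])) > divergence_bound:
                monotone = True
            break
        delta = ll_new - ll
        applied = cand - theta
        theta, ll, grad, H = cand, ll_new, grad_new, H_new
        if np.max(np.abs(theta[beta_slice])) > divergence_bound:
            monotone = True
            break
        if abs(delta) < tol * (abs(ll) + 1.0):
            # a Newton step that is still large while the log-likelihood has
            # flattened means the maximizer lies at infinity (separation)
            if np.max(np.abs(applied[beta_slice])) > 1e-3:
                monotone = True
            else:
                converged = True
            break

    if converged:
        # quadratic tail-off: a couple of cheap extra steps sharpen the
        # maximizer to near machine precision
        for _ in range(n_refine):
            step = _solve_step(H, grad)
            if not np.all(np.isfinite(step)) or np.max(np.abs(step)) < 1e-14:
                break
            cand = theta + step
            ll_new, grad_new, H_new = loglik_grad_hess(cand, data)
            if not np.isfinite(ll_new) or ll_new < ll - 1e-10:
                break
            theta, ll, grad, H = cand, ll_new, grad_new, H_new
    return theta, ll, H, converged, it, monotone


def _solve_step(H, grad):
    try:
        return np.linalg.solve(-H, grad)
    except np.linalg.LinAlgError:
        return np.linalg.lstsq(-H, grad, rcond=None)[0]


def breslow_baseline(theta, data: CoxTVData):
    """Breslow cumulative-baseline-hazard increments at the event ages.

    Returns (ut, dLambda0) with the time-varying linear predictor evaluated
    at each event age.
    """
    a = data.statics @ theta[data.spos]
    beta1 = theta[1] if data.include_tv else 0.0
    b = data.statics[:, 0] * beta1
    A = a.max()
    c = data.ut - data.t0
    m = np.maximum(c * b.max(), c * b.min())
    S0, _, _ = _risk_moments(data, a, beta1, b, A, c, m)
    log_denom = np.log(S0) + A + m
    dlam = data.d * np.exp(-log_denom)
    return data.ut.copy(), dlam
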