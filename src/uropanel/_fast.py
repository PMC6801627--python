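"""Compiled numerical kernels (numba).

Two hot paths live here because they are executed hundreds of thousands of
times by the repeated-CV procedures:

* :func:`logistic_lasso_path` — coordinate-descent solver for the
  L1-penalized logistic regression path (IRLS outer loop, active-set inner
  loop with a full KKT sweep), warm-started along a decreasing lambda grid.
  The objective is ``(1/n) * sum(log-loss) + lambda * ||beta||_1`` with an
  unpenalized intercept, matching the usual regularization-path convention.
* :func:`score_panels_cv` — scores every candidate marker panel within one
  cross-validation split by fitting a small ridge-stabilized logistic model
  (Newton with step halving) per panel per fold and averaging the held-out
  fold AUCs.

Both kernels are deterministic functions of their inputs; all randomness
(fold assignment, resampling) stays in the calling Python code.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_ETA_CLIP = 30.0


@njit(cache=True)
def midrank_auc(scores_pos, scores_neg):
    """Mann–Whitney AUC with midrank tie handling."""
    m = scores_pos.shape[0]
    n = scores_neg.shape[0]
    total = m + n
    allv = np.empty(total)
    allv[:m] = scores_pos
    allv[m:] = scores_neg
    order = np.argsort(allv)
    ranks = np.empty(total)
    i = 0
    while i < total:
        j = i
        while j + 1 < total and allv[order[j + 1]] == allv[order[i]]:
            j += 1
        r = 0.5 * (i + j) + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = r
        i = j + 1
    rank_sum = 0.0
    for k in range(m):
        rank_sum += ranks[k]
    return (rank_sum - m * (m + 1) / 2.0) / (m * n)


@njit(cache=True)
def _soft_threshold(v, lam):
    if v > lam:
        return v - lam
    if v < -lam:
        return v + lam
    return 0.0


@njit(cache=True, fastmath=True)
def logistic_lasso_path(X, y, lambdas, max_outer=30, max_sweeps=1000, tol=1e-7):
    """L1 logistic path over a decreasing lambda grid, warm-started.

    Parameters
    ----------
    X : (n, p) float64, predictors (typically standardized)
    y : (n,) float64 in {0, 1}
    lambdas : (L,) float64, decreasing
    tol : convergence threshold on the maximum coefficient update within a
        coordinate-descent sweep; the IRLS outer loop stops when its first
        sweep moves no coefficient by more than 10 * tol.
    Returns
    -------
    intercepts : (L,)  coefs : (L, p)  converged : (L,) bool
    """
    n, p = X.shape
    L = lambdas.shape[0]
    coefs = np.zeros((L, p))
    icpts = np.zeros(L)
    converged = np.zeros(L, dtype=np.bool_)
    Xc = np.empty((p, n))  # contiguous columns
    for j in range(p):
        for i in range(n):
            Xc[j, i] = X[i, j]

    ybar = y.mean()
    beta = np.zeros(p)
    b0 = np.log(ybar / (1.0 - ybar))
    eta = np.full(n, b0)
    active = np.zeros(p, dtype=np.bool_)
    w = np.empty(n)
    r = np.empty(n)
    wx2 = np.empty(p)

    for li in range(L):
        lam = lambdas[li]
        ok = False
        for outer in range(max_outer):
            # quadratic approximation at the current linear predictor
            sum_w = 0.0
            for i in range(n):
                e = eta[i]
                if e > _ETA_CLIP:
                    e = _ETA_CLIP
                elif e < -_ETA_CLIP:
                    e = -_ETA_CLIP
                mu = 1.0 / (1.0 + np.exp(-e))
                wi = mu * (1.0 - mu)
                if wi < 1e-5:
                    wi = 1e-5
                w[i] = wi
                # working residual: z - eta with z = eta + (y - mu)/w
                r[i] = (y[i] - mu) / wi
                sum_w += wi
            for j in range(p):
                s = 0.0
                for i in range(n):
                    s += w[i] * Xc[j, i] * Xc[j, i]
                wx2[j] = s / n

            # coordinate descent: full sweep, then active-set sweeps, with
            # periodic full sweeps to check the KKT conditions
            outer_delta = 0.0
            for sweep in range(max_sweeps):
                full = sweep == 0 or (sweep % 10 == 9)
                max_delta = 0.0
                # intercept (unpenalized)
                num = 0.0
                for i in range(n):
                    num += w[i] * r[i]
                d0 = num / sum_w
                if d0 != 0.0:
                    b0 += d0
                    for i in range(n):
                        r[i] -= d0
                    ad = abs(d0)
                    if ad > max_delta:
                        max_delta = ad
                for j in range(p):
                    if not full and not active[j]:
                        continue
                    bj = beta[j]
                    num = 0.0
                    for i in range(n):
                        num += w[i] * Xc[j, i] * r[i]
                    num = num / n + wx2[j] * bj
                    bnew = _soft_threshold(num, lam) / wx2[j]
                    delta = bnew - bj
                    if delta != 0.0:
                        beta[j] = bnew
                        active[j] = bnew != 0.0
                        for i in range(n):
                            r[i] -= delta * Xc[j, i]
                        ad = abs(delta)
                        if ad > max_delta:
                            max_delta = ad
                if sweep == 0:
                    outer_delta = max_delta
                if max_delta < tol and full:
                    break
            # refresh eta exactly (avoids incremental drift)
            for i in range(n):
                eta[i] = b0
            for j in range(p):
                bj = beta[j]
                if bj != 0.0:
                    for i in range(n):
                        eta[i] += Xc[j, i] * bj
            if outer_delta < 10.0 * tol:
                ok = True
                break
        icpts[li] = b0
        for j in range(p):
            coefs[li, j] = beta[j]
        converged[li] = ok
    return icpts, coefs, converged


@njit(cache=True)
def newton_logistic(X, y, ridge, max_iter=50, tol=1e-10):
    """Logistic regression by damped Newton; column 0 of X is the intercept.

    The L2 stabilizer *ridge* applies to all non-intercept coefficients.
    Returns (beta, converged).
    """
    n, k = X.shape
    beta = np.zeros(k)
    ybar = y.mean()
    if ybar <= 0.0 or ybar >= 1.0:
        # one-class fold: intercept at a large finite log-odds
        beta[0] = _ETA_CLIP if ybar >= 1.0 else -_ETA_CLIP
        return beta, True

    beta[0] = np.log(ybar / (1.0 - ybar))
    eta = np.empty(n)
    mu = np.empty(n)
    wv = np.empty(n)

    def _nll(b):
        v = 0.0
        for i in range(n):
            e = 0.0
            for j in range(k):
                e += X[i, j] * b[j]
            if e > _ETA_CLIP:
                e = _ETA_CLIP
            elif e < -_ETA_CLIP:
                e = -_ETA_CLIP
            v += np.log(1.0 + np.exp(e)) - y[i] * e
        v /= n
        for j in range(1, k):
            v += 0.5 * ridge * b[j] * b[j]
        return v

    f_old = _nll(beta)
    ok = False
    for it in range(max_iter):
        for i in range(n):
            e = 0.0
            for j in range(k):
                e += X[i, j] * beta[j]
            if e > _ETA_CLIP:
                e = _ETA_CLIP
            elif e < -_ETA_CLIP:
                e = -_ETA_CLIP
            eta[i] = e
            m = 1.0 / (1.0 + np.exp(-e))
            mu[i] = m
            wi = m * (1.0 - m)
            if wi < 1e-10:
                wi = 1e-10
            wv[i] = wi
        g = np.zeros(k)
        H = np.zeros((k, k))
        for i in range(n):
            resid = mu[i] - y[i]
            for j in range(k):
                g[j] += X[i, j] * resid
                for l in range(j, k):
                    H[j, l] += wv[i] * X[i, j] * X[i, l]
        for j in range(k):
            g[j] /= n
            for l in range(j, k):
                H[j, l] /= n
                H[l, j] = H[j, l]
        for j in range(1, k):
            g[j] += ridge * beta[j]
            H[j, j] += ridge
        step = np.linalg.solve(H, g)
        # backtracking line search on the penalized deviance
        t = 1.0
        improved = False
        for _ in range(20):
            cand = beta - t * step
            f_new = _nll(cand)
            if f_new <= f_old + 1e-14:
                beta = cand
                f_old = f_new
                improved = True
                break
            t *= 0.5
        if not improved:
            ok = True  # cannot improve further: treat as converged
            break
        smax = 0.0
        for j in range(k):
            a = abs(t * step[j])
            if a > smax:
                smax = a
        if smax < tol:
            ok = True
            break
    return beta, ok


@njit(cache=True)
def score_panels_cv(X, y, fold_id, n_folds, panels, sizes, ridge):
    """Mean held-out-fold AUC per candidate panel for one CV split.

    X : (n, M) pool predictor matrix (transformed scale)
    y : (n,) float64 in {0, 1}
    fold_id : (n,) int64 fold assignment in [0, n_folds)
    panels : (P, kmax) int64 column indices into X, padded with -1
    sizes : (P,) int64 number of markers per panel
    """
    n, M = X.shape
    P = panels.shape[0]
    auc_sum = np.zeros(P)
    auc_cnt = np.zeros(P)
    for f in range(n_folds):
        ntr = 0
        for i in range(n):
            if fold_id[i] != f:
                ntr += 1
        nte = n - ntr
        if nte == 0 or ntr == 0:
            continue
        tr = np.empty(ntr, dtype=np.int64)
        te = np.empty(nte, dtype=np.int64)
        a = 0
        b = 0
        for i in range(n):
            if fold_id[i] != f:
                tr[a] = i
                a += 1
            else:
                te[b] = i
                b += 1
        n_pos_te = 0
        for i in range(nte):
            if y[te[i]] == 1.0:
                n_pos_te += 1
        n_neg_te = nte - n_pos_te
        if n_pos_te == 0 or n_neg_te == 0:
            continue  # fold cannot contribute an AUC
        for pi in range(P):
            k = sizes[pi]
            Xtr = np.ones((ntr, k + 1))
            for c in range(k):
                col = panels[pi, c]
                for i in range(ntr):
                    Xtr[i, c + 1] = X[tr[i], col]
            beta, _ = newton_logistic(Xtr, y[tr], ridge, 25, 1e-6)
            spos = np.empty(n_pos_te)
            sneg = np.empty(n_neg_te)
            ip = 0
            iq = 0
            for i in range(nte):
                s = beta[0]
                for c in range(k):
                    s += X[te[i], panels[pi, c]] * beta[c + 1]
                if y[te[i]] == 1.0:
                    spos[ip] = s
                    ip += 1
                else:
                    sneg[iq] = s
                    iq += 1
            auc = midrank_auc(spos, sneg)
            auc_sum[pi] += auc
            auc_cnt[pi] += 1.0
    out = np.full(P, 0.5)
    for pi in range(P):
        if auc_cnt[pi] > 0:
            out[pi] = auc_sum[pi] / auc_cnt[pi]
    return out
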