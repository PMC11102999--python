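"""Numba graphical-lasso solver (Friedman block coordinate descent).

Solves, for a correlation/covariance matrix S and penalty lam,

    minimise_K  -log det K + tr(S K) + lam * sum_{i != j} |K_ij|

i.e. the L1 penalty is applied to off-diagonal precision entries only, so
the fitted covariance keeps diag(W) = diag(S).  The column problems are
lasso regressions solved by coordinate descent; warm starts across a
descending lambda path make whole-path fits cheap.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def _soft(x, t):
    if x > t:
        return x - t
    if x < -t:
        return x + t
    return 0.0


@njit(cache=True)
def glasso_fit(S, lam, W, B, tol, max_iter, inner_tol, inner_max):
    """One glasso fit, warm-started from (W, B) in place.

    W is the working covariance estimate, B the p x p matrix of column
    regression coefficients (B[k, j] = beta_k for column j, B[j, j] = 0).
    Returns the number of outer sweeps used (max_iter + 1 if not converged).
    """
    p = S.shape[0]
    off = 0.0
    for i in range(p):
        for j in range(p):
            if i != j:
                off += abs(S[i, j])
    thr = tol * off / (p * (p - 1)) if p > 1 else tol
    if thr <= 0.0:
        thr = tol * 1e-4

    n_sweeps = max_iter + 1
    for sweep in range(max_iter):
        delta = 0.0
        for j in range(p):
            # lasso for column j: (1/2) b' W11 b - s12' b + lam |b|_1
            for _ in range(inner_max):
                dmax = 0.0
                for k in range(p):
                    if k == j:
                        continue
                    g = S[k, j]
                    for l in range(p):
                        if l == j or l == k:
                            continue
                        g -= W[k, l] * B[l, j]
                    bnew = _soft(g, lam) / W[k, k]
                    db = bnew - B[k, j]
                    if db != 0.0:
                        B[k, j] = bnew
                        if abs(db) > dmax:
                            dmax = abs(db)
                if dmax < inner_tol:
                    break
            # w12 = W11 beta
            for k in range(p):
                if k == j:
                    continue
                w = 0.0
                for l in range(p):
                    if l == j:
                        continue
                    w += W[k, l] * B[l, j]
                d = abs(w - W[k, j])
                if d > delta:
                    delta = d
                W[k, j] = w
                W[j, k] = w
        if delta < thr:
            n_sweeps = sweep + 1
            break
    return n_sweeps


@njit(cache=True)
def precision_from_wb(W, B):
    """Recover the sparse precision matrix from (W, B)."""
    p = W.shape[0]
    K = np.zeros((p, p))
    for j in range(p):
        q = W[j, j]
        for l in range(p):
            if l != j:
                q -= W[l, j] * B[l, j]
        kjj = 1.0 / q
        K[j, j] = kjj
        for l in range(p):
            if l != j:
                K[l, j] = -B[l, j] * kjj
    # symmetrise, preserving exact zeros of the support
    for i in range(p):
        for j in range(i):
            if K[i, j] == 0.0 or K[j, i] == 0.0:
                K[i, j] = 0.0
                K[j, i] = 0.0
            else:
                v = 0.5 * (K[i, j] + K[j, i])
                K[i, j] = v
                K[j, i] = v
    return K


@njit(cache=True)
def glasso_path(S, lams, tol, max_iter, inner_tol, inner_max):
    """Warm-started glasso along a descending lambda path.

    Returns (Ks, n_sweeps): precision stack (nlam, p, p) and per-lambda
    outer sweep counts (max_iter + 1 flags non-convergence).
    """
    p = S.shape[0]
    nlam = lams.shape[0]
    W = S.copy()
    B = np.zeros((p, p))
    Ks = np.zeros((nlam, p, p))
    sweeps = np.zeros(nlam, dtype=np.int64)
    for t in range(nlam):
        sweeps[t] = glasso_fit(S, lams[t], W, B, tol, max_iter, inner_tol, inner_max)
        Ks[t] = precision_from_wb(W, B)
    return Ks, sweeps
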