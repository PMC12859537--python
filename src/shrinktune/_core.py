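"""Numba-compiled numerical kernels for penalized logistic regression.

Everything here works on float64 arrays and the *standardized* scale
internally (covariates centred and scaled by the 1/n standard deviation);
public modules wrap these kernels and handle back-transformation, input
checking and bookkeeping.

Conventions (shared with :mod:`shrinktune.models`):

* penalized objective: maximize ``(1/n) * loglik(beta) - lam * s(beta)``
  with ``s`` the L1 or squared-L2 norm of the slopes; the intercept is
  never penalized;
* linear predictors are clipped to ``|eta| <= 23.03`` (probabilities to
  roughly ``[1e-10, 1 - 1e-10]``) when evaluating the deviance so held-out
  deviances are always finite.
"""

import numpy as np
from numba import njit

ETA_CLIP = 23.03          # |eta| bound used when scoring deviance
GRAD_TOL = 1e-8           # convergence tolerance on the penalized score
MAX_ITER = 200


@njit(cache=True)
def _sigmoid(z):
    out = np.empty_like(z)
    for i in range(z.shape[0]):
        if z[i] >= 0.0:
            out[i] = 1.0 / (1.0 + np.exp(-z[i]))
        else:
            e = np.exp(z[i])
            out[i] = e / (1.0 + e)
    return out


@njit(cache=True)
def _softplus(z):
    # log(1 + exp(z)), numerically stable
    if z > 0.0:
        return z + np.log1p(np.exp(-z))
    return np.log1p(np.exp(z))


@njit(cache=True)
def _loglik(y, eta):
    """Binomial log-likelihood sum_i [y*eta - log(1+exp(eta))]."""
    s = 0.0
    for i in range(y.shape[0]):
        s += y[i] * eta[i] - _softplus(eta[i])
    return s


@njit(cache=True)
def deviance_total(y, eta):
    """-2 * loglik with eta clipped away from +/-inf probabilities."""
    s = 0.0
    for i in range(y.shape[0]):
        e = eta[i]
        if e > ETA_CLIP:
            e = ETA_CLIP
        elif e < -ETA_CLIP:
            e = -ETA_CLIP
        s += y[i] * e - _softplus(e)
    return -2.0 * s


@njit(cache=True)
def standardize(X):
    """Centre and scale columns; sd uses denominator n (glmnet convention)."""
    n, p = X.shape
    mean = np.empty(p)
    sd = np.empty(p)
    Xs = np.empty_like(X)
    for j in range(p):
        m = 0.0
        for i in range(n):
            m += X[i, j]
        m /= n
        v = 0.0
        for i in range(n):
            d = X[i, j] - m
            v += d * d
        v /= n
        s = np.sqrt(v)
        mean[j] = m
        sd[j] = s
        if s > 0.0:
            for i in range(n):
                Xs[i, j] = (X[i, j] - m) / s
        else:
            for i in range(n):
                Xs[i, j] = 0.0
    return Xs, mean, sd


@njit(cache=True)
def newton_penalized(A, y, offset, penvec, beta, tol, maxit):
    """Newton-Raphson for logistic regression with per-coefficient L2 penalty.

    Maximizes (1/n)*loglik(A @ beta + offset) - 0.5 * sum(penvec * beta^2).
    ``beta`` is updated in place; returns (converged, n_iter).
    """
    n, p = A.shape
    eta = A @ beta + offset
    obj = _loglik(y, eta) / n
    for j in range(p):
        obj -= 0.5 * penvec[j] * beta[j] * beta[j]
    for it in range(maxit):
        prob = _sigmoid(eta)
        grad = A.T @ (y - prob) / n - penvec * beta
        gmax = 0.0
        for j in range(p):
            if abs(grad[j]) > gmax:
                gmax = abs(grad[j])
        if gmax < tol:
            return True, it
        w = prob * (1.0 - prob)
        Aw = A * w.reshape(-1, 1)
        H = (A.T @ Aw) / n
        for j in range(p):
            H[j, j] += penvec[j] + 1e-12
        step = np.linalg.solve(H, grad)
        # step-halving on the penalized objective
        t = 1.0
        for _ in range(30):
            cand = beta + t * step
            eta_c = A @ cand + offset
            obj_c = _loglik(y, eta_c) / n
            for j in range(p):
                obj_c -= 0.5 * penvec[j] * cand[j] * cand[j]
            if obj_c >= obj - 1e-14:
                beta[:] = cand
                eta = eta_c
                obj = obj_c
                break
            t *= 0.5
        else:
            return False, it
    return False, maxit


@njit(cache=True)
def _ridge_path_std(Xs, y, lams, tol, maxit):
    """Warm-started ridge path on standardized covariates.

    Plain Newton steps (the warm start along a dense descending grid keeps
    each step well inside the quadratic regime; a step-size cap guards the
    rare wild step). Returns (L, p+1): column 0 is the intercept, then
    slopes, all on the standardized scale. lams must be descending.
    """
    n, p = Xs.shape
    L = lams.shape[0]
    A = np.empty((n, p + 1))
    for i in range(n):
        A[i, 0] = 1.0
        for j in range(p):
            A[i, j + 1] = Xs[i, j]
    ybar = y.mean()
    beta = np.zeros(p + 1)
    beta[0] = np.log(ybar / (1.0 - ybar))
    eta = np.full(n, beta[0])
    out = np.empty((L, p + 1))
    conv = np.empty(L, dtype=np.bool_)
    prob = np.empty(n)
    resid = np.empty(n)
    Aw = np.empty((n, p + 1))
    for k in range(L):
        lam2 = 2.0 * lams[k]
        ok = False
        for it in range(maxit):
            for i in range(n):
                e = eta[i]
                if e >= 0.0:
                    prob[i] = 1.0 / (1.0 + np.exp(-e))
                else:
                    ex = np.exp(e)
                    prob[i] = ex / (1.0 + ex)
                resid[i] = y[i] - prob[i]
            grad = A.T @ resid
            gmax = 0.0
            for j in range(p + 1):
                grad[j] /= n
                if j >= 1:
                    grad[j] -= lam2 * beta[j]
                if abs(grad[j]) > gmax:
                    gmax = abs(grad[j])
            if gmax < tol:
                ok = True
                break
            for i in range(n):
                wi = prob[i] * (1.0 - prob[i])
                for j in range(p + 1):
                    Aw[i, j] = A[i, j] * wi
            H = A.T @ Aw
            for j in range(p + 1):
                for l in range(p + 1):
                    H[j, l] /= n
                H[j, j] += 1e-12
                if j >= 1:
                    H[j, j] += lam2
            step = np.linalg.solve(H, grad)
            smax = 0.0
            for j in range(p + 1):
                if abs(step[j]) > smax:
                    smax = abs(step[j])
            if smax > 5.0:
                for j in range(p + 1):
                    step[j] *= 5.0 / smax
            beta += step
            eta += A @ step
        conv[k] = ok
        out[k] = beta
    return out, conv


@njit(cache=True)
def _lasso_path_std(Xs, y, lams, tol, maxit):
    """Warm-started lasso path via IRLS + coordinate descent (glmnet-style).

    Soft-thresholding yields exact zeros. Returns as _ridge_path_std.
    """
    n, p = Xs.shape
    L = lams.shape[0]
    XT = np.ascontiguousarray(Xs.T)  # XT[j] is the contiguous j-th column
    ybar = y.mean()
    b0 = np.log(ybar / (1.0 - ybar))
    beta = np.zeros(p)
    eta = np.full(n, b0)
    out = np.empty((L, p + 1))
    conv = np.empty(L, dtype=np.bool_)
    xwx = np.empty(p)
    prob = np.empty(n)
    w = np.empty(n)
    r = np.empty(n)
    WX = np.empty((p, n))
    active = np.empty(p, dtype=np.bool_)
    for k in range(L):
        lam = lams[k]
        ok = False
        for outer in range(maxit):
            g0 = 0.0
            for i in range(n):
                e = eta[i]
                if e >= 0.0:
                    prob[i] = 1.0 / (1.0 + np.exp(-e))
                else:
                    ex = np.exp(e)
                    prob[i] = ex / (1.0 + ex)
                wi = prob[i] * (1.0 - prob[i])
                if wi < 1e-5:
                    wi = 1e-5
                w[i] = wi
                # working residual r_i = w_i*(z_i - eta_i) = y_i - prob_i,
                # kept updated exactly as beta moves within the LS problem
                r[i] = y[i] - prob[i]
                g0 += r[i]
            # KKT check on the penalized score before doing any work
            gmax = abs(g0) / n
            for j in range(p):
                g = np.dot(XT[j], r) / n
                if beta[j] != 0.0:
                    viol = abs(g - lam * np.sign(beta[j]))
                elif abs(g) > lam:
                    viol = abs(g) - lam
                else:
                    viol = 0.0
                if viol > gmax:
                    gmax = viol
            if gmax < tol:
                ok = True
                break
            wsum = w.sum()
            for j in range(p):
                s = 0.0
                for i in range(n):
                    wx = XT[j, i] * w[i]
                    WX[j, i] = wx
                    s += wx * XT[j, i]
                xwx[j] = s / n
            # coordinate descent: full sweeps to find the active set, then
            # sweeps restricted to it until stable (glmnet's strategy);
            # only the working residual r is maintained per update, eta is
            # rebuilt once the inner problem has converged
            for j in range(p):
                active[j] = beta[j] != 0.0
            for cycle in range(1000):
                full = cycle % 4 == 0
                dmax = 0.0
                for j in range(p):
                    if not full and not active[j]:
                        continue
                    if xwx[j] <= 0.0:
                        continue
                    num = np.dot(XT[j], r) / n + beta[j] * xwx[j]
                    if num > lam:
                        bnew = (num - lam) / xwx[j]
                    elif num < -lam:
                        bnew = (num + lam) / xwx[j]
                    else:
                        bnew = 0.0
                    d = bnew - beta[j]
                    if d != 0.0:
                        for i in range(n):
                            r[i] -= WX[j, i] * d
                        beta[j] = bnew
                        active[j] = bnew != 0.0
                        if abs(d) > dmax:
                            dmax = abs(d)
                # intercept (unpenalized)
                d = r.sum() / wsum
                if d != 0.0:
                    b0 += d
                    for i in range(n):
                        r[i] -= w[i] * d
                    if abs(d) > dmax:
                        dmax = abs(d)
                if full and dmax < 1e-10:
                    break
            for i in range(n):
                eta[i] = b0
            for j in range(p):
                bj = beta[j]
                if bj != 0.0:
                    for i in range(n):
                        eta[i] += XT[j, i] * bj
        conv[k] = ok
        out[k, 0] = b0
        for j in range(p):
            out[k, j + 1] = beta[j]
    return out, conv


@njit(cache=True)
def fit_path(X, y, lams, is_lasso, tol, maxit):
    """Fit a descending-lambda path on raw covariates.

    Standardizes internally, fits, and back-transforms. Returns
    (intercepts (L,), coefs (L,p), converged (L,)).
    """
    Xs, mean, sd = standardize(X)
    if is_lasso:
        B, conv = _lasso_path_std(Xs, y, lams, tol, maxit)
    else:
        B, conv = _ridge_path_std(Xs, y, lams, tol, maxit)
    L = lams.shape[0]
    p = X.shape[1]
    intercepts = np.empty(L)
    coefs = np.empty((L, p))
    for k in range(L):
        b0 = B[k, 0]
        for j in range(p):
            if sd[j] > 0.0:
                c = B[k, j + 1] / sd[j]
            else:
                c = 0.0
            coefs[k, j] = c
            b0 -= c * mean[j]
        intercepts[k] = b0
    return intercepts, coefs, conv


@njit(cache=True)
def lasso_lambda_max(X, y):
    """Smallest lambda with an all-zero lasso fit: max_j |x_j'(y - ybar)|/n
    on standardized covariates."""
    Xs, mean, sd = standardize(X)
    n, p = Xs.shape
    ybar = y.mean()
    lmax = 0.0
    for j in range(p):
        g = 0.0
        for i in range(n):
            g += Xs[i, j] * (y[i] - ybar)
        g = abs(g) / n
        if g > lmax:
            lmax = g
    return lmax


@njit(cache=True)
def cv_deviance_kernel(X, y, lams, fold_id, k, is_lasso, tol, maxit):
    """k-fold cross-validated total deviance per lambda, divided by n.

    fold_id[i] in {0..k-1} assigns row i to its held-out fold.
    """
    n, p = X.shape
    L = lams.shape[0]
    dev = np.zeros(L)
    for f in range(k):
        ntr = 0
        for i in range(n):
            if fold_id[i] != f:
                ntr += 1
        nte = n - ntr
        Xtr = np.empty((ntr, p))
        ytr = np.empty(ntr)
        Xte = np.empty((nte, p))
        yte = np.empty(nte)
        a = 0
        b = 0
        for i in range(n):
            if fold_id[i] != f:
                for j in range(p):
                    Xtr[a, j] = X[i, j]
                ytr[a] = y[i]
                a += 1
            else:
                for j in range(p):
                    Xte[b, j] = X[i, j]
                yte[b] = y[i]
                b += 1
        intercepts, coefs, conv = fit_path(Xtr, ytr, lams, is_lasso, tol, maxit)
        for l in range(L):
            eta = np.empty(nte)
            for i in range(nte):
                e = intercepts[l]
                for j in range(p):
                    e += coefs[l, j] * Xte[i, j]
                eta[i] = e
            dev[l] += deviance_total(yte, eta)
    return dev / n


@njit(cache=True)
def path_deviance_kernel(Xtr, ytr, Xev, yev, lams, is_lasso, tol, maxit):
    """Fit the path on (Xtr, ytr), score per-lambda deviance on (Xev, yev)/n_ev."""
    intercepts, coefs, conv = fit_path(Xtr, ytr, lams, is_lasso, tol, maxit)
    L = lams.shape[0]
    nev, p = Xev.shape
    dev = np.empty(L)
    for l in range(L):
        eta = np.empty(nev)
        for i in range(nev):
            e = intercepts[l]
            for j in range(p):
                e += coefs[l, j] * Xev[i, j]
            eta[i] = e
        dev[l] = deviance_total(yev, eta) / nev
    return dev
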