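"""Independent brute-force oracles used only by the test suite."""
from __future__ import annotations

import numpy as np


def wls_normal_equations(y, X, w):
    """Weighted LS by directly solving (X'WX) b = X'Wy."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    w = np.asarray(w, float)
    return np.linalg.solve(X.T @ (w[:, None] * X), X.T @ (w * y))


def hc0_sandwich(y, X):
    """Heteroskedasticity-robust covariance of OLS coefficients."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    beta = np.linalg.lstsq(X, y, rcond=None)[0]
    e = y - X @ beta
    bread = np.linalg.inv(X.T @ X)
    meat = X.T @ (X * (e**2)[:, None])
    return bread @ meat @ bread


def jackknife_se(y, X, w, stratum, psu, coef_idx):
    """Delete-one-PSU stratified jackknife SE of a WLS coefficient.

    For each stratum h and PSU j: drop the PSU, rescale the remaining PSUs'
    weights in that stratum by n_h/(n_h - 1), refit; the variance is
    sum_h (n_h - 1)/n_h sum_j (theta_hj - theta_hat)^2.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    w = np.asarray(w, float)
    theta_hat = wls_normal_equations(y, X, w)[coef_idx]
    var = 0.0
    for h in np.unique(stratum):
        in_h = stratum == h
        psus = np.unique(psu[in_h])
        n_h = len(psus)
        for j in psus:
            drop = in_h & (psu == j)
            w_rep = w.copy()
            w_rep[in_h & ~drop] *= n_h / (n_h - 1)
            w_rep[drop] = 0.0
            keep = ~drop
            theta = wls_normal_equations(y[keep], X[keep], w_rep[keep])[coef_idx]
            var += (n_h - 1) / n_h * (theta - theta_hat) ** 2
    return np.sqrt(var)


def power_iteration(corr, n_iter=10_000, tol=1e-14):
    """Leading eigenvector of a symmetric PSD matrix by power iteration."""
    corr = np.asarray(corr, float)
    v = np.ones(corr.shape[0]) / np.sqrt(corr.shape[0])
    for _ in range(n_iter):
        nv = corr @ v
        nv /= np.linalg.norm(nv)
        if np.linalg.norm(nv - v) < tol and np.linalg.norm(nv + v) > tol:
            v = nv
            break
        v = nv
    if v.sum() < 0:
        v = -v
    return v


def ridge_closed_form(y, X, w, lam, penalized_idx):
    """(X'WX + lam I_pen)^{-1} X'Wy with the penalty only on given columns."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    w = np.asarray(w, float)
    pen = np.zeros(X.shape[1])
    pen[list(penalized_idx)] = lam
    return np.linalg.solve(X.T @ (w[:, None] * X) + np.diag(pen), X.T @ (w * y))


def pdm_2d_maximum(a, b, C, n_grid=200_001):
    """Global maximum of |(w'a)(w'b)/(w'Cw)| by 2-D reduction.

    Substituting u = C^{1/2} w turns the objective into
    (u' a~)(u' b~)/(u'u) with a~ = C^{-1/2} a, b~ = C^{-1/2} b, whose optimum
    lies in span{a~, b~}; a dense angular grid over that plane brackets the
    maximum.
    """
    C = np.asarray(C, float)
    evals, evecs = np.linalg.eigh(C)
    c_inv_half = evecs @ np.diag(evals**-0.5) @ evecs.T
    at = c_inv_half @ np.asarray(a, float)
    bt = c_inv_half @ np.asarray(b, float)
    e1 = at / np.linalg.norm(at)
    b2 = bt - (bt @ e1) * e1
    if np.linalg.norm(b2) < 1e-12:
        # collinear case: optimum along a~
        return abs((e1 @ at) * (e1 @ bt))
    e2 = b2 / np.linalg.norm(b2)
    theta = np.linspace(0.0, np.pi, n_grid)
    u = np.outer(np.cos(theta), e1) + np.outer(np.sin(theta), e2)
    vals = np.abs((u @ at) * (u @ bt))
    return float(vals.max())
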