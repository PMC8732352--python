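"""Independent brute-force oracles used to verify the package's numerics.

Everything here is deliberately naive (nested loops, O(n^2) risk sets,
textbook formulas) and shares no code with the implementation under test.
"""
import numpy as np


def cox_loglik_brute(beta, X, entry, stop, event, w):
    """Weighted Breslow log partial likelihood by explicit risk-set loops."""
    eta = X @ beta
    n = len(stop)
    ll = 0.0
    for i in range(n):
        if not event[i]:
            continue
        denom = 0.0
        for j in range(n):
            at_risk = stop[j] >= stop[i] and (entry is None or entry[j] < stop[i])
            if at_risk:
                denom += w[j] * np.exp(eta[j])
        ll += w[i] * (eta[i] - np.log(denom))
    return ll


def cox_newton_brute(X, entry, stop, event, w, ridge=0.0, n_iter=100,
                     tol=1e-12):
    """Unpenalized (or ridge-penalized) weighted Cox fit by full Newton
    iterations with analytic gradient/Hessian from explicit risk sets.

    Weights are normalized to sum to one, and the ridge term is
    ridge/2 * ||beta||^2 on that normalized-likelihood scale (matching an
    elastic-net objective with alpha = 0 and lambda = ridge).
    """
    X = np.asarray(X, dtype=float)
    w = np.asarray(w, dtype=float)
    v = w / w.sum()
    n, p = X.shape
    beta = np.zeros(p)
    for _ in range(n_iter):
        grad = np.zeros(p)
        hess = np.zeros((p, p))
        eta = X @ beta
        for i in range(n):
            if not event[i]:
                continue
            s0 = 0.0
            s1 = np.zeros(p)
            s2 = np.zeros((p, p))
            for j in range(n):
                at_risk = stop[j] >= stop[i] and (
                    entry is None or entry[j] < stop[i])
                if at_risk:
                    r = v[j] * np.exp(eta[j])
                    s0 += r
                    s1 += r * X[j]
                    s2 += r * np.outer(X[j], X[j])
            xbar = s1 / s0
            grad += v[i] * (X[i] - xbar)
            hess += v[i] * (s2 / s0 - np.outer(xbar, xbar))
        grad -= ridge * beta
        hess += ridge * np.eye(p)
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    return beta


def logistic_irls(X, y, n_iter=100, tol=1e-12):
    """Maximum-likelihood logistic regression by hand-coded IRLS.

    X must already include an intercept column.  Returns (coef, cov)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    beta = np.zeros(X.shape[1])
    for _ in range(n_iter):
        p = 1.0 / (1.0 + np.exp(-(X @ beta)))
        W = p * (1 - p)
        grad = X.T @ (y - p)
        hess = (X * W[:, None]).T @ X
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    p = 1.0 / (1.0 + np.exp(-(X @ beta)))
    W = p * (1 - p)
    cov = np.linalg.inv((X * W[:, None]).T @ X)
    return beta, cov


def auc_all_pairs(score, case):
    """AUC as the explicit all-pairs concordance count (ties count 1/2)."""
    score = np.asarray(score, dtype=float)
    case = np.asarray(case).astype(bool)
    pos = score[case]
    neg = score[~case]
    total = 0.0
    for a in pos:
        for b in neg:
            if a > b:
                total += 1.0
            elif a == b:
                total += 0.5
    return total / (pos.size * neg.size)


def residualize_normal_equations(y, Z, ref_mask):
    """Least-squares residuals of y on [1, Z] fit in the reference subset,
    standardized by the reference residual SD (ddof=1)."""
    y = np.asarray(y, dtype=float)
    X = np.column_stack([np.ones(len(y)), np.asarray(Z, dtype=float)])
    Xr, yr = X[ref_mask], y[ref_mask]
    coef = np.linalg.solve(Xr.T @ Xr, Xr.T @ yr)
    resid = y - X @ coef
    sd = np.std(resid[ref_mask], ddof=1)
    return resid / sd


def pearson_r_formula(x, y):
    """Textbook covariance / (sd_x * sd_y)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc = x - x.mean()
    yc = y - y.mean()
    return float((xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum()))
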