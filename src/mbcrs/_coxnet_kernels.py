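"""Numerical kernels for the penalized weighted Cox solver.

The inner loop is an elastic-net penalized weighted-least-squares coordinate
descent on the quadratic (IRLS) approximation of the partial likelihood.  It
is JIT-compiled when numba is importable and falls back to the identical pure
Python implementation otherwise.
"""
from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def deco(f):
            return f

        return deco


@njit(cache=False)
def cd_elastic_net_wls(X, h, z, b, l1, l2, tol, max_iter):
    """Minimize 0.5*sum_i h_i (z_i - x_i'b)^2 + l1*||b||_1 + 0.5*l2*||b||^2.

    Updates ``b`` in place; returns the number of full/active sweeps used,
    or -1 if the sweep budget was exhausted before convergence.
    """
    n, p = X.shape
    # residual r = z - X b
    r = z.copy()
    for j in range(p):
        bj = b[j]
        if bj != 0.0:
            col = X[:, j]
            for i in range(n):
                r[i] -= col[i] * bj
    # curvature per coordinate: sum_i h_i x_ij^2
    xv = np.zeros(p)
    for j in range(p):
        s = 0.0
        col = X[:, j]
        for i in range(n):
            s += h[i] * col[i] * col[i]
        xv[j] = s

    active = np.zeros(p, dtype=np.bool_)
    for j in range(p):
        active[j] = b[j] != 0.0

    n_sweeps = 0
    full_sweep = True
    while n_sweeps < max_iter:
        n_sweeps += 1
        max_change = 0.0
        for j in range(p):
            if not full_sweep and not active[j]:
                continue
            denom = xv[j] + l2
            if denom <= 0.0:
                continue
            col = X[:, j]
            # partial residual gradient
            g = xv[j] * b[j]
            for i in range(n):
                g += h[i] * col[i] * r[i]
            if g > l1:
                bj_new = (g - l1) / denom
            elif g < -l1:
                bj_new = (g + l1) / denom
            else:
                bj_new = 0.0
            delta = bj_new - b[j]
            if delta != 0.0:
                for i in range(n):
                    r[i] -= col[i] * delta
                b[j] = bj_new
                ad = abs(delta)
                if ad > max_change:
                    max_change = ad
                active[j] = bj_new != 0.0
        if full_sweep:
            # converged only when a full pass moves nothing beyond tol
            if max_change < tol:
                return n_sweeps
            full_sweep = False
        else:
            if max_change < tol:
                full_sweep = True
    return -1
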