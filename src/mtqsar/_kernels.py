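"""Coordinate-descent inner loops for the SVR duals.

Two kernels: the single-model epsilon-SVR dual (with optional per-instance
linear terms folded into the effective labels by the caller) and the
graph-coupled multi-task dual, where the effective kernel is
``M_{t_i t_j} x_i . x_j`` and the per-task weights ``w_t = sum_s M_ts v_s``
are maintained incrementally.  Both permute the coordinate order each epoch
from an explicit integer seed and stop when the largest projected-gradient
violation over an epoch falls below the (caller-scaled) tolerance.

The loops are JIT-compiled with numba when available; a pure-Python
equivalent keeps the package importable without it.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba is normally present
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def deco(f):
            return f
        if args and callable(args[0]):
            return args[0]
        return deco


@njit(cache=False)
def _shuffle(perm):
    for k in range(len(perm) - 1, 0, -1):
        j = np.random.randint(0, k + 1)
        tmp = perm[k]
        perm[k] = perm[j]
        perm[j] = tmp


@njit(cache=False)
def cd_svr(indptr, indices, data, yp, C, epsilon, loss_order, tol, max_iter,
           seed, n):
    l = len(yp)
    w = np.zeros(n)
    beta = np.zeros(l)
    inv2C = 1.0 / (2.0 * C) if loss_order == 2 else 0.0
    H = np.empty(l)
    for i in range(l):
        s = 0.0
        for k in range(indptr[i], indptr[i + 1]):
            s += data[k] * data[k]
        H[i] = s + inv2C
        if H[i] <= 0.0:
            H[i] = 1.0
    np.random.seed(seed)
    perm = np.arange(l)
    converged = False
    epoch = 0
    max_violation = 0.0
    for epoch in range(1, max_iter + 1):
        _shuffle(perm)
        max_violation = 0.0
        for idx in range(l):
            i = perm[idx]
            dot = 0.0
            for k in range(indptr[i], indptr[i + 1]):
                dot += w[indices[k]] * data[k]
            b = beta[i]
            g = dot - yp[i] + b * inv2C
            if b > 0.0:
                viol = abs(g + epsilon)
            elif b < 0.0:
                viol = abs(g - epsilon)
            else:
                viol = abs(g) - epsilon
                if viol < 0.0:
                    viol = 0.0
            if loss_order == 1:
                # at a box bound only the inward direction is feasible
                if b >= C:
                    viol = max(0.0, g + epsilon)
                elif b <= -C:
                    viol = max(0.0, -(g - epsilon))
            if viol > max_violation:
                max_violation = viol
            g0 = g - H[i] * b
            if g0 + epsilon < 0.0:
                b_new = -(g0 + epsilon) / H[i]
            elif g0 - epsilon > 0.0:
                b_new = -(g0 - epsilon) / H[i]
            else:
                b_new = 0.0
            if loss_order == 1:
                if b_new > C:
                    b_new = C
                elif b_new < -C:
                    b_new = -C
            delta = b_new - b
            if delta != 0.0:
                beta[i] = b_new
                for k in range(indptr[i], indptr[i + 1]):
                    w[indices[k]] += delta * data[k]
        if max_violation < tol:
            converged = True
            break
    return w, beta, epoch, converged, max_violation


@njit(cache=False)
def cd_grmt(indptr, indices, data, yc, t0, M, C, epsilon, tol, max_iter,
            seed, n):
    l = len(yc)
    T = M.shape[0]
    V = np.zeros((T, n))
    W = np.zeros((T, n))
    beta = np.zeros(l)
    inv2C = 1.0 / (2.0 * C)
    H = np.empty(l)
    for i in range(l):
        s = 0.0
        for k in range(indptr[i], indptr[i + 1]):
            s += data[k] * data[k]
        H[i] = M[t0[i], t0[i]] * s + inv2C
        if H[i] <= 0.0:
            H[i] = 1.0
    np.random.seed(seed)
    perm = np.arange(l)
    converged = False
    epoch = 0
    max_violation = 0.0
    for epoch in range(1, max_iter + 1):
        _shuffle(perm)
        max_violation = 0.0
        for idx in range(l):
            i = perm[idx]
            t = t0[i]
            dot = 0.0
            for k in range(indptr[i], indptr[i + 1]):
                dot += W[t, indices[k]] * data[k]
            b = beta[i]
            g = dot - yc[i] + b * inv2C
            if b > 0.0:
                viol = abs(g + epsilon)
            elif b < 0.0:
                viol = abs(g - epsilon)
            else:
                viol = abs(g) - epsilon
                if viol < 0.0:
                    viol = 0.0
            if viol > max_violation:
                max_violation = viol
            g0 = g - H[i] * b
            if g0 + epsilon < 0.0:
                b_new = -(g0 + epsilon) / H[i]
            elif g0 - epsilon > 0.0:
                b_new = -(g0 - epsilon) / H[i]
            else:
                b_new = 0.0
            delta = b_new - b
            if delta != 0.0:
                beta[i] = b_new
                for k in range(indptr[i], indptr[i + 1]):
                    col = indices[k]
                    dv = delta * data[k]
                    V[t, col] += dv
                    for s in range(T):
                        W[s, col] += M[s, t] * dv
        if max_violation < tol:
            converged = True
            break
    return W, V, beta, epoch, converged, max_violation
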