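"""Shared fixtures and independent oracles.

The oracles minimize the smooth convex L2-loss primal objectives directly
with L-BFGS at tight tolerance; they share no code path with the
coordinate-descent solvers under test.
"""

import numpy as np
import pytest
from scipy.optimize import minimize


def lbfgs(fun, x0):
    res = minimize(
        fun, x0, method="L-BFGS-B",
        options=dict(ftol=1e-16, gtol=1e-12, maxiter=50000, maxfun=200000),
    )
    return res.x


def svr_primal_oracle(X, y, C, epsilon):
    """Dense minimizer of the standard L2-loss epsilon-SVR primal."""
    X = np.asarray(X, dtype=float)

    def P(w):
        r = np.abs(X @ w - y) - epsilon
        return 0.5 * w @ w + C * np.sum(np.maximum(r, 0.0) ** 2)

    return lbfgs(P, np.zeros(X.shape[1]))


def grmt_primal_oracle(X, y, task_ids, A, C, epsilon):
    """Dense minimizer of the graph-coupled joint primal (centered labels)."""
    X = np.asarray(X, dtype=float)
    T = A.shape[0]
    n = X.shape[1]
    t0 = np.asarray(task_ids) - 1
    D = np.diag(A.sum(axis=0))
    L = D - A

    def P(flat):
        W = flat.reshape(T, n)
        pred = np.einsum("ij,ij->i", X, W[t0])
        loss = np.maximum(np.abs(pred - y) - epsilon, 0.0) ** 2
        return 0.5 * (W * W).sum() + 0.5 * np.einsum("st,si,ti->", L, W, W) \
            + C * loss.sum()

    return lbfgs(P, np.zeros(T * n)).reshape(T, n)


def tdmt_node_oracle(X, y, wp, B, C, epsilon):
    """Dense minimizer of the parent-pulled node primal (centered labels)."""
    X = np.asarray(X, dtype=float)

    def P(w):
        r = np.abs(X @ w - y) - epsilon
        return (
            0.5 * (1 - B) * w @ w
            + 0.5 * B * (w - wp) @ (w - wp)
            + C * np.sum(np.maximum(r, 0.0) ** 2)
        )

    return lbfgs(P, np.zeros(X.shape[1]))


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_problem(rng):
    """A small dense regression problem: 8 instances, 4 features."""
    X = rng.random((8, 4))
    y = rng.normal(0.0, 2.0, 8)
    return X, y - y.mean()
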