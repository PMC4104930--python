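"""Linear epsilon-insensitive support vector regression.

Implements the primal

    min_w  1/2 ||w||^2 + C * sum_i loss_eps(w.x_i, y_i)

with the L1 loss ``max(|w.x - y| - eps, 0)`` or the (default) L2 loss
``max(|w.x - y| - eps, 0)^2``, solved in the dual by coordinate descent in the
style of large-scale linear SVM solvers.  The dual for L2 loss is

    min_beta  1/2 beta' Q beta + sum_i eps*|beta_i| - y_i*beta_i
              + beta_i^2/(4C)  -  p_i*beta_i

with ``Q_ij = x_i.x_j`` and ``w = sum_i beta_i x_i``.  The optional linear
terms ``p_i`` support the top-down multi-task node problems, which differ from
a standard SVR only in this linear term.  For L1 loss the ``beta^2/(4C)`` term
is replaced by the box constraint ``|beta_i| <= C``.

No bias term is regularized; callers center labels and carry the mean as the
model offset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from ._kernels import cd_svr


def _seed_int(seed) -> int:
    """Normalize any seed-like (int, None, SeedSequence) to a 31-bit int."""
    return int(np.random.default_rng(seed).integers(0, 2 ** 31 - 1))

__all__ = [
    "eps_insensitive_loss",
    "DualState",
    "SVRModel",
    "solve_dual",
    "train_svr",
    "predict",
]


def eps_insensitive_loss(xi: float, y: float, epsilon: float, order: int = 2) -> float:
    """Epsilon-insensitive loss ``max(|xi - y| - epsilon, 0) ** order``.

    ``xi`` is the predicted value ``w.x``, ``y`` the actual target.  Residuals
    inside the epsilon-tube incur zero loss; ``order`` selects L1 or L2 loss.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be non-negative")
    if order not in (1, 2):
        raise ValueError("loss order must be 1 or 2")
    return max(abs(xi - y) - epsilon, 0.0) ** order


@dataclass
class DualState:
    """Dual coefficients and diagnostics of a coordinate-descent run.

    An instance i is a support vector iff ``beta[i] != 0``; such points lie on
    the boundary of or outside the epsilon-tube.
    """

    beta: np.ndarray
    objective: float
    linear_terms: np.ndarray
    converged: bool = True
    n_epochs: int = 0


@dataclass
class SVRModel:
    """Linear SVR model: prediction is ``weight . x + offset``.

    The offset is the mean of the training labels at fit time (label
    centering stands in for a regularized bias term).
    """

    weight: np.ndarray
    offset: float = 0.0
    C: float = 1.0
    epsilon: float = 0.1
    loss_order: int = 2
    dual: DualState = field(default=None, repr=False)

    def predict(self, X) -> np.ndarray:
        return predict(self, X)


def _as_csr(instances):
    if isinstance(instances, sp.spmatrix):
        return sp.csr_matrix(instances, dtype=np.float64)
    return sp.csr_matrix(np.atleast_2d(np.asarray(instances, dtype=np.float64)))


def solve_dual(
    instances,
    y,
    C: float,
    epsilon: float,
    loss_order: int = 2,
    linear_terms=None,
    tol: float = 1e-3,
    max_iter: int = 1000,
    seed: int = 0,
):
    """Minimize the SVR dual with optional per-instance linear terms.

    Minimizes ``f_D(beta) - sum_i p_i beta_i`` where ``f_D`` is the standard
    epsilon-insensitive dual; the linear terms shift the effective labels to
    ``y_i + p_i``.  Labels are expected to be centered by the caller.

    Coordinate order is randomly permuted each epoch (seeded), and every
    coordinate update is an exact one-dimensional minimization (soft
    threshold, plus clipping to ``[-C, C]`` for L1 loss).  Terminates when
    the largest projected-gradient violation over an epoch falls below
    ``tol`` scaled by the label magnitude (gradients scale with the labels,
    so an absolute threshold would be arbitrarily strict or loose).

    Returns
    -------
    (DualState, ndarray)
        The dual state and the primal weight vector ``w = sum beta_i x_i``.
    """
    X = _as_csr(instances)
    y = np.asarray(y, dtype=np.float64)
    l, n = X.shape
    if linear_terms is None:
        p = np.zeros(l)
    else:
        p = np.asarray(linear_terms, dtype=np.float64)
        if p.shape != (l,):
            raise ValueError("linear_terms must have one entry per instance")
    if C < 0:
        raise ValueError("C must be non-negative")
    if epsilon < 0:
        raise ValueError("epsilon must be non-negative")
    if loss_order not in (1, 2):
        raise ValueError("loss order must be 1 or 2")

    w = np.zeros(n)
    beta = np.zeros(l)
    if C == 0 or l == 0:
        state = DualState(beta, 0.0, p, converged=True, n_epochs=0)
        return state, w

    yp = y + p
    tol_eff = tol * max(1.0, float(np.max(np.abs(yp))) if l else 1.0)
    X.sort_indices()
    w, beta, epoch, converged, max_violation = cd_svr(
        X.indptr.astype(np.int64), X.indices.astype(np.int64),
        np.ascontiguousarray(X.data, dtype=np.float64),
        np.ascontiguousarray(yp), float(C), float(epsilon), int(loss_order),
        float(tol_eff), int(max_iter), _seed_int(seed), n,
    )
    if not converged:
        warnings.warn(
            f"SVR dual solver did not converge in {max_iter} epochs "
            f"(last violation {max_violation:.3g})",
            RuntimeWarning,
        )
    obj = dual_objective(X, yp, beta, C, epsilon, loss_order)
    state = DualState(beta, obj, p, converged=converged, n_epochs=epoch)
    return state, w


def dual_objective(X, y_eff, beta, C, epsilon, loss_order=2) -> float:
    """Dual objective value at ``beta`` (effective labels already shifted)."""
    w = X.T @ beta
    val = 0.5 * float(w @ w) + epsilon * np.abs(beta).sum() - float(y_eff @ beta)
    if loss_order == 2:
        val += float(beta @ beta) / (4.0 * C)
    return val


def primal_objective(X, y, w, C, epsilon, loss_order=2) -> float:
    """Primal SVR objective at ``w`` on (already centered) labels."""
    X = _as_csr(X)
    resid = np.abs(X @ w - y) - epsilon
    loss = np.maximum(resid, 0.0)
    if loss_order == 2:
        loss = loss ** 2
    return 0.5 * float(w @ w) + C * float(loss.sum())


def train_svr(
    dataset,
    C: float = 1.0,
    epsilon: float = 0.1,
    loss_order: int = 2,
    tol: float = 1e-3,
    max_iter: int = 1000,
    seed: int = 0,
) -> SVRModel:
    """Fit a linear epsilon-SVR on a dataset (or an ``(X, y)`` pair).

    Labels are centered before the dual solve and the mean is kept as the
    model offset, standing in for an (unregularized) bias.
    """
    if hasattr(dataset, "X"):
        X, y = dataset.X, dataset.y
    else:
        X, y = dataset
    X = _as_csr(X)
    y = np.asarray(y, dtype=np.float64)
    if X.shape[0] == 0:
        raise ValueError("cannot train on an empty dataset")
    offset = float(y.mean())
    state, w = solve_dual(
        X, y - offset, C, epsilon, loss_order=loss_order,
        tol=tol, max_iter=max_iter, seed=seed,
    )
    return SVRModel(w, offset, C, epsilon, loss_order, dual=state)


def predict(model: SVRModel, X) -> np.ndarray:
    """Predict ``w . x + offset`` for one or more instances."""
    X = _as_csr(X)
    return np.asarray(X @ model.weight + model.offset).ravel()
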