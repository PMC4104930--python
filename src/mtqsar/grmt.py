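"""Graph-regularized multi-task SVR (GRMT).

Tasks are nodes of a graph whose weighted adjacency matrix ``A`` (symmetric,
non-negative entries) encodes pairwise task similarity.  The joint primal

    min_{w_1..w_T}  1/2 sum_t ||w_t||^2
                    + 1/4 sum_{s,t} A_st ||w_s - w_t||^2
                    + C sum_i loss_eps(w_{t_i}.x_i, y_i)

couples the task weight vectors through the graph Laplacian ``L = D - A``
(the similarity-weighted penalty equals ``1/2 sum_{s,t} L_st w_s.w_t``).  In
the block-vector view the regularizer is ``1/2 w' block(I_T + L) w`` and the
dual replaces the kernel by ``Q_ij = M_{t_i t_j} x_i.x_j`` with
``M = (I_T + L)^{-1}``, which we solve by the same seeded dual coordinate
descent as the single-task case, maintaining the per-task weights
``w_t = sum_s M_ts v_s`` with ``v_s = sum_{i: t_i = s} beta_i x_i``.

All tasks share one label-centering offset (the global training-label mean).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.sparse as sp

from ._kernels import cd_grmt
from .data import MultiTaskDataset
from .svr import DualState, _as_csr, _seed_int

__all__ = [
    "GraphLaplacian",
    "MultiTaskModel",
    "graph_laplacian",
    "grmt_regularizer",
    "train_grmt",
    "predict_task",
    "adapt_for_unseen_task",
]


def _check_adjacency(A: np.ndarray) -> np.ndarray:
    A = np.asarray(A, dtype=np.float64)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency matrix must be square")
    if not np.allclose(A, A.T, atol=1e-12):
        raise ValueError("adjacency matrix must be symmetric")
    if np.any(A < 0):
        raise ValueError("adjacency entries must be non-negative")
    return A


@dataclass
class GraphLaplacian:
    """Graph Laplacian ``L = D - A`` and the cached ``M = (I_T + L)^{-1}``.

    ``D`` is diagonal with the column sums of ``A``.  The diagonal of ``A``
    cancels in ``D - A``, so any convention for self-similarity yields the
    same ``L``.  ``L`` is positive semidefinite for symmetric non-negative
    ``A``, hence ``I_T + L`` is positive definite and ``M`` always exists.
    """

    L: np.ndarray
    M: np.ndarray

    @property
    def n_tasks(self) -> int:
        return self.L.shape[0]


def graph_laplacian(A) -> GraphLaplacian:
    """Build ``L = D - A`` and solve ``(I_T + L) M = I_T`` (SPD solve)."""
    A = _check_adjacency(A)
    D = np.diag(A.sum(axis=0))
    L = D - A
    T = A.shape[0]
    K = np.eye(T) + L
    c, low = scipy.linalg.cho_factor(K)
    M = scipy.linalg.cho_solve((c, low), np.eye(T))
    return GraphLaplacian(L, M)


def grmt_regularizer(weights, A) -> float:
    """Similarity-weighted coupling penalty ``1/4 sum_st A_st ||w_s - w_t||^2``."""
    A = _check_adjacency(A)
    W = np.asarray(weights, dtype=np.float64)
    if W.shape[0] != A.shape[0]:
        raise ValueError("number of weight vectors must match dim(A)")
    G = W @ W.T
    sq = np.diag(G)
    dist2 = sq[:, None] + sq[None, :] - 2 * G
    return 0.25 * float((A * dist2).sum())


@dataclass
class MultiTaskModel:
    """Per-task linear models with a shared label-centering offset."""

    weights: np.ndarray  # (T, n)
    offset: float
    C: float = 1.0
    epsilon: float = 0.1
    dual: DualState = field(default=None, repr=False)

    @property
    def n_tasks(self) -> int:
        return self.weights.shape[0]

    def predict(self, X, task: int) -> np.ndarray:
        return predict_task(self, X, task)


def predict_task(model: MultiTaskModel, X, task: int) -> np.ndarray:
    """Predict ``w_t . x + offset`` for task ``t`` (1-based)."""
    if not 1 <= task <= model.n_tasks:
        raise ValueError(f"unknown task {task}")
    X = _as_csr(X)
    return np.asarray(X @ model.weights[task - 1] + model.offset).ravel()


def train_grmt(
    dataset: MultiTaskDataset,
    A,
    C: float = 1.0,
    epsilon: float = 0.1,
    n_tasks: int | None = None,
    laplacian: GraphLaplacian | None = None,
    regularized_bias: bool = False,
    tol: float = 1e-3,
    max_iter: int = 1000,
    seed: int = 0,
) -> MultiTaskModel:
    """Jointly train all task models with graph regularization.

    Labels are centered by the global mean over all tasks.  ``laplacian`` may
    be passed to reuse a precomputed ``M`` (e.g. the leave-one-sequence-out
    adaptation from :func:`adapt_for_unseen_task`); otherwise it is built
    from ``A``.  With ``regularized_bias`` a constant feature is appended to
    every instance so that per-task biases are learned (and coupled) like
    ordinary weights.
    """
    if laplacian is None:
        laplacian = graph_laplacian(A)
    M = laplacian.M
    T = laplacian.n_tasks
    if n_tasks is not None and n_tasks != T:
        raise ValueError("n_tasks does not match similarity matrix")
    X = _as_csr(dataset.X)
    if regularized_bias:
        X = sp.csr_matrix(sp.hstack([X, np.ones((X.shape[0], 1))]))
    y = np.asarray(dataset.y, dtype=np.float64)
    t_ids = np.asarray(dataset.task_ids, dtype=np.int64)
    if len(y) and (t_ids.min() < 1 or t_ids.max() > T):
        raise ValueError("task id outside 1..T")
    l, n = X.shape
    offset = float(y.mean()) if l else 0.0
    yc = y - offset

    t0 = t_ids - 1
    tol_eff = tol * max(1.0, float(np.max(np.abs(yc))) if l else 1.0)
    X.sort_indices()
    W, V, beta, epoch, converged, max_violation = cd_grmt(
        X.indptr.astype(np.int64), X.indices.astype(np.int64),
        np.ascontiguousarray(X.data, dtype=np.float64),
        np.ascontiguousarray(yc), t0.astype(np.int64),
        np.ascontiguousarray(M), float(C), float(epsilon),
        float(tol_eff), int(max_iter), _seed_int(seed), n,
    )
    if not converged:
        warnings.warn(
            f"GRMT dual solver did not converge in {max_iter} epochs "
            f"(last violation {max_violation:.3g})",
            RuntimeWarning,
        )
    obj = (
        0.5 * float(np.einsum("st,si,ti->", M, V, V))
        + epsilon * np.abs(beta).sum()
        - float(yc @ beta)
        + float(beta @ beta) / (4.0 * C)
    )
    state = DualState(beta, obj, np.zeros(l), converged=converged, n_epochs=epoch)
    return MultiTaskModel(W, offset, C, epsilon, dual=state)


def grmt_primal_objective(dataset, weights, A, C, epsilon, offset=None) -> float:
    """Joint primal objective at given per-task weights (centered labels)."""
    W = np.asarray(weights, dtype=np.float64)
    X = _as_csr(dataset.X)
    y = np.asarray(dataset.y, dtype=np.float64)
    if offset is None:
        offset = float(y.mean()) if len(y) else 0.0
    yc = y - offset
    t0 = np.asarray(dataset.task_ids) - 1
    all_pred = np.asarray((X @ W.T))
    pred = all_pred[np.arange(len(yc)), t0]
    loss = np.maximum(np.abs(pred - yc) - epsilon, 0.0) ** 2
    return (
        0.5 * float((W * W).sum())
        + grmt_regularizer(W, A)
        + C * float(loss.sum())
    )


def adapt_for_unseen_task(A, t_out: int) -> GraphLaplacian:
    """Leave-one-sequence-out adaptation of the Laplacian system.

    For a task ``t_out`` (1-based) with no training instances, the ridge term
    ``||w_{t_out}||^2`` is dropped from the joint regularizer — its identity
    contribution is removed from ``block(I_T + L)`` — while every coupling
    term ``A_st ||w_s - w_t||^2`` is kept, so the held-out model is purely
    interpolated from its similar tasks.

    Raises
    ------
    ValueError
        If the modified system is not positive definite (e.g. the held-out
        task has zero similarity to every other task, leaving its weight
        unconstrained).
    """
    A = _check_adjacency(A)
    T = A.shape[0]
    if not 1 <= t_out <= T:
        raise ValueError(f"task {t_out} outside 1..{T}")
    D = np.diag(A.sum(axis=0))
    L = D - A
    K = np.eye(T) + L
    K[t_out - 1, t_out - 1] -= 1.0
    try:
        c, low = scipy.linalg.cho_factor(K)
    except scipy.linalg.LinAlgError as exc:
        raise ValueError(
            f"leave-one-out system for task {t_out} is not positive definite "
            "(held-out task has no effective similarity edges)"
        ) from exc
    M = scipy.linalg.cho_solve((c, low), np.eye(T))
    return GraphLaplacian(L, M)
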