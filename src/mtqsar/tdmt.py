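"""Top-down multi-task SVR (TDMT) over a task taxonomy.

One linear SVR model is trained per taxonomy node, root first.  A node solves

    min_w  (1-B)/2 ||w||^2 + B/2 ||w - w_p||^2 + C sum_{i in S} loss_eps(w.x_i, y_i)

where ``S`` holds the instances whose task is a leaf of the node's subtree
and ``w_p`` is the (fixed) optimal weight of the parent model.  ``B`` in
[0, 1] trades model margin against similarity to the ancestor: ``B = 0``
trains independently of the parent, ``B = 1`` pins the model to it.  Up to a
constant the regularizer equals ``1/2 ||w||^2 - B w.w_p``, so the dual is the
standard SVR dual plus a per-instance linear term — a node solve costs the
same as an independent SVR.

``B`` comes either from the scaled taxonomy edge weights (TDMTtax) or from a
local per-node grid search with inner cross-validation (TDMTgs).  Adding
``B = 0`` to the leaf grids prevents negative transfer by allowing a leaf to
opt out of the hierarchy.

Labels are centered per node; predictions use the full node weight plus the
node offset.  (The alternative convention of summing the node and parent
weights at prediction time is available as a compatibility switch but is
inconsistent with the ``B = 0`` independence property.)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .data import MultiTaskDataset
from .svr import _as_csr, solve_dual
from .taxonomy import TaskTaxonomy

__all__ = [
    "NodeModel",
    "TDMTConfig",
    "TDMTModel",
    "train_node",
    "local_grid_search_B",
    "train_topdown",
    "predict_leaf",
]

DEFAULT_B_GRID = (0.0, 0.1, 0.25, 0.5, 0.75, 0.9, 1.0)
DEFAULT_C_GRID = tuple(float(2.0 ** k) for k in range(-5, 8, 2))


@dataclass
class NodeModel:
    """Fitted model of one taxonomy node."""

    node_id: str
    weight: np.ndarray
    B: float
    C: float
    offset: float
    parent_id: str | None
    subtree_tasks: frozenset
    inherited: bool = False  # True when S was empty and the parent was copied


@dataclass
class TDMTConfig:
    """Configuration of a top-down training run.

    mode 'tax' takes ``B`` from the scaled taxonomy edge weights and searches
    only ``C``; mode 'gs' searches ``(B, C)`` jointly per node.
    """

    mode: str = "tax"
    C_grid: tuple = DEFAULT_C_GRID
    B_grid: tuple = DEFAULT_B_GRID
    inner_folds: int = 3
    prevent_negative_transfer: bool = False
    epsilon: float = 0.1
    tol: float = 1e-3
    max_iter: int = 1000
    seed: int = 0
    literal_parent_sum: bool = False

    def __post_init__(self):
        if self.mode not in ("tax", "gs"):
            raise ValueError("mode must be 'tax' or 'gs'")
        if not self.C_grid or (self.mode == "gs" and not self.B_grid):
            raise ValueError("parameter grids must be non-empty")


def train_node(
    instances,
    y,
    parent_weight,
    B: float,
    C: float,
    epsilon: float = 0.1,
    tol: float = 1e-3,
    max_iter: int = 1000,
    seed: int = 0,
):
    """Solve one node problem given the fixed parent weight.

    ``y`` must already be centered by the node offset.  The solve shifts the
    labels by the parent's pull (equivalently, passes the pull to the dual as
    a linear term) and returns the full node weight.
    """
    if not 0.0 <= B <= 1.0:
        raise ValueError("B must lie in [0, 1]")
    X = _as_csr(instances)
    parent_weight = np.asarray(parent_weight, dtype=np.float64)
    pull = B * np.asarray(X @ parent_weight).ravel()
    state, u = solve_dual(
        X, y, C, epsilon, linear_terms=-pull,
        tol=tol, max_iter=max_iter, seed=seed,
    )
    w = u + B * parent_weight
    return w, state


def node_objective(X, y, w, parent_weight, B, C, epsilon) -> float:
    """Primal node objective at ``w`` (centered labels)."""
    X = _as_csr(X)
    w = np.asarray(w, dtype=np.float64)
    wp = np.asarray(parent_weight, dtype=np.float64)
    loss = np.maximum(np.abs(np.asarray(X @ w).ravel() - y) - epsilon, 0.0) ** 2
    return (
        0.5 * (1.0 - B) * float(w @ w)
        + 0.5 * B * float((w - wp) @ (w - wp))
        + C * float(loss.sum())
    )


def _cv_folds(n, k, seed):
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    return [order[j::k] for j in range(k)]


def local_grid_search_B(
    instances,
    y,
    parent_weight,
    B_grid,
    C_grid,
    inner_folds: int = 3,
    epsilon: float = 0.1,
    tol: float = 1e-3,
    max_iter: int = 1000,
    seed: int = 0,
):
    """Pick ``(B, C)`` minimizing mean inner-CV MSE of the node model.

    The parent weight stays fixed during the search.  Ties break toward the
    smaller ``B``, then the smaller ``C``.  If the node has fewer instances
    than folds, the fold count is reduced (with a warning).
    """
    X = _as_csr(instances)
    y = np.asarray(y, dtype=np.float64)
    n = X.shape[0]
    if n == 0:
        raise ValueError("grid search on an empty node")
    k = min(inner_folds, n)
    if k < inner_folds:
        warnings.warn(
            f"node has {n} instances; reducing inner folds to {k}", RuntimeWarning
        )
    if k < 2:
        # degenerate: no held-out data; fall back to smallest grid entries
        return float(sorted(B_grid)[0]), float(sorted(C_grid)[0])
    folds = _cv_folds(n, k, seed)
    best = (np.inf, None, None)
    for B in sorted(set(float(b) for b in B_grid)):
        for C in sorted(set(float(c) for c in C_grid)):
            errs = []
            for j, val_idx in enumerate(folds):
                tr_idx = np.concatenate([folds[m] for m in range(k) if m != j])
                Xtr, ytr = X[tr_idx], y[tr_idx]
                off = float(ytr.mean())
                w, _ = train_node(
                    Xtr, ytr - off, parent_weight, B, C, epsilon,
                    tol=tol, max_iter=max_iter, seed=seed,
                )
                pred = np.asarray(X[val_idx] @ w).ravel() + off
                errs.append(float(np.mean((pred - y[val_idx]) ** 2)))
            mean_err = float(np.mean(errs))
            if mean_err < best[0] - 1e-12:
                best = (mean_err, B, C)
    return best[1], best[2]


class TDMTModel:
    """The trained per-node models of a top-down run."""

    def __init__(self, models: dict, task_leaf: dict, literal_parent_sum=False):
        self.models = models
        self.task_leaf = task_leaf  # task id -> leaf node label
        self.literal_parent_sum = literal_parent_sum

    def __getitem__(self, node_id: str) -> NodeModel:
        return self.models[node_id]

    def predict(self, X, task: int) -> np.ndarray:
        return predict_leaf(self, X, task)

    @property
    def root(self) -> NodeModel:
        return next(m for m in self.models.values() if m.parent_id is None)


def _leaf_task_map(taxonomy: TaskTaxonomy, dataset: MultiTaskDataset, task_map=None):
    leaves = taxonomy.leaf_labels
    if task_map is not None:
        mapping = dict(task_map)
    else:
        mapping = {}
        for pos, label in enumerate(leaves):
            if label.isdigit():
                mapping[label] = int(label)
            elif label.startswith("T") and label[1:].isdigit():
                mapping[label] = int(label[1:])
            else:
                mapping[label] = pos + 1
    present = set(np.unique(dataset.task_ids))
    covered = set(mapping.values())
    if not present <= covered:
        raise ValueError(f"tasks {sorted(present - covered)} missing from taxonomy leaves")
    return mapping


def train_topdown(
    taxonomy: TaskTaxonomy,
    dataset: MultiTaskDataset,
    config: TDMTConfig | None = None,
    task_map: dict | None = None,
) -> TDMTModel:
    """Train models for every taxonomy node, root first.

    The root is trained on all instances with no parent pull (it coincides
    with the pooled single-model baseline).  Each descendant is trained on
    the instances of its subtree, pulled toward its parent's fixed optimal
    weight.  A node with no training instances (a held-out task under
    leave-one-sequence-out) inherits its parent's model.
    """
    config = config or TDMTConfig()
    mapping = _leaf_task_map(taxonomy, dataset, task_map)
    X = _as_csr(dataset.X)
    n = X.shape[1]
    models: dict[str, NodeModel] = {}

    def subtree_tasks(node):
        if node.is_leaf:
            return frozenset({mapping[node.label]})
        out = set()
        for c in node.children:
            out |= subtree_tasks(c)
        return frozenset(out)

    for node in taxonomy.nodes():  # breadth-first: parents precede children
        tasks = subtree_tasks(node)
        mask = np.isin(dataset.task_ids, list(tasks))
        parent_model = models[node.parent.label] if node.parent is not None else None
        if not mask.any():
            pm = parent_model
            models[node.label] = NodeModel(
                node.label, pm.weight.copy(), 0.0, pm.C, pm.offset,
                node.parent.label, tasks, inherited=True,
            )
            continue
        Xs, ys = X[np.flatnonzero(mask)], dataset.y[mask]
        offset = float(ys.mean())
        ysc = ys - offset
        wp = parent_model.weight if parent_model is not None else np.zeros(n)
        if node.is_root:
            B_candidates = [0.0]
        elif config.mode == "tax":
            B_candidates = [float(node.edge_weight)]
            if config.prevent_negative_transfer and node.is_leaf:
                B_candidates = sorted({0.0, float(node.edge_weight)})
        else:
            B_candidates = list(config.B_grid)
        if len(B_candidates) == 1 and len(config.C_grid) == 1:
            B_star, C_star = float(B_candidates[0]), float(config.C_grid[0])
        else:
            B_star, C_star = local_grid_search_B(
                Xs, ys, wp, B_candidates, config.C_grid,
                inner_folds=config.inner_folds, epsilon=config.epsilon,
                tol=config.tol, max_iter=config.max_iter, seed=config.seed,
            )
        w, _ = train_node(
            Xs, ysc, wp, B_star, C_star, config.epsilon,
            tol=config.tol, max_iter=config.max_iter, seed=config.seed,
        )
        models[node.label] = NodeModel(
            node.label, w, B_star, C_star, offset,
            node.parent.label if node.parent is not None else None, tasks,
        )

    task_leaf = {}
    for leaf in taxonomy.leaves():
        task_leaf[mapping[leaf.label]] = leaf.label
    return TDMTModel(models, task_leaf, literal_parent_sum=config.literal_parent_sum)


def predict_leaf(model: TDMTModel, X, task: int) -> np.ndarray:
    """Predict for a leaf task: full leaf weight plus leaf offset.

    A leaf with an inherited model (unseen task) yields its parent's
    prediction.  With the ``literal_parent_sum`` compatibility switch the
    node and parent weights are summed instead.
    """
    if task not in model.task_leaf:
        raise ValueError(f"unknown task {task}")
    node = model.models[model.task_leaf[task]]
    X = _as_csr(X)
    if model.literal_parent_sum and node.parent_id is not None and not node.inherited:
        parent = model.models[node.parent_id]
        w = node.weight + parent.weight
        return np.asarray(X @ w).ravel() + node.offset
    return np.asarray(X @ node.weight).ravel() + node.offset
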