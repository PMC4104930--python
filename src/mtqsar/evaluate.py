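"""Experiment protocols, model selection, and paired significance testing.

The harness evaluates the five algorithms — independent per-task SVRs
(tSVM), one pooled SVR (1SVM), graph-regularized multi-task SVR (GRMT) and
the two top-down variants (TDMTtax, TDMTgs) — on shared train/test splits,
selects hyperparameters by inner cross-validation, and compares algorithms
per task with two-sided Wilcoxon signed-rank tests under family-wise
(Holm) or false-discovery-rate (Benjamini-Hochberg) control.

All algorithms always see identical splits: pairing of performance values by
``(task, split)`` is enforced structurally by running every algorithm over
the same ``Split`` objects.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .data import MultiTaskDataset
from .grmt import adapt_for_unseen_task, train_grmt
from .simulate import (
    SimulationConfig,
    similarity_from_weights,
    simulate_task_set,
    taxonomy_from_weights,
)
from .svr import train_svr
from .tdmt import TDMTConfig, train_topdown
from .taxonomy import TaskTaxonomy

logger = logging.getLogger(__name__)

__all__ = [
    "ALGORITHMS",
    "ExperimentProtocol",
    "Split",
    "mse",
    "make_grids",
    "simulated_splits",
    "random_splits",
    "run_protocol",
    "leave_one_sequence_out",
    "paired_tests",
]

ALGORITHMS = ("tSVM", "1SVM", "GRMT", "TDMTtax", "TDMTgs")


def mse(y_true, y_pred) -> float:
    """Mean squared error."""
    y_true = np.asarray(y_true, dtype=np.float64)
    y_pred = np.asarray(y_pred, dtype=np.float64)
    if y_true.shape != y_pred.shape or y_true.size == 0:
        raise ValueError("inputs must be equal-length and non-empty")
    return float(np.mean((y_true - y_pred) ** 2))


def make_grids(setting: str = "default"):
    """Hyperparameter grids: ``(C_grid, B_grid, epsilon)``.

    'default' uses log2(C) in {-5, -3, ..., 7}; 'kinome_grmt' the coarser
    high-C grid log2(C) in {2, 4, 6, 8} used when many tasks make the joint
    regularizer dominate.  The B grid is {0, 0.1, 0.25, 0.5, 0.75, 0.9, 1}
    and epsilon is fixed at 0.1 pIC50 units (a 25% relative IC50 deviation:
    log10(1.25) ~ 0.1).
    """
    B_grid = (0.0, 0.1, 0.25, 0.5, 0.75, 0.9, 1.0)
    if setting == "default":
        C_grid = tuple(float(2.0 ** k) for k in range(-5, 8, 2))
    elif setting == "kinome_grmt":
        C_grid = tuple(float(2.0 ** k) for k in range(2, 9, 2))
    else:
        raise ValueError(f"unknown grid setting {setting!r}")
    return C_grid, B_grid, 0.1


@dataclass
class ExperimentProtocol:
    """How to split and repeat: random splits, nested CV or
    leave-one-sequence-out."""

    kind: str = "random_splits"
    repetitions: int = 10
    outer_folds: int = 3
    inner_folds: int = 3
    train_size: int = 60
    test_size: int = 25
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("random_splits", "nested_cv", "leave_one_sequence_out"):
            raise ValueError(f"unknown protocol kind {self.kind!r}")
        if self.inner_folds < 2 or (self.kind == "nested_cv" and self.outer_folds < 2):
            raise ValueError("fold counts must be >= 2")
        if self.test_size < 5:
            raise ValueError("test size must be >= 5")


@dataclass
class Split:
    """One shared train/test split plus the task-similarity inputs.

    ``pool`` optionally holds additional per-task instances for the
    leave-one-sequence-out budget redistribution.
    """

    train: MultiTaskDataset
    test: MultiTaskDataset
    similarity: np.ndarray = None
    taxonomy: TaskTaxonomy = None
    pool: MultiTaskDataset = None
    index: int = 0


def simulated_splits(
    config: SimulationConfig,
    n_splits: int = 10,
    similarity_variant: str = "true",
    shared_instances: bool = False,
    pool_factor: int = 0,
):
    """Generate shared splits from the simulation benchmark.

    Each split is an independent draw of task weights, train and test sets;
    similarities for the multi-task algorithms are computed from the
    generating weights (variant 'true', 'anti' or 'random').  With
    ``pool_factor`` > 0 an enlarged training pool (``pool_factor * N`` per
    task) is attached for leave-one-sequence-out budget redistribution.
    """
    splits = []
    base = np.random.SeedSequence(config.seed)
    for j, child in enumerate(base.spawn(n_splits)):
        seed_j = int(child.generate_state(1)[0] % (2 ** 31))
        cfg = SimulationConfig(
            N=config.N * pool_factor if pool_factor else config.N,
            T=config.T, D=config.D, beta=config.beta, sigma2=config.sigma2,
            n_test=config.n_test, seed=seed_j,
        )
        ts = simulate_task_set(cfg, shared_instances=shared_instances)
        if pool_factor:
            pool = ts.train
            keep = np.concatenate([
                np.flatnonzero(pool.task_ids == t)[: config.N] for t in pool.tasks
            ])
            train = pool.subset(np.sort(keep))
        else:
            pool, train = None, ts.train
        A = similarity_from_weights(ts.task_weights, variant=similarity_variant,
                                    seed=seed_j)
        tax = taxonomy_from_weights(ts.task_weights, cfg.beta, cfg.D,
                                    variant=similarity_variant, seed=seed_j)
        splits.append(Split(train, ts.test, A, tax, pool=pool, index=j))
    return splits


def random_splits(dataset: MultiTaskDataset, protocol: ExperimentProtocol,
                  similarity=None, taxonomy=None):
    """Repeated random per-task train/test splits of a fixed dataset.

    Per repetition and task, ``train_size`` training and ``test_size`` test
    instances are drawn without overlap; tasks too small for the protocol are
    excluded with a logged warning.  The remaining pool rows are attached for
    leave-one-sequence-out use.
    """
    need = protocol.train_size + protocol.test_size
    splits = []
    base = np.random.SeedSequence(protocol.seed)
    for j, child in enumerate(base.spawn(protocol.repetitions)):
        rng = np.random.default_rng(child)
        tr_idx, te_idx = [], []
        for t in dataset.tasks:
            rows = np.flatnonzero(dataset.task_ids == t)
            if rows.size < need:
                logger.warning(
                    "task %s has %d instances < %d required; excluded",
                    t, rows.size, need,
                )
                continue
            rows = rng.permutation(rows)
            tr_idx.append(rows[: protocol.train_size])
            te_idx.append(rows[protocol.train_size: need])
        splits.append(Split(
            dataset.subset(np.concatenate(tr_idx)),
            dataset.subset(np.concatenate(te_idx)),
            similarity, taxonomy, pool=dataset, index=j,
        ))
    return splits


def _stratified_folds(task_ids, k, seed):
    """Fold assignment stratified by task: every task appears in every fold
    where its size allows."""
    rng = np.random.default_rng(seed)
    fold = np.empty(len(task_ids), dtype=np.int64)
    for t in np.unique(task_ids):
        rows = rng.permutation(np.flatnonzero(task_ids == t))
        fold[rows] = np.arange(len(rows)) % k
    return fold


def _select_C_pooled(train, C_grid, inner_folds, epsilon, seed, trainer):
    """Inner-CV selection of C by pooled validation MSE; ties -> smaller C."""
    folds = _stratified_folds(train.task_ids, inner_folds, seed)
    best = (np.inf, None)
    for C in sorted(set(float(c) for c in C_grid)):
        errs = []
        for j in range(inner_folds):
            tr = train.subset(folds != j)
            va = train.subset(folds == j)
            if len(tr) == 0 or len(va) == 0:
                continue
            pred = trainer(tr, C, va)
            errs.append(mse(va.y, pred))
        m = float(np.mean(errs))
        if m < best[0] - 1e-12:
            best = (m, C)
    return best[1]


def _fit_predict(algo, split, C_grid, B_grid, inner_folds, epsilon, seed,
                 tol=1e-3, max_iter=1000, heldout_task=None):
    """Train one algorithm on a split and return {task: predictions}."""
    train, test = split.train, split.test
    tasks = list(np.unique(test.task_ids))
    T = split.similarity.shape[0] if split.similarity is not None else (
        int(max(train.task_ids.max(), test.task_ids.max())))
    preds = {}
    if algo == "tSVM":
        for t in tasks:
            tr = train.task_subset(t)
            C = _select_C_pooled(
                tr, C_grid, min(inner_folds, max(2, len(tr))), epsilon, seed,
                lambda d, C, va: train_svr(
                    d, C, epsilon, tol=tol, max_iter=max_iter, seed=seed
                ).predict(va.X),
            )
            model = train_svr(tr, C, epsilon, tol=tol, max_iter=max_iter, seed=seed)
            preds[t] = model.predict(test.task_subset(t).X)
    elif algo == "1SVM":
        C = _select_C_pooled(
            train, C_grid, inner_folds, epsilon, seed,
            lambda d, C, va: train_svr(
                d, C, epsilon, tol=tol, max_iter=max_iter, seed=seed
            ).predict(va.X),
        )
        model = train_svr(train, C, epsilon, tol=tol, max_iter=max_iter, seed=seed)
        for t in tasks:
            preds[t] = model.predict(test.task_subset(t).X)
    elif algo == "GRMT":
        A = split.similarity
        if A is None:
            raise ValueError("GRMT requires a similarity matrix on the split")
        lap = adapt_for_unseen_task(A, heldout_task) if heldout_task else None

        def grmt_trainer(d, C, va):
            m = train_grmt(d, A, C, epsilon, laplacian=lap,
                           tol=tol, max_iter=max_iter, seed=seed)
            return np.array([
                m.predict(va.X[i], int(va.task_ids[i]))[0] for i in range(len(va))
            ])

        C = _select_C_pooled(train, C_grid, inner_folds, epsilon, seed, grmt_trainer)
        model = train_grmt(train, A, C, epsilon, laplacian=lap,
                           tol=tol, max_iter=max_iter, seed=seed)
        for t in tasks:
            preds[t] = model.predict(test.task_subset(t).X, int(t))
    elif algo in ("TDMTtax", "TDMTgs"):
        if split.taxonomy is None:
            raise ValueError(f"{algo} requires a taxonomy on the split")
        cfg = TDMTConfig(
            mode="tax" if algo == "TDMTtax" else "gs",
            C_grid=tuple(C_grid), B_grid=tuple(B_grid),
            inner_folds=inner_folds, epsilon=epsilon,
            tol=tol, max_iter=max_iter, seed=seed,
        )
        model = train_topdown(split.taxonomy, train, cfg)
        for t in tasks:
            preds[t] = model.predict(test.task_subset(t).X, int(t))
    else:
        raise ValueError(f"unknown algorithm {algo!r}")
    return preds


def run_protocol(
    algorithms,
    splits,
    C_grid=None,
    B_grid=None,
    inner_folds: int = 3,
    epsilon: float = 0.1,
    seed: int = 0,
    tol: float = 1e-3,
    max_iter: int = 1000,
) -> pd.DataFrame:
    """Evaluate algorithms on shared splits; returns the performance table.

    Per split and algorithm: inner-CV model selection over the grids, a
    final fit on the full training portion, and the per-task test MSE.  The
    result is a tidy frame with columns ``algorithm, task, split, mse``,
    paired across algorithms by ``(task, split)`` by construction.
    """
    dC, dB, deps = make_grids("default")
    C_grid = tuple(C_grid) if C_grid is not None else dC
    B_grid = tuple(B_grid) if B_grid is not None else dB
    rows = []
    for split in splits:
        for algo in algorithms:
            preds = _fit_predict(algo, split, C_grid, B_grid, inner_folds,
                                 epsilon, seed, tol=tol, max_iter=max_iter)
            for t, p in preds.items():
                rows.append({
                    "algorithm": algo, "task": int(t), "split": split.index,
                    "mse": mse(split.test.task_subset(t).y, p),
                })
    return pd.DataFrame(rows)


def _redistribute_budget(pool, tasks, t_out, train_size):
    """Training rows for a leave-one-sequence-out round.

    The held-out task's budget is spread uniformly over the remaining tasks;
    the remainder goes to the tasks with the largest pools (ties: lowest
    id).  Rows come from each task's pool in pool order (pools are sampled
    or pre-shuffled upstream).
    """
    rest = [t for t in tasks if t != t_out]
    extra, remainder = divmod(train_size, len(rest))
    by_pool = sorted(rest, key=lambda t: (-np.sum(pool.task_ids == t), t))
    bonus = {t: (1 if i < remainder else 0) for i, t in enumerate(by_pool)}
    rows = []
    for t in rest:
        want = train_size + extra + bonus[t]
        have = np.flatnonzero(pool.task_ids == t)
        rows.append(have[: min(want, have.size)])
    return np.sort(np.concatenate(rows))


def leave_one_sequence_out(
    algorithms,
    splits,
    C_grid=None,
    B_grid=None,
    inner_folds: int = 3,
    epsilon: float = 0.1,
    seed: int = 0,
    tol: float = 1e-3,
    max_iter: int = 1000,
    train_size: int | None = None,
) -> pd.DataFrame:
    """Novel-target evaluation: hold out each task's training data in turn.

    The held-out task keeps its fixed test set; its training budget is
    redistributed over the remaining tasks from the split's pool, so the
    total training size matches the standard protocol.  The top-down methods
    predict through the held-out leaf's parent model; the graph method drops
    the held-out ridge term via the adapted Laplacian, and is skipped (with
    a log entry) when the held-out task has zero similarity to every other
    task.
    """
    dC, dB, _ = make_grids("default")
    C_grid = tuple(C_grid) if C_grid is not None else dC
    B_grid = tuple(B_grid) if B_grid is not None else dB
    rows = []
    for split in splits:
        pool = split.pool if split.pool is not None else split.train
        tasks = list(np.unique(split.train.task_ids))
        if len(tasks) < 2:
            raise ValueError("leave-one-sequence-out needs at least two tasks")
        n_train = train_size or int(np.max(
            [np.sum(split.train.task_ids == t) for t in tasks]
        ))
        for t_out in tasks:
            keep = _redistribute_budget(pool, tasks, t_out, n_train)
            loso_train = pool.subset(keep)
            loso_test = split.test.task_subset(t_out)
            sub = Split(loso_train, loso_test, split.similarity,
                        split.taxonomy, index=split.index)
            for algo in algorithms:
                if algo == "GRMT":
                    A = split.similarity
                    off_diag = np.delete(A[int(t_out) - 1], int(t_out) - 1)
                    if np.all(off_diag == 0):
                        logger.info(
                            "GRMT skipped for held-out task %s: zero similarity "
                            "to all other tasks", t_out,
                        )
                        continue
                preds = _fit_predict(
                    algo, sub, C_grid, B_grid, inner_folds, epsilon, seed,
                    tol=tol, max_iter=max_iter,
                    heldout_task=int(t_out) if algo == "GRMT" else None,
                )
                rows.append({
                    "algorithm": algo, "task": int(t_out), "split": split.index,
                    "mse": mse(loso_test.y, preds[int(t_out)]),
                })
    return pd.DataFrame(rows)


def paired_tests(
    table: pd.DataFrame,
    algo_a: str,
    algo_b: str,
    correction: str = "holm",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-task paired Wilcoxon signed-rank comparison of two algorithms.

    MSE values are paired by ``(task, split)``.  The two-sided test is exact
    for <= 25 pairs (no ties/zeros) and a continuity-corrected normal
    approximation otherwise.  P-values are adjusted across tasks by Holm
    ('holm', family-wise control) or Benjamini-Hochberg ('fdr_bh', FDR 5%).
    Each task is labeled Better/NoChange/Worse for ``algo_a`` relative to
    ``algo_b`` by the sign of the median paired difference among significant
    results.  All-zero differences yield p = 1 with a 'degenerate' flag.
    """
    if correction not in ("holm", "fdr_bh"):
        raise ValueError("correction must be 'holm' or 'fdr_bh'")
    wide = table[table.algorithm.isin([algo_a, algo_b])].pivot_table(
        index=["task", "split"], columns="algorithm", values="mse"
    )
    if wide.isna().any().any():
        raise ValueError("algorithms are not paired on identical (task, split)")
    out = []
    for task, grp in wide.groupby(level="task"):
        a = grp[algo_a].to_numpy()
        b = grp[algo_b].to_numpy()
        diffs = a - b
        degenerate = bool(np.all(diffs == 0))
        if degenerate:
            p = 1.0
        else:
            n = len(diffs)
            method = "exact" if (
                n <= 25 and not np.any(diffs == 0) and
                len(np.unique(np.abs(diffs))) == n
            ) else "approx"
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                p = float(scipy.stats.wilcoxon(
                    a, b, alternative="two-sided", correction=True, method=method
                ).pvalue)
        out.append({
            "task": task, "n_pairs": len(diffs), "p_raw": p,
            "median_diff": float(np.median(diffs)), "degenerate": degenerate,
        })
    res = pd.DataFrame(out)
    reject, p_adj, _, _ = multipletests(res.p_raw, alpha=alpha, method=correction)
    res["p_adj"] = p_adj
    res["significant"] = reject
    res["label"] = np.where(
        ~res.significant, "NoChange",
        np.where(res.median_diff < 0, "Better", "Worse"),
    )
    return res
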