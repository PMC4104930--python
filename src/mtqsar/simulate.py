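"""Synthetic multi-task regression benchmark.

Each instance has ``D`` categorical attributes with 6 possible values,
ordered from very negative to very positive influence on the target; an
attribute choice is encoded one-hot, so an instance is a ``6*D``-dimensional
binary vector with exactly ``D`` ones.  A task model is a ``6*D`` weight
vector whose six sub-weights per attribute are drawn independently from
Gaussians with means

    -b, -2b/3, -b/3, b/3, 2b/3, b

and common variance ``sigma^2``.  The scale ``b`` (``beta``) controls the
noise level (we default to ``beta = 3``, low noise); the variance controls
how similar the task models are — ``sigma^2 = 3*beta`` yields low task
similarity, ``sigma^2 = 0.5*beta`` high similarity.  Targets are exact,
noise-free linear responses ``y = w_t . x``.

Task similarities for the multi-task algorithms are computed directly from
the generating weight vectors: pairwise cosine similarities for the
graph-based method, and a star taxonomy (root = the mean-of-Gaussians model)
with edge weights ``cos(w_t, w_mean)`` for the top-down method.  "anti"
variants (``1 - cos``) and "random" variants (uniform in [0, 1]) probe the
sensitivity of the methods to wrong similarities; a task's self-similarity
is always 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .data import MultiTaskDataset
from .taxonomy import TaskTaxonomy, star_taxonomy

__all__ = [
    "SimulationConfig",
    "SimulatedTaskSet",
    "attribute_means",
    "sample_task_weights",
    "sample_instances",
    "compute_targets",
    "similarity_from_weights",
    "taxonomy_from_weights",
    "simulate_task_set",
]

N_VALUES = 6  # attribute levels, very negative .. very positive


@dataclass
class SimulationConfig:
    """Benchmark conditions: instances/tasks/attributes and the Gaussian
    noise (beta) and task-similarity (sigma2) parameters."""

    N: int = 45
    T: int = 5
    D: int = 14
    beta: float = 3.0
    sigma2: float = 1.5  # 0.5*beta: high task similarity; 3*beta: low
    n_test: int = 25
    seed: int = 0

    def __post_init__(self):
        if min(self.N, self.T, self.D) < 1:
            raise ValueError("N, T and D must be positive")
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.sigma2 < 0:
            raise ValueError("sigma2 must be non-negative")


def attribute_means(beta: float) -> np.ndarray:
    """The six Gaussian means, very negative to very positive influence."""
    return beta * np.array([-1.0, -2.0 / 3.0, -1.0 / 3.0, 1.0 / 3.0, 2.0 / 3.0, 1.0])


def sample_task_weights(T: int, D: int, beta: float, sigma2: float, seed=0) -> np.ndarray:
    """Draw ``T`` task weight vectors of length ``6*D`` attribute-wise.

    With ``sigma2 = 0`` every task equals the tiled mean pattern exactly.
    """
    if T < 1 or D < 1:
        raise ValueError("T and D must be positive")
    if beta <= 0 or sigma2 < 0:
        raise ValueError("invalid beta/sigma2")
    rng = np.random.default_rng(seed)
    mu = np.tile(attribute_means(beta), D)
    return rng.normal(mu, np.sqrt(sigma2), size=(T, N_VALUES * D))


def sample_instances(N: int, D: int, seed=0) -> np.ndarray:
    """Draw ``N`` one-hot instances: per attribute one of 6 values, uniform."""
    if N < 1 or D < 1:
        raise ValueError("N and D must be positive")
    rng = np.random.default_rng(seed)
    choice = rng.integers(0, N_VALUES, size=(N, D))
    X = np.zeros((N, N_VALUES * D))
    cols = np.arange(D) * N_VALUES + choice
    X[np.arange(N)[:, None], cols] = 1.0
    return X


def compute_targets(task_weights: np.ndarray, instances: np.ndarray) -> np.ndarray:
    """Noise-free targets ``y = w_t . x``; returns shape (n_instances, T)."""
    return np.asarray(instances) @ np.asarray(task_weights).T


def similarity_from_weights(
    task_weights: np.ndarray, variant: str = "true", seed=0, clip: bool = True
) -> np.ndarray:
    """Pairwise task-similarity matrix from the generating weights.

    variant 'true' uses cosine similarities, 'anti' uses ``1 - cos`` and
    'random' uniform draws in [0, 1]; the diagonal is fixed to 1.  Negative
    cosines (possible at low task similarity) are clipped to 0 when ``clip``
    so the matrix is a valid graph adjacency; pass ``clip=False`` for the
    raw values.
    """
    W = np.asarray(task_weights, dtype=np.float64)
    norms = np.linalg.norm(W, axis=1)
    if np.any(norms == 0):
        raise ValueError("zero-norm task weight vector")
    Wn = W / norms[:, None]
    cos = Wn @ Wn.T
    if variant == "true":
        A = cos
    elif variant == "anti":
        A = 1.0 - cos
    elif variant == "random":
        rng = np.random.default_rng(seed)
        A = rng.uniform(0.0, 1.0, size=cos.shape)
        A = np.triu(A, 1)
        A = A + A.T
    else:
        raise ValueError(f"unknown similarity variant {variant!r}")
    if clip:
        A = np.clip(A, 0.0, 1.0)
    np.fill_diagonal(A, 1.0)
    return (A + A.T) / 2.0


def taxonomy_from_weights(
    task_weights: np.ndarray, beta: float, D: int, variant: str = "true", seed=0
) -> TaskTaxonomy:
    """Star taxonomy: root (the mean-of-Gaussians model) joined to every task,
    edge weight = cosine of the task model to the mean model (or its 'anti' /
    'random' variant), clipped into [0, 1]."""
    W = np.asarray(task_weights, dtype=np.float64)
    mean_model = np.tile(attribute_means(beta), D)
    cos = (W @ mean_model) / (np.linalg.norm(W, axis=1) * np.linalg.norm(mean_model))
    if variant == "true":
        edge = cos
    elif variant == "anti":
        edge = 1.0 - cos
    elif variant == "random":
        edge = np.random.default_rng(seed).uniform(0.0, 1.0, size=len(cos))
    else:
        raise ValueError(f"unknown similarity variant {variant!r}")
    edge = np.clip(edge, 0.0, 1.0)
    return star_taxonomy(edge)


@dataclass
class SimulatedTaskSet:
    """A full benchmark draw: task weights, per-task train sets and a fixed
    per-task test set, all with exact targets."""

    config: SimulationConfig
    task_weights: np.ndarray
    train: MultiTaskDataset
    test: MultiTaskDataset

    @property
    def attribute_mean_vector(self) -> np.ndarray:
        return np.tile(attribute_means(self.config.beta), self.config.D)


def simulate_task_set(
    config: SimulationConfig, shared_instances: bool = False
) -> SimulatedTaskSet:
    """Generate one train/test draw under the benchmark conditions.

    Training instances are sampled separately for each task (pass
    ``shared_instances=True`` to give every task the same instances, the
    input-space-coverage control condition); the test set has ``n_test``
    fresh instances per task.  The global seed fans out to independent
    substreams for weights, train and test draws.
    """
    cfg = config
    ss = np.random.SeedSequence(cfg.seed)
    s_w, s_tr, s_te = ss.spawn(3)
    W = sample_task_weights(cfg.T, cfg.D, cfg.beta, cfg.sigma2, seed=s_w)

    Xtr_parts, ytr_parts, ttr_parts = [], [], []
    tr_rng = s_tr.spawn(cfg.T)
    shared = sample_instances(cfg.N, cfg.D, seed=s_tr) if shared_instances else None
    for t in range(cfg.T):
        Xt = shared if shared_instances else sample_instances(cfg.N, cfg.D, seed=tr_rng[t])
        Xtr_parts.append(Xt)
        ytr_parts.append(Xt @ W[t])
        ttr_parts.append(np.full(cfg.N, t + 1))
    Xte_parts, yte_parts, tte_parts = [], [], []
    te_rng = s_te.spawn(cfg.T)
    for t in range(cfg.T):
        Xt = sample_instances(cfg.n_test, cfg.D, seed=te_rng[t])
        Xte_parts.append(Xt)
        yte_parts.append(Xt @ W[t])
        tte_parts.append(np.full(cfg.n_test, t + 1))

    train = MultiTaskDataset(
        sp.csr_matrix(np.vstack(Xtr_parts)),
        np.concatenate(ytr_parts),
        np.concatenate(ttr_parts),
    )
    test = MultiTaskDataset(
        sp.csr_matrix(np.vstack(Xte_parts)),
        np.concatenate(yte_parts),
        np.concatenate(tte_parts),
    )
    return SimulatedTaskSet(cfg, W, train, test)


def similarity_statistics(
    T: int = 10, D: int = 10, N: int = 100, beta: float = 3.0,
    sigma2: float = 9.0, n_seeds: int = 20, seed: int = 0,
):
    """Mean pairwise cosine similarity of task weights and mean pairwise
    Pearson correlation of targets on a common instance set, averaged over
    seeds.  Returns ``(mean_cos, sd_cos, mean_pearson, sd_pearson)`` where
    the sds are over task pairs (pooled across seeds)."""
    cos_all, pear_all = [], []
    root = np.random.SeedSequence(seed).spawn(n_seeds)
    iu = np.triu_indices(T, 1)
    for s in root:
        s_w, s_x = s.spawn(2)
        W = sample_task_weights(T, D, beta, sigma2, seed=s_w)
        Wn = W / np.linalg.norm(W, axis=1, keepdims=True)
        cos_all.append((Wn @ Wn.T)[iu])
        X = sample_instances(N, D, seed=s_x)
        Y = compute_targets(W, X)  # N x T
        pear_all.append(np.corrcoef(Y.T)[iu])
    cos_all = np.concatenate(cos_all)
    pear_all = np.concatenate(pear_all)
    return (
        float(cos_all.mean()), float(cos_all.std()),
        float(pear_all.mean()), float(pear_all.std()),
    )
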