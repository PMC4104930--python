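"""Multi-task regression dataset container and I/O.

A multi-target QSAR dataset is a set of triples ``(x_i, y_i, t_i)``: a sparse
non-negative feature vector (e.g. a hashed circular fingerprint), a real-valued
label (pIC50) and an integer task id identifying the protein target.  Task ids
are 1-based; feature indices are 0-based and may live in a hash space of up to
2**20 bits.

The on-disk format is a plain delimited text file with columns
``instance_id<TAB>task_id<TAB>label<TAB>idx:val idx:val ...``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

__all__ = [
    "MultiTaskDataset",
    "normalize_features",
    "read_dataset",
    "write_dataset",
    "read_similarity_matrix",
    "write_similarity_matrix",
]


def normalize_features(X: sp.spmatrix | np.ndarray) -> sp.csr_matrix:
    """Scale every row of ``X`` to unit Euclidean norm.

    With non-negative features, dot products of normalized vectors lie in
    [0, 1]; the linear kernel on normalized vectors equals the cosine kernel.

    Raises
    ------
    ValueError
        If any row is all-zero (the cosine of a zero vector is undefined).
    """
    X = sp.csr_matrix(X, dtype=np.float64)
    norms = np.sqrt(np.asarray(X.multiply(X).sum(axis=1)).ravel())
    if np.any(norms == 0):
        bad = int(np.flatnonzero(norms == 0)[0])
        raise ValueError(f"cannot normalize all-zero feature vector (row {bad})")
    inv = sp.diags(1.0 / norms)
    return sp.csr_matrix(inv @ X)


@dataclass
class MultiTaskDataset:
    """Instances ``(x_i, y_i, t_i)`` stored as a sparse matrix plus label and
    task-id arrays.

    Attributes
    ----------
    X : scipy.sparse.csr_matrix, shape (l, n)
        Feature vectors, one instance per row.
    y : ndarray, shape (l,)
        Real-valued labels (pIC50 or simulated targets).
    task_ids : ndarray of int, shape (l,)
        1-based task id per instance.
    instance_ids : list of str, optional
        Stable external identifiers (compound ids); generated if absent.
    """

    X: sp.csr_matrix
    y: np.ndarray
    task_ids: np.ndarray
    instance_ids: list = field(default=None)

    def __post_init__(self):
        self.X = sp.csr_matrix(self.X, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.float64)
        self.task_ids = np.asarray(self.task_ids, dtype=np.int64)
        if len(self.y) != self.X.shape[0] or len(self.task_ids) != self.X.shape[0]:
            raise ValueError("X, y and task_ids must agree in length")
        if len(self.y) and self.task_ids.min() < 1:
            raise ValueError("task ids must be >= 1")
        if self.instance_ids is None:
            self.instance_ids = [f"i{k}" for k in range(self.X.shape[0])]

    def __len__(self) -> int:
        return self.X.shape[0]

    @property
    def n_tasks(self) -> int:
        return int(self.task_ids.max()) if len(self) else 0

    @property
    def tasks(self) -> np.ndarray:
        return np.unique(self.task_ids)

    def subset(self, mask_or_index) -> "MultiTaskDataset":
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return MultiTaskDataset(
            self.X[idx], self.y[idx], self.task_ids[idx],
            [self.instance_ids[i] for i in idx],
        )

    def task_subset(self, task: int) -> "MultiTaskDataset":
        return self.subset(self.task_ids == task)

    def normalized(self) -> "MultiTaskDataset":
        return MultiTaskDataset(
            normalize_features(self.X), self.y, self.task_ids, list(self.instance_ids)
        )


def write_dataset(dataset: MultiTaskDataset, path_or_buf) -> None:
    """Write a dataset in the shared delimited sparse format."""
    close = False
    if isinstance(path_or_buf, (str, bytes)):
        fh = open(path_or_buf, "w")
        close = True
    else:
        fh = path_or_buf
    try:
        fh.write("instance_id\ttask_id\tlabel\tfeatures\n")
        X = dataset.X.tocsr()
        for i in range(len(dataset)):
            row = X.getrow(i)
            feats = " ".join(
                f"{j}:{v:.17g}" for j, v in zip(row.indices, row.data)
            )
            fh.write(
                f"{dataset.instance_ids[i]}\t{dataset.task_ids[i]}\t"
                f"{dataset.y[i]:.17g}\t{feats}\n"
            )
    finally:
        if close:
            fh.close()


def read_dataset(path_or_buf, n_features: int | None = None) -> MultiTaskDataset:
    """Read a dataset from the shared delimited sparse format."""
    close = False
    if isinstance(path_or_buf, (str, bytes)):
        fh = open(path_or_buf)
        close = True
    else:
        fh = path_or_buf
    try:
        header = fh.readline()
        if not header.startswith("instance_id"):
            raise ValueError("missing dataset header line")
        ids, tasks, labels = [], [], []
        rows, cols, vals = [], [], []
        for lineno, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed dataset line {lineno + 2}")
            ids.append(parts[0])
            tasks.append(int(parts[1]))
            labels.append(float(parts[2]))
            if len(parts) > 3 and parts[3]:
                for tok in parts[3].split():
                    j, v = tok.split(":")
                    rows.append(len(ids) - 1)
                    cols.append(int(j))
                    vals.append(float(v))
    finally:
        if close:
            fh.close()
    if n_features is None:
        n_features = (max(cols) + 1) if cols else 0
    X = sp.csr_matrix(
        (vals, (rows, cols)), shape=(len(ids), n_features), dtype=np.float64
    )
    return MultiTaskDataset(X, np.array(labels), np.array(tasks), ids)


def write_similarity_matrix(A: np.ndarray, labels, path_or_buf) -> None:
    """Write a square task-similarity matrix with a header row of task labels.

    Decimal values round-trip bit-exactly (written with repr precision).
    """
    A = np.asarray(A, dtype=np.float64)
    out = io.StringIO()
    out.write("\t".join(str(l) for l in labels) + "\n")
    for row in A:
        out.write("\t".join(f"{v:.17g}" for v in row) + "\n")
    text = out.getvalue()
    if isinstance(path_or_buf, (str, bytes)):
        with open(path_or_buf, "w") as fh:
            fh.write(text)
    else:
        path_or_buf.write(text)


def read_similarity_matrix(path_or_buf):
    """Read a square similarity matrix; returns ``(A, labels)``."""
    if isinstance(path_or_buf, (str, bytes)):
        with open(path_or_buf) as fh:
            lines = fh.read().splitlines()
    else:
        lines = path_or_buf.read().splitlines()
    labels = lines[0].split("\t")
    A = np.array([[float(v) for v in line.split("\t")] for line in lines[1:] if line])
    if A.shape != (len(labels), len(labels)):
        raise ValueError("similarity matrix is not square w.r.t. its header")
    return A, labels
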