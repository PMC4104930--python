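"""Task taxonomies: Newick I/O, branch-weight scaling, patristic distances,
distance-to-similarity conversion and UPGMA construction.

A task taxonomy is a rooted tree whose leaves correspond to learning tasks
(protein targets) and whose edge weights encode evolutionary or empirical
similarity.  Top-down multi-task training walks this tree; the graph-based
method consumes the derived pairwise similarity matrix ``s = 1 - d`` with
``d`` the normalized shortest-path (patristic) distance.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "TaxonomyNode",
    "TaskTaxonomy",
    "parse_newick",
    "write_newick",
    "scale_weights",
    "pairwise_distances",
    "distances_to_similarity",
    "upgma_from_correlation",
    "star_taxonomy",
]


@dataclass
class TaxonomyNode:
    """A node of a rooted task taxonomy.

    ``edge_weight`` is the weight of the edge to the parent (None at the
    root).  Leaves carry the task labels.
    """

    label: str
    edge_weight: float | None = None
    parent: "TaxonomyNode" = field(default=None, repr=False)
    children: list = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def is_root(self) -> bool:
        return self.parent is None


class TaskTaxonomy:
    """Rooted tree with non-negative edge weights; leaves map 1:1 to tasks."""

    def __init__(self, root: TaxonomyNode):
        self.root = root
        labels = [n.label for n in self.leaves()]
        if len(set(labels)) != len(labels):
            raise ValueError("leaf labels must be unique")
        for node in self.nodes():
            if not node.is_root and node.edge_weight is not None and node.edge_weight < 0:
                raise ValueError("edge weights must be non-negative")

    def nodes(self):
        """Breadth-first node iteration (root first)."""
        queue = [self.root]
        while queue:
            node = queue.pop(0)
            yield node
            queue.extend(node.children)

    def leaves(self):
        return [n for n in self.nodes() if n.is_leaf]

    @property
    def leaf_labels(self):
        return [n.label for n in self.leaves()]

    def find(self, label: str) -> TaxonomyNode:
        for n in self.nodes():
            if n.label == label:
                return n
        raise KeyError(label)


def _from_dendropy(tree: dendropy.Tree, default_length: float | None) -> TaskTaxonomy:
    def build(dnode, parent):
        label = dnode.taxon.label if dnode.taxon is not None else (dnode.label or "")
        weight = dnode.edge.length
        if parent is not None and weight is None:
            if default_length is None:
                raise ValueError(
                    f"missing branch length at node {label!r} (strict mode)"
                )
            weight = default_length
        node = TaxonomyNode(label=label, edge_weight=weight, parent=parent)
        if parent is not None:
            parent.children.append(node)
        for child in dnode.child_nodes():
            build(child, node)
        return node

    root = build(tree.seed_node, None)
    # name anonymous internal nodes deterministically
    counter = [0]
    tax = TaskTaxonomy(root)
    for node in tax.nodes():
        if not node.label:
            node.label = "node%d" % counter[0] if not node.is_root else "root"
            counter[0] += 1
    return tax


def parse_newick(text: str, lenient: bool = False) -> TaskTaxonomy:
    """Parse a Newick string with branch lengths into a task taxonomy.

    In strict mode (default) a missing branch length is an error; with
    ``lenient=True`` missing lengths default to 1.0 (the convention used for
    attaching taxonomically distant tasks directly to the root).
    """
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=False
        )
    except Exception as exc:  # dendropy raises several error types
        raise ValueError(f"malformed Newick input: {exc}") from exc
    return _from_dendropy(tree, default_length=1.0 if lenient else None)


def write_newick(taxonomy: TaskTaxonomy) -> str:
    """Serialize a taxonomy to Newick; round-trips topology and weights."""

    def fmt(node: TaxonomyNode) -> str:
        if node.is_leaf:
            core = node.label
        else:
            core = "(" + ",".join(fmt(c) for c in node.children) + ")"
            if not node.label.startswith(("node", "root")):
                core += node.label
        if not node.is_root and node.edge_weight is not None:
            core += ":" + repr(float(node.edge_weight))
        return core

    return fmt(taxonomy.root) + ";"


def scale_weights(taxonomy: TaskTaxonomy) -> TaskTaxonomy:
    """Scale edge weights into [0, 1] by dividing by the maximum weight.

    A no-op when all weights already lie in [0, 1] (no rescaling of trees
    whose branch lengths are already similarity-calibrated).
    """
    weights = [n.edge_weight for n in taxonomy.nodes() if not n.is_root]
    if not weights or max(weights) <= 0:
        raise ValueError("taxonomy has no positive edge weight to scale")
    wmax = max(weights)
    if wmax <= 1.0:
        return taxonomy
    for n in taxonomy.nodes():
        if not n.is_root:
            n.edge_weight = n.edge_weight / wmax
    return taxonomy


def pairwise_distances(taxonomy: TaskTaxonomy):
    """Leaf-to-leaf shortest-path (patristic) distance matrix.

    Returns ``(D, labels)`` with ``D`` symmetric and zero-diagonal; the
    distance of two taxa is the sum of edge weights on the unique path.
    """
    leaves = taxonomy.leaves()
    labels = [n.label for n in leaves]

    def path_to_root(node):
        path = {}
        dist = 0.0
        while node.parent is not None:
            dist += node.edge_weight
            node = node.parent
            path[id(node)] = dist
        return path

    up = [path_to_root(n) for n in leaves]
    T = len(leaves)
    D = np.zeros((T, T))
    for a in range(T):
        for b in range(a + 1, T):
            # lowest common ancestor by walking b's ancestry against a's
            node = leaves[b]
            dist_b = 0.0
            while id(node) not in up[a] and node.parent is not None:
                dist_b += node.edge_weight
                node = node.parent
            D[a, b] = D[b, a] = up[a].get(id(node), 0.0) + dist_b
    return D, labels


def distances_to_similarity(D, atypical: list | None = None, labels=None):
    """Convert a distance matrix to task similarities ``s = 1 - d``.

    Distances are first normalized by the maximum off-diagonal entry (so the
    most distant pair gets similarity 0); the diagonal is set to 1.  Tasks
    named in ``atypical`` (by label, requires ``labels``, or by 0-based
    index) get similarity 0 to every other task regardless of distance.
    """
    D = np.asarray(D, dtype=np.float64)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    off = D[~np.eye(D.shape[0], dtype=bool)]
    dmax = off.max() if off.size else 0.0
    if dmax <= 0:
        raise ValueError("all distances are zero; similarity undefined")
    A = 1.0 - D / dmax
    np.fill_diagonal(A, 1.0)
    if atypical:
        for item in atypical:
            if isinstance(item, str):
                if labels is None:
                    raise ValueError("labels required to resolve atypical names")
                i = labels.index(item)
            else:
                i = int(item)
            A[i, :] = 0.0
            A[:, i] = 0.0
            A[i, i] = 1.0
    A = np.clip(A, 0.0, 1.0)
    return A


def upgma_from_correlation(corr, labels=None) -> TaskTaxonomy:
    """Build an ultrametric taxonomy by UPGMA on distance ``1 - corr``.

    Average-linkage agglomeration (scipy) on the correlation-derived distance;
    edge weights are the differences of merge heights, so all root-to-leaf
    path lengths are equal.
    """
    import scipy.cluster.hierarchy as sch
    import scipy.spatial.distance as ssd

    corr = np.asarray(corr, dtype=np.float64)
    T = corr.shape[0]
    if T < 2:
        raise ValueError("need at least two tasks for UPGMA")
    if not np.allclose(corr, corr.T) or np.any(np.abs(corr) > 1 + 1e-12):
        raise ValueError("correlation matrix must be symmetric with |r| <= 1")
    if labels is None:
        labels = [f"T{i + 1}" for i in range(T)]
    Dm = 1.0 - corr
    np.fill_diagonal(Dm, 0.0)
    Z = sch.linkage(ssd.squareform(Dm, checks=False), method="average")

    nodes = {}
    heights = {}
    for i in range(T):
        nodes[i] = TaxonomyNode(label=labels[i])
        heights[i] = 0.0
    for k, (a, b, h, _cnt) in enumerate(Z):
        a, b = int(a), int(b)
        parent = TaxonomyNode(label=f"node{k}")
        for child_id in (a, b):
            child = nodes[child_id]
            child.parent = parent
            # ultrametric: branch length is half the merge distance minus
            # the child's own height
            child.edge_weight = h / 2.0 - heights[child_id]
            parent.children.append(child)
        nodes[T + k] = parent
        heights[T + k] = h / 2.0
    root = nodes[T + len(Z) - 1]
    root.label = "root"
    return TaskTaxonomy(root)


def star_taxonomy(edge_weights, labels=None) -> TaskTaxonomy:
    """A root directly connected to every task — the flat taxonomy used by
    the simulation benchmark (edge weight = similarity of task to the mean
    model)."""
    edge_weights = np.asarray(edge_weights, dtype=np.float64)
    T = len(edge_weights)
    if labels is None:
        labels = [f"T{i + 1}" for i in range(T)]
    root = TaxonomyNode(label="root")
    for t in range(T):
        child = TaxonomyNode(label=labels[t], edge_weight=float(edge_weights[t]), parent=root)
        root.children.append(child)
    return TaskTaxonomy(root)
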