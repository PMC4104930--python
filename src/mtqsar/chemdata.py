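"""Chemistry-facing utilities: bioactivity-record curation, fingerprint
folding and filtering, Tanimoto distances and chemotype clustering.

Curation applies the standard cascade for assembling multi-target IC50 data
from heterogeneous assay databases: assay-to-target confidence, binding-assay
type, wild-type targets only, exactly determined values, conversion to pIC50,
an activity floor, reconciliation of repeated measurements, a drug-likeness
physicochemical window, organic structures only, and a minimum per-target
compound count for cross-validation viability.  Every exclusion is logged
with the rule that fired.

Fingerprints are hashed circular substructure features; the raw feature ids
of an external generator are folded into a ``2**bits`` space by modulo.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ActivityRecord",
    "CurationRules",
    "CuratedDataset",
    "curate",
    "fold_fingerprint",
    "filter_frequent_features",
    "tanimoto_distance_matrix",
    "kmedians",
    "choose_k",
]


@dataclass
class ActivityRecord:
    """One measured activity: compound vs target with provenance flags."""

    compound_id: str
    target_id: str
    value: float
    value_type: str = "pIC50"  # or "IC50" in molar units
    relation: str = "="        # "=", "<" or ">"
    confidence_score: int = 9
    assay_type: str = "B"
    target_is_mutant: bool = False
    mw: float | None = None
    alogp: float | None = None
    hba: int | None = None
    hbd: int | None = None
    rotatable_bonds: int | None = None
    organic_only: bool = True


@dataclass
class CurationRules:
    """Thresholds of the curation cascade; defaults follow common practice
    for kinase IC50 compilations."""

    min_confidence: int = 8
    assay_type: str = "B"
    wild_type_only: bool = True
    exact_relation_only: bool = True
    min_pic50: float = 5.0
    max_value_range: float = 1.0   # log units across repeated measurements
    mw_min: float = 90.0           # exclusive
    mw_max: float = 900.0          # inclusive
    alogp_min: float = -7.0
    alogp_max: float = 9.0
    max_hba: int = 18
    max_hbd: int = 18
    max_rotatable_bonds: int = 18
    organic_only: bool = True
    min_compounds: int = 15


@dataclass
class CuratedDataset:
    """Per-target compound -> pIC50 maps plus the exclusion log.

    Every retained value satisfies the activity floor and every retained
    target the minimum compound count.
    """

    activities: dict            # target_id -> {compound_id: pIC50}
    exclusions: list = field(default_factory=list)  # (rule, target, compound, detail)

    @property
    def targets(self):
        return sorted(self.activities)

    def n_compounds(self, target_id: str) -> int:
        return len(self.activities[target_id])


def to_pic50(record: ActivityRecord) -> float:
    """Convert a record's value to pIC50 (``-log10`` of molar IC50)."""
    if record.value_type == "pIC50":
        return float(record.value)
    if record.value_type == "IC50":
        if record.value <= 0:
            raise ValueError("IC50 must be positive to convert to pIC50")
        return -math.log10(record.value)
    raise ValueError(f"unknown value type {record.value_type!r}")


def _record_filter(rec: ActivityRecord, rules: CurationRules) -> str | None:
    """Return the id of the first record-level rule that rejects, else None.

    The record-level rules commute: each looks at one record in isolation,
    so any application order retains the same set.
    """
    if rec.confidence_score < rules.min_confidence:
        return "confidence"
    if rules.assay_type and rec.assay_type != rules.assay_type:
        return "assay_type"
    if rules.wild_type_only and rec.target_is_mutant:
        return "mutant"
    if rules.exact_relation_only and rec.relation != "=":
        return "relation"
    if to_pic50(rec) < rules.min_pic50:
        return "activity_floor"
    if rec.mw is not None and not (rules.mw_min < rec.mw <= rules.mw_max):
        return "mw"
    if rec.alogp is not None and not (rules.alogp_min <= rec.alogp <= rules.alogp_max):
        return "alogp"
    if rec.hba is not None and rec.hba > rules.max_hba:
        return "hba"
    if rec.hbd is not None and rec.hbd > rules.max_hbd:
        return "hbd"
    if rec.rotatable_bonds is not None and rec.rotatable_bonds > rules.max_rotatable_bonds:
        return "rotatable_bonds"
    if rules.organic_only and not rec.organic_only:
        return "non_organic"
    return None


def curate(records, rules: CurationRules | None = None,
           id_merge: dict | None = None) -> CuratedDataset:
    """Run the full curation cascade over activity records.

    Record-level filters run first (order-insensitive); repeated
    measurements of a compound on one target are then reconciled — rejected
    if they span more than ``max_value_range`` log units, otherwise replaced
    by their geometric mean (of the pIC50 values themselves); finally,
    targets with fewer than ``min_compounds`` retained compounds are dropped.
    ``id_merge`` maps duplicate-structure compound ids onto a canonical id
    before reconciliation.
    """
    rules = rules or CurationRules()
    exclusions = []
    per_pair: dict = {}
    for rec in records:
        rule = _record_filter(rec, rules)
        if rule is not None:
            exclusions.append((rule, rec.target_id, rec.compound_id, ""))
            continue
        cid = rec.compound_id
        if id_merge:
            cid = id_merge.get(cid, cid)
        per_pair.setdefault((rec.target_id, cid), []).append(to_pic50(rec))

    activities: dict = {}
    for (target, compound), values in per_pair.items():
        if max(values) - min(values) > rules.max_value_range:
            exclusions.append(
                ("value_range", target, compound,
                 f"range {max(values) - min(values):.3g} log units")
            )
            continue
        gm = float(np.exp(np.mean(np.log(values))))
        activities.setdefault(target, {})[compound] = gm

    for target in sorted(activities):
        if len(activities[target]) < rules.min_compounds:
            for compound in activities[target]:
                exclusions.append(("min_compounds", target, compound, ""))
            del activities[target]
    return CuratedDataset(activities, exclusions)


def fold_fingerprint(raw_feature_ids, bits: int = 20):
    """Fold raw hashed feature ids into a ``2**bits`` space by modulo.

    Bins accumulate and then binarize (presence semantics).  Returns
    ``(sorted folded ids, collision_fraction)`` where the collision fraction
    is the share of distinct raw ids lost to shared bins.
    """
    if bits > 32 or bits < 1:
        raise ValueError("bits must be in 1..32")
    raw = {int(i) for i in raw_feature_ids}
    if any(i < 0 for i in raw):
        raise ValueError("raw feature ids must be unsigned")
    space = 1 << bits
    folded = {i % space for i in raw}
    collisions = (len(raw) - len(folded)) / len(raw) if raw else 0.0
    return np.array(sorted(folded), dtype=np.int64), collisions


def filter_frequent_features(X, max_fraction: float = 0.9):
    """Drop features present in strictly more than ``max_fraction`` of rows.

    Returns ``(X_reduced, kept_columns)``; apply ``kept_columns`` to held-out
    data so train and test agree on the feature space.
    """
    import scipy.sparse as sp

    if not 0 < max_fraction <= 1:
        raise ValueError("max_fraction must be in (0, 1]")
    Xc = sp.csc_matrix(X)
    n = Xc.shape[0]
    present = np.diff(Xc.indptr)  # nnz per column == presence count (binary)
    kept = np.flatnonzero(present <= max_fraction * n)
    return sp.csr_matrix(Xc[:, kept]), kept


def tanimoto_distance_matrix(fps) -> np.ndarray:
    """Pairwise Tanimoto distances ``1 - |A & B| / |A | B|`` on binary
    fingerprints given as iterables of on-bit ids."""
    sets = [frozenset(int(b) for b in fp) for fp in fps]
    if any(not s for s in sets):
        raise ValueError("Tanimoto undefined for an all-zero fingerprint")
    n = len(sets)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            inter = len(sets[i] & sets[j])
            union = len(sets[i] | sets[j])
            D[i, j] = D[j, i] = 1.0 - inter / union
    return D


def _kmedians_once(D, k, rng):
    n = D.shape[0]
    medoids = rng.choice(n, size=k, replace=False)
    labels = np.argmin(D[:, medoids], axis=1)
    for _ in range(100):
        new_medoids = medoids.copy()
        for c in range(k):
            members = np.flatnonzero(labels == c)
            if members.size == 0:
                continue
            costs = D[np.ix_(members, members)].sum(axis=0)
            new_medoids[c] = members[int(np.argmin(costs))]
        new_labels = np.argmin(D[:, new_medoids], axis=1)
        if np.array_equal(new_medoids, medoids) and np.array_equal(new_labels, labels):
            break
        medoids, labels = new_medoids, new_labels
    cost = float(D[np.arange(n), medoids[labels]].sum())
    return labels, medoids, cost


def kmedians(D, k: int, seed: int = 0, n_restarts: int = 10):
    """k-medians (medoid) clustering on a precomputed distance matrix.

    Random distinct medoid initialization from the seed; ``n_restarts``
    restarts, best assignment cost kept.  Returns ``(labels, medoids)``.
    """
    D = np.asarray(D, dtype=np.float64)
    n = D.shape[0]
    if k < 1 or k > n:
        raise ValueError("k must be in 1..n")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_restarts):
        labels, medoids, cost = _kmedians_once(D, k, rng)
        if best is None or cost < best[2]:
            best = (labels, medoids, cost)
    return best[0], best[1]


def within_cluster_ss(D, labels, medoids) -> float:
    """Within-cluster sum of squared distances to the medoids."""
    return float((D[np.arange(len(labels)), medoids[labels]] ** 2).sum())


def choose_k(D, k_range, seed: int = 0) -> int:
    """Elbow choice of ``k``: the largest second difference of the
    within-cluster sum of squares over ``k_range``."""
    k_range = sorted(k_range)
    if len(k_range) < 3:
        raise ValueError("need at least three candidate k values for an elbow")
    wss = []
    for k in k_range:
        labels, medoids = kmedians(D, k, seed=seed)
        wss.append(within_cluster_ss(D, labels, medoids))
    second_diff = [wss[i - 1] - 2 * wss[i] + wss[i + 1] for i in range(1, len(wss) - 1)]
    return k_range[1 + int(np.argmax(second_diff))]
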