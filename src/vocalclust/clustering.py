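"""Hierarchical clustering of vocal elements with automated tree pruning.

Pipeline stage: a dissimilarity matrix over vocal elements is clustered by
average-linkage (UPGMA); the dendrogram is pruned by an adaptive, gap-based
cut that derives the number of clusters from tree shape (no user-supplied
count); each cluster is summarized by its "eigensyllable"/"eigencall" — the
first principal component of the members' similarity profiles — and small
clusters are then merged iteratively: at Pearson thresholds rho = 0.99 down
to 0, any pair of clusters whose eigen-profiles correlate at or above rho is
merged (highest-correlated pair first, eigens recomputed after each merge).
Cluster counts that stay stable over multiple thresholds ("plateaus") are
candidate repertoire sizes; per-plateau cohesion (mean intracluster
similarity, IGS, or explained variance) supports the final choice.

The tree cut is an in-package adaptive algorithm in the spirit of dynamic
hybrid dendrogram pruning: descending from the root, a branch becomes a
cluster at the first node whose merge gap to its parent — relative to the
parent's height — exceeds a sensitivity-dependent minimum. Higher
``deep_split`` demands larger gaps, descends deeper, and never yields fewer
clusters. Branches merging at height zero (exact duplicates) are never
separated. Clusters below ``min_cluster_size`` are absorbed into the
nearest cluster by average distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import squareform

__all__ = [
    "CANONICAL_CALL_TYPES",
    "EXTENDED_CALL_TYPES",
    "CutParams",
    "ClusterSet",
    "MergeTrace",
    "hcluster",
    "cut_tree",
    "eigen_summary",
    "iterative_merge",
    "select_plateau",
    "qc_and_classify",
    "apply_relabeling",
]

#: the ten canonical mouse-pup retrieval-call categories
CANONICAL_CALL_TYPES = [
    "complex",
    "two_syllable",
    "upward",
    "downward",
    "chevron",
    "short",
    "composite",
    "frequency_steps",
    "flat",
    "harmonics",
]
#: extended vocabulary: multi-call clips and a catch-all
EXTENDED_CALL_TYPES = CANONICAL_CALL_TYPES + ["double", "triple", "miscellaneous"]

#: minimum relative merge gap per deep_split sensitivity level 0..4
_GAP_BY_DEEPSPLIT = (0.15, 0.35, 0.55, 0.75, 0.95)


@dataclass
class CutParams:
    """Tree-cut tuning: minimum cluster size and split sensitivity (0-4)."""

    min_cluster_size: int = 1
    deep_split: int = 4

    def __post_init__(self) -> None:
        if self.min_cluster_size < 1:
            raise ValueError("min_cluster_size must be >= 1")
        if not 0 <= self.deep_split <= 4:
            raise ValueError("deep_split must be in 0..4")


def hcluster(d: np.ndarray) -> np.ndarray:
    """Average-linkage (UPGMA) linkage matrix from a dissimilarity matrix."""
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("dissimilarity matrix must be square")
    if not np.allclose(d, d.T, atol=1e-8):
        raise ValueError("dissimilarity matrix must be symmetric")
    condensed = squareform(d, checks=False)
    return linkage(condensed, method="average")


def _leaf_ids(node) -> list[int]:
    return node.pre_order(lambda leaf: leaf.id)


def cut_tree(z: np.ndarray, d: np.ndarray, p: CutParams | None = None) -> np.ndarray:
    """Prune a dendrogram into clusters; returns integer labels per leaf.

    A branch becomes a cluster at the first node (descending from the root)
    whose relative merge gap (parent height - node height) / parent height
    reaches the ``deep_split``-dependent minimum. Leaves trivially qualify,
    so the recursion always terminates in a partition. Clusters smaller than
    ``min_cluster_size`` are merged into the cluster at minimal average
    distance.
    """
    p = p or CutParams()
    g_min = _GAP_BY_DEEPSPLIT[p.deep_split]
    root = to_tree(z)
    m = root.get_count()
    labels = np.zeros(m, dtype=int)
    if root.dist <= 0:
        return labels  # all merges at height zero: a single tight cluster
    clusters: list[list[int]] = []

    def descend(node) -> None:
        for child in (node.left, node.right):
            gap = (node.dist - child.dist) / node.dist
            if gap >= g_min:
                clusters.append(_leaf_ids(child))
            else:
                descend(child)

    descend(root)
    for cid, members in enumerate(clusters):
        labels[members] = cid
    labels = _enforce_min_size(labels, d, p.min_cluster_size)
    return _relabel_by_first_member(labels)


def _enforce_min_size(labels: np.ndarray, d: np.ndarray, min_size: int) -> np.ndarray:
    labels = labels.copy()
    while True:
        ids, counts = np.unique(labels, return_counts=True)
        small = ids[counts < min_size]
        if len(small) == 0 or len(ids) == 1:
            return labels
        # absorb the smallest offender into its nearest cluster
        cid = small[np.argmin(counts[np.isin(ids, small)])]
        members = labels == cid
        best, best_dist = None, np.inf
        for other in ids:
            if other == cid:
                continue
            avg = d[np.ix_(members, labels == other)].mean()
            if avg < best_dist:
                best, best_dist = other, avg
        labels[members] = best


def _relabel_by_first_member(labels: np.ndarray) -> np.ndarray:
    order: dict[int, int] = {}
    out = np.empty_like(labels)
    for i, lab in enumerate(labels):
        if lab not in order:
            order[lab] = len(order)
        out[i] = order[lab]
    return out


def _eigen_corr_matrix(eigens: np.ndarray) -> np.ndarray:
    """Pairwise Pearson correlations between eigen-profiles (upper triangle;
    the rest is -inf so argmax lands on a mergeable pair). Flat profiles
    correlate 1 with each other and 0 with modulated ones."""
    k = len(eigens)
    good = eigens.std(axis=1) > 1e-12
    corr = np.zeros((k, k))
    if good.sum() >= 2:
        corr[np.ix_(good, good)] = np.corrcoef(eigens[good])
    bad = ~good
    if bad.any():
        corr[np.ix_(bad, bad)] = 1.0
    corr[np.tril_indices(k)] = -np.inf
    return corr


def _safe_corr(x: np.ndarray, y: np.ndarray, tol: float = 1e-12) -> float:
    sx, sy = x.std(), y.std()
    if sx < tol and sy < tol:
        return 1.0
    if sx < tol or sy < tol:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def eigen_summary(profiles: np.ndarray) -> tuple[np.ndarray, float, np.ndarray]:
    """Eigen-profile of a cluster from its members' similarity profiles.

    Each member profile (row) is standardized across elements, and the
    stack is decomposed by SVD. Returns the first principal direction over
    elements (the eigensyllable/eigencall), the fraction of variance it
    explains, and each member's Pearson correlation with it. A singleton or
    a cluster of identical members has explained variance 1 and member
    correlations 1.
    """
    x = np.atleast_2d(np.asarray(profiles, dtype=float))
    sd = x.std(axis=1, keepdims=True)
    mean = x.mean(axis=1, keepdims=True)
    z = np.where(sd > 1e-12, (x - mean) / np.where(sd > 1e-12, sd, 1.0), 0.0)
    if not np.any(np.abs(z) > 1e-12):
        # all profiles flat: no direction to estimate, perfectly cohesive
        return x.mean(axis=0), 1.0, np.ones(len(x))
    _, s, vt = np.linalg.svd(z, full_matrices=False)
    ev = float(s[0] ** 2 / np.sum(s**2))
    eigen = vt[0]
    corrs = np.array([_safe_corr(row, eigen) for row in x])
    if corrs.mean() < 0:  # orient the eigen-profile with its members
        eigen = -eigen
        corrs = -corrs
    return eigen, ev, corrs


@dataclass
class ClusterSet:
    """Cluster labels plus per-cluster eigen summaries.

    ``profiles`` holds one similarity profile per element (rows aligned with
    ``element_ids``); for a first-session clustering these are the rows of
    the M x M similarity matrix, for novel-element clustering the rows of
    the M x N element-vs-representative score matrix.
    """

    element_ids: list[str]
    labels: np.ndarray
    profiles: np.ndarray
    eigenvectors: dict[int, np.ndarray] = field(default_factory=dict)
    explained_variance: dict[int, float] = field(default_factory=dict)
    member_corr: np.ndarray | None = None
    representatives: dict[int, list[str]] = field(default_factory=dict)
    igs: dict[int, float] = field(default_factory=dict)

    @classmethod
    def build(
        cls,
        element_ids: list[str],
        labels: np.ndarray,
        profiles: np.ndarray,
        sim_values: np.ndarray | None = None,
        backend_max: float = 1.0,
    ) -> "ClusterSet":
        labels = np.asarray(labels)
        cs = cls(list(element_ids), labels, np.asarray(profiles, dtype=float))
        cs.member_corr = np.zeros(len(labels))
        for cid in np.unique(labels):
            idx = np.flatnonzero(labels == cid)
            eigen, ev, corrs = eigen_summary(cs.profiles[idx])
            cs.eigenvectors[int(cid)] = eigen
            cs.explained_variance[int(cid)] = ev
            cs.member_corr[idx] = corrs
            ranked = idx[np.argsort(-corrs, kind="stable")]
            cs.representatives[int(cid)] = [element_ids[i] for i in ranked]
            if sim_values is not None:
                cs.igs[int(cid)] = _intracluster_similarity(
                    sim_values, idx, backend_max
                )
        return cs

    @property
    def cluster_ids(self) -> list[int]:
        return sorted(int(c) for c in np.unique(self.labels))

    @property
    def labels_dict(self) -> dict[str, int]:
        return {e: int(l) for e, l in zip(self.element_ids, self.labels)}

    def members(self, cid: int) -> list[str]:
        return [e for e, l in zip(self.element_ids, self.labels) if l == cid]

    def to_dataframe(self) -> pd.DataFrame:
        reps = {c: ids[0] for c, ids in self.representatives.items()}
        return pd.DataFrame(
            {
                "element_id": self.element_ids,
                "cluster_id": self.labels,
                "member_eigen_corr": self.member_corr,
                "is_representative": [
                    reps.get(int(l)) == e
                    for e, l in zip(self.element_ids, self.labels)
                ],
            }
        )


def _intracluster_similarity(
    sim: np.ndarray, idx: np.ndarray, backend_max: float
) -> float:
    """Mean pairwise similarity within a cluster (IGS); singletons score max."""
    if len(idx) < 2:
        return float(backend_max)
    block = sim[np.ix_(idx, idx)]
    off = block[~np.eye(len(idx), dtype=bool)]
    return float(off.mean())


@dataclass
class MergeTrace:
    """Record of the iterative rho sweep (0.99 down to 0)."""

    rho_grid: np.ndarray
    n_clusters: np.ndarray
    cohesion: np.ndarray  # mean IGS (or mean explained variance) per rho
    cohesion_metric: str
    labels_per_rho: list[np.ndarray]
    plateaus: list[dict] = field(default_factory=list)

    def plateau_summary(self) -> pd.DataFrame:
        return pd.DataFrame(self.plateaus)


def iterative_merge(
    labels: np.ndarray,
    profiles: np.ndarray,
    sim_values: np.ndarray | None = None,
    backend_max: float = 1.0,
    rho_grid: np.ndarray | None = None,
    cohesion_metric: str = "igs",
) -> MergeTrace:
    """Merge clusters over a descending Pearson-rho grid.

    At each rho (0.99, 0.98, ..., 0.00) the pair of clusters whose
    eigen-profiles correlate highest is merged whenever that correlation is
    at or above rho, eigens are recomputed, and the process repeats until no
    pair qualifies. Per rho, the cluster count and mean cohesion (IGS for a
    within-session similarity matrix, explained variance otherwise) are
    recorded; cluster counts stable over >= 2 consecutive thresholds are
    reported as plateaus.
    """
    if cohesion_metric not in ("igs", "explained_variance"):
        raise ValueError(f"unknown cohesion metric {cohesion_metric!r}")
    if cohesion_metric == "igs" and sim_values is None:
        raise ValueError("IGS cohesion requires the within-session matrix")
    if rho_grid is None:
        rho_grid = np.round(np.arange(99, -1, -1) / 100.0, 2)
    profiles = np.asarray(profiles, dtype=float)
    current = {
        int(cid): np.flatnonzero(labels == cid).tolist()
        for cid in np.unique(labels)
    }
    eigen_cache: dict[tuple, tuple[np.ndarray, float]] = {}

    def cluster_eigen(members: list[int]) -> tuple[np.ndarray, float]:
        key = tuple(members)
        if key not in eigen_cache:
            eigen, ev, _ = eigen_summary(profiles[members])
            eigen_cache[key] = (eigen, ev)
        return eigen_cache[key]

    n_per_rho, coh_per_rho, labels_per_rho = [], [], []
    next_id = max(current) + 1
    max_corr: float | None = None  # highest eigen correlation left unmerged
    cached: tuple[float, np.ndarray] | None = None
    for rho in rho_grid:
        if max_corr is None or max_corr >= rho - 1e-12:
            while len(current) > 1:
                cids = sorted(current)
                eigens = np.vstack([cluster_eigen(current[c])[0] for c in cids])
                corr = _eigen_corr_matrix(eigens)
                i, j = np.unravel_index(np.argmax(corr), corr.shape)
                max_corr = float(corr[i, j])
                if max_corr < rho - 1e-12:
                    break
                merged = sorted(current.pop(cids[i]) + current.pop(cids[j]))
                current[next_id] = merged
                next_id += 1
            if len(current) == 1:
                max_corr = -np.inf
            if cohesion_metric == "igs":
                coh = float(
                    np.mean(
                        [
                            _intracluster_similarity(
                                sim_values, np.array(m), backend_max
                            )
                            for m in current.values()
                        ]
                    )
                )
            else:
                coh = float(
                    np.mean([cluster_eigen(m)[1] for m in current.values()])
                )
            snapshot = np.empty(len(labels), dtype=int)
            for cid, members in current.items():
                snapshot[members] = cid
            cached = (coh, _relabel_by_first_member(snapshot))
        n_per_rho.append(len(current))
        coh_per_rho.append(cached[0])
        labels_per_rho.append(cached[1])

    trace = MergeTrace(
        rho_grid=np.asarray(rho_grid),
        n_clusters=np.asarray(n_per_rho),
        cohesion=np.asarray(coh_per_rho),
        cohesion_metric=cohesion_metric,
        labels_per_rho=labels_per_rho,
    )
    trace.plateaus = _find_plateaus(trace)
    return trace


def _find_plateaus(trace: MergeTrace) -> list[dict]:
    plateaus = []
    start = 0
    n = trace.n_clusters
    for i in range(1, len(n) + 1):
        if i == len(n) or n[i] != n[start]:
            if i - start >= 2:
                plateaus.append(
                    {
                        "n_clusters": int(n[start]),
                        "rho_high": float(trace.rho_grid[start]),
                        "rho_low": float(trace.rho_grid[i - 1]),
                        "span": int(i - start),
                        "cohesion": float(trace.cohesion[start:i].mean()),
                        "first_index": start,
                    }
                )
            start = i
    return plateaus


def select_plateau(
    trace: MergeTrace,
    policy: str = "largest_span",
    expected_n: int | None = None,
) -> tuple[np.ndarray, dict]:
    """Pick a plateau from the merge trace and return its labels.

    ``largest_span`` (default) selects the cluster count stable over the
    most thresholds (ties: more clusters, i.e. the more conservative
    merge); ``expected_n`` selects the plateau at a user-expected repertoire
    size.
    """
    if not trace.plateaus:
        raise ValueError("merge trace contains no plateau (no stable cluster count)")
    if expected_n is not None:
        matches = [p for p in trace.plateaus if p["n_clusters"] == expected_n]
        if not matches:
            raise ValueError(f"no plateau with {expected_n} clusters")
        chosen = max(matches, key=lambda p: p["span"])
    elif policy == "largest_span":
        chosen = max(trace.plateaus, key=lambda p: (p["span"], p["n_clusters"]))
    else:
        raise ValueError(f"unknown plateau policy {policy!r}")
    return trace.labels_per_rho[chosen["first_index"]], chosen


def qc_and_classify(cs: ClusterSet, cohesion_threshold: float = 0.8) -> pd.DataFrame:
    """Emit the manual-classification task list after cluster quality control.

    Clusters whose mean member-to-eigen correlation is at or above the
    threshold are represented by their single best-correlated member (one
    row labels the whole cluster); clusters below it are dissolved and every
    member is listed for individual classification. The category vocabulary
    for the human step is :data:`EXTENDED_CALL_TYPES`.
    """
    rows = []
    for cid in cs.cluster_ids:
        idx = np.flatnonzero(cs.labels == cid)
        mean_corr = float(cs.member_corr[idx].mean())
        if mean_corr >= cohesion_threshold:
            rows.append(
                {
                    "cluster_id": cid,
                    "element_id": cs.representatives[cid][0],
                    "mode": "representative",
                    "n_covered": len(idx),
                    "mean_eigen_corr": mean_corr,
                }
            )
        else:
            for i in idx:
                rows.append(
                    {
                        "cluster_id": cid,
                        "element_id": cs.element_ids[i],
                        "mode": "manual",
                        "n_covered": 1,
                        "mean_eigen_corr": mean_corr,
                    }
                )
    return pd.DataFrame(rows)


def apply_relabeling(cs: ClusterSet, mapping: dict[str, int] | pd.DataFrame) -> ClusterSet:
    """Manual error correction: override cluster ids for named elements."""
    if isinstance(mapping, pd.DataFrame):
        mapping = dict(zip(mapping["element_id"].astype(str), mapping["cluster_id"]))
    labels = cs.labels.copy()
    for eid, cid in mapping.items():
        try:
            labels[cs.element_ids.index(str(eid))] = int(cid)
        except ValueError:
            raise KeyError(f"relabeling refers to unknown element {eid!r}") from None
    return ClusterSet.build(cs.element_ids, labels, cs.profiles)
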