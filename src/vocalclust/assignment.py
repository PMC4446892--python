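"""Assignment of a later session's elements to established clusters.

Each element from session B is scored against the representatives of every
session-A cluster (the top fraction of members by eigen correlation, 10% by
default). Clusters whose representatives yield a mean score at or above a
user-set similarity floor are candidates:

* no candidate — the element is *novel*;
* one candidate — it is *assigned*;
* several — a one-way ANOVA over the per-representative score groups,
  followed by Bonferroni-corrected pairwise comparisons of the top-mean
  cluster against each other candidate, decides between *assigned* (top
  cluster significantly above all others) and a *tie* queue for manual or
  scripted resolution.

Novel elements are then clustered among themselves using their score
profiles against the established representatives, so new types appearing in
session B get fresh cluster ids.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .clustering import ClusterSet, CutParams, cut_tree, hcluster, iterative_merge, select_plateau
from .segmentation import VocalElement
from .signal_io import PitchContour
from .similarity import (
    FeatureTrajectory,
    feature_trajectory,
    pitch_contour,
    score_pair_finch,
    score_pair_usv,
)

__all__ = [
    "AssignmentParams",
    "AssignmentResult",
    "select_representatives",
    "score_against_representatives",
    "assign_elements",
    "resolve_ties",
    "cluster_novel",
]


@dataclass
class AssignmentParams:
    """Assignment gates: score floor, representative fraction, alpha."""

    gs_floor: float = 60.0
    rep_fraction: float = 0.10
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.rep_fraction <= 1:
            raise ValueError("rep_fraction must be in (0, 1]")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class AssignmentResult:
    """Per-element outcomes plus the candidate table and novel clustering."""

    table: pd.DataFrame  # element_id, outcome, cluster_id, best_mean, p values
    candidate_means: pd.DataFrame  # element x cluster mean scores
    novel_clusters: ClusterSet | None = None

    @property
    def outcomes(self) -> dict[str, str]:
        return dict(zip(self.table["element_id"], self.table["outcome"]))

    def counts(self) -> dict[str, int]:
        c = self.table["outcome"].value_counts().to_dict()
        return {k: int(c.get(k, 0)) for k in ("assigned", "tie", "novel")}


def select_representatives(
    cs: ClusterSet, rep_fraction: float = 0.10
) -> dict[int, list[str]]:
    """Top ``ceil(fraction * size)`` members per cluster by eigen correlation
    (at least one) — the members carrying most of the cluster's variance."""
    if not 0 < rep_fraction <= 1:
        raise ValueError("rep_fraction must be in (0, 1]")
    out = {}
    for cid in cs.cluster_ids:
        ranked = cs.representatives[cid]
        n = max(1, math.ceil(rep_fraction * len(ranked)))
        out[cid] = ranked[:n]
    return out


def _representation(e, backend: str):
    if backend == "mouse_contour":
        if isinstance(e, PitchContour):
            return e
        w = e.audio if isinstance(e, VocalElement) else e
        return pitch_contour(w)
    if isinstance(e, FeatureTrajectory):
        return e
    return feature_trajectory(e)


def score_against_representatives(
    elements_b: list,
    rep_elements: dict[int, list],
    backend: str,
    element_ids: list[str] | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Score matrix of session-B elements against cluster representatives.

    Returns the B x (total representatives) score table and the mapping from
    representative column to its cluster id.
    """
    if element_ids is None:
        element_ids = [
            e.element_id if isinstance(e, VocalElement) else f"b{i:04d}"
            for i, e in enumerate(elements_b)
        ]
    reps_b = [_representation(e, backend) for e in elements_b]
    columns, rep_cluster, rep_reps = [], {}, []
    for cid, reps in rep_elements.items():
        for k, r in enumerate(reps):
            name = (
                r.element_id
                if isinstance(r, VocalElement)
                else f"c{cid}_rep{k}"
            )
            columns.append(name)
            rep_cluster[name] = int(cid)
            rep_reps.append(_representation(r, backend))
    if not columns:
        raise ValueError("no cluster representatives to score against")
    score = (
        (lambda a, b: score_pair_usv(a, b).score)
        if backend == "mouse_contour"
        else (lambda a, b: score_pair_finch(a, b).gs)
    )
    values = np.array([[score(b, r) for r in rep_reps] for b in reps_b])
    return pd.DataFrame(values, index=element_ids, columns=columns), rep_cluster


def _posthoc_pair(top: np.ndarray, other: np.ndarray) -> float:
    """Two-sample comparison p-value with a degenerate-variance rule: a
    single-score group is compared by a one-sample t-test of the other group
    against its value; two singletons cannot reach significance (p = 1)."""
    if len(top) >= 2 and len(other) >= 2:
        return float(sstats.ttest_ind(top, other, equal_var=False).pvalue)
    if len(top) >= 2:
        return float(sstats.ttest_1samp(top, other[0]).pvalue)
    if len(other) >= 2:
        return float(sstats.ttest_1samp(other, top[0]).pvalue)
    return 1.0


def assign_elements(
    scores: pd.DataFrame,
    rep_cluster: dict[str, int],
    p: AssignmentParams | None = None,
) -> AssignmentResult:
    """Gate, test, and label each session-B element.

    ``scores`` is the element x representative table from
    :func:`score_against_representatives`.
    """
    p = p or AssignmentParams()
    clusters = sorted(set(rep_cluster.values()))
    groups = {
        c: [col for col in scores.columns if rep_cluster[col] == c] for c in clusters
    }
    means = pd.DataFrame(
        {c: scores[cols].mean(axis=1) for c, cols in groups.items()}
    )
    rows = []
    for eid in scores.index:
        cand = [c for c in clusters if means.at[eid, c] >= p.gs_floor]
        record = {
            "element_id": eid,
            "outcome": "novel",
            "cluster_id": pd.NA,
            "best_mean": float(means.loc[eid].max()),
            "p_anova": np.nan,
            "p_posthoc_max": np.nan,
        }
        if len(cand) == 1:
            record.update(outcome="assigned", cluster_id=cand[0])
        elif len(cand) > 1:
            samples = {c: scores.loc[eid, groups[c]].to_numpy(float) for c in cand}
            top = max(cand, key=lambda c: samples[c].mean())
            sizes = [len(s) for s in samples.values()]
            if sum(sizes) > len(sizes) and max(sizes) >= 2:
                p_anova = float(sstats.f_oneway(*samples.values()).pvalue)
            else:
                p_anova = 1.0  # all singleton groups: no within-group variance
            record["p_anova"] = p_anova
            if p_anova < p.alpha:
                others = [c for c in cand if c != top]
                raw = [_posthoc_pair(samples[top], samples[c]) for c in others]
                corrected = [min(1.0, q * len(others)) for q in raw]
                record["p_posthoc_max"] = max(corrected)
                separated = all(q < p.alpha for q in corrected) and all(
                    samples[top].mean() > samples[c].mean() for c in others
                )
                record.update(
                    outcome="assigned" if separated else "tie",
                    cluster_id=top if separated else pd.NA,
                )
            else:
                record["outcome"] = "tie"
        rows.append(record)
    return AssignmentResult(table=pd.DataFrame(rows), candidate_means=means)


def resolve_ties(
    result: AssignmentResult,
    policy: str = "best_mean",
    decisions: pd.DataFrame | None = None,
) -> AssignmentResult:
    """Resolve the tie queue.

    ``best_mean`` assigns each tied element to its highest-mean candidate;
    ``unassigned`` pushes ties to the novel queue; ``interactive`` applies a
    decisions table (columns element_id, cluster_id) — elements without a
    decision row stay tied.
    """
    if policy not in ("best_mean", "unassigned", "interactive"):
        raise ValueError(f"unknown tie policy {policy!r}")
    table = result.table.copy()
    tied = table["outcome"] == "tie"
    if policy == "best_mean":
        for i in table.index[tied]:
            eid = table.at[i, "element_id"]
            table.at[i, "cluster_id"] = result.candidate_means.loc[eid].idxmax()
            table.at[i, "outcome"] = "assigned"
    elif policy == "unassigned":
        table.loc[tied, "outcome"] = "novel"
    else:
        if decisions is None:
            raise ValueError("interactive policy requires a decisions table")
        chosen = dict(
            zip(decisions["element_id"].astype(str), decisions["cluster_id"])
        )
        for i in table.index[tied]:
            eid = str(table.at[i, "element_id"])
            if eid in chosen:
                table.at[i, "cluster_id"] = int(chosen[eid])
                table.at[i, "outcome"] = "assigned"
    return AssignmentResult(
        table=table,
        candidate_means=result.candidate_means,
        novel_clusters=result.novel_clusters,
    )


def cluster_novel(
    novel_scores: pd.DataFrame,
    first_new_id: int = 0,
    cut: CutParams | None = None,
    plateau_policy: str = "largest_span",
) -> ClusterSet:
    """Cluster novel elements by their profiles against established
    representatives.

    ``novel_scores`` is the M x N score matrix (novel elements x session-A
    representatives). Rows are correlated pairwise, the correlations are
    subtracted from 1 to give a dissimilarity matrix, and the usual
    cluster/cut/merge machinery runs on it. Because no within-session scores
    exist, the cohesion metric tracked during merging is the explained
    variance of each cluster's eigen-profile. New ids start at
    ``first_new_id``.
    """
    if novel_scores.shape[1] == 0:
        raise ValueError("no established representatives: cannot profile novel elements")
    ids = [str(i) for i in novel_scores.index]
    profiles = novel_scores.to_numpy(float)
    m = len(ids)
    if m == 0:
        return ClusterSet.build([], np.array([], dtype=int), np.zeros((0, novel_scores.shape[1])))
    if m == 1:
        return ClusterSet.build(ids, np.array([first_new_id]), profiles)
    corr = np.array(
        [
            [1.0 if i == j else _row_corr(profiles[i], profiles[j]) for j in range(m)]
            for i in range(m)
        ]
    )
    d = 1.0 - corr
    np.fill_diagonal(d, 0.0)
    z = hcluster(d)
    labels = cut_tree(z, d, cut)
    trace = iterative_merge(
        labels, profiles, cohesion_metric="explained_variance"
    )
    if trace.plateaus:
        labels, _ = select_plateau(trace, policy=plateau_policy)
    else:
        labels = trace.labels_per_rho[-1]
    return ClusterSet.build(ids, labels + first_new_id, profiles)


def _row_corr(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = x.std(), y.std()
    if sx < 1e-12 and sy < 1e-12:
        return 1.0
    if sx < 1e-12 or sy < 1e-12:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])
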