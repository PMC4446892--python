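"""Dendrogram construction, adaptive tree cut, eigen summaries, merging, QC."""

import numpy as np
import pytest
from scipy.spatial.distance import squareform

from vocalclust.clustering import (
    ClusterSet,
    CutParams,
    apply_relabeling,
    cut_tree,
    eigen_summary,
    hcluster,
    iterative_merge,
    qc_and_classify,
    select_plateau,
)


def naive_upgma(d: np.ndarray) -> list[float]:
    """Brute-force O(M^3) UPGMA: returns sorted merge heights."""
    clusters = {i: [i] for i in range(len(d))}
    heights = []
    while len(clusters) > 1:
        best, pair = np.inf, None
        keys = sorted(clusters)
        for ai in range(len(keys)):
            for bi in range(ai + 1, len(keys)):
                a, b = keys[ai], keys[bi]
                avg = np.mean([d[i, j] for i in clusters[a] for j in clusters[b]])
                if avg < best:
                    best, pair = avg, (a, b)
        a, b = pair
        clusters[a] = clusters[a] + clusters.pop(b)
        heights.append(best)
    return sorted(heights)


def random_distance_matrix(m: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    d = squareform(rng.uniform(0.1, 2.0, m * (m - 1) // 2))
    return d


def blob_distances(sizes, separation, spread, seed=0):
    """Points in 1-D blobs; returns the distance matrix and true labels."""
    rng = np.random.default_rng(seed)
    pts, labels = [], []
    for k, n in enumerate(sizes):
        pts.extend(rng.normal(k * separation, spread, n))
        labels.extend([k] * n)
    pts = np.asarray(pts)
    return np.abs(pts[:, None] - pts[None, :]), np.asarray(labels)


class TestHcluster:
    def test_three_point_merge_heights(self):
        d = np.array([[0, 1, 10.0], [1, 0, 10], [10, 10, 0]])
        z = hcluster(d)
        assert z[0, 2] == pytest.approx(1.0)
        assert z[1, 2] == pytest.approx(10.0)

    def test_all_zero_distances_merge_at_zero(self):
        z = hcluster(np.zeros((5, 5)))
        assert np.allclose(z[:, 2], 0.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_merge_heights_match_bruteforce_oracle(self, seed):
        d = random_distance_matrix(12, seed)
        z = hcluster(d)
        assert np.allclose(sorted(z[:, 2]), naive_upgma(d), atol=1e-10)

    def test_asymmetric_matrix_rejected(self):
        d = np.array([[0, 1.0], [2.0, 0]])
        with pytest.raises(ValueError, match="symmetric"):
            hcluster(d)


class TestCutTree:
    def test_two_tight_blobs_recovered_exactly(self):
        d, truth = blob_distances([10, 10], separation=10.0, spread=0.5, seed=1)
        labels = cut_tree(hcluster(d), d, CutParams(deep_split=1))
        assert len(np.unique(labels)) == 2
        # the partition matches ground truth (up to label names)
        assert all(
            len(np.unique(labels[truth == k])) == 1 for k in np.unique(truth)
        )

    def test_far_singleton_gets_own_cluster(self):
        rng = np.random.default_rng(2)
        pts = np.r_[rng.normal(0, 0.5, 12), 50.0]
        d = np.abs(pts[:, None] - pts[None, :])
        labels = cut_tree(hcluster(d), d, CutParams(min_cluster_size=1, deep_split=1))
        assert (labels == labels[-1]).sum() == 1

    def test_deep_split_monotone_in_cluster_count(self):
        d = random_distance_matrix(20, 3)
        z = hcluster(d)
        counts = [
            len(np.unique(cut_tree(z, d, CutParams(deep_split=ds))))
            for ds in range(5)
        ]
        assert all(a <= b for a, b in zip(counts, counts[1:]))

    def test_exact_duplicates_never_separated(self):
        d, _ = blob_distances([8, 8], separation=8.0, spread=0.6, seed=4)
        # make elements 0 and 1 exact duplicates
        d[0, :] = d[1, :]
        d[:, 0] = d[:, 1]
        d[0, 1] = d[1, 0] = 0.0
        for ds in range(5):
            labels = cut_tree(hcluster(d), d, CutParams(deep_split=ds))
            assert labels[0] == labels[1]

    def test_min_cluster_size_enforced(self):
        d, _ = blob_distances([10, 10, 1], separation=10.0, spread=0.5, seed=5)
        labels = cut_tree(hcluster(d), d, CutParams(min_cluster_size=3, deep_split=1))
        _, counts = np.unique(labels, return_counts=True)
        assert counts.min() >= 3


class TestEigenSummary:
    def test_identical_members_fully_cohesive(self):
        profile = np.linspace(0, 1, 12)
        eigen, ev, corrs = eigen_summary(np.tile(profile, (5, 1)))
        assert ev == pytest.approx(1.0)
        assert np.allclose(corrs, 1.0)

    def test_singleton_explained_variance_one(self):
        _, ev, corrs = eigen_summary(np.random.default_rng(0).normal(size=(1, 10)))
        assert ev == pytest.approx(1.0)
        assert corrs[0] == pytest.approx(1.0)

    def test_explained_variance_matches_dense_svd_oracle(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(6, 15))
        _, ev, _ = eigen_summary(x)
        # independent oracle: eigenvalues of the Gram matrix of the
        # row-standardized profiles
        z = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, keepdims=True)
        eig = np.linalg.eigvalsh(z @ z.T)
        assert ev == pytest.approx(eig.max() / eig.sum(), abs=1e-10)

    def test_cohesive_cluster_has_high_member_correlations(self):
        rng = np.random.default_rng(7)
        base = np.sin(np.linspace(0, 3, 20))
        x = base + rng.normal(0, 0.05, size=(6, 20))
        _, ev, corrs = eigen_summary(x)
        assert corrs.min() > 0.9


class TestIterativeMerge:
    def _clusters_from_profiles(self, profiles, labels):
        return np.asarray(labels), np.asarray(profiles, float)

    def test_highly_correlated_pair_merges_at_first_threshold(self):
        rng = np.random.default_rng(8)
        base = rng.normal(size=20)
        profiles = np.vstack([
            base + rng.normal(0, 0.01, 20),  # cluster 0 (2 members)
            base + rng.normal(0, 0.01, 20),
            -base + rng.normal(0, 0.01, 20),  # cluster 1: anticorrelated
            -base + rng.normal(0, 0.01, 20),
        ])
        labels = np.array([0, 0, 1, 1])
        # split cluster 0 artificially into two singletons to give the merge
        # step something to do
        labels = np.array([0, 1, 2, 2])
        sim = np.corrcoef(profiles)
        trace = iterative_merge(labels, profiles, sim_values=sim, backend_max=1.0)
        assert trace.n_clusters[0] == 2  # merged already at rho = 0.99

    def test_mutually_anticorrelated_clusters_never_merge(self):
        base = np.sin(np.linspace(0, 2 * np.pi, 24))
        profiles = np.vstack([base, -base])
        labels = np.array([0, 1])
        sim = np.corrcoef(profiles)
        trace = iterative_merge(labels, profiles, sim_values=sim, backend_max=1.0)
        assert (trace.n_clusters == 2).all()

    def test_cluster_count_non_increasing_over_grid(self, usv_session_k3):
        n = usv_session_k3["trace"].n_clusters
        assert (np.diff(n) <= 0).all()

    def test_oversplit_archetypes_plateau_at_true_count(self, usv_session_k3):
        trace = usv_session_k3["trace"]
        truth = usv_session_k3["truth"]
        k_true = truth["archetype"].nunique()
        n_initial = len(np.unique(usv_session_k3["initial_labels"]))
        assert n_initial > k_true  # maximal deep_split over-splits
        spans = {p["n_clusters"]: p["span"] for p in trace.plateaus}
        assert spans.get(k_true, 0) >= 5

    def test_merging_reduces_mean_cohesion_on_average(self, usv_session_k3):
        trace = usv_session_k3["trace"]
        # cohesion at the over-split start is at least that of the floor
        assert trace.cohesion[0] >= trace.cohesion[-1]

    def test_selected_plateau_matches_ground_truth(self, usv_session_k3):
        from sklearn.metrics import adjusted_rand_score

        labels, plateau = select_plateau(usv_session_k3["trace"])
        truth = usv_session_k3["truth"]["archetype"].to_numpy()
        assert plateau["n_clusters"] == 3
        assert adjusted_rand_score(truth, labels) >= 0.9

    def test_expected_n_plateau_selection(self, usv_session_k3):
        labels, plateau = select_plateau(usv_session_k3["trace"], expected_n=3)
        assert plateau["n_clusters"] == 3
        with pytest.raises(ValueError, match="no plateau"):
            select_plateau(usv_session_k3["trace"], expected_n=97)


class TestQCAndClassify:
    def _cluster_set(self):
        rng = np.random.default_rng(9)
        base = np.sin(np.linspace(0, 3, 30))
        profiles = np.vstack(
            [base + rng.normal(0, 0.02, 30) for _ in range(6)]
            + [rng.normal(0, 1, 30) for _ in range(5)]
        )
        labels = np.array([0] * 6 + [1] * 5)
        ids = [f"e{i}" for i in range(11)]
        return ClusterSet.build(ids, labels, profiles)

    def test_threshold_boundary_is_inclusive(self):
        cs = self._cluster_set()
        mean0 = float(cs.member_corr[cs.labels == 0].mean())
        at = qc_and_classify(cs, cohesion_threshold=mean0)
        above = qc_and_classify(cs, cohesion_threshold=mean0 + 1e-9)
        rows_at = at[at["cluster_id"] == 0]
        rows_above = above[above["cluster_id"] == 0]
        assert list(rows_at["mode"]) == ["representative"]  # >= passes
        assert set(rows_above["mode"]) == {"manual"}  # just above fails

    def test_incohesive_cluster_members_listed_individually(self):
        cs = self._cluster_set()
        tasks = qc_and_classify(cs, cohesion_threshold=0.8)
        noisy = tasks[tasks["cluster_id"] == 1]
        assert set(noisy["mode"]) == {"manual"}
        assert len(noisy) == 5

    def test_zero_threshold_gives_one_representative_per_cluster(self):
        cs = self._cluster_set()
        tasks = qc_and_classify(cs, cohesion_threshold=0.0)
        assert (tasks["mode"] == "representative").all()
        assert len(tasks) == len(cs.cluster_ids)

    def test_representative_is_cluster_member(self):
        cs = self._cluster_set()
        for cid, ranked in cs.representatives.items():
            assert set(ranked) == set(cs.members(cid))


def test_apply_relabeling_overrides_named_elements():
    rng = np.random.default_rng(10)
    profiles = rng.normal(size=(6, 12))
    cs = ClusterSet.build([f"e{i}" for i in range(6)], np.array([0, 0, 0, 1, 1, 1]), profiles)
    updated = apply_relabeling(cs, {"e0": 1})
    assert updated.labels_dict["e0"] == 1
    with pytest.raises(KeyError, match="unknown element"):
        apply_relabeling(cs, {"nope": 0})
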