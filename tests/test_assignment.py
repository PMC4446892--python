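"""Cross-session assignment: gating, ANOVA separation, ties, novelty."""

import numpy as np
import pandas as pd
import pytest

from conftest import cluster_session
from vocalclust import assignment as asg
from vocalclust.clustering import ClusterSet
from vocalclust.segmentation import SegmentationParams, segment_usv
from vocalclust.synthetic import (
    SessionSpec,
    default_archetypes,
    novel_archetypes,
    synth_session,
)


@pytest.fixture(scope="module")
def established(usv_session_k3):
    cs = usv_session_k3["clusters"]
    amap = {e.element_id: e for e in usv_session_k3["elements"]}
    reps = asg.select_representatives(cs, 0.10)
    rep_elements = {c: [amap[i] for i in ids] for c, ids in reps.items()}
    return {"cs": cs, "amap": amap, "rep_elements": rep_elements,
            "session": usv_session_k3}


class TestSelectRepresentatives:
    def _cs(self, sizes):
        rng = np.random.default_rng(0)
        labels = np.concatenate([[k] * n for k, n in enumerate(sizes)])
        base = np.sin(np.linspace(0, 3, 20))
        profiles = np.vstack(
            [base * (k + 1) + rng.normal(0, 0.1, 20) for k in labels]
        )
        ids = [f"e{i}" for i in range(len(labels))]
        return ClusterSet.build(ids, labels, profiles)

    def test_top_ten_percent_of_thirty_is_three(self):
        reps = asg.select_representatives(self._cs([30]), 0.10)
        assert len(reps[0]) == 3

    def test_small_cluster_keeps_at_least_one(self):
        reps = asg.select_representatives(self._cs([5]), 0.10)
        assert len(reps[0]) == 1

    def test_fraction_one_returns_all_members(self):
        cs = self._cs([7, 4])
        reps = asg.select_representatives(cs, 1.0)
        assert len(reps[0]) == 7 and len(reps[1]) == 4

    def test_representatives_ranked_by_eigen_correlation(self):
        cs = self._cs([10])
        reps = asg.select_representatives(cs, 0.3)
        corrs = [cs.member_corr[cs.element_ids.index(r)] for r in reps[0]]
        assert corrs == sorted(corrs, reverse=True)


class TestAssignElements:
    def test_single_candidate_assigned(self):
        scores = pd.DataFrame(
            {"r1": [0.9], "r2": [0.85], "r3": [0.1], "r4": [0.05]}, index=["b0"]
        )
        rep_cluster = {"r1": 0, "r2": 0, "r3": 1, "r4": 1}
        res = asg.assign_elements(scores, rep_cluster, asg.AssignmentParams(gs_floor=0.6))
        assert res.table.loc[0, "outcome"] == "assigned"
        assert res.table.loc[0, "cluster_id"] == 0

    def test_below_floor_everywhere_is_novel(self):
        scores = pd.DataFrame({"r1": [0.2], "r2": [0.3]}, index=["b0"])
        res = asg.assign_elements(
            scores, {"r1": 0, "r2": 1}, asg.AssignmentParams(gs_floor=0.6)
        )
        assert res.table.loc[0, "outcome"] == "novel"

    def test_overlapping_candidates_tie(self):
        # symmetric construction: two candidate clusters with interleaved
        # score distributions that ANOVA cannot separate
        scores = pd.DataFrame(
            {
                "a1": [0.80], "a2": [0.75], "a3": [0.85],
                "b1": [0.82], "b2": [0.74], "b3": [0.84],
            },
            index=["b0"],
        )
        rep_cluster = {"a1": 0, "a2": 0, "a3": 0, "b1": 1, "b2": 1, "b3": 1}
        res = asg.assign_elements(scores, rep_cluster, asg.AssignmentParams(gs_floor=0.6))
        assert res.table.loc[0, "outcome"] == "tie"

    def test_separated_candidates_assigned_to_top(self):
        scores = pd.DataFrame(
            {
                "a1": [0.95], "a2": [0.96], "a3": [0.94],
                "b1": [0.70], "b2": [0.71], "b3": [0.69],
            },
            index=["b0"],
        )
        rep_cluster = {"a1": 0, "a2": 0, "a3": 0, "b1": 1, "b2": 1, "b3": 1}
        res = asg.assign_elements(scores, rep_cluster, asg.AssignmentParams(gs_floor=0.6))
        assert res.table.loc[0, "outcome"] == "assigned"
        assert res.table.loc[0, "cluster_id"] == 0

    def test_outcomes_partition_session(self, established):
        sess = established["session"]
        scores, rc = asg.score_against_representatives(
            sess["elements"], established["rep_elements"], "mouse_contour"
        )
        res = asg.assign_elements(scores, rc, asg.AssignmentParams(gs_floor=0.6))
        counts = res.counts()
        assert sum(counts.values()) == len(sess["elements"])

    def test_raising_floor_never_increases_assignments(self, established):
        sess = established["session"]
        scores, rc = asg.score_against_representatives(
            sess["elements"], established["rep_elements"], "mouse_contour"
        )
        assigned = []
        for floor in (0.3, 0.6, 0.9, 0.99):
            res = asg.assign_elements(scores, rc, asg.AssignmentParams(gs_floor=floor))
            assigned.append(res.counts()["assigned"])
        assert all(a >= b for a, b in zip(assigned, assigned[1:]))

    def test_self_assignment_reproduces_labels(self, established):
        sess = established["session"]
        cs = established["cs"]
        scores, rc = asg.score_against_representatives(
            sess["elements"], established["rep_elements"], "mouse_contour"
        )
        res = asg.assign_elements(scores, rc, asg.AssignmentParams(gs_floor=0.6))
        table = res.table.set_index("element_id")
        original = cs.labels_dict
        assert all(
            table.at[e, "outcome"] == "assigned"
            and table.at[e, "cluster_id"] == original[e]
            for e in cs.element_ids
        )

    def test_top_fraction_matches_full_cluster_assignment(self, established):
        sess = established["session"]
        amap = established["amap"]
        wave_b, _ = synth_session(
            SessionSpec(archetypes=default_archetypes(3), n_calls=45, seed=2)
        )
        els_b = segment_usv(wave_b, SegmentationParams(), session_id="b")
        results = {}
        for frac in (0.10, 1.0):
            reps = asg.select_representatives(established["cs"], frac)
            rep_elements = {c: [amap[i] for i in ids] for c, ids in reps.items()}
            scores, rc = asg.score_against_representatives(
                els_b, rep_elements, "mouse_contour"
            )
            res = asg.assign_elements(scores, rc, asg.AssignmentParams(gs_floor=0.6))
            results[frac] = res.table.set_index("element_id")
        t1, t2 = results[0.10], results[1.0]
        for e in t1.index:
            assert t1.at[e, "outcome"] == t2.at[e, "outcome"]
            if t1.at[e, "outcome"] == "assigned":
                assert t1.at[e, "cluster_id"] == t2.at[e, "cluster_id"]


class TestResolveTies:
    def _tied_result(self):
        scores = pd.DataFrame(
            {
                "a1": [0.80, 0.72], "a2": [0.75, 0.68],
                "b1": [0.82, 0.66], "b2": [0.74, 0.70],
            },
            index=["b0", "b1"],
        )
        rep_cluster = {"a1": 0, "a2": 0, "b1": 1, "b2": 1}
        return asg.assign_elements(
            scores, rep_cluster, asg.AssignmentParams(gs_floor=0.6)
        )

    def test_best_mean_assigns_highest_candidate(self):
        res = self._tied_result()
        assert (res.table["outcome"] == "tie").all()
        resolved = asg.resolve_ties(res, "best_mean")
        assert (resolved.table["outcome"] == "assigned").all()
        row0 = resolved.table.set_index("element_id").loc["b0"]
        assert row0["cluster_id"] == res.candidate_means.loc["b0"].idxmax()

    def test_unassigned_policy_moves_ties_to_novel(self):
        resolved = asg.resolve_ties(self._tied_result(), "unassigned")
        counts = resolved.counts()
        assert counts["tie"] == 0
        assert counts["novel"] == 2

    def test_interactive_decisions_file(self):
        decisions = pd.DataFrame([{"element_id": "b0", "cluster_id": 1}])
        resolved = asg.resolve_ties(self._tied_result(), "interactive", decisions)
        table = resolved.table.set_index("element_id")
        assert table.at["b0", "outcome"] == "assigned"
        assert table.at["b0", "cluster_id"] == 1
        assert table.at["b1", "outcome"] == "tie"  # no decision row: stays tied


class TestClusterNovel:
    def test_out_of_repertoire_archetypes_form_two_new_clusters(self, established):
        wave_n, truth_n = synth_session(
            SessionSpec(archetypes=novel_archetypes(), n_calls=40, seed=5)
        )
        els_n = segment_usv(wave_n, SegmentationParams(), session_id="n")
        scores, rc = asg.score_against_representatives(
            els_n, established["rep_elements"], "mouse_contour"
        )
        res = asg.assign_elements(scores, rc, asg.AssignmentParams(gs_floor=0.6))
        assert res.counts()["novel"] == len(els_n)  # all declared novel
        novel_ids = res.table.loc[res.table["outcome"] == "novel", "element_id"]
        nov = asg.cluster_novel(scores.loc[novel_ids], first_new_id=3)
        assert len(nov.cluster_ids) == 2
        assert min(nov.cluster_ids) >= 3  # fresh ids beyond the established set
        # each novel cluster is dominated by one archetype
        truth = truth_n["archetype"].to_numpy()
        for cid in nov.cluster_ids:
            members = truth[nov.labels == cid]
            top = max(np.unique(members, return_counts=True)[1])
            assert top / len(members) > 0.5

    def test_single_novel_element_is_singleton_cluster(self):
        scores = pd.DataFrame({"r1": [0.1], "r2": [0.2]}, index=["n0"])
        nov = asg.cluster_novel(scores, first_new_id=7)
        assert nov.cluster_ids == [7]
        assert nov.explained_variance[7] == pytest.approx(1.0)

    def test_identical_novel_elements_single_cluster(self):
        row = [0.1, 0.5, 0.2, 0.4]
        scores = pd.DataFrame([row] * 4, index=[f"n{i}" for i in range(4)],
                              columns=["r1", "r2", "r3", "r4"])
        nov = asg.cluster_novel(scores, first_new_id=0)
        assert len(nov.cluster_ids) == 1
        assert nov.explained_variance[0] == pytest.approx(1.0)

    def test_no_representatives_rejected(self):
        scores = pd.DataFrame(index=["n0", "n1"])
        with pytest.raises(ValueError, match="representatives"):
            asg.cluster_novel(scores)
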