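"""Overlap tables, pair classification and incremental merging."""

import numpy as np
import pytest

from leaf3d.fusion import (
    FusionState,
    classify_pairs,
    group_mean,
    incremental_fuse,
    merge_pair,
    overlap_tables,
)
from leaf3d.lifting import FusionConfig, ViewLabeling
from leaf3d.metrics import evaluate

CFG = FusionConfig()


def vl(labels, conf=None, view_id=0):
    labels = np.asarray(labels)
    if conf is None:
        conf = np.where(labels >= 0, 0.5, 0.0)
    return ViewLabeling(view_id, labels, np.asarray(conf, dtype=float))


class TestOverlapTables:
    def test_worked_example(self):
        q = overlap_tables(np.array([1, 1, 2, 2, -1]), np.array([5, 5, 5, 6, 6]))
        assert q.Qx == {1: {5: 1.0}, 2: {5: 0.5, 6: 0.5}}
        assert q.Qy[5] == pytest.approx({1: 2 / 3, 2: 1 / 3})
        assert q.Qy[6] == {2: 0.5, -1: 0.5}

    def test_self_correspondence_is_identity(self):
        a = np.array([0, 0, 1, 1, 2, -1])
        q = overlap_tables(a, a)
        assert q.Qx == {0: {0: 1.0}, 1: {1: 1.0}, 2: {2: 1.0}}
        assert q.Qy == q.Qx

    def test_disjoint_supports_map_to_unlabeled(self):
        q = overlap_tables(np.array([1, 1, -1, -1]), np.array([-1, -1, 7, 7]))
        assert q.Qx == {1: {-1: 1.0}}
        assert q.Qy == {7: {-1: 1.0}}

    def test_rows_are_distributions(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            a = rng.integers(-1, 4, 60)
            b = rng.integers(-1, 4, 60)
            q = overlap_tables(a, b)
            for row in list(q.Qx.values()) + list(q.Qy.values()):
                assert sum(row.values()) == pytest.approx(1.0, abs=1e-9)
                assert all(0 <= g <= 1 for g in row.values())

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            overlap_tables(np.zeros(3, dtype=int), np.zeros(4, dtype=int))


class TestClassifyPairs:
    def test_majority_unlabeled_is_unmatched(self):
        a = np.array([1] * 10 + [-1] * 10)
        b = np.array([-1] * 9 + [5, -1] + [-1] * 9)  # 9/10 of group 1 see -1
        cls = classify_pairs(overlap_tables(a, b), CFG)
        assert 1 in cls.unmatched_a

    def test_identical_groups_match(self):
        a = np.array([1, 1, 1, -1])
        b = np.array([5, 5, 5, -1])
        cls = classify_pairs(overlap_tables(a, b), CFG)
        assert cls.matched == [(1, 5)]
        assert cls.conflicts == []

    def test_one_sided_overlap_is_a_conflict(self):
        # gamma_x = 0.4 < tau, gamma_y = 1.0 >= tau: fails the mutual test
        a = np.array([1, 1, 1, 1, 1])
        b = np.array([5, 5, -1, -1, -1])
        cls = classify_pairs(overlap_tables(a, b), CFG)
        assert cls.matched == []
        assert (1, 5) in cls.conflicts


class TestGroupMean:
    def test_examples(self):
        assert group_mean([0.2, 0.4, 0.6]) == pytest.approx(0.4)
        assert group_mean([0.7]) == 0.7

    def test_matches_summation_oracle(self):
        rng = np.random.default_rng(4)
        vals = rng.uniform(0, 2, 1000)
        acc = 0.0
        for x in vals:
            acc += x
        assert group_mean(vals) == pytest.approx(acc / len(vals), abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            group_mean([])


class TestMergePair:
    def test_empty_state_adopts_everything(self):
        inc = vl([0, 0, 1, 1, 2, -1], [0.2, 0.3, 0.4, 0.5, 0.6, 0.0])
        state = FusionState.empty(6)
        merge_pair(state, inc, CFG)
        assert evaluate(state.labels, inc.labels).f1 == 1.0
        assert np.array_equal(state.conf, inc.conf)

    def test_matched_confidences_sum_pointwise(self):
        state = FusionState(labels=np.array([0, 0, -1]), conf=np.array([0.5, 0.6, 0.0]),
                            next_label=1)
        merge_pair(state, vl([7, 7, -1], [0.3, 0.2, 0.0]), CFG)
        assert list(state.labels) == [0, 0, -1]
        assert state.conf == pytest.approx([0.8, 0.8, 0.0])

    def test_conflict_overlap_keeps_higher_mean_side_with_abs_difference(self):
        state = FusionState(labels=np.array([0] * 5), conf=np.array([0.8] * 5), next_label=1)
        merge_pair(state, vl([3, 3, -1, -1, -1], [0.6, 0.6, 0, 0, 0]), CFG)
        assert list(state.labels) == [0] * 5  # state mean 0.8 > incoming 0.6
        assert state.conf == pytest.approx([0.2, 0.2, 0.8, 0.8, 0.8])

    def test_conflict_lower_mean_state_cedes_overlap(self):
        state = FusionState(labels=np.array([0] * 5), conf=np.array([0.4] * 5), next_label=1)
        merge_pair(state, vl([3, 3, -1, -1, -1], [0.9, 0.9, 0, 0, 0]), CFG)
        assert state.labels[0] == state.labels[1] != 0
        assert list(state.labels[2:]) == [0, 0, 0]  # losers outside overlap keep their label
        assert state.conf[:2] == pytest.approx([0.5, 0.5])

    def test_unmatched_incoming_group_enters_verbatim(self):
        state = FusionState(labels=np.array([0, 0, -1, -1, -1]),
                            conf=np.array([0.5, 0.5, 0, 0, 0]), next_label=1)
        merge_pair(state, vl([-1, -1, 4, 4, 4], [0, 0, 0.1, 0.2, 0.3]), CFG)
        assert len(set(state.labels[2:])) == 1
        assert state.labels[2] != 0
        assert state.conf[2:] == pytest.approx([0.1, 0.2, 0.3])


class TestIncrementalFuse:
    def test_single_view_is_adopted(self):
        inc = vl([0, 1, -1], [0.1, 0.2, 0.0])
        state = incremental_fuse([inc], CFG)
        assert evaluate(state.labels, inc.labels).f1 == 1.0

    def test_same_view_twice_doubles_confidence(self):
        inc = vl([0, 0, 1, 1, -1], [0.1, 0.2, 0.3, 0.4, 0.0])
        once = incremental_fuse([inc], CFG)
        twice = incremental_fuse([inc, inc], CFG)
        assert np.array_equal(once.labels, twice.labels)
        assert twice.conf == pytest.approx(2 * inc.conf)

    def test_empty_view_list_rejected(self):
        with pytest.raises(ValueError):
            incremental_fuse([], CFG)

    def test_partition_and_conf_invariants_hold_after_every_merge(self, corrupted_lifted):
        vls, _ = corrupted_lifted

        def check(state):
            assert (state.conf >= 0).all()
            assert (state.conf[state.labels == -1] == 0).all()
            live = np.unique(state.labels[state.labels >= 0])
            assert (live < state.next_label).all()

        incremental_fuse(vls, CFG, on_merge=check)

    def test_clean_fusion_recovers_ground_truth(self, scene, clean_lifted):
        vls, visible = clean_lifted
        state = incremental_fuse(vls, CFG)
        rep = evaluate(state.labels, scene.cloud.labels, conf=state.conf, mask=visible)
        assert rep.precision == 1.0 and rep.recall == 1.0 and rep.miou == 1.0

    def test_view_order_rotation_gives_same_partition_on_clean_data(self, clean_lifted):
        vls, visible = clean_lifted
        base = incremental_fuse(vls, CFG)
        for shift in (5, 16):
            rotated = vls[shift:] + vls[:shift]
            other = incremental_fuse(rotated, CFG)
            rep = evaluate(base.labels[visible], other.labels[visible])
            assert rep.f1 == 1.0 and rep.miou == 1.0
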