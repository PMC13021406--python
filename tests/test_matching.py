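"""IOU scoring and the greedy correct/false/missed assignment."""

from __future__ import annotations

import numpy as np
import pytest

from lesionmatch import (
    AnnotationSet,
    ImageGrid,
    MatchConfig,
    PathologyClass,
    Source,
    iou,
    match_all,
    match_pathology,
    optimal_match_oracle,
)

from .conftest import block, make_lesion


def random_instance(rng, grid=ImageGrid(30, 30), max_side=6):
    """Random rectangle lesions with arbitrary overlap, one pathology."""
    def lesions(n):
        out = []
        for _ in range(n):
            h = int(rng.integers(1, 6))
            w = int(rng.integers(1, 6))
            r = int(rng.integers(0, grid.height - h))
            c = int(rng.integers(0, grid.width - w))
            out.append(make_lesion(block(r, c, h, w), grid))
        return out
    return lesions(int(rng.integers(0, max_side + 1))), lesions(int(rng.integers(0, max_side + 1)))


class TestIou:
    def test_identical_blocks_score_one(self):
        a = frozenset(block(0, 0, 2, 2))
        assert iou(a, a) == 1.0

    def test_disjoint_blocks_score_zero(self):
        assert iou(frozenset(block(0, 0, 2, 2)), frozenset(block(5, 5, 2, 2))) == 0.0

    def test_edge_sharing_blocks_score_one_third(self):
        # two 2x2 blocks overlapping in a 1x2 strip: inter 2, union 6
        a = frozenset(block(0, 0, 2, 2))
        b = frozenset(block(1, 0, 2, 2))
        assert iou(a, b) == pytest.approx(1 / 3)

    def test_symmetry_on_random_sets(self, rng):
        for _ in range(50):
            a = frozenset(map(tuple, rng.integers(0, 10, size=(rng.integers(1, 20), 2))))
            b = frozenset(map(tuple, rng.integers(0, 10, size=(rng.integers(1, 20), 2))))
            assert iou(a, b) == iou(b, a)
            assert iou(a, a) == 1.0

    def test_both_empty_is_rejected(self):
        with pytest.raises(ValueError):
            iou(frozenset(), frozenset())


def strip(col0: int, length: int = 30, grid=ImageGrid(1, 70)):
    return make_lesion({(0, c) for c in range(col0, col0 + length)}, grid)


class TestGreedyMatching:
    def test_identical_lesion_is_one_correct_pair(self):
        d = [make_lesion(block(1, 1, 3, 3))]
        m = [make_lesion(block(1, 1, 3, 3), d[0].grid)]
        res = match_pathology(d, m)
        assert len(res.correct_pairs) == 1
        assert res.correct_pairs[0].iou == 1.0
        assert res.false_marked == [] and res.missed_detected == []

    def test_half_overlap_strip_is_correct_at_default_threshold(self):
        # 1x30 strips shifted by 10: intersection 20, union 40, IOU exactly 0.5,
        # and the boundary is inclusive ("0.5 or higher").
        res = match_pathology([strip(0)], [strip(10)])
        assert len(res.correct_pairs) == 1
        assert res.correct_pairs[0].iou == pytest.approx(0.5)

    def test_strip_below_threshold_is_false_and_missed(self):
        res = match_pathology([strip(0)], [strip(11)])  # IOU 19/41 < 0.5
        assert res.correct_pairs == []
        assert res.false_marked == [0] and res.missed_detected == [0]

    def test_two_detected_competing_for_one_marked(self):
        # Both detected lesions overlap the single marked lesion at >= 0.5;
        # the canonical-order first (larger) detected lesion takes it.
        grid = ImageGrid(10, 40)
        d_big = make_lesion(block(0, 0, 2, 10), grid)     # area 20, IOU 1 with marked
        d_small = make_lesion(block(0, 0, 1, 10), grid)   # area 10, IOU 0.5 with marked
        marked = make_lesion(block(0, 0, 2, 10), grid)
        res = match_pathology([d_small, d_big], [marked])
        assert len(res.correct_pairs) == 1
        assert res.correct_pairs[0].detected_index == 1  # the big one
        assert res.missed_detected == [0]
        oracle = optimal_match_oracle([d_small, d_big], [marked])
        assert len(oracle.correct_pairs) == len(res.correct_pairs)

    def test_subthreshold_overlap_does_not_consume_marked_lesion(self):
        # The first detected lesion overlaps weakly (< 0.5); deletion must be
        # conditional on the threshold, so the marked lesion stays available
        # for the second detected lesion which it matches exactly.
        grid = ImageGrid(1, 70)
        d_weak = strip(0, 31, grid)   # vs marked at 20: IOU 11/50 < 0.5 (larger: visited first)
        d_exact = strip(20, 30, grid)
        marked = strip(20, 30, grid)
        res = match_pathology([d_weak, d_exact], [marked])
        assert len(res.correct_pairs) == 1
        assert res.correct_pairs[0].detected_index == 1
        assert res.correct_pairs[0].iou == 1.0
        assert res.missed_detected == [0] and res.false_marked == []

    def test_equal_iou_tie_breaks_to_lower_canonical_index(self):
        grid = ImageGrid(10, 10)
        d = make_lesion(block(2, 0, 2, 4), grid)   # 2x4 block
        # two marked lesions each overlapping half of d symmetrically
        m_a = make_lesion(block(1, 0, 2, 4), grid)
        m_b = make_lesion(block(3, 0, 2, 4), grid)
        for order in ([m_a, m_b], [m_b, m_a]):
            res = match_pathology([d], order, MatchConfig(iou_threshold=1 / 3))
            assert len(res.correct_pairs) == 1
            winner = order[res.correct_pairs[0].marked_index]
            assert winner.bbox[:2] == (1, 0)  # canonical: top-left first

    def test_mismatched_pathology_rejected(self):
        a = make_lesion(block(0, 0, 2, 2), pathology=PathologyClass.HEMORRHAGE)
        b = make_lesion(block(0, 0, 2, 2), grid=a.grid, pathology=PathologyClass.MICROANEURYSM)
        with pytest.raises(ValueError):
            match_pathology([a], [b])


class TestMatchAll:
    def _aset(self, source, lesions_by_class, grid=ImageGrid(20, 20)):
        return AnnotationSet(
            image_id="img", grid=grid, source=source, lesions=dict(lesions_by_class)
        )

    def test_all_empty_gives_all_empty_result(self):
        res = match_all(self._aset(Source.REFERENCE, {}), self._aset(Source.MARKED, {}))
        for p in PathologyClass:
            entry = res.per_pathology[p]
            assert entry.correct_pairs == [] and entry.false_marked == [] and entry.missed_detected == []

    def test_matching_never_crosses_pathology_classes(self):
        grid = ImageGrid(20, 20)
        lesion = lambda p: make_lesion(block(5, 5, 4, 4), grid, p)
        ref = self._aset(Source.REFERENCE, {PathologyClass.HARD_EXUDATE: [lesion(PathologyClass.HARD_EXUDATE)]}, grid)
        mark = self._aset(Source.MARKED, {PathologyClass.HEMORRHAGE: [lesion(PathologyClass.HEMORRHAGE)]}, grid)
        res = match_all(ref, mark)
        assert res.per_pathology[PathologyClass.HARD_EXUDATE].missed_detected == [0]
        assert res.per_pathology[PathologyClass.HEMORRHAGE].false_marked == [0]
        assert all(res.per_pathology[p].correct_pairs == [] for p in PathologyClass)

    def test_image_id_mismatch_rejected(self):
        ref = self._aset(Source.REFERENCE, {})
        mark = AnnotationSet(image_id="other", grid=ref.grid, source=Source.MARKED)
        with pytest.raises(ValueError, match="image_id"):
            match_all(ref, mark)

    def test_source_roles_enforced(self):
        ref = self._aset(Source.REFERENCE, {})
        with pytest.raises(ValueError):
            match_all(ref, ref)


class TestInvariants:
    def test_partition_and_threshold_guarantee(self, rng):
        cfg = MatchConfig()
        for _ in range(100):
            detected, marked = random_instance(rng)
            res = match_pathology(detected, marked, cfg)
            assert len(marked) == len(res.correct_pairs) + len(res.false_marked)
            assert len(detected) == len(res.correct_pairs) + len(res.missed_detected)
            marked_used = [p.marked_index for p in res.correct_pairs] + res.false_marked
            detected_used = [p.detected_index for p in res.correct_pairs] + res.missed_detected
            assert sorted(marked_used) == list(range(len(marked)))
            assert sorted(detected_used) == list(range(len(detected)))
            assert all(p.iou >= cfg.iou_threshold for p in res.correct_pairs)

    def test_raising_threshold_never_adds_correct_pairs(self, rng):
        thresholds = [0.0, 0.25, 0.5, 0.75, 1.0]
        for _ in range(50):
            detected, marked = random_instance(rng)
            counts = [
                len(match_pathology(detected, marked, MatchConfig(iou_threshold=t)).correct_pairs)
                for t in thresholds
            ]
            assert counts == sorted(counts, reverse=True)

    def test_greedy_never_beats_brute_force_oracle(self, rng):
        for _ in range(200):
            detected, marked = random_instance(rng)
            greedy = match_pathology(detected, marked)
            oracle = optimal_match_oracle(detected, marked)
            assert len(greedy.correct_pairs) <= len(oracle.correct_pairs)

    def test_greedy_equals_oracle_on_one_to_one_instances(self, rng):
        # Lesions placed on a sparse lattice so each marked lesion overlaps at
        # most one detected lesion and vice versa.
        grid = ImageGrid(60, 60)
        for _ in range(200):
            n = int(rng.integers(0, 6))
            cells = rng.permutation(36)[:n]
            detected, marked = [], []
            for cell in cells:
                r, c = 10 * (cell // 6), 10 * (cell % 6)
                detected.append(make_lesion(block(r, c, 4, 4), grid))
                action = rng.random()
                if action < 0.4:
                    marked.append(make_lesion(block(r, c, 4, 4), grid))  # exact
                elif action < 0.7:
                    marked.append(make_lesion(block(r, c + 1, 4, 4), grid))  # IOU 3/5
            greedy = match_pathology(detected, marked)
            oracle = optimal_match_oracle(detected, marked)
            assert len(greedy.correct_pairs) == len(oracle.correct_pairs)
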