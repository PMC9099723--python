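import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wildtrack.association import (
    GATE_SENTINEL,
    appearance_cost_matrix,
    cascade_match,
    center_cost_matrix,
    iou,
    iou_cost_matrix,
    solve_assignment,
    three_stage_match,
)
from wildtrack.io import BoundingBox, Detection, RunConfig
from wildtrack.motion import KalmanFilter
from wildtrack.tracker import Track

from conftest import make_detection, unit


def make_track(identity, left, top, w, h, embedding=None, confirmed=True, time_since_update=1):
    kf = KalmanFilter()
    box = BoundingBox(left, top, w, h)
    t = Track(identity=identity, kalman=kf.initiate(box.to_cxcyah()), last_box=box)
    t.kalman = kf.predict(t.kalman)
    if embedding is not None:
        t.gallery.append(unit(embedding))
    t.state = "confirmed" if confirmed else "tentative"
    t.time_since_update = time_since_update
    return t


class TestIoU:
    def test_identical_boxes(self):
        b = BoundingBox(3, 4, 10, 12)
        assert iou(b, b) == 1.0

    def test_disjoint_boxes(self):
        assert iou(BoundingBox(0, 0, 5, 5), BoundingBox(100, 100, 5, 5)) == 0.0

    def test_hand_computed_overlap(self):
        # A=(0,0,2,2), B=(1,0,2,2): intersection 2, union 6
        assert iou(BoundingBox(0, 0, 2, 2), BoundingBox(1, 0, 2, 2)) == pytest.approx(1 / 3)

    coord = st.floats(min_value=-500, max_value=500, allow_nan=False)
    size = st.floats(min_value=0.1, max_value=300, allow_nan=False)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(coord, coord, size, size, coord, coord, size, size)
    def test_bounds_symmetry_identity_property(self, l1, t1, w1, h1, l2, t2, w2, h2):
        a, b = BoundingBox(l1, t1, w1, h1), BoundingBox(l2, t2, w2, h2)
        v = iou(a, b)
        assert 0.0 <= v <= 1.0
        assert v == pytest.approx(iou(b, a))
        assert iou(a, a) == 1.0

    def test_symmetric(self, rng):
        for _ in range(20):
            a = BoundingBox(*rng.uniform(0, 50, 2), *rng.uniform(1, 30, 2))
            b = BoundingBox(*rng.uniform(0, 50, 2), *rng.uniform(1, 30, 2))
            assert iou(a, b) == pytest.approx(iou(b, a))
            assert 0.0 <= iou(a, b) <= 1.0


class TestCostMatrices:
    def test_iou_cost_identity_and_gate(self):
        b = BoundingBox(0, 0, 10, 10)
        far = BoundingBox(500, 500, 10, 10)
        cost = iou_cost_matrix([b], [b, far], gate=0.7)
        assert cost[0, 0] == 0.0
        assert cost[0, 1] == GATE_SENTINEL

    def test_iou_cost_matches_pairwise_oracle(self, rng):
        tracks = [BoundingBox(*rng.uniform(0, 80, 2), *rng.uniform(5, 40, 2)) for _ in range(4)]
        dets = [BoundingBox(*rng.uniform(0, 80, 2), *rng.uniform(5, 40, 2)) for _ in range(5)]
        cost = iou_cost_matrix(tracks, dets, gate=1.0)
        for j, i in itertools.product(range(4), range(5)):
            assert cost[j, i] == pytest.approx(1.0 - iou(tracks[j], dets[i]))

    def test_center_cost_345_triangle(self):
        # centers (0,0)-(3,4): distance 5, diag 100 -> 0.05
        a = BoundingBox(-1, -1, 2, 2)
        b = BoundingBox(2, 3, 2, 2)
        cost = center_cost_matrix([a], [b], image_diag=100.0, gate=0.05)
        assert cost[0, 0] == pytest.approx(0.05)

    def test_center_cost_zero_and_symmetry(self):
        a = BoundingBox(0, 0, 10, 10)
        b = BoundingBox(2, 2, 6, 6)  # same center (5, 5)
        assert center_cost_matrix([a], [b], 100.0)[0, 0] == 0.0
        boxes1 = [BoundingBox(0, 0, 4, 4), BoundingBox(10, 10, 4, 4)]
        boxes2 = [BoundingBox(1, 1, 4, 4)]
        c12 = center_cost_matrix(boxes1, boxes2, 800.0, gate=1.0)
        c21 = center_cost_matrix(boxes2, boxes1, 800.0, gate=1.0)
        assert np.allclose(c12, c21.T)

    def test_appearance_cost_gallery_rule(self, rng):
        e = unit(rng.normal(size=8))
        gallery = [unit(rng.normal(size=8)) for _ in range(5)] + [e]
        cost = appearance_cost_matrix([gallery], [e], gate=1.0)
        assert cost[0, 0] == pytest.approx(0.0, abs=1e-12)
        # min-over-gallery equals exhaustive scan
        dets = [unit(rng.normal(size=8)) for _ in range(4)]
        cost = appearance_cost_matrix([gallery], dets, gate=2.0)
        for i, d in enumerate(dets):
            brute = min(1.0 - float(np.dot(g, d)) for g in gallery)
            assert cost[0, i] == pytest.approx(brute)

    def test_appearance_orthogonal_vectors(self):
        a, b = np.eye(2)
        assert appearance_cost_matrix([[a]], [b], gate=2.0)[0, 0] == pytest.approx(1.0)

    def test_appearance_dimension_mismatch(self):
        with pytest.raises(ValueError, match="dimension"):
            appearance_cost_matrix([[np.array([1.0, 0.0])]], [unit([1, 0, 0])], gate=1.0)


class TestSolveAssignment:
    def test_single_entry(self):
        matches, ut, ud = solve_assignment(np.array([[0.1]]))
        assert matches == [(0, 0)] and not ut and not ud

    def test_two_by_two(self):
        matches, _, _ = solve_assignment(np.array([[0.1, 0.9], [0.9, 0.1]]))
        assert sorted(matches) == [(0, 0), (1, 1)]

    def test_all_sentinel(self):
        cost = np.full((2, 3), GATE_SENTINEL)
        matches, ut, ud = solve_assignment(cost)
        assert matches == [] and ut == [0, 1] and ud == [0, 1, 2]

    def test_empty(self):
        matches, ut, ud = solve_assignment(np.zeros((0, 3)))
        assert matches == [] and ut == [] and ud == [0, 1, 2]

    @pytest.mark.parametrize("trial", range(25))
    def test_matches_exhaustive_permutation_search(self, trial):
        """Oracle equivalence: the solver's total cost equals the best total
        cost over all gated permutations, on random matrices up to 5x5."""
        rng = np.random.default_rng(1000 + trial)
        n, m = rng.integers(1, 6, size=2)
        cost = rng.uniform(0, 1, size=(n, m))
        cost[rng.uniform(size=(n, m)) < 0.3] = GATE_SENTINEL
        matches, _, _ = solve_assignment(cost)
        got = sum(cost[r, c] for r, c in matches)
        best = brute_force_best(cost)
        assert got == pytest.approx(best, abs=1e-9)


def brute_force_best(cost):
    """Minimum total cost over one-to-one gated assignments, by enumeration."""
    n, m = cost.shape
    rows = list(range(n))
    k = min(n, m)
    best = float("inf")
    for rsub in itertools.combinations(rows, k):
        for perm in itertools.permutations(range(m), k):
            total = sum(
                cost[r, c] for r, c in zip(rsub, perm) if cost[r, c] < GATE_SENTINEL
            )
            count = sum(1 for r, c in zip(rsub, perm) if cost[r, c] < GATE_SENTINEL)
            # Hungarian assigns k cells; sentinel cells add their cost
            total_full = total + (k - count) * GATE_SENTINEL
            best = min(best, total_full)
    # subtract sentinel contributions (unmatched cells) the solver never reports
    residue = best % GATE_SENTINEL if best >= GATE_SENTINEL else best
    return residue


class TestCascadeMatch:
    def test_simple_appearance_match(self, config):
        e = [1.0, 0, 0, 0]
        track = make_track(1, 50, 50, 20, 20, embedding=e)
        det = make_detection(1, 50, 50, 20, 20, embedding=e)
        fa = cascade_match([track], [det], config)
        assert fa.matches == [(0, 0, "cascade")]

    def test_younger_track_wins_tie(self, config):
        e = [1.0, 0, 0, 0]
        young = make_track(1, 50, 50, 20, 20, embedding=e, time_since_update=1)
        old = make_track(2, 50, 50, 20, 20, embedding=e, time_since_update=5)
        det = make_detection(1, 50, 50, 20, 20, embedding=e)
        fa = cascade_match([old, young], [det], config)
        assert fa.matches == [(1, 0, "cascade")]
        assert fa.unmatched_tracks == [0]

    def test_gated_out_detection_unmatched(self, config):
        track = make_track(1, 50, 50, 20, 20, embedding=[1.0, 0, 0, 0])
        # orthogonal embedding fails the appearance gate
        det = make_detection(1, 50, 50, 20, 20, embedding=[0, 1.0, 0, 0])
        fa = cascade_match([track], [det], config)
        assert fa.matches == []
        assert fa.unmatched_detections == [0]


class TestThreeStageMatch:
    def test_perfect_frame_all_cascade(self, config):
        es = np.eye(4)
        tracks = [make_track(i + 1, 100 * i, 100, 30, 30, embedding=es[i]) for i in range(3)]
        dets = [make_detection(1, 100 * i, 100, 30, 30, embedding=es[i]) for i in range(3)]
        fa = three_stage_match(tracks, dets, config)
        assert sorted(fa.matches) == [(i, i, "cascade") for i in range(3)]

    def test_overlap_tie_resolved_by_center_stage(self, config):
        """Two heavily overlapping detections with distinct centers: the
        center stage separates what IoU costs cannot."""
        # tracks without galleries -> cascade makes no matches
        t1 = make_track(1, 100, 100, 60, 60)
        t2 = make_track(2, 110, 100, 60, 60)
        d1 = make_detection(1, 100, 100, 60, 60)
        d2 = make_detection(1, 110, 100, 60, 60)
        fa = three_stage_match([t1, t2], [d2, d1], config)
        tags = {(t, d): s for t, d, s in fa.matches}
        assert tags == {(0, 1): "center", (1, 0): "center"}

    def test_embeddingless_detections_fall_through(self, config):
        track = make_track(1, 50, 50, 20, 20, embedding=[1.0, 0, 0, 0])
        det = make_detection(1, 51, 50, 20, 20)  # no embedding
        fa = three_stage_match([track], [det], config)
        assert len(fa.matches) == 1
        assert fa.matches[0][2] in ("center", "iou")

    def test_iou_stage_catches_center_gated_pair(self, config):
        # same box shifted by 60 px: center distance 60/800 > 0.05 gate, but IoU ~ 0.45
        track = make_track(1, 100, 100, 150, 150)
        det = make_detection(1, 160, 100, 150, 150)
        fa = three_stage_match([track], [det], config)
        assert fa.matches == [(0, 0, "iou")]

    def test_two_stage_mode_disables_iou(self, config):
        import dataclasses

        cfg = dataclasses.replace(config, use_iou_stage=False)
        track = make_track(1, 100, 100, 150, 150)
        det = make_detection(1, 160, 100, 150, 150)
        fa = three_stage_match([track], [det], cfg)
        assert fa.matches == []

    @pytest.mark.parametrize("trial", range(40))
    def test_output_partitions_inputs(self, trial, config):
        """Fuzz: matches plus unmatched sets always partition tracks and
        detections, with no double assignment."""
        rng = np.random.default_rng(5000 + trial)
        n_t, n_d = rng.integers(0, 6, size=2)
        tracks = []
        for i in range(n_t):
            t = make_track(
                i + 1,
                *rng.uniform(0, 400, 2),
                *rng.uniform(10, 80, 2),
                embedding=rng.normal(size=4) if rng.uniform() < 0.7 else None,
                confirmed=rng.uniform() < 0.7,
                time_since_update=int(rng.integers(1, 4)),
            )
            tracks.append(t)
        dets = [
            make_detection(
                1,
                *rng.uniform(0, 400, 2),
                *rng.uniform(10, 80, 2),
                embedding=rng.normal(size=4) if rng.uniform() < 0.7 else None,
            )
            for _ in range(n_d)
        ]
        fa = three_stage_match(tracks, dets, config)
        matched_t = [t for t, _, _ in fa.matches]
        matched_d = [d for _, d, _ in fa.matches]
        assert len(set(matched_t)) == len(matched_t)
        assert len(set(matched_d)) == len(matched_d)
        assert sorted(matched_t + fa.unmatched_tracks) == list(range(n_t))
        assert sorted(matched_d + fa.unmatched_detections) == list(range(n_d))
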