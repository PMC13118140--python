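"""Evaluation metrics: closed forms, matching oracle, AP, confusion matrix."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from posekin.annotation import BoundingBox, Keypoint, Pose
from posekin.evaluation import (
    COCO_THRESHOLDS,
    OKSParams,
    average_precision,
    box_loss,
    iou,
    keypoint_confusion,
    keypoint_confusion_single,
    match,
    oks,
    pose_error,
    summarize,
    symmetry_swap_rate,
)

from conftest import grid_points, make_pose


class TestIoU:
    def test_identical_boxes(self):
        b = BoundingBox(0.5, 0.5, 0.2, 0.4)
        assert iou(b, b) == 1.0
        assert box_loss(b, b) == 0.0

    def test_disjoint_boxes(self):
        a = BoundingBox.from_xyxy(0, 0, 1, 1)
        b = BoundingBox.from_xyxy(5, 5, 6, 6)
        assert iou(a, b) == 0.0
        assert box_loss(a, b) == 1.0

    def test_corner_overlap_is_one_seventh(self):
        a = BoundingBox.from_xyxy(0, 0, 2, 2)
        b = BoundingBox.from_xyxy(1, 1, 3, 3)
        assert iou(a, b) == pytest.approx(1 / 7, abs=1e-12)
        assert box_loss(a, b) == pytest.approx(6 / 7, abs=1e-12)

    def test_symmetric(self):
        a = BoundingBox.from_xyxy(0, 0, 2, 3)
        b = BoundingBox.from_xyxy(1, 1, 4, 2.5)
        assert iou(a, b) == iou(b, a)

    def test_zero_area_rejected(self):
        with pytest.raises(ValueError):
            iou(BoundingBox(0.5, 0.5, 0.0, 0.1), BoundingBox(0.5, 0.5, 0.1, 0.1))


class TestPoseError:
    def test_exact_prediction_zero(self):
        pose = make_pose(grid_points())
        assert pose_error(pose, pose) == 0.0

    def test_uniform_unit_shift(self):
        gt = make_pose(grid_points())
        pred = make_pose([(x + 1.0, y) for x, y in grid_points()])
        assert pose_error(pred, gt) == pytest.approx(1.0)

    def test_single_two_px_miss(self):
        pts = grid_points()
        shifted = list(pts)
        shifted[7] = (pts[7][0] + 2.0, pts[7][1])
        assert pose_error(make_pose(shifted), make_pose(pts)) == pytest.approx(4 / 25)

    def test_visible_only_variant_masks(self):
        pts = grid_points()
        shifted = list(pts)
        shifted[7] = (pts[7][0] + 2.0, pts[7][1])
        vis = [2] * 25
        vis[7] = 0
        gt = make_pose(pts, visibility=vis)
        assert pose_error(make_pose(shifted), gt, visible_only=True) == 0.0
        assert pose_error(make_pose(shifted), gt) == pytest.approx(4 / 25)


class TestOKS:
    def test_exact_prediction_is_one(self):
        pose = make_pose(grid_points())
        assert oks(pose, pose, OKSParams.uniform(0.1)) == 1.0

    def test_closed_form_single_keypoint(self):
        # one visible keypoint with d² = 2·s²·k² → exp(−1)
        box = BoundingBox(50.0, 50.0, 10.0, 10.0)       # s² = area = 100
        k = 0.5
        d = math.sqrt(2 * 100 * k * k)
        vis = [0] * 25
        vis[0] = 2
        pts = grid_points()
        gt = make_pose(pts, visibility=vis, box=box)
        shifted = list(pts)
        shifted[0] = (pts[0][0] + d, pts[0][1])
        pred = make_pose(shifted, box=box)
        assert oks(pred, gt, OKSParams.uniform(k)) == pytest.approx(math.exp(-1), abs=1e-12)

    def test_far_predictions_approach_zero(self):
        gt = make_pose(grid_points())
        pred = make_pose([(x + 1e6, y + 1e6) for x, y in grid_points()])
        assert oks(pred, gt, OKSParams.uniform(0.1)) < 1e-12

    def test_monotone_in_displacement(self):
        gt = make_pose(grid_points())
        params = OKSParams.uniform(0.2)
        values = [
            oks(make_pose([(x + dx, y) for x, y in grid_points()]), gt, params)
            for dx in (0.0, 1.0, 3.0, 10.0, 30.0)
        ]
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_no_visible_ground_truth_rejected(self):
        gt = make_pose(grid_points(), visibility=[0] * 25)
        pred = make_pose(grid_points())
        with pytest.raises(ValueError, match="visible"):
            oks(pred, gt, OKSParams.uniform(0.1))

    def test_bounded_unit_interval(self, rng):
        params = OKSParams.uniform(0.15)
        for _ in range(100):
            pts = [(float(x), float(y)) for x, y in rng.uniform(0, 100, size=(25, 2))]
            gt = make_pose(grid_points())
            v = oks(make_pose(pts), gt, params)
            assert 0.0 <= v <= 1.0


def _box_at(x, y, w=10.0, h=10.0):
    return BoundingBox(x, y, w, h)


def _detection(x, y, score=None):
    pts = [(x + i * 0.01, y) for i in range(25)]
    return make_pose(pts, box=_box_at(x, y), score=score)


def optimal_tp(preds, gts, threshold):
    """Exhaustive maximum one-to-one assignment with IoU ≥ threshold."""
    sims = [[iou(p.box, g.box) for g in gts] for p in preds]
    best = 0
    n = min(len(preds), len(gts))
    for size in range(n, 0, -1):
        for pred_subset in itertools.combinations(range(len(preds)), size):
            for gt_perm in itertools.permutations(range(len(gts)), size):
                if all(sims[p][g] >= threshold for p, g in zip(pred_subset, gt_perm)):
                    return size
    return best


class TestMatch:
    def test_perfect_predictions(self):
        gts = [_detection(10, 10), _detection(50, 50)]
        preds = [_detection(10, 10, 0.9), _detection(50, 50, 0.8)]
        res = match(preds, gts, similarity="iou", threshold=0.5)
        assert (res.tp, res.fp, res.fn) == (2, 0, 0)

    def test_empty_predictions(self):
        gts = [_detection(10, 10), _detection(50, 50)]
        res = match([], gts, similarity="iou", threshold=0.5)
        assert (res.tp, res.fp, res.fn) == (0, 0, 2)

    def test_two_predictions_one_ground_truth(self):
        gts = [_detection(10, 10)]
        preds = [_detection(10.5, 10, 0.6), _detection(10, 10, 0.9)]
        res = match(preds, gts, similarity="iou", threshold=0.5)
        assert (res.tp, res.fp, res.fn) == (1, 1, 0)
        assert res.pairs[0][0] == 1      # higher-scored prediction wins the gt

    def test_similarity_tie_goes_to_lower_gt_id(self):
        gts = [_detection(10, 10), _detection(30, 10)]
        mid = _detection(20, 10, 0.9)    # equidistant: equal IoU with both
        res = match([mid], gts, similarity="iou", threshold=0.0)
        assert res.pairs[0][1] == 0

    def test_greedy_never_beats_exhaustive_optimum(self, rng):
        for _ in range(150):
            n_p, n_g = rng.integers(0, 5), rng.integers(1, 5)
            preds = [
                _detection(rng.uniform(0, 40), rng.uniform(0, 40), float(rng.random()))
                for _ in range(n_p)
            ]
            gts = [_detection(rng.uniform(0, 40), rng.uniform(0, 40)) for _ in range(n_g)]
            thr = float(rng.uniform(0.05, 0.9))
            res = match(preds, gts, similarity="iou", threshold=thr)
            opt = optimal_tp(preds, gts, thr)
            assert res.tp <= opt
            assert res.tp == len(res.pairs)
            assert res.fp == len(preds) - res.tp
            assert res.fn == len(gts) - res.tp

    def test_threshold_monotonicity(self, rng):
        for _ in range(50):
            preds = [
                _detection(rng.uniform(0, 30), rng.uniform(0, 30), float(rng.random()))
                for _ in range(rng.integers(1, 5))
            ]
            gts = [_detection(rng.uniform(0, 30), rng.uniform(0, 30)) for _ in range(rng.integers(1, 5))]
            tps = [
                match(preds, gts, similarity="iou", threshold=t).tp
                for t in (0.9, 0.7, 0.5, 0.3, 0.1)
            ]
            assert all(a <= b for a, b in zip(tps, tps[1:]))


def allpoint_ap_oracle(scored, n_gt):
    """Exact all-point interpolated AP over the finite PR staircase."""
    order = sorted(range(len(scored)), key=lambda i: (-scored[i][0], i))
    tp = fp = 0
    points = []
    for i in order:
        if scored[i][1]:
            tp += 1
        else:
            fp += 1
        points.append((tp / (tp + fp), tp / n_gt))
    ap, prev_r = 0.0, 0.0
    for j, (_, r) in enumerate(points):
        if r > prev_r:
            p_best = max(p for p, rr in points[j:])
            ap += (r - prev_r) * p_best
            prev_r = r
    return ap


class TestAveragePrecision:
    def test_all_correct_gives_one(self):
        scored = [(0.9, True), (0.2, True), (0.5, True)]
        assert average_precision(scored, n_gt=3) == 1.0

    def test_all_wrong_gives_zero(self):
        scored = [(0.9, False), (0.5, False)]
        assert average_precision(scored, n_gt=2) == 0.0

    def test_three_prediction_staircase_vs_oracle(self):
        # ranked TP, FP, TP over 2 ground truths
        scored = [(0.9, True), (0.8, False), (0.7, True)]
        oracle = allpoint_ap_oracle(scored, n_gt=2)
        assert oracle == pytest.approx(5 / 6)
        got = average_precision(scored, n_gt=2)
        assert got == pytest.approx(oracle, abs=0.02)    # 101-point vs all-point grid gap

    def test_random_staircases_close_to_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(1, 20))
            n_gt = int(rng.integers(1, 10))
            flags = rng.random(n) < 0.6
            flags[: min(n, n_gt)] &= True
            scored = [(float(rng.random()), bool(f)) for f in flags]
            tp_total = min(sum(f for _, f in scored), n_gt)
            scored = [(s, f if i < n_gt else False) for i, (s, f) in enumerate(scored)]
            got = average_precision(scored, n_gt)
            oracle = allpoint_ap_oracle(scored, n_gt)
            assert got == pytest.approx(oracle, abs=0.05)

    def test_no_ground_truth_rejected(self):
        with pytest.raises(ValueError):
            average_precision([(0.9, True)], n_gt=0)


class TestSummarize:
    def _perfect_pairs(self, n=10):
        pairs = []
        for i in range(n):
            gt = _detection(10 + i, 10)
            pred = _detection(10 + i, 10, score=0.9)
            pairs.append(([pred], [gt]))
        return pairs

    def test_perfect_predictions_all_ones(self, schema):
        report = summarize(
            self._perfect_pairs(), similarity="oks",
            params=OKSParams.from_schema(schema), schema=schema,
        )
        assert report.precision == report.recall == report.f1 == 1.0
        assert report.map50 == 1.0
        assert report.map5095 == 1.0
        assert set(report.ap_per_threshold) == set(COCO_THRESHOLDS)
        assert np.all(np.diag(report.confusion[:, :25]) == report.confusion[:, :25].sum(axis=1))

    def test_no_ground_truth_rejected(self):
        with pytest.raises(ValueError):
            summarize([([_detection(1, 1, 0.5)], [])])


class TestKeypointConfusion:
    def test_perfect_prediction_diagonal(self):
        pose = make_pose(grid_points())
        mat = keypoint_confusion_single(pose, pose, radius_frac=0.1)
        assert np.array_equal(np.diag(mat[:, :25]), np.ones(25, dtype=int))
        assert mat[:, 25].sum() == 0

    def test_left_right_swap_lands_on_symmetry_cells(self, schema):
        pts = grid_points(step=5.0)
        gt = make_pose(pts)
        swapped = [pts[schema.mirror_index(i)] for i in range(25)]
        pred = make_pose(swapped)
        mat = keypoint_confusion([(pred, gt)], schema, radius_frac=0.5)
        for i in range(25):
            j = schema.mirror_index(i)
            assert mat[i, j] == 1
            if i != j:
                assert mat[i, i] == 0
        assert symmetry_swap_rate(mat, schema) == pytest.approx(22 / 25)

    def test_far_predictions_all_missed(self):
        gt = make_pose(grid_points())
        pred = make_pose([(x + 500, y + 500) for x, y in grid_points()])
        mat = keypoint_confusion_single(pred, gt, radius_frac=0.1)
        assert mat[:, 25].sum() == 25
        assert mat[:, :25].sum() == 0


def test_oks_params_validation(schema):
    with pytest.raises(ValueError):
        OKSParams(k=(0.1,) * 24)
    with pytest.raises(ValueError):
        OKSParams(k=(0.1,) * 24 + (0.0,))
    params = OKSParams.from_schema(schema)
    assert len(params.k) == 25
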