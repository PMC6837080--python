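"""Metric oracles: IoU, keypoint PRF, mean pixel deviation, aggregation."""

import itertools

import numpy as np
import pytest

from rowgraphics.annotation import (
    KEYPOINT_CLASS_MAP,
    Keypoint,
    SemanticGraphic,
    rasterize_keypoints,
    rasterize_lines,
)
from rowgraphics.evaluation import (
    EvalReport,
    evaluate,
    iou,
    keypoint_prf,
    mean_pixel_deviation,
    miou,
)


def loop_iou(pred, target, c):
    inter = union = 0
    for i in range(pred.shape[0]):
        for j in range(pred.shape[1]):
            p, t = pred[i, j] == c, target[i, j] == c
            inter += p and t
            union += p or t
    return 1.0 if union == 0 else inter / union


class TestIoU:
    def test_identity_is_one(self, rng):
        m = rng.integers(0, 2, size=(8, 8))
        assert iou(m, m, 1) == 1.0

    def test_disjoint_is_zero(self):
        a = np.zeros((4, 4), dtype=int)
        b = np.zeros((4, 4), dtype=int)
        a[0, 0] = 1
        b[3, 3] = 1
        assert iou(a, b, 1) == 0.0

    def test_both_empty_is_one(self):
        z = np.zeros((4, 4), dtype=int)
        assert iou(z, z, 1) == 1.0

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="shape"):
            iou(np.zeros((3, 3), int), np.zeros((4, 4), int), 1)

    def test_symmetry(self, rng):
        a = rng.integers(0, 3, size=(16, 16))
        b = rng.integers(0, 3, size=(16, 16))
        for c in range(3):
            assert iou(a, b, c) == iou(b, a, c)

    def test_matches_counting_loop_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            a = rng.integers(0, 3, size=(16, 16))
            b = rng.integers(0, 3, size=(16, 16))
            c = int(rng.integers(0, 3))
            assert iou(a, b, c) == loop_iou(a, b, c)


def exhaustive_max_tp(pred_centers, gt_centers, d_thresh):
    """Oracle: maximum true positives over all one-to-one assignments."""
    n_p, n_g = len(pred_centers), len(gt_centers)
    k = min(n_p, n_g)
    best = 0
    for preds in itertools.permutations(range(n_p), k):
        tp = 0
        for g_idx, p_idx in zip(range(k), preds):
            d = np.linalg.norm(np.asarray(pred_centers[p_idx]) - np.asarray(gt_centers[g_idx]))
            if d <= d_thresh:
                tp += 1
        best = max(best, tp)
    return best


def mask_with_dots(shape, centers, class_index=1):
    values = np.zeros(shape, dtype=np.uint8)
    for r, c in centers:
        values[int(r), int(c)] = class_index
    return values


class TestKeypointPRF:
    def test_exact_predictions(self):
        centers = [(10, 10), (40, 40), (70, 20)]
        pred = mask_with_dots((80, 80), centers)
        truth = [("paddy", c) for c in centers]
        res = keypoint_prf(pred, truth, d_thresh=15)
        assert res["paddy"]["precision"] == 1.0
        assert res["paddy"]["recall"] == 1.0

    def test_threshold_boundary_distance_16(self):
        pred = mask_with_dots((64, 64), [(10, 26)])
        truth = [("paddy", (10.0, 10.0))]
        res = keypoint_prf(pred, truth, d_thresh=15)
        assert (res["paddy"]["tp"], res["paddy"]["fp"], res["paddy"]["fn"]) == (0, 1, 1)

    def test_distance_15_is_inside(self):
        pred = mask_with_dots((64, 64), [(10, 25)])
        res = keypoint_prf(pred, [("paddy", (10.0, 10.0))], d_thresh=15)
        assert res["paddy"]["tp"] == 1

    def test_empty_both_scores_one(self):
        res = keypoint_prf(np.zeros((32, 32), dtype=np.uint8), [], d_thresh=15)
        assert res["paddy"]["precision"] == 1.0 and res["paddy"]["recall"] == 1.0

    def test_blob_centroid_is_used(self):
        g = SemanticGraphic((64, 64), keypoints=[Keypoint("millet", (30, 30), 5)])
        pred = rasterize_keypoints(g)
        res = keypoint_prf(pred.values, [("millet", (30.0, 30.0))], d_thresh=2)
        assert res["millet"]["tp"] == 1

    def test_matches_exhaustive_assignment_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            gt = rng.uniform(0, 255, size=(5, 2))
            pr = rng.uniform(0, 255, size=(7, 2)).round()
            pred = mask_with_dots((256, 256), pr)
            truth = [("paddy", tuple(c)) for c in gt]
            res = keypoint_prf(pred, truth, d_thresh=15)
            assert res["paddy"]["tp"] == exhaustive_max_tp(pr, gt, 15)


class TestMeanPixelDeviation:
    def test_identical_lines(self):
        lines = [(0.1, 40.0, (0, 99)), (0.0, 80.0, (0, 99))]
        dev = mean_pixel_deviation(lines, lines)
        assert dev.mpd == 0.0
        assert dev.deviation_range == (0.0, 0.0)

    def test_constant_offset(self):
        gt = [(0.0, 40.0, (0, 99))]
        pred = [(0.0, 43.0, (0, 99))]
        dev = mean_pixel_deviation(pred, gt)
        assert dev.mpd == pytest.approx(3.0)
        assert dev.deviation_range == (3.0, 3.0)

    def test_two_lines_mixed_offsets(self):
        gt = [(0.0, 40.0, (0, 99)), (0.0, 80.0, (0, 99))]
        pred = [(0.0, 42.0, (0, 99)), (0.0, 76.0, (0, 99))]
        dev = mean_pixel_deviation(pred, gt)
        assert dev.mpd == pytest.approx(3.0)  # (2 + 4) / 2 over equal row counts
        assert dev.deviation_range == (-4.0, 2.0)

    def test_no_predictions_nan_and_missed(self):
        dev = mean_pixel_deviation([], [(0.0, 40.0, (0, 99))])
        assert np.isnan(dev.mpd)
        assert dev.n_missed == 1

    def test_translation_consistency(self):
        gt = [(0.05, 40.0, (0, 99))]
        pred = [(0.05, 41.5, (0, 99))]
        d1 = mean_pixel_deviation(pred, gt)
        shift = 17.0
        d2 = mean_pixel_deviation(
            [(0.05, 41.5 + shift, (0, 99))], [(0.05, 40.0 + shift, (0, 99))]
        )
        assert d1.mpd == pytest.approx(d2.mpd)

    def test_rows_restricted_to_shared_extent(self):
        gt = [(0.0, 40.0, (0, 50))]
        pred = [(0.0, 42.0, (25, 99))]
        dev = mean_pixel_deviation(pred, gt)
        assert dev.mpd == pytest.approx(2.0)
        assert dev.n_rows == 26

    def test_requires_ground_truth(self):
        with pytest.raises(ValueError):
            mean_pixel_deviation([(0.0, 1.0, (0, 9))], [])


class OracleModel:
    """Returns the ground-truth mask for each image (perfect predictor)."""

    def __init__(self, masks):
        self._it = iter(masks)

    def __call__(self, image):
        return next(self._it)


def line_pairs(n, seed=0):
    from rowgraphics.synthetic_scene import SceneSpec, generate_scene

    spec = SceneSpec(image_height=96, image_width=96, n_rows=3,
                     vanishing_point=(-60.0, 48.0), row_spacing_at_bottom=24.0,
                     plant_spacing=12.0, plant_radius_near=4.0, plant_radius_far=1.5,
                     weed_density=0.3, weed_radius_range=(1.5, 3.0), jitter_sd=0.0)
    pairs = []
    for i in range(n):
        img, gt = generate_scene(spec.replace(seed=seed + i))
        pairs.append((img, gt.to_graphic((96, 96))))
    return pairs


class TestEvaluate:
    def test_oracle_model_perfect_lines(self):
        pairs = line_pairs(3)
        masks = [rasterize_lines(g, 5) for _, g in pairs]
        # d_thresh scaled to the 96-px scene so converging neighbour rows
        # (closer than 15 px near the top) stay outside the inlier band
        report = evaluate(OracleModel(masks), pairs, task="lines", d_thresh=6)
        assert report.miou == 1.0
        assert report.mpd == pytest.approx(0.0, abs=0.5)
        assert report.missed_lines == 0

    def test_oracle_model_perfect_keypoints(self):
        pairs = line_pairs(3, seed=50)
        masks = [rasterize_keypoints(g) for _, g in pairs]
        report = evaluate(OracleModel(masks), pairs, task="keypoints")
        assert report.miou == 1.0
        for rec in report.keypoint_metrics.values():
            assert rec["precision"] == 1.0 and rec["recall"] == 1.0

    def test_report_json_round_trip(self):
        pairs = line_pairs(2)
        masks = [rasterize_lines(g, 5) for _, g in pairs]
        report = evaluate(OracleModel(masks), pairs, task="lines")
        again = EvalReport.from_json(report.to_json())
        assert again == report

    def test_pooled_aggregation_matches_count_oracle(self, rng):
        # dataset-level IoU must equal pooling raw counts image by image
        pairs = line_pairs(4, seed=9)
        gt_masks = [rasterize_lines(g, 5) for _, g in pairs]
        noisy = []
        for m in gt_masks:
            v = m.values.copy()
            flip = rng.random(v.shape) < 0.02
            v = np.where(flip, 1 - v, v).astype(np.uint8)
            noisy.append(v)
        model = OracleModel(noisy)
        report = evaluate(model, pairs, task="lines", extract_lines=False)
        inter = np.zeros(2, dtype=int)
        union = np.zeros(2, dtype=int)
        for p, t in zip(noisy, gt_masks):
            for c in range(2):
                inter[c] += np.count_nonzero((p == c) & (t.values == c))
                union[c] += np.count_nonzero((p == c) | (t.values == c))
        expected = (inter / union).mean()
        assert report.miou == pytest.approx(expected)

    def test_miou_background_flag(self, rng):
        a = rng.integers(0, 2, size=(16, 16))
        b = rng.integers(0, 2, size=(16, 16))
        both = miou(a, b, 2, include_background=True)
        fg = miou(a, b, 2, include_background=False)
        assert fg == pytest.approx(iou(a, b, 1))
        assert both == pytest.approx((iou(a, b, 0) + iou(a, b, 1)) / 2)

    def test_task_mismatch_rejected(self):
        pairs = [(np.zeros((32, 32, 3), dtype=np.uint8), SemanticGraphic((32, 32)))]
        with pytest.raises(ValueError, match="keypoint"):
            evaluate(OracleModel([np.zeros((32, 32), np.uint8)]), pairs, task="keypoints")
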