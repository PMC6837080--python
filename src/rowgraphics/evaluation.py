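"""Evaluation metrics: IoU/mIoU, thresholded keypoint PRF, line deviation.

Dataset-level IoU pools intersection and union counts across images (robust
to images where a class is absent); per-image averaging is available by flag.
Keypoint precision/recall counts a prediction as a true positive when its
component centroid lies within ``d_thresh`` pixels of an unmatched ground
truth center of the same class (greedy one-to-one matching in ascending
distance order). Line accuracy is the mean horizontal pixel deviation (mpd)
between matched predicted and ground-truth lines, evaluated on the rows
where both exist.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .annotation import (
    KEYPOINT_CLASS_MAP,
    LabelMask,
    SemanticGraphic,
    rasterize_keypoints,
    rasterize_lines,
)
from .line_extraction import extract_dominant_lines, fit_line
from .training import images_to_batch

__all__ = [
    "EvalReport",
    "LineDeviation",
    "iou",
    "miou",
    "keypoint_prf",
    "greedy_match",
    "mean_pixel_deviation",
    "evaluate",
]

_EIGHT = np.ones((3, 3), dtype=int)


def _values(mask) -> np.ndarray:
    return mask.values if isinstance(mask, LabelMask) else np.asarray(mask)


def iou(pred, target, class_index: int) -> float:
    """|T n P| / |T u P| for one class; 1.0 when both sets are empty."""
    p, t = _values(pred), _values(target)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    pc, tc = p == class_index, t == class_index
    union = np.count_nonzero(pc | tc)
    if union == 0:
        return 1.0
    return np.count_nonzero(pc & tc) / union


def miou(pred, target, n_classes: int, include_background: bool = True) -> float:
    classes = range(0 if include_background else 1, n_classes)
    return float(np.mean([iou(pred, target, c) for c in classes]))


def greedy_match(distances: np.ndarray, threshold: float) -> list[tuple[int, int]]:
    """One-to-one matching of rows to columns, ascending distance.

    Pairs farther apart than ``threshold`` are never matched.
    """
    n, m = distances.shape
    order = np.argsort(distances, axis=None, kind="stable")
    used_r, used_c = set(), set()
    pairs = []
    for flat in order:
        r, c = divmod(int(flat), m)
        if distances[r, c] > threshold:
            break
        if r in used_r or c in used_c:
            continue
        used_r.add(r)
        used_c.add(c)
        pairs.append((r, c))
    return pairs


def _component_centroids(values: np.ndarray, class_index: int) -> np.ndarray:
    labeled, n = ndimage.label(values == class_index, structure=_EIGHT)
    if n == 0:
        return np.empty((0, 2))
    return np.asarray(ndimage.center_of_mass(values == class_index, labeled, range(1, n + 1)))


def keypoint_prf(
    pred,
    truth: list[tuple[str, tuple[float, float]]],
    d_thresh: float = 15.0,
    class_map: dict[str, int] | None = None,
) -> dict[str, dict[str, float]]:
    """Per-class precision/recall/F1 of predicted keypoints at ``d_thresh``.

    Predicted centers are centroids of 8-connected components of each
    foreground class in ``pred``; both-empty classes score 1.0 by convention.
    Returns {class: {precision, recall, f1, tp, fp, fn}}.
    """
    if d_thresh <= 0:
        raise ValueError("d_thresh must be > 0")
    class_map = class_map or KEYPOINT_CLASS_MAP
    values = _values(pred)
    out = {}
    for label, idx in class_map.items():
        if idx == 0:
            continue
        centers = _component_centroids(values, idx)
        gts = np.asarray([c for lab, c in truth if lab == label], dtype=np.float64).reshape(-1, 2)
        if len(centers) and len(gts):
            d = np.linalg.norm(centers[:, None, :] - gts[None, :, :], axis=2)
            tp = len(greedy_match(d, d_thresh))
        else:
            tp = 0
        fp = len(centers) - tp
        fn = len(gts) - tp
        out[label] = _prf_record(tp, fp, fn)
    return out


def _prf_record(tp: int, fp: int, fn: int) -> dict[str, float]:
    precision = tp / (tp + fp) if (tp + fp) else 1.0
    recall = tp / (tp + fn) if (tp + fn) else 1.0
    f1 = 2 * precision * recall / (precision + recall) if (precision + recall) else 0.0
    return {"precision": precision, "recall": recall, "f1": f1, "tp": tp, "fp": fp, "fn": fn}


@dataclass
class LineDeviation:
    """Pooled horizontal deviation between matched line sets."""

    mpd: float
    deviation_range: tuple[float, float]
    n_matched: int
    n_missed: int
    n_rows: int = 0


def _as_line(obj) -> tuple[float, float, tuple[float, float]]:
    if hasattr(obj, "slope_a"):
        return obj.slope_a, obj.intercept_b, obj.y_extent
    a, b, extent = obj
    return float(a), float(b), (float(extent[0]), float(extent[1]))


def mean_pixel_deviation(pred_lines, gt_lines, y_range=None) -> LineDeviation:
    """Match predictions to ground-truth lines and pool row-wise deviations.

    pd = |x_p - x_g| per shared row; mpd is the mean of pd over all rows of
    all matched lines; deviation_range is [min, max] of the signed
    differences. Unmatched ground-truth lines count as missed, not into mpd.
    With no predictions mpd is NaN.
    """
    gt = [_as_line(g) for g in gt_lines]
    if not gt:
        raise ValueError("at least one ground-truth line is required")
    pred = [_as_line(p) for p in pred_lines]
    if not pred:
        return LineDeviation(float("nan"), (float("nan"), float("nan")), 0, len(gt))

    def rows_for(p, g):
        y0 = max(p[2][0], g[2][0])
        y1 = min(p[2][1], g[2][1])
        if y_range is not None:
            y0, y1 = max(y0, y_range[0]), min(y1, y_range[1])
        if y1 < y0:
            return None
        return np.arange(int(np.ceil(y0)), int(np.floor(y1)) + 1)

    cost = np.full((len(pred), len(gt)), np.inf)
    for i, p in enumerate(pred):
        for j, g in enumerate(gt):
            ys = rows_for(p, g)
            if ys is None or len(ys) == 0:
                continue
            cost[i, j] = np.mean(np.abs((p[0] * ys + p[1]) - (g[0] * ys + g[1])))
    pairs = greedy_match(cost, np.inf)

    signed = []
    for i, j in pairs:
        p, g = pred[i], gt[j]
        ys = rows_for(p, g)
        signed.append((p[0] * ys + p[1]) - (g[0] * ys + g[1]))
    if not signed:
        return LineDeviation(float("nan"), (float("nan"), float("nan")), 0, len(gt))
    signed = np.concatenate(signed)
    return LineDeviation(
        mpd=float(np.mean(np.abs(signed))),
        deviation_range=(float(signed.min()), float(signed.max())),
        n_matched=len(pairs),
        n_missed=len(gt) - len(pairs),
        n_rows=int(signed.size),
    )


@dataclass
class EvalReport:
    """Aggregated metrics for one dataset evaluation."""

    task: str
    n_images: int
    per_class_iou: dict[str, float]
    miou: float
    miou_foreground: float
    keypoint_metrics: dict[str, dict[str, float]] = field(default_factory=dict)
    mpd: float | None = None
    deviation_range: tuple[float, float] | None = None
    missed_lines: int = 0

    def to_json(self, path=None) -> str:
        doc = {
            "task": self.task,
            "n_images": self.n_images,
            "per_class_iou": self.per_class_iou,
            "miou": self.miou,
            "miou_foreground": self.miou_foreground,
            "keypoint_metrics": self.keypoint_metrics,
            "mpd": self.mpd,
            "deviation_range": list(self.deviation_range) if self.deviation_range else None,
            "missed_lines": self.missed_lines,
        }
        text = json.dumps(doc, indent=1)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, text: str) -> "EvalReport":
        doc = json.loads(text)
        rng = doc.pop("deviation_range")
        return cls(deviation_range=tuple(rng) if rng else None, **doc)


def _predict_masks(model, images) -> np.ndarray:
    if hasattr(model, "predict"):
        return model.predict(images_to_batch(images))
    return np.stack([_values(model(im)) for im in images])


def gt_lines_from_graphic(graphic: SemanticGraphic) -> list:
    """Analytic (a, b, y_extent) for each ground-truth polyline."""
    out = []
    for line in graphic.polylines:
        pts = np.asarray(line, dtype=np.float64)
        a, b = fit_line(pts)
        out.append((a, b, (float(pts[:, 0].min()), float(pts[:, 0].max()))))
    return out


def evaluate(
    model,
    dataset,
    task: str,
    d_thresh: float = 15.0,
    n_lines: int = 4,
    line_thickness: int = 5,
    extract_lines: bool = True,
    per_image: bool = False,
) -> EvalReport:
    """Run a model over (image, SemanticGraphic) pairs and compute metrics.

    ``model`` is either a trained network (has ``predict``) or any callable
    mapping an image to a LabelMask — an oracle returning the ground truth
    reproduces perfect scores. IoU is pooled over the dataset unless
    ``per_image`` is set.
    """
    if task not in ("lines", "keypoints"):
        raise ValueError(f"unknown task {task!r}")
    images, graphics = [], []
    for image, graphic in dataset:
        images.append(np.asarray(image))
        graphics.append(graphic)
    if not images:
        raise ValueError("empty dataset")
    if task == "lines":
        gt_masks = [rasterize_lines(g, thickness=line_thickness) for g in graphics]
        class_map = gt_masks[0].class_map
    else:
        gt_masks = [rasterize_keypoints(g) for g in graphics]
        class_map = gt_masks[0].class_map
        for g in graphics:
            if not g.keypoints:
                raise ValueError("keypoint task but an annotation has no keypoints")
    n_classes = len(class_map)
    preds = _predict_masks(model, images)

    inter = np.zeros(n_classes, dtype=np.int64)
    union = np.zeros(n_classes, dtype=np.int64)
    per_image_iou = np.zeros(n_classes, dtype=np.float64)
    for pred, gt in zip(preds, gt_masks):
        for c in range(n_classes):
            pc, tc = pred == c, gt.values == c
            inter[c] += np.count_nonzero(pc & tc)
            union[c] += np.count_nonzero(pc | tc)
            per_image_iou[c] += iou(pred, gt.values, c)
    if per_image:
        class_iou = per_image_iou / len(preds)
    else:
        class_iou = np.where(union > 0, inter / np.maximum(union, 1), 1.0)
    inv_map = {v: k for k, v in class_map.items()}
    per_class = {inv_map[c]: float(class_iou[c]) for c in range(n_classes)}
    miou_all = float(class_iou.mean())
    miou_fg = float(class_iou[1:].mean())

    report = EvalReport(
        task=task,
        n_images=len(preds),
        per_class_iou=per_class,
        miou=miou_all,
        miou_foreground=miou_fg,
    )

    if task == "keypoints":
        counts = {lab: {"tp": 0, "fp": 0, "fn": 0} for lab in class_map if class_map[lab] != 0}
        for pred, graphic in zip(preds, graphics):
            truth = [(kp.class_label, kp.center) for kp in graphic.keypoints]
            prf = keypoint_prf(pred, truth, d_thresh=d_thresh, class_map=class_map)
            for lab, rec in prf.items():
                for k in ("tp", "fp", "fn"):
                    counts[lab][k] += rec[k]
        report.keypoint_metrics = {
            lab: _prf_record(c["tp"], c["fp"], c["fn"]) for lab, c in counts.items()
        }
    elif extract_lines:
        all_signed = []
        missed = 0
        n_matched = 0
        for pred, graphic in zip(preds, graphics):
            if not graphic.polylines:
                continue
            gt_lines = gt_lines_from_graphic(graphic)
            result = extract_dominant_lines(
                pred == class_map.get("line", 1), n_lines=min(n_lines, len(gt_lines)), d_thresh=d_thresh
            )
            dev = mean_pixel_deviation(result.lines, gt_lines)
            missed += dev.n_missed
            n_matched += dev.n_matched
            if dev.n_matched:
                all_signed.append(dev)
        if all_signed:
            # pool all rows of all matched lines across the dataset
            total_rows = sum(dev.n_rows for dev in all_signed)
            acc = sum(dev.mpd * dev.n_rows for dev in all_signed)
            lo = min(dev.deviation_range[0] for dev in all_signed)
            hi = max(dev.deviation_range[1] for dev in all_signed)
            report.mpd = acc / total_rows
            report.deviation_range = (lo, hi)
        else:
            report.mpd = float("nan")
            report.deviation_range = None
        report.missed_lines = missed
    return report
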