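"""Graphic annotations and their rasterization to label masks.

An annotation for one image is a :class:`SemanticGraphic`: polylines tracing
crop rows plus class-labeled keypoints (plant bases) with depth-scaled radii.
Training targets are integer label masks produced by rasterizing these
graphics; class imbalance is handled by inverse-frequency class weights.

Class index conventions: background = 0 always. The line task uses
{background: 0, line: 1}; the keypoint task uses
{background: 0, paddy: 1, millet: 2}.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

LINE_CLASS_MAP = {"background": 0, "line": 1}
KEYPOINT_CLASS_MAP = {"background": 0, "paddy": 1, "millet": 2}

__all__ = [
    "SemanticGraphic",
    "Keypoint",
    "LabelMask",
    "ClassWeights",
    "LINE_CLASS_MAP",
    "KEYPOINT_CLASS_MAP",
    "rasterize_lines",
    "rasterize_keypoints",
    "radius_from_depth",
    "compute_class_weights",
    "read_annotation",
    "write_annotation",
    "read_mask",
    "write_mask",
]


@dataclass
class Keypoint:
    """A plant-base marker: class label, (row, col) center, disc radius."""

    class_label: str
    center: tuple[float, float]
    radius: float

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError(f"keypoint radius must be > 0, got {self.radius}")


@dataclass
class SemanticGraphic:
    """Vector annotation for one image: row polylines and base keypoints."""

    image_shape: tuple[int, int]
    polylines: list[list[tuple[float, float]]] = field(default_factory=list)
    keypoints: list[Keypoint] = field(default_factory=list)

    def __post_init__(self):
        h, w = self.image_shape
        self.polylines = [
            [(min(max(r, 0.0), h - 1.0), min(max(c, 0.0), w - 1.0)) for r, c in line]
            for line in self.polylines
        ]
        for kp in self.keypoints:
            r, c = kp.center
            kp.center = (min(max(r, 0.0), h - 1.0), min(max(c, 0.0), w - 1.0))


@dataclass
class LabelMask:
    """Integer class map aligned to an image; background is class 0."""

    values: np.ndarray
    class_map: dict[str, int]

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("LabelMask values must be 2-D")
        if not np.issubdtype(self.values.dtype, np.integer):
            raise ValueError("LabelMask values must be integers")
        n_classes = len(self.class_map)
        if self.values.size and (self.values.min() < 0 or self.values.max() >= n_classes):
            raise ValueError(f"mask values must lie in [0, {n_classes})")

    @property
    def n_classes(self) -> int:
        return len(self.class_map)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class ClassWeights:
    """Positive per-class loss weights, indexed by class integer."""

    weights: np.ndarray

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if np.any(~np.isfinite(self.weights)) or np.any(self.weights <= 0):
            raise ValueError("class weights must be positive and finite")

    def as_array(self) -> np.ndarray:
        return self.weights


def _segment_distance_stamp(mask, p0, p1, radius):
    """Set mask pixels whose center lies within ``radius`` of segment p0-p1."""
    h, w = mask.shape
    r0, c0 = p0
    r1, c1 = p1
    rmin = max(int(np.floor(min(r0, r1) - radius)), 0)
    rmax = min(int(np.ceil(max(r0, r1) + radius)), h - 1)
    cmin = max(int(np.floor(min(c0, c1) - radius)), 0)
    cmax = min(int(np.ceil(max(c0, c1) + radius)), w - 1)
    if rmin > rmax or cmin > cmax:
        return
    rr, cc = np.mgrid[rmin : rmax + 1, cmin : cmax + 1]
    dr, dc = r1 - r0, c1 - c0
    seg_len2 = dr * dr + dc * dc
    if seg_len2 == 0:
        dist2 = (rr - r0) ** 2 + (cc - c0) ** 2
    else:
        t = ((rr - r0) * dr + (cc - c0) * dc) / seg_len2
        t = np.clip(t, 0.0, 1.0)
        dist2 = (rr - (r0 + t * dr)) ** 2 + (cc - (c0 + t * dc)) ** 2
    mask[rmin : rmax + 1, cmin : cmax + 1] |= dist2 <= radius * radius


def rasterize_lines(graphic: SemanticGraphic, thickness: int = 5) -> LabelMask:
    """Draw each polyline as a stroke of the given (odd) thickness, class 1.

    A stroke pixel is one whose center lies within thickness/2 of a segment
    (round caps/joins). Overlapping polylines label pixels idempotently. An
    empty polyline list yields an all-background mask; a single-point polyline
    yields a disc.
    """
    if thickness < 1 or thickness % 2 == 0:
        raise ValueError(f"thickness must be odd and >= 1, got {thickness}")
    h, w = graphic.image_shape
    fg = np.zeros((h, w), dtype=bool)
    radius = thickness / 2.0
    for line in graphic.polylines:
        if not line:
            continue
        if len(line) == 1:
            _segment_distance_stamp(fg, line[0], line[0], radius)
        for p0, p1 in zip(line[:-1], line[1:]):
            _segment_distance_stamp(fg, p0, p1, radius)
    return LabelMask(fg.astype(np.uint8), LINE_CLASS_MAP)


def _disc_indices(center, radius, shape):
    h, w = shape
    r0, c0 = center
    rmin = max(int(np.floor(r0 - radius)), 0)
    rmax = min(int(np.ceil(r0 + radius)), h - 1)
    cmin = max(int(np.floor(c0 - radius)), 0)
    cmax = min(int(np.ceil(c0 + radius)), w - 1)
    if rmin > rmax or cmin > cmax:
        return None
    rr, cc = np.mgrid[rmin : rmax + 1, cmin : cmax + 1]
    inside = (rr - r0) ** 2 + (cc - c0) ** 2 <= radius * radius
    return rr[inside], cc[inside]


def rasterize_keypoints(
    graphic: SemanticGraphic, class_map: dict[str, int] | None = None
) -> LabelMask:
    """Draw each keypoint as a filled disc of its class index.

    Disc membership is Euclidean distance <= radius on pixel centers, ties
    included. Later keypoints in list order overwrite earlier ones where
    discs overlap.
    """
    class_map = dict(class_map or KEYPOINT_CLASS_MAP)
    h, w = graphic.image_shape
    values = np.zeros((h, w), dtype=np.uint8)
    for kp in graphic.keypoints:
        if kp.class_label not in class_map:
            raise ValueError(f"unknown keypoint class {kp.class_label!r}")
        idx = _disc_indices(kp.center, kp.radius, (h, w))
        if idx is not None:
            values[idx] = class_map[kp.class_label]
    return LabelMask(values, class_map)


def radius_from_depth(y: float, y_near: float, y_far: float, r_near: float, r_far: float) -> float:
    """Depth-scaled keypoint radius: linear in image row, clamped.

    The image bottom (largest row index) is nearest the camera, so markers
    there get the larger radius; rows toward ``y_far`` shrink to ``r_far``.
    """
    if not (r_near >= r_far > 0):
        raise ValueError(f"need r_near >= r_far > 0, got {r_near}, {r_far}")
    if y_near == y_far:
        return float(r_near)
    if y_near < y_far:
        raise ValueError("y_near must be below y_far in the image (larger row index)")
    t = (y - y_far) / (y_near - y_far)
    return float(np.clip(r_far + t * (r_near - r_far), r_far, r_near))


def compute_class_weights(masks: list[LabelMask]) -> ClassWeights:
    """Inverse-frequency class weights over a set of training masks.

    weight_c = total_pixels / (L * pixels_of_class_c), so a perfectly uniform
    class distribution yields all-ones weights and
    sum_c weight_c * freq_c = 1.
    """
    if not masks:
        raise ValueError("at least one mask is required")
    n_classes = masks[0].n_classes
    class_map = masks[0].class_map
    counts = np.zeros(n_classes, dtype=np.int64)
    for m in masks:
        if m.n_classes != n_classes:
            raise ValueError("masks disagree on the number of classes")
        counts += np.bincount(m.values.ravel(), minlength=n_classes)
    if np.any(counts == 0):
        inv = {v: k for k, v in class_map.items()}
        missing = [inv.get(i, str(i)) for i in np.nonzero(counts == 0)[0]]
        raise ValueError(f"class(es) absent from all masks: {', '.join(missing)}")
    total = counts.sum()
    return ClassWeights(total / (n_classes * counts.astype(np.float64)))


# ---------------------------------------------------------------------------
# Serialization


def write_annotation(graphic: SemanticGraphic, path: str | Path):
    """Write a graphic as JSON (schema: polylines, keypoints, image_shape)."""
    doc = {
        "image_shape": [int(graphic.image_shape[0]), int(graphic.image_shape[1])],
        "polylines": [
            [[round(float(r), 3), round(float(c), 3)] for r, c in line]
            for line in graphic.polylines
        ],
        "keypoints": [
            {
                "class": kp.class_label,
                "center": [round(float(kp.center[0]), 3), round(float(kp.center[1]), 3)],
                "radius": round(float(kp.radius), 3),
            }
            for kp in graphic.keypoints
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1) + "\n")


def read_annotation(path: str | Path, known_classes=("paddy", "millet")) -> SemanticGraphic:
    """Read and validate an annotation JSON; missing keys default to empty."""
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"malformed annotation JSON at {path}: {exc}") from exc
    if "image_shape" not in doc:
        raise ValueError(f"annotation {path} missing required field 'image_shape'")
    shape = tuple(int(v) for v in doc["image_shape"])
    polylines = [[(float(r), float(c)) for r, c in line] for line in doc.get("polylines", [])]
    keypoints = []
    for i, item in enumerate(doc.get("keypoints", [])):
        label = item.get("class")
        if label not in known_classes:
            raise ValueError(f"annotation {path}: keypoint {i} has unknown class {label!r}")
        radius = float(item.get("radius", 0.0))
        if radius <= 0:
            raise ValueError(f"annotation {path}: keypoint {i} field 'radius' must be > 0")
        center = item.get("center")
        if not (isinstance(center, list) and len(center) == 2):
            raise ValueError(f"annotation {path}: keypoint {i} field 'center' malformed")
        keypoints.append(Keypoint(label, (float(center[0]), float(center[1])), radius))
    return SemanticGraphic(image_shape=shape, polylines=polylines, keypoints=keypoints)


def write_mask(mask: LabelMask, path: str | Path):
    """Store a mask as single-channel 8-bit PNG, class index as pixel value."""
    Image.fromarray(mask.values.astype(np.uint8), mode="L").save(path)


def read_mask(path: str | Path, class_map: dict[str, int]) -> LabelMask:
    values = np.asarray(Image.open(path).convert("L"), dtype=np.uint8)
    return LabelMask(values, class_map)
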