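"""Dominant-row extraction from a binary line mask.

A consensus-style procedure: the longest remaining connected segment seeds a
least-squares line (col as a function of row, so vertical rows are regular);
inliers within a horizontal distance threshold are gathered from all
remaining foreground pixels, the line is refit once, and the refit line with
its inliers is the dominant line. Its inlier pixels are removed and segments
mostly explained by it are excluded before seeding the next line.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "DominantLine",
    "ExtractionResult",
    "binarize",
    "segment_components",
    "fit_line",
    "extract_dominant_lines",
]

_EIGHT_CONNECTED = np.ones((3, 3), dtype=int)


@dataclass
class DominantLine:
    """Fitted straight line col = slope_a * row + intercept_b."""

    slope_a: float
    intercept_b: float
    inliers: np.ndarray  # (n, 2) int array of (row, col)
    y_extent: tuple[int, int]

    def x_at(self, rows) -> np.ndarray:
        return self.slope_a * np.asarray(rows, dtype=np.float64) + self.intercept_b

    def to_dict(self) -> dict:
        return {
            "a": self.slope_a,
            "b": self.intercept_b,
            "y_min": int(self.y_extent[0]),
            "y_max": int(self.y_extent[1]),
            "n_inliers": int(len(self.inliers)),
        }


@dataclass
class ExtractionResult:
    lines: list[DominantLine]
    requested: int

    @property
    def shortfall(self) -> int:
        return max(self.requested - len(self.lines), 0)


def binarize(scores: np.ndarray, line_class: int = 1) -> np.ndarray:
    """Foreground where the argmax over the class axis equals ``line_class``.

    Accepts (C, H, W) or (N, C, H, W) score arrays; a batch returns (N, H, W).
    """
    scores = np.asarray(scores)
    if scores.ndim == 3:
        return np.argmax(scores, axis=0) == line_class
    if scores.ndim == 4:
        return np.argmax(scores, axis=1) == line_class
    raise ValueError(f"expected 3-D or 4-D scores, got shape {scores.shape}")


def segment_components(mask: np.ndarray) -> list[np.ndarray]:
    """8-connected components as (n, 2) pixel arrays, longest first.

    Length is pixel count; ties break on the topmost-then-leftmost pixel so
    the ordering is deterministic.
    """
    mask = np.asarray(mask).astype(bool)
    labeled, n = ndimage.label(mask, structure=_EIGHT_CONNECTED)
    comps = []
    for lab in range(1, n + 1):
        rows, cols = np.nonzero(labeled == lab)
        comps.append(np.column_stack([rows, cols]))
    comps.sort(key=lambda p: (-len(p), int(p[0, 0]), int(p[0, 1])))
    return comps


def fit_line(points: np.ndarray) -> tuple[float, float]:
    """Least-squares fit of col = a * row + b.

    Requires at least two points spanning at least two distinct rows (a
    single-row point set has no defined line in this parameterization).
    """
    points = np.asarray(points, dtype=np.float64)
    if points.ndim != 2 or points.shape[0] < 2:
        raise ValueError("need at least 2 points")
    rows, cols = points[:, 0], points[:, 1]
    if np.unique(rows).size < 2:
        raise ValueError("all points lie in a single image row; line undefined")
    design = np.column_stack([rows, np.ones_like(rows)])
    (a, b), *_ = np.linalg.lstsq(design, cols, rcond=None)
    return float(a), float(b)


def _inliers_of(line, pixels: np.ndarray, d_thresh: float) -> np.ndarray:
    a, b = line
    resid = np.abs(pixels[:, 1] - (a * pixels[:, 0] + b))
    return pixels[resid <= d_thresh]


def extract_dominant_lines(
    mask: np.ndarray,
    n_lines: int = 4,
    d_thresh: float = 15.0,
    overlap_frac: float = 0.5,
    min_seed_pixels: int = 20,
) -> ExtractionResult:
    """Extract up to ``n_lines`` dominant lines from a binary mask.

    Per line: seed on the longest admissible remaining segment, fit, collect
    inliers within ``d_thresh`` horizontally from all remaining foreground
    pixels, refit, and take the refit line with its own inlier set (two
    fitting iterations total). The line's inliers are then removed and any
    segment with more than ``overlap_frac`` of its pixels among them is
    excluded from seeding. Returns fewer lines than requested (flagged via
    ``shortfall``) when no admissible seed remains.
    """
    if n_lines < 1:
        raise ValueError("n_lines must be >= 1")
    mask = np.asarray(mask).astype(bool)
    remaining = mask.copy()
    segments = segment_components(mask)
    active = list(range(len(segments)))
    lines: list[DominantLine] = []

    while len(lines) < n_lines:
        seed_idx = None
        for idx in active:
            seg = segments[idx]
            alive = seg[remaining[seg[:, 0], seg[:, 1]]]
            if len(alive) < max(min_seed_pixels, 2):
                continue
            if np.unique(alive[:, 0]).size < 2:
                continue
            if seed_idx is None or len(alive) > seed_idx[1]:
                seed_idx = (idx, len(alive), alive)
        if seed_idx is None:
            break
        idx, _, seed_pixels = seed_idx
        fg = np.column_stack(np.nonzero(remaining))
        line0 = fit_line(seed_pixels)
        inliers0 = _inliers_of(line0, fg, d_thresh)
        if np.unique(inliers0[:, 0]).size < 2:
            active.remove(idx)
            continue
        line1 = fit_line(inliers0)
        inliers1 = _inliers_of(line1, fg, d_thresh)
        if len(inliers1) == 0:
            active.remove(idx)
            continue
        y_extent = (int(inliers1[:, 0].min()), int(inliers1[:, 0].max()))
        lines.append(DominantLine(line1[0], line1[1], inliers1, y_extent))

        inlier_mask = np.zeros_like(remaining)
        inlier_mask[inliers1[:, 0], inliers1[:, 1]] = True
        remaining &= ~inlier_mask
        survivors = []
        for j in active:
            seg = segments[j]
            frac = np.count_nonzero(inlier_mask[seg[:, 0], seg[:, 1]]) / len(seg)
            if frac <= overlap_frac and j != idx:
                survivors.append(j)
        active = survivors

    return ExtractionResult(lines=lines, requested=n_lines)
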