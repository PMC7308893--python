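"""Sliding-window localisation shared by all patch classifiers.

Full scenes are scanned with a pyramidal structure of sliding windows:
the image is repeatedly downscaled by a constant factor and a
fixed-size window slides over every level with a constant stride, so a
single canonical-size classifier detects trunks of any apparent size.
Positive windows are mapped back to original-image coordinates and
merged by greedy non-maximum suppression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Iterator, Protocol

import numpy as np
from skimage.transform import rescale

from treestump.boxes import Box, box_iou, clip_box


@dataclass(frozen=True)
class WindowSpec:
    """Geometry of the sliding-window pyramid.

    ``scale`` is the downscaling factor of a level: at scale s the
    window covers ``s * window`` pixels of the original image.  Levels
    run from ``min_scale`` to ``max_scale`` in multiplicative steps of
    ``scale_factor``.
    """

    window_w: int = 64
    window_h: int = 64
    stride_px: int = 16
    scale_factor: float = 1.25
    min_scale: float = 1.0
    max_scale: float = 4.0

    def validate(self) -> None:
        if self.window_w <= 0 or self.window_h <= 0:
            raise ValueError("window dimensions must be positive")
        if self.stride_px <= 0 or self.stride_px > min(self.window_w, self.window_h):
            raise ValueError("stride must be positive and no larger than the window")
        if self.scale_factor <= 1.0:
            raise ValueError("scale_factor must exceed 1")
        if self.min_scale <= 0 or self.max_scale < self.min_scale:
            raise ValueError("scale bounds must satisfy 0 < min_scale <= max_scale")

    def scales(self) -> list[float]:
        out = []
        s = self.min_scale
        while s <= self.max_scale * (1 + 1e-9):
            out.append(s)
            s *= self.scale_factor
        return out


@dataclass
class Detection:
    """A scored, labelled box in original-image pixel coordinates."""

    box: Box
    score: float
    label: str = "tree"
    scale: float = 1.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.score):
            raise ValueError("detection scores must be finite")


def _axis_offsets(extent: int, window: int, stride: int) -> list[int]:
    """Window offsets along one axis; the final window is snapped to the
    image edge so every pixel is covered when stride <= window."""
    offs = list(range(0, extent - window + 1, stride))
    if offs and offs[-1] != extent - window:
        offs.append(extent - window)
    return offs


def pyramid_windows(
    image: np.ndarray, spec: WindowSpec = WindowSpec()
) -> Iterator[tuple[np.ndarray, Box, float]]:
    """Yield ``(patch, box, scale)`` over every pyramid level.

    Boxes are half-open original-image coordinates (clamped to the image
    extent); the patch is the window crop at the level's resolution.
    An image smaller than the window at every scale yields nothing,
    with a warning.
    """
    spec.validate()
    image = np.asarray(image, dtype=float)
    h, w = image.shape[:2]
    yielded = False
    for s in spec.scales():
        if abs(s - 1.0) < 1e-12:
            level = image
        else:
            level = rescale(image, 1.0 / s, channel_axis=2 if image.ndim == 3 else None,
                            anti_aliasing=s > 1.0, mode="reflect")
        lh, lw = level.shape[:2]
        if lw < spec.window_w or lh < spec.window_h:
            continue
        for y in _axis_offsets(lh, spec.window_h, spec.stride_px):
            for x in _axis_offsets(lw, spec.window_w, spec.stride_px):
                patch = level[y:y + spec.window_h, x:x + spec.window_w]
                box = clip_box(
                    (x * s, y * s, (x + spec.window_w) * s, (y + spec.window_h) * s),
                    w, h,
                )
                yielded = True
                yield patch, box, s
    if not yielded:
        warnings.warn("image smaller than the window at every pyramid scale")


class PatchClassifier(Protocol):
    """Anything that scores a batch of RGB patches (positive = trunk)."""

    def predict_score(self, patches: np.ndarray) -> np.ndarray: ...


def classify_windows(
    windows: Iterable[tuple[np.ndarray, Box, float]],
    classifier: PatchClassifier,
    score_threshold: float = 0.0,
    batch_size: int = 256,
) -> list[Detection]:
    """Score every window and keep those above the positive threshold.

    The classifier receives batches of same-size window patches; its
    continuous margins become detection scores.  The default threshold
    of 0 is the SVM decision boundary; raising it trades recall for
    precision.
    """
    detections: list[Detection] = []
    buf: list[tuple[np.ndarray, Box, float]] = []

    def flush() -> None:
        if not buf:
            return
        scores = classifier.predict_score(np.stack([p for p, _, _ in buf]))
        for (patch, box, scale), score in zip(buf, scores):
            if score > score_threshold:
                detections.append(Detection(box=box, score=float(score), scale=scale))
        buf.clear()

    for item in windows:
        buf.append(item)
        if len(buf) >= batch_size:
            flush()
    flush()
    return detections


def nms(detections: list[Detection], iou_threshold: float = 0.3) -> list[Detection]:
    """Greedy score-descending non-maximum suppression.

    Repeatedly keeps the highest-scoring remaining detection and drops
    every other detection whose IoU with it exceeds the threshold.  Ties
    break on input order, so the result is deterministic.
    """
    if not 0.0 < iou_threshold < 1.0:
        raise ValueError("iou_threshold must lie in (0, 1)")
    order = sorted(range(len(detections)),
                   key=lambda i: (-detections[i].score, i))
    kept: list[Detection] = []
    suppressed = set()
    for i in order:
        if i in suppressed:
            continue
        kept.append(detections[i])
        for j in order:
            if j != i and j not in suppressed and \
                    box_iou(detections[i].box, detections[j].box) > iou_threshold:
                suppressed.add(j)
    return kept


def detect_stumps(
    image: np.ndarray,
    classifier: PatchClassifier,
    spec: WindowSpec = WindowSpec(),
    score_threshold: float = 0.0,
    nms_iou: float = 0.3,
) -> list[Detection]:
    """Full detection pass: pyramid windows, classification, NMS."""
    dets = classify_windows(pyramid_windows(image, spec), classifier,
                            score_threshold=score_threshold)
    return nms(dets, iou_threshold=nms_iou)
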