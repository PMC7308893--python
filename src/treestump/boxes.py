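"""Axis-aligned box utilities.

Boxes are 0-based, half-open ``(x0, y0, x1, y1)`` tuples in pixel
coordinates with ``x0 < x1`` and ``y0 < y1``.  Every module uses this one
convention; conversions happen only at file I/O.
"""

from __future__ import annotations

from typing import Sequence

Box = tuple[float, float, float, float]


def validate_box(box: Sequence[float]) -> Box:
    x0, y0, x1, y1 = box
    if not (x0 < x1 and y0 < y1):
        raise ValueError(f"degenerate box {box!r}: requires x0 < x1 and y0 < y1")
    return (float(x0), float(y0), float(x1), float(y1))


def box_area(box: Sequence[float]) -> float:
    x0, y0, x1, y1 = box
    return max(0.0, x1 - x0) * max(0.0, y1 - y0)


def box_intersection_area(a: Sequence[float], b: Sequence[float]) -> float:
    x0 = max(a[0], b[0])
    y0 = max(a[1], b[1])
    x1 = min(a[2], b[2])
    y1 = min(a[3], b[3])
    return max(0.0, x1 - x0) * max(0.0, y1 - y0)


def box_iou(a: Sequence[float], b: Sequence[float]) -> float:
    """Intersection over union of two half-open boxes, in [0, 1]."""
    inter = box_intersection_area(a, b)
    if inter == 0.0:
        return 0.0
    union = box_area(a) + box_area(b) - inter
    return inter / union


def clip_box(box: Sequence[float], width: float, height: float) -> Box:
    """Clamp a box to the image extent ``[0, width) x [0, height)``."""
    x0 = min(max(box[0], 0.0), width)
    y0 = min(max(box[1], 0.0), height)
    x1 = min(max(box[2], 0.0), width)
    y1 = min(max(box[3], 0.0), height)
    return (x0, y0, x1, y1)


def box_within(box: Sequence[float], width: float, height: float) -> bool:
    x0, y0, x1, y1 = box
    return 0 <= x0 < x1 <= width and 0 <= y0 < y1 <= height


def expand_to_square(box: Sequence[float], margin_frac: float = 0.0) -> Box:
    """Grow a box to a square about its centre, with optional relative margin."""
    x0, y0, x1, y1 = box
    cx, cy = (x0 + x1) / 2.0, (y0 + y1) / 2.0
    side = max(x1 - x0, y1 - y0) * (1.0 + margin_frac)
    h = side / 2.0
    return (cx - h, cy - h, cx + h, cy + h)
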