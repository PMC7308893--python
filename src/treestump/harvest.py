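"""Street-level data assembly: road sampling, stitching, triangulation.

Large eye-level corpora are assembled by sampling capture points along
roads (from a binary road mask), fetching several narrow views per
point at different compass headings, stitching them into a wide
panorama, and -- once trunks are detected in multiple views --
triangulating each trunk's ground position from bearing rays.

Network fetching is deliberately out of scope: a ``Fetcher`` is any
callable ``(location, heading_deg) -> image``, and a disk-backed
fixture fetcher is provided, so the full pipeline runs on local data.
Stitching uses a pure horizontal-translation model with normalised
cross-correlation offset search and linear seam blending, which is
adequate for narrow-baseline views captured from a single point.
Coordinates are planar local metres (east, north); compass bearings are
degrees clockwise from north.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from skimage.measure import label as cc_label
from skimage.morphology import skeletonize

Fetcher = Callable[[tuple[float, float], float], np.ndarray]


@dataclass(frozen=True)
class CameraPose:
    """Planar camera pose: position in metres, optical-axis bearing."""

    east: float
    north: float
    heading_deg: float
    hfov_deg: float = 90.0

    def __post_init__(self) -> None:
        if not 0.0 < self.hfov_deg < 180.0:
            raise ValueError("horizontal field of view must lie in (0, 180) degrees")
        object.__setattr__(self, "heading_deg", self.heading_deg % 360.0)


@dataclass
class PanoramaResult:
    """Stitched panorama with per-source placements and seam quality."""

    image: np.ndarray
    source_offsets: list[int]
    seam_error: float

    def __post_init__(self) -> None:
        if self.seam_error < 0:
            raise ValueError("seam error must be non-negative")


class StitchError(RuntimeError):
    """No acceptable overlap could be found between neighbouring views."""


def sample_road_points(road_mask: np.ndarray, spacing_px: float) -> list[tuple[int, int]]:
    """Sample capture points along road centrelines at a fixed arc spacing.

    The mask is skeletonised; each skeleton component is walked from an
    endpoint (or its lexicographically smallest pixel for loops),
    emitting a point whenever the accumulated arc length since the last
    emitted point reaches ``spacing_px``.  Every returned (x, y) lies on
    a mask-true pixel.  Deterministic for a fixed mask.
    """
    road_mask = np.asarray(road_mask, dtype=bool)
    if spacing_px < 1:
        raise ValueError("spacing must be at least 1 pixel")
    if not road_mask.any():
        return []
    skel = skeletonize(road_mask)
    points: list[tuple[int, int]] = []
    labels = cc_label(skel, connectivity=2)
    for comp_id in range(1, labels.max() + 1):
        comp = labels == comp_id
        pix = {(int(y), int(x)) for y, x in zip(*np.nonzero(comp))}

        def neighbours(p: tuple[int, int]) -> list[tuple[int, int]]:
            y, x = p
            out = []
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    if (dy or dx) and (y + dy, x + dx) in pix:
                        out.append((y + dy, x + dx))
            return out

        endpoints = sorted(p for p in pix if len(neighbours(p)) <= 1)
        start = endpoints[0] if endpoints else min(pix)
        visited = {start}
        current = start
        acc = float("inf")  # emit the first pixel of each component
        while True:
            if acc >= spacing_px:
                points.append((current[1], current[0]))
                acc = 0.0
            nxt = [p for p in sorted(neighbours(current)) if p not in visited]
            if not nxt:
                break
            step = nxt[0]
            acc += math.hypot(step[0] - current[0], step[1] - current[1])
            visited.add(step)
            current = step
    return points


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    """Normalised cross-correlation of two equal-shape arrays."""
    a = a.ravel() - a.mean()
    b = b.ravel() - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom == 0:
        return 0.0
    return float(a @ b / denom)


def _pairwise_offset(left: np.ndarray, right: np.ndarray,
                     overlap_hint: int | None, min_overlap: int = 16,
                     ncc_floor: float = 0.2) -> tuple[int, float]:
    """Horizontal offset of ``right`` relative to ``left`` by NCC search.

    Returns (offset, seam_error) where offset is the column of ``left``
    at which ``right`` begins.  Raises StitchError when the best
    correlation falls below the floor.
    """
    wl = left.shape[1]
    wr = right.shape[1]
    if overlap_hint is not None:
        lo = max(min_overlap, overlap_hint // 2)
        hi = min(wl, wr, overlap_hint * 2)
    else:
        lo, hi = min_overlap, min(wl, wr)
    best_ncc, best_off = -np.inf, None
    for ov in range(lo, hi + 1):
        score = _ncc(left[:, wl - ov:], right[:, :ov])
        if score > best_ncc:
            best_ncc, best_off = score, wl - ov
    if best_off is None or best_ncc < ncc_floor:
        raise StitchError(
            f"no acceptable horizontal overlap found (best NCC {best_ncc:.3f})"
        )
    ov = wl - best_off
    seam = float(np.mean(np.abs(left[:, best_off:] - right[:, :ov])))
    return best_off, seam


def stitch_panorama(
    images: Sequence[np.ndarray],
    poses: Sequence[CameraPose] | None = None,
    overlap_hint: int | None = None,
) -> PanoramaResult:
    """Stitch horizontally overlapping views into one wide panorama.

    Views are ordered left to right (by heading when poses are given),
    pairwise offsets are estimated by normalised cross-correlation in
    the expected overlap band, and overlaps are composited with a
    linear blend ramp.  Pixels outside any overlap are copied verbatim
    from their source, so cropping the panorama back at the recorded
    offsets reproduces each source exactly there.  A single image
    returns itself with seam error 0.
    """
    if len(images) == 0:
        raise ValueError("stitching requires at least one image")
    images = [np.asarray(im, dtype=float) for im in images]
    heights = {im.shape[0] for im in images}
    if len(heights) != 1:
        raise ValueError("all source images must share height")
    if poses is not None:
        if len(poses) != len(images):
            raise ValueError("one pose per image required")
        order = sorted(range(len(images)), key=lambda i: poses[i].heading_deg)
        images = [images[i] for i in order]
    if len(images) == 1:
        return PanoramaResult(image=images[0].copy(), source_offsets=[0], seam_error=0.0)

    offsets = [0]
    seams = []
    for left, right in zip(images[:-1], images[1:]):
        off, seam = _pairwise_offset(left, right, overlap_hint)
        offsets.append(offsets[-1] + off)
        seams.append(seam)

    width = max(off + im.shape[1] for off, im in zip(offsets, images))
    h = images[0].shape[0]
    shape = (h, width) + images[0].shape[2:]
    canvas = np.zeros(shape)
    weight = np.zeros((h, width))
    for idx, (off, im) in enumerate(zip(offsets, images)):
        w_im = im.shape[1]
        ramp = np.ones(w_im)
        # blend only where this image overlaps its left neighbour
        if idx > 0:
            left_ov = max(0, offsets[idx - 1] + images[idx - 1].shape[1] - off)
            ramp[:left_ov] = np.linspace(1.0 / (left_ov + 1), 1.0, left_ov)
        wmap = np.broadcast_to(ramp, (h, w_im))
        contrib = im * wmap[..., None] if im.ndim == 3 else im * wmap
        canvas[:, off:off + w_im] += contrib
        weight[:, off:off + w_im] += wmap
    nz = weight > 0
    if canvas.ndim == 3:
        canvas[nz] /= weight[nz][:, None]
    else:
        canvas[nz] /= weight[nz]
    return PanoramaResult(image=canvas, source_offsets=offsets,
                          seam_error=float(np.mean(seams)))


def bearing_of_detection(detection_box: Sequence[float], image_width_px: int,
                         pose: CameraPose) -> float:
    """Compass bearing of a detection under the linear pinhole approximation.

    The horizontal position of the box centre maps linearly across the
    field of view: a centred box looks along the optical axis, the right
    edge looks ``hfov/2`` clockwise of it.
    """
    x0, _, x1, _ = detection_box
    if not 0 <= x0 < x1 <= image_width_px:
        raise ValueError("detection box must lie within the image")
    centre = (x0 + x1) / 2.0
    return (pose.heading_deg + (centre / image_width_px - 0.5) * pose.hfov_deg) % 360.0


def triangulate(
    observations: Sequence[tuple[CameraPose, float]],
    parallel_tol_deg: float = 0.5,
) -> tuple[float, float, float]:
    """Least-squares intersection of bearing rays from known poses.

    Each observation is (pose, bearing_deg).  Minimises the sum of
    squared perpendicular distances from the solution to every ray;
    the returned residual is the RMS of those distances.  Raises when
    fewer than two observations are given or all bearings are parallel
    within ``parallel_tol_deg``.
    """
    if len(observations) < 2:
        raise ValueError("triangulation requires at least two observations")
    bearings = [b % 180.0 for _, b in observations]
    spread = max(bearings) - min(bearings)
    if min(spread, 180.0 - spread) < parallel_tol_deg and len(set(bearings)) >= 1:
        if all(min(abs(b - bearings[0]), 180 - abs(b - bearings[0])) < parallel_tol_deg
               for b in bearings):
            raise ValueError("degenerate geometry: all bearings are parallel")
    A = np.zeros((2, 2))
    rhs = np.zeros(2)
    normals = []
    origins = []
    for pose, bearing in observations:
        theta = math.radians(bearing)
        # ray direction (east, north); normal is perpendicular to it
        n = np.array([math.cos(theta), -math.sin(theta)])
        p = np.array([pose.east, pose.north])
        A += np.outer(n, n)
        rhs += np.outer(n, n) @ p
        normals.append(n)
        origins.append(p)
    solution = np.linalg.solve(A, rhs)
    dists = [float(n @ (solution - p)) for n, p in zip(normals, origins)]
    residual = float(np.sqrt(np.mean(np.square(dists))))
    return float(solution[0]), float(solution[1]), residual


def disk_fetcher(root: str | Path, loader: Callable[[Path], np.ndarray]) -> Fetcher:
    """Fixture fetcher reading ``<root>/<east>_<north>_<heading>.png``.

    Stands in for a live street-imagery service: any callable with the
    same signature can be swapped in.
    """
    root = Path(root)

    def fetch(location: tuple[float, float], heading_deg: float) -> np.ndarray:
        east, north = location
        path = root / f"{east:g}_{north:g}_{heading_deg:g}.png"
        if not path.exists():
            raise FileNotFoundError(f"no fixture image for {path.name} under {root}")
        return loader(path)

    return fetch
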