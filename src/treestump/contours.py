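"""Edge-based trunk delineation: Gabor edges, segments and linking.

The engineered approach refines the bark-colour gate with structural
constraints: trunk-like regions must be bounded by a pair of roughly
parallel, near-vertical edges enclosing high bark-likelihood pixels.
Candidate *segments* (short paired-edge runs) are then iteratively
concatenated into full trunks whenever two segments agree in direction
and width and the vertical gap between them is itself bark-likely --
repeated greedily until no further joining is possible.

This engineered pipeline is retained in full even though, by design, it
is expected to be the weakest of the three detectors on cluttered
scenes; it exists as the conventional-computer-vision baseline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import correlate
from skimage.filters import gabor_kernel
from skimage.measure import label as cc_label

from treestump.boxes import Box
from treestump.colormodel import LikelihoodMap


@dataclass
class EdgeMap:
    """Max-over-bank Gabor response magnitude and winning edge orientation.

    ``orientation`` is the edge direction in radians in [0, pi), where
    pi/2 denotes a vertical edge.
    """

    magnitude: np.ndarray
    orientation: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.magnitude < 0):
            raise ValueError("edge magnitudes must be non-negative")
        if self.magnitude.shape != self.orientation.shape:
            raise ValueError("magnitude and orientation must share shape")


@dataclass
class StumpSegment:
    """One paired-edge trunk candidate.

    ``centerline`` runs top to bottom in (x, y) pixel coordinates;
    ``direction_deg`` is the tilt of the principal axis from vertical
    (0 = perfectly vertical); ``mean_likelihood`` is the mean bark-model
    Mahalanobis distance inside the segment (lower = more bark-like).
    """

    centerline: list[tuple[float, float]]
    mean_width_px: float
    direction_deg: float
    mean_likelihood: float
    left_edge: list[tuple[float, float]] = field(default_factory=list)
    right_edge: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.centerline) < 2:
            raise ValueError("a segment needs at least 2 centerline points")
        if self.mean_width_px <= 0:
            raise ValueError("segment width must be positive")
        if abs(self.direction_deg) > 90:
            raise ValueError("direction must lie within +/-90 degrees of vertical")

    @property
    def top(self) -> tuple[float, float]:
        return self.centerline[0]

    @property
    def bottom(self) -> tuple[float, float]:
        return self.centerline[-1]

    @property
    def length_px(self) -> float:
        return self.bottom[1] - self.top[1] + 1


@dataclass
class Stump:
    """An ordered chain of linked segments forming one trunk."""

    segments: list[StumpSegment]

    @property
    def bounding_box(self) -> Box:
        xs = [x for s in self.segments for x, _ in s.left_edge + s.right_edge + s.centerline]
        ys = [y for s in self.segments for _, y in s.left_edge + s.right_edge + s.centerline]
        return (min(xs), min(ys), max(xs) + 1, max(ys) + 1)

    @property
    def mean_width_px(self) -> float:
        total = sum(s.length_px for s in self.segments)
        return sum(s.mean_width_px * s.length_px for s in self.segments) / total

    @property
    def direction_deg(self) -> float:
        (x0, y0), (x1, y1) = self.segments[0].top, self.segments[-1].bottom
        if y1 == y0:
            return 0.0
        return math.degrees(math.atan2(x1 - x0, y1 - y0))


def gabor_edges(
    image_gray: np.ndarray,
    frequencies: tuple[float, ...] = (0.1, 0.2),
    orientations_deg: tuple[float, ...] = (0.0, 45.0, 90.0, 135.0),
) -> EdgeMap:
    """Detect edges with a Gabor filter bank.

    Each (frequency, orientation) pair contributes the response energy
    ``sqrt(real^2 + imag^2)`` of the complex Gabor filter; the real part
    is DC-corrected so constant images produce zero response.  The
    per-pixel magnitude is the max over the bank and the orientation is
    the *edge* direction of the winning filter (a filter whose harmonic
    varies along x responds to vertical edges).
    """
    image_gray = np.asarray(image_gray, dtype=float)
    if image_gray.ndim != 2:
        raise ValueError("gabor_edges expects a 2-D grayscale image")
    if len(frequencies) == 0 or len(orientations_deg) == 0:
        raise ValueError("the filter bank needs at least one frequency and orientation")
    magnitude = np.zeros_like(image_gray)
    orientation = np.zeros_like(image_gray)
    for theta_deg in orientations_deg:
        theta = math.radians(theta_deg)
        edge_dir = (theta + math.pi / 2.0) % math.pi
        for freq in frequencies:
            kern = gabor_kernel(frequency=freq, theta=theta)
            k_re = np.real(kern)
            k_re = k_re - k_re.mean()          # DC removal
            k_im = np.imag(kern)
            resp_re = correlate(image_gray, k_re, mode="reflect")
            resp_im = correlate(image_gray, k_im, mode="reflect")
            energy = np.hypot(resp_re, resp_im)
            better = energy > magnitude
            magnitude[better] = energy[better]
            orientation[better] = edge_dir
    return EdgeMap(magnitude=magnitude, orientation=orientation)


@dataclass(frozen=True)
class SegmentParams:
    """Acceptance rules for paired-edge segments."""

    min_height_px: int = 12
    min_width_px: int = 3
    min_fill: float = 0.6               # bark fraction of the enclosed region
    max_direction_deg: float = 30.0     # near-vertical gate
    min_edge_support: float = 0.05      # mean Gabor magnitude along each edge


def extract_stump_segments(
    edge_map: EdgeMap,
    bark_mask: np.ndarray,
    likelihood_map: LikelihoodMap | None,
    params: SegmentParams = SegmentParams(),
) -> list[StumpSegment]:
    """Extract paired-edge trunk segments enclosing bark-likely regions.

    Connected bark-mask regions are traced row by row into left/right
    edge chains; a region becomes a segment when it is tall enough,
    near-vertical, sufficiently filled with bark pixels between its two
    edges, and both edge chains are supported by Gabor edge energy.
    Segments are returned sorted by topmost centerline point.
    """
    bark_mask = np.asarray(bark_mask, dtype=bool)
    if bark_mask.shape != edge_map.magnitude.shape:
        raise ValueError("edge map and bark mask must share shape")
    if likelihood_map is not None and likelihood_map.distances.shape != bark_mask.shape:
        raise ValueError("likelihood map and bark mask must share shape")
    if not bark_mask.any():
        return []
    segments: list[StumpSegment] = []
    labels = cc_label(bark_mask, connectivity=2)
    for region_id in range(1, labels.max() + 1):
        region = labels == region_id
        rows = np.flatnonzero(region.any(axis=1))
        if len(rows) < params.min_height_px:
            continue
        left, right, centre, widths = [], [], [], []
        for y in rows:
            cols = np.flatnonzero(region[y])
            lo, hi = cols[0], cols[-1]
            left.append((float(lo), float(y)))
            right.append((float(hi), float(y)))
            centre.append(((lo + hi) / 2.0, float(y)))
            widths.append(hi - lo + 1)
        widths = np.asarray(widths, dtype=float)
        mean_width = float(widths.mean())
        if mean_width < params.min_width_px:
            continue
        # enclosed-region fill: bark pixels over the area between the edges
        fill = region.sum() / widths.sum()
        if fill < params.min_fill:
            continue
        xs = np.array([c[0] for c in centre])
        ys = np.array([c[1] for c in centre])
        slope = np.polyfit(ys, xs, 1)[0] if len(rows) > 1 else 0.0
        direction = math.degrees(math.atan(slope))
        if abs(direction) > params.max_direction_deg:
            continue
        mags = edge_map.magnitude
        left_support = float(np.mean([mags[int(y), int(x)] for x, y in left]))
        right_support = float(np.mean([mags[int(y), int(x)] for x, y in right]))
        if min(left_support, right_support) < params.min_edge_support:
            continue
        if likelihood_map is not None:
            mean_like = float(likelihood_map.distances[region].mean())
        else:
            mean_like = float("nan")
        segments.append(StumpSegment(
            centerline=centre,
            mean_width_px=mean_width,
            direction_deg=direction,
            mean_likelihood=mean_like,
            left_edge=left,
            right_edge=right,
        ))
    segments.sort(key=lambda s: (s.top[1], s.top[0]))
    return segments


@dataclass(frozen=True)
class LinkParams:
    """Compatibility rules for joining two vertically adjacent candidates."""

    max_angle_diff_deg: float = 20.0
    max_width_ratio: float = 1.5
    max_gap_px: float | None = None     # None -> 0.5 x mean segment length
    min_gap_likelihood_fill: float = 0.5
    gap_tau: float = 3.0                # bark acceptance threshold in the corridor


def _gap_fill(upper: Stump, lower: Stump, likelihood: LikelihoodMap | None,
              tau: float) -> float:
    """Fraction of bark-likely pixels in the corridor between two chains."""
    if likelihood is None:
        return 1.0
    (bx, by) = upper.segments[-1].bottom
    (tx, ty) = lower.segments[0].top
    if ty - by < 1.5:
        return 1.0   # touching chains: nothing to bridge
    half_w = (upper.mean_width_px + lower.mean_width_px) / 4.0
    h, w = likelihood.distances.shape
    y0, y1 = int(math.ceil(by)) + 1, int(math.floor(ty))
    samples = []
    for y in range(max(0, y0), min(h, y1)):
        t = (y - by) / (ty - by)
        cx = bx + t * (tx - bx)
        x0 = int(round(cx - half_w))
        x1 = int(round(cx + half_w)) + 1
        row = likelihood.distances[y, max(0, x0):min(w, x1)]
        if row.size:
            samples.append(row <= tau)
    if not samples:
        return 1.0
    return float(np.concatenate(samples).mean())


def _compatible(upper: Stump, lower: Stump, params: LinkParams,
                likelihood: LikelihoodMap | None, max_gap: float) -> float | None:
    """Pair score in [0, 1] if two chains may join, else None."""
    angle = abs(upper.segments[-1].direction_deg - lower.segments[0].direction_deg)
    if angle > params.max_angle_diff_deg:
        return None
    wa, wb = upper.mean_width_px, lower.mean_width_px
    ratio = max(wa, wb) / min(wa, wb)
    if ratio > params.max_width_ratio:
        return None
    gap = lower.segments[0].top[1] - upper.segments[-1].bottom[1]
    if gap < 0 or gap > max_gap:
        return None
    # the connecting line must stay near-vertical too
    (bx, by) = upper.segments[-1].bottom
    (tx, ty) = lower.segments[0].top
    if ty > by:
        bridge = abs(math.degrees(math.atan2(tx - bx, ty - by)))
        if bridge > 2 * params.max_angle_diff_deg:
            return None
    fill = _gap_fill(upper, lower, likelihood, params.gap_tau)
    if fill < params.min_gap_likelihood_fill:
        return None
    angle_score = 1.0 - angle / params.max_angle_diff_deg
    width_score = 1.0 - (ratio - 1.0) / max(params.max_width_ratio - 1.0, 1e-9)
    return (angle_score + width_score + fill) / 3.0


def link_segments(
    segments: list[StumpSegment],
    params: LinkParams = LinkParams(),
    likelihood_map: LikelihoodMap | None = None,
) -> list[Stump]:
    """Greedily concatenate segments into trunks until a fixed point.

    At each round every ordered pair of chains (upper above lower) is
    tested for compatibility -- direction difference, width ratio,
    vertical gap, and bark-likelihood fill of the connecting corridor --
    and the best-scoring pair is merged.  Ties break on the lowest
    (upper, lower) index pair after sorting chains by topmost point, so
    the output is independent of input order.  The result partitions the
    input segments.
    """
    chains = [Stump(segments=[s]) for s in segments]
    chains.sort(key=lambda c: (c.segments[0].top[1], c.segments[0].top[0]))
    if not chains:
        return []
    if params.max_gap_px is not None:
        max_gap = params.max_gap_px
    else:
        max_gap = 0.5 * float(np.mean([s.length_px for s in segments]))
    while True:
        best: tuple[float, int, int] | None = None
        for i, upper in enumerate(chains):
            for j, lower in enumerate(chains):
                if i == j:
                    continue
                if lower.segments[0].top[1] < upper.segments[-1].bottom[1]:
                    continue
                score = _compatible(upper, lower, params, likelihood_map, max_gap)
                if score is None:
                    continue
                if best is None or score > best[0] + 1e-12:
                    best = (score, i, j)
        if best is None:
            break
        _, i, j = best
        merged = Stump(segments=chains[i].segments + chains[j].segments)
        chains = [c for k, c in enumerate(chains) if k not in (i, j)] + [merged]
        chains.sort(key=lambda c: (c.segments[0].top[1], c.segments[0].top[0]))
    return chains
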