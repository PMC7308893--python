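"""Synthetic suburban scenes with exact tree-trunk ground truth.

Street-level imagery of suburban scenes cannot be redistributed, so this
module procedurally emulates its relevant statistics: vertically
elongated, striated, brown/grey bark-textured trunks of varying width,
height and hue, embedded among clutter (lamp-post-like poles, box-like
structures, bush-like blobs) over gradient or textured backgrounds.
Every generated scene carries exact bounding boxes and per-trunk paint
masks, so detectors can be trained and scored without any downloads.

All generators are pure functions of their configuration: the same seed
produces byte-identical output.  A ``difficulty`` knob monotonically
increases the number of bark-coloured (confusable) clutter objects,
which is how detector-ordering experiments vary the hardness of the
discrimination task.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from skimage.draw import ellipse as draw_ellipse
from skimage.transform import resize

from treestump.boxes import Box, box_intersection_area, box_iou, clip_box
from treestump.seeds import derive_seed

# (mean RGB, per-channel spread) pairs spanning common bark hues:
# mid brown, dark brown, grey-brown, reddish brown, pale grey.
DEFAULT_BARK_PALETTE: tuple[tuple[tuple[float, float, float], float], ...] = (
    ((0.42, 0.30, 0.20), 0.04),
    ((0.30, 0.22, 0.16), 0.04),
    ((0.50, 0.44, 0.38), 0.04),
    ((0.45, 0.28, 0.18), 0.04),
    ((0.55, 0.50, 0.46), 0.04),
)

_CLUTTER_KINDS = ("pole", "box", "blob")


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of one synthetic suburban scene.

    Trunk aspect ratios implied by the default ranges span roughly 1:4
    to 1:12 (width:height), matching the elongation of real trunks seen
    at eye level.  ``difficulty`` in [0, 1] scales the number of
    bark-coloured clutter objects from 0 to ``max_confusable``.
    """

    width_px: int = 320
    height_px: int = 240
    n_stumps: int = 3
    stump_width_range_px: tuple[int, int] = (10, 28)
    stump_height_range_px: tuple[int, int] = (60, 160)
    bark_palette: Sequence[tuple[tuple[float, float, float], float]] = DEFAULT_BARK_PALETTE
    n_clutter: int = 8
    clutter_kinds: tuple[str, ...] = _CLUTTER_KINDS
    background_kind: str = "gradient"
    difficulty: float = 0.0
    max_confusable: int = 8
    non_overlapping: bool = True
    canopy_prob: float = 0.7
    stria_strength: float = 0.35
    seed: int = 0

    def validate(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("scene dimensions must be positive")
        if self.n_stumps < 0 or self.n_clutter < 0:
            raise ValueError("object counts must be non-negative")
        for lo, hi in (self.stump_width_range_px, self.stump_height_range_px):
            if lo > hi:
                raise ValueError(f"degenerate range ({lo}, {hi}): requires lo <= hi")
        if self.stump_width_range_px[0] < 4:
            raise ValueError("stump width must be at least 4 px")
        if self.stump_height_range_px[0] > self.height_px - 4:
            raise ValueError("stump height range exceeds image height")
        if self.stump_width_range_px[0] > self.width_px - 4:
            raise ValueError("stump width range exceeds image width")
        for mean, spread in self.bark_palette:
            if not all(0.0 <= c <= 1.0 for c in mean):
                raise ValueError("palette colour means must lie in [0, 1]")
            if spread < 0:
                raise ValueError("palette spread must be non-negative")
        if not set(self.clutter_kinds) <= set(_CLUTTER_KINDS):
            raise ValueError(f"clutter kinds must be a subset of {_CLUTTER_KINDS}")
        if self.background_kind not in ("gradient", "textured"):
            raise ValueError("background_kind must be 'gradient' or 'textured'")
        if not 0.0 <= self.difficulty <= 1.0:
            raise ValueError("difficulty must lie in [0, 1]")


@dataclass
class SceneGroundTruth:
    """A rendered scene with exact trunk annotations.

    ``boxes`` are half-open ``(x0, y0, x1, y1)`` trunk boxes, one per
    generated stump; ``stump_masks`` are the generator's own boolean
    paint masks (which pixels each trunk actually covered), enabling
    ground-truth soundness checks that do not rely on colour heuristics.
    """

    image: np.ndarray
    boxes: list[Box]
    labels: list[str]
    config: SceneConfig
    stump_masks: list[np.ndarray] = field(default_factory=list)
    n_confusable_clutter: int = 0

    def __post_init__(self) -> None:
        h, w = self.image.shape[:2]
        for x0, y0, x1, y1 in self.boxes:
            if not (0 <= x0 < x1 <= w and 0 <= y0 < y1 <= h):
                raise ValueError("ground-truth box outside image bounds")


def _smooth_columns(values: np.ndarray, sigma_cols: float = 2.0) -> np.ndarray:
    """Gaussian-smooth a 1-D column profile and re-centre it to zero mean."""
    radius = max(1, int(round(3 * sigma_cols)))
    xs = np.arange(-radius, radius + 1)
    kern = np.exp(-0.5 * (xs / sigma_cols) ** 2)
    kern /= kern.sum()
    padded = np.pad(values, radius, mode="wrap")
    smooth = np.convolve(padded, kern, mode="valid")
    smooth -= smooth.mean()
    std = smooth.std()
    if std > 0:
        smooth /= std
    return smooth


def generate_bark_patch(
    width_px: int,
    height_px: int,
    palette_entry: tuple[Sequence[float], float],
    stria_strength: float = 0.35,
    seed: int = 0,
) -> np.ndarray:
    """Render a bark texture patch around a palette colour.

    The texture is a column-wise correlated multiplicative striation
    (vertical ridges, the dominant structure of real bark at trunk
    scale) on top of additive colour noise with the palette's spread.
    The striation profile is exactly zero-mean over columns, so the
    expected pixel colour equals the palette mean.

    Parameters
    ----------
    palette_entry : ((r, g, b), spread)
        Mean colour in [0, 1]^3 and per-channel noise scale.
    stria_strength : float
        Relative amplitude of the vertical striation; 0 disables it.
    """
    if width_px < 8 or height_px < 8:
        raise ValueError("bark patches require width_px, height_px >= 8")
    mean = np.asarray(palette_entry[0], dtype=float)
    spread = float(palette_entry[1])
    rng = np.random.default_rng(seed)

    profile = _smooth_columns(rng.standard_normal(width_px))
    patch = np.broadcast_to(mean, (height_px, width_px, 3)).copy()
    patch *= 1.0 + stria_strength * profile[None, :, None]
    if spread > 0:
        col_tint = rng.standard_normal((width_px, 3))
        pixel_noise = rng.standard_normal((height_px, width_px, 1))
        patch = patch + spread * (0.6 * col_tint[None, :, :] + 0.8 * pixel_noise)
    return np.clip(patch, 0.0, 1.0)


def _paint_background(config: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    h, w = config.height_px, config.width_px
    sky = np.array([0.62, 0.72, 0.88]) + rng.uniform(-0.06, 0.06, 3)
    ground = np.array([0.44, 0.47, 0.40]) + rng.uniform(-0.06, 0.06, 3)
    t = np.linspace(0.0, 1.0, h)[:, None, None]
    img = (1 - t) * sky[None, None, :] + t * ground[None, None, :]
    if config.background_kind == "textured":
        noise = rng.standard_normal((max(2, h // 8), max(2, w // 8), 3)) * 0.05
        img = img + resize(noise, (h, w, 3), order=1, mode="reflect", anti_aliasing=False)
    else:
        img = img + rng.standard_normal((h, w, 3)) * 0.01
    return np.clip(img, 0.0, 1.0)


def _paint_rect(img: np.ndarray, box: tuple[int, int, int, int], color: np.ndarray,
                rng: np.random.Generator, noise: float = 0.02) -> None:
    x0, y0, x1, y1 = box
    block = color[None, None, :] + rng.standard_normal((y1 - y0, x1 - x0, 3)) * noise
    img[y0:y1, x0:x1] = np.clip(block, 0.0, 1.0)


def _sample_clutter(config: SceneConfig, rng: np.random.Generator,
                    confusable: bool) -> tuple[str, tuple[int, int, int, int], np.ndarray]:
    h, w = config.height_px, config.width_px
    kinds = config.clutter_kinds if config.clutter_kinds else _CLUTTER_KINDS
    kind = kinds[rng.integers(len(kinds))]
    if confusable:
        mean, spread = config.bark_palette[rng.integers(len(config.bark_palette))]
        color = np.asarray(mean) + rng.uniform(-spread, spread, 3)
    elif kind == "pole":
        g = rng.uniform(0.35, 0.75)
        color = np.array([g, g, g]) + rng.uniform(-0.03, 0.03, 3)
    elif kind == "blob":
        color = np.array([rng.uniform(0.15, 0.35), rng.uniform(0.35, 0.6), rng.uniform(0.1, 0.3)])
    else:
        color = rng.uniform(0.1, 0.9, 3)
    if kind == "pole":
        cw = int(rng.integers(3, 9))
        ch = int(rng.integers(h // 3, max(h // 3 + 1, h - 10)))
    elif kind == "box":
        cw = int(rng.integers(16, max(17, w // 4)))
        ch = int(rng.integers(12, max(13, h // 4)))
    else:
        cw = int(rng.integers(20, max(21, w // 4)))
        ch = int(rng.integers(16, max(17, h // 4)))
    x0 = int(rng.integers(0, max(1, w - cw)))
    y0 = int(rng.integers(0, max(1, h - ch)))
    return kind, (x0, y0, x0 + cw, y0 + ch), np.clip(color, 0.0, 1.0)


def _paint_clutter(img: np.ndarray, kind: str, box: tuple[int, int, int, int],
                   color: np.ndarray, rng: np.random.Generator) -> None:
    x0, y0, x1, y1 = box
    if kind == "blob":
        cy, cx = (y0 + y1) / 2.0, (x0 + x1) / 2.0
        rr, cc = draw_ellipse(cy, cx, (y1 - y0) / 2.0, (x1 - x0) / 2.0, shape=img.shape[:2])
        vals = color[None, :] + rng.standard_normal((rr.size, 3)) * 0.03
        img[rr, cc] = np.clip(vals, 0.0, 1.0)
    else:
        _paint_rect(img, box, color, rng)


def _sample_stump_geometry(config: SceneConfig, rng: np.random.Generator
                           ) -> tuple[int, int, int, int, float]:
    """Sample (x0, y0, width, height, taper) for one trunk."""
    h, w = config.height_px, config.width_px
    wlo, whi = config.stump_width_range_px
    hlo, hhi = config.stump_height_range_px
    for _ in range(200):
        sw = int(rng.integers(wlo, whi + 1))
        # keep eye-level trunk elongation (height 4-12x width) inside range
        aspect = rng.uniform(4.0, 12.0)
        sh = int(np.clip(round(sw * aspect), hlo, min(hhi, h - 6)))
        if sh < hlo or sh > h - 6 or sw > w - 6:
            continue
        taper = rng.uniform(0.7, 1.0)
        x0 = int(rng.integers(2, w - sw - 2))
        y1 = int(rng.integers(max(sh + 4, int(0.55 * h)), h - 1))
        y0 = y1 - sh
        if y0 < 2:
            continue
        return x0, y0, sw, sh, taper
    raise ValueError("stump dimensions exceed image: no valid placement exists")


def _trapezoid_mask(sw: int, sh: int, taper: float) -> np.ndarray:
    """Boolean trunk mask: width tapers linearly from sw (bottom) to taper*sw (top)."""
    mask = np.zeros((sh, sw), dtype=bool)
    centre = (sw - 1) / 2.0
    for row in range(sh):
        frac = row / max(1, sh - 1)  # 0 at top, 1 at bottom
        half = (taper + (1.0 - taper) * frac) * sw / 2.0
        lo = int(np.floor(centre - half + 0.5))
        hi = int(np.ceil(centre + half - 0.5)) + 1
        mask[row, max(0, lo):min(sw, hi)] = True
    return mask


def generate_scene(config: SceneConfig) -> SceneGroundTruth:
    """Render a scene and its exact trunk ground truth.

    Draw order is background, clutter, canopies, trunks: trunks may
    occlude clutter but never the reverse, which keeps ground-truth
    boxes unambiguous.  With ``non_overlapping`` the trunk boxes are
    rejection-sampled to pairwise zero IoU.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    img = _paint_background(config, rng)

    n_confusable = int(round(config.difficulty * config.max_confusable))
    for i in range(config.n_clutter + n_confusable):
        kind, cbox, color = _sample_clutter(config, rng, confusable=i >= config.n_clutter)
        _paint_clutter(img, kind, cbox, color, rng)

    geoms: list[tuple[int, int, int, int, float]] = []
    boxes: list[Box] = []
    for _ in range(config.n_stumps):
        placed = False
        for _ in range(500):
            x0, y0, sw, sh, taper = _sample_stump_geometry(config, rng)
            box = (float(x0), float(y0), float(x0 + sw), float(y0 + sh))
            if config.non_overlapping and any(
                box_intersection_area(box, b) > 0 for b in boxes
            ):
                continue
            geoms.append((x0, y0, sw, sh, taper))
            boxes.append(box)
            placed = True
            break
        if not placed:
            raise ValueError("could not place all stumps without overlap")

    # canopies first so trunks stay un-occluded
    for x0, y0, sw, sh, taper in geoms:
        if rng.uniform() < config.canopy_prob:
            cx = x0 + sw / 2.0
            green = np.array([0.18, 0.42, 0.15]) + rng.uniform(-0.05, 0.05, 3)
            rr, cc = draw_ellipse(y0 - 0.4 * sw, cx, 0.9 * sw, 1.4 * sw, shape=img.shape[:2])
            vals = np.clip(green, 0, 1)[None, :] + rng.standard_normal((rr.size, 3)) * 0.04
            img[rr, cc] = np.clip(vals, 0.0, 1.0)

    masks: list[np.ndarray] = []
    for x0, y0, sw, sh, taper in geoms:
        palette_entry = config.bark_palette[rng.integers(len(config.bark_palette))]
        bark = generate_bark_patch(
            max(8, sw), max(8, sh), palette_entry,
            stria_strength=config.stria_strength,
            seed=int(rng.integers(2**31 - 1)),
        )[:sh, :sw]
        tmask = _trapezoid_mask(sw, sh, taper)
        region = img[y0:y0 + sh, x0:x0 + sw]
        region[tmask] = bark[tmask]
        full = np.zeros(img.shape[:2], dtype=bool)
        full[y0:y0 + sh, x0:x0 + sw] = tmask
        masks.append(full)

    return SceneGroundTruth(
        image=img,
        boxes=boxes,
        labels=["stump"] * len(boxes),
        config=config,
        stump_masks=masks,
        n_confusable_clutter=n_confusable,
    )


def generate_patch_dataset(
    n_pos: int,
    n_neg: int,
    patch_size: int = 64,
    seed: int = 0,
    difficulty: float = 0.0,
    scene_config: SceneConfig | None = None,
    pos_per_scene: int = 5,
    neg_per_scene: int = 25,
    context_frac: float = 0.15,
    return_info: bool = False,
):
    """Crop labelled training/evaluation patches from generated scenes.

    Positives are square crops centred on trunk boxes (with a small
    context margin) resized to ``patch_size``; negatives are random
    square crops whose intersection with every trunk box of their scene
    is exactly zero.  Scenes are generated on the fly with per-scene
    seeds derived from ``seed``; roughly ``max(n_pos/pos_per_scene,
    n_neg/neg_per_scene)`` scenes are consumed.

    Returns ``(patches, labels)`` with patches of shape
    ``(n, patch_size, patch_size, 3)`` and integer labels (1 = trunk).
    With ``return_info`` a third element lists, per patch, the seed of
    its source scene and the crop box, enabling exact provenance checks
    (e.g. that a negative crop intersects no trunk box of its scene).
    """
    if n_pos < 0 or n_neg < 0:
        raise ValueError("patch counts must be non-negative")
    base = scene_config or SceneConfig(n_stumps=pos_per_scene, difficulty=difficulty)
    if patch_size > min(base.width_px, base.height_px):
        raise ValueError(
            f"patch_size {patch_size} exceeds scene size "
            f"{base.width_px}x{base.height_px}"
        )
    rng = np.random.default_rng(derive_seed(seed, "patch-dataset"))
    pos: list[np.ndarray] = []
    neg: list[np.ndarray] = []
    pos_info: list[tuple[int, Box]] = []
    neg_info: list[tuple[int, Box]] = []
    scene_idx = 0
    while (len(pos) < n_pos or len(neg) < n_neg) and scene_idx < 10_000:
        scene_seed = derive_seed(seed, f"scene-{scene_idx}")
        scene = generate_scene(replace(base, seed=scene_seed))
        scene_idx += 1
        h, w = scene.image.shape[:2]
        for box in scene.boxes:
            if len(pos) >= n_pos:
                break
            sq = clip_box(
                tuple(np.round(v) for v in _square_about(box, context_frac)), w, h
            )
            x0, y0, x1, y1 = (int(v) for v in sq)
            if x1 - x0 < 8 or y1 - y0 < 8:
                continue
            crop = scene.image[y0:y1, x0:x1]
            pos.append(resize(crop, (patch_size, patch_size, 3), order=1,
                              mode="reflect", anti_aliasing=True))
            pos_info.append((scene_seed, (float(x0), float(y0), float(x1), float(y1))))
        taken = 0
        attempts = 0
        while taken < neg_per_scene and len(neg) < n_neg and attempts < 50 * neg_per_scene:
            attempts += 1
            side = int(rng.integers(patch_size, min(w, h, 2 * patch_size) + 1))
            x0 = int(rng.integers(0, w - side + 1))
            y0 = int(rng.integers(0, h - side + 1))
            cand = (float(x0), float(y0), float(x0 + side), float(y0 + side))
            if any(box_intersection_area(cand, b) > 0 for b in scene.boxes):
                continue
            crop = scene.image[y0:y0 + side, x0:x0 + side]
            neg.append(resize(crop, (patch_size, patch_size, 3), order=1,
                              mode="reflect", anti_aliasing=True))
            neg_info.append((scene_seed, cand))
            taken += 1
    if len(pos) < n_pos or len(neg) < n_neg:
        raise RuntimeError("could not harvest requested patch counts from scenes")
    patches = np.stack(pos + neg) if (pos or neg) else np.zeros((0, patch_size, patch_size, 3))
    labels = np.concatenate([np.ones(len(pos), dtype=int), np.zeros(len(neg), dtype=int)])
    if return_info:
        return patches, labels, pos_info + neg_info
    return patches, labels


def _square_about(box: Box, margin_frac: float) -> Box:
    x0, y0, x1, y1 = box
    cx, cy = (x0 + x1) / 2.0, (y0 + y1) / 2.0
    side = max(x1 - x0, y1 - y0) * (1.0 + margin_frac)
    h = side / 2.0
    return (cx - h, cy - h, cx + h, cy + h)


def pairwise_max_iou(boxes: Sequence[Box]) -> float:
    """Largest IoU over all distinct box pairs (0 for fewer than 2 boxes)."""
    best = 0.0
    for i in range(len(boxes)):
        for j in range(i + 1, len(boxes)):
            best = max(best, box_iou(boxes[i], boxes[j]))
    return best
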