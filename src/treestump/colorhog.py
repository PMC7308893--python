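"""Colour-aware HOG features on YUV channels with an RBF-kernel SVM.

The third detection approach keeps the dense, learning-heavy character
of the BoVW pipeline but restores colour: each patch is converted from
RGB to YUV by the fixed linear transform below, histograms of oriented
gradients are computed independently per channel, and the concatenated
Y,U,V descriptor is classified by an SVM with a radial-basis-function
kernel.  Luma (Y) carries the bark texture; the chrominance planes (U,
V) separate brown/grey bark from similarly textured but differently
coloured clutter such as lamp posts.

HOG geometry follows the canonical pedestrian-detection layout: 64x64
window, 8-px cells, 2x2-cell blocks with L2-Hys normalisation, 9
unsigned orientation bins.  Gradients use centred [-1, 0, 1]
differences with zero borders; orientation binning is hard (no
interpolation), which keeps every stage checkable against a direct
per-pixel oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize
from sklearn.svm import SVC

# Rows map (R, G, B) -> Y, U, V.  The V row sums exactly to zero and the
# U row to 1e-5, so equal-channel (grey) pixels have (near-)zero chroma.
YUV_MATRIX = np.array([
    [0.299, 0.587, 0.114],
    [-0.14713, -0.28886, 0.436],
    [0.615, -0.51499, -0.10001],
])


def rgb_to_yuv(image: np.ndarray) -> np.ndarray:
    """Apply the fixed linear RGB -> YUV transform per pixel (no clipping)."""
    image = np.asarray(image, dtype=float)
    if image.shape[-1] != 3:
        raise ValueError("rgb_to_yuv expects a trailing RGB axis of length 3")
    if not np.all(np.isfinite(image)):
        raise ValueError("input contains non-finite values")
    return image @ YUV_MATRIX.T


@dataclass(frozen=True)
class HogGeometry:
    """Cell/block layout of the per-channel HOG."""

    window: tuple[int, int] = (64, 64)   # (width, height)
    cell_px: int = 8
    block_cells: int = 2
    n_bins: int = 9
    signed: bool = False

    def descriptor_length(self, width: int | None = None, height: int | None = None) -> int:
        w = self.window[0] if width is None else width
        h = self.window[1] if height is None else height
        ncx, ncy = w // self.cell_px, h // self.cell_px
        nbx, nby = ncx - self.block_cells + 1, ncy - self.block_cells + 1
        return nbx * nby * self.block_cells**2 * self.n_bins


@dataclass
class ColorHogDescriptor:
    """Concatenated per-channel HOG blocks, fixed channel order Y, U, V."""

    vector: np.ndarray
    geometry: HogGeometry


def _cell_histograms(channel: np.ndarray, cell_px: int, n_bins: int,
                     signed: bool) -> np.ndarray:
    """Gradient-orientation histograms per non-overlapping cell."""
    h, w = channel.shape
    gx = np.zeros_like(channel)
    gy = np.zeros_like(channel)
    gx[:, 1:-1] = channel[:, 2:] - channel[:, :-2]
    gy[1:-1, :] = channel[2:, :] - channel[:-2, :]
    mag = np.hypot(gx, gy)
    period = 2 * np.pi if signed else np.pi
    ori = np.arctan2(gy, gx) % period
    bins = np.minimum((ori / (period / n_bins)).astype(int), n_bins - 1)
    ncy, ncx = h // cell_px, w // cell_px
    hists = np.zeros((ncy, ncx, n_bins))
    for b in range(n_bins):
        sel = np.where(bins == b, mag, 0.0)
        hists[:, :, b] = (
            sel.reshape(ncy, cell_px, ncx, cell_px).sum(axis=(1, 3))
        )
    return hists


def _l2hys_blocks(cells: np.ndarray, block_cells: int, eps: float = 1e-5,
                  clip: float = 0.2) -> np.ndarray:
    """Overlapping block L2-Hys normalisation (stride of one cell)."""
    ncy, ncx, n_bins = cells.shape
    nby, nbx = ncy - block_cells + 1, ncx - block_cells + 1
    if nby < 1 or nbx < 1:
        raise ValueError(
            f"geometry yields zero blocks: {ncy}x{ncx} cells with "
            f"{block_cells}x{block_cells} blocks"
        )
    out = np.zeros((nby, nbx, block_cells * block_cells * n_bins))
    for by in range(nby):
        for bx in range(nbx):
            v = cells[by:by + block_cells, bx:bx + block_cells].ravel()
            v = v / np.sqrt((v**2).sum() + eps**2)
            v = np.minimum(v, clip)
            v = v / np.sqrt((v**2).sum() + eps**2)
            out[by, bx] = v
    return out


def hog_channel(
    channel: np.ndarray,
    cell_px: int = 8,
    block_cells: int = 2,
    n_bins: int = 9,
    signed: bool = False,
    flatten: bool = True,
    block_norm: bool = True,
) -> np.ndarray:
    """HOG descriptor of a single channel.

    The channel must divide into whole cells.  With ``block_norm``
    disabled the raw (unnormalised) cell histograms are returned
    instead, which is useful for analysing near-constant channels where
    L2-Hys would amplify numerically tiny gradients.
    """
    channel = np.asarray(channel, dtype=float)
    if channel.ndim != 2:
        raise ValueError("hog_channel expects a 2-D array")
    h, w = channel.shape
    if h % cell_px or w % cell_px:
        raise ValueError(f"channel {h}x{w} does not divide into {cell_px}-px cells")
    cells = _cell_histograms(channel, cell_px, n_bins, signed)
    if not block_norm:
        return cells.ravel() if flatten else cells
    blocks = _l2hys_blocks(cells, block_cells)
    return blocks.ravel() if flatten else blocks


def describe_patch(patch_rgb: np.ndarray,
                   geometry: HogGeometry = HogGeometry()) -> ColorHogDescriptor:
    """Colour-aware HOG of an RGB patch: per-channel HOG in YUV, Y|U|V order.

    The patch is resized to the canonical window first, so descriptors
    from sliding windows at any pyramid scale are commensurate.
    """
    patch_rgb = np.asarray(patch_rgb, dtype=float)
    if patch_rgb.ndim != 3 or patch_rgb.shape[2] != 3:
        raise ValueError(f"expected an (h, w, 3) RGB patch, got shape {patch_rgb.shape}")
    w, h = geometry.window
    if patch_rgb.shape[:2] != (h, w):
        patch_rgb = resize(patch_rgb, (h, w, 3), order=1, mode="reflect",
                           anti_aliasing=True)
    yuv = rgb_to_yuv(patch_rgb)
    parts = [
        hog_channel(yuv[:, :, c], cell_px=geometry.cell_px,
                    block_cells=geometry.block_cells, n_bins=geometry.n_bins,
                    signed=geometry.signed)
        for c in range(3)
    ]
    return ColorHogDescriptor(vector=np.concatenate(parts), geometry=geometry)


@dataclass
class RbfSvmModel:
    """RBF-kernel SVM decision rule evaluated by explicit kernel expansion.

    Stores the fitted support vectors, dual coefficients, intercept and
    resolved gamma, so the model serialises to plain arrays and its
    predictions can be reproduced without the training-time estimator.
    """

    support_vectors: np.ndarray
    dual_coef: np.ndarray
    intercept: float
    gamma: float
    classes: np.ndarray = field(default_factory=lambda: np.array([0, 1]))

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        sv = self.support_vectors
        d2 = ((X**2).sum(axis=1)[:, None] - 2 * X @ sv.T + (sv**2).sum(axis=1)[None, :])
        K = np.exp(-self.gamma * np.maximum(d2, 0.0))
        return K @ self.dual_coef + self.intercept

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes[(self.decision_function(X) > 0).astype(int)]


def train_rbf_svm(descriptors: np.ndarray, labels: np.ndarray,
                  C: float = 10.0, gamma: float | str = "scale"
                  ) -> tuple[RbfSvmModel, SVC]:
    """Fit an RBF-kernel SVM on colour-HOG descriptors.

    ``gamma='scale'`` resolves to ``1 / (d * var(X))``.  Returns both
    the serialisable kernel-expansion model and the underlying
    scikit-learn estimator (useful for cross-checks); the package's
    prediction path uses the former.
    """
    X = np.asarray(descriptors, dtype=float)
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("RBF SVM training requires at least two classes")
    est = SVC(kernel="rbf", C=C, gamma=gamma, tol=1e-6)
    est.fit(X, y)
    model = RbfSvmModel(
        support_vectors=est.support_vectors_.copy(),
        dual_coef=est.dual_coef_.ravel().copy(),
        intercept=float(est.intercept_[0]),
        gamma=float(est._gamma),
        classes=est.classes_.copy(),
    )
    return model, est


@dataclass
class ColorHogClassifier:
    """End-to-end HOG-SVM(RBF) patch classifier over YUV colour-HOG features."""

    svm: RbfSvmModel
    geometry: HogGeometry = HogGeometry()
    training_seed: int = 0

    method_tag = "hog_rbf"

    @classmethod
    def train(
        cls,
        patches: np.ndarray,
        labels: np.ndarray,
        geometry: HogGeometry = HogGeometry(),
        C: float = 10.0,
        gamma: float | str = "scale",
        seed: int = 0,
    ) -> "ColorHogClassifier":
        X = np.stack([describe_patch(p, geometry).vector for p in patches])
        model, _ = train_rbf_svm(X, labels, C=C, gamma=gamma)
        return cls(svm=model, geometry=geometry, training_seed=seed)

    def encode(self, patch_rgb: np.ndarray) -> np.ndarray:
        return describe_patch(patch_rgb, self.geometry).vector

    def predict_score(self, patches: np.ndarray) -> np.ndarray:
        X = np.stack([self.encode(p) for p in patches])
        return self.svm.decision_function(X)

    def predict(self, patches: np.ndarray) -> np.ndarray:
        return self.svm.classes[(self.predict_score(patches) > 0).astype(int)]
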