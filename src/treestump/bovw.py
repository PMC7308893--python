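"""Bag of visual words over densely extracted SIFT descriptors.

The second detection approach is appearance-only machine learning:
grayscale patches are described by 128-dimensional SIFT descriptors
(4x4 spatial cells x 8 orientation bins) computed on a dense grid at a
small number of scales, a visual vocabulary of k = 200 words is learnt
by k-means over a descriptor pool, each patch is encoded as an
L1-normalised histogram of nearest-word assignments, and a linear SVM
separates trunk from non-trunk histograms.

No installed library exposes dense (grid-based) SIFT, so the descriptor
is computed here directly: hard orientation binning into 8 signed bins,
box spatial pooling per 4x4 cell grid via integral images, then the
standard L2 -> clamp(0.2) -> L2 normalisation.  Zero-gradient patches
produce zero descriptors, which are kept and quantised like any other
(flat sky regions stay in the histogram rather than being
special-cased away).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.color import rgb2gray
from skimage.transform import resize
from sklearn.cluster import KMeans
from sklearn.svm import SVC

N_ORI_BINS = 8
N_SPATIAL = 4          # 4x4 cell grid -> 128-dim descriptors
SIFT_CLAMP = 0.2


@dataclass
class DenseDescriptorSet:
    """Descriptors plus their (x, y, scale) grid keypoints."""

    descriptors: np.ndarray    # (n, 128)
    keypoints: np.ndarray      # (n, 3): x, y, scale

    def __len__(self) -> int:
        return len(self.descriptors)


@dataclass
class VisualVocabulary:
    """k cluster centroids over descriptor space."""

    k: int
    centroids: np.ndarray
    training_seed: int
    norm_tag: str = "l1"

    def __post_init__(self) -> None:
        if self.centroids.shape[0] != self.k:
            raise ValueError("vocabulary must hold exactly k centroids")


@dataclass
class BoVWHistogram:
    """L1-normalised visual-word frequencies for one patch."""

    values: np.ndarray
    empty: bool = False


def _orientation_channels(patch: np.ndarray) -> np.ndarray:
    """Split gradient magnitude into 8 hard signed-orientation channels."""
    gy, gx = np.gradient(patch)
    mag = np.hypot(gx, gy)
    ori = np.arctan2(gy, gx) % (2 * np.pi)
    bins = np.minimum((ori / (2 * np.pi / N_ORI_BINS)).astype(int), N_ORI_BINS - 1)
    channels = np.zeros((N_ORI_BINS,) + patch.shape)
    for b in range(N_ORI_BINS):
        channels[b][bins == b] = mag[bins == b]
    return channels


def sift_grid_positions(width: int, height: int, stride_px: int, bin_px: int
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Keypoint centres whose full 4x4-cell support fits in the patch.

    The descriptor support is ``4 * bin_px`` pixels square, centred on
    the keypoint; valid centres run from ``2 * bin_px`` to
    ``dim - 2 * bin_px`` inclusive, stepped by the stride.
    """
    half = 2 * bin_px
    xs = np.arange(half, width - half + 1, stride_px)
    ys = np.arange(half, height - half + 1, stride_px)
    return xs, ys


def dense_sift(
    patch_gray: np.ndarray,
    stride_px: int = 8,
    scales: tuple[int, ...] = (1, 2),
    base_bin_px: int = 4,
) -> DenseDescriptorSet:
    """Extract SIFT descriptors on a dense grid at the given scales.

    ``scales`` multiply the spatial bin size (a scale of s pools over
    ``4*s``-pixel cells, a 16s-pixel support).  Patches too small for
    any keypoint return an empty set with a warning rather than failing,
    so callers can treat undersized windows uniformly.
    """
    patch_gray = np.asarray(patch_gray, dtype=float)
    if patch_gray.ndim != 2:
        raise ValueError("dense_sift expects a 2-D grayscale patch")
    h, w = patch_gray.shape
    channels = _orientation_channels(patch_gray)
    # integral images, one per orientation channel
    integral = np.zeros((N_ORI_BINS, h + 1, w + 1))
    integral[:, 1:, 1:] = channels.cumsum(axis=1).cumsum(axis=2)

    descs: list[np.ndarray] = []
    kps: list[np.ndarray] = []
    for scale in scales:
        bin_px = base_bin_px * scale
        xs, ys = sift_grid_positions(w, h, stride_px, bin_px)
        if len(xs) == 0 or len(ys) == 0:
            continue
        gx, gy = np.meshgrid(xs, ys)
        gx, gy = gx.ravel(), gy.ravel()
        # top-left corner of each of the 16 cells, per keypoint
        offs = (np.arange(N_SPATIAL) * bin_px) - 2 * bin_px
        cy = gy[:, None, None] + offs[None, :, None]     # (n, 4, 1)
        cx = gx[:, None, None] + offs[None, None, :]     # (n, 1, 4)
        cy = np.broadcast_to(cy, (len(gx), N_SPATIAL, N_SPATIAL)).reshape(-1)
        cx = np.broadcast_to(cx, (len(gx), N_SPATIAL, N_SPATIAL)).reshape(-1)
        sums = (
            integral[:, cy + bin_px, cx + bin_px]
            + integral[:, cy, cx]
            - integral[:, cy + bin_px, cx]
            - integral[:, cy, cx + bin_px]
        )                                               # (8, n*16)
        vec = sums.T.reshape(len(gx), N_SPATIAL * N_SPATIAL, N_ORI_BINS)
        vec = vec.reshape(len(gx), -1)                  # cell-major, then orientation
        descs.append(_normalise_sift(vec))
        kps.append(np.column_stack([gx, gy, np.full(len(gx), scale)]).astype(float))
    if not descs:
        warnings.warn("patch too small for any dense-SIFT keypoint; returning empty set")
        dim = N_SPATIAL * N_SPATIAL * N_ORI_BINS
        return DenseDescriptorSet(np.zeros((0, dim)), np.zeros((0, 3)))
    return DenseDescriptorSet(np.vstack(descs), np.vstack(kps))


def _normalise_sift(vec: np.ndarray) -> np.ndarray:
    """L2 normalise, clamp at 0.2, renormalise; zero vectors stay zero."""
    out = vec.astype(float).copy()
    norms = np.linalg.norm(out, axis=1, keepdims=True)
    nz = norms[:, 0] > 0
    out[nz] /= norms[nz]
    out = np.minimum(out, SIFT_CLAMP)
    norms = np.linalg.norm(out, axis=1, keepdims=True)
    nz = norms[:, 0] > 0
    out[nz] /= norms[nz]
    return out


def build_vocabulary(
    descriptor_pool: np.ndarray,
    k: int = 200,
    seed: int = 0,
    n_init: int = 10,
    max_iter: int = 300,
    tol: float = 1e-4,
) -> VisualVocabulary:
    """Learn a visual vocabulary by k-means over a descriptor pool.

    Uses k-means++ initialisation with ``n_init`` restarts and keeps the
    minimum-inertia solution.  The pool must contain at least k
    descriptors.
    """
    pool = np.asarray(descriptor_pool, dtype=float)
    if pool.ndim != 2:
        raise ValueError("descriptor pool must be a 2-D array")
    if len(pool) < k:
        raise ValueError(f"descriptor pool of size {len(pool)} is smaller than k={k}")
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_init,
                max_iter=max_iter, tol=tol, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        km.fit(pool)
    return VisualVocabulary(k=k, centroids=km.cluster_centers_, training_seed=seed)


def encode_histogram(descriptors: DenseDescriptorSet | np.ndarray,
                     vocab: VisualVocabulary) -> BoVWHistogram:
    """Quantise descriptors to their nearest word and L1-normalise counts.

    Assignment is by Euclidean distance with ties resolved to the
    lowest centroid index.  An empty descriptor set encodes to the zero
    vector with the ``empty`` flag raised; by convention such patches
    classify as negative.
    """
    desc = descriptors.descriptors if isinstance(descriptors, DenseDescriptorSet) else np.asarray(descriptors)
    if len(desc) == 0:
        return BoVWHistogram(values=np.zeros(vocab.k), empty=True)
    if desc.shape[1] != vocab.centroids.shape[1]:
        raise ValueError(
            f"descriptor length {desc.shape[1]} does not match "
            f"centroid length {vocab.centroids.shape[1]}"
        )
    assign = nearest_centroid_indices(desc, vocab.centroids)
    counts = np.bincount(assign, minlength=vocab.k).astype(float)
    return BoVWHistogram(values=counts / counts.sum())


def nearest_centroid_indices(desc: np.ndarray, centroids: np.ndarray,
                             chunk: int = 8192) -> np.ndarray:
    """Index of the nearest centroid per descriptor (ties -> lowest index)."""
    c_sq = (centroids**2).sum(axis=1)
    out = np.empty(len(desc), dtype=int)
    for start in range(0, len(desc), chunk):
        block = desc[start:start + chunk]
        d2 = (block**2).sum(axis=1)[:, None] - 2 * block @ centroids.T + c_sq[None, :]
        out[start:start + chunk] = np.argmin(d2, axis=1)
    return out


@dataclass
class LinearSvmModel:
    """Linear decision rule sign(w . h + b) with continuous margins."""

    w: np.ndarray
    b: float
    classes: np.ndarray = field(default_factory=lambda: np.array([0, 1]))

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X) @ self.w + self.b

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes[(self.decision_function(X) > 0).astype(int)]


def train_linear_svm(histograms: np.ndarray, labels: np.ndarray,
                     C: float = 1.0) -> LinearSvmModel:
    """Fit a soft-margin linear SVM on encoded histograms."""
    X = np.asarray(histograms, dtype=float)
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("linear SVM training requires at least two classes")
    est = SVC(kernel="linear", C=C, tol=1e-7)
    est.fit(X, y)
    return LinearSvmModel(w=est.coef_.ravel().copy(), b=float(est.intercept_[0]),
                          classes=est.classes_.copy())


@dataclass
class BovwClassifier:
    """End-to-end BoVW-SVM(lin) patch classifier.

    Wraps the full feature pipeline -- grayscale conversion, window
    resize, dense SIFT, histogram encoding -- around the trained
    vocabulary and linear SVM, so the sliding-window detector can treat
    it as a black box scoring RGB patches.
    """

    vocab: VisualVocabulary
    svm: LinearSvmModel
    window: tuple[int, int] = (64, 64)
    stride_px: int = 8
    scales: tuple[int, ...] = (1, 2)
    training_seed: int = 0

    method_tag = "bovw_lin"

    @classmethod
    def train(
        cls,
        patches: np.ndarray,
        labels: np.ndarray,
        k: int = 200,
        seed: int = 0,
        C: float = 1.0,
        window: tuple[int, int] = (64, 64),
        stride_px: int = 8,
        scales: tuple[int, ...] = (1, 2),
        max_pool: int = 15_000,
        n_init: int = 10,
    ) -> "BovwClassifier":
        """Learn vocabulary and SVM from labelled RGB patches.

        ``max_pool`` caps the descriptor pool fed to k-means (a uniform
        subsample at the training seed); histograms are still encoded
        from every descriptor of every patch.
        """
        sets = [cls._describe_static(p, window, stride_px, scales) for p in patches]
        pool = np.vstack([s.descriptors for s in sets if len(s)])
        rng = np.random.default_rng(seed)
        if len(pool) > max_pool:
            pool = pool[rng.choice(len(pool), max_pool, replace=False)]
        vocab = build_vocabulary(pool, k=k, seed=seed, n_init=n_init)
        hists = np.stack([encode_histogram(s, vocab).values for s in sets])
        svm = train_linear_svm(hists, labels, C=C)
        return cls(vocab=vocab, svm=svm, window=window, stride_px=stride_px,
                   scales=scales, training_seed=seed)

    @staticmethod
    def _describe_static(patch_rgb: np.ndarray, window: tuple[int, int],
                         stride_px: int, scales: tuple[int, ...]) -> DenseDescriptorSet:
        patch_rgb = np.asarray(patch_rgb, dtype=float)
        if patch_rgb.ndim != 3 or patch_rgb.shape[2] != 3:
            raise ValueError(
                f"expected an (h, w, 3) RGB patch, got shape {patch_rgb.shape}"
            )
        gray = rgb2gray(patch_rgb)
        if gray.shape != (window[1], window[0]):
            gray = resize(gray, (window[1], window[0]), order=1,
                          mode="reflect", anti_aliasing=True)
        return dense_sift(gray, stride_px=stride_px, scales=scales)

    def encode(self, patch_rgb: np.ndarray) -> np.ndarray:
        desc = self._describe_static(patch_rgb, self.window, self.stride_px, self.scales)
        return encode_histogram(desc, self.vocab).values

    def predict_score(self, patches: np.ndarray) -> np.ndarray:
        """Continuous SVM margins for a batch of RGB patches."""
        H = np.stack([self.encode(p) for p in patches])
        return self.svm.decision_function(H)

    def predict(self, patches: np.ndarray) -> np.ndarray:
        return self.svm.classes[(self.predict_score(patches) > 0).astype(int)]
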