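"""Gaussian-mixture bark-colour model with Mahalanobis scoring.

The engineered detection approach opens with a colour gate: bark colour
is modelled as a mixture of full-covariance Gaussians in RGB, fitted by
expectation-maximisation on hand-segmented (or synthetic) bark pixels
after photometric augmentation of the training patches.  At test time
every pixel is scored by its minimum Mahalanobis distance to any mixture
component; thresholding that distance and cleaning the result with
morphological opening and closing yields a candidate bark mask.

Distances are reported on the standard-deviation scale (the distance is
1 when a pixel sits one component sigma from a mean), so the default
threshold tau = 3 is a conventional three-sigma acceptance region.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.linalg import cho_factor, cho_solve
from skimage.morphology import closing as _closing, disk, opening as _opening
from sklearn.exceptions import ConvergenceWarning
from sklearn.mixture import GaussianMixture


@dataclass
class ColorModel:
    """Fitted bark-colour mixture: weights, means and covariances in RGB."""

    weights: np.ndarray          # (k,), sums to 1
    means: np.ndarray            # (k, 3)
    covariances: np.ndarray      # (k, 3, 3), symmetric positive definite
    colour_space_tag: str = "RGB"
    reg_floor: float = 1e-4
    log_likelihood_path: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.covariances = np.asarray(self.covariances, dtype=float)
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        for cov in self.covariances:
            if not np.allclose(cov, cov.T, atol=1e-10):
                raise ValueError("covariances must be symmetric")
            if np.linalg.eigvalsh(cov).min() < 0.5 * self.reg_floor:
                raise ValueError("covariance eigenvalues fell below the regularisation floor")

    @property
    def n_components(self) -> int:
        return len(self.weights)


@dataclass
class LikelihoodMap:
    """Per-pixel minimum Mahalanobis distance to the bark mixture.

    Lower values mean more bark-like colour; a pixel equal to some
    component mean scores exactly 0.
    """

    distances: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.distances < 0):
            raise ValueError("Mahalanobis distances must be non-negative")


@dataclass(frozen=True)
class AugmentConfig:
    """Ranges of the random photometric transforms.

    Each augmented patch is an original under a global brightness gain,
    a gamma curve, per-channel gains and additive Gaussian noise, in
    that order, clipped to [0, 1].  Degenerate ranges (lo == hi) make
    the corresponding transform deterministic; all-identity ranges with
    zero noise reproduce the inputs exactly.
    """

    gain_range: tuple[float, float] = (0.8, 1.2)
    gamma_range: tuple[float, float] = (0.8, 1.25)
    channel_gain_range: tuple[float, float] = (0.9, 1.1)
    noise_sigma: float = 0.02


def augment_photometric(
    patches: list[np.ndarray],
    target_count: int,
    seed: int = 0,
    config: AugmentConfig = AugmentConfig(),
) -> list[np.ndarray]:
    """Expand a patch set to at least ``target_count`` by photometric jitter.

    Originals are kept verbatim; augmented copies cycle through the
    originals with independently sampled transforms.
    """
    if len(patches) == 0:
        raise ValueError("augment_photometric requires at least one input patch")
    if target_count < len(patches):
        raise ValueError("target_count must be >= the number of input patches")
    rng = np.random.default_rng(seed)
    out = [np.asarray(p, dtype=float) for p in patches]
    i = 0
    while len(out) < target_count:
        src = out[i % len(patches)]
        gamma = rng.uniform(*config.gamma_range)
        gain = rng.uniform(*config.gain_range)
        cgain = rng.uniform(*config.channel_gain_range, size=3)
        aug = np.power(np.clip(src, 0.0, 1.0), gamma) * gain * cgain[None, None, :]
        if config.noise_sigma > 0:
            aug = aug + rng.normal(0.0, config.noise_sigma, size=src.shape)
        out.append(np.clip(aug, 0.0, 1.0))
        i += 1
    return out


def fit_color_model(
    pixels: np.ndarray,
    n_components: int = 5,
    seed: int = 0,
    reg_floor: float = 1e-4,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> ColorModel:
    """EM-fit a Gaussian mixture to bark pixels.

    Runs expectation-maximisation one step at a time (warm-started) so
    the per-iteration log-likelihood path can be recorded and checked
    for the EM monotonicity guarantee.  Covariance matrices are floored
    at ``reg_floor`` on the diagonal, which also resolves degenerate
    (single-colour) components without NaNs.

    Parameters
    ----------
    pixels : (n, 3) array of RGB values in [0, 1]; requires
        ``n >= 10 * n_components``.
    """
    pixels = np.asarray(pixels, dtype=float)
    if pixels.ndim != 2 or pixels.shape[1] != 3:
        raise ValueError("pixels must be an (n, 3) RGB array")
    if len(pixels) < 10 * n_components:
        raise ValueError(
            f"need at least {10 * n_components} pixels to fit {n_components} components"
        )
    gm = GaussianMixture(
        n_components=n_components,
        covariance_type="full",
        reg_covar=reg_floor,
        init_params="k-means++",
        random_state=seed,
        warm_start=True,
        max_iter=1,
        tol=0.0,
    )
    path: list[float] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for _ in range(max_iter):
            gm.fit(pixels)
            ll = float(gm.lower_bound_)
            if not np.isfinite(ll):
                raise RuntimeError("EM produced a non-finite log-likelihood")
            path.append(ll)
            if len(path) >= 2 and path[-1] - path[-2] < tol:
                break
    return ColorModel(
        weights=gm.weights_,
        means=gm.means_,
        covariances=gm.covariances_,
        reg_floor=reg_floor,
        log_likelihood_path=np.asarray(path),
    )


def score_pixels(model: ColorModel, image: np.ndarray) -> LikelihoodMap:
    """Score every pixel by its minimum component-wise Mahalanobis distance."""
    image = np.asarray(image, dtype=float)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("image must be an (h, w, 3) RGB array")
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite pixel values")
    flat = image.reshape(-1, 3)
    best = np.full(len(flat), np.inf)
    for mean, cov in zip(model.means, model.covariances):
        delta = flat - mean[None, :]
        factor = cho_factor(cov, lower=True)
        solved = cho_solve(factor, delta.T)
        d2 = np.einsum("ij,ji->i", delta, solved)
        np.minimum(best, np.sqrt(np.maximum(d2, 0.0)), out=best)
    return LikelihoodMap(distances=best.reshape(image.shape[:2]))


def threshold_and_clean(
    likelihood: LikelihoodMap,
    tau: float = 3.0,
    open_radius: int = 1,
    close_radius: int = 2,
) -> np.ndarray:
    """Threshold the distance map and clean the mask morphologically.

    The mask keeps pixels with distance <= tau, then applies an opening
    (removes speckle smaller than the disc) followed by a closing (fills
    holes and gaps smaller than the disc).  A radius of 0 disables the
    corresponding operation.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    if open_radius < 0 or close_radius < 0:
        raise ValueError("morphology radii must be non-negative")
    mask = likelihood.distances <= tau
    if open_radius > 0:
        mask = _opening(mask, disk(open_radius))
    if close_radius > 0:
        mask = _closing(mask, disk(close_radius))
    return mask


def save_color_model(model: ColorModel, path: str) -> None:
    """Serialise a colour model to a single YAML document."""
    doc = {
        "format_version": 1,
        "colour_space": model.colour_space_tag,
        "reg_floor": float(model.reg_floor),
        "weights": model.weights.tolist(),
        "means": model.means.tolist(),
        "covariances": model.covariances.tolist(),
        "log_likelihood_path": model.log_likelihood_path.tolist(),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def load_color_model(path: str) -> ColorModel:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if doc.get("format_version", 0) > 1:
        raise ValueError(f"colour model at {path} uses an unsupported format version")
    return ColorModel(
        weights=np.asarray(doc["weights"]),
        means=np.asarray(doc["means"]),
        covariances=np.asarray(doc["covariances"]),
        colour_space_tag=doc.get("colour_space", "RGB"),
        reg_floor=float(doc.get("reg_floor", 1e-4)),
        log_likelihood_path=np.asarray(doc.get("log_likelihood_path", [])),
    )
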