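"""File formats and the versioned model bundle.

Images travel as PNG/JPEG and live in memory as float RGB rasters in
[0, 1]; boxes, poses and detections as CSV with documented columns;
configs and manifests as YAML.  Trained classifiers serialise to a
single *model bundle*: a deterministic ZIP archive holding one YAML
metadata document plus one ``.npy`` member per array, with per-array
SHA-256 checksums.  Saving, loading and re-saving a bundle is
byte-identical, and loading a bundle written by a newer format version
fails loudly.
"""

from __future__ import annotations

import hashlib
import io as _io
import logging
import zipfile
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from treestump.bovw import BovwClassifier, LinearSvmModel, VisualVocabulary
from treestump.colorhog import ColorHogClassifier, HogGeometry, RbfSvmModel
from treestump.detector import Detection
from treestump.harvest import CameraPose

logger = logging.getLogger("treestump")

BUNDLE_FORMAT_VERSION = 1
_ZIP_DATE = (1980, 1, 1, 0, 0, 0)


class BundleError(RuntimeError):
    pass


class BundleVersionError(BundleError):
    pass


class BundleIntegrityError(BundleError):
    pass


# ---------------------------------------------------------------- images

def load_image(path: str | Path) -> np.ndarray:
    """Read a PNG/JPEG as a float RGB raster in [0, 1].

    Grayscale inputs are promoted to three identical channels (with a
    warning); an alpha channel is dropped.
    """
    path = Path(path)
    try:
        raw = iio.imread(path)
    except Exception as exc:  # noqa: BLE001 - re-raise with the path named
        raise IOError(f"could not read image {path}: {exc}") from exc
    arr = np.asarray(raw)
    if arr.dtype == np.uint8:
        arr = arr.astype(float) / 255.0
    elif arr.dtype == np.uint16:
        arr = arr.astype(float) / 65535.0
    else:
        arr = arr.astype(float)
    if arr.ndim == 2:
        logger.warning("grayscale image %s promoted to 3 channels", path)
        arr = np.stack([arr] * 3, axis=-1)
    elif arr.shape[2] == 4:
        arr = arr[:, :, :3]
    return arr


def save_image(path: str | Path, image: np.ndarray) -> None:
    """Write a float [0, 1] raster as an 8-bit PNG/JPEG."""
    arr = np.clip(np.asarray(image, dtype=float), 0.0, 1.0)
    iio.imwrite(Path(path), np.round(arr * 255.0).astype(np.uint8))


# ------------------------------------------------------------------ CSVs

BOX_COLUMNS = ["image", "x0", "y0", "x1", "y1", "label"]
DETECTION_COLUMNS = ["image", "x0", "y0", "x1", "y1", "score", "label"]
POSE_COLUMNS = ["image", "east_m", "north_m", "heading_deg", "hfov_deg"]


def write_boxes_csv(path: str | Path, image_name: str, boxes, labels) -> None:
    rows = [
        {"image": image_name, "x0": b[0], "y0": b[1], "x1": b[2], "y1": b[3],
         "label": lab}
        for b, lab in zip(boxes, labels)
    ]
    pd.DataFrame(rows, columns=BOX_COLUMNS).to_csv(path, index=False)


def read_boxes_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(BOX_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"boxes CSV {path} is missing columns {sorted(missing)}")
    return df


def write_detections_csv(path: str | Path, image_name: str,
                         detections: list[Detection]) -> None:
    rows = [
        {"image": image_name, "x0": d.box[0], "y0": d.box[1], "x1": d.box[2],
         "y1": d.box[3], "score": d.score, "label": d.label}
        for d in detections
    ]
    pd.DataFrame(rows, columns=DETECTION_COLUMNS).to_csv(path, index=False)


def read_detections_csv(path: str | Path) -> list[Detection]:
    df = pd.read_csv(path)
    return [
        Detection(box=(r.x0, r.y0, r.x1, r.y1), score=float(r.score),
                  label=str(r.label))
        for r in df.itertuples()
    ]


def read_poses_csv(path: str | Path) -> dict[str, CameraPose]:
    df = pd.read_csv(path)
    missing = set(POSE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"poses CSV {path} is missing columns {sorted(missing)}")
    return {
        str(r.image): CameraPose(east=float(r.east_m), north=float(r.north_m),
                                 heading_deg=float(r.heading_deg),
                                 hfov_deg=float(r.hfov_deg))
        for r in df.itertuples()
    }


# --------------------------------------------------------- model bundles

@dataclass
class ModelBundle:
    """Serializable classifier: tag, config, arrays and provenance."""

    method_tag: str
    feature_config: dict
    arrays: dict[str, np.ndarray]
    provenance: dict = field(default_factory=dict)
    format_version: int = BUNDLE_FORMAT_VERSION


def _array_bytes(arr: np.ndarray) -> bytes:
    buf = _io.BytesIO()
    np.save(buf, np.ascontiguousarray(arr), allow_pickle=False)
    return buf.getvalue()


def save_bundle(bundle: ModelBundle, path: str | Path) -> None:
    """Write a bundle as a deterministic ZIP with checksummed members."""
    members: list[tuple[str, bytes]] = []
    checksums = {}
    for name in sorted(bundle.arrays):
        payload = _array_bytes(bundle.arrays[name])
        checksums[name] = hashlib.sha256(payload).hexdigest()
        members.append((f"arrays/{name}.npy", payload))
    meta = {
        "format_version": bundle.format_version,
        "method_tag": bundle.method_tag,
        "feature_config": bundle.feature_config,
        "provenance": bundle.provenance,
        "array_sha256": checksums,
    }
    meta_bytes = yaml.safe_dump(meta, sort_keys=True).encode()
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_STORED) as zf:
        for name, payload in [("meta.yaml", meta_bytes)] + members:
            info = zipfile.ZipInfo(name, date_time=_ZIP_DATE)
            zf.writestr(info, payload)


def load_bundle(path: str | Path) -> ModelBundle:
    path = Path(path)
    with zipfile.ZipFile(path) as zf:
        meta = yaml.safe_load(zf.read("meta.yaml"))
        version = int(meta.get("format_version", 0))
        if version > BUNDLE_FORMAT_VERSION:
            raise BundleVersionError(
                f"bundle {path} has format version {version}; "
                f"this build supports up to {BUNDLE_FORMAT_VERSION}"
            )
        arrays = {}
        for name, digest in meta["array_sha256"].items():
            payload = zf.read(f"arrays/{name}.npy")
            if hashlib.sha256(payload).hexdigest() != digest:
                raise BundleIntegrityError(
                    f"checksum mismatch for array {name!r} in {path}"
                )
            arrays[name] = np.load(_io.BytesIO(payload), allow_pickle=False)
    return ModelBundle(
        method_tag=meta["method_tag"],
        feature_config=meta["feature_config"],
        arrays=arrays,
        provenance=meta.get("provenance", {}),
        format_version=version,
    )


def classifier_to_bundle(classifier, provenance: dict | None = None) -> ModelBundle:
    """Convert a trained classifier into a ModelBundle."""
    prov = dict(provenance or {})
    prov.setdefault("seed", getattr(classifier, "training_seed", None))
    if isinstance(classifier, BovwClassifier):
        return ModelBundle(
            method_tag="bovw_lin",
            feature_config={
                "window": list(classifier.window),
                "stride_px": classifier.stride_px,
                "scales": list(classifier.scales),
                "k": classifier.vocab.k,
                "norm": classifier.vocab.norm_tag,
            },
            arrays={
                "centroids": classifier.vocab.centroids,
                "svm_w": classifier.svm.w,
                "svm_b": np.array([classifier.svm.b]),
                "classes": classifier.svm.classes.astype(float),
            },
            provenance=prov,
        )
    if isinstance(classifier, ColorHogClassifier):
        g = classifier.geometry
        return ModelBundle(
            method_tag="hog_rbf",
            feature_config={
                "window": list(g.window), "cell_px": g.cell_px,
                "block_cells": g.block_cells, "n_bins": g.n_bins,
                "signed": g.signed,
            },
            arrays={
                "support_vectors": classifier.svm.support_vectors,
                "dual_coef": classifier.svm.dual_coef,
                "intercept": np.array([classifier.svm.intercept]),
                "gamma": np.array([classifier.svm.gamma]),
                "classes": classifier.svm.classes.astype(float),
            },
            provenance=prov,
        )
    raise TypeError(f"cannot bundle classifier of type {type(classifier).__name__}")


def classifier_from_bundle(bundle: ModelBundle):
    """Reconstruct a classifier from a ModelBundle."""
    cfg = bundle.feature_config
    seed = bundle.provenance.get("seed") or 0
    if bundle.method_tag == "bovw_lin":
        vocab = VisualVocabulary(k=int(cfg["k"]), centroids=bundle.arrays["centroids"],
                                 training_seed=int(seed), norm_tag=cfg.get("norm", "l1"))
        svm = LinearSvmModel(w=bundle.arrays["svm_w"],
                             b=float(bundle.arrays["svm_b"][0]),
                             classes=bundle.arrays["classes"].astype(int))
        return BovwClassifier(vocab=vocab, svm=svm, window=tuple(cfg["window"]),
                              stride_px=int(cfg["stride_px"]),
                              scales=tuple(cfg["scales"]), training_seed=int(seed))
    if bundle.method_tag == "hog_rbf":
        geometry = HogGeometry(window=tuple(cfg["window"]), cell_px=int(cfg["cell_px"]),
                               block_cells=int(cfg["block_cells"]),
                               n_bins=int(cfg["n_bins"]), signed=bool(cfg["signed"]))
        svm = RbfSvmModel(
            support_vectors=bundle.arrays["support_vectors"],
            dual_coef=bundle.arrays["dual_coef"],
            intercept=float(bundle.arrays["intercept"][0]),
            gamma=float(bundle.arrays["gamma"][0]),
            classes=bundle.arrays["classes"].astype(int),
        )
        return ColorHogClassifier(svm=svm, geometry=geometry, training_seed=int(seed))
    raise BundleError(f"unknown method tag {bundle.method_tag!r}")


def dataset_fingerprint(patches: np.ndarray, labels: np.ndarray) -> str:
    """SHA-256 of the training data, recorded in bundle provenance."""
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(patches).tobytes())
    h.update(np.ascontiguousarray(labels).tobytes())
    return h.hexdigest()
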