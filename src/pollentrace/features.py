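"""Color codebooks and per-image frequency histograms.

An image's color content is summarized against a learned *codebook* of k
representative colors: masked pixels are transformed into the chosen color
representation, k-means (mini-batch, for tractability on millions of pixels)
finds k centroids, every pixel is assigned to its nearest centroid by
Euclidean distance, and the image becomes the k-vector of assignment
frequencies.  The admissible range of k, 16-35 with a default of 32, comes
from palynological species counts per sample: one centroid per putative
floral color source.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.cluster import MiniBatchKMeans

from . import colorspace
from .errors import (
    ConfigError,
    ContractError,
    InsufficientDataError,
)
from .io import DatasetManifest, load_image

logger = logging.getLogger(__name__)

K_MIN, K_MAX = 16, 35
DEFAULT_K = 32

__all__ = [
    "ColorCodebook",
    "pool_pixels",
    "subsample_pixels",
    "fit_codebook",
    "assign_colors",
    "histogram_features",
    "save_codebook",
    "load_codebook",
]


@dataclass
class ColorCodebook:
    """k representative colors in one of the feature representations."""

    centroids: np.ndarray  # (k, d)
    representation: str

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float)
        if self.centroids.ndim != 2:
            raise ConfigError("centroids must be a (k, d) matrix")
        if not np.all(np.isfinite(self.centroids)):
            raise ConfigError("centroid coordinates must be finite")
        if self.k < 1:
            raise ConfigError("codebook needs at least one centroid")
        d = colorspace.representation_dim(self.representation)
        if self.centroids.shape[1] != d:
            raise ConfigError(
                f"representation {self.representation!r} has dimension {d}, "
                f"centroids have {self.centroids.shape[1]}"
            )

    @property
    def k(self) -> int:
        return self.centroids.shape[0]


def subsample_pixels(
    pixel_arrays: list[np.ndarray], max_per_image: int, seed: int
) -> np.ndarray:
    """Stack per-image pixel arrays, keeping at most ``max_per_image`` rows
    from each, sampled uniformly without replacement; deterministic in seed."""
    rng = np.random.default_rng(seed)
    kept = []
    for arr in pixel_arrays:
        arr = np.asarray(arr, dtype=float)
        if arr.shape[0] <= max_per_image:
            kept.append(arr)
        else:
            idx = rng.choice(arr.shape[0], size=max_per_image, replace=False)
            kept.append(arr[np.sort(idx)])
    if not kept:
        raise InsufficientDataError("no pixel arrays to pool")
    return np.vstack(kept)


def pool_pixels(
    manifest: DatasetManifest,
    masks: Mapping[str, np.ndarray],
    representation: str,
    max_per_image: int = 5000,
    seed: int = 0,
) -> np.ndarray:
    """Pool masked pixels from all *training* images into one matrix.

    ``masks`` maps each record's ``image_path`` to its boolean segmentation
    mask.  Pixels are transformed to ``representation`` before pooling.
    Images with an empty mask are skipped with a warning; if every mask is
    empty an error is raised.
    """
    arrays = []
    for rec in manifest.records:
        if rec.split != "train":
            continue
        mask = np.asarray(masks[rec.image_path], dtype=bool)
        if not mask.any():
            logger.warning("skipping %s: empty segmentation mask", rec.image_path)
            continue
        img = load_image(manifest.resolve(rec))
        arrays.append(colorspace.rgb_to_representation(img[mask], representation))
    if not arrays:
        raise InsufficientDataError("all segmentation masks are empty")
    return subsample_pixels(arrays, max_per_image, seed)


def fit_codebook(
    pixels: np.ndarray,
    k: int = DEFAULT_K,
    seed: int = 0,
    representation: str = "uv",
    batch_size: int = 4096,
    n_iter: int = 100,
) -> ColorCodebook:
    """Fit a k-color codebook with mini-batch k-means (k-means++ seeding).

    Centroids are sorted lexicographically by coordinates before storage so a
    codebook is a canonical object independent of cluster numbering.
    """
    pixels = np.asarray(pixels, dtype=float)
    if pixels.ndim != 2:
        raise ContractError(f"expected a 2-d pixel matrix, got shape {pixels.shape}")
    if pixels.shape[0] < k:
        raise InsufficientDataError(
            f"need at least k={k} pixels to fit a codebook, got {pixels.shape[0]}"
        )
    if k == 1:  # closed form: the single centroid is the pixel mean
        return ColorCodebook(pixels.mean(axis=0, keepdims=True), representation)
    km = MiniBatchKMeans(
        n_clusters=k,
        random_state=seed,
        batch_size=batch_size,
        max_iter=n_iter,
        n_init=3,
        init="k-means++",
    )
    km.fit(pixels)
    centroids = km.cluster_centers_
    order = np.lexsort(centroids.T[::-1])  # sort by first column, then second, ...
    return ColorCodebook(centroids[order], representation)


def assign_colors(pixels: np.ndarray, codebook: ColorCodebook) -> np.ndarray:
    """Nearest-centroid index (Euclidean) per pixel; ties -> lowest index."""
    pixels = np.asarray(pixels, dtype=float)
    if pixels.ndim != 2 or pixels.shape[1] != codebook.centroids.shape[1]:
        raise ContractError(
            f"pixel matrix of shape {pixels.shape} does not match codebook "
            f"dimension {codebook.centroids.shape[1]}"
        )
    # squared distances suffice for argmin; argmin returns the first minimum
    d2 = (
        np.sum(pixels**2, axis=1)[:, None]
        - 2.0 * pixels @ codebook.centroids.T
        + np.sum(codebook.centroids**2, axis=1)[None, :]
    )
    return np.argmin(d2, axis=1)


def histogram_features(
    img: np.ndarray, mask: np.ndarray, codebook: ColorCodebook
) -> np.ndarray:
    """k-vector of relative frequencies of codebook colors among masked pixels."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ContractError("cannot featurize an image with an empty mask")
    pixels = colorspace.rgb_to_representation(
        np.asarray(img, dtype=float)[mask], codebook.representation
    )
    return histogram_from_pixels(pixels, codebook)


def histogram_from_pixels(pixels: np.ndarray, codebook: ColorCodebook) -> np.ndarray:
    """Frequency histogram for pixels already in the codebook's representation."""
    idx = assign_colors(pixels, codebook)
    counts = np.bincount(idx, minlength=codebook.k).astype(float)
    return counts / counts.sum()


def save_codebook(codebook: ColorCodebook, path: str | Path) -> Path:
    """Write centroids as CSV plus a JSON sidecar with the representation tag."""
    path = Path(path)
    d = codebook.centroids.shape[1]
    pd.DataFrame(codebook.centroids, columns=[f"d{i}" for i in range(d)]).to_csv(
        path, index=False
    )
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    with open(sidecar, "w", encoding="utf-8") as fh:
        json.dump(
            {"representation": codebook.representation, "k": codebook.k}, fh, indent=2
        )
    return path


def load_codebook(path: str | Path) -> ColorCodebook:
    path = Path(path)
    centroids = pd.read_csv(path).to_numpy(float)
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    with open(sidecar, "r", encoding="utf-8") as fh:
        meta = json.load(fh)
    return ColorCodebook(centroids, meta["representation"])
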