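"""Segmentation of the pollen region and shadow cleanup.

The pollen area in a macroscopic sample photograph is texturally busy (many
small grains of different colors) while the acquisition template behind it is
nearly uniform.  Segmentation therefore thresholds a *local entropy* map:
per pixel, the Shannon entropy (bits) of the histogram of quantized gray
levels inside a circular patch (radius 5 px by default).  Otsu's criterion
applied to the entropy values separates the high-entropy pollen region from
the low-entropy background.

Grain shadows survive this step because they hug grain borders and are just
as "busy" locally.  They are, however, nearly achromatic: their RGB triples
sit close to the gray diagonal of the RGB cube.  The cleanup stage computes
each masked pixel's Euclidean distance to the achromatic line
``d(P) = ||U x P|| / ||U||`` with ``U = [1,1,1]`` and drops pixels whose
distance falls below one standard deviation of the masked distances.
"""

from __future__ import annotations

import numpy as np
from skimage.filters.rank import entropy as _rank_entropy
from skimage.morphology import disk

from .errors import ContractError, DegenerateInputError, ParameterError

__all__ = [
    "to_gray",
    "local_entropy",
    "otsu_threshold",
    "segment_pollen",
    "diagonal_distance",
    "remove_shadows",
]

#: Luminance weights (the Y row of the RGB->XYZ matrix).
_LUMA = np.array([0.299, 0.587, 0.114])

_OTSU_LEVELS = 256


def to_gray(img: np.ndarray) -> np.ndarray:
    """Luminance gray conversion: ``0.299 R + 0.587 G + 0.114 B``."""
    img = np.asarray(img, dtype=float)
    if img.ndim != 3 or img.shape[-1] != 3:
        raise ContractError(f"expected an HxWx3 RGB image, got shape {img.shape}")
    return img @ _LUMA


def local_entropy(gray: np.ndarray, radius: int = 5, n_bins: int = 256) -> np.ndarray:
    """Per-pixel Shannon entropy (bits) of gray levels in a circular patch.

    Gray values in [0,1] are quantized to ``n_bins`` levels (<= 256); the
    patch is the set of pixels within Euclidean distance ``radius`` of the
    center, truncated to in-bounds pixels at the image border.
    """
    gray = np.asarray(gray, dtype=float)
    if gray.ndim != 2:
        raise ContractError(f"expected a 2-d gray image, got shape {gray.shape}")
    if radius < 1:
        raise ParameterError("radius must be >= 1")
    if radius > min(gray.shape) / 2:
        raise ParameterError(
            f"radius {radius} too large for image of shape {gray.shape}"
        )
    if not 2 <= n_bins <= 256:
        raise ParameterError("n_bins must be in [2, 256]")
    q = np.clip(np.round(gray * (n_bins - 1)), 0, n_bins - 1).astype(np.uint8)
    return _rank_entropy(q, disk(radius))


def otsu_threshold(values: np.ndarray) -> float:
    """Otsu threshold of a collection of reals over a 256-level histogram.

    Values are binned uniformly between their min and max; the returned
    threshold is the upper edge of the last bin assigned to the low class, so
    the two classes are ``values <= t`` and ``values > t``.  Among thresholds
    that tie on between-class variance the lowest level wins.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise DegenerateInputError("cannot threshold an empty collection")
    lo, hi = float(values.min()), float(values.max())
    if hi <= lo:
        raise DegenerateInputError("all values identical; Otsu threshold undefined")
    idx = np.minimum(
        ((values - lo) / (hi - lo) * _OTSU_LEVELS).astype(int), _OTSU_LEVELS - 1
    )
    hist = np.bincount(idx, minlength=_OTSU_LEVELS).astype(float)
    if np.count_nonzero(hist) < 2:
        raise DegenerateInputError(
            "fewer than two distinct quantized levels; Otsu threshold undefined"
        )
    levels = np.arange(_OTSU_LEVELS)
    w0 = np.cumsum(hist)
    w1 = w0[-1] - w0
    mu = np.cumsum(hist * levels)
    mu0 = np.divide(mu, w0, out=np.zeros_like(mu), where=w0 > 0)
    mu1 = np.divide(mu[-1] - mu, w1, out=np.zeros_like(mu), where=w1 > 0)
    between = w0 * w1 * (mu0 - mu1) ** 2
    between[-1] = -np.inf  # threshold must leave the high class nonempty
    t = int(np.argmax(between))  # argmax takes the lowest index on ties
    return lo + (t + 1) * (hi - lo) / _OTSU_LEVELS


def segment_pollen(img: np.ndarray, radius: int = 5, n_bins: int = 256) -> np.ndarray:
    """Boolean mask of the pollen region: entropy map above its Otsu threshold."""
    ent = local_entropy(to_gray(img), radius=radius, n_bins=n_bins)
    return ent > otsu_threshold(ent)


def diagonal_distance(pixels: np.ndarray) -> np.ndarray:
    """Euclidean distance from RGB triples to the achromatic line R=G=B.

    Computed as ``||U x P|| / ||U||`` with ``U = [1,1,1]``; zero exactly for
    gray pixels and homogeneous of degree 1 in the pixel values.
    """
    p = np.asarray(pixels, dtype=float)
    if p.shape[-1] != 3:
        raise ContractError(f"expected RGB triples, got shape {p.shape}")
    u = np.ones(3)
    cross = np.cross(np.broadcast_to(u, p.shape), p)
    return np.linalg.norm(cross, axis=-1) / np.linalg.norm(u)


def remove_shadows(
    img: np.ndarray, mask: np.ndarray, rule: str = "remove_low"
) -> np.ndarray:
    """Refine a segmentation mask using distance to the achromatic line.

    With ``rule="remove_low"`` (default) masked pixels whose diagonal
    distance is below one standard deviation of the masked distances are
    dropped — these are the near-gray shadow pixels.  ``rule="keep_low"``
    inverts the comparison and retains only the near-gray pixels instead.
    If the masked distances have zero spread the mask is returned unchanged.
    The result is always a subset of the input mask.
    """
    if rule not in ("remove_low", "keep_low"):
        raise ParameterError(f"unknown shadow rule {rule!r}")
    img = np.asarray(img, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != img.shape[:2]:
        raise ContractError(
            f"mask shape {mask.shape} does not match image shape {img.shape[:2]}"
        )
    if not mask.any():
        raise ContractError("cannot refine an empty mask")
    d = diagonal_distance(img[mask])
    sigma = float(d.std())
    if sigma == 0.0:
        return mask.copy()
    keep = d >= sigma if rule == "remove_low" else d < sigma
    refined = np.zeros_like(mask)
    refined[mask] = keep
    return refined
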