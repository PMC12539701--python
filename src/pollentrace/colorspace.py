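"""Color-space transforms used to featurize pollen pixels.

Two device-independent descriptions of pollen color are supported:

* **HSV** — hue/saturation/value, with hue computed as the quadrant-aware
  angle ``atan2(sqrt(3)(G-B), 2R-G-B)`` in ``[0, 2*pi)``.  Saturation and hue
  are invariant to a uniform rescaling of the RGB channels, which is what
  makes this space attractive under illumination changes.
* **CIE L*u*v*** — a perceptually uniform space reached through a fixed
  linear RGB->XYZ matrix followed by the cube-root lightness function and the
  chromaticity offsets against a standard white point.

Four feature representations are derived from these: ``hsv``, ``luv`` (the
full 3-d spaces) and ``hs``, ``uv`` (their 2-d chroma-only projections).

All functions are vectorized over arrays whose last axis has length 3; RGB
values are expected in ``[0, 1]``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ContractError, ParameterError

__all__ = [
    "WhitePoint",
    "REPRESENTATIONS",
    "rgb_to_hsv",
    "rgb_to_xyz",
    "xyz_to_luv",
    "rgb_to_luv",
    "project",
    "rgb_to_representation",
    "representation_dim",
]

#: RGB -> XYZ transfer matrix (rows produce X, Y, Z).  The Y row is the
#: classic NTSC luminance vector, reused by :func:`pollentrace.preprocess.to_gray`.
RGB_TO_XYZ_MATRIX = np.array(
    [
        [0.607, 0.174, 0.200],
        [0.299, 0.587, 0.114],
        [0.000, 0.066, 1.116],
    ]
)

#: Lightness branch point of the L* function.
_L_BRANCH = 0.008856

# Representation tag -> (source space, dimensionality)
REPRESENTATIONS = {
    "hsv": ("hsv", 3),
    "luv": ("luv", 3),
    "hs": ("hsv", 2),
    "uv": ("luv", 2),
}


@dataclass(frozen=True)
class WhitePoint:
    """Reference white used by the L*u*v* chromaticity offsets.

    The defaults are the standard-illuminant chromaticity coordinates
    ``u0 = 0.19793943`` and ``v0 = 0.46831096`` with unit luminance ``Y0``
    (RGB in [0,1] maps to Y in [0,1]).
    """

    u0: float = 0.19793943
    v0: float = 0.46831096
    Y0: float = 1.0


def _check_rgb(rgb: np.ndarray) -> np.ndarray:
    rgb = np.asarray(rgb, dtype=float)
    if rgb.shape[-1] != 3:
        raise ContractError(f"expected last axis of length 3, got shape {rgb.shape}")
    return rgb


def rgb_to_hsv(rgb: np.ndarray) -> np.ndarray:
    """Convert RGB in [0,1] to (H, S, V).

    H is in ``[0, 2*pi)`` with H = 0 for achromatic pixels (C = 0);
    S = C / V (0 when C = 0); V = max(R, G, B).
    """
    rgb = _check_rgb(rgb)
    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    v = np.maximum(np.maximum(r, g), b)
    c = v - np.minimum(np.minimum(r, g), b)
    chromatic = c > 0
    s = np.where(chromatic, c / np.where(v > 0, v, 1.0), 0.0)
    h = np.where(
        chromatic,
        np.mod(np.arctan2(np.sqrt(3.0) * (g - b), 2.0 * r - g - b), 2.0 * np.pi),
        0.0,
    )
    # mod can round a hair below 2*pi up to 2*pi exactly; fold it back to 0
    h = np.where(h >= 2.0 * np.pi, 0.0, h)
    return np.stack([h, s, v], axis=-1)


def rgb_to_xyz(rgb: np.ndarray) -> np.ndarray:
    """Linear RGB -> XYZ by the fixed transfer matrix."""
    rgb = _check_rgb(rgb)
    return rgb @ RGB_TO_XYZ_MATRIX.T


def xyz_to_luv(
    xyz: np.ndarray,
    white: WhitePoint = WhitePoint(),
    v_prime: str = "as_printed",
) -> np.ndarray:
    """Convert XYZ (all channels >= 0) to (L, u*, v*).

    ``v_prime`` selects the numerator of the v chromaticity term:
    ``"as_printed"`` uses 6Y/(X+15Y+3Z); ``"cie1976"`` uses the CIE-1976
    definition 9Y/(X+15Y+3Z), which is the convention the default white-point
    constant ``v0`` actually derives from.  Pixels with a zero denominator or
    zero lightness get u* = v* = 0.
    """
    if v_prime not in ("as_printed", "cie1976"):
        raise ParameterError(f"unknown v_prime convention: {v_prime!r}")
    xyz = np.asarray(xyz, dtype=float)
    if xyz.shape[-1] != 3:
        raise ContractError(f"expected last axis of length 3, got shape {xyz.shape}")
    if np.any(xyz < 0):
        raise ContractError("XYZ channels must be nonnegative")
    x, y, z = xyz[..., 0], xyz[..., 1], xyz[..., 2]
    yn = y / white.Y0
    big = yn > _L_BRANCH
    ell = np.where(big, 116.0 * np.cbrt(np.where(big, yn, 1.0)) - 16.0, 903.3 * yn)
    denom = x + 15.0 * y + 3.0 * z
    safe = denom > 0
    d = np.where(safe, denom, 1.0)
    u_c = 4.0 * x / d
    v_factor = 6.0 if v_prime == "as_printed" else 9.0
    v_c = v_factor * y / d
    u = np.where(safe, 13.0 * ell * (u_c - white.u0), 0.0)
    v = np.where(safe, 13.0 * ell * (v_c - white.v0), 0.0)
    return np.stack([ell, u, v], axis=-1)


def rgb_to_luv(
    rgb: np.ndarray,
    white: WhitePoint = WhitePoint(),
    v_prime: str = "as_printed",
) -> np.ndarray:
    """RGB -> L*u*v* through the XYZ intermediate."""
    return xyz_to_luv(rgb_to_xyz(rgb), white=white, v_prime=v_prime)


def representation_dim(representation: str) -> int:
    """Feature dimensionality of a representation tag (3 for hsv/luv, 2 for hs/uv)."""
    try:
        return REPRESENTATIONS[representation][1]
    except KeyError:
        raise ParameterError(
            f"unknown representation {representation!r}; expected one of {sorted(REPRESENTATIONS)}"
        ) from None


def project(full: np.ndarray, representation: str, space_tag: str) -> np.ndarray:
    """Project a full-space array (HSV or LUV triples) onto a representation.

    ``space_tag`` names the space `full` lives in (``"hsv"`` or ``"luv"``) and
    must match the representation's source space: ``hs`` drops V from HSV,
    ``uv`` drops L from LUV, while ``hsv``/``luv`` are identity projections.
    """
    source, _ = REPRESENTATIONS.get(representation, (None, None))
    if source is None:
        raise ParameterError(
            f"unknown representation {representation!r}; expected one of {sorted(REPRESENTATIONS)}"
        )
    if space_tag != source:
        raise ContractError(
            f"representation {representation!r} requires {source} input, got {space_tag!r}"
        )
    full = np.asarray(full, dtype=float)
    if full.shape[-1] != 3:
        raise ContractError(f"expected last axis of length 3, got shape {full.shape}")
    if representation in ("hsv", "luv"):
        return full
    if representation == "hs":
        return full[..., :2]
    return full[..., 1:]  # uv: drop L


def rgb_to_representation(
    rgb: np.ndarray,
    representation: str,
    white: WhitePoint = WhitePoint(),
    v_prime: str = "as_printed",
) -> np.ndarray:
    """Transform RGB pixels straight into one of the four feature representations."""
    source, _ = REPRESENTATIONS.get(representation, (None, None))
    if source is None:
        raise ParameterError(
            f"unknown representation {representation!r}; expected one of {sorted(REPRESENTATIONS)}"
        )
    if source == "hsv":
        full = rgb_to_hsv(rgb)
    else:
        full = rgb_to_luv(rgb, white=white, v_prime=v_prime)
    return project(full, representation, source)
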