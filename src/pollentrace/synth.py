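"""Synthetic macroscopic pollen-sample images with known ground truth.

The generator emulates the statistical structure the classification pipeline
relies on rather than the optics of a light-box photograph:

* All producers share one global pool of ``palette_size`` chromatic base
  colors (the regional flora).  Each producer is characterized by *mixture
  weights* over that pool — the same flowers occur everywhere, in
  producer-specific proportions (floral constancy makes those proportions
  stable).  A single ``separation`` knob interpolates between one shared
  weight vector (``separation = 0``, producers indistinguishable) and fully
  producer-specific weights.
* A seasonal *visit drift* tilts the mixture weights per sampling visit.
  The tilt direction is global — shared by all producers — so drift models a
  temporal shift of the pollen spectrum without leaking producer identity.
* An image is a near-uniform gray template at ``background_gray`` (with a
  small illumination jitter) on which elliptical grains are stamped at
  random positions (no grain center falls inside an existing grain) until a
  target pixel ``coverage`` is reached.  Each grain draws its color from the
  producer's visit-tilted mixture plus small per-grain noise, and casts a
  darker *achromatic* partial ring on one side — a shadow that sits on the
  RGB gray diagonal, exactly the artifact the preprocessing stage removes.

Every image comes with its ground-truth grain and shadow masks, and the
whole dataset is deterministic given ``(config, seed)``.
"""

from __future__ import annotations

import colorsys
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io import DatasetManifest, SampleRecord, save_image, write_manifest

logger = logging.getLogger(__name__)

__all__ = [
    "ProducerPalette",
    "SynthConfig",
    "RenderedSample",
    "make_producer_palettes",
    "visit_weights",
    "render_sample_image",
    "generate_dataset",
]


@dataclass
class ProducerPalette:
    """A producer's color signature: shared base colors + mixture weights."""

    producer_id: str
    base_colors: np.ndarray  # (m, 3) RGB in [0,1]
    mixture_weights: np.ndarray  # (m,), sums to 1
    visit_drift: float = 0.0

    def __post_init__(self) -> None:
        self.base_colors = np.asarray(self.base_colors, dtype=float)
        self.mixture_weights = np.asarray(self.mixture_weights, dtype=float)
        if self.base_colors.ndim != 2 or self.base_colors.shape[1] != 3:
            raise ConfigError("base_colors must be an (m, 3) matrix")
        if np.any(self.base_colors < 0) or np.any(self.base_colors > 1):
            raise ConfigError("base_colors must lie in [0,1]^3")
        if abs(self.mixture_weights.sum() - 1.0) > 1e-9:
            raise ConfigError("mixture_weights must sum to 1")
        if np.any(self.mixture_weights < 0):
            raise ConfigError("mixture_weights must be nonnegative")
        if self.visit_drift < 0:
            raise ConfigError("visit_drift must be >= 0")


@dataclass
class SynthConfig:
    """Study-design parameters of a synthetic pollen-image dataset.

    Defaults mirror the field study's structure: 20 producers paired into 10
    municipalities, 4 seasonal visits, ~14 samples per producer and visit,
    4 images per sample.
    """

    n_producers: int = 20
    municipalities: Optional[dict[str, str]] = None  # producer -> municipality
    n_visits: int = 4
    samples_per_visit: int = 14
    images_per_sample: int = 4
    image_size: tuple[int, int] = (256, 256)
    grain_radius_range: tuple[float, float] = (4.0, 7.0)
    coverage: float = 0.30
    shadow_strength: float = 0.35
    background_gray: float = 0.78
    illumination_jitter: float = 0.02
    pixel_noise: float = 0.002
    grain_texture_noise: float = 0.025
    grain_color_noise: float = 0.02
    palette_size: int = 24
    separation: float = 0.28
    visit_drift: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        if not 16 <= self.palette_size <= 35:
            raise ConfigError(
                f"palette_size must be in [16, 35], got {self.palette_size}"
            )
        if not 0.0 < self.coverage < 1.0:
            raise ConfigError("coverage must be in (0, 1)")
        if not 1 <= self.n_visits <= 4:
            raise ConfigError("n_visits must be in 1..4")
        if self.n_producers < 1 or self.samples_per_visit < 1:
            raise ConfigError("n_producers and samples_per_visit must be >= 1")
        if self.images_per_sample < 1:
            raise ConfigError("images_per_sample must be >= 1")
        lo, hi = self.grain_radius_range
        if not 0 < lo <= hi:
            raise ConfigError("grain_radius_range must satisfy 0 < lo <= hi")
        if hi >= min(self.image_size) / 2:
            raise ConfigError("grain radii must be smaller than half the image")
        if self.separation < 0:
            raise ConfigError("separation must be >= 0")
        if not 0.0 <= self.shadow_strength < 1.0:
            raise ConfigError("shadow_strength must be in [0, 1)")
        if not 0.0 <= self.background_gray <= 1.0:
            raise ConfigError("background_gray must be in [0, 1]")

    def producer_ids(self) -> list[str]:
        return [f"P{i + 1:02d}" for i in range(self.n_producers)]

    def municipality_map(self) -> dict[str, str]:
        """Configured mapping, or the default pairing of producers into
        municipalities (two producers per municipality)."""
        if self.municipalities is not None:
            return dict(self.municipalities)
        return {
            pid: f"M{i // 2 + 1:02d}" for i, pid in enumerate(self.producer_ids())
        }


@dataclass
class RenderedSample:
    """One rendered image with its ground-truth masks."""

    image: np.ndarray  # (H, W, 3) in [0,1]
    grain_mask: np.ndarray  # bool, True on grain pixels
    shadow_mask: np.ndarray  # bool, True on cast-shadow pixels


def _chromatic_pool(rng: np.random.Generator, m: int) -> np.ndarray:
    """m saturated base colors spread over hue; none sits near the gray axis."""
    hues = (np.arange(m) / m + rng.uniform(0, 1 / m, m)) % 1.0
    sats = rng.uniform(0.45, 0.9, m)
    vals = rng.uniform(0.35, 0.95, m)
    return np.array(
        [colorsys.hsv_to_rgb(h, s, v) for h, s, v in zip(hues, sats, vals)]
    )


def make_producer_palettes(config: SynthConfig) -> list[ProducerPalette]:
    """Build per-producer palettes over a shared base-color pool.

    A single symmetric-Dirichlet draw gives the common weight vector; each
    producer's weights are shifted toward a producer-specific Dirichlet mode
    by ``min(separation * u_p, 1)``, where ``u_p ~ Uniform(0.5, 1.5)`` is a
    per-producer distinctiveness factor: real producers differ in how
    distinctive their floral mix is, and this stable trait is what
    test-retest reliability measures.  ``separation = 0`` leaves every
    producer with the identical shared vector.
    """
    rng = np.random.default_rng(config.seed)
    m = config.palette_size
    pool = _chromatic_pool(rng, m)
    shared = rng.dirichlet(2.0 * np.ones(m))
    palettes = []
    for pid in config.producer_ids():
        mode = rng.dirichlet(0.5 * np.ones(m))
        s = min(config.separation * rng.uniform(0.5, 1.5), 1.0)
        weights = (1.0 - s) * shared + s * mode
        palettes.append(
            ProducerPalette(pid, pool, weights / weights.sum(), config.visit_drift)
        )
    return palettes


def visit_weights(
    palette: ProducerPalette, visit: int, config: SynthConfig
) -> np.ndarray:
    """Mixture weights tilted by the global seasonal drift of a visit.

    The tilt is an exponential reweighting ``w * exp(drift * g_visit)`` with
    a standard-normal direction ``g_visit`` derived from the config seed and
    the visit alone, so all producers experience the same seasonal shift.
    """
    if not 1 <= visit <= config.n_visits:
        raise ConfigError(f"visit must be in 1..{config.n_visits}, got {visit}")
    if palette.visit_drift == 0.0:
        return palette.mixture_weights.copy()
    g = np.random.default_rng([config.seed, 7919, visit]).standard_normal(
        palette.mixture_weights.shape[0]
    )
    w = palette.mixture_weights * np.exp(palette.visit_drift * g)
    return w / w.sum()


def _ellipse_patch(
    cy: float, cx: float, a: float, b: float, theta: float, shape: tuple[int, int]
):
    """In-bounds bounding-box slices and the ellipse membership test inside."""
    H, W = shape
    r = max(a, b)
    y0, y1 = max(int(cy - r - 3), 0), min(int(cy + r + 4), H)
    x0, x1 = max(int(cx - r - 3), 0), min(int(cx + r + 4), W)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dy, dx = yy - cy, xx - cx
    ct, st = np.cos(theta), np.sin(theta)
    u = (dx * ct + dy * st) / a
    v = (-dx * st + dy * ct) / b
    return (slice(y0, y1), slice(x0, x1)), u, v, dy, dx


def render_sample_image(
    palette: ProducerPalette,
    visit: int,
    config: SynthConfig,
    seed: int,
) -> RenderedSample:
    """Render one synthetic sample image for a producer and visit.

    Grain colors are drawn per grain from the visit-tilted mixture; each
    grain casts a darker achromatic arc on the image's common shadow side.
    Grain pixels receive a small achromatic texture noise so the pollen
    region is locally heterogeneous the way a real spread of grains is.
    """
    rng = np.random.default_rng(seed)
    H, W = config.image_size
    w_v = visit_weights(palette, visit, config)
    m = w_v.shape[0]

    bg = config.background_gray + rng.uniform(-1, 1) * config.illumination_jitter
    bg = float(np.clip(bg, 0.05, 0.95))
    gray = np.full((H, W), bg)
    if config.illumination_jitter > 0:
        ramp = rng.uniform(-1, 1) * 0.5 * config.illumination_jitter
        gray += ramp * (np.arange(W) / max(W - 1, 1) - 0.5)[None, :]
    if config.pixel_noise > 0:
        gray += rng.normal(0.0, config.pixel_noise, (H, W))
    img = np.repeat(gray[:, :, None], 3, axis=2)

    grain_mask = np.zeros((H, W), dtype=bool)
    shadow_mask = np.zeros((H, W), dtype=bool)
    target = config.coverage * H * W
    phi = rng.uniform(0, 2 * np.pi)  # common shadow direction for the image
    shadow_dir = np.array([np.sin(phi), np.cos(phi)])  # (dy, dx)
    lo, hi = config.grain_radius_range
    mean_area = np.pi * ((lo + hi) / 2) ** 2
    max_attempts = int(50 * target / mean_area) + 1000

    covered = 0
    for _ in range(max_attempts):
        if covered >= target:
            break
        cy, cx = rng.uniform(0, H), rng.uniform(0, W)
        if grain_mask[int(cy), int(cx)]:
            continue  # centers never land inside an existing grain
        a, b = rng.uniform(lo, hi), rng.uniform(lo, hi)
        theta = rng.uniform(0, np.pi)
        color = palette.base_colors[rng.choice(m, p=w_v)]
        color = np.clip(color + rng.normal(0, config.grain_color_noise, 3), 0, 1)

        box, u, v, dy, dx = _ellipse_patch(cy, cx, a + 2.5, b + 2.5, theta, (H, W))
        scale_a, scale_b = (a + 2.5) / a, (b + 2.5) / b
        inside = (u * scale_a) ** 2 + (v * scale_b) ** 2 <= 1.0
        ring = (u**2 + v**2 <= 1.0) & ~inside
        if config.shadow_strength > 0:
            side = dy * shadow_dir[0] + dx * shadow_dir[1] > 0
            shade = ring & side & ~grain_mask[box]
            depth = config.shadow_strength * rng.uniform(0.6, 1.0)
            img[box][shade] = np.clip(bg * (1.0 - depth), 0, 1)
            shadow_mask[box] |= shade
        if config.grain_texture_noise > 0:
            texture = rng.normal(0, config.grain_texture_noise, inside.shape)
            grain_px = np.clip(color[None, :] + texture[..., None], 0, 1)
        else:
            grain_px = np.broadcast_to(color, inside.shape + (3,))
        patch = img[box]
        patch[inside] = grain_px[inside]
        img[box] = patch
        covered += int((inside & ~grain_mask[box]).sum())
        grain_mask[box] |= inside
        shadow_mask[box] &= ~inside
    else:
        logger.warning(
            "coverage target %.2f not reached (%.3f placed)",
            config.coverage,
            grain_mask.mean(),
        )

    return RenderedSample(np.clip(img, 0, 1), grain_mask, shadow_mask)


def _split_plan(config: SynthConfig) -> tuple[list[tuple[int, int]], int]:
    """Per-producer allocation of samples to the test split.

    Returns the ordered (visit, sample) pairs chosen as full test samples,
    and the number of extra test *images* (split evenly between acquisition
    rounds) taken from one additional "mixed" sample, so that each
    producer's train fraction is within one image of 2/3.
    """
    ips = config.images_per_sample
    order = [
        (v, s)
        for s in range(config.samples_per_visit)
        for v in range(1, config.n_visits + 1)
    ]
    n_img = len(order) * ips
    # even test count keeps acquisition rounds balanced per producer
    n_test_img = 2 * int(round(n_img / 6.0))
    full = n_test_img // ips
    extra = n_test_img - full * ips
    return order[: full + (1 if extra else 0)], extra


def generate_dataset(config: SynthConfig, out_dir: str | Path) -> DatasetManifest:
    """Write a full synthetic dataset: images, manifest and ground truth.

    Roughly one third of each producer's images (whole samples where
    possible) form the test split, with test images split evenly between
    acquisition rounds 1 and 2; the rest are training images.  Ground-truth
    grain masks and the producer palettes are saved under
    ``out_dir/ground_truth``.
    """
    out_dir = Path(out_dir)
    img_dir = out_dir / "images"
    mask_dir = out_dir / "ground_truth" / "masks"
    img_dir.mkdir(parents=True, exist_ok=True)
    mask_dir.mkdir(parents=True, exist_ok=True)

    palettes = make_producer_palettes(config)
    mapping = config.municipality_map()
    missing = [p.producer_id for p in palettes if p.producer_id not in mapping]
    if missing:
        raise ConfigError(f"municipality mapping missing producers: {missing}")

    test_samples, extra_imgs = _split_plan(config)
    test_set = set(test_samples)
    mixed = test_samples[-1] if extra_imgs else None
    ips = config.images_per_sample

    records = []
    for p_idx, palette in enumerate(palettes):
        for visit in range(1, config.n_visits + 1):
            for s_idx in range(config.samples_per_visit):
                key = (visit, s_idx)
                for i_idx in range(ips):
                    rnd = 1 if i_idx < ips / 2 else 2
                    if key == mixed:
                        # per round, the first extra/2 images go to test
                        pos_in_round = i_idx if rnd == 1 else i_idx - (ips + 1) // 2
                        split = "test" if pos_in_round < extra_imgs // 2 else "train"
                    elif key in test_set:
                        split = "test"
                    else:
                        split = "train"
                    seed = np.random.default_rng(
                        [config.seed, 104729, p_idx, visit, s_idx, i_idx]
                    ).integers(0, 2**31)
                    sample = render_sample_image(palette, visit, config, int(seed))
                    name = f"{palette.producer_id}_v{visit}_s{s_idx + 1}_i{i_idx + 1}.png"
                    save_image(sample.image, img_dir / name)
                    save_image(sample.grain_mask, mask_dir / name)
                    records.append(
                        SampleRecord(
                            image_path=f"images/{name}",
                            producer_id=palette.producer_id,
                            municipality=mapping[palette.producer_id],
                            visit=visit,
                            acquisition_round=rnd,
                            split=split,
                        )
                    )

    rows = []
    for palette in palettes:
        for c_idx, (rgb, w) in enumerate(
            zip(palette.base_colors, palette.mixture_weights)
        ):
            rows.append(
                {
                    "producer_id": palette.producer_id,
                    "color_index": c_idx,
                    "R": rgb[0],
                    "G": rgb[1],
                    "B": rgb[2],
                    "weight": w,
                }
            )
    pd.DataFrame(rows).to_csv(out_dir / "ground_truth" / "palettes.csv", index=False)

    manifest = DatasetManifest(records, mapping, root=out_dir)
    write_manifest(manifest, out_dir / "manifest.csv")
    logger.info(
        "generated %d images for %d producers under %s",
        len(records),
        config.n_producers,
        out_dir,
    )
    return manifest
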