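"""End-to-end orchestration: images -> masks -> features -> model -> reports.

`run_pipeline` wires the stages together for a manifest of images:

1. segment every image (local-entropy + Otsu) and drop shadow pixels
   (diagonal-distance rule);
2. pool masked training pixels, fit one color codebook per
   (representation, k) appearing in the model grid, and build per-image
   frequency histograms;
3. cross-validate every grid spec with stratified folds on the training
   split, select the best by mean weighted F1, and refit it on the full
   training split;
4. predict the test split and expose producer / municipality / temporal /
   test-retest reports.

All randomness derives from the single ``seed`` in :class:`PipelineConfig`,
so a rerun with the same inputs reproduces identical predictions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import colorspace, features as feat, model_select as ms, preprocess
from .errors import ConfigError
from .evaluate import (
    MetricsReport,
    ReliabilityReport,
    confusion,
    metrics,
    municipality_rollup,
    temporal_table,
    test_retest,
)
from .io import DatasetManifest, load_image

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "predict_manifest"]


@dataclass
class PipelineConfig:
    """Tunable parameters of the full pipeline."""

    representation: str = "uv"  # used when no grid is supplied
    k: int = 32
    radius: int = 5
    n_bins: int = 256
    shadow_rule: str = "remove_low"
    codebook_scope: str = "train_only"  # or "all": pool test pixels too
    max_per_image: int = 4000  # pixels pooled per image for codebook fitting
    max_hist_pixels: int = 25000  # masked pixels retained per image
    batch_size: int = 4096
    n_iter: int = 100
    n_folds: int = 10
    v_prime: str = "as_printed"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.codebook_scope not in ("train_only", "all"):
            raise ConfigError(f"unknown codebook_scope {self.codebook_scope!r}")
        # codebook sizes track the 16-35 species-per-sample range
        from .features import K_MAX, K_MIN

        if not K_MIN <= self.k <= K_MAX:
            raise ConfigError(f"k must be in [{K_MIN}, {K_MAX}], got {self.k}")


@dataclass
class PipelineResult:
    """Fitted pipeline plus test-split predictions and report accessors."""

    config: PipelineConfig
    manifest: DatasetManifest
    cv_results: list[ms.CVResult]
    best_spec: ms.ClassifierSpec
    bundle: ms.ModelBundle
    features: pd.DataFrame  # per-image histograms for the winning (rep, k)
    predictions: pd.DataFrame  # test rows: image_path, labels, pred, visit, round
    segmentation_fraction: pd.Series = field(default=None)

    @property
    def y_true(self) -> np.ndarray:
        return self.predictions["producer_id"].to_numpy()

    @property
    def y_pred(self) -> np.ndarray:
        return self.predictions["predicted"].to_numpy()

    def producer_report(self) -> MetricsReport:
        classes = sorted(self.manifest.producer_to_municipality)
        return metrics(confusion(self.y_true, self.y_pred, classes))

    def municipality_report(self) -> MetricsReport:
        return municipality_rollup(
            self.y_true, self.y_pred, self.manifest.producer_to_municipality
        )

    def temporal_report(self) -> pd.DataFrame:
        return temporal_table(
            self.y_true, self.y_pred, self.predictions["visit"].to_numpy()
        )

    def reliability_report(self, level: str = "producer") -> ReliabilityReport:
        """Test-retest reliability at producer or municipality level."""
        rounds = self.predictions["acquisition_round"].to_numpy()
        if level == "producer":
            return test_retest(self.y_true, self.y_pred, rounds)
        if level == "municipality":
            mapping = self.manifest.producer_to_municipality
            t = np.array([mapping[p] for p in self.y_true])
            p = np.array([mapping[q] for q in self.y_pred])
            return test_retest(t, p, rounds)
        raise ConfigError(f"unknown reliability level {level!r}")


def _masked_pixels(
    manifest: DatasetManifest, config: PipelineConfig
) -> tuple[list[np.ndarray], pd.Series]:
    """Segment every image; return per-record masked RGB pixels (subsampled
    to ``max_hist_pixels``) and the per-image masked-pixel fraction."""
    arrays: list[np.ndarray] = []
    fractions = []
    for i, rec in enumerate(manifest.records):
        img = load_image(manifest.resolve(rec))
        raw = preprocess.segment_pollen(img, radius=config.radius, n_bins=config.n_bins)
        refined = preprocess.remove_shadows(img, raw, rule=config.shadow_rule)
        pixels = img[refined].astype(np.float32)
        if pixels.shape[0] > config.max_hist_pixels:
            rng = np.random.default_rng([config.seed, 15485863, i])
            idx = rng.choice(
                pixels.shape[0], size=config.max_hist_pixels, replace=False
            )
            pixels = pixels[np.sort(idx)]
        arrays.append(pixels)
        fractions.append(refined.mean())
    paths = [r.image_path for r in manifest.records]
    return arrays, pd.Series(fractions, index=paths, name="masked_fraction")


def run_pipeline(
    manifest: DatasetManifest,
    grid: Optional[Sequence[ms.ClassifierSpec]] = None,
    config: PipelineConfig = None,
) -> PipelineResult:
    """Run segmentation, featurization, model selection and test prediction."""
    config = config or PipelineConfig()
    if grid is None:
        grid = ms.default_grid(
            representations=(config.representation,), k_values=(config.k,)
        )
    grid = list(grid)
    if not grid:
        raise ConfigError("empty classifier grid")

    records = manifest.records
    is_train = np.array([r.split == "train" for r in records])
    labels = np.array([r.producer_id for r in records])
    logger.info("segmenting %d images", len(records))
    pixel_arrays, masked_fraction = _masked_pixels(manifest, config)

    empty = [records[i].image_path for i, a in enumerate(pixel_arrays) if not len(a)]
    if empty:
        raise ConfigError(f"empty refined masks for image(s): {empty[:5]}")

    folds = ms.stratified_folds(
        labels[is_train], n_folds=config.n_folds, seed=config.seed
    )

    groups: dict[tuple[str, int], list[ms.ClassifierSpec]] = {}
    for spec in grid:
        groups.setdefault((spec.representation, spec.k), []).append(spec)

    rep_cache: dict[str, list[np.ndarray]] = {}
    all_results: list[ms.CVResult] = []
    group_artifacts: dict[tuple[str, int], tuple] = {}
    for (rep, k), specs in groups.items():
        if rep not in rep_cache:
            rep_cache[rep] = [
                colorspace.rgb_to_representation(a, rep, v_prime=config.v_prime)
                for a in pixel_arrays
            ]
        rep_arrays = rep_cache[rep]
        pool_source = (
            [a for a, t in zip(rep_arrays, is_train) if t]
            if config.codebook_scope == "train_only"
            else list(rep_arrays)
        )
        pooled = feat.subsample_pixels(
            pool_source, config.max_per_image, seed=config.seed
        )
        codebook = feat.fit_codebook(
            pooled,
            k=k,
            seed=config.seed,
            representation=rep,
            batch_size=config.batch_size,
            n_iter=config.n_iter,
        )
        hist = np.vstack(
            [feat.histogram_from_pixels(a, codebook) for a in rep_arrays]
        )
        group_artifacts[(rep, k)] = (codebook, hist)
        for spec in specs:
            result = ms.cross_validate(
                hist[is_train], labels[is_train], spec, folds, seed=config.seed
            )
            logger.info(
                "CV %s: mean weighted F1 = %.4f", spec.to_dict(), result.mean_weighted_f1
            )
            all_results.append(result)

    best = ms.select_best(all_results)
    codebook, hist = group_artifacts[(best.representation, best.k)]
    bundle = ms.train_final(
        hist[is_train], labels[is_train], best, seed=config.seed, codebook=codebook
    )

    feat_df = pd.DataFrame(
        hist, columns=[f"c{i}" for i in range(hist.shape[1])]
    )
    feat_df.insert(0, "image_path", [r.image_path for r in records])

    test_idx = np.flatnonzero(~is_train)
    preds = bundle.predict(hist[test_idx])
    predictions = pd.DataFrame(
        {
            "image_path": [records[i].image_path for i in test_idx],
            "producer_id": [records[i].producer_id for i in test_idx],
            "predicted": preds,
            "municipality": [records[i].municipality for i in test_idx],
            "visit": [records[i].visit for i in test_idx],
            "acquisition_round": [records[i].acquisition_round for i in test_idx],
        }
    )
    return PipelineResult(
        config=config,
        manifest=manifest,
        cv_results=all_results,
        best_spec=best,
        bundle=bundle,
        features=feat_df,
        predictions=predictions,
        segmentation_fraction=masked_fraction,
    )


def predict_manifest(
    bundle: ms.ModelBundle,
    manifest: DatasetManifest,
    config: PipelineConfig = None,
) -> pd.DataFrame:
    """Apply a fitted bundle to every image of a manifest."""
    config = config or PipelineConfig()
    rows = []
    for rec in manifest.records:
        img = load_image(manifest.resolve(rec))
        raw = preprocess.segment_pollen(img, radius=config.radius, n_bins=config.n_bins)
        refined = preprocess.remove_shadows(img, raw, rule=config.shadow_rule)
        h = feat.histogram_features(img, refined, bundle.codebook)
        rows.append((rec, bundle.predict(h[None, :])[0]))
    return pd.DataFrame(
        {
            "image_path": [r.image_path for r, _ in rows],
            "producer_id": [r.producer_id for r, _ in rows],
            "predicted": [p for _, p in rows],
            "municipality": [r.municipality for r, _ in rows],
            "visit": [r.visit for r, _ in rows],
            "acquisition_round": [r.acquisition_round for r, _ in rows],
        }
    )
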