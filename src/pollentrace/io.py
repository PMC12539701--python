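"""Reading and writing of manifests, images, configs, features and models.

The dataset manifest is a UTF-8 CSV with header
``image_path,producer_id,municipality,visit,acquisition_round,split`` and
image paths relative to the manifest's directory.  A manifest binds each
image to its producer (the classification label), the producer's
municipality, the seasonal sampling visit (1-4), the acquisition round
(1 or 2, the two time-separated photo sessions used for test-retest
reliability) and the train/test split.

Trained models are persisted as a *directory* — codebook table, classifier
parameters and a JSON metadata file — rather than one opaque blob, so every
part of a fitted pipeline stays inspectable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import joblib
import numpy as np
import pandas as pd
import yaml
from PIL import Image, UnidentifiedImageError

from .errors import (
    ConsistencyError,
    ContractError,
    FormatError,
    IncompatibilityError,
    SchemaError,
)

logger = logging.getLogger(__name__)

MANIFEST_COLUMNS = [
    "image_path",
    "producer_id",
    "municipality",
    "visit",
    "acquisition_round",
    "split",
]

#: Format version stamped into persisted model bundles.
BUNDLE_FORMAT_VERSION = 1

__all__ = [
    "SampleRecord",
    "DatasetManifest",
    "read_manifest",
    "write_manifest",
    "load_image",
    "save_image",
    "read_config",
    "write_config",
    "write_features",
    "read_features",
    "persist_model",
    "load_model",
]


@dataclass(frozen=True)
class SampleRecord:
    """One image of one pollen sample with its labels and metadata."""

    image_path: str
    producer_id: str
    municipality: str
    visit: int
    acquisition_round: int
    split: str

    def __post_init__(self) -> None:
        if not self.image_path:
            raise SchemaError("image_path must be nonempty")
        if self.visit not in (1, 2, 3, 4):
            raise SchemaError(f"visit must be in 1..4, got {self.visit}")
        if self.acquisition_round not in (1, 2):
            raise SchemaError(
                f"acquisition_round must be 1 or 2, got {self.acquisition_round}"
            )
        if self.split not in ("train", "test"):
            raise SchemaError(f"split must be 'train' or 'test', got {self.split!r}")


@dataclass
class DatasetManifest:
    """Ordered image records plus the producer -> municipality mapping."""

    records: list[SampleRecord]
    producer_to_municipality: dict[str, str]
    root: Path = field(default_factory=Path)

    def __post_init__(self) -> None:
        for rec in self.records:
            mapped = self.producer_to_municipality.get(rec.producer_id)
            if mapped is None:
                raise ConsistencyError(
                    f"producer {rec.producer_id!r} missing from municipality mapping"
                )
            if mapped != rec.municipality:
                raise ConsistencyError(
                    f"producer {rec.producer_id!r} mapped to both "
                    f"{mapped!r} and {rec.municipality!r}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def subset(self, split: str) -> "DatasetManifest":
        """Records restricted to one split, sharing root and mapping."""
        recs = [r for r in self.records if r.split == split]
        producers = {r.producer_id for r in recs}
        mapping = {
            p: m for p, m in self.producer_to_municipality.items() if p in producers
        }
        return DatasetManifest(recs, mapping, root=self.root)

    def resolve(self, record: SampleRecord) -> Path:
        """Absolute path of a record's image file."""
        return self.root / record.image_path

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.records], columns=MANIFEST_COLUMNS)


def read_manifest(path: str | Path) -> DatasetManifest:
    """Parse a manifest CSV, validating schema and the municipality mapping."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"manifest {path} missing required column(s): {missing}")
    records = []
    for row in df.itertuples(index=False):
        try:
            visit = int(row.visit)
            rnd = int(row.acquisition_round)
        except (TypeError, ValueError) as exc:
            raise SchemaError(f"non-integer visit/round in row {row!r}") from exc
        records.append(
            SampleRecord(
                image_path=row.image_path,
                producer_id=row.producer_id,
                municipality=row.municipality,
                visit=visit,
                acquisition_round=rnd,
                split=row.split,
            )
        )
    mapping: dict[str, str] = {}
    for rec in records:
        prev = mapping.setdefault(rec.producer_id, rec.municipality)
        if prev != rec.municipality:
            raise ConsistencyError(
                f"producer {rec.producer_id!r} assigned to two municipalities: "
                f"{prev!r} and {rec.municipality!r}"
            )
    manifest = DatasetManifest(records, mapping, root=path.parent)
    logger.info("read manifest %s: %d records, %d producers", path, len(records), len(mapping))
    return manifest


def write_manifest(manifest: DatasetManifest, path: str | Path) -> Path:
    """Write a manifest CSV (image paths are stored as given, i.e. relative)."""
    path = Path(path)
    manifest.to_frame().to_csv(path, index=False)
    return path


def load_image(path: str | Path) -> np.ndarray:
    """Load an 8-bit PNG/JPEG as an HxWx3 float array in [0,1].

    An alpha channel is dropped; single-channel (grayscale or palette) input
    raises :class:`FormatError`.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            mode = im.mode
            if mode == "RGBA":
                im = im.convert("RGB")
            elif mode != "RGB":
                raise FormatError(
                    f"{path}: expected an RGB image, got mode {mode!r}"
                )
            arr = np.asarray(im, dtype=np.uint8)
    except FileNotFoundError:
        raise
    except UnidentifiedImageError as exc:
        raise FormatError(f"{path}: not a readable PNG/JPEG image") from exc
    return arr.astype(float) / 255.0


def save_image(img: np.ndarray, path: str | Path) -> Path:
    """Write a float RGB image in [0,1] (or a boolean mask) as PNG."""
    path = Path(path)
    arr = np.asarray(img)
    if arr.dtype == bool:
        Image.fromarray(arr).save(path)
        return path
    data = np.clip(np.round(arr * 255.0), 0, 255).astype(np.uint8)
    Image.fromarray(data).save(path)
    return path


def read_config(path: str | Path) -> dict:
    """Read a YAML key/value configuration file."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def write_config(config: Mapping, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(dict(config), fh, sort_keys=True)
    return path


def write_features(
    image_paths: Iterable[str], histograms: np.ndarray, path: str | Path
) -> Path:
    """Write per-image codebook frequency vectors as CSV (one row per image)."""
    histograms = np.asarray(histograms, dtype=float)
    paths = list(image_paths)
    if histograms.ndim != 2 or len(paths) != histograms.shape[0]:
        raise ContractError("image_paths and histogram rows must align")
    k = histograms.shape[1]
    df = pd.DataFrame(histograms, columns=[f"c{i}" for i in range(k)])
    df.insert(0, "image_path", paths)
    df.to_csv(path, index=False)
    return Path(path)


def read_features(path: str | Path) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path)
    if "image_path" not in df.columns:
        raise SchemaError(f"feature file {path} missing 'image_path' column")
    return df["image_path"].tolist(), df.drop(columns="image_path").to_numpy(float)


def persist_model(bundle, path: str | Path) -> Path:
    """Persist a trained-model bundle as an inspectable directory.

    Layout: ``codebook.csv`` (centroid table), ``classifier.joblib`` (fitted
    estimator), ``meta.json`` (format version, representation, classifier
    spec, class list).
    """
    from .features import save_codebook
    from .model_select import ModelBundle

    if not isinstance(bundle, ModelBundle):
        raise ContractError(f"expected a ModelBundle, got {type(bundle).__name__}")
    if bundle.codebook is None:
        raise ContractError("bundle is missing its color codebook")
    if bundle.estimator is None or bundle.classes is None:
        raise ContractError("bundle is missing its fitted classifier or class list")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    save_codebook(bundle.codebook, path / "codebook.csv")
    joblib.dump(bundle.estimator, path / "classifier.joblib")
    meta = {
        "format_version": BUNDLE_FORMAT_VERSION,
        "representation": bundle.codebook.representation,
        "classes": list(bundle.classes),
        "spec": bundle.spec.to_dict(),
    }
    with open(path / "meta.json", "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=2)
    logger.info("persisted model bundle to %s", path)
    return path


def load_model(path: str | Path):
    """Load a model bundle directory; raises IncompatibilityError when the
    directory is truncated, corrupt, or written by an unsupported version."""
    from .features import load_codebook
    from .model_select import ClassifierSpec, ModelBundle

    path = Path(path)
    meta_path = path / "meta.json"
    try:
        with open(meta_path, "r", encoding="utf-8") as fh:
            meta = json.load(fh)
    except (FileNotFoundError, json.JSONDecodeError) as exc:
        raise IncompatibilityError(f"{path}: missing or corrupt meta.json") from exc
    version = meta.get("format_version")
    if version != BUNDLE_FORMAT_VERSION:
        raise IncompatibilityError(
            f"{path}: bundle format version {version!r} not supported "
            f"(expected {BUNDLE_FORMAT_VERSION})"
        )
    try:
        codebook = load_codebook(path / "codebook.csv")
        estimator = joblib.load(path / "classifier.joblib")
    except Exception as exc:  # truncated/corrupt artifacts surface uniformly
        raise IncompatibilityError(f"{path}: bundle artifacts unreadable") from exc
    spec = ClassifierSpec.from_dict(meta["spec"])
    return ModelBundle(
        spec=spec,
        estimator=estimator,
        classes=list(meta["classes"]),
        codebook=codebook,
    )
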