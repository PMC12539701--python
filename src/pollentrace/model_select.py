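"""Classifier grid, stratified cross-validation and final-model training.

Three classifier families compete for the producer-identification task:
support vector machines with polynomial kernels (degrees 4-10), random
forests with up to 200 trees, and small multilayer perceptrons.  Each family
is crossed with the four color representations and the candidate codebook
sizes; the winner is the specification with the highest mean weighted
F1-score under stratified 10-fold cross-validation on the training split.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import f1_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .errors import ConfigError, ContractError, StratificationError
from .features import ColorCodebook

logger = logging.getLogger(__name__)

FAMILIES = ("svm_poly", "random_forest", "mlp")
SVM_DEGREE_RANGE = (4, 10)
RF_MAX_TREES = 200

__all__ = [
    "ClassifierSpec",
    "CVResult",
    "ModelBundle",
    "default_grid",
    "build_estimator",
    "stratified_folds",
    "cross_validate",
    "select_best",
    "train_final",
]


@dataclass(frozen=True)
class ClassifierSpec:
    """One point of the model-selection grid."""

    family: str
    representation: str
    k: int
    degree: Optional[int] = None  # svm_poly
    C: Optional[float] = None  # svm_poly
    coef0: Optional[float] = None  # svm_poly
    n_trees: Optional[int] = None  # random_forest
    hidden_layers: Optional[tuple[int, ...]] = None  # mlp

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ConfigError(f"unknown classifier family {self.family!r}")
        if self.family == "svm_poly":
            if not (SVM_DEGREE_RANGE[0] <= (self.degree or 0) <= SVM_DEGREE_RANGE[1]):
                raise ConfigError(
                    f"svm_poly degree must be in {SVM_DEGREE_RANGE}, got {self.degree}"
                )
            if self.C is None or self.C <= 0:
                raise ConfigError("svm_poly requires C > 0")
        elif self.family == "random_forest":
            if not 1 <= (self.n_trees or 0) <= RF_MAX_TREES:
                raise ConfigError(f"n_trees must be in [1, {RF_MAX_TREES}]")
        elif self.family == "mlp" and not self.hidden_layers:
            raise ConfigError("mlp requires at least one hidden layer")

    def complexity(self) -> int:
        """Scalar parameter-count proxy used as the tie-break in selection."""
        if self.family == "svm_poly":
            return self.degree
        if self.family == "random_forest":
            return self.n_trees
        return sum(self.hidden_layers)

    def sort_key(self) -> tuple:
        """Deterministic lexicographic ordering of specs (final tie-break)."""
        return (
            self.family,
            self.representation,
            self.k,
            self.degree or 0,
            self.C or 0.0,
            self.coef0 or 0.0,
            self.n_trees or 0,
            self.hidden_layers or (),
        )

    def to_dict(self) -> dict:
        d = {"family": self.family, "representation": self.representation, "k": self.k}
        for name in ("degree", "C", "coef0", "n_trees"):
            if getattr(self, name) is not None:
                d[name] = getattr(self, name)
        if self.hidden_layers is not None:
            d["hidden_layers"] = list(self.hidden_layers)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ClassifierSpec":
        d = dict(d)
        if "hidden_layers" in d and d["hidden_layers"] is not None:
            d["hidden_layers"] = tuple(d["hidden_layers"])
        return cls(**d)


@dataclass
class CVResult:
    """Cross-validation outcome for one spec."""

    spec: ClassifierSpec
    fold_scores: np.ndarray

    def __post_init__(self) -> None:
        self.fold_scores = np.asarray(self.fold_scores, dtype=float)

    @property
    def mean_weighted_f1(self) -> float:
        return float(self.fold_scores.mean())


@dataclass
class ModelBundle:
    """A fitted classifier together with everything needed to apply it."""

    spec: ClassifierSpec
    estimator: object
    classes: list[str]
    codebook: Optional[ColorCodebook] = None

    def predict(self, features: np.ndarray) -> np.ndarray:
        return self.estimator.predict(np.asarray(features, dtype=float))


def default_grid(
    representations: Sequence[str] = ("hsv", "luv", "hs", "uv"),
    k_values: Sequence[int] = (32,),
    svm_degrees: Sequence[int] = tuple(range(4, 11)),
    svm_C: Sequence[float] = (0.91,),
    svm_coef0: Sequence[float] = (1.3,),
    rf_trees: Sequence[int] = (50, 100, 200),
    mlp_hidden: Sequence[tuple[int, ...]] = ((32,), (64,), (128,), (64, 64)),
) -> list[ClassifierSpec]:
    """Cartesian product of families, hyperparameters, representations and k.

    The defaults span the search families (SVM poly degrees 4-10, random
    forests up to 200 trees, small MLPs) and include the reference winning
    configuration (svm_poly, degree 6, C=0.91, coef0=1.3, uv, k=32).
    """
    grid: list[ClassifierSpec] = []
    for rep in representations:
        for k in k_values:
            for deg in svm_degrees:
                for C in svm_C:
                    for c0 in svm_coef0:
                        grid.append(
                            ClassifierSpec(
                                "svm_poly", rep, k, degree=deg, C=C, coef0=c0
                            )
                        )
            for n in rf_trees:
                grid.append(ClassifierSpec("random_forest", rep, k, n_trees=n))
            for hidden in mlp_hidden:
                grid.append(ClassifierSpec("mlp", rep, k, hidden_layers=tuple(hidden)))
    return grid


def build_estimator(spec: ClassifierSpec, seed: int = 0):
    """Instantiate the scikit-learn estimator for a spec."""
    if spec.family == "svm_poly":
        return SVC(
            kernel="poly",
            degree=spec.degree,
            C=spec.C,
            coef0=spec.coef0 if spec.coef0 is not None else 0.0,
            gamma="scale",
            random_state=seed,
        )
    if spec.family == "random_forest":
        return RandomForestClassifier(n_estimators=spec.n_trees, random_state=seed)
    return MLPClassifier(
        hidden_layer_sizes=spec.hidden_layers,
        max_iter=500,
        random_state=seed,
    )


def stratified_folds(
    labels: Sequence[str], n_folds: int = 10, seed: int = 0
) -> np.ndarray:
    """Fold assignment (0..n_folds-1 per sample) preserving class proportions.

    Every class must have at least ``n_folds`` members; each fold's per-class
    count then differs from the proportional share by at most one sample.
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    small = classes[counts < n_folds]
    if small.size:
        raise StratificationError(
            f"class(es) {small.tolist()} have fewer than {n_folds} members"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    assignment = np.empty(labels.shape[0], dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(labels.shape[0]), labels)):
        assignment[test_idx] = fold
    return assignment


def cross_validate(
    features: np.ndarray,
    labels: Sequence[str],
    spec: ClassifierSpec,
    folds: np.ndarray,
    seed: int = 0,
) -> CVResult:
    """Weighted-F1 cross-validation of one spec over precomputed folds.

    A fold whose training part degenerates to a single class is scored 0
    with a warning rather than aborting the sweep.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    folds = np.asarray(folds)
    if not (features.shape[0] == labels.shape[0] == folds.shape[0]):
        raise ContractError("features, labels and folds must align")
    scores = []
    for fold in np.unique(folds):
        train = folds != fold
        if np.unique(labels[train]).size < 2:
            warnings.warn(
                f"fold {fold}: training part has a single class; scored 0",
                stacklevel=2,
            )
            scores.append(0.0)
            continue
        est = build_estimator(spec, seed=seed)
        est.fit(features[train], labels[train])
        pred = est.predict(features[~train])
        scores.append(
            f1_score(labels[~train], pred, average="weighted", zero_division=0)
        )
    return CVResult(spec, np.array(scores))


def select_best(results: Iterable[CVResult]) -> ClassifierSpec:
    """Spec with the highest mean weighted F1.

    Exact ties go to the lower-complexity spec (fewer effective parameters),
    then to the lexicographically smaller spec, so selection is invariant to
    the order of the results.
    """
    results = list(results)
    if not results:
        raise ContractError("select_best requires at least one CVResult")
    return min(
        results,
        key=lambda r: (-r.mean_weighted_f1, r.spec.complexity(), r.spec.sort_key()),
    ).spec


def train_final(
    features: np.ndarray,
    labels: Sequence[str],
    spec: ClassifierSpec,
    seed: int = 0,
    codebook: Optional[ColorCodebook] = None,
) -> ModelBundle:
    """Fit the selected spec on the full training split."""
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    est = build_estimator(spec, seed=seed)
    est.fit(features, labels)
    classes = sorted(np.unique(labels).tolist())
    return ModelBundle(spec=spec, estimator=est, classes=classes, codebook=codebook)
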