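"""Class-weighted gradient-boosted table classifier: training with AUC-ROC
early stopping, grid-search tuning by 10-fold cross-validated macro-F1, and a
persisted pipeline bundle (model + vocabulary + serialization config).

The boosted ensemble is realized with scikit-learn's
``GradientBoostingClassifier`` (multinomial cross-entropy objective).
Hyperparameter names keep the boosted-tree vocabulary and map onto the
underlying estimator: ``min_child_weight``→``min_samples_leaf``,
``gamma``→``min_impurity_decrease``, ``colsample_bytree``→``max_features``.
"""
from __future__ import annotations

import itertools
import logging
import math
import pickle
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split

from . import evaluation
from .features import Vocabulary, bow_encode, fit_vocabulary
from .labels import CLASS_ORDER, Label
from .serialization import FieldKind, select_field
from .table_io import Corpus, ExtractedTable

logger = logging.getLogger(__name__)

__all__ = [
    "Hyperparameters",
    "TABLE1_GRID",
    "BoostedModel",
    "Prediction",
    "TableClassifier",
    "compute_class_weights",
    "grid_candidates",
    "train",
    "tune",
    "predict",
    "predict_many",
    "prediction_from_probabilities",
    "fit_table_classifier",
]


@dataclass(frozen=True)
class Hyperparameters:
    """Boosted-tree settings; learning rate is fixed at 0.1 by default and the
    boosting loop is capped at 1000 rounds with 10-round AUC patience."""

    max_depth: int = 6
    min_child_weight: int = 1
    gamma: float = 0.0
    subsample: float = 1.0
    colsample_bytree: float = 1.0
    learning_rate: float = 0.1
    max_rounds: int = 1000
    early_stopping_rounds: int = 10

    def __post_init__(self) -> None:
        if self.max_depth < 1:
            raise ValueError(f"max_depth must be >= 1, got {self.max_depth}")
        if not 0 < self.subsample <= 1:
            raise ValueError(f"subsample must be in (0, 1], got {self.subsample}")
        if not 0 < self.colsample_bytree <= 1:
            raise ValueError(
                f"colsample_bytree must be in (0, 1], got {self.colsample_bytree}"
            )
        if self.gamma < 0:
            raise ValueError(f"gamma must be >= 0, got {self.gamma}")


#: Published tuning grid: (low, high, step) per dimension.
TABLE1_GRID: dict[str, tuple[float, float, float]] = {
    "max_depth": (2, 10, 2),
    "min_child_weight": (1, 6, 2),
    "gamma": (0.1, 0.5, 0.1),
    "subsample": (0.5, 1.0, 0.1),
    "colsample_bytree": (0.3, 1.0, 0.1),
}

_GRID_DIMENSIONS = tuple(TABLE1_GRID)


def _axis_values(low, high, step) -> list:
    """Inclusive arithmetic range generated by integer index scaling (exact
    value counts even for fractional steps)."""
    if step <= 0:
        raise ValueError(f"grid step must be positive, got {step}")
    count = int(math.floor((high - low) / step + 1e-9)) + 1
    values = [low + i * step for i in range(count)]
    if all(isinstance(v, int) for v in (low, high, step)):
        return [int(v) for v in values]
    return [round(v, 10) for v in values]


def grid_candidates(
    spec: Mapping[str, tuple] | None = None,
) -> list[Hyperparameters]:
    """Cartesian product of the per-dimension ranges in deterministic
    row-major order (dimension order: max_depth, min_child_weight, gamma,
    subsample, colsample_bytree)."""
    spec = dict(spec) if spec is not None else dict(TABLE1_GRID)
    axes = []
    for name in _GRID_DIMENSIONS:
        if name in spec:
            axes.append(_axis_values(*spec[name]))
        else:
            axes.append([getattr(Hyperparameters(), name)])
    return [
        Hyperparameters(
            max_depth=d, min_child_weight=w, gamma=g, subsample=s, colsample_bytree=c
        )
        for d, w, g, s, c in itertools.product(*axes)
    ]


def compute_class_weights(label_counts: Mapping[Label, int]) -> dict[Label, float]:
    """Sample weights inverse to class frequency: w_c = N / (K * n_c).

    The weighted sample mass is conserved (sum over classes of n_c * w_c = N),
    i.e. the mean sample weight is 1.
    """
    for label in CLASS_ORDER:
        if label_counts.get(label, 0) < 1:
            raise ValueError(f"class {label.value} is missing from label_counts")
    total = sum(label_counts[label] for label in CLASS_ORDER)
    k = len(CLASS_ORDER)
    return {label: total / (k * label_counts[label]) for label in CLASS_ORDER}


@dataclass
class Prediction:
    """Per-class probabilities (canonical class order), argmax label, and
    confidence = max probability."""

    probabilities: np.ndarray
    label: Label
    confidence: float

    def to_dict(self) -> dict:
        return {
            "probabilities": {
                label.value: float(p)
                for label, p in zip(CLASS_ORDER, self.probabilities)
            },
            "label": self.label.value,
            "confidence": self.confidence,
        }


def prediction_from_probabilities(probabilities: Sequence[float]) -> Prediction:
    """Argmax read-out; exact ties resolve to the earlier class in the
    canonical (PK, DEMOGRAPHICS, OTHER) order."""
    probs = np.asarray(probabilities, dtype=float)
    if probs.shape != (len(CLASS_ORDER),):
        raise ValueError(f"expected {len(CLASS_ORDER)} probabilities, got {probs.shape}")
    winner = int(np.argmax(probs))
    return Prediction(
        probabilities=probs, label=CLASS_ORDER[winner], confidence=float(probs[winner])
    )


@dataclass
class BoostedModel:
    """A fitted boosted ensemble plus its training metadata."""

    estimator: GradientBoostingClassifier
    class_order: tuple[Label, ...]
    hyperparameters: Hyperparameters
    best_iteration: int
    rounds_used: int
    n_features: int
    representation_tag: str = "bow"


def _macro_ovr_auc(y_true: np.ndarray, probabilities: np.ndarray) -> float:
    """Macro one-vs-rest AUC-ROC over classes present in ``y_true`` with both
    positives and negatives; 0.5 if none is computable."""
    aucs = []
    for class_idx in range(probabilities.shape[1]):
        positives = y_true == class_idx
        if positives.any() and (~positives).any():
            aucs.append(roc_auc_score(positives, probabilities[:, class_idx]))
    return float(np.mean(aucs)) if aucs else 0.5


def _encode_labels(labels: Sequence) -> np.ndarray:
    index = {label: i for i, label in enumerate(CLASS_ORDER)}
    try:
        return np.array([index[Label(l)] for l in labels], dtype=np.int64)
    except (KeyError, ValueError) as exc:
        raise ValueError(f"labels outside the three-class set: {exc}") from exc


def train(
    features: np.ndarray,
    labels: Sequence,
    sample_weights: Sequence[float] | None = None,
    hp: Hyperparameters | None = None,
    eval_fraction: float = 0.1,
    seed: int = 0,
) -> BoostedModel:
    """Fit the boosted classifier with AUC-ROC early stopping.

    A stratified ``eval_fraction`` of the data is carved out for monitoring;
    boosting halts after ``hp.early_stopping_rounds`` rounds without AUC
    improvement and is capped at ``hp.max_rounds``. The returned ensemble is
    truncated to the best iteration. Deterministic given ``seed``.
    """
    hp = hp or Hyperparameters()
    X = np.asarray(features, dtype=float)
    y = _encode_labels(labels)
    if X.shape[0] != y.shape[0]:
        raise ValueError(
            f"feature/label length mismatch: {X.shape[0]} rows vs {y.shape[0]} labels"
        )
    if len(np.unique(y)) < 2:
        raise ValueError("training requires at least 2 classes present in labels")
    weights = (
        np.ones(len(y), dtype=float)
        if sample_weights is None
        else np.asarray(sample_weights, dtype=float)
    )
    if weights.shape[0] != y.shape[0]:
        raise ValueError("sample_weights length does not match labels")

    X_fit, X_eval, y_fit, y_eval, w_fit, _ = train_test_split(
        X, y, weights, test_size=eval_fraction, stratify=y, random_state=seed
    )

    estimator = GradientBoostingClassifier(
        learning_rate=hp.learning_rate,
        max_depth=hp.max_depth,
        min_samples_leaf=hp.min_child_weight,
        min_impurity_decrease=hp.gamma,
        subsample=hp.subsample,
        max_features=hp.colsample_bytree if hp.colsample_bytree < 1 else None,
        n_estimators=1,
        warm_start=True,
        random_state=seed,
    )

    best_auc = -np.inf
    best_iteration = 0
    stagnant = 0
    rounds_used = 0
    for boosting_round in range(1, hp.max_rounds + 1):
        estimator.set_params(n_estimators=boosting_round)
        estimator.fit(X_fit, y_fit, sample_weight=w_fit)
        rounds_used = boosting_round
        auc = _macro_ovr_auc(y_eval, estimator.predict_proba(X_eval))
        if auc > best_auc + 1e-9:
            best_auc = auc
            best_iteration = boosting_round - 1
            stagnant = 0
        else:
            stagnant += 1
            if stagnant >= hp.early_stopping_rounds:
                break

    # keep only the ensemble prefix up to the best monitored iteration
    estimator.estimators_ = estimator.estimators_[: best_iteration + 1]
    estimator.set_params(warm_start=False, n_estimators=best_iteration + 1)
    logger.debug(
        "trained %d rounds (best iteration %d, eval AUC %.4f)",
        rounds_used,
        best_iteration,
        best_auc,
    )
    return BoostedModel(
        estimator=estimator,
        class_order=CLASS_ORDER,
        hyperparameters=hp,
        best_iteration=best_iteration,
        rounds_used=rounds_used,
        n_features=X.shape[1],
    )


def predict(model: BoostedModel, features: np.ndarray) -> Prediction:
    """Probability read-out for a single feature vector."""
    vector = np.asarray(features, dtype=float).reshape(1, -1)
    if vector.shape[1] != model.n_features:
        raise ValueError(
            f"feature dimension mismatch: model expects {model.n_features}, "
            f"got {vector.shape[1]}"
        )
    probabilities = model.estimator.predict_proba(vector)[0]
    return prediction_from_probabilities(probabilities)


def predict_many(model: BoostedModel, features: np.ndarray) -> list[Prediction]:
    matrix = np.asarray(features, dtype=float)
    if matrix.ndim != 2 or matrix.shape[1] != model.n_features:
        raise ValueError(
            f"feature dimension mismatch: model expects (*, {model.n_features}), "
            f"got {matrix.shape}"
        )
    return [
        prediction_from_probabilities(row)
        for row in model.estimator.predict_proba(matrix)
    ]


def tune(
    train_features: np.ndarray,
    train_labels: Sequence,
    grid: Sequence[Hyperparameters] | None = None,
    folds: int = 10,
    seed: int = 0,
) -> tuple[Hyperparameters, list[dict]]:
    """Stratified k-fold cross-validated grid search selecting on mean
    macro-F1 (ties go to the earlier grid candidate).

    Sample weights are recomputed from each fold's training counts. The report
    records per-fold scores plus their mean and sample standard deviation.
    """
    grid = list(grid) if grid is not None else grid_candidates()
    if not grid:
        raise ValueError("grid is empty")
    X = np.asarray(train_features, dtype=float)
    y = _encode_labels(train_labels)
    class_counts = np.bincount(y, minlength=len(CLASS_ORDER))
    min_count = int(class_counts.min())
    if min_count < folds:
        raise ValueError(
            f"smallest class has {min_count} members, fewer than {folds} folds; "
            f"use at most {min_count} folds"
        )

    splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_indices = list(splitter.split(X, y))

    report: list[dict] = []
    best_hp = grid[0]
    best_mean = -np.inf
    for candidate in grid:
        fold_scores = []
        for fold_idx, (fit_idx, test_idx) in enumerate(fold_indices):
            y_fit = y[fit_idx]
            counts = {
                label: int((y_fit == i).sum()) for i, label in enumerate(CLASS_ORDER)
            }
            weights_by_class = compute_class_weights(counts)
            w_fit = np.array(
                [weights_by_class[CLASS_ORDER[i]] for i in y_fit], dtype=float
            )
            model = train(
                X[fit_idx],
                [CLASS_ORDER[i] for i in y_fit],
                sample_weights=w_fit,
                hp=candidate,
                seed=seed + fold_idx,
            )
            predictions = predict_many(model, X[test_idx])
            fold_report = evaluation.score(
                [CLASS_ORDER[i] for i in y[test_idx]], [p.label for p in predictions]
            )
            fold_scores.append(fold_report.macro_f1)
        mean = float(np.mean(fold_scores))
        sd = float(np.std(fold_scores, ddof=1)) if len(fold_scores) > 1 else 0.0
        report.append(
            {
                "hyperparameters": candidate.__dict__ | {},
                "fold_macro_f1": fold_scores,
                "mean_macro_f1": mean,
                "sd_macro_f1": sd,
            }
        )
        if mean > best_mean:
            best_mean = mean
            best_hp = candidate
    return best_hp, report


# ---------------------------------------------------------------------------
# Persisted pipeline bundle
# ---------------------------------------------------------------------------

_FORMAT_VERSION = 1


@dataclass
class TableClassifier:
    """End-to-end table pipeline: field selection + BoW + boosted model.

    A prediction is meaningless without its featurization, so the persisted
    artifact bundles the ensemble with the vocabulary, the field kind, the
    serialization config, and the class order.
    """

    model: BoostedModel
    vocabulary: Vocabulary
    field_kind: FieldKind
    first_few_rows_k: int = 3
    escape_pipes: bool = True
    format_version: int = _FORMAT_VERSION
    metadata: dict = field(default_factory=dict)

    def featurize(self, table: ExtractedTable) -> np.ndarray:
        text = select_field(
            table,
            self.field_kind,
            first_few_rows_k=self.first_few_rows_k,
            escape_pipes=self.escape_pipes,
        )
        return bow_encode(text, self.vocabulary).values

    def predict_table(self, table: ExtractedTable) -> Prediction:
        return predict(self.model, self.featurize(table))

    def predict_tables(self, tables: Sequence[ExtractedTable]) -> list[Prediction]:
        matrix = np.stack([self.featurize(t) for t in tables])
        return predict_many(self.model, matrix)

    def save(self, path) -> None:
        with open(path, "wb") as handle:
            pickle.dump({"format_version": self.format_version, "payload": self}, handle)

    @classmethod
    def load(cls, path) -> "TableClassifier":
        with open(path, "rb") as handle:
            blob = pickle.load(handle)
        if blob.get("format_version") != _FORMAT_VERSION:
            raise ValueError(
                f"unsupported model format version {blob.get('format_version')!r}"
            )
        return blob["payload"]


def fit_table_classifier(
    corpus: Corpus,
    field_kind: FieldKind = FieldKind.CAPTION_PLUS_TABLE,
    hp: Hyperparameters | None = None,
    first_few_rows_k: int = 3,
    min_df: int = 1,
    seed: int = 0,
) -> TableClassifier:
    """Train the full pipeline on a labeled corpus with class-inverse sample
    weights."""
    if not corpus.is_labeled:
        raise ValueError("training requires a labeled corpus")
    from .features import VocabularyConfig

    texts = [
        select_field(t, field_kind, first_few_rows_k=first_few_rows_k) for t in corpus
    ]
    vocabulary = fit_vocabulary(texts, VocabularyConfig(min_df=min_df))
    X = np.stack([bow_encode(text, vocabulary).values for text in texts])
    labels = corpus.labels()
    weights_by_class = compute_class_weights(corpus.label_counts())
    weights = np.array([weights_by_class[l] for l in labels], dtype=float)
    model = train(X, labels, sample_weights=weights, hp=hp, seed=seed)
    return TableClassifier(
        model=model,
        vocabulary=vocabulary,
        field_kind=FieldKind(field_kind),
        first_few_rows_k=first_few_rows_k,
        metadata={"n_training_tables": len(corpus), "seed": seed},
    )
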