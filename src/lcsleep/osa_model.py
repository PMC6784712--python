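"""Two-stage OSA severity classifier.

Stage one (S1DT) is a shallow decision tree on {X1, X4, X6} that gates
each study night into normal vs abnormal. Stage two (S2LR) is a linear
regression that estimates the apnea-hypopnea index for abnormal nights
from {X2^2, X3, X5}:

    AHI = 11.94 + 23.06 * X2^2 + 8.74 * X3 - 15.04 * X5

These frozen coefficients are the published pilot-study model and are the
default predictor; refitting both stages on new data (e.g. a simulated
cohort) is available via :func:`fit_lopo` / :func:`fit_pipeline`. The
published split thresholds of the detection tree were never released, so
a refit tree (Gini impurity, depth <= 3, fixed seed) stands in whenever a
trained stage-one model is required.

Severity mapping: AHI < 5 -> normal, 5 <= AHI <= 15 -> mild,
AHI > 15 -> moderate/severe (moderate and severe are one predicted class).
"""
from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.linear_model import LinearRegression
from sklearn.tree import DecisionTreeClassifier

from .errors import DataError, ValidationError
from .spectral import STAGE1_FEATURES, STAGE2_FEATURES
from .types import CensoredAHI, Category, Severity

#: Lowest AHI reportable for a night gated abnormal; stage-two outputs
#: below it are clamped up so category and severity stay consistent.
ABNORMAL_FLOOR = 5.0
MILD_UPPER = 15.0


@dataclass(frozen=True)
class S2LRCoefficients:
    """Stage-two regression coefficients (events/h per unit feature)."""

    intercept: float
    coef_x2sq: float
    coef_x3: float
    coef_x5: float

    def __post_init__(self) -> None:
        for name in ("intercept", "coef_x2sq", "coef_x3", "coef_x5"):
            if not np.isfinite(getattr(self, name)):
                raise ValidationError(f"{name} must be finite")


#: The published pilot-study regression model.
PUBLISHED_S2LR = S2LRCoefficients(11.94, 23.06, 8.74, -15.04)


def s2lr_predict(x: Sequence[float], coeffs: S2LRCoefficients = PUBLISHED_S2LR) -> float:
    """Raw stage-two AHI estimate (events/h) from a feature vector X1..X6.

    May fall below 5 (or 0); clamping is the caller's concern
    (:func:`predict_study` applies the abnormal floor).
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (6,):
        raise ValidationError(f"expected 6 features X1..X6, got shape {x.shape}")
    if not np.all(np.isfinite(x)):
        raise DataError("feature vector contains non-finite values")
    x2, x3, x5 = x[1], x[2], x[4]
    return float(
        coeffs.intercept
        + coeffs.coef_x2sq * x2 ** 2
        + coeffs.coef_x3 * x3
        + coeffs.coef_x5 * x5
    )


def severity_from_ahi(ahi: float) -> Severity:
    """Map a numeric AHI (events/h) to a severity class.

    Boundaries: < 5 normal, [5, 15] mild, > 15 moderate/severe.
    """
    if not np.isfinite(ahi) or ahi < 0:
        raise ValidationError(f"AHI must be finite and >= 0, got {ahi}")
    if ahi < ABNORMAL_FLOOR:
        return Severity.NORMAL
    if ahi <= MILD_UPPER:
        return Severity.MILD
    return Severity.MODERATE_SEVERE


def severity_of(ahi: CensoredAHI) -> Severity:
    """Severity of a possibly censored AHI (censored -> normal)."""
    return Severity.NORMAL if ahi.is_censored else severity_from_ahi(ahi.value)


@dataclass(frozen=True)
class StudyPrediction:
    """Per-study-night output of the two-stage classifier."""

    category: Category
    ahi: CensoredAHI
    severity: Severity


@dataclass
class TrainedPipeline:
    """A stage-one tree plus stage-two coefficients, with fit metadata."""

    tree: DecisionTreeClassifier | None
    coeffs: S2LRCoefficients = PUBLISHED_S2LR
    seed: int = 0
    cv_scheme: str = "none"
    training_hash: str | None = field(default=None, repr=False)

    def s1dt_classify(self, x: Sequence[float]) -> Category:
        return s1dt_classify(x, self)

    def predict_study(self, x: Sequence[float]) -> StudyPrediction:
        return predict_study(x, self)


def s1dt_classify(x: Sequence[float], pipeline: TrainedPipeline) -> Category:
    """Stage-one normal/abnormal gate on features X1, X4, X6."""
    if pipeline.tree is None:
        raise ValidationError("pipeline has no trained stage-one tree")
    x = np.asarray(x, dtype=float)
    if x.shape != (6,):
        raise ValidationError(f"expected 6 features X1..X6, got shape {x.shape}")
    label = pipeline.tree.predict(x[list(STAGE1_FEATURES)].reshape(1, -1))[0]
    return Category.ABNORMAL if label == 1 else Category.NORMAL


def predict_study(x: Sequence[float], pipeline: TrainedPipeline) -> StudyPrediction:
    """Full two-stage prediction for one study night.

    Normal gate -> censored "<5" / normal severity. Abnormal gate -> the
    stage-two estimate, clamped to at least 5 events/h so the reported
    category, AHI and severity remain mutually consistent.
    """
    if s1dt_classify(x, pipeline) is Category.NORMAL:
        return StudyPrediction(Category.NORMAL, CensoredAHI.censored(), Severity.NORMAL)
    ahi = max(s2lr_predict(x, pipeline.coeffs), ABNORMAL_FLOOR)
    return StudyPrediction(Category.ABNORMAL, CensoredAHI.of(ahi), severity_from_ahi(ahi))


# ---------------------------------------------------------------------------
# Fitting


def _training_hash(X: np.ndarray, y: np.ndarray, ahi: np.ndarray) -> str:
    h = hashlib.sha256()
    for a in (X, y, ahi):
        h.update(np.ascontiguousarray(a, dtype=float).tobytes())
    return h.hexdigest()


def fit_pipeline(
    X: np.ndarray,
    abnormal: np.ndarray,
    ahi: np.ndarray,
    seed: int = 0,
    max_depth: int = 3,
) -> TrainedPipeline:
    """Fit both stages on a feature matrix.

    Parameters
    ----------
    X : ndarray, shape (n_studies, 6)
        Feature vectors X1..X6 per study night.
    abnormal : ndarray of bool
        Gold-standard night label (AHI >= 5).
    ahi : ndarray
        Gold-standard AHI per night; the stage-two regression is fit only
        on abnormal nights, as in the published protocol.
    """
    X = np.asarray(X, dtype=float)
    abnormal = np.asarray(abnormal, dtype=bool)
    ahi = np.asarray(ahi, dtype=float)
    if X.ndim != 2 or X.shape[1] != 6:
        raise ValidationError(f"X must be (n, 6), got {X.shape}")
    if len({len(X), len(abnormal), len(ahi)}) != 1:
        raise ValidationError("X, abnormal and ahi must have equal length")
    if abnormal.all() or not abnormal.any():
        raise ValidationError("training set must contain both normal and abnormal nights")

    tree = DecisionTreeClassifier(criterion="gini", max_depth=max_depth, random_state=seed)
    tree.fit(X[:, list(STAGE1_FEATURES)], abnormal.astype(int))

    reg = LinearRegression()
    Xab = X[abnormal]
    design = np.column_stack([Xab[:, 1] ** 2, Xab[:, 2], Xab[:, 4]])
    reg.fit(design, ahi[abnormal])
    coeffs = S2LRCoefficients(float(reg.intercept_), *map(float, reg.coef_))
    return TrainedPipeline(
        tree=tree, coeffs=coeffs, seed=seed, cv_scheme="refit-all",
        training_hash=_training_hash(X, abnormal, ahi),
    )


@dataclass
class LopoResult:
    """Leave-one-patient-out cross-validated predictions."""

    predictions: dict  # (subject_id, night_key) -> StudyPrediction
    final_pipeline: TrainedPipeline
    fold_hashes: dict  # subject_id -> training-matrix hash
    fold_errors: dict  # subject_id -> error message for unfittable folds


def fit_lopo(
    subjects: np.ndarray,
    X: np.ndarray,
    abnormal: np.ndarray,
    ahi: np.ndarray,
    night_keys: np.ndarray | None = None,
    seed: int = 0,
) -> LopoResult:
    """Leave-one-patient-out training and prediction.

    For each subject, every study night of that subject (regardless of the
    concurrent gold-standard test) is held out; the two-stage pipeline is
    fit on all remaining studies and applied to the held-out nights. Also
    returns a final pipeline fit on the full dataset.
    """
    subjects = np.asarray(subjects)
    X = np.asarray(X, dtype=float)
    uniq = np.unique(subjects)
    if len(uniq) < 3:
        raise ValidationError("leave-one-patient-out needs >= 3 subjects")
    if night_keys is None:
        night_keys = np.arange(len(X))
    predictions: dict = {}
    fold_hashes: dict = {}
    fold_errors: dict = {}
    for subj in uniq:
        hold = subjects == subj
        try:
            pipe = fit_pipeline(X[~hold], np.asarray(abnormal)[~hold],
                                np.asarray(ahi)[~hold], seed=seed)
        except ValidationError as exc:
            fold_errors[subj] = str(exc)
            continue
        fold_hashes[subj] = pipe.training_hash
        for idx in np.flatnonzero(hold):
            predictions[(subj, night_keys[idx])] = predict_study(X[idx], pipe)
    final = fit_pipeline(X, abnormal, ahi, seed=seed)
    final.cv_scheme = "leave-one-patient-out"
    return LopoResult(predictions, final, fold_hashes, fold_errors)
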