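"""Logistic confirmation model with zero-false-positive threshold calibration.

The model estimates, per variant call, the probability that orthogonal
(Sanger) confirmation would find the variant present, from the 14 features in
:data:`vartriage.callsignals.FEATURE_NAMES`. It is an L2-penalized logistic
regression on training-set-standardized features. A "positive" prediction is
HIGH confidence (no confirmation needed); the costly error is therefore the
false positive — a call predicted HIGH that Sanger finds not present — and the
decision threshold ``tau`` is calibrated to eliminate it on the calibration
set: ``tau`` sits immediately above the highest score of any unconfirmed
example (midpoint to the next confirmed score above, when one exists). The
classification rule is HIGH iff ``predict_proba >= tau``.

Everything is deterministic: the same inputs and seed produce byte-identical
serialized models, and scoring a vector twice gives bit-identical
probabilities.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import expit
from scipy.stats import norm
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import KFold, StratifiedKFold

from .callsignals import FEATURE_NAMES, SOFT_MISSING, FeatureVector
from .errors import ConvergenceError, InputError, SchemaError

HIGH = "HIGH"
LOW = "LOW"


@dataclass
class ConfusionTable:
    """Prediction-vs-Sanger counts; positive = predicted HIGH confidence."""

    tp: int = 0  # HIGH, confirmed present
    fp: int = 0  # HIGH, not present  (the error tau eliminates)
    fn: int = 0  # LOW, confirmed present
    tn: int = 0  # LOW, not present

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def accuracy(self) -> float:
        if self.n == 0:
            raise InputError("empty confusion table")
        return (self.tp + self.tn) / self.n

    def __add__(self, other: "ConfusionTable") -> "ConfusionTable":
        return ConfusionTable(
            self.tp + other.tp, self.fp + other.fp, self.fn + other.fn, self.tn + other.tn
        )

    def as_dict(self) -> dict[str, int]:
        return {"tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn}


@dataclass
class ConfidenceModel:
    """Standardizer + logistic coefficients + calibrated threshold."""

    schema: tuple[str, ...]
    center: np.ndarray
    scale: np.ndarray
    impute: np.ndarray  # training medians used for missing entries
    coef: np.ndarray
    intercept: float
    tau: float = math.nan
    metadata: dict = field(default_factory=dict)

    # -- scoring ------------------------------------------------------------

    def _matrix(self, values: np.ndarray | FeatureVector) -> np.ndarray:
        if isinstance(values, FeatureVector):
            if tuple(values.schema) != tuple(self.schema):
                raise SchemaError(
                    f"vector schema {values.schema} does not match model schema"
                )
            values = values.values
        X = np.atleast_2d(np.asarray(values, dtype=float))
        if X.shape[1] != len(self.schema):
            raise SchemaError(
                f"expected {len(self.schema)} features, got {X.shape[1]}"
            )
        X = np.where(np.isnan(X), self.impute, X)
        return (X - self.center) / self.scale

    def decision_score(self, values) -> np.ndarray:
        """Linear predictor intercept + coef . standardized(values)."""
        return self._matrix(values) @ self.coef + self.intercept

    def predict_proba(self, values) -> np.ndarray:
        """sigmoid of the linear predictor, in (0, 1)."""
        return expit(self.decision_score(values))

    # -- serialization (lossless JSON round-trip) ---------------------------

    def to_json(self) -> str:
        payload = {
            "schema": list(self.schema),
            "center": self.center.tolist(),
            "scale": self.scale.tolist(),
            "impute": self.impute.tolist(),
            "coef": self.coef.tolist(),
            "intercept": self.intercept,
            "tau": None if math.isnan(self.tau) else self.tau,
            "metadata": self.metadata,
        }
        return json.dumps(payload, sort_keys=True, indent=1)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n")

    @classmethod
    def from_json(cls, text: str) -> "ConfidenceModel":
        d = json.loads(text)
        return cls(
            schema=tuple(d["schema"]),
            center=np.asarray(d["center"], dtype=float),
            scale=np.asarray(d["scale"], dtype=float),
            impute=np.asarray(d["impute"], dtype=float),
            coef=np.asarray(d["coef"], dtype=float),
            intercept=float(d["intercept"]),
            tau=math.nan if d["tau"] is None else float(d["tau"]),
            metadata=d.get("metadata", {}),
        )

    @classmethod
    def load(cls, path: str | Path) -> "ConfidenceModel":
        return cls.from_json(Path(path).read_text())


# ---------------------------------------------------------------------------
# Splitting


def split_dataset(
    labels: Sequence[int],
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Disjoint, exhaustive (train, dev, test) index partition.

    Stratified by label with largest-remainder rounding so split sizes match
    the fractions as closely as integer counts allow; reproducible for a
    given seed. Falls back to an unstratified split (with a warning) when
    some class is too small to appear in every split.
    """
    labels = np.asarray(labels)
    n = len(labels)
    if n == 0:
        raise InputError("cannot split an empty dataset")
    if abs(sum(fractions) - 1.0) > 1e-9 or any(f < 0 for f in fractions):
        raise InputError(f"fractions must be non-negative and sum to 1, got {fractions}")

    rng = np.random.default_rng(seed)
    classes, counts = np.unique(labels, return_counts=True)
    strata: list[np.ndarray]
    if counts.min() < len(fractions):
        warnings.warn(
            "a label stratum has fewer examples than splits; "
            "falling back to an unstratified split",
            stacklevel=2,
        )
        strata = [np.arange(n)]
    else:
        strata = [np.flatnonzero(labels == c) for c in classes]

    parts: list[list[np.ndarray]] = [[], [], []]
    for idx in strata:
        idx = rng.permutation(idx)
        quota = np.array([f * len(idx) for f in fractions])
        base = np.floor(quota).astype(int)
        remainder = quota - base
        for _ in range(len(idx) - base.sum()):
            j = int(np.argmax(remainder))
            base[j] += 1
            remainder[j] = -1.0
        stops = np.cumsum(base)
        parts[0].append(idx[: stops[0]])
        parts[1].append(idx[stops[0] : stops[1]])
        parts[2].append(idx[stops[1] : stops[2]])
    return tuple(np.sort(np.concatenate(p)).astype(int) for p in parts)


# ---------------------------------------------------------------------------
# Fitting


def fit_logistic(
    X: np.ndarray,
    y: Sequence[int],
    l2_strength: float = 1.0,
    seed: int = 0,
    max_iter: int = 5000,
    schema: Sequence[str] | None = None,
) -> ConfidenceModel:
    """Fit the standardized L2-penalized logistic regression (tau untuned).

    ``l2_strength`` is the coefficient of the ridge penalty relative to the
    summed binomial log-likelihood (sklearn's ``C = 1 / l2_strength``); a
    small fixed penalty keeps the optimum finite even on separable data.
    Missing entries (nan) are imputed with training-column medians, which the
    returned model stores for scoring. Raises :class:`ConvergenceError` at
    the iteration cap and :class:`InputError` on single-class input.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2 or X.shape[0] != len(y):
        raise InputError("X must be 2-D with one row per label")
    if schema is None:
        schema = (
            FEATURE_NAMES
            if X.shape[1] == len(FEATURE_NAMES)
            else tuple(f"x{i}" for i in range(X.shape[1]))
        )
    elif len(tuple(schema)) != X.shape[1]:
        raise SchemaError(
            f"schema of {len(tuple(schema))} names does not match {X.shape[1]} columns"
        )
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise InputError("training data must contain both classes")
    if counts.min() < 2:
        raise InputError("need at least 2 examples of each class")
    if l2_strength <= 0:
        raise InputError("l2_strength must be positive")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-nan columns
        impute = np.nanmedian(X, axis=0)
    impute = np.where(np.isnan(impute), 0.0, impute)
    Xf = np.where(np.isnan(X), impute, X)

    center = Xf.mean(axis=0)
    scale = Xf.std(axis=0)
    scale = np.where(scale == 0.0, 1.0, scale)
    Z = (Xf - center) / scale

    clf = LogisticRegression(
        penalty="l2",
        C=1.0 / l2_strength,
        solver="lbfgs",
        max_iter=max_iter,
        tol=1e-10,
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf.fit(Z, y)
    n_iter = int(np.max(clf.n_iter_))
    if n_iter >= max_iter:
        raise ConvergenceError(
            f"lbfgs hit the iteration cap ({max_iter}); "
            f"n={len(y)}, class counts={dict(zip(classes.tolist(), counts.tolist()))}",
            n_iter=n_iter,
        )

    return ConfidenceModel(
        schema=tuple(schema),
        center=center,
        scale=scale,
        impute=impute,
        coef=clf.coef_[0].astype(float),
        intercept=float(clf.intercept_[0]),
        metadata={
            "seed": int(seed),
            "l2_strength": float(l2_strength),
            "n_train": int(len(y)),
            "n_confirmed": int(counts[classes == 1].sum()),
            "n_unconfirmed": int(counts[classes == 0].sum()),
            "n_iter": n_iter,
        },
    )


def predict_proba(model: ConfidenceModel, values) -> np.ndarray:
    """Functional alias for :meth:`ConfidenceModel.predict_proba`."""
    return model.predict_proba(values)


# ---------------------------------------------------------------------------
# Threshold calibration and classification


def calibrate_threshold(
    probas: Sequence[float], labels: Sequence[int], floor: float = 0.5
) -> float:
    """Smallest threshold with zero false positives on the calibration set.

    ``tau`` is placed above the highest score among unconfirmed examples —
    at the midpoint of the straddling score pair when a confirmed score lies
    above it, else immediately above in floating point. With the rule
    "HIGH iff proba >= tau" this guarantees FP = 0 on the calibration set.
    When the set has no unconfirmed example tau falls back to ``floor``.
    """
    probas = np.asarray(probas, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if probas.size == 0:
        raise InputError("cannot calibrate on an empty set")
    if probas.shape != labels.shape:
        raise InputError("probas and labels must have equal length")
    unconfirmed = probas[labels == 0]
    if unconfirmed.size == 0:
        return float(floor)
    top_unconfirmed = float(unconfirmed.max())
    above = probas[(labels == 1) & (probas > top_unconfirmed)]
    if above.size:
        return float((top_unconfirmed + above.min()) / 2.0)
    # one ulp above the worst unconfirmed score; may exceed 1.0 by one ulp
    # in the degenerate case of an unconfirmed score of exactly 1
    return float(np.nextafter(top_unconfirmed, np.inf))


def classify(
    model: ConfidenceModel, vector: FeatureVector | np.ndarray
) -> tuple[str, str | None]:
    """(class, reason): HIGH iff proba >= tau and no fail-safe feature state.

    A hard-missing feature (anything undefined other than the imputable
    MQ/GQ/FS) routes the call to LOW with reason ``"undefined_feature"``,
    never an exception.
    """
    if math.isnan(model.tau):
        raise InputError("model threshold is not calibrated")
    if isinstance(vector, FeatureVector):
        if vector.hard_missing:
            return LOW, "undefined_feature"
    else:
        arr = np.asarray(vector, dtype=float)
        hard = {
            name
            for name, v in zip(model.schema, arr)
            if np.isnan(v) and name not in SOFT_MISSING
        }
        if hard:
            return LOW, "undefined_feature"
    proba = float(model.predict_proba(vector)[0])
    if proba >= model.tau:
        return HIGH, None
    return LOW, "below_threshold"


def confusion_from_predictions(
    high: Sequence[bool], confirmed: Sequence[int]
) -> ConfusionTable:
    """Tally Table-2-style counts from HIGH flags and Sanger outcomes."""
    high = np.asarray(high, dtype=bool)
    confirmed = np.asarray(confirmed, dtype=int).astype(bool)
    return ConfusionTable(
        tp=int(np.sum(high & confirmed)),
        fp=int(np.sum(high & ~confirmed)),
        fn=int(np.sum(~high & confirmed)),
        tn=int(np.sum(~high & ~confirmed)),
    )


# ---------------------------------------------------------------------------
# Evaluation


def cross_validate(
    X: np.ndarray,
    y: Sequence[int],
    k: int = 10,
    seed: int = 0,
    l2_strength: float = 1.0,
    tau_floor: float = 0.5,
    per_fold_tau: bool = True,
    return_folds: bool = False,
):
    """Aggregated out-of-fold confusion counts from stratified k-fold CV.

    Each fold refits the model on its training portion; by default tau is
    also recalibrated per fold on that same training portion
    (``per_fold_tau=False`` instead applies one global tau calibrated on a
    full-data fit). Reproducible for a given seed. Folds are unstratified
    (with a warning) when the minority class has fewer than k members, which
    also covers leave-one-out.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n = len(y)
    if not 2 <= k <= n:
        raise InputError(f"k must be between 2 and n={n}, got {k}")
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        warnings.warn(
            "minority class smaller than k; using unstratified folds", stacklevel=2
        )
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        split_iter = splitter.split(X)
    else:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        split_iter = splitter.split(X, y)

    global_tau = math.nan
    if not per_fold_tau:
        full = fit_logistic(X, y, l2_strength=l2_strength, seed=seed)
        global_tau = calibrate_threshold(full.predict_proba(X), y, floor=tau_floor)

    total = ConfusionTable()
    folds: list[ConfusionTable] = []
    for train_idx, test_idx in split_iter:
        model = fit_logistic(X[train_idx], y[train_idx], l2_strength=l2_strength, seed=seed)
        if per_fold_tau:
            tau = calibrate_threshold(
                model.predict_proba(X[train_idx]), y[train_idx], floor=tau_floor
            )
        else:
            tau = global_tau
        high = model.predict_proba(X[test_idx]) >= tau
        fold = confusion_from_predictions(high, y[test_idx])
        folds.append(fold)
        total = total + fold
    if return_folds:
        return total, folds
    return total


def roc_auc(
    probas: Sequence[float], labels: Sequence[int]
) -> tuple[np.ndarray, float]:
    """ROC points (FPR, TPR columns) and trapezoidal AUC.

    The AUC equals the Mann-Whitney concordance probability
    P(score_confirmed > score_unconfirmed) + 0.5 P(tie). Raises
    :class:`InputError` when only one class is present.
    """
    probas = np.asarray(probas, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise InputError("ROC requires both classes")
    fpr, tpr, _ = _sk_roc_curve(labels, probas)
    return np.column_stack([fpr, tpr]), float(_sk_auc(fpr, tpr))


def accuracy_ci(
    confusion: ConfusionTable, level: float = 0.95, method: str = "normal"
) -> tuple[float, tuple[float, float]]:
    """Accuracy with a binomial confidence interval.

    ``method="normal"`` is the symmetric normal approximation
    acc +/- z * sqrt(acc (1-acc) / n); ``"wilson"`` gives the Wilson score
    interval. Intervals are clipped to [0, 1].
    """
    n = confusion.n
    if n == 0:
        raise InputError("empty confusion table")
    if not 0 < level < 1:
        raise InputError("level must be in (0, 1)")
    acc = confusion.accuracy
    z = float(norm.ppf((1 + level) / 2.0))
    if method == "normal":
        half = z * math.sqrt(acc * (1 - acc) / n)
        lo, hi = acc - half, acc + half
    elif method == "wilson":
        denom = 1 + z**2 / n
        mid = (acc + z**2 / (2 * n)) / denom
        half = z * math.sqrt(acc * (1 - acc) / n + z**2 / (4 * n**2)) / denom
        lo, hi = mid - half, mid + half
    else:
        raise InputError(f"unknown CI method {method!r}")
    return acc, (max(0.0, lo), min(1.0, hi))


# ---------------------------------------------------------------------------
# End-to-end training convenience


def train_confidence_model(
    X: np.ndarray,
    y: Sequence[int],
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
    seed: int = 0,
    l2_strength: float = 1.0,
    tau_floor: float = 0.5,
) -> tuple[ConfidenceModel, dict]:
    """Split 70/15/15, fit on train, calibrate tau on dev, evaluate on test.

    Returns the calibrated model and an evaluation report (held-out confusion
    counts, accuracy with CI, AUC and ROC points).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    train_idx, dev_idx, test_idx = split_dataset(y, fractions, seed=seed)
    model = fit_logistic(X[train_idx], y[train_idx], l2_strength=l2_strength, seed=seed)
    calib_idx = dev_idx if dev_idx.size else train_idx
    model.tau = calibrate_threshold(
        model.predict_proba(X[calib_idx]), y[calib_idx], floor=tau_floor
    )
    model.metadata.update(
        {
            "fractions": list(fractions),
            "n_total": int(len(y)),
            "n_dev": int(dev_idx.size),
            "n_test": int(test_idx.size),
            "tau_floor": float(tau_floor),
        }
    )

    report: dict = {"tau": model.tau}
    if test_idx.size:
        probas = model.predict_proba(X[test_idx])
        confusion = confusion_from_predictions(probas >= model.tau, y[test_idx])
        acc, (lo, hi) = accuracy_ci(confusion)
        report["test_confusion"] = confusion.as_dict()
        report["test_accuracy"] = acc
        report["test_accuracy_ci"] = [lo, hi]
        if len(np.unique(y[test_idx])) == 2:
            points, auc_value = roc_auc(probas, y[test_idx])
            report["test_auc"] = auc_value
            report["roc_points"] = points.tolist()
    return model, report
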