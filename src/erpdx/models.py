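"""Classifier zoo: logistic regression, kNN, SVM, and per-paradigm stacking.

All models consume a :class:`~erpdx.features.FeatureTable`, with the
patient class positive.  A fitted model bundles its scaler (fitted on
the training rows only) with the estimator and remembers the training
feature names; prediction reorders incoming columns by name and refuses
tables missing any of them.

Class imbalance (132 controls vs 68 patients in the study design) is
handled by inverse-frequency class weights or seeded minority
upsampling — the two were found roughly equivalent and both are kept.

SVM class probabilities come from a Platt (sigmoid) calibration of the
decision values, fitted on the training data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import MinMaxScaler, RobustScaler, StandardScaler
from sklearn.svm import SVC
from sklearn.utils import resample

from erpdx.errors import ConfigError, ValidationError
from erpdx.features import BEHAVIOR_FEATURES, FeatureTable

MODEL_FAMILIES = ("logreg", "knn", "svm", "stacking")
IMBALANCE_MODES = ("class_weight", "weighted_loss", "upsample")
SCALERS = ("none", "standard", "minmax", "robust")
CONDITION_PREFIXES = ("plus1", "plus2", "nogo", "go", "ph")


@dataclass(frozen=True)
class ModelSpec:
    """Hyperparameters of one classifier.

    Defaults follow the best reported settings: logreg L1 with C=1,
    kNN with 11 neighbors, SVM with an RBF kernel, gamma scaled as
    1/(n_features x feature variance) and C=1/3.
    """

    family: str = "svm"
    penalty: str = "l2"          # logreg: l1 | l2
    C: float = 1.0 / 3.0         # logreg / svm regularization
    kernel: str = "rbf"          # svm: rbf | poly | sigmoid
    gamma_mode: str = "scale"
    n_neighbors: int = 11
    imbalance: str = "class_weight"
    scaler: str = "standard"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in MODEL_FAMILIES:
            raise ConfigError(f"unknown model family {self.family!r}")
        if self.C <= 0:
            raise ConfigError("C must be > 0")
        if self.n_neighbors < 1:
            raise ConfigError("n_neighbors must be >= 1")
        if self.imbalance not in IMBALANCE_MODES:
            raise ConfigError(f"unknown imbalance mode {self.imbalance!r}")
        if self.scaler not in SCALERS:
            raise ConfigError(f"unknown scaler {self.scaler!r}")
        if self.penalty not in ("l1", "l2"):
            raise ConfigError(f"unknown penalty {self.penalty!r}")


def make_scaler(name: str):
    if name == "none":
        return None
    return {"standard": StandardScaler(),
            "minmax": MinMaxScaler(),
            "robust": RobustScaler()}[name]


class PlattSVC(BaseEstimator, ClassifierMixin):
    """SVC with sigmoid (Platt) probability calibration on the training set.

    The calibrator maps decision values d to P(y=1) = sigmoid(a*d + b),
    with (a, b) minimizing the regularized log-loss (Platt's target
    smoothing) on the same training rows the SVC was fitted on.
    """

    def __init__(self, C=1.0, kernel="rbf", gamma="scale", class_weight=None):
        self.C = C
        self.kernel = kernel
        self.gamma = gamma
        self.class_weight = class_weight

    def fit(self, X, y):
        self.svc_ = SVC(C=self.C, kernel=self.kernel, gamma=self.gamma,
                        class_weight=self.class_weight)
        self.svc_.fit(X, y)
        self.classes_ = self.svc_.classes_
        y = np.asarray(y)
        # calibration is lazy: decision values are stored, the sigmoid is
        # fitted on first predict_proba (hard predictions never need it)
        self._cal_d = self.svc_.decision_function(X)
        self._cal_t = self._platt_targets(y)
        self.a_ = None
        self.b_ = None
        return self

    def _platt_targets(self, y):
        n_pos = int((y == self.classes_[1]).sum())
        n_neg = len(y) - n_pos
        t_pos = (n_pos + 1.0) / (n_pos + 2.0)
        t_neg = 1.0 / (n_neg + 2.0)
        return np.where(y == self.classes_[1], t_pos, t_neg)

    def _calibrate(self):
        d, t = self._cal_d, self._cal_t
        a, b = 1.0, 0.0
        # Newton iterations on the 2-parameter regularized log-loss
        for _ in range(50):
            z = a * d + b
            p = expit(z)
            g = p - t
            grad = np.array([np.dot(g, d), g.sum()])
            w = p * (1 - p) + 1e-12
            h11 = np.dot(w, d * d)
            h12 = np.dot(w, d)
            h22 = w.sum()
            det = h11 * h22 - h12 * h12
            if det <= 1e-300:
                break
            step = np.array([h22 * grad[0] - h12 * grad[1],
                             -h12 * grad[0] + h11 * grad[1]]) / det
            a, b = a - step[0], b - step[1]
            if np.abs(step).max() < 1e-10:
                break
        self.a_, self.b_ = float(a), float(b)

    def decision_function(self, X):
        return self.svc_.decision_function(X)

    def predict_proba(self, X):
        if self.a_ is None:
            self._calibrate()
        p1 = expit(self.a_ * self.svc_.decision_function(X) + self.b_)
        return np.column_stack([1 - p1, p1])

    def predict(self, X):
        return self.classes_[(self.svc_.decision_function(X) > 0).astype(int)]


def build_estimator(spec: ModelSpec):
    """Instantiate the sklearn estimator for a :class:`ModelSpec`."""
    weighted = spec.imbalance in ("class_weight", "weighted_loss")
    cw = "balanced" if weighted else None
    if spec.family == "logreg":
        return LogisticRegression(l1_ratio=1.0 if spec.penalty == "l1" else 0.0,
                                  C=spec.C, solver="liblinear", class_weight=cw,
                                  random_state=spec.seed, max_iter=2000)
    if spec.family == "knn":
        return KNeighborsClassifier(n_neighbors=spec.n_neighbors)
    if spec.family == "svm":
        return PlattSVC(C=spec.C, kernel=spec.kernel, gamma=spec.gamma_mode,
                        class_weight=cw)
    raise ConfigError(f"build_estimator cannot build family {spec.family!r}")


def _upsample(X: np.ndarray, y: np.ndarray, seed: int):
    """Resample the minority class with replacement to the majority size."""
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValidationError("upsampling needs exactly two classes")
    minority = classes[np.argmin(counts)]
    maj_n = counts.max()
    idx_min = np.flatnonzero(y == minority)
    idx_maj = np.flatnonzero(y != minority)
    idx_res = resample(idx_min, replace=True, n_samples=maj_n, random_state=seed)
    idx = np.concatenate([idx_maj, idx_res])
    return X[idx], y[idx]


@dataclass
class FittedModel:
    """A fitted scaler + estimator bound to its training feature names."""

    spec: ModelSpec
    feature_names: list[str]
    scaler: object | None
    estimator: object

    def _matrix(self, table: FeatureTable | pd.DataFrame) -> np.ndarray:
        df = table.values if isinstance(table, FeatureTable) else table
        missing = [c for c in self.feature_names if c not in df.columns]
        if missing:
            raise ValidationError(f"prediction input missing columns {missing[:5]}"
                                  + ("..." if len(missing) > 5 else ""))
        X = df[self.feature_names].to_numpy(dtype=float)
        if self.scaler is not None:
            X = self.scaler.transform(X)
        return X

    def predict_proba(self, table) -> np.ndarray:
        """Positive-class (patient) probability per subject."""
        return self.estimator.predict_proba(self._matrix(table))[:, 1]

    def predict(self, table, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(table) >= threshold).astype(int)

    def predict_labels(self, table) -> np.ndarray:
        """Hard class labels from the estimator's own decision rule
        (skips probability calibration)."""
        return np.asarray(self.estimator.predict(self._matrix(table)))

    def predict_proba_array(self, X: np.ndarray) -> np.ndarray:
        """Probability from an already-ordered raw feature matrix."""
        if self.scaler is not None:
            X = self.scaler.transform(X)
        return self.estimator.predict_proba(X)[:, 1]


def fit(spec: ModelSpec, table: FeatureTable) -> FittedModel:
    """Fit scaler + estimator on a feature table (training rows only)."""
    y = table.y
    if len(np.unique(y)) < 2:
        raise ValidationError("training table must contain both classes")
    X = table.X
    bad = [c for c, ok in zip(table.feature_names,
                              np.isfinite(X).all(axis=0)) if not ok]
    if bad:
        raise ValidationError(f"non-finite feature columns: {bad[:5]}")

    scaler = make_scaler(spec.scaler)
    if scaler is not None:
        X = scaler.fit_transform(X)
    if spec.imbalance == "upsample":
        X, y = _upsample(X, y, spec.seed)
    est = build_estimator(spec)
    est.fit(X, y)
    return FittedModel(spec=spec, feature_names=table.feature_names,
                       scaler=scaler, estimator=est)


def predict_proba(model: FittedModel, table: FeatureTable) -> np.ndarray:
    """Positive-class probability per subject (functional form)."""
    return model.predict_proba(table)


@dataclass(frozen=True)
class StackingSpec:
    """Per-paradigm stacking: one logistic base model per feature group,
    an SVM meta-model on the base probabilities."""

    base_spec: ModelSpec = field(default_factory=lambda: ModelSpec(
        family="logreg", penalty="l2", C=1.0))
    meta_spec: ModelSpec = field(default_factory=lambda: ModelSpec(
        family="svm", scaler="none"))
    include_behavior: bool = True


def stacking_groups(feature_names: list[str], include_behavior: bool
                    ) -> dict[str, list[str]]:
    """Partition feature names into per-condition groups (+ behavior)."""
    groups: dict[str, list[str]] = {}
    for cond in CONDITION_PREFIXES:
        cols = [c for c in feature_names if c.startswith(cond + "_")]
        if cols:
            groups[cond] = cols
    if include_behavior:
        beh = [c for c in feature_names if c in BEHAVIOR_FEATURES]
        if not beh:
            raise ConfigError("behavior group enabled but no behavior columns present")
        groups["behavior"] = beh
    grouped = [c for cols in groups.values() for c in cols]
    leftover = set(feature_names) - set(grouped) - set(BEHAVIOR_FEATURES)
    if leftover:
        raise ConfigError(f"columns not assignable to any group: {sorted(leftover)[:5]}")
    if not groups:
        raise ConfigError("no non-empty base groups")
    return groups


@dataclass
class FittedStacking:
    """Fitted stacking ensemble; satisfies the FittedModel prediction API."""

    spec: StackingSpec
    feature_names: list[str]
    groups: dict[str, list[str]]
    base_models: dict[str, FittedModel]
    meta_model: FittedModel

    def predict_proba(self, table) -> np.ndarray:
        df = table.values if isinstance(table, FeatureTable) else table
        meta = pd.DataFrame(
            {f"p_{g}": self.base_models[g].predict_proba(df) for g in self.groups},
            index=df.index)
        return self.meta_model.predict_proba(meta)

    def predict(self, table, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(table) >= threshold).astype(int)


def fit_stacking(spec: StackingSpec, table: FeatureTable,
                 inner_folds: int = 5, seed: int = 0) -> FittedStacking:
    """Fit the stacking ensemble with out-of-fold meta-features.

    Each base logistic regression is trained on one paradigm's columns
    (or the behavior columns).  The meta SVM is trained on base
    probabilities computed out-of-fold via seeded stratified inner CV,
    so the meta-model never sees a base probability produced by a model
    trained on the same row; base models are then refitted on all rows
    for inference.
    """
    groups = stacking_groups(table.feature_names, spec.include_behavior)
    y = table.y
    if len(np.unique(y)) < 2:
        raise ValidationError("training table must contain both classes")

    skf = StratifiedKFold(n_splits=inner_folds, shuffle=True, random_state=seed)
    oof = pd.DataFrame(index=table.values.index,
                       columns=[f"p_{g}" for g in groups], dtype=float)
    for tr, va in skf.split(table.X, y):
        tr_table = table.select_rows(tr)
        for g, cols in groups.items():
            m = fit(spec.base_spec, tr_table.select_features(cols))
            oof.iloc[va, oof.columns.get_loc(f"p_{g}")] = \
                m.predict_proba(table.select_rows(va).values)

    meta_table = FeatureTable(oof, table.groups.copy())
    meta_model = fit(spec.meta_spec, meta_table)
    base_models = {g: fit(spec.base_spec, table.select_features(cols))
                   for g, cols in groups.items()}
    return FittedStacking(spec=spec, feature_names=table.feature_names,
                          groups=groups, base_models=base_models,
                          meta_model=meta_model)
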