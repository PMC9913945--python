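"""Cross-validated evaluation with balanced thresholds and grid search.

The evaluation contract: stratified 10-fold CV; inside each fold the
scaler, any feature selection, and the classifier are fitted on the
training rows only; the decision threshold is chosen on out-of-fold
predictions *within the training side* (an inner stratified split), so
the held-out fold influences nothing.  Per-fold sensitivity (TPR over
patients), specificity (TNR over controls), F1 (patient positive) and
ROC AUC are aggregated to mean +/- SD, and the per-fold test confusion
counts are summed into one matrix covering every subject exactly once.

Thresholds are "balanced": among midpoints of sorted unique predicted
probabilities, the one minimizing |TPR - TNR| (ties: larger TPR + TNR,
then smaller threshold).

Grid search ranks full pipeline configurations (window parameters x
selection x model hyperparameters) by mean F1, ties by mean AUC, then
fewer selected features.

``ERPClassifier`` wraps all of this in a statsmodels-style model
object: construct from an :class:`~erpdx.erp_data.ERPDataset`, call
``fit()`` to obtain a :class:`CrossValidationResults` with a
``summary()`` table, and refit on all subjects for prediction on new
cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import f1_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold, KFold

from erpdx.erp_data import ERPDataset
from erpdx.errors import ConfigError, ValidationError
from erpdx.features import FeatureTable, WindowParams, build_feature_table, default_window_params
from erpdx.models import FittedModel, ModelSpec, StackingSpec, fit, fit_stacking
from erpdx.selection import SelectionConfig, apply_selection

METRIC_NAMES = ("sensitivity", "specificity", "f1", "auc")


@dataclass(frozen=True)
class CVConfig:
    outer_folds: int = 10
    stratified: bool = True
    seed: int = 0
    threshold_inner_folds: int = 5

    def __post_init__(self) -> None:
        if self.outer_folds < 2:
            raise ConfigError("outer_folds must be >= 2")


@dataclass(frozen=True)
class GridPoint:
    """One fully explicit pipeline configuration."""

    window_params: dict[str, WindowParams] = field(default_factory=default_window_params)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    model: ModelSpec = field(default_factory=ModelSpec)
    include_behavior: bool = True
    stacking: StackingSpec | None = None  # used when model.family == "stacking"

    def label(self) -> str:
        parts = [self.model.family]
        if self.include_behavior:
            parts.append("behavior")
        if self.selection.strategy != "none":
            parts.append(self.selection.strategy)
        return " + ".join(parts)


@dataclass
class ConfusionMatrix:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def add(self, other: "ConfusionMatrix") -> None:
        self.tp += other.tp
        self.fp += other.fp
        self.tn += other.tn
        self.fn += other.fn

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def n_positive(self) -> int:
        return self.tp + self.fn

    @property
    def n_negative(self) -> int:
        return self.tn + self.fp

    def as_dict(self) -> dict[str, int]:
        return {"tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn}


def choose_threshold(probs, labels) -> float:
    """Balanced decision threshold: minimize |TPR - TNR|.

    Candidates are midpoints of consecutive sorted unique
    probabilities; ties break by larger TPR + TNR, then by the smaller
    threshold.  Classification rule: prob >= threshold -> positive.
    """
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValidationError("choose_threshold needs both classes")
    uniq = np.unique(probs)
    if uniq.size < 2:
        return float(uniq[0])
    candidates = (uniq[:-1] + uniq[1:]) / 2.0

    n_pos = int((labels == 1).sum())
    n_neg = labels.size - n_pos
    best_t, best_key = None, None
    for t in candidates:
        pred = probs >= t
        tpr = (pred & (labels == 1)).sum() / n_pos
        tnr = (~pred & (labels == 0)).sum() / n_neg
        key = (abs(tpr - tnr), -(tpr + tnr), t)
        if best_key is None or key < best_key:
            best_key, best_t = key, float(t)
    return best_t


def compute_metrics(probs, labels, threshold: float
                    ) -> tuple[dict[str, float], ConfusionMatrix]:
    """Thresholded sensitivity/specificity/F1 plus rank-based AUC."""
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if not np.isfinite(threshold):
        raise ValidationError("threshold must be finite")
    if probs.size == 0:
        raise ValidationError("empty input")
    pred = (probs >= threshold).astype(int)
    tp = int(((pred == 1) & (labels == 1)).sum())
    fp = int(((pred == 1) & (labels == 0)).sum())
    tn = int(((pred == 0) & (labels == 0)).sum())
    fn = int(((pred == 0) & (labels == 1)).sum())
    cm = ConfusionMatrix(tp=tp, fp=fp, tn=tn, fn=fn)

    sens = tp / (tp + fn) if (tp + fn) else float("nan")
    spec = tn / (tn + fp) if (tn + fp) else float("nan")
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
    if len(np.unique(labels)) == 2:
        auc = float(roc_auc_score(labels, probs))
    else:
        auc = float("nan")
    return {"sensitivity": sens, "specificity": spec, "f1": f1, "auc": auc}, cm


@dataclass
class FoldRecord:
    """Training-side artifacts + test metrics of one outer fold."""

    fold: int
    test_subjects: list[str]
    selected_features: list[str]
    scaler_stats: np.ndarray | None
    threshold: float
    metrics: dict[str, float]
    confusion: ConfusionMatrix


class CrossValidationResults:
    """Fold-aggregated results of one pipeline configuration.

    Attributes
    ----------
    folds : list of :class:`FoldRecord`
    confusion : summed test-fold confusion matrix
    """

    def __init__(self, point: GridPoint, cv: CVConfig, folds: list[FoldRecord],
                 n_subjects: int, n_features_extracted: int):
        self.point = point
        self.cv = cv
        self.folds = folds
        self.n_subjects = n_subjects
        self.n_features_extracted = n_features_extracted
        self.confusion = ConfusionMatrix()
        for f in folds:
            self.confusion.add(f.confusion)

    def metric_values(self, name: str) -> np.ndarray:
        return np.array([f.metrics[name] for f in self.folds], dtype=float)

    def mean(self, name: str) -> float:
        return float(np.nanmean(self.metric_values(name)))

    def sd(self, name: str) -> float:
        return float(np.nanstd(self.metric_values(name), ddof=1))

    @property
    def mean_f1(self) -> float:
        return self.mean("f1")

    @property
    def mean_auc(self) -> float:
        return self.mean("auc")

    @property
    def mean_n_selected(self) -> float:
        return float(np.mean([len(f.selected_features) for f in self.folds]))

    def summary(self) -> str:
        lines = [
            "Cross-validated classification results",
            "=" * 54,
            f"pipeline:            {self.point.label()}",
            f"subjects:            {self.n_subjects} "
            f"(patients {self.confusion.n_positive}, "
            f"controls {self.confusion.n_negative})",
            f"outer folds:         {len(self.folds)} (stratified={self.cv.stratified})",
            f"features extracted:  {self.n_features_extracted}"
            f" | mean selected: {self.mean_n_selected:.1f}",
            "-" * 54,
            f"{'metric':<14}{'mean':>8}{'sd':>8}",
        ]
        for m in METRIC_NAMES:
            lines.append(f"{m:<14}{self.mean(m):>8.3f}{self.sd(m):>8.3f}")
        c = self.confusion
        lines += [
            "-" * 54,
            "summed test-fold confusion matrix (rows = truth):",
            f"{'':>12}{'pred. patient':>15}{'pred. healthy':>15}",
            f"{'patient':>12}{c.tp:>15}{c.fn:>15}",
            f"{'healthy':>12}{c.fp:>15}{c.tn:>15}",
        ]
        return "\n".join(lines)

    def as_dict(self) -> dict:
        return {
            "pipeline": self.point.label(),
            "metrics": {m: {"per_fold": self.metric_values(m).tolist(),
                            "mean": self.mean(m), "sd": self.sd(m)}
                        for m in METRIC_NAMES},
            "thresholds": [f.threshold for f in self.folds],
            "confusion": self.confusion.as_dict(),
            "selected_features": [f.selected_features for f in self.folds],
        }


def _fit_point(point: GridPoint, train: FeatureTable):
    """Fit selection + model on a training table; return (model, transform, kept)."""
    if point.model.family == "stacking":
        spec = point.stacking or StackingSpec(include_behavior=point.include_behavior)
        model = fit_stacking(spec, train, seed=point.model.seed)
        names = list(train.feature_names)
        return model, (lambda t: t.select_features(names)), names
    sel_train, transform = apply_selection(train, point.model, point.selection)
    model = fit(point.model, sel_train)
    return model, transform, list(sel_train.feature_names)


def _training_side_threshold(point: GridPoint, train: FeatureTable,
                             cv: CVConfig) -> float:
    """Balanced threshold from out-of-fold predictions within the training side.

    ``train`` is already in the selected feature space; the feature set
    is held fixed while the model is refit per inner fold.
    """
    y = train.y
    k = min(cv.threshold_inner_folds, np.bincount(y).min())
    if k < 2:
        return 0.5
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=cv.seed)
    oof = np.empty(len(y))
    for tr, va in skf.split(train.X, y):
        sub = train.select_rows(tr)
        if point.model.family == "stacking":
            spec = point.stacking or StackingSpec(include_behavior=point.include_behavior)
            m = fit_stacking(spec, sub, seed=point.model.seed)
        else:
            m = fit(point.model, sub)
        oof[va] = m.predict_proba(train.select_rows(va).values)
    return choose_threshold(oof, y)


def cross_validate(dataset: ERPDataset, point: GridPoint,
                   cv: CVConfig | None = None,
                   table: FeatureTable | None = None) -> CrossValidationResults:
    """Evaluate one pipeline configuration with outer cross-validation.

    Window-feature extraction is per-subject and parameter-driven (it
    fits nothing), so the table is built once; everything that learns —
    scaler, selection, classifier, threshold — is fitted per fold on
    training rows only.  Pass ``table`` to reuse an extracted table.
    """
    if cv is None:
        cv = CVConfig()
    if table is None:
        table = build_feature_table(dataset, point.window_params,
                                    include_behavior=point.include_behavior)
    y = table.y
    if np.bincount(y).min() < cv.outer_folds:
        raise ConfigError("outer_folds exceeds minority class count")

    if cv.stratified:
        splitter = StratifiedKFold(n_splits=cv.outer_folds, shuffle=True,
                                   random_state=cv.seed)
    else:
        splitter = KFold(n_splits=cv.outer_folds, shuffle=True, random_state=cv.seed)

    folds: list[FoldRecord] = []
    for i, (tr, te) in enumerate(splitter.split(table.X, y)):
        train = table.select_rows(tr)
        test = table.select_rows(te)
        if len(np.unique(train.y)) < 2 or len(np.unique(test.y)) < 2:
            raise ValidationError(f"fold {i}: a split contains a single class")

        model, transform, kept = _fit_point(point, train)
        threshold = _training_side_threshold(point, transform(train), cv)
        probs = model.predict_proba(transform(test).values)
        metrics, cm = compute_metrics(probs, test.y, threshold)

        scaler_stats = None
        if getattr(model, "scaler", None) is not None:
            sc = model.scaler
            for attr in ("mean_", "center_", "data_min_"):
                if hasattr(sc, attr):
                    scaler_stats = np.array(getattr(sc, attr), dtype=float).copy()
                    break
        folds.append(FoldRecord(
            fold=i, test_subjects=list(test.values.index),
            selected_features=kept, scaler_stats=scaler_stats,
            threshold=threshold, metrics=metrics, confusion=cm))

    return CrossValidationResults(point, cv, folds, len(table), table.n_features)


class GridSearchResults:
    """Ranked cross-validation results over a pipeline grid."""

    def __init__(self, results: list[CrossValidationResults],
                 failures: list[tuple[GridPoint, str]]):
        # rank: mean F1 desc, ties mean AUC desc, then fewer selected features
        self.results = sorted(
            results,
            key=lambda r: (-r.mean_f1, -r.mean_auc, r.mean_n_selected))
        self.failures = failures

    @property
    def best(self) -> CrossValidationResults:
        if not self.results:
            raise ValidationError("no grid point succeeded")
        return self.results[0]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            row = {"pipeline": r.point.label()}
            for m in METRIC_NAMES:
                row[m] = r.mean(m)
                row[m + "_sd"] = r.sd(m)
            row["n_selected"] = r.mean_n_selected
            rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> str:
        df = self.to_frame()
        lines = ["Grid search results (ranked by mean F1)", "=" * 72]
        header = f"{'pipeline':<32}" + "".join(f"{m:>10}" for m in METRIC_NAMES)
        lines.append(header)
        for _, row in df.iterrows():
            lines.append(f"{row['pipeline']:<32}" +
                         "".join(f"{row[m]:>10.3f}" for m in METRIC_NAMES))
        if self.failures:
            lines.append(f"failed points: {len(self.failures)}")
        return "\n".join(lines)


def grid_search(dataset: ERPDataset, grid: list[GridPoint],
                cv: CVConfig | None = None) -> GridSearchResults:
    """Cross-validate every grid point; failures are recorded, not fatal."""
    if not grid:
        raise ConfigError("empty grid")
    results, failures = [], []
    for point in grid:
        try:
            results.append(cross_validate(dataset, point, cv))
        except Exception as e:  # degenerate windows etc.
            failures.append((point, f"{type(e).__name__}: {e}"))
    return GridSearchResults(results, failures)


class ERPClassifier:
    """Statsmodels-style front door to the pipeline.

    Parameters
    ----------
    dataset : ERPDataset
        Cohort with group labels (and behavior summaries if used).
    point : GridPoint, optional
        Pipeline configuration; defaults to the best reported setup
        (SVM, RBF kernel, standard scaling, behavior included).

    ``fit()`` runs the outer cross-validation and returns a
    :class:`CrossValidationResults`; ``fit_final()`` refits the
    pipeline on all subjects for prediction on new data.
    """

    def __init__(self, dataset: ERPDataset, point: GridPoint | None = None):
        self.dataset = dataset
        self.point = point or GridPoint()

    @classmethod
    def from_tables(cls, erp_csv, behavior_csv=None,
                    point: GridPoint | None = None) -> "ERPClassifier":
        from erpdx.erp_data import load_erp_table, load_behavior_table, attach_behavior
        ds = load_erp_table(erp_csv)
        if behavior_csv is not None:
            attach_behavior(ds, load_behavior_table(behavior_csv))
        return cls(ds, point)

    def fit(self, cv: CVConfig | None = None) -> CrossValidationResults:
        return cross_validate(self.dataset, self.point, cv)

    def fit_final(self):
        """Fit selection + model on the full cohort; returns the fitted model."""
        table = build_feature_table(self.dataset, self.point.window_params,
                                    include_behavior=self.point.include_behavior)
        model, transform, kept = _fit_point(self.point, table)
        self.model_ = model
        self.transform_ = transform
        self.selected_features_ = kept
        self.table_ = table
        return model

    def predict_proba(self, dataset: ERPDataset) -> np.ndarray:
        if not hasattr(self, "model_"):
            raise ValidationError("call fit_final() before predict_proba()")
        table = build_feature_table(dataset, self.point.window_params,
                                    include_behavior=self.point.include_behavior)
        return self.model_.predict_proba(self.transform_(table).values)
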