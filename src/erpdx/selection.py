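"""Feature selection: random-probe Shapley filtering, sequential
selection on inner cross-validation, and truncated-SVD reduction.

Three strategies, all fitted strictly on training rows:

- **probe_shap**: append one standard-normal "probe" column, fit the
  model, compute each feature's global importance as the mean absolute
  Shapley attribution over training rows, and keep only the features
  strictly more important than the probe.  Under pure noise the probe
  importance is a draw from the same null, so almost everything is
  discarded.
- **sfs_forward / sfs_backward**: greedy stepwise addition/removal
  scored by seeded stratified inner CV.  Backward elimination accepts a
  removal while the inner-CV score does not decrease; forward addition
  requires strict improvement.  Score ties between candidates break by
  lexicographically smallest feature name (deterministic).
- **truncated_svd**: linear projection onto the smallest number of
  singular components whose cumulative explained variance reaches a
  configured fraction.

``probe_then_sfs`` chains the probe filter with SFS on its survivors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import f1_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from erpdx.errors import ConfigError, ValidationError
from erpdx.features import FeatureTable
from erpdx.models import ModelSpec, fit
from erpdx.shapley import mean_abs_attribution, shapley_values

STRATEGIES = ("none", "probe_shap", "sfs_forward", "sfs_backward",
              "probe_then_sfs", "truncated_svd")

PROBE_NAME = "__random_probe__"


@dataclass(frozen=True)
class SelectionConfig:
    strategy: str = "none"
    inner_folds: int = 5
    score_metric: str = "f1"            # f1 | roc_auc
    svd_variance_frac: float = 0.95
    probe_seed: int = 0                 # seed for probe draw, attributions, inner CV
    max_steps: int | None = None        # cap on SFS accepted moves (None = unlimited)
    shap_permutations: int = 8          # permutation estimator draws per row
    shap_background: int = 100          # background subsample size
    shap_explain_rows: int | None = 100  # rows to explain (None = all)

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ConfigError(f"unknown selection strategy {self.strategy!r}")
        if self.inner_folds < 2:
            raise ConfigError("inner_folds must be >= 2")
        if not 0 < self.svd_variance_frac <= 1:
            raise ConfigError("svd_variance_frac must be in (0, 1]")
        if self.score_metric not in ("f1", "roc_auc"):
            raise ConfigError(f"unknown score metric {self.score_metric!r}")


@dataclass
class SelectionResult:
    kept: list[str]
    trace: list[dict] = field(default_factory=list)
    probe_importance: float | None = None
    status: str = "ok"


def _inner_cv_score(table: FeatureTable, feature_subset: list[str],
                    model_spec: ModelSpec, cfg: SelectionConfig) -> float:
    """Seeded stratified inner-CV score of a feature subset."""
    if not feature_subset:
        return 0.0
    sub = table.select_features(list(feature_subset))
    y = sub.y
    skf = StratifiedKFold(n_splits=cfg.inner_folds, shuffle=True,
                          random_state=cfg.probe_seed)
    scores = []
    for tr, va in skf.split(sub.X, y):
        m = fit(model_spec, sub.select_rows(tr))
        va_table = sub.select_rows(va)
        if cfg.score_metric == "f1":
            pred = m.predict_labels(va_table)
            scores.append(f1_score(y[va], pred, zero_division=0))
        else:
            if len(np.unique(y[va])) < 2:
                continue
            scores.append(roc_auc_score(y[va], m.predict_proba(va_table.values)))
    return float(np.mean(scores)) if scores else 0.0


def _make_array_scorer(table: FeatureTable, model_spec: ModelSpec,
                       cfg: SelectionConfig):
    """Fast inner-CV scorer over feature-name subsets.

    Pre-splits the folds and pre-scales each fold's full matrix once:
    all supported scalers are per-column, so column statistics do not
    depend on which other columns are selected, and the per-candidate
    cost reduces to one estimator fit per fold.  Scores agree with
    :func:`_inner_cv_score` exactly.
    """
    from erpdx.models import _upsample, build_estimator, make_scaler

    X, y = table.X, table.y
    name_idx = {n: i for i, n in enumerate(table.feature_names)}
    skf = StratifiedKFold(n_splits=cfg.inner_folds, shuffle=True,
                          random_state=cfg.probe_seed)
    folds = []
    for tr, va in skf.split(X, y):
        Xtr, Xva = X[tr], X[va]
        scaler = make_scaler(model_spec.scaler)
        if scaler is not None:
            Xtr = scaler.fit_transform(Xtr)
            Xva = scaler.transform(Xva)
        ytr = y[tr]
        if model_spec.imbalance == "upsample":
            Xtr, ytr = _upsample(Xtr, ytr, model_spec.seed)
        folds.append((Xtr, ytr, Xva, y[va]))

    def score(subset: list[str]) -> float:
        if not subset:
            return 0.0
        cols = [name_idx[n] for n in subset]
        vals = []
        for Xtr, ytr, Xva, yva in folds:
            est = build_estimator(model_spec)
            est.fit(Xtr[:, cols], ytr)
            if cfg.score_metric == "f1":
                vals.append(f1_score(yva, est.predict(Xva[:, cols]), zero_division=0))
            else:
                if len(np.unique(yva)) < 2:
                    continue
                vals.append(roc_auc_score(yva, est.predict_proba(Xva[:, cols])[:, 1]))
        return float(np.mean(vals)) if vals else 0.0

    return score


def probe_shap_filter(table: FeatureTable, model_spec: ModelSpec,
                      cfg: SelectionConfig) -> SelectionResult:
    """Keep features whose mean |Shapley| exceeds a random probe's.

    A standard-normal column is appended (seeded), the model is fitted
    on the augmented table, and permutation-sampling Shapley
    attributions of the positive-class probability are computed over a
    (sub)sample of training rows against a background subsample.
    """
    if table.n_features < 2:
        raise ValidationError("probe filter needs at least 2 features")
    if len(np.unique(table.y)) < 2:
        raise ValidationError("probe filter needs both classes")

    rng = np.random.default_rng(cfg.probe_seed)
    aug = table.values.copy()
    aug[PROBE_NAME] = rng.standard_normal(len(aug))
    aug_table = FeatureTable(aug, table.groups.copy())

    model = fit(model_spec, aug_table)
    Xs = aug_table.X
    if model.scaler is not None:
        Xs = model.scaler.transform(Xs)
    n = Xs.shape[0]
    bg_idx = rng.choice(n, size=min(cfg.shap_background, n), replace=False)
    if cfg.shap_explain_rows is None or cfg.shap_explain_rows >= n:
        ex_idx = np.arange(n)
    else:
        ex_idx = rng.choice(n, size=cfg.shap_explain_rows, replace=False)

    predict = lambda Z: model.estimator.predict_proba(Z)[:, 1]
    phi, _ = shapley_values(predict, Xs[ex_idx], Xs[bg_idx],
                            method="permutation",
                            n_permutations=cfg.shap_permutations,
                            seed=cfg.probe_seed)
    importance = mean_abs_attribution(phi)
    names = aug_table.feature_names
    probe_imp = importance[names.index(PROBE_NAME)]

    kept = [nm for nm, imp in zip(names, importance)
            if nm != PROBE_NAME and imp > probe_imp]
    status = "ok" if kept else "warning: all features below probe importance"
    trace = [{"feature": nm, "importance": float(imp)}
             for nm, imp in zip(names, importance) if nm != PROBE_NAME]
    return SelectionResult(kept=kept, trace=trace,
                           probe_importance=float(probe_imp), status=status)


def sequential_select(table: FeatureTable, model_spec: ModelSpec,
                      cfg: SelectionConfig, direction: str) -> SelectionResult:
    """Greedy stepwise feature selection scored by inner CV.

    Backward: drop, at each sweep, the single feature whose removal
    gives the best score, while that score is >= the current one.
    Forward: add the best-scoring feature while it strictly improves.
    """
    if direction not in ("forward", "backward"):
        raise ConfigError(f"direction must be forward or backward, got {direction!r}")
    all_features = list(table.feature_names)
    trace: list[dict] = []
    scorer = _make_array_scorer(table, model_spec, cfg)

    if direction == "backward":
        current = list(all_features)
        score = scorer(current)
        trace.append({"action": "start", "score": score, "n_features": len(current)})
        steps = 0
        while len(current) > 1:
            if cfg.max_steps is not None and steps >= cfg.max_steps:
                break
            best_feat, best_score = None, -np.inf
            for f in current:
                cand = [c for c in current if c != f]
                s = scorer(cand)
                if s > best_score or (s == best_score and best_feat is not None
                                      and f < best_feat):
                    best_feat, best_score = f, s
            if best_score >= score:
                current.remove(best_feat)
                score = best_score
                steps += 1
                trace.append({"action": "remove", "feature": best_feat,
                              "score": score, "n_features": len(current)})
            else:
                break
        return SelectionResult(kept=current, trace=trace)

    # forward
    current: list[str] = []
    score = 0.0
    trace.append({"action": "start", "score": score, "n_features": 0})
    steps = 0
    remaining = list(all_features)
    while remaining:
        if cfg.max_steps is not None and steps >= cfg.max_steps:
            break
        best_feat, best_score = None, -np.inf
        for f in remaining:
            s = scorer(current + [f])
            if s > best_score or (s == best_score and best_feat is not None
                                  and f < best_feat):
                best_feat, best_score = f, s
        if best_score > score:
            current.append(best_feat)
            remaining.remove(best_feat)
            score = best_score
            steps += 1
            trace.append({"action": "add", "feature": best_feat,
                          "score": score, "n_features": len(current)})
        else:
            break
    return SelectionResult(kept=current, trace=trace)


@dataclass
class SVDProjection:
    """A fitted rank-k linear projection (no centering, as in truncated SVD)."""

    components: np.ndarray          # (k, n_features)
    explained_variance_ratio: np.ndarray
    feature_names: list[str]

    @property
    def k(self) -> int:
        return self.components.shape[0]

    def transform(self, table: FeatureTable) -> FeatureTable:
        X = table.values[self.feature_names].to_numpy(dtype=float)
        Z = X @ self.components.T
        cols = [f"svd_{i + 1}" for i in range(self.k)]
        return FeatureTable(pd.DataFrame(Z, index=table.values.index, columns=cols),
                            table.groups.copy())


def svd_reduce(table: FeatureTable, cfg: SelectionConfig
               ) -> tuple[FeatureTable, SVDProjection]:
    """Project onto the smallest k components reaching the variance cutoff.

    Fitted on the given (training) rows only; apply the returned
    projection to held-out rows unchanged.
    """
    if table.n_features < 2:
        raise ValidationError("svd_reduce needs at least 2 features")
    X = table.X
    _, s, vt = np.linalg.svd(X, full_matrices=False)
    var = s ** 2
    total = var.sum()
    ratio = var / total if total > 0 else np.full_like(var, 1.0 / var.size)
    k = int(np.searchsorted(np.cumsum(ratio), cfg.svd_variance_frac - 1e-12) + 1)
    k = min(k, len(s))
    proj = SVDProjection(components=vt[:k], explained_variance_ratio=ratio[:k],
                         feature_names=list(table.feature_names))
    return proj.transform(table), proj


def apply_selection(table: FeatureTable, model_spec: ModelSpec,
                    cfg: SelectionConfig):
    """Dispatch a selection strategy on a training table.

    Returns ``(selected_train_table, transformer)`` where transformer
    maps any compatible table to the selected feature space.
    """
    if cfg.strategy == "none":
        names = list(table.feature_names)
        return table, lambda t: t.select_features(names)
    if cfg.strategy == "probe_shap":
        res = probe_shap_filter(table, model_spec, cfg)
        kept = res.kept or list(table.feature_names)  # degenerate: keep all
        return table.select_features(kept), lambda t: t.select_features(kept)
    if cfg.strategy in ("sfs_forward", "sfs_backward"):
        res = sequential_select(table, model_spec, cfg,
                                cfg.strategy.removeprefix("sfs_"))
        kept = res.kept or list(table.feature_names)
        return table.select_features(kept), lambda t: t.select_features(kept)
    if cfg.strategy == "probe_then_sfs":
        probe_res = probe_shap_filter(table, model_spec, cfg)
        kept0 = probe_res.kept or list(table.feature_names)
        res = sequential_select(table.select_features(kept0), model_spec, cfg,
                                "backward")
        kept = res.kept or kept0
        return table.select_features(kept), lambda t: t.select_features(kept)
    if cfg.strategy == "truncated_svd":
        reduced, proj = svd_reduce(table, cfg)
        return reduced, proj.transform
    raise ConfigError(f"unknown strategy {cfg.strategy!r}")
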