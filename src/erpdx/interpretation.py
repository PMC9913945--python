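"""Model interpretation: global Shapley importance and signed direction.

Global importance of each feature is the mean absolute Shapley
attribution of the positive-class (patient) probability over a set of
explained rows; the sign direction summarizes whether larger feature
values push predictions toward the patient class (positive rank
correlation between feature value and signed attribution) or away from
it.  Reports are plain tables, ready for any plotting layer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from erpdx.errors import ValidationError
from erpdx.features import FeatureTable
from erpdx.models import FittedModel
from erpdx.shapley import EXACT_MAX_FEATURES, mean_abs_attribution, shapley_values


@dataclass
class ImportanceReport:
    """Per-feature global importance + per-subject signed attributions."""

    features: list[str]
    mean_abs: np.ndarray              # aligned with features
    attributions: pd.DataFrame        # subjects x features, signed
    base_value: float
    ranking: list[str]                # non-increasing mean |attribution|
    top_k: int

    def top_features(self) -> list[str]:
        return self.ranking[: self.top_k]

    def to_frame(self) -> pd.DataFrame:
        order = np.argsort(-self.mean_abs, kind="stable")
        return pd.DataFrame({
            "feature": [self.features[i] for i in order],
            "mean_abs_shap": self.mean_abs[order],
        })


def global_importance(model: FittedModel, table: FeatureTable,
                      top_k: int = 15, seed: int = 0,
                      method: str = "auto",
                      n_permutations: int = 16,
                      background_size: int = 100) -> ImportanceReport:
    """Shapley attribution report for a fitted model on a feature table.

    Uses exact subset enumeration when the feature count is small
    (axioms hold exactly), otherwise the seeded permutation estimator.
    The background is a seeded subsample of the table's rows and
    attributions are computed for every row.
    """
    names = model.feature_names
    missing = [n for n in names if n not in table.feature_names]
    if missing:
        raise ValidationError(f"table missing model features {missing[:5]}")
    sub = table.select_features(names)
    X = sub.X
    if model.scaler is not None:
        X = model.scaler.transform(X)

    rng = np.random.default_rng(seed)
    bg = X[rng.choice(X.shape[0], size=min(background_size, X.shape[0]),
                      replace=False)]
    predict = lambda Z: model.estimator.predict_proba(Z)[:, 1]
    phi, base = shapley_values(predict, X, bg, method=method,
                               n_permutations=n_permutations, seed=seed)

    mean_abs = mean_abs_attribution(phi)
    order = np.argsort(-mean_abs, kind="stable")
    ranking = [names[i] for i in order]
    if top_k > len(names):
        warnings.warn(f"top_k={top_k} exceeds feature count {len(names)}; clipped")
        top_k = len(names)
    attributions = pd.DataFrame(phi, index=sub.values.index, columns=names)
    return ImportanceReport(features=list(names), mean_abs=mean_abs,
                            attributions=attributions, base_value=base,
                            ranking=ranking, top_k=top_k)


def direction_summary(report: ImportanceReport, table: FeatureTable) -> pd.DataFrame:
    """Per-feature rank correlation of feature value with signed attribution.

    Positive direction means larger feature values push toward the
    patient class.  Constant features (or constant attributions) have
    an undefined correlation, reported as 0 with ``degenerate=True``.
    """
    rows = []
    for feat in report.features:
        vals = table.values[feat].to_numpy(dtype=float)
        attr = report.attributions[feat].to_numpy(dtype=float)
        if np.ptp(vals) == 0 or np.ptp(attr) == 0:
            rows.append({"feature": feat, "direction": 0.0, "degenerate": True})
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rho = stats.spearmanr(vals, attr).statistic
        if not np.isfinite(rho):
            rows.append({"feature": feat, "direction": 0.0, "degenerate": True})
        else:
            rows.append({"feature": feat, "direction": float(rho), "degenerate": False})
    return pd.DataFrame(rows)
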