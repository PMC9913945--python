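"""Thresholding, metrics, cross-validation, grid search, model wrapper."""

import numpy as np
import pytest

from erpdx.errors import ConfigError, ValidationError
from erpdx.evaluation import (
    CVConfig,
    ERPClassifier,
    GridPoint,
    choose_threshold,
    compute_metrics,
    cross_validate,
    grid_search,
)
from erpdx.models import ModelSpec
from erpdx.selection import SelectionConfig


def exhaustive_threshold_scan(probs, labels):
    """Independent oracle: best |TPR - TNR| over all candidate midpoints."""
    uniq = np.unique(probs)
    cands = (uniq[:-1] + uniq[1:]) / 2 if uniq.size > 1 else uniq
    n_pos = (labels == 1).sum()
    n_neg = (labels == 0).sum()
    gaps = []
    for t in cands:
        pred = probs >= t
        tpr = (pred & (labels == 1)).sum() / n_pos
        tnr = (~pred & (labels == 0)).sum() / n_neg
        gaps.append(abs(tpr - tnr))
    return min(gaps)


def balance_gap(probs, labels, t):
    pred = probs >= t
    tpr = (pred & (labels == 1)).sum() / (labels == 1).sum()
    tnr = (~pred & (labels == 0)).sum() / (labels == 0).sum()
    return abs(tpr - tnr)


def test_threshold_separates_perfectly():
    probs = np.array([0.1, 0.2, 0.8, 0.9])
    labels = np.array([0, 0, 1, 1])
    t = choose_threshold(probs, labels)
    assert 0.2 < t < 0.8
    assert balance_gap(probs, labels, t) == 0.0


def test_threshold_on_exact_labels():
    labels = np.array([0, 1, 0, 1, 1])
    t = choose_threshold(labels.astype(float), labels)
    assert balance_gap(labels.astype(float), labels, t) == 0.0


def test_threshold_minimizes_gap_against_exhaustive_scan():
    rng = np.random.default_rng(0)
    for _ in range(100):
        n = int(rng.integers(10, 200))
        labels = (rng.random(n) < 0.4).astype(int)
        if labels.sum() in (0, n):
            continue
        probs = rng.random(n)
        t = choose_threshold(probs, labels)
        assert balance_gap(probs, labels, t) == pytest.approx(
            exhaustive_threshold_scan(probs, labels), abs=1e-12)


def test_threshold_requires_both_classes():
    with pytest.raises(ValidationError):
        choose_threshold(np.array([0.2, 0.8]), np.array([1, 1]))


def test_metrics_worked_counts():
    """62 of 68 patients correct: sensitivity 62/68 ~ 0.9118."""
    labels = np.array([1] * 68 + [0] * 132)
    probs = np.concatenate([
        np.full(62, 0.9), np.full(6, 0.1),      # patients
        np.full(121, 0.1), np.full(11, 0.9),    # controls
    ])
    m, cm = compute_metrics(probs, labels, threshold=0.5)
    assert m["sensitivity"] == pytest.approx(62 / 68)
    assert (cm.tp, cm.fn, cm.tn, cm.fp) == (62, 6, 121, 11)
    assert cm.total == 200


def test_auc_tie_credit_and_perfect_ranking():
    labels = np.array([0, 0, 1, 1])
    m, _ = compute_metrics(np.full(4, 0.5), labels, 0.5)
    assert m["auc"] == 0.5
    m, _ = compute_metrics(np.array([0.1, 0.2, 0.8, 0.9]), labels, 0.5)
    assert m["auc"] == 1.0


def test_cross_validate_confusion_conservation(medium_cohort, smoke_params):
    point = GridPoint(window_params=smoke_params,
                      model=ModelSpec(family="logreg"))
    res = cross_validate(medium_cohort, point, CVConfig(outer_folds=5, seed=0))
    cm = res.confusion
    assert cm.total == len(medium_cohort)
    assert cm.n_positive == medium_cohort.n_by_group()["schizophrenia"]
    assert cm.n_negative == medium_cohort.n_by_group()["healthy"]
    # every subject appears in exactly one test fold
    seen = [s for f in res.folds for s in f.test_subjects]
    assert sorted(seen) == sorted(s.subject_id for s in medium_cohort.subjects)


def test_cross_validate_mean_sd_match_fold_values(medium_cohort, smoke_params):
    point = GridPoint(window_params=smoke_params, model=ModelSpec(family="logreg"))
    res = cross_validate(medium_cohort, point, CVConfig(outer_folds=4, seed=1))
    for m in ("sensitivity", "specificity", "f1", "auc"):
        vals = res.metric_values(m)
        assert res.mean(m) == pytest.approx(np.mean(vals))
        assert res.sd(m) == pytest.approx(np.std(vals, ddof=1))
        assert np.min(vals) <= res.mean(m) <= np.max(vals)


def test_cross_validate_deterministic(medium_cohort, smoke_params):
    point = GridPoint(window_params=smoke_params, model=ModelSpec(family="svm"))
    cv = CVConfig(outer_folds=4, seed=2)
    a = cross_validate(medium_cohort, point, cv)
    b = cross_validate(medium_cohort, point, cv)
    for m in ("sensitivity", "specificity", "f1", "auc"):
        np.testing.assert_array_equal(a.metric_values(m), b.metric_values(m))
    assert [f.threshold for f in a.folds] == [f.threshold for f in b.folds]


def test_cross_validate_rejects_too_many_folds(small_cohort, smoke_params):
    point = GridPoint(window_params=smoke_params, model=ModelSpec(family="logreg"))
    with pytest.raises(ConfigError):
        cross_validate(small_cohort, point, CVConfig(outer_folds=10, seed=0))


def test_no_leakage_test_fold_perturbation(medium_cohort, smoke_params):
    """Replacing test-fold rows with noise leaves every training-side
    artifact (selected features, scaler statistics, threshold) unchanged."""
    from erpdx.features import build_feature_table, FeatureTable

    point = GridPoint(window_params=smoke_params,
                      selection=SelectionConfig(strategy="sfs_backward",
                                                inner_folds=3, max_steps=1),
                      model=ModelSpec(family="logreg"))
    cv = CVConfig(outer_folds=3, seed=0)
    table = build_feature_table(medium_cohort, smoke_params)
    res_a = cross_validate(medium_cohort, point, cv, table=table)

    rng = np.random.default_rng(99)
    fold0_test = set(res_a.folds[0].test_subjects)
    perturbed = table.values.copy()
    mask = perturbed.index.isin(fold0_test)
    perturbed.loc[mask, :] = rng.normal(size=(mask.sum(), table.n_features))
    res_b = cross_validate(medium_cohort, point, cv,
                           table=FeatureTable(perturbed, table.groups.copy()))

    fa, fb = res_a.folds[0], res_b.folds[0]
    assert fa.selected_features == fb.selected_features
    assert fa.threshold == fb.threshold
    np.testing.assert_array_equal(fa.scaler_stats, fb.scaler_stats)
    # ... while the test metrics do change
    assert fa.metrics != fb.metrics


def test_grid_search_single_point_and_determinism(medium_cohort, smoke_params):
    p1 = GridPoint(window_params=smoke_params, model=ModelSpec(family="logreg"))
    res = grid_search(medium_cohort, [p1], CVConfig(outer_folds=3, seed=0))
    assert res.best.point is p1
    res2 = grid_search(medium_cohort, [p1, p1], CVConfig(outer_folds=3, seed=0))
    assert res2.results[0].mean_f1 == res2.results[1].mean_f1


def test_grid_search_records_failures(medium_cohort, smoke_params):
    from erpdx.features import WindowParams

    bad = dict(smoke_params)
    bad["ph"] = WindowParams(500, 100)  # window larger than the ph interval
    p_bad = GridPoint(window_params=bad, model=ModelSpec(family="logreg"))
    p_ok = GridPoint(window_params=smoke_params, model=ModelSpec(family="logreg"))
    res = grid_search(medium_cohort, [p_ok, p_bad], CVConfig(outer_folds=3, seed=0))
    assert len(res.results) == 1
    assert len(res.failures) == 1


def test_grid_search_empty_grid():
    with pytest.raises(ConfigError):
        grid_search(None, [], CVConfig())


def test_stacking_point_runs(medium_cohort, smoke_params):
    point = GridPoint(window_params=smoke_params,
                      model=ModelSpec(family="stacking"))
    res = cross_validate(medium_cohort, point, CVConfig(outer_folds=3, seed=0))
    assert res.confusion.total == len(medium_cohort)


def test_truncated_svd_point_runs(medium_cohort, smoke_params):
    point = GridPoint(window_params=smoke_params,
                      selection=SelectionConfig(strategy="truncated_svd",
                                                svd_variance_frac=0.9),
                      model=ModelSpec(family="logreg"))
    res = cross_validate(medium_cohort, point, CVConfig(outer_folds=3, seed=0))
    assert res.confusion.total == len(medium_cohort)
    assert all(f.selected_features[0].startswith("svd_") for f in res.folds)


def test_results_summary_renders(medium_cohort, smoke_params):
    point = GridPoint(window_params=smoke_params, model=ModelSpec(family="logreg"))
    res = cross_validate(medium_cohort, point, CVConfig(outer_folds=3, seed=0))
    text = res.summary()
    assert "sensitivity" in text and "confusion" in text
    d = res.as_dict()
    assert set(d["metrics"]) == {"sensitivity", "specificity", "f1", "auc"}


def test_erp_classifier_wrapper(medium_cohort, smoke_params):
    model = ERPClassifier(medium_cohort,
                          GridPoint(window_params=smoke_params,
                                    model=ModelSpec(family="logreg")))
    res = model.fit(CVConfig(outer_folds=3, seed=0))
    assert 0.0 <= res.mean_f1 <= 1.0
    model.fit_final()
    probs = model.predict_proba(medium_cohort)
    assert probs.shape == (len(medium_cohort),)
    assert np.all((probs >= 0) & (probs <= 1))
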