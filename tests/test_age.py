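"""Logistic CV, exact linear SHAP, keyframe selection, and video
classifier contracts."""

import warnings
from itertools import combinations
from math import factorial

import numpy as np
import pytest

from flyheart.age import (FEATURES, KeyframeSet, LogisticAgeClassifier,
                          VideoAgeClassifier, explain_shap, fit_logistic_cv,
                          motion_keyframes, predict_age,
                          train_video_classifier)
from flyheart.errors import DataError


# -- logistic pipeline --------------------------------------------------------

def test_cv_folds_partition_dataset(cohort_features):
    df = cohort_features.sample(n=50, random_state=0)
    _, report = fit_logistic_cv(df, df["label"], k=5, seed=0)
    all_idx = np.sort(np.concatenate(report.test_indices))
    np.testing.assert_array_equal(all_idx, np.arange(50))
    assert report.confusion.sum() == 50
    assert all(0.0 <= a <= 1.0 for a in report.fold_auroc)


def test_separable_cohorts_classified_accurately(cohort_features):
    _, report = fit_logistic_cv(cohort_features, cohort_features["label"], seed=0)
    assert report.mean_accuracy >= 0.9
    assert report.mean_auroc >= 0.9


def test_permuted_labels_fall_to_chance(cohort_features):
    rng = np.random.default_rng(0)
    perm = rng.permutation(cohort_features["label"].to_numpy())
    _, report = fit_logistic_cv(cohort_features, perm, seed=0)
    assert abs(report.mean_accuracy - 0.5) <= 0.1


def test_single_class_labels_rejected(cohort_features):
    with pytest.raises(DataError, match="class"):
        fit_logistic_cv(cohort_features, np.zeros(len(cohort_features)), seed=0)


# -- SHAP ---------------------------------------------------------------------

def _brute_force_shapley(model, background, x):
    """Exhaustive 2^7-coalition Shapley with mean-imputation values."""
    M = len(FEATURES)
    mean_bg = background.mean(axis=0)

    def value(S):
        v = mean_bg.copy()
        for j in S:
            v[j] = x[j]
        return model.decision_function(v[None, :])[0]

    sv = np.zeros(M)
    for j in range(M):
        others = [i for i in range(M) if i != j]
        for r in range(M):
            for S in combinations(others, r):
                w = factorial(r) * factorial(M - r - 1) / factorial(M)
                sv[j] += w * (value(S + (j,)) - value(S))
    return sv


def test_shap_matches_exhaustive_enumeration(cohort_features):
    X = cohort_features[list(FEATURES)].to_numpy()
    y = cohort_features["label"].to_numpy()
    model = LogisticAgeClassifier(seed=0).fit(X, y)
    x = X[7]
    exp = explain_shap(model, X, x)
    brute = _brute_force_shapley(model, X, x)
    for j, f in enumerate(FEATURES):
        assert abs(exp.values[f] - brute[j]) < 1e-9
    assert exp.efficiency_gap < 1e-9


def test_shap_zero_at_background_mean(cohort_features):
    X = cohort_features[list(FEATURES)].to_numpy()
    model = LogisticAgeClassifier(seed=0).fit(X, cohort_features["label"])
    exp = explain_shap(model, X, X.mean(axis=0))
    assert max(abs(v) for v in exp.values.values()) < 1e-9


# -- motion keyframes ---------------------------------------------------------

def _clip_with_binary_series(values):
    """A clip whose normalized, binarized SSD series equals ``values``."""
    return np.asarray(values, dtype=float)[:, None, None] * np.ones((1, 2, 2))


def test_keyframes_match_hand_enumerated_runs():
    ks = motion_keyframes(_clip_with_binary_series([0, 0, 1, 1, 1, 0, 0, 1, 1]),
                          n=4)
    np.testing.assert_array_equal(ks.indices, [0, 3, 5, 7])
    np.testing.assert_array_equal(ks.durations, [3, 2, 2])


def test_keyframes_alternating_series():
    ks = motion_keyframes(_clip_with_binary_series([0, 1] * 100), n=96)
    np.testing.assert_array_equal(ks.indices, np.arange(96))
    assert (ks.durations == 1).all()
    assert ks.padded == 0


def test_keyframes_ordering_scale_invariance_and_padding():
    rng = np.random.default_rng(3)
    clip = rng.random((60, 4, 4))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ks = motion_keyframes(clip, n=96)
        ks_scaled = motion_keyframes(clip * 7.5, n=96)
    np.testing.assert_array_equal(ks.indices, ks_scaled.indices)
    real = ks.indices[: len(ks.indices) - ks.padded]
    assert (np.diff(real) >= 1).all()
    assert ks.padded > 0
    assert len(ks.frames) == 96
    assert (ks.durations[-ks.padded:] == 0).all()


def test_keyframes_constant_video_rejected():
    with pytest.raises(DataError, match="constant"):
        motion_keyframes(np.ones((10, 3, 3)), n=4)


# -- video classifier ---------------------------------------------------------

def _toy_keyframe_sets(n_per_class, rng, shape=(16, 16), n_frames=12):
    """Separable classes: bright vs dark band pattern + short vs long runs."""
    sets, labels = [], []
    for label in (0, 1):
        for _ in range(n_per_class):
            frames = rng.normal(0.2 + 0.5 * label, 0.05,
                                size=(n_frames, *shape))
            durations = np.full(n_frames - 1, 2.0 + 4.0 * label)
            durations += rng.normal(0, 0.2, n_frames - 1)
            idx = np.cumsum(np.concatenate([[0], durations])).astype(int)
            sets.append(KeyframeSet(frames, idx, durations))
            labels.append(label)
    return sets, np.array(labels)


def test_video_classifier_learns_separable_toy_data():
    rng = np.random.default_rng(0)
    sets, labels = _toy_keyframe_sets(8, rng)
    model, report = train_video_classifier(
        sets, labels, k=2, seed=0, epochs=15, conv_channels=(4, 8, 8),
        dense=(16, 8))
    assert report.mean_accuracy >= 0.9
    proba = model.predict_proba(sets)
    assert (proba >= 0).all() and (proba <= 1).all()
    np.testing.assert_allclose(proba.sum(axis=1), 1.0)


def test_video_classifier_seed_determinism_and_geometry_check():
    rng = np.random.default_rng(1)
    sets, labels = _toy_keyframe_sets(3, rng)
    clf1 = VideoAgeClassifier(epochs=2, conv_channels=(4, 4, 4), dense=(8, 4),
                              seed=5).fit(sets, labels)
    clf2 = VideoAgeClassifier(epochs=2, conv_channels=(4, 4, 4), dense=(8, 4),
                              seed=5).fit(sets, labels)
    np.testing.assert_array_equal(clf1.predict_proba(sets),
                                  clf2.predict_proba(sets))
    bad = sets[:2] + [KeyframeSet(np.zeros((12, 8, 8)), np.arange(12),
                                  np.ones(11))]
    with pytest.raises(DataError, match="geometry"):
        clf1.fit(bad, np.array([0, 1, 1]))


# -- predict_age --------------------------------------------------------------

def test_predict_age_labels_and_likelihood(cohort_features):
    X = cohort_features[list(FEATURES)].to_numpy()
    y = cohort_features["label"].to_numpy()
    model = LogisticAgeClassifier(seed=0).fit(X, y)
    out = predict_age(model, X[:20])
    assert (out["log_likelihood"] <= 0).all()
    assert set(out["label"]) <= {"young", "old"}
    # tie at exactly 0.5 resolves to old
    assert np.all((out["p_old"] >= 0.5) == (out["label"] == "old"))


def test_predict_age_requires_fitted_model():
    from sklearn.exceptions import NotFittedError

    with pytest.raises(NotFittedError):
        predict_age(LogisticAgeClassifier(), np.zeros((1, 7)))
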