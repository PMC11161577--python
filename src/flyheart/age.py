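"""Age classification from cardiac statistics and from video keyframes.

Two pipelines:

1. Logistic classification on the seven per-heart cardiac statistics
   (DD, SD, FS, DI, SI, HP, AI), features standardized per training
   fold, evaluated with stratified 5-fold cross-validation, and
   explained with exact linear-model Shapley attributions on the link
   (log-odds) scale: for a linear model with mean-imputation value
   function the Shapley value of feature j collapses to
   w_j (x_j - E_bg[x_j]).

2. A convolutional video classifier on motion-selected keyframes: the
   frame-wise sum of squared differences against a reference frame t0
   is min-max normalized, binarized at 0.5, decomposed into maximal
   runs of equal value, and the center frame of each run is kept until
   96 frames are collected; the 95 inter-keyframe durations join the
   flattened convolutional features before three dense layers and a
   sigmoid output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import confusion_matrix, roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_is_fitted

from .beats import aggregate_stats, detect_beats
from .errors import DataError, ParameterError
from .nn import Adam, Tensor, VideoCNN, bce_with_logits
from .trace import DiameterTrace

__all__ = [
    "FEATURES",
    "CVReport",
    "ShapExplanation",
    "KeyframeSet",
    "LogisticAgeClassifier",
    "VideoAgeClassifier",
    "cohort_feature_table",
    "cohort_keyframes",
    "fit_logistic_cv",
    "explain_shap",
    "motion_keyframes",
    "train_video_classifier",
    "predict_age",
]

FEATURES = ("dd", "sd", "fs", "di", "si", "hp", "ai")


@dataclass
class CVReport:
    """k-fold cross-validation report (binary classification)."""

    fold_accuracy: list[float]
    fold_auroc: list[float]
    confusion: np.ndarray       # summed over test folds, rows = true class
    test_indices: list[np.ndarray]
    n: int

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracy))

    @property
    def mean_auroc(self) -> float:
        return float(np.mean(self.fold_auroc))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "fold": np.arange(len(self.fold_accuracy)),
            "accuracy": self.fold_accuracy,
            "auroc": self.fold_auroc,
        })

    def summary(self) -> dict:
        return {
            "mean_accuracy": self.mean_accuracy,
            "mean_auroc": self.mean_auroc,
            "confusion": self.confusion.tolist(),
            "n": self.n,
        }


@dataclass
class ShapExplanation:
    """Per-feature attributions on the model's link (log-odds) scale."""

    values: dict[str, float]
    base_value: float
    link_output: float

    @property
    def efficiency_gap(self) -> float:
        return abs(sum(self.values.values()) + self.base_value - self.link_output)


@dataclass
class KeyframeSet:
    """Motion-selected keyframes + inter-keyframe durations (frames)."""

    frames: np.ndarray          # (n, H, W)
    indices: np.ndarray         # (n,) strictly increasing before padding
    durations: np.ndarray       # (n-1,)
    fps: Optional[float] = None
    padded: int = 0             # number of repeat-padded tail entries


def cohort_feature_table(samples, smooth_window: int = 5) -> pd.DataFrame:
    """Per-heart cardiac-statistic features for a synthetic cohort.

    Runs beat analysis on each sample's diameter trace (ground-truth
    waveform when no masks were rendered) and tabulates the seven
    classifier features plus the age label.
    """
    rows = []
    for s in samples:
        tr = DiameterTrace.from_waveform(s.waveform, s.spec.fps, s.spec.pixel_size)
        bt = detect_beats(tr, smooth_window=smooth_window)
        if len(bt) < 2:
            continue
        st = aggregate_stats(bt)
        rows.append({f: getattr(st, f) for f in FEATURES} | {"label": s.label})
    return pd.DataFrame(rows, columns=list(FEATURES) + ["label"])


class LogisticAgeClassifier(BaseEstimator, ClassifierMixin):
    """L2-regularized logistic regression on standardized features."""

    def __init__(self, C: float = 1.0, seed: int = 0):
        self.C = C
        self.seed = seed

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise DataError("need two classes to fit an age classifier")
        self.scaler_ = StandardScaler().fit(X)
        self.lr_ = LogisticRegression(C=self.C, random_state=self.seed)
        self.lr_.fit(self.scaler_.transform(X), y)
        return self

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "lr_")
        return self.lr_.decision_function(self.scaler_.transform(np.asarray(X)))

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "lr_")
        return self.lr_.predict_proba(self.scaler_.transform(np.asarray(X)))

    def predict(self, X) -> np.ndarray:
        # tie at p = 0.5 resolves to the old (positive) class
        return self.classes_[(self.predict_proba(X)[:, 1] >= 0.5).astype(int)]


def _run_cv(fit_predict, y, k: int, seed: int) -> CVReport:
    """Shared stratified-k-fold evaluation loop."""
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise DataError("cross-validation needs two classes")
    if counts.min() < k:
        raise DataError(f"need >= {k} samples per class, got {counts.min()}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    accs, aucs, tests = [], [], []
    conf = np.zeros((2, 2), dtype=int)
    for tr_idx, te_idx in skf.split(np.zeros(len(y)), y):
        prob = fit_predict(tr_idx, te_idx)
        pred = (prob >= 0.5).astype(int)
        yt = (y[te_idx] == classes[1]).astype(int)
        accs.append(float(np.mean(pred == yt)))
        aucs.append(float(roc_auc_score(yt, prob)))
        conf += confusion_matrix(yt, pred, labels=[0, 1])
        tests.append(te_idx)
    return CVReport(accs, aucs, conf, tests, n=len(y))


def fit_logistic_cv(features, labels, k: int = 5, seed: int = 0,
                    C: float = 1.0):
    """Stratified k-fold CV of the logistic age model.

    ``features`` is a DataFrame with the FEATURES columns (or a plain
    (n, 7) array). Returns (model fit on all data, CVReport); features
    are standardized inside each training fold.
    """
    if isinstance(features, pd.DataFrame):
        X = features[list(FEATURES)].to_numpy(dtype=np.float64)
    else:
        X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels)

    def fold(tr_idx, te_idx):
        clf = LogisticAgeClassifier(C=C, seed=seed).fit(X[tr_idx], y[tr_idx])
        return clf.predict_proba(X[te_idx])[:, 1]

    report = _run_cv(fold, y, k, seed)
    model = LogisticAgeClassifier(C=C, seed=seed).fit(X, y)
    return model, report


def explain_shap(model: LogisticAgeClassifier, background, x) -> ShapExplanation:
    """Exact Shapley attributions for the linear logistic model.

    On the link scale with a mean-imputation value function the
    Shapley value of feature j is w_j (z_j - E_bg[z_j]) where z is the
    standardized feature vector; the base value is the link output at
    the background mean, and efficiency holds exactly.
    """
    check_is_fitted(model, "lr_")
    bg = np.asarray(background, dtype=np.float64)
    x = np.asarray(x, dtype=np.float64).reshape(-1)
    if bg.ndim != 2 or bg.shape[1] != x.size or x.size != len(FEATURES):
        raise DataError(
            f"expected background (n, {len(FEATURES)}) and x ({len(FEATURES)},)"
        )
    zx = model.scaler_.transform(x[None, :])[0]
    zbg = model.scaler_.transform(bg).mean(axis=0)
    w = model.lr_.coef_[0]
    contrib = w * (zx - zbg)
    base = float(model.lr_.intercept_[0] + w @ zbg)
    return ShapExplanation(
        values={f: float(c) for f, c in zip(FEATURES, contrib)},
        base_value=base,
        link_output=float(model.decision_function(x[None, :])[0]),
    )


def motion_keyframes(clip: np.ndarray, n: int = 96,
                     binarize_threshold: float = 0.5, t0: int = 0,
                     fps: Optional[float] = None) -> KeyframeSet:
    """Select motion keyframes by thresholded frame differencing.

    SSD(t) = sum over pixels of (frame_t - frame_t0)^2 is min-max
    normalized to [0, 1] and binarized at ``binarize_threshold``; the
    binary series decomposes into maximal runs of equal value, and the
    center frame (floor((start + end) / 2)) of each run is collected in
    temporal order until ``n`` frames are found. Durations are the
    differences of successive keyframe indices. If fewer than ``n``
    runs exist, the last keyframe is repeat-padded with duration 0 and
    a warning is issued.
    """
    clip = np.asarray(clip, dtype=np.float64)
    if clip.ndim != 3 or clip.shape[0] < 2:
        raise DataError("clip must be (T, H, W) with T >= 2")
    ssd = ((clip - clip[t0]) ** 2).sum(axis=(1, 2))
    span = ssd.max() - ssd.min()
    if span == 0:
        raise DataError(
            "constant video: frame-difference series is all zero, "
            "no motion keyframes can be selected"
        )
    norm = (ssd - ssd.min()) / span
    binary = (norm >= binarize_threshold).astype(int)
    change = np.flatnonzero(np.diff(binary)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change - 1, [len(binary) - 1]))
    centers = (starts + ends) // 2
    indices = centers[:n]
    padded = 0
    if len(indices) < n:
        padded = n - len(indices)
        warnings.warn(
            f"only {len(indices)} motion runs; repeat-padding {padded} keyframes"
        )
    frames = clip[indices]
    durations = np.diff(indices).astype(float)
    if padded:
        frames = np.concatenate([frames, np.repeat(frames[-1:], padded, axis=0)])
        durations = np.concatenate([durations, np.zeros(padded)])
        indices = np.concatenate([indices, np.repeat(indices[-1], padded)])
    return KeyframeSet(frames, indices, durations, fps=fps, padded=padded)


def cohort_keyframes(young_spec, old_spec, n_each: int, seed: int = 0,
                     n: int = 96, perturb_cv: float = 0.05):
    """Render a synthetic cohort heart-by-heart and extract keyframes.

    Clips are rendered one at a time and discarded after keyframe
    selection, so memory stays flat. Returns (keyframe_sets, labels).
    Short recordings that yield fewer than ``n`` motion runs are
    repeat-padded silently (the per-set ``padded`` count records it).
    """
    from .synth import make_cohort, render_frames

    cohort = make_cohort(young_spec, old_spec, n_each, seed=seed,
                         perturb_cv=perturb_cv, render=False)
    sets, labels = [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for s in cohort:
            clip, _ = render_frames(s.waveform, s.spec)
            sets.append(motion_keyframes(clip, n=n, fps=s.spec.fps))
            labels.append(s.label)
    return sets, np.array(labels)


def _resize_nearest(frames: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Nearest-neighbour spatial resize of an (..., H, W) stack."""
    h, w = frames.shape[-2], frames.shape[-1]
    rows = np.clip(np.round(np.linspace(0, h - 1, shape[0])).astype(int), 0, h - 1)
    cols = np.clip(np.round(np.linspace(0, w - 1, shape[1])).astype(int), 0, w - 1)
    return frames[..., rows[:, None], cols[None, :]]


class VideoAgeClassifier(BaseEstimator, ClassifierMixin):
    """Convolutional keyframe video classifier (sklearn-style).

    X is a list of KeyframeSet with identical frame geometry; y is a
    binary label vector (1 = old). Keyframes are optionally resized to
    ``frame_shape`` (None keeps the native size; dims must be divisible
    by 8 for the three pooling stages). Durations are standardized with
    statistics stored from the training set.
    """

    def __init__(self, conv_channels=(8, 16, 32), dense=(64, 32),
                 frame_shape=None, epochs=40, batch_size=16, lr=1e-3, seed=0):
        self.conv_channels = conv_channels
        self.dense = dense
        self.frame_shape = frame_shape
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.seed = seed

    def _prepare(self, keyframe_sets, fit: bool):
        shapes = {ks.frames.shape for ks in keyframe_sets}
        if len(shapes) != 1:
            raise DataError(f"keyframe sets differ in geometry: {shapes}")
        frames = np.stack([ks.frames for ks in keyframe_sets])  # (N, n, H, W)
        if self.frame_shape is not None:
            frames = _resize_nearest(frames, tuple(self.frame_shape))
        durations = np.stack([ks.durations for ks in keyframe_sets])
        if fit:
            self.dur_mean_ = durations.mean()
            self.dur_std_ = durations.std() or 1.0
            self.n_frames_ = frames.shape[1]
            self.native_shape_ = frames.shape[2:]
        durations = (durations - self.dur_mean_) / self.dur_std_
        return frames, durations

    def fit(self, X: Sequence[KeyframeSet], y):
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise DataError("need two classes to fit an age classifier")
        frames, durations = self._prepare(X, fit=True)
        yb = (y == self.classes_[1]).astype(np.float64)
        model = VideoCNN(
            n_frames=self.n_frames_, frame_shape=self.native_shape_,
            conv_channels=self.conv_channels, dense=self.dense, seed=self.seed,
        )
        opt = Adam(model.parameters(), lr=self.lr)
        rng = np.random.default_rng(self.seed)
        for _ in range(self.epochs):
            order = rng.permutation(len(frames))
            for s in range(0, len(order), self.batch_size):
                b = order[s: s + self.batch_size]
                logits = model(Tensor(frames[b]), Tensor(durations[b]))
                loss = bce_with_logits(logits, yb[b])
                opt.zero_grad()
                loss.backward()
                opt.step()
        self.model_ = model
        return self

    def predict_proba(self, X: Sequence[KeyframeSet]) -> np.ndarray:
        check_is_fitted(self, "model_")
        frames, durations = self._prepare(X, fit=False)
        logits = self.model_(Tensor(frames), Tensor(durations)).data
        p1 = 1.0 / (1.0 + np.exp(-np.clip(logits, -60, 60)))
        return np.column_stack([1 - p1, p1])

    def predict(self, X) -> np.ndarray:
        return self.classes_[(self.predict_proba(X)[:, 1] >= 0.5).astype(int)]


def train_video_classifier(keyframe_sets, labels, k: int = 5, seed: int = 0,
                           **params):
    """Stratified k-fold CV of the video classifier.

    Returns (model fit on all data, CVReport). ``params`` forward to
    VideoAgeClassifier.
    """
    y = np.asarray(labels)
    ks = list(keyframe_sets)

    def fold(tr_idx, te_idx):
        clf = VideoAgeClassifier(seed=seed, **params)
        clf.fit([ks[i] for i in tr_idx], y[tr_idx])
        return clf.predict_proba([ks[i] for i in te_idx])[:, 1]

    report = _run_cv(fold, y, k, seed)
    model = VideoAgeClassifier(seed=seed, **params).fit(ks, y)
    return model, report


def predict_age(model, X) -> pd.DataFrame:
    """Class probability, thresholded label, and log-likelihood.

    Works with either fitted classifier. Label is the old (positive)
    class when P(old) >= 0.5; log-likelihood is the log probability of
    the predicted class (always <= 0).
    """
    check_is_fitted(model)
    proba = model.predict_proba(X)
    p_old = proba[:, 1]
    label = np.where(p_old >= 0.5, "old", "young")
    p_pred = np.where(p_old >= 0.5, p_old, 1 - p_old)
    return pd.DataFrame({
        "p_old": p_old,
        "label": label,
        "log_likelihood": np.log(np.clip(p_pred, 1e-300, 1.0)),
    })
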