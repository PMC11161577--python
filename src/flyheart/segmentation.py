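"""Attention U-Net heart-wall segmentation.

Temporal context enters through 3-channel stacks of the frames at
t-4, t, t+4 (clamped at clip edges), encoding local wall motion.
Training frames are sampled per integer diameter bin (75 per bin) to
balance diastolic and systolic poses, the loss is Dice loss on the
sigmoid output, optimization is Adam with 16-image batches, and the
epoch with the lowest validation loss is kept. Inference thresholds
the per-pixel wall probability at an operator-chosen tau.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .errors import DataError, ParameterError
from .nn import Adam, AttentionUNet, Tensor, sigmoid

__all__ = [
    "UNetConfig",
    "WallSegmenter",
    "build_temporal_stack",
    "temporal_stacks",
    "sample_training_frames",
    "dice_loss",
    "dice_coefficient",
    "train_segmenter",
    "segment_frames",
    "save_checkpoint",
    "load_checkpoint",
]


def build_temporal_stack(clip: np.ndarray, t: int, offset: int = 4) -> np.ndarray:
    """3-channel stack of frames at (t-offset, t, t+offset), edge-clamped."""
    T = clip.shape[0]
    if not (0 <= t < T):
        raise IndexError(f"frame {t} out of range [0, {T})")
    idx = (max(t - offset, 0), t, min(t + offset, T - 1))
    return np.stack([clip[i] for i in idx], axis=0)


def temporal_stacks(clip: np.ndarray, indices, offset: int = 4) -> np.ndarray:
    """(N, 3, H, W) batch of temporal stacks for the given frame indices."""
    return np.stack([build_temporal_stack(clip, int(t), offset) for t in indices])


def sample_training_frames(mask_diameters, per_bin: int = 75,
                           seed: int = 0) -> np.ndarray:
    """Diameter-balanced frame sampling.

    Frames are binned by their mask diameter rounded to the nearest
    integer pixel; from each bin at most ``per_bin`` frames are drawn
    without replacement (all frames when the bin is smaller). Returns
    the sorted union of sampled frame indices.
    """
    d = np.asarray(mask_diameters, dtype=np.float64)
    if d.size == 0:
        return np.array([], dtype=int)
    bins = np.rint(d).astype(int)
    rng = np.random.default_rng(seed)
    chosen: list[np.ndarray] = []
    for b in np.unique(bins):
        members = np.flatnonzero(bins == b)
        if members.size > per_bin:
            members = rng.choice(members, size=per_bin, replace=False)
        chosen.append(members)
    return np.sort(np.concatenate(chosen))


def dice_loss(pred: np.ndarray, target: np.ndarray, eps: float = 1e-6) -> float:
    """1 - (2 sum(p t) + eps) / (sum p + sum t + eps)."""
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.shape != target.shape:
        raise ParameterError(
            f"shape mismatch: pred {pred.shape} vs target {target.shape}"
        )
    inter = float((pred * target).sum())
    return 1.0 - (2.0 * inter + eps) / (pred.sum() + target.sum() + eps)


def dice_coefficient(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice overlap 2|A n B| / (|A| + |B|) of two binary masks."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ParameterError(f"shape mismatch: {a.shape} vs {b.shape}")
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(a, b).sum() / denom


@dataclass
class UNetConfig:
    """Segmenter hyperparameters (defaults follow the training protocol).

    ``epochs`` defaults to 30 as in full-scale training; scaled-down
    runs (tests, desk hardware) use far fewer. The rectangular kernel
    default 3x7 is wider along the horizontal heart-tube axis.
    """

    filters: tuple = (8, 16, 32, 64, 128)
    kernel: tuple = (3, 7)
    attention_gates: bool = True
    batch_size: int = 16
    epochs: int = 30
    lr: float = 1e-3
    val_frac: float = 0.15
    augment: bool = True
    offset: int = 4
    seed: int = 0


class WallSegmenter(BaseEstimator):
    """sklearn-style estimator wrapping the attention U-Net.

    fit(X, y) takes X as (N, 3, H, W) temporal stacks and y as
    (N, H, W) binary wall masks; predict(X, threshold) returns binary
    masks. Fitted attributes: ``model_``, ``history_`` (per-epoch
    train/validation Dice loss), ``best_epoch_``.
    """

    def __init__(self, filters=(8, 16, 32, 64, 128), kernel=(3, 7),
                 attention_gates=True, batch_size=16, epochs=30, lr=1e-3,
                 val_frac=0.15, augment=True, offset=4, seed=0):
        self.filters = filters
        self.kernel = kernel
        self.attention_gates = attention_gates
        self.batch_size = batch_size
        self.epochs = epochs
        self.lr = lr
        self.val_frac = val_frac
        self.augment = augment
        self.offset = offset
        self.seed = seed

    @classmethod
    def from_config(cls, config: UNetConfig) -> "WallSegmenter":
        return cls(**asdict(config))

    # -- internals ------------------------------------------------------------
    def _pad_factor(self) -> int:
        return 2 ** (len(self.filters) - 1)

    def _pad(self, x: np.ndarray):
        f = self._pad_factor()
        h, w = x.shape[-2], x.shape[-1]
        ph, pw = (-h) % f, (-w) % f
        if ph or pw:
            pad = [(0, 0)] * (x.ndim - 2) + [(0, ph), (0, pw)]
            x = np.pad(x, pad, mode="edge")
        return x, (h, w)

    def _batch_loss(self, model, xb: np.ndarray, yb: np.ndarray,
                    train: bool = True):
        logits = model(Tensor(xb))
        pred = sigmoid(logits).reshape(-1)
        t = Tensor(yb.astype(np.float64).reshape(-1))
        eps = 1e-6
        inter = (pred * t).sum()
        loss = 1.0 - (2.0 * inter + eps) / (pred.sum() + t.sum() + eps)
        return loss

    def _augment_batch(self, xb, yb, rng):
        xb = xb.copy()
        yb = yb.copy()
        for i in range(len(xb)):
            if rng.random() < 0.5:
                xb[i] = xb[i, :, :, ::-1]
                yb[i] = yb[i, :, ::-1]
            if rng.random() < 0.5:
                xb[i] = xb[i, :, ::-1, :]
                yb[i] = yb[i, ::-1, :]
            scale = 1.0 + rng.uniform(-0.1, 0.1)
            xb[i] = np.clip(xb[i] * scale, 0.0, 1.0)
        return xb, yb

    # -- estimator API --------------------------------------------------------
    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=bool)
        if X.ndim != 4 or y.ndim != 3 or len(X) != len(y):
            raise DataError("X must be (N,3,H,W) stacks and y (N,H,W) masks")
        if len(X) < 2:
            raise DataError("need at least 2 samples (one train, one val)")
        X, _ = self._pad(X)
        y, _ = self._pad(y)
        rng = np.random.default_rng(self.seed)
        perm = rng.permutation(len(X))
        n_val = max(1, int(round(self.val_frac * len(X))))
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        if tr_idx.size == 0:
            raise DataError("validation split left no training samples")
        model = AttentionUNet(
            in_channels=X.shape[1], filters=self.filters, kernel=self.kernel,
            attention_gates=self.attention_gates, seed=self.seed,
        )
        opt = Adam(model.parameters(), lr=self.lr)
        history = []
        best = (np.inf, None, -1)
        for epoch in range(self.epochs):
            order = rng.permutation(tr_idx)
            train_losses = []
            for s in range(0, len(order), self.batch_size):
                batch = order[s: s + self.batch_size]
                xb, yb = X[batch], y[batch]
                if self.augment:
                    xb, yb = self._augment_batch(xb, yb, rng)
                loss = self._batch_loss(model, xb, yb)
                opt.zero_grad()
                loss.backward()
                opt.step()
                train_losses.append(float(loss.data))
            val_loss = float(
                self._batch_loss(model, X[val_idx], y[val_idx]).data
            )
            history.append({
                "epoch": epoch,
                "train_loss": float(np.mean(train_losses)),
                "val_loss": val_loss,
            })
            if val_loss < best[0]:
                best = (val_loss, model.state_dict(), epoch)
        model.load_state_dict(best[1])
        self.model_ = model
        self.history_ = pd.DataFrame(history)
        self.best_epoch_ = best[2]
        return self

    def predict_proba(self, X, batch_size: int = 16) -> np.ndarray:
        """Per-pixel wall probabilities, shape (N, H, W)."""
        check_is_fitted(self, "model_")
        X = np.asarray(X, dtype=np.float64)
        Xp, (h, w) = self._pad(X)
        out = np.empty((len(Xp), Xp.shape[2], Xp.shape[3]))
        for s in range(0, len(Xp), batch_size):
            out[s: s + batch_size] = self.model_.predict_proba(Xp[s: s + batch_size])
        return out[:, :h, :w]

    def predict(self, X, threshold: float = 0.5) -> np.ndarray:
        """Binary wall masks {p >= threshold}."""
        if not (0.0 <= threshold <= 1.0):
            raise ParameterError(f"threshold must be in [0, 1], got {threshold}")
        return self.predict_proba(X) >= threshold


def train_segmenter(stacks, masks, config: UNetConfig | None = None):
    """Train a WallSegmenter; returns (estimator, per-epoch loss table)."""
    config = config or UNetConfig()
    est = WallSegmenter.from_config(config).fit(stacks, masks)
    return est, est.history_


def segment_frames(model: WallSegmenter, clip: np.ndarray, threshold: float,
                   offset: int = 4, batch_size: int = 16) -> np.ndarray:
    """Segment every frame of a clip into binary wall masks.

    Each frame t becomes a (t-offset, t, t+offset) temporal stack; the
    resulting probability maps are thresholded at ``threshold``.
    """
    if not (0.0 <= threshold <= 1.0):
        raise ParameterError(f"threshold must be in [0, 1], got {threshold}")
    T = clip.shape[0]
    masks = np.empty(clip.shape, dtype=bool)
    for s in range(0, T, batch_size):
        idx = range(s, min(s + batch_size, T))
        stacks = temporal_stacks(clip, idx, offset)
        masks[s: s + batch_size] = model.predict(stacks, threshold)
    return masks


def save_checkpoint(est: WallSegmenter, path) -> None:
    """Persist weights + hyperparameters (config and seed embedded)."""
    check_is_fitted(est, "model_")
    state = {f"w{i}": w for i, w in enumerate(est.model_.state_dict())}
    np.savez_compressed(
        path,
        _config=json.dumps(est.get_params()),
        _best_epoch=est.best_epoch_,
        **state,
    )


def load_checkpoint(path) -> WallSegmenter:
    data = np.load(path, allow_pickle=False)
    params = json.loads(str(data["_config"]))
    for key in ("filters", "kernel"):
        params[key] = tuple(params[key])
    est = WallSegmenter(**params)
    model = AttentionUNet(
        in_channels=3, filters=est.filters, kernel=est.kernel,
        attention_gates=est.attention_gates, seed=est.seed,
    )
    n = len(model.parameters())
    model.load_state_dict([data[f"w{i}"] for i in range(n)])
    est.model_ = model
    est.history_ = pd.DataFrame()
    est.best_epoch_ = int(data["_best_epoch"])
    return est
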