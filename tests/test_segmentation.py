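"""Temporal stacking, balanced sampling, Dice loss, and segmenter
training/inference contracts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flyheart.errors import ParameterError
from flyheart.segmentation import (WallSegmenter, build_temporal_stack,
                                   dice_coefficient, dice_loss, load_checkpoint,
                                   sample_training_frames, save_checkpoint,
                                   segment_frames, temporal_stacks)


@pytest.mark.parametrize("t,expected", [
    (10, (6, 10, 14)),
    (0, (0, 0, 4)),
    (99, (95, 99, 99)),
])
def test_temporal_stack_indices(t, expected):
    clip = np.arange(100, dtype=float)[:, None, None] * np.ones((1, 4, 5))
    stack = build_temporal_stack(clip, t)
    assert stack.shape == (3, 4, 5)
    assert tuple(int(stack[i, 0, 0]) for i in range(3)) == expected


def test_temporal_stack_out_of_range():
    clip = np.zeros((10, 4, 4))
    with pytest.raises(IndexError):
        build_temporal_stack(clip, 10)


def test_sampling_per_bin_rule():
    # one bin of 200 frames -> 75; bin of 40 -> all 40; (200, 80, 75) -> 225
    d = np.zeros(200)
    assert len(sample_training_frames(d)) == 75
    assert len(sample_training_frames(np.zeros(40))) == 40
    d = np.concatenate([np.full(200, 10), np.full(80, 11), np.full(75, 12)])
    idx = sample_training_frames(d, seed=1)
    assert len(idx) == 225
    assert len(np.unique(idx)) == 225


@settings(max_examples=25, derandomize=True, deadline=None)
@given(
    sizes=st.lists(st.integers(1, 150), min_size=1, max_size=5),
    per_bin=st.integers(1, 80),
    seed=st.integers(0, 10),
)
def test_sampling_counts_bounded_and_unique(sizes, per_bin, seed):
    d = np.concatenate([np.full(n, k) for k, n in enumerate(sizes)])
    idx = sample_training_frames(d, per_bin=per_bin, seed=seed)
    assert len(np.unique(idx)) == len(idx)
    bins = np.rint(d[idx]).astype(int)
    for k, n in enumerate(sizes):
        assert (bins == k).sum() == min(per_bin, n)


def test_sampling_empty_input():
    assert len(sample_training_frames(np.array([]))) == 0


def test_dice_loss_examples():
    a = np.zeros((4, 4))
    a[0, :2] = 1
    assert dice_loss(a, a) < 1e-5
    b = np.zeros((4, 4))
    b[3, :2] = 1
    assert dice_loss(a, b) > 1 - 1e-5
    # pred covers 2 px, target 2 px, intersection 1 px -> 0.5
    c = np.zeros((4, 4))
    c[0, 1:3] = 1
    assert dice_loss(a, c) == pytest.approx(0.5, abs=1e-5)


@settings(max_examples=25, derandomize=True, deadline=None)
@given(st.integers(0, 2**16))
def test_dice_loss_symmetric_and_bounded_on_binary(seed):
    rng = np.random.default_rng(seed)
    a = rng.random((6, 6)) < 0.4
    b = rng.random((6, 6)) < 0.4
    l1, l2 = dice_loss(a, b), dice_loss(b, a)
    assert l1 == pytest.approx(l2)
    assert 0.0 <= l1 <= 1.0


def test_dice_loss_shape_mismatch():
    with pytest.raises(ParameterError, match="mismatch"):
        dice_loss(np.zeros((2, 2)), np.zeros((3, 2)))


def test_training_reduces_validation_loss(tiny_segmenter):
    h = tiny_segmenter.history_
    assert h.val_loss.iloc[-1] < h.val_loss.iloc[0]
    assert tiny_segmenter.best_epoch_ == int(h.val_loss.idxmin())


def test_training_is_seed_deterministic(tiny_training_data):
    _, _, stacks, masks = tiny_training_data
    est1 = WallSegmenter(filters=(4, 8), epochs=2, seed=3).fit(stacks[:40], masks[:40])
    est2 = WallSegmenter(filters=(4, 8), epochs=2, seed=3).fit(stacks[:40], masks[:40])
    assert est1.best_epoch_ == est2.best_epoch_
    np.testing.assert_array_equal(
        est1.predict_proba(stacks[:4]), est2.predict_proba(stacks[:4])
    )


def test_threshold_monotone_nesting_and_extremes(tiny_segmenter, tiny_training_data):
    _, clip, stacks, _ = tiny_training_data
    proba = tiny_segmenter.predict_proba(stacks[:6])
    assert proba.min() >= 0 and proba.max() <= 1
    m_lo = tiny_segmenter.predict(stacks[:6], threshold=0.3)
    m_hi = tiny_segmenter.predict(stacks[:6], threshold=0.7)
    assert np.all(m_hi <= m_lo)  # nesting
    assert tiny_segmenter.predict(stacks[:2], threshold=0.0).all()
    assert not tiny_segmenter.predict(stacks[:2], threshold=1.0).any()
    with pytest.raises(ParameterError, match="threshold"):
        tiny_segmenter.predict(stacks[:1], threshold=1.5)
    with pytest.raises(ParameterError, match="threshold"):
        segment_frames(tiny_segmenter, clip[:2], threshold=-0.1)


def test_checkpoint_round_trip(tmp_path, tiny_segmenter, tiny_training_data):
    _, _, stacks, _ = tiny_training_data
    path = tmp_path / "seg.npz"
    save_checkpoint(tiny_segmenter, path)
    restored = load_checkpoint(path)
    np.testing.assert_array_equal(
        tiny_segmenter.predict_proba(stacks[:3]), restored.predict_proba(stacks[:3])
    )


def test_segment_frames_shapes(tiny_segmenter, tiny_training_data):
    _, clip, _, _ = tiny_training_data
    masks = segment_frames(tiny_segmenter, clip[:10], threshold=0.5)
    assert masks.shape == clip[:10].shape
    assert masks.dtype == bool


def test_fit_rejects_bad_data():
    with pytest.raises(Exception, match="stacks|samples"):
        WallSegmenter(epochs=1).fit(np.zeros((1, 3, 8, 8)), np.zeros((1, 8, 8)))
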