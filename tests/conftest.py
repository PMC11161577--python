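import numpy as np
import pytest

from flyheart.beats import aggregate_stats, detect_beats
from flyheart.synth import (SyntheticHeartSpec, generate_waveform, make_cohort,
                            old_spec, render_frames, young_spec)
from flyheart.trace import ROI, extract_trace


@pytest.fixture(scope="session")
def recovery_hearts():
    """Ten jittered hearts analyzed from ground-truth masks.

    Conditions: hp_mean 0.5 s, hp_cv 0.05, DD 60 µm, SD 40 µm, 200 fps,
    10 s. Yields (spec, true_beats, stats) per heart.
    """
    out = []
    for seed in range(10):
        spec = SyntheticHeartSpec(dd_true=60, sd_true=40, hp_mean=0.5,
                                  hp_cv=0.05, fps=200, duration=10.0, seed=seed)
        waveform, true_beats = generate_waveform(spec)
        _, masks = render_frames(waveform, spec)
        trace = extract_trace(masks, ROI.full(spec.width), spec.pixel_size,
                              spec.fps)
        stats = aggregate_stats(detect_beats(trace), trace=trace)
        out.append((spec, true_beats, stats))
    return out


@pytest.fixture(scope="session")
def cohort_features():
    """Cardiac-statistic features of a 100-per-class synthetic cohort."""
    from flyheart.age import cohort_feature_table

    cohort = make_cohort(young_spec(), old_spec(), n_each=100, seed=42,
                         render=False)
    return cohort_feature_table(cohort)


@pytest.fixture(scope="session")
def tiny_training_data():
    """A small stack/mask training set from one low-resolution heart."""
    from flyheart.segmentation import sample_training_frames, temporal_stacks

    spec = SyntheticHeartSpec(dd_true=24, sd_true=12, hp_mean=0.5, hp_cv=0.05,
                              wall_thickness=3, noise_sigma=0.05, fps=100,
                              duration=2.0, height=48, width=64, seed=5)
    waveform, _ = generate_waveform(spec)
    clip, masks = render_frames(waveform, spec)
    idx = sample_training_frames(np.rint(waveform / spec.pixel_size), seed=0)
    return spec, clip, temporal_stacks(clip, idx), masks[idx]


@pytest.fixture(scope="session")
def tiny_segmenter(tiny_training_data):
    """A quickly trained small segmenter for inference-contract tests."""
    from flyheart.segmentation import WallSegmenter

    _, _, stacks, masks = tiny_training_data
    return WallSegmenter(filters=(4, 8, 16), epochs=2, seed=0).fit(stacks, masks)
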