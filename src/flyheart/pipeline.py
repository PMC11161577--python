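"""End-to-end analysis: segmentation -> trace -> beats -> statistics.

``run_pipeline`` ties the stages together and writes a self-describing
output directory: trace.csv, beats.csv, stats.csv, events.csv,
mmode.png, and the configuration snapshot config.yaml plus run.log.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .beats import (ArrhythmiaEvents, BeatTable, CardiacStats, aggregate_stats,
                    detect_beats, flag_arrhythmia_events)
from .io import RunConfig, VideoClip, write_png
from .segmentation import WallSegmenter, segment_frames
from .trace import ROI, DiameterTrace, MModeImage, extract_trace, make_mmode

__all__ = ["PipelineResult", "run_pipeline"]

log = logging.getLogger("flyheart")


@dataclass
class PipelineResult:
    trace: DiameterTrace
    beat_table: BeatTable
    stats: CardiacStats
    events: ArrhythmiaEvents
    mmode: MModeImage
    masks: np.ndarray


def run_pipeline(clip: VideoClip, config: RunConfig,
                 model: Optional[WallSegmenter] = None,
                 masks: Optional[np.ndarray] = None,
                 out_dir=None) -> PipelineResult:
    """Analyze one cardiac recording.

    Either a trained ``model`` (frames are segmented at
    ``config.threshold``) or precomputed ``masks`` (segmentation
    bypassed, e.g. ground truth) must be provided. When ``out_dir`` is
    given, all artifacts plus the config snapshot and a log are written
    there.
    """
    config.validate()
    if masks is None:
        if model is None:
            raise ValueError("provide a trained model or precomputed masks")
        log.info("segmenting %d frames at threshold %.2f",
                 clip.n_frames, config.threshold)
        masks = segment_frames(model, clip.frames, config.threshold)
    T, H, W = clip.frames.shape
    roi = ROI(*config.roi) if config.roi is not None else ROI.full(W)
    log.info("extracting diameter trace over ROI [%d, %d)", roi.c0, roi.c1)
    trace = extract_trace(masks, roi, config.pixel_size, config.fps)
    beat_table = detect_beats(
        trace, smooth_window=config.smooth_window, v_thr_frac=config.v_thr_frac
    )
    log.info("detected %d beats (%d complete)", len(beat_table),
             len(beat_table.complete()))
    stats = aggregate_stats(
        beat_table, roi_length_um=roi.length_um(config.pixel_size),
        trace=trace, smooth_window=config.smooth_window,
    )
    events = flag_arrhythmia_events(
        beat_table, config.tachy_threshold_s, config.brady_threshold_s
    )
    column = (roi.c0 + roi.c1) // 2  # M-mode default: ROI center column
    mmode = make_mmode(clip.frames, masks, column, beat_table)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        handler = logging.FileHandler(out / "run.log")
        log.addHandler(handler)
        try:
            trace.to_frame().to_csv(out / "trace.csv", index=False)
            beat_table.to_frame().to_csv(out / "beats.csv", index=False)
            stats.to_frame().to_csv(out / "stats.csv", index=False)
            events.to_frame().to_csv(out / "events.csv", index=False)
            write_png(out / "mmode.png", mmode.image)
            config.to_yaml(out / "config.yaml")
            log.info("artifacts written to %s", out)
        finally:
            log.removeHandler(handler)
            handler.close()
    return PipelineResult(trace, beat_table, stats, events, mmode, masks)
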