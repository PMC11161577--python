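"""Beat detection and per-beat/per-heart cardiac statistics.

Beat detection is a velocity-threshold state machine on the (optionally
smoothed) diameter trace: a contraction onset fires when the wall
velocity drops below -v_thr; after the subsequent positive (relaxation)
excursion, the relaxation end fires when velocity re-enters the
[-v_thr, +v_thr] band. The diastolic interval runs from relaxation end
to the next onset, and the heart period is onset-to-next-onset, so
HP = SI + DI for every complete beat. Partial beats at the trace edges
are discarded.

Per-beat statistics follow the standard fly-heart conventions:
DD is the largest diameter over the beat's DI, SD the smallest over its
SI, FS = 100 (DD - SD) / DD, EF = 100 (DD^2 - SD^2) / DD^2
(cross-sectional-area model), AI = sample std(HP) / median(HP),
SV = pi L ((DD/2)^2 - (SD/2)^2) for a cylinder of length L (the ROI
length), CO = sum(SV) / sum(HP). Tachycardic events are SIs longer than
0.5 s and bradycardic events DIs longer than 1.0 s (strict inequality).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, ParameterError
from .trace import DiameterTrace

__all__ = [
    "Beat",
    "BeatTable",
    "CardiacStats",
    "ArrhythmiaEvents",
    "compute_velocity",
    "detect_beats",
    "beat_morphology",
    "fractional_shortening",
    "ejection_fraction",
    "arrhythmia_index",
    "stroke_volume",
    "cardiac_output",
    "contractile_latency",
    "flag_arrhythmia_events",
    "aggregate_stats",
]

TACHY_SI_THRESHOLD_S = 0.5
BRADY_DI_THRESHOLD_S = 1.0


@dataclass
class Beat:
    """One cardiac cycle: SI (onset -> relaxation end) + DI.

    A beat whose DI is cut off by the end of the trace (complete SI but
    no following onset) is kept in the table with ``truncated=True``;
    such edge beats are excluded from all aggregate statistics.
    """

    onset_t: float
    rel_end_t: float
    si: float
    di: float
    dd: float
    sd: float
    hp: float
    fs: float
    ef: float
    sv: Optional[float] = None
    onset_f: int = 0
    rel_end_f: int = 0
    truncated: bool = False


@dataclass
class BeatTable:
    """Time-ordered complete beats of one heart."""

    beats: list[Beat]
    fps: float
    source: str = ""

    def __len__(self) -> int:
        return len(self.beats)

    def __iter__(self):
        return iter(self.beats)

    @property
    def hp_list(self) -> np.ndarray:
        return np.array([b.hp for b in self.beats])

    def complete(self) -> "BeatTable":
        """Beats with both interval boundaries inside the trace."""
        return BeatTable([b for b in self.beats if not b.truncated],
                         self.fps, self.source)

    def to_frame(self) -> pd.DataFrame:
        cols = ["onset_t", "rel_end_t", "si", "di", "dd", "sd", "hp",
                "fs", "ef", "sv", "truncated"]
        return pd.DataFrame([{c: getattr(b, c) for c in cols} for b in self.beats])


@dataclass
class CardiacStats:
    """Per-heart aggregates (means over complete beats)."""

    dd: float
    sd: float
    fs: float
    ef: float
    hp: float
    hr: float
    di: float
    si: float
    n_beats: int
    ai: Optional[float] = None
    sv: Optional[float] = None
    co: Optional[float] = None
    t_peak_contraction: Optional[float] = None
    t_contraction_to_relaxation: Optional[float] = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(self)])


@dataclass
class ArrhythmiaEvents:
    """Tachycardic (long-SI) and bradycardic (long-DI) events."""

    tachy_beats: list[int]
    brady_beats: list[int]
    tachy_si: np.ndarray
    brady_di: np.ndarray
    tachy_threshold_s: float = TACHY_SI_THRESHOLD_S
    brady_threshold_s: float = BRADY_DI_THRESHOLD_S

    @property
    def n_tachy(self) -> int:
        return len(self.tachy_beats)

    @property
    def n_brady(self) -> int:
        return len(self.brady_beats)

    @property
    def mean_tachy_si(self) -> float:
        return float(np.mean(self.tachy_si)) if self.n_tachy else float("nan")

    @property
    def mean_brady_di(self) -> float:
        return float(np.mean(self.brady_di)) if self.n_brady else float("nan")

    def to_frame(self) -> pd.DataFrame:
        rows = [{"beat": b, "kind": "tachy", "length_s": s}
                for b, s in zip(self.tachy_beats, self.tachy_si)]
        rows += [{"beat": b, "kind": "brady", "length_s": s}
                 for b, s in zip(self.brady_beats, self.brady_di)]
        return pd.DataFrame(rows, columns=["beat", "kind", "length_s"])


def _smooth(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with edge replication."""
    if window <= 1:
        return values
    pad = window // 2
    padded = np.pad(values, pad, mode="edge")
    kernel = np.ones(window) / window
    sm = np.convolve(padded, kernel, mode="valid")
    return sm[: len(values)]


def compute_velocity(trace: DiameterTrace, smooth_window: int = 5) -> np.ndarray:
    """Wall velocity in µm/s by numeric differentiation of the trace.

    Central differences at interior frames, one-sided at the endpoints,
    after an optional centered moving average of ``smooth_window``
    frames.
    """
    if int(trace.valid.sum()) < 3:
        raise ParameterError("velocity needs at least 3 valid frames")
    if smooth_window >= len(trace):
        raise ParameterError(
            f"smooth_window {smooth_window} >= trace length {len(trace)}"
        )
    sm = _smooth(trace.values, smooth_window)
    return np.gradient(sm) * trace.fps


def detect_beats(trace: DiameterTrace, smooth_window: int = 5,
                 v_thr_frac: float = 0.2, min_amplitude_um: float = 2.0,
                 source: str = "") -> BeatTable:
    """Detect complete beats with the velocity-threshold state machine.

    v_thr is ``v_thr_frac`` of the 95th percentile of |velocity| over
    the valid region. Traces whose peak-to-peak excursion is below
    ``min_amplitude_um`` (no oscillation above the noise floor) return
    an empty table. A contraction already in progress at the first
    analyzed frame is counted from that frame; the final onset (with no
    following onset) is dropped as a partial beat.
    """
    vidx = np.flatnonzero(trace.valid)
    if vidx.size < 4:
        return BeatTable([], trace.fps, source)
    lo, hi = vidx[0], vidx[-1] + 1
    seg = trace.values[lo:hi]
    if np.ptp(seg) < min_amplitude_um:
        return BeatTable([], trace.fps, source)
    sub = DiameterTrace(seg, np.ones(len(seg), bool), trace.fps, trace.pixel_size)
    v = compute_velocity(sub, smooth_window)
    v_thr = v_thr_frac * np.percentile(np.abs(v), 95)
    if v_thr <= 0:
        return BeatTable([], trace.fps, source)

    onsets: list[int] = []
    rel_ends: list[int] = []
    state = "diastole"  # trace start is treated as armed
    for i, vi in enumerate(v):
        if state == "diastole":
            if vi < -v_thr:
                onsets.append(i)
                state = "contracting"
        elif state == "contracting":
            if vi > v_thr:
                state = "relaxing"
        elif state == "relaxing":
            if vi <= v_thr:
                rel_ends.append(i)
                state = "diastole"
    if state != "diastole" and onsets and len(rel_ends) < len(onsets):
        onsets.pop()  # trailing incomplete SI

    beats: list[Beat] = []
    # pair each onset with the next onset; the last SI-complete beat has
    # no following onset and keeps a DI truncated at the trace end
    ends = onsets[1:]
    if len(onsets) == len(rel_ends) and onsets and rel_ends[-1] < len(seg) - 1:
        ends = ends + [len(seg) - 1]
    for k, nxt in enumerate(ends):
        o, r = onsets[k], rel_ends[k]
        truncated = k >= len(onsets) - 1
        si = (r - o) / trace.fps
        di = (nxt - r) / trace.fps
        dd = float(seg[r: nxt + 1].max())
        sd = float(seg[o: r + 1].min())
        beats.append(Beat(
            onset_t=(lo + o) / trace.fps,
            rel_end_t=(lo + r) / trace.fps,
            si=si, di=di, dd=dd, sd=sd, hp=si + di,
            fs=fractional_shortening(dd, sd),
            ef=ejection_fraction(dd, sd),
            onset_f=lo + o, rel_end_f=lo + r,
            truncated=truncated,
        ))
    return BeatTable(beats, trace.fps, source)


def beat_morphology(beat: Beat, trace: DiameterTrace) -> tuple[float, float]:
    """(DD, SD): max diameter over the beat's DI, min over its SI."""
    fps = trace.fps
    o = beat.onset_f
    r = beat.rel_end_f
    nxt = int(round((beat.onset_t + beat.hp) * fps))
    if r <= o or nxt <= r or nxt >= len(trace):
        raise ParameterError("beat intervals must lie inside the trace")
    dd = float(trace.values[r: nxt + 1].max())
    sd = float(trace.values[o: r + 1].min())
    return dd, sd


def fractional_shortening(dd: float, sd: float) -> float:
    """FS (%) = 100 (DD - SD) / DD."""
    if dd <= 0:
        raise ParameterError(f"require dd > 0, got {dd}")
    return 100.0 * (dd - sd) / dd


def ejection_fraction(dd: float, sd: float) -> float:
    """EF (%) = 100 (DD^2 - SD^2) / DD^2 (cross-sectional area model)."""
    if dd <= 0:
        raise ParameterError(f"require dd > 0, got {dd}")
    return 100.0 * (dd**2 - sd**2) / dd**2


def arrhythmia_index(hp_list) -> float:
    """AI = sample standard deviation of HP / median HP."""
    hp = np.asarray(hp_list, dtype=np.float64)
    if hp.size < 2:
        raise InsufficientDataError("arrhythmia index needs >= 2 beats")
    return float(np.std(hp, ddof=1) / np.median(hp))


def stroke_volume(dd: float, sd: float, roi_length_um: float) -> float:
    """SV (pL) for a cylindrical tube segment of length L µm.

    SV = pi L ((DD/2)^2 - (SD/2)^2) µm^3, converted at 1 pL = 1000 µm^3.
    """
    if dd < 0 or sd < 0 or roi_length_um <= 0:
        raise ParameterError("require dd, sd >= 0 and roi_length_um > 0")
    return np.pi * roi_length_um * ((dd / 2) ** 2 - (sd / 2) ** 2) / 1000.0


def cardiac_output(beat_table: BeatTable, roi_length_um: float) -> float:
    """CO (pL/s) = sum of per-beat stroke volumes / sum of heart periods.

    Edge-truncated beats are excluded.
    """
    bt = beat_table.complete()
    if len(bt) == 0:
        raise InsufficientDataError("cardiac output needs >= 1 complete beat")
    sv = sum(stroke_volume(b.dd, b.sd, roi_length_um) for b in bt)
    return float(sv / bt.hp_list.sum())


def contractile_latency(trace: DiameterTrace, beat_table: BeatTable,
                        smooth_window: int = 5):
    """Per-beat contraction/relaxation velocity latencies, in seconds.

    For each beat: the time from contraction onset to the most-negative
    velocity sample within the beat, and the time from that sample to
    the most-positive velocity sample later in the same beat. Beats
    shorter than 3 frames are skipped with a warning.

    Returns (t_peak_contraction, t_contraction_to_relaxation) arrays.
    """
    v = compute_velocity(trace, smooth_window)
    fps = trace.fps
    t_peak, t_c2r = [], []
    for k, b in enumerate(beat_table.complete()):
        o = b.onset_f
        end = int(round(o + b.hp * fps))
        if end - o < 3:
            warnings.warn(f"beat {k} shorter than 3 frames; skipped")
            continue
        end = min(end, len(v))
        i_min = o + int(np.argmin(v[o:end]))
        i_max = i_min + int(np.argmax(v[i_min:end]))
        t_peak.append((i_min - o) / fps)
        t_c2r.append((i_max - i_min) / fps)
    return np.array(t_peak), np.array(t_c2r)


def flag_arrhythmia_events(beat_table: BeatTable,
                           tachy_threshold_s: float = TACHY_SI_THRESHOLD_S,
                           brady_threshold_s: float = BRADY_DI_THRESHOLD_S
                           ) -> ArrhythmiaEvents:
    """Tachy = beats with SI strictly over 0.5 s; brady = DI over 1.0 s.

    Edge-truncated beats are excluded.
    """
    bt = beat_table.complete()
    tachy = [(k, b.si) for k, b in enumerate(bt) if b.si > tachy_threshold_s]
    brady = [(k, b.di) for k, b in enumerate(bt) if b.di > brady_threshold_s]
    return ArrhythmiaEvents(
        tachy_beats=[k for k, _ in tachy],
        brady_beats=[k for k, _ in brady],
        tachy_si=np.array([s for _, s in tachy]),
        brady_di=np.array([s for _, s in brady]),
        tachy_threshold_s=tachy_threshold_s,
        brady_threshold_s=brady_threshold_s,
    )


def aggregate_stats(beat_table: BeatTable, roi_length_um: Optional[float] = None,
                    trace: Optional[DiameterTrace] = None,
                    smooth_window: int = 5) -> CardiacStats:
    """Per-heart means of per-beat quantities; HR = 1 / mean(HP).

    AI requires at least two beats and is None otherwise. SV and CO
    require an ROI length; latencies require the source trace.
    Edge-truncated beats are excluded from every aggregate.
    """
    beat_table = beat_table.complete()
    if len(beat_table) == 0:
        raise InsufficientDataError("aggregate_stats needs >= 1 complete beat")
    df = beat_table.to_frame()
    hp_mean = float(df["hp"].mean())
    stats = CardiacStats(
        dd=float(df["dd"].mean()),
        sd=float(df["sd"].mean()),
        fs=float(df["fs"].mean()),
        ef=float(df["ef"].mean()),
        hp=hp_mean,
        hr=1.0 / hp_mean,
        di=float(df["di"].mean()),
        si=float(df["si"].mean()),
        n_beats=len(beat_table),
    )
    if len(beat_table) >= 2:
        stats.ai = arrhythmia_index(beat_table.hp_list)
    if roi_length_um is not None:
        for b in beat_table:
            b.sv = stroke_volume(b.dd, b.sd, roi_length_um)
        stats.sv = float(np.mean([b.sv for b in beat_table]))
        stats.co = cardiac_output(beat_table, roi_length_um)
    if trace is not None:
        t_peak, t_c2r = contractile_latency(trace, beat_table, smooth_window)
        if t_peak.size:
            stats.t_peak_contraction = float(t_peak.mean())
            stats.t_contraction_to_relaxation = float(t_c2r.mean())
    return stats
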