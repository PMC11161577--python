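"""Velocity, beat detection against simulator/constructed oracles, and
the cardiac statistic formulas."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flyheart.beats import (BeatTable, Beat, aggregate_stats, arrhythmia_index,
                            beat_morphology, cardiac_output, compute_velocity,
                            contractile_latency, detect_beats,
                            ejection_fraction, flag_arrhythmia_events,
                            fractional_shortening, stroke_volume)
from flyheart.errors import InsufficientDataError, ParameterError
from flyheart.synth import SyntheticHeartSpec, generate_waveform
from flyheart.trace import DiameterTrace


def _trace(values, fps=100.0):
    return DiameterTrace.from_waveform(np.asarray(values, float), fps)


# -- velocity -----------------------------------------------------------------

def test_velocity_constant_and_linear():
    assert np.allclose(compute_velocity(_trace(np.full(50, 42.0))), 0.0)
    ramp = 10.0 + 0.25 * np.arange(50)  # 0.25 µm/frame at 100 fps
    v = compute_velocity(_trace(ramp), smooth_window=1)
    np.testing.assert_allclose(v, 25.0)


def test_velocity_sinusoid_extremum_matches_analytic():
    T0 = 1.0
    fps = 500.0
    t = np.arange(int(4 * T0 * fps)) / fps
    d = 50 + 10 * np.cos(2 * np.pi * t / T0)
    v = compute_velocity(_trace(d, fps), smooth_window=1)
    assert v.min() == pytest.approx(-20 * np.pi / T0, rel=1e-3)


def test_velocity_window_too_large():
    with pytest.raises(ParameterError, match="smooth_window"):
        compute_velocity(_trace(np.zeros(10) + 1), smooth_window=10)


# -- beat detection -----------------------------------------------------------

def test_detect_beats_on_regular_simulator_heart():
    spec = SyntheticHeartSpec(hp_mean=0.5, hp_cv=0.0, duration=5.0, seed=0)
    waveform, _ = generate_waveform(spec)
    bt = detect_beats(DiameterTrace.from_waveform(waveform, spec.fps))
    complete = bt.complete()
    assert 9 <= len(complete) <= 10
    assert np.abs(complete.hp_list - 0.5).max() <= 1.0 / spec.fps


def test_detect_beats_constant_trace_empty():
    bt = detect_beats(_trace(np.full(200, 55.0)))
    assert len(bt) == 0


def test_detect_single_dip_yields_one_truncated_beat():
    spec = SyntheticHeartSpec(hp_mean=0.5, hp_cv=0.0, duration=0.7, seed=0)
    waveform, true_beats = generate_waveform(spec)
    assert len(true_beats) == 1
    bt = detect_beats(DiameterTrace.from_waveform(waveform, spec.fps))
    assert len(bt) == 1
    assert bt.beats[0].truncated
    assert bt.beats[0].si == pytest.approx(true_beats["si"][0], abs=1.5 / spec.fps)


def test_beats_are_ordered_and_hp_is_si_plus_di():
    spec = SyntheticHeartSpec(hp_cv=0.1, duration=8.0, seed=12)
    waveform, _ = generate_waveform(spec)
    bt = detect_beats(DiameterTrace.from_waveform(waveform, spec.fps))
    df = bt.to_frame()
    np.testing.assert_allclose(df["hp"], df["si"] + df["di"])
    assert (np.diff(df["onset_t"]) > 0).all()
    assert df["hp"].sum() <= spec.duration


def test_beat_morphology_max_min_rules():
    # DI samples {58, 60, 59} -> dd 60; SI samples {45, 40, 42} -> sd 40
    values = np.array([50.0, 45, 40, 42, 50, 58, 60, 59, 50, 45, 40, 45, 58,
                       60, 60, 60])
    beat = Beat(onset_t=0.1, rel_end_t=0.4, si=0.3, di=0.5, dd=0, sd=0,
                hp=0.8, fs=0, ef=0, onset_f=1, rel_end_f=4)
    dd, sd = beat_morphology(beat, _trace(values, fps=10.0))
    assert dd == 60.0 and sd == 40.0
    bad = Beat(onset_t=0.0, rel_end_t=0.0, si=0, di=0, dd=0, sd=0, hp=0,
               fs=0, ef=0, onset_f=4, rel_end_f=4)
    with pytest.raises(ParameterError):
        beat_morphology(bad, _trace(values, fps=10.0))


def test_simulator_morphology_recovery():
    spec = SyntheticHeartSpec(hp_cv=0.0, duration=3.0, seed=6)
    waveform, _ = generate_waveform(spec)
    bt = detect_beats(DiameterTrace.from_waveform(waveform, spec.fps))
    for b in bt.complete():
        assert b.dd == pytest.approx(spec.dd_true, abs=spec.pixel_size)
        assert b.sd == pytest.approx(spec.sd_true, abs=spec.pixel_size)


# -- statistic formulas -------------------------------------------------------

def test_fs_ef_examples_and_errors():
    assert fractional_shortening(100, 50) == 50.0
    assert fractional_shortening(80, 60) == 25.0
    assert fractional_shortening(70, 70) == 0.0
    assert ejection_fraction(100, 50) == 75.0
    assert ejection_fraction(55, 55) == 0.0
    for fn in (fractional_shortening, ejection_fraction):
        with pytest.raises(ParameterError):
            fn(0, 0)


@settings(max_examples=30, derandomize=True, deadline=None)
@given(dd=st.floats(10, 100), frac=st.floats(0.1, 1.0), c=st.floats(0.1, 10))
def test_fs_ef_scale_invariance(dd, frac, c):
    sd = dd * frac
    assert fractional_shortening(dd * c, sd * c) == pytest.approx(
        fractional_shortening(dd, sd), rel=1e-9)
    assert ejection_fraction(dd * c, sd * c) == pytest.approx(
        ejection_fraction(dd, sd), rel=1e-9)


def test_arrhythmia_index_values():
    assert arrhythmia_index([0.5, 0.5, 0.5]) == 0.0
    assert arrhythmia_index([1, 1, 1, 1, 2]) == pytest.approx(np.sqrt(0.2), rel=1e-9)
    base = arrhythmia_index([0.4, 0.5, 0.6, 0.55])
    assert arrhythmia_index([1.2, 1.5, 1.8, 1.65]) == pytest.approx(base)
    with pytest.raises(InsufficientDataError):
        arrhythmia_index([0.5])


def test_stroke_volume_and_cardiac_output():
    # pi * 100 * (400 - 100) µm^3 = 94.25 pL
    assert stroke_volume(40, 20, 100) == pytest.approx(94.2477, rel=1e-4)
    assert stroke_volume(30, 30, 50) == 0.0
    assert stroke_volume(40, 20, 200) == pytest.approx(2 * stroke_volume(40, 20, 100))
    with pytest.raises(ParameterError):
        stroke_volume(-1, 0, 10)

    def beat(sv_dd, sv_sd, hp):
        return Beat(0, 0, hp / 2, hp / 2, sv_dd, sv_sd, hp, 0, 0)

    bt = BeatTable([beat(40, 20, 0.5)] * 4, fps=100)
    sv = stroke_volume(40, 20, 100)
    assert cardiac_output(bt, 100) == pytest.approx(sv / 0.5)
    with pytest.raises(InsufficientDataError):
        cardiac_output(BeatTable([], 100), 100)


# -- latency ------------------------------------------------------------------

def test_latency_cosine_half_period_separation():
    T0, fps = 1.0, 200.0
    t = np.arange(int(4 * T0 * fps)) / fps
    trace = _trace(50 + 10 * np.cos(2 * np.pi * t / T0), fps)
    bt = detect_beats(trace, smooth_window=1)
    t_peak, t_c2r = contractile_latency(trace, bt, smooth_window=1)
    assert len(t_c2r) >= 2
    assert np.abs(t_c2r - T0 / 2).max() <= 2.0 / fps
    assert (t_peak >= 0).all() and (t_c2r >= 0).all()


def test_latency_instant_contraction():
    fps = 100.0
    cycle = np.concatenate([np.full(20, 60.0), [40.0],
                            np.linspace(40, 60, 30)])
    trace = _trace(np.tile(cycle, 4), fps)
    bt = detect_beats(trace, smooth_window=1)
    t_peak, _ = contractile_latency(trace, bt, smooth_window=1)
    assert len(t_peak) >= 2
    assert t_peak.max() <= 1.0 / fps + 1e-12


# -- arrhythmia events --------------------------------------------------------

def _table_from_intervals(sis, dis, fps=100.0):
    beats = [Beat(onset_t=i, rel_end_t=i + si, si=si, di=di, dd=60, sd=40,
                  hp=si + di, fs=33.3, ef=55.6)
             for i, (si, di) in enumerate(zip(sis, dis))]
    return BeatTable(beats, fps)


def test_arrhythmia_filters_strict_thresholds():
    bt = _table_from_intervals([0.3, 0.6, 0.51], [0.9, 1.0, 1.01])
    ev = flag_arrhythmia_events(bt)
    assert ev.n_tachy == 2
    assert ev.n_brady == 1
    assert ev.mean_brady_di == pytest.approx(1.01)
    empty = flag_arrhythmia_events(BeatTable([], 100.0))
    assert empty.n_tachy == 0 and empty.n_brady == 0


@settings(max_examples=25, derandomize=True, deadline=None)
@given(st.integers(0, 2**16), st.floats(0.1, 2.0), st.floats(0.1, 2.0))
def test_event_counts_monotone_in_thresholds(seed, thr_a, thr_b):
    rng = np.random.default_rng(seed)
    bt = _table_from_intervals(rng.uniform(0.05, 1.5, 10),
                               rng.uniform(0.05, 2.0, 10))
    lo, hi = sorted([thr_a, thr_b])
    ev_lo = flag_arrhythmia_events(bt, tachy_threshold_s=lo, brady_threshold_s=lo)
    ev_hi = flag_arrhythmia_events(bt, tachy_threshold_s=hi, brady_threshold_s=hi)
    assert ev_hi.n_tachy <= ev_lo.n_tachy
    assert ev_hi.n_brady <= ev_lo.n_brady


# -- aggregates ---------------------------------------------------------------

def test_aggregate_stats_basics():
    bt = _table_from_intervals([0.2, 0.2, 0.2], [0.3, 0.3, 0.3])
    st_ = aggregate_stats(bt, roi_length_um=100.0)
    assert st_.hp == pytest.approx(0.5)
    assert st_.hr == pytest.approx(2.0)
    assert st_.ai == pytest.approx(0.0)
    assert st_.sv == pytest.approx(stroke_volume(60, 40, 100))
    single = _table_from_intervals([0.2], [0.3])
    assert aggregate_stats(single).ai is None
    with pytest.raises(InsufficientDataError):
        aggregate_stats(BeatTable([], 100.0))


def test_parameter_recovery_across_jittered_hearts(recovery_hearts):
    """DD/SD within 2%, FS within 1 point, HR within 2%, AI within 0.02
    of the generator's realized values, per heart."""
    for spec, true_beats, stats in recovery_hearts:
        hp = true_beats["hp"].to_numpy()
        assert abs(stats.dd - spec.dd_true) / spec.dd_true < 0.02
        assert abs(stats.sd - spec.sd_true) / spec.sd_true < 0.02
        fs_true = 100 * (spec.dd_true - spec.sd_true) / spec.dd_true
        assert abs(stats.fs - fs_true) < 1.0
        hr_true = 1.0 / hp.mean()
        assert abs(stats.hr - hr_true) / hr_true < 0.02
        ai_true = np.std(hp, ddof=1) / np.median(hp)
        assert abs(stats.ai - ai_true) < 0.02
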