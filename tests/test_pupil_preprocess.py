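import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from attnpupil import pupil_preprocess as pp
from conftest import make_series


# ---------------------------------------------------------------------------
# invalid runs
# ---------------------------------------------------------------------------

def test_all_valid_no_runs(constant_series):
    assert pp.find_invalid_runs(constant_series) == []


def test_single_run_bounds():
    valid = np.ones(500, dtype=bool)
    valid[100:200] = False
    series = make_series(np.zeros(500), valid=valid)
    assert pp.find_invalid_runs(series) == [(100, 200)]


def test_two_runs_one_valid_gap():
    valid = np.ones(300, dtype=bool)
    valid[50:100] = False
    valid[101:150] = False
    series = make_series(np.zeros(300), valid=valid)
    assert pp.find_invalid_runs(series) == [(50, 100), (101, 150)]


def test_runs_match_scan_oracle():
    rng = np.random.default_rng(0)
    valid = rng.random(1000) > 0.2
    series = make_series(np.zeros(1000), valid=valid)
    # brute-force scan
    expected, start = [], None
    for i, v in enumerate(valid):
        if not v and start is None:
            start = i
        if v and start is not None:
            expected.append((start, i))
            start = None
    if start is not None:
        expected.append((start, 1000))
    assert pp.find_invalid_runs(series) == expected


# ---------------------------------------------------------------------------
# blink interpolation
# ---------------------------------------------------------------------------

def test_interpolation_exact_on_ramp():
    ramp = np.linspace(0, 10, 2000)
    valid = np.ones(2000, dtype=bool)
    valid[800:900] = False
    series = make_series(ramp.copy(), valid=valid)
    out = pp.interpolate_blinks(series)
    assert out.valid.all()
    np.testing.assert_allclose(out.pupil, ramp, atol=1e-9)


def test_interpolation_step_is_linear():
    fs = 1000.0
    pupil = np.concatenate([np.full(1000, 4.0), np.full(1000, 6.0)])
    valid = np.ones(2000, dtype=bool)
    valid[950:1050] = False
    series = make_series(pupil, fs=fs, valid=valid)
    out = pp.interpolate_blinks(series, pre_pad=0.050, post_pad=0.150)
    a, b = 900, 1200  # padded interval
    span = out.pupil[a:b]
    assert np.all(np.diff(span) > 0)
    np.testing.assert_allclose(np.diff(span), np.diff(span)[0], atol=1e-9)
    assert out.pupil[a - 1] == 4.0 and out.pupil[b] == 6.0
    np.testing.assert_array_equal(out.pupil[:a], 4.0)
    np.testing.assert_array_equal(out.pupil[b:], 6.0)


def test_overlapping_pads_merge():
    pupil = np.linspace(0, 1, 1000) ** 2  # curved so merging matters
    valid = np.ones(1000, dtype=bool)
    valid[300:320] = False
    valid[340:360] = False  # pads overlap: 320+150 > 340-50
    series = make_series(pupil.copy(), valid=valid)
    out = pp.interpolate_blinks(series)
    a, b = 250, 510
    inner = out.pupil[a:b]
    np.testing.assert_allclose(np.diff(inner), np.diff(inner)[0], atol=1e-12)


def test_edge_blink_hold():
    pupil = np.linspace(5, 6, 1000)
    valid = np.ones(1000, dtype=bool)
    valid[:100] = False
    series = make_series(pupil.copy(), valid=valid)
    out = pp.interpolate_blinks(series, pre_pad=0.05, post_pad=0.15)
    np.testing.assert_array_equal(out.pupil[:250], out.pupil[250])


def test_fully_invalid_rejected():
    series = make_series(np.zeros(100), valid=np.zeros(100, dtype=bool))
    with pytest.raises(ValueError, match="fully invalid"):
        pp.interpolate_blinks(series)


def test_interpolation_idempotent_on_clean_series(constant_series):
    out = pp.interpolate_blinks(constant_series)
    np.testing.assert_array_equal(out.pupil, constant_series.pupil)
    np.testing.assert_array_equal(out.valid, constant_series.valid)


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def test_lowpass_unit_dc_gain(constant_series):
    out = pp.lowpass(constant_series)
    np.testing.assert_allclose(out.pupil, 5.0, atol=1e-8)


def test_lowpass_stopband_attenuation():
    fs, f0 = 1000.0, 20.0
    t = np.arange(int(20 * fs)) / fs
    series = make_series(np.sin(2 * np.pi * f0 * t), fs=fs)
    out = pp.lowpass(series, order=4, cutoff=10.0)
    mid = out.pupil[int(8 * fs): int(12 * fs)]
    measured = np.max(np.abs(mid))
    expected = (1 / np.sqrt(1 + (f0 / 10.0) ** 8)) ** 2  # squared magnitude
    assert measured == pytest.approx(expected, rel=0.02)


def test_lowpass_zero_phase_peak_position():
    fs = 1000.0
    pulse = np.zeros(4000)
    tri = np.concatenate([np.linspace(0, 1, 200), np.linspace(1, 0, 200)])
    pulse[1800:2200] = tri
    out = pp.lowpass(make_series(pulse, fs=fs))
    assert abs(int(np.argmax(out.pupil)) - 1999) <= 1


def test_lowpass_cutoff_above_nyquist_rejected():
    series = make_series(np.zeros(100), fs=15.0)
    with pytest.raises(ValueError, match="Nyquist"):
        pp.lowpass(series, cutoff=10.0)


def test_lowpass_requires_valid_series():
    valid = np.ones(1000, dtype=bool)
    valid[10] = False
    series = make_series(np.zeros(1000), valid=valid)
    with pytest.raises(ValueError, match="interpolate"):
        pp.lowpass(series)


# ---------------------------------------------------------------------------
# epoching
# ---------------------------------------------------------------------------

def test_epoch_constant(constant_series):
    es = pp.epoch(constant_series, [1.0], window=(-0.5, 0.5))
    assert es.epochs.shape == (1, 1000)
    np.testing.assert_array_equal(es.epochs, 5.0)
    assert es.epoch_time[0] == pytest.approx(-0.5)


def test_epoch_sample_arithmetic():
    fs = 100.0
    series = make_series(np.arange(2000, dtype=float), fs=fs)
    es = pp.epoch(series, [10.0], window=(-1.0, 7.0))
    assert es.epochs.shape == (1, 800)
    # covers t in [9, 17): samples 900 .. 1699
    assert es.epochs[0, 0] == 900
    assert es.epochs[0, -1] == 1699


def test_epoch_pulse_alignment():
    fs = 200.0
    n = int(60 * fs)
    pupil = np.zeros(n)
    cues = [5.0, 20.0, 35.0]
    for c in cues:
        pupil[int((c + 2.0) * fs)] = 1.0  # pulse 2 s after each cue
    es = pp.epoch(make_series(pupil, fs=fs), cues, window=(-1.0, 7.0))
    for row in es.epochs:
        t_peak = es.epoch_time[int(np.argmax(row))]
        assert t_peak == pytest.approx(2.0, abs=1 / fs)


def test_epoch_out_of_bounds_names_trial():
    series = make_series(np.zeros(1000), fs=100.0)
    with pytest.raises(ValueError, match="trial 1"):
        pp.epoch(series, [2.0, 9.5], window=(-1.0, 7.0))


def test_epoch_missing_fraction_uses_raw_validity():
    fs = 100.0
    n = int(30 * fs)
    valid = np.ones(n, dtype=bool)
    valid[int(10 * fs): int(12 * fs)] = False  # inside first epoch
    series = make_series(np.zeros(n), fs=fs)
    es = pp.epoch(series, [10.0, 20.0], window=(-1.0, 7.0), raw_valid=valid)
    assert es.missing_fraction[0] == pytest.approx(2 / 8)
    assert es.missing_fraction[1] == 0.0


# ---------------------------------------------------------------------------
# exclusion
# ---------------------------------------------------------------------------

def test_exclusion_boundary():
    retained, report = pp.exclude_high_missing(
        {0: 0.0, 1: 0.51, 2: 0.50})
    assert retained == [0, 2]
    assert report.set_index("subject").loc[1, "excluded"]
    assert not report.set_index("subject").loc[2, "excluded"]


def test_exclusion_matches_brute_count():
    rng = np.random.default_rng(3)
    fractions = {}
    for s in range(10):
        valid = rng.random(5000) > rng.uniform(0.2, 0.8)
        fractions[s] = float(np.sum(~valid)) / 5000  # brute-force count
    retained, report = pp.exclude_high_missing(fractions)
    for s, f in fractions.items():
        assert (s in retained) == (f <= 0.5)


# ---------------------------------------------------------------------------
# baselining and phasic traces
# ---------------------------------------------------------------------------

def _toy_epochs(rows, fs=10.0, t0=-0.5):
    rows = np.asarray(rows, dtype=float)
    time = t0 + np.arange(rows.shape[1]) / fs
    labels = pd.DataFrame(index=range(rows.shape[0]))
    return pp.EpochSet(epochs=rows, epoch_time=time, trial_labels=labels,
                       missing_fraction=np.zeros(rows.shape[0]),
                       sampling_rate=fs)


def test_baseline_constant_epochs():
    es = _toy_epochs(np.full((3, 10), 7.0))
    stats = pp.baseline_stats(es)
    np.testing.assert_allclose(stats.per_trial_baseline, 7.0)
    assert stats.tonic_mean == pytest.approx(7.0)
    assert stats.tonic_sd == 0.0


def test_baseline_hand_arithmetic():
    es = _toy_epochs([np.full(10, 4.0), np.full(10, 6.0)])
    stats = pp.baseline_stats(es)
    assert stats.tonic_mean == pytest.approx(5.0)
    assert stats.tonic_sd == pytest.approx(np.sqrt(2))  # n-1 estimator


def test_baseline_shift_equivariance():
    rng = np.random.default_rng(1)
    rows = rng.random((4, 20))
    es1 = _toy_epochs(rows)
    es2 = _toy_epochs(rows + 3.7)
    s1, s2 = pp.baseline_stats(es1), pp.baseline_stats(es2)
    assert s2.tonic_mean == pytest.approx(s1.tonic_mean + 3.7)
    assert s2.tonic_sd == pytest.approx(s1.tonic_sd)


def test_baseline_window_half_open():
    # 1 Hz-scale toy: only samples with t in [-0.5, 0) count
    fs = 10.0
    es = _toy_epochs(np.tile(np.arange(10.0), (2, 1)), fs=fs, t0=-0.5)
    stats = pp.baseline_stats(es, baseline_window=(-0.5, 0.0))
    np.testing.assert_allclose(stats.per_trial_baseline, np.mean([0, 1, 2, 3, 4]))


def test_phasic_zero_when_epochs_equal_baseline():
    es = _toy_epochs(np.full((3, 10), 2.5))
    stats = pp.baseline_stats(es)
    for mode in ("subtract_only", "proportional"):
        trace = pp.phasic(es, stats, mode)
        np.testing.assert_allclose(trace.trace, 0.0)
    with pytest.raises(ValueError, match="degenerate"):
        pp.phasic(es, stats, "zscore")


def test_phasic_zscore_hand_arithmetic():
    rows = np.array([
        [4.0, 4.0, 4.0, 4.0, 4.0, 5.0, 6.0, 5.0],
        [6.0, 6.0, 6.0, 6.0, 6.0, 7.0, 9.0, 6.0],
        [5.0, 5.0, 5.0, 5.0, 5.0, 5.0, 7.0, 5.5],
    ])
    fs = 10.0
    es = _toy_epochs(rows, fs=fs, t0=-0.5)
    stats = pp.baseline_stats(es)  # baselines 4, 6, 5
    assert stats.tonic_sd == pytest.approx(1.0)
    trace = pp.phasic(es, stats, "zscore")
    sub = rows - np.array([4.0, 6.0, 5.0])[:, None]
    np.testing.assert_allclose(trace.trace, sub.mean(axis=0))


@settings(max_examples=25, deadline=None)
@given(a=st.floats(0.1, 10), b=st.floats(-5, 5))
def test_phasic_zscore_affine_invariant(a, b):
    rng = np.random.default_rng(0)
    rows = rng.random((5, 20)) + 3
    es1 = _toy_epochs(rows)
    es2 = _toy_epochs(a * rows + b)
    t1 = pp.phasic(es1, pp.baseline_stats(es1), "zscore")
    t2 = pp.phasic(es2, pp.baseline_stats(es2), "zscore")
    np.testing.assert_allclose(t1.trace, t2.trace, rtol=1e-8, atol=1e-8)


@settings(max_examples=25, deadline=None)
@given(a=st.floats(0.1, 10), b=st.floats(-5, 5))
def test_phasic_subtract_only_equivariance(a, b):
    rng = np.random.default_rng(1)
    rows = rng.random((5, 20)) + 3
    es1 = _toy_epochs(rows)
    es2 = _toy_epochs(a * rows + b)
    t1 = pp.phasic(es1, pp.baseline_stats(es1), "subtract_only")
    t2 = pp.phasic(es2, pp.baseline_stats(es2), "subtract_only")
    np.testing.assert_allclose(t2.trace, a * t1.trace, rtol=1e-8, atol=1e-8)


def test_filter_then_epoch_commutes():
    fs = 100.0
    rng = np.random.default_rng(2)
    pupil = np.cumsum(rng.standard_normal(int(60 * fs))) * 0.01 + 5
    series = make_series(pupil, fs=fs)
    filtered = pp.lowpass(series)
    cues = [20.0, 35.0]
    a = pp.epoch(filtered, cues, window=(-1.0, 7.0)).epochs
    # filtering each long epoch separately, away from edges, matches
    wide = pp.epoch(series, cues, window=(-6.0, 12.0))
    for row_a, row_w in zip(a, wide.epochs):
        filt_row = pp.lowpass(make_series(row_w, fs=fs)).pupil
        np.testing.assert_allclose(row_a, filt_row[500:1300], atol=1e-6)


def test_sample_series_frame_round_trip(constant_series):
    df = constant_series.to_frame()
    back = pp.SampleSeries.from_frame(df, sampling_rate=1000.0)
    np.testing.assert_allclose(back.pupil, constant_series.pupil)
    np.testing.assert_array_equal(back.valid, constant_series.valid)
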