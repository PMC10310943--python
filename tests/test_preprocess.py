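"""Signal conditioning and event detection.

Oracles: injected motion with known onset/amplitude built from an
independent raised-cosine profile (conftest), plus closed-form velocity
values for ramps and isolated jumps.
"""

import numpy as np
import pytest

from oculokit import (
    DetectionConfig,
    denoise,
    detect_intrusions,
    detect_saccades,
    remove_artifacts,
    velocity,
)
from oculokit.preprocess import ArtifactInterval, ConfigError, ProcessingError

from conftest import DT, RATE, make_recording, raised_cosine_step, saccade_trace


# ---------------------------------------------------------------- denoise

def test_denoise_preserves_constant_signal():
    rec = make_recording(np.full(50, 3.0), np.full(50, -2.0))
    out = denoise(rec)
    assert np.array_equal(out.x, rec.x) and np.array_equal(out.y, rec.y)
    assert np.array_equal(out.t, rec.t)


def test_denoise_removes_single_sample_impulse():
    x = np.zeros(50)
    x[20] = 4.0
    out = denoise(make_recording(x, np.zeros(50)))
    assert out.x[20] == 0.0


def test_denoise_reduces_noise_sd():
    rng = np.random.default_rng(42)
    n = 420
    x = rng.normal(0.0, 0.3, n)
    y = rng.normal(0.0, 0.3, n)
    out = denoise(make_recording(x, y))
    assert out.x.std() < x.std()
    assert out.y.std() < y.std()


def test_denoise_displaces_step_by_at_most_one_sample():
    n = 120
    x = np.zeros(n)
    x[60:] = 10.0
    out = denoise(make_recording(x, np.zeros(n)))
    # crossing of half amplitude must stay within one sample of the original
    orig = np.argmax(x >= 5.0)
    filt = np.argmax(out.x >= 5.0)
    assert abs(int(filt) - int(orig)) <= 1


def test_denoise_rejects_even_window():
    rec = make_recording(np.zeros(50), np.zeros(50))
    with pytest.raises(ConfigError):
        denoise(rec, median_window=4)


def test_denoise_rejects_tiny_recording():
    rec = make_recording(np.zeros(3), np.zeros(3))
    with pytest.raises(ProcessingError):
        denoise(rec)


# -------------------------------------------------------- remove_artifacts

def test_long_invalid_run_becomes_padded_blink():
    n = 240
    valid = np.ones(n, bool)
    valid[100:110] = False  # 150 ms from first to last invalid sample
    rec = make_recording(np.zeros(n), np.zeros(n), valid=valid)
    out, intervals = remove_artifacts(rec)
    assert len(intervals) == 1
    iv = intervals[0]
    assert iv.kind == "blink"
    assert iv.start_t == pytest.approx(rec.t[100] - 0.05, abs=1e-9)
    assert iv.end_t == pytest.approx(rec.t[109] + 0.05, abs=1e-9)
    # padding invalidates neighbouring samples too
    assert not out.valid[97] and not out.valid[112]
    assert out.valid[96] and out.valid[113]


def test_short_dropout_classified_as_dropout():
    n = 120
    valid = np.ones(n, bool)
    valid[50:52] = False
    _, intervals = remove_artifacts(make_recording(np.zeros(n), np.zeros(n), valid=valid))
    assert [iv.kind for iv in intervals] == ["dropout"]


def test_touching_artifacts_merge():
    n = 240
    valid = np.ones(n, bool)
    valid[100:102] = False
    valid[105:107] = False  # gap 50 ms < 2 * padding
    _, intervals = remove_artifacts(make_recording(np.zeros(n), np.zeros(n), valid=valid))
    assert len(intervals) == 1


def test_impossible_velocity_flagged_as_spike():
    n = 120
    x = np.zeros(n)
    x[60:] = 30.0  # 30 deg in one 16.7 ms interval = 1800 deg/s
    out, intervals = remove_artifacts(make_recording(x, np.zeros(n)))
    assert any(iv.kind == "spike" for iv in intervals)
    assert not out.valid[60]


def test_clean_recording_untouched():
    rec = make_recording(np.zeros(120), np.zeros(120))
    out, intervals = remove_artifacts(rec)
    assert intervals == []
    assert out.valid.all()


def test_artifact_interval_requires_positive_length():
    with pytest.raises(ProcessingError):
        ArtifactInterval(1.0, 1.0, "blink")


# ----------------------------------------------------------------- velocity

def test_velocity_of_linear_ramp_is_exact():
    n = 60
    x = np.arange(n) * 1.0  # 1 deg per sample = 60 deg/s
    vel = velocity(make_recording(x, np.zeros(n)))
    assert np.allclose(vel.v, 60.0, atol=1e-9)
    assert np.allclose(vel.vx, 60.0, atol=1e-9)
    assert np.allclose(vel.vy, 0.0, atol=1e-9)


def test_velocity_of_constant_position_is_zero():
    vel = velocity(make_recording(np.full(60, 2.0), np.full(60, -1.0)))
    assert np.allclose(vel.v, 0.0, atol=1e-12)


def test_central_difference_of_isolated_jump():
    n = 60
    x = np.zeros(n)
    x[30:] = 5.0
    vel = velocity(make_recording(x, np.zeros(n)))
    # central difference spreads the 5 deg jump over 2*dt on both neighbours
    assert vel.v[29] == pytest.approx(5.0 / (2 * DT))
    assert vel.v[30] == pytest.approx(5.0 / (2 * DT))


def test_velocity_nan_on_invalid_samples():
    n = 60
    valid = np.ones(n, bool)
    valid[10:13] = False
    vel = velocity(make_recording(np.zeros(n), np.zeros(n), valid=valid))
    assert np.all(np.isnan(vel.v[10:13]))
    assert np.all(np.isfinite(np.delete(vel.v, [10, 11, 12])))


# ----------------------------------------------------------- detect_saccades

def test_single_saccade_amplitude_and_onset():
    rec, onset, _ = saccade_trace(10.0, onset=2.0, noise_sd=0.1, seed=5)
    events = detect_saccades(denoise(rec))
    big = [e for e in events if e.amplitude >= 1.0]
    assert len(big) == 1
    e = big[0]
    assert e.amplitude == pytest.approx(10.0, abs=0.5)
    assert abs(e.onset_t - onset) <= DT  # within one sample


def test_noiseless_onset_within_half_sample_any_phase():
    for k in range(6):
        onset = 1.5 + k * DT / 6.0
        rec, true_onset, _ = saccade_trace(6.0, onset=onset, noise_sd=0.0)
        events = detect_saccades(rec)
        assert len(events) == 1
        assert abs(events[0].onset_t - true_onset) <= 0.5 * DT + 1e-9


def test_pure_fixation_noise_yields_no_events():
    rng = np.random.default_rng(2024)
    n = int(7 * RATE)
    rec = make_recording(rng.normal(0, 0.2, n), rng.normal(0, 0.2, n))
    assert detect_saccades(denoise(rec)) == []


def test_two_saccades_400ms_apart_both_found_in_order():
    n = int(4 * RATE)
    t = np.arange(n) * DT
    x = raised_cosine_step(t, 1.5, 8.0, 0.040)
    x += raised_cosine_step(t, 1.9, -8.0, 0.040)
    rng = np.random.default_rng(8)
    rec = make_recording(x + rng.normal(0, 0.05, n), rng.normal(0, 0.05, n))
    events = [e for e in detect_saccades(denoise(rec)) if e.amplitude >= 1.0]
    assert len(events) == 2
    assert events[0].onset_t < events[1].onset_t
    assert events[0].onset_t == pytest.approx(1.5, abs=DT)
    assert events[1].onset_t == pytest.approx(1.9, abs=DT)
    assert events[0].direction[0] > 0 > events[1].direction[0]


def test_event_overlapping_artifact_discarded():
    rec, onset, off = saccade_trace(8.0, onset=2.0, noise_sd=0.05, seed=3)
    events = detect_saccades(rec)
    assert len(events) == 1
    shadow = [ArtifactInterval(onset - 0.01, off + 0.01, "blink")]
    assert detect_saccades(rec, artifacts=shadow) == []


def test_peak_velocity_never_below_mean_velocity():
    rng = np.random.default_rng(77)
    for rep in range(20):
        n = int(5 * RATE)
        t = np.arange(n) * DT
        x = np.zeros(n)
        for _ in range(rng.integers(1, 4)):
            x += raised_cosine_step(t, rng.uniform(0.5, 4.0), rng.uniform(-8, 8), rng.uniform(0.02, 0.06))
        rec = make_recording(x + rng.normal(0, 0.15, n), rng.normal(0, 0.15, n))
        for e in detect_saccades(denoise(rec)):
            assert e.peak_velocity >= e.mean_velocity - 1e-9
            assert e.offset_t > e.onset_t


def test_event_count_monotone_in_onset_threshold():
    rng = np.random.default_rng(31)
    n = int(6 * RATE)
    t = np.arange(n) * DT
    x = np.zeros(n)
    for onset in (1.0, 2.0, 3.2, 4.5):
        x += raised_cosine_step(t, onset, rng.uniform(1.0, 6.0), 0.03)
    rec = make_recording(x + rng.normal(0, 0.15, n), rng.normal(0, 0.15, n))
    rec = denoise(rec)
    counts = [
        len(detect_saccades(rec, DetectionConfig(onset_vel_deg_s=thr)))
        for thr in (30.0, 60.0, 120.0, 240.0)
    ]
    assert counts == sorted(counts, reverse=True)


def test_detection_config_validation():
    with pytest.raises(ConfigError):
        DetectionConfig(min_dur_ms=0.0)
    with pytest.raises(ConfigError):
        DetectionConfig(onset_vel_deg_s=20.0, offset_vel_deg_s=30.0)
    with pytest.raises(ConfigError):
        DetectionConfig(median_window=4)
    with pytest.raises(ConfigError):
        DetectionConfig(intrusion_count_mode="pairs?")
    with pytest.raises(ConfigError):
        DetectionConfig(displacement_check_frac=1.0)


# --------------------------------------------------------- detect_intrusions

def _swj_trace(amp, pair_onsets, noise_sd=0.05, seed=9, total_s=7.0):
    """Square-wave jerks: out-and-back horizontal steps of `amp` degrees."""
    n = int(total_s * RATE)
    t = np.arange(n) * DT
    x = np.zeros(n)
    for onset in pair_onsets:
        x += raised_cosine_step(t, onset, amp, 0.025)
        x += raised_cosine_step(t, onset + 0.25, -amp, 0.025)
    rng = np.random.default_rng(seed)
    return make_recording(x + rng.normal(0, noise_sd, n), rng.normal(0, noise_sd, n))


def test_swj_pairs_counted_as_intrusions():
    rec = _swj_trace(1.6, (1.0, 3.0, 5.0))
    found = detect_intrusions(denoise(rec), (0.0, 7.0))
    assert len(found) == 6  # three out-and-back pairs
    assert all(e.amplitude >= 0.5 for e in found)


def test_sub_floor_wobble_not_counted():
    rec = _swj_trace(0.3, (1.0, 3.0, 5.0))
    assert detect_intrusions(denoise(rec), (0.0, 7.0)) == []


def test_clean_fixation_has_no_intrusions():
    rng = np.random.default_rng(15)
    n = int(7 * RATE)
    rec = make_recording(rng.normal(0, 0.15, n), rng.normal(0, 0.15, n))
    assert detect_intrusions(denoise(rec), (0.0, 7.0)) == []


def test_acquisition_window_skipped():
    rec = _swj_trace(1.6, (0.05, 3.0))
    found = detect_intrusions(denoise(rec), (0.0, 7.0))
    # the pair starting at 50 ms falls in the 200 ms skip window
    assert all(e.onset_t >= 0.2 for e in found)
    assert len(found) < 4


def test_empty_window_rejected():
    rec = _swj_trace(1.6, (1.0,))
    with pytest.raises(ProcessingError):
        detect_intrusions(rec, (3.0, 3.0))
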