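"""Task-level metrics: BCEA, fixation stability, pro-/anti-saccade scoring.

Oracles: closed-form BCEA values on exactly-whitened samples, Monte-Carlo
coverage of the fitted ellipse, and hand-built event lists with arithmetic
worked out inline.
"""

import math

import numpy as np
import pytest

from oculokit import (
    AnalysisConfig,
    DetectionConfig,
    Task,
    Trial,
    TrialSchedule,
    aggregate_antisaccade,
    aggregate_prosaccade,
    antisaccade_trial,
    bcea,
    extract_subject_parameters,
    fixation_metrics,
    prosaccade_trial,
)
from oculokit.metrics import AntiSaccadeTrialMetrics, ProSaccadeTrialMetrics
from oculokit.preprocess import SaccadeEvent

from conftest import DT, RATE, make_recording


def _whitened(n=200, seed=0):
    """Points with sample SDs exactly 1 and sample correlation exactly 0."""
    rng = np.random.default_rng(seed)
    pts = rng.normal(size=(n, 2))
    pts -= pts.mean(axis=0)
    # Gram-Schmidt on the columns, then rescale to unit sample SD
    pts[:, 1] -= pts[:, 0] * (pts[:, 0] @ pts[:, 1]) / (pts[:, 0] @ pts[:, 0])
    pts /= pts.std(axis=0, ddof=1)
    return pts


def mk_event(onset, offset, amp, direction=(1.0, 0.0)):
    mean = amp / (offset - onset)
    return SaccadeEvent(onset, offset, amp, direction, mean * 1.5, mean)


# ------------------------------------------------------------------- bcea

def test_bcea_closed_form_unit_circular():
    pts = _whitened()
    # 2*pi*k with k = -ln(1-P); sd_h = sd_v = 1, rho = 0
    assert bcea(pts, 0.68) == pytest.approx(2 * math.pi * -math.log(0.32), rel=1e-9)
    assert bcea(pts, 0.68) == pytest.approx(7.159, abs=5e-4)
    assert bcea(pts, 0.95) == pytest.approx(18.82, abs=5e-3)


def test_bcea_ratio_is_coverage_ratio():
    rng = np.random.default_rng(4)
    pts = rng.normal(size=(60, 2)) @ np.array([[1.0, 0.4], [0.0, 0.7]])
    assert bcea(pts, 0.95) / bcea(pts, 0.68) == pytest.approx(
        math.log(0.05) / math.log(0.32), rel=1e-12
    )


def test_bcea_scales_with_variance_and_correlation():
    pts = _whitened(seed=1)
    base = bcea(pts, 0.68)
    assert bcea(pts * 2.0, 0.68) == pytest.approx(4.0 * base, rel=1e-9)
    sheared = pts.copy()
    sheared[:, 1] = 0.6 * sheared[:, 0] + 0.8 * sheared[:, 1]
    assert bcea(sheared, 0.68) < base + 1e-9  # correlation shrinks the ellipse


def test_bcea_zero_spread_is_zero():
    pts = np.zeros((10, 2))
    pts[:, 0] = np.arange(10)  # all on a horizontal line
    assert bcea(pts, 0.68) == 0.0


def test_bcea_input_validation():
    with pytest.raises(ValueError):
        bcea(np.zeros((2, 2)))
    with pytest.raises(ValueError):
        bcea(np.zeros((10, 3)))
    with pytest.raises(ValueError):
        bcea(_whitened(), coverage=1.0)


def test_bcea_monte_carlo_coverage():
    rng = np.random.default_rng(99)
    cov = np.array([[1.0, 0.5], [0.5, 2.0]])
    pts = rng.multivariate_normal([0, 0], cov, size=5000)
    for p in (0.68, 0.95):
        area = bcea(pts, p)
        # fraction of points inside the ellipse of that area, oriented by
        # the sample covariance: quadratic form <= 2k covers fraction p
        c = np.cov(pts.T)
        d2 = np.einsum("ij,jk,ik->i", pts - pts.mean(axis=0), np.linalg.inv(c), pts - pts.mean(axis=0))
        k = -math.log(1.0 - p)
        inside = float(np.mean(d2 <= 2.0 * k))
        assert inside == pytest.approx(p, abs=0.02)
        # and that ellipse's area matches the reported BCEA
        assert area == pytest.approx(
            2.0 * math.pi * k * math.sqrt(np.linalg.det(c)), rel=1e-2
        )


# ------------------------------------------------------------ fixation task

def _fix_schedule(n_trials=1, dur=7.0, target=(0.0, 0.0)):
    trials = [
        Trial(i, target[0], target[1], i * (dur + 1.0), i * (dur + 1.0), dur)
        for i in range(n_trials)
    ]
    return TrialSchedule(Task.FIXATION, trials)


def _fix_recording(noise_sd, seed, dur=7.0, target=(0.0, 0.0)):
    rng = np.random.default_rng(seed)
    n = int(dur * RATE) + 1
    x = target[0] + rng.normal(0, noise_sd, n)
    y = target[1] + rng.normal(0, noise_sd, n)
    return make_recording(x, y, task=Task.FIXATION)


def test_fixation_sd_recovers_injected_noise():
    vals_h, vals_v = [], []
    for seed in range(20):
        rec = _fix_recording(0.5, seed)
        fm = fixation_metrics(rec, _fix_schedule(), events=[])
        vals_h.append(fm.sd_h)
        vals_v.append(fm.sd_v)
    assert np.mean(vals_h) == pytest.approx(0.5, rel=0.10)
    assert np.mean(vals_v) == pytest.approx(0.5, rel=0.10)
    # with sd_h = sd_v = 0.5 and rho ~ 0: bcea68 ~ 2*pi*1.139*0.25
    fm = fixation_metrics(_fix_recording(0.5, 0), _fix_schedule(), events=[])
    assert fm.bcea68 == pytest.approx(2 * math.pi * -math.log(0.32) * 0.25, rel=0.25)


def test_fixation_intrusion_rate_counts_events_over_analyzed_time():
    rec = _fix_recording(0.1, 7)
    events = [mk_event(1.0 + i * 1.5, 1.03 + i * 1.5, 1.6) for i in range(3)]
    fm = fixation_metrics(rec, _fix_schedule(), events)
    assert fm.n_intrusions == 3
    # window starts 200 ms in, so ~6.8 s analyzed out of the 7 s trial
    assert fm.analyzed_time_s == pytest.approx(6.8, abs=0.1)
    assert fm.intrusion_rate == pytest.approx(3 / 7.0, rel=0.05)
    assert fm.intrusion_rate == pytest.approx(3 / fm.analyzed_time_s, rel=1e-9)


def test_fixation_pair_mode_halves_the_count():
    rec = _fix_recording(0.1, 7)
    events = [mk_event(1.0 + i * 0.8, 1.03 + i * 0.8, 1.6, ((-1.0) ** i, 0.0)) for i in range(4)]
    sac = fixation_metrics(rec, _fix_schedule(), events, DetectionConfig())
    pair = fixation_metrics(
        rec, _fix_schedule(), events, DetectionConfig(intrusion_count_mode="pair")
    )
    assert pair.intrusion_rate == pytest.approx(sac.intrusion_rate / 2.0, rel=1e-9)


def test_fixation_sub_amplitude_events_not_counted():
    rec = _fix_recording(0.1, 7)
    events = [mk_event(2.0, 2.03, 0.3)]  # below the 0.5 deg floor
    fm = fixation_metrics(rec, _fix_schedule(), events)
    assert fm.n_intrusions == 0


def test_fixation_trial_with_too_little_valid_time_dropped():
    rec = _fix_recording(0.1, 3)
    rec.valid[30:] = False  # ~0.5 s valid, below the 1 s floor
    with pytest.warns(UserWarning, match="dropped"):
        fm = fixation_metrics(rec, _fix_schedule(), events=[])
    assert math.isnan(fm.bcea68) and fm.n_trials_used == 0


def test_fixation_requires_fixation_schedule():
    sched = TrialSchedule(Task.PROSACCADE, [Trial(0, 10.0, 0.0, 0.0, 0.0, 3.0)])
    with pytest.raises(ValueError):
        fixation_metrics(_fix_recording(0.1, 0), sched, events=[])


# ----------------------------------------------------------- pro-saccade task

def _pro_recording(step_at=1.2, land=9.0, total=3.2):
    n = int(total * RATE)
    t = np.arange(n) * DT
    x = np.where(t >= step_at, land, 0.0)
    return make_recording(x, np.zeros(n), task=Task.PROSACCADE)


PRO_TRIAL = Trial(0, 10.0, 0.0, 0.0, 1.0, 2.0, eccentricity_class="large")


def test_prosaccade_trial_worked_example():
    # 9 deg saccade at 200 ms latency toward a 10 deg target; the gaze step
    # lands between samples so the pre-saccade sample precedes the onset
    rec = _pro_recording(step_at=1.21)
    ev = [mk_event(1.2, 1.245, 9.0)]
    m = prosaccade_trial(rec, PRO_TRIAL, ev)
    assert m.status == "ok"
    assert m.latency == pytest.approx(0.2, abs=1e-9)
    assert m.first_gain == pytest.approx(0.9, abs=1e-9)
    assert m.first_gain_error == pytest.approx(1.0, abs=1e-6)
    assert m.n_saccades_to_target == 1
    assert m.time_to_target == pytest.approx(0.2, abs=3 * DT)
    assert m.mean_velocity == pytest.approx(9.0 / 0.045, rel=1e-9)


def test_prosaccade_anticipatory_flagged():
    rec = _pro_recording(step_at=1.04)
    m = prosaccade_trial(rec, PRO_TRIAL, [mk_event(1.04, 1.085, 9.0)])
    assert m.status == "anticipatory"
    assert m.latency == pytest.approx(0.04, abs=1e-9)


def test_prosaccade_no_response():
    rec = make_recording(np.zeros(192), np.zeros(192), task=Task.PROSACCADE)
    m = prosaccade_trial(rec, PRO_TRIAL, [])
    assert m.status == "non_responsive"
    assert m.n_saccades_to_target == 0
    assert math.isnan(m.latency)


def test_prosaccade_wrong_direction_ignored():
    rec = make_recording(np.zeros(192), np.zeros(192), task=Task.PROSACCADE)
    m = prosaccade_trial(rec, PRO_TRIAL, [mk_event(1.2, 1.25, 9.0, (-1.0, 0.0))])
    assert m.status == "non_responsive"


def test_prosaccade_multistep_counted():
    n = int(3.2 * RATE)
    t = np.arange(n) * DT
    x = np.zeros(n)
    x[t >= 1.2] = 6.0
    x[t >= 1.5] = 9.5
    rec = make_recording(x, np.zeros(n), task=Task.PROSACCADE)
    ev = [mk_event(1.2, 1.24, 6.0), mk_event(1.5, 1.53, 3.5)]
    m = prosaccade_trial(rec, PRO_TRIAL, ev)
    assert m.status == "ok"
    assert m.first_gain == pytest.approx(0.6, abs=1e-9)
    assert m.n_saccades_to_target == 2


def _pm(ecc, latency, gain, n_sacc=1, status="ok"):
    return ProSaccadeTrialMetrics(
        trial_id=0,
        eccentricity_class=ecc,
        latency=latency,
        time_to_target=latency + 0.05,
        mean_velocity=200.0,
        peak_velocity=300.0,
        first_gain=gain,
        first_gain_error=abs(1 - gain) * 10.0,
        n_saccades_to_target=n_sacc,
        status=status,
    )


def test_aggregate_prosaccade_means_and_exclusions():
    trials = [
        _pm("short", 0.20, 0.90),
        _pm("short", 0.30, 0.80, n_sacc=2),
        _pm("short", 0.05, 0.70, status="anticipatory"),
        _pm("short", float("nan"), float("nan"), n_sacc=0, status="non_responsive"),
        _pm("large", 0.25, 1.00),
    ]
    out = aggregate_prosaccade(trials)
    # anticipatory excluded from latency but kept for gain / n_saccades
    assert out["pro_short_latency"] == pytest.approx(0.25)
    assert out["pro_short_first_gain"] == pytest.approx((0.9 + 0.8 + 0.7) / 3)
    assert out["pro_short_n_saccades"] == pytest.approx((1 + 2 + 1) / 3)
    assert out["pro_large_latency"] == pytest.approx(0.25)
    assert len(out) == 14


def test_aggregate_prosaccade_empty_class_is_nan():
    out = aggregate_prosaccade([_pm("short", 0.2, 0.9)])
    assert math.isnan(out["pro_large_latency"])
    assert math.isnan(out["pro_large_n_saccades"])


# ---------------------------------------------------------- anti-saccade task

ANTI_TRIAL = Trial(
    0, 10.0, 0.0, 0.0, 1.0, 0.1,
    arrow_direction="left", arrow_onset=2.3, arrow_duration=0.4, response_window=5.0,
)


def _anti_recording(xs):
    """Piecewise-constant horizontal gaze: list of (from_t, x)."""
    n = int(8.0 * RATE)
    t = np.arange(n) * DT
    x = np.zeros(n)
    for t0, val in xs:
        x[t >= t0] = val
    return make_recording(x, np.zeros(n), task=Task.ANTISACCADE)


def test_antisaccade_correct_trial():
    rec = _anti_recording([(1.25, -8.0)])
    ev = [mk_event(1.25, 1.29, 8.0, (-1.0, 0.0))]
    m = antisaccade_trial(rec, ANTI_TRIAL, ev)
    assert m.first_direction == "correct"
    assert m.corrected is None
    assert m.latency == pytest.approx(0.25, abs=1e-9)
    assert m.recognized_arrow  # gaze parked at x = -8 during the arrow answer


def test_antisaccade_error_corrected():
    rec = _anti_recording([(1.25, 8.0), (1.8, -8.0)])
    ev = [mk_event(1.25, 1.29, 8.0, (1.0, 0.0)), mk_event(1.8, 1.84, 16.0, (-1.0, 0.0))]
    m = antisaccade_trial(rec, ANTI_TRIAL, ev)
    assert m.first_direction == "error"
    assert m.corrected is True


def test_antisaccade_error_uncorrected():
    rec = _anti_recording([(1.25, 8.0)])
    ev = [mk_event(1.25, 1.29, 8.0, (1.0, 0.0))]
    m = antisaccade_trial(rec, ANTI_TRIAL, ev)
    assert m.first_direction == "error"
    assert m.corrected is False
    assert not m.recognized_arrow  # dwell on the right, arrow points left


def test_antisaccade_vertical_saccades_not_candidates():
    rec = _anti_recording([])
    ev = [mk_event(1.3, 1.34, 5.0, (0.0, 1.0))]
    m = antisaccade_trial(rec, ANTI_TRIAL, ev)
    assert m.status == "no_saccade"


def test_aggregate_antisaccade_worked_example():
    trials = []
    for i in range(6):
        trials.append(AntiSaccadeTrialMetrics(i, "correct", None, True, 0.30))
    for i in range(4):
        trials.append(
            AntiSaccadeTrialMetrics(6 + i, "error", i < 3, i % 2 == 0, 0.22)
        )
    out = aggregate_antisaccade(trials)
    assert out["anti_error_rate"] == pytest.approx(0.4)
    assert out["anti_corrected_rate"] == pytest.approx(0.75)
    assert out["anti_recognition_rate"] == pytest.approx(8 / 10)
    assert out["anti_correct_latency"] == pytest.approx(0.30)
    assert out["anti_incorrect_latency"] == pytest.approx(0.22)


def test_aggregate_antisaccade_no_errors_gives_nan_corrected():
    trials = [AntiSaccadeTrialMetrics(i, "correct", None, True, 0.3) for i in range(5)]
    out = aggregate_antisaccade(trials)
    assert math.isnan(out["anti_corrected_rate"])
    assert out["anti_error_rate"] == 0.0
    assert math.isnan(out["anti_incorrect_latency"])


# ----------------------------------------------------- subject-level pipeline

def test_extract_subject_parameters_full_battery(small_cohort):
    subjects, _ = small_cohort
    info = subjects["PD000"]
    params, qc = extract_subject_parameters(info["recordings"], info["schedules"])
    assert len(params) == 24
    for name in ("fix_bcea68", "fix_sd_h", "pro_short_latency", "pro_large_first_gain"):
        assert np.isfinite(params[name]), name
    assert 0.0 <= params["anti_error_rate"] <= 1.0
    tasks = {row["task"] for row in qc}
    assert tasks == {"fixation", "prosaccade", "antisaccade"}


def test_extract_subject_parameters_missing_task_gives_nan(small_cohort):
    subjects, _ = small_cohort
    info = subjects["HC000"]
    recs = {k: v for k, v in info["recordings"].items() if k != Task.ANTISACCADE}
    scheds = {k: v for k, v in info["schedules"].items() if k != Task.ANTISACCADE}
    params, _ = extract_subject_parameters(recs, scheds)
    assert math.isnan(params["anti_error_rate"])
    assert np.isfinite(params["fix_bcea68"])
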