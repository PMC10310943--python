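"""Task-level oculomotor parameters.

Turns detected events plus a trial schedule into the 24 canonical
per-subject parameters: 5 fixation-stability measures, 7 pro-saccade
measures per eccentricity class (short/large), and 5 anti-saccade measures.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .preprocess import (
    DetectionConfig,
    SaccadeEvent,
    denoise,
    detect_saccades,
    remove_artifacts,
)
from .types import (
    ANTISACCADE_PARAMETERS,
    CANONICAL_PARAMETERS,
    GazeRecording,
    Task,
    Trial,
    TrialSchedule,
)

__all__ = [
    "AnalysisConfig",
    "FixationMetrics",
    "ProSaccadeTrialMetrics",
    "AntiSaccadeTrialMetrics",
    "bcea",
    "fixation_metrics",
    "prosaccade_trial",
    "aggregate_prosaccade",
    "antisaccade_trial",
    "aggregate_antisaccade",
    "preprocess_recording",
    "extract_subject_parameters",
]


@dataclass(frozen=True)
class AnalysisConfig:
    """Scoring thresholds shared across tasks.

    acceptance_radius_deg / dwell_ms:
        A target counts as reached when gaze stays within this radius for
        at least this long (defaults 2 deg / 100 ms, typical for 5–12 deg
        targets).
    min_saccade_amp_deg:
        Amplitude floor for task-relevant saccades (latency, direction).
    anticipatory_ms:
        Latencies below this are anticipatory and excluded from latency and
        velocity aggregates (the trial still counts toward n_saccades).
    min_fixation_analyzed_s:
        A fixation trial with less valid analysis time than this is dropped.
    response_dead_zone_deg:
        Gaze closer to screen center than this is not assigned to any arrow
        sector when scoring the anti-saccade recognition answer.
    """

    acceptance_radius_deg: float = 2.0
    dwell_ms: float = 100.0
    min_saccade_amp_deg: float = 1.0
    anticipatory_ms: float = 80.0
    min_fixation_analyzed_s: float = 1.0
    acquisition_search_s: float = 0.6
    response_dead_zone_deg: float = 2.0


@dataclass
class FixationMetrics:
    bcea68: float
    bcea95: float
    sd_h: float
    sd_v: float
    intrusion_rate: float
    n_trials_used: int = 0
    n_intrusions: int = 0
    analyzed_time_s: float = 0.0


@dataclass
class ProSaccadeTrialMetrics:
    trial_id: int
    eccentricity_class: str
    latency: float
    time_to_target: float
    mean_velocity: float
    peak_velocity: float
    first_gain: float
    first_gain_error: float
    n_saccades_to_target: int
    status: str = "ok"  # ok | anticipatory | non_responsive


@dataclass
class AntiSaccadeTrialMetrics:
    trial_id: int
    first_direction: str  # correct | error
    corrected: Optional[bool]
    recognized_arrow: bool
    latency: float
    status: str = "ok"


def bcea(points: np.ndarray, coverage: float = 0.68) -> float:
    """Bivariate contour ellipse area (deg^2) at coverage probability P.

    ``area = 2*pi*k*sd_h*sd_v*sqrt(1 - rho^2)`` with ``k = -ln(1 - P)``,
    where sd_h/sd_v are the sample SDs of the horizontal/vertical gaze
    positions and rho their sample correlation. Under bivariate normality
    the ellipse of that area centred on the mean contains a fraction P of
    the gaze points; smaller area = steadier fixation.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("bcea needs an (n >= 3, 2) array of gaze points")
    if not 0.0 < coverage < 1.0:
        raise ValueError("coverage must be in (0, 1)")
    sd = pts.std(axis=0, ddof=1)
    if sd[0] == 0.0 or sd[1] == 0.0:
        return 0.0
    rho = float(np.corrcoef(pts[:, 0], pts[:, 1])[0, 1])
    k = -math.log(1.0 - coverage)
    return float(2.0 * math.pi * k * sd[0] * sd[1] * math.sqrt(max(0.0, 1.0 - rho**2)))


def preprocess_recording(
    recording: GazeRecording, config: DetectionConfig | None = None
) -> tuple[GazeRecording, list, list[SaccadeEvent]]:
    """Standard conditioning chain: denoise → artifact removal → detection."""
    config = config or DetectionConfig()
    clean = denoise(recording, median_window=config.median_window)
    clean, artifacts = remove_artifacts(clean, config)
    events = detect_saccades(clean, config)
    return clean, artifacts, events


def _acquisition_end(
    events: Sequence[SaccadeEvent], t0: float, config: DetectionConfig, acfg: AnalysisConfig
) -> float:
    """Start of the per-trial analysis window.

    At least ``intrusion_skip_ms`` after target onset, and past the end of
    the acquiring saccade when one is detected early in the trial (typical
    latencies exceed 200 ms, so a fixed skip alone would let the
    acquisition saccade masquerade as an intrusion).
    """
    start = t0 + config.intrusion_skip_ms / 1000.0
    for e in events:
        if t0 <= e.onset_t <= t0 + acfg.acquisition_search_s and e.amplitude >= acfg.min_saccade_amp_deg:
            start = max(start, e.offset_t + 0.05)
            break
    return start


def fixation_metrics(
    recording: GazeRecording,
    schedule: TrialSchedule,
    events: Sequence[SaccadeEvent],
    config: DetectionConfig | None = None,
    analysis: AnalysisConfig | None = None,
) -> FixationMetrics:
    """Fixation stability and intrusion rate, averaged across trials.

    Per trial, gaze samples from the end of target acquisition to trial end
    are re-centred on the trial target; samples inside detected saccades are
    excluded from the stability statistics (BCEA at 68%/95%, horizontal and
    vertical SD). The intrusion rate is the total number of intrusion
    saccades (>= 0.5 deg, after the acquisition window) divided by the total
    valid fixation time analysed.
    """
    config = config or DetectionConfig()
    analysis = analysis or AnalysisConfig()
    if schedule.task != Task.FIXATION:
        raise ValueError("fixation_metrics requires a fixation schedule")
    dt = recording.dt
    per_trial = {"bcea68": [], "bcea95": [], "sd_h": [], "sd_v": []}
    total_intrusions = 0
    total_time = 0.0

    for trial in schedule.trials:
        t0 = trial.target_onset
        t1 = t0 + trial.target_duration
        start = _acquisition_end(events, t0, config, analysis)
        in_win = (recording.t >= start) & (recording.t <= t1) & recording.valid
        if not in_win.any():
            warnings.warn(f"fixation trial {trial.trial_id}: no valid samples, dropped")
            continue
        analyzed = float(in_win.sum()) * dt
        if analyzed < analysis.min_fixation_analyzed_s:
            warnings.warn(
                f"fixation trial {trial.trial_id}: only {analyzed:.2f}s valid, dropped"
            )
            continue
        trial_events = [e for e in events if start <= e.onset_t and e.offset_t <= t1]
        intrusions = [
            e for e in trial_events if e.amplitude >= config.intrusion_min_amp_deg
        ]
        total_intrusions += len(intrusions)
        total_time += analyzed

        stable = in_win.copy()
        for e in trial_events:
            stable &= ~((recording.t >= e.onset_t) & (recording.t <= e.offset_t))
        pts = np.column_stack(
            [recording.x[stable] - trial.target_x, recording.y[stable] - trial.target_y]
        )
        if pts.shape[0] < 3:
            continue
        per_trial["bcea68"].append(bcea(pts, 0.68))
        per_trial["bcea95"].append(bcea(pts, 0.95))
        per_trial["sd_h"].append(float(pts[:, 0].std(ddof=1)))
        per_trial["sd_v"].append(float(pts[:, 1].std(ddof=1)))

    n_used = len(per_trial["bcea68"])
    if n_used == 0 or total_time <= 0:
        return FixationMetrics(*(float("nan"),) * 5)
    count = total_intrusions / 2.0 if config.intrusion_count_mode == "pair" else total_intrusions
    return FixationMetrics(
        bcea68=float(np.mean(per_trial["bcea68"])),
        bcea95=float(np.mean(per_trial["bcea95"])),
        sd_h=float(np.mean(per_trial["sd_h"])),
        sd_v=float(np.mean(per_trial["sd_v"])),
        intrusion_rate=count / total_time,
        n_trials_used=n_used,
        n_intrusions=total_intrusions,
        analyzed_time_s=total_time,
    )


def _first_arrival(
    recording: GazeRecording,
    trial: Trial,
    analysis: AnalysisConfig,
    t_end: float,
) -> Optional[float]:
    """First time gaze enters the acceptance radius and dwells long enough."""
    m = (recording.t >= trial.target_onset) & (recording.t <= t_end) & recording.valid
    idx = np.flatnonzero(m)
    if idx.size == 0:
        return None
    dist = np.hypot(
        recording.x[idx] - trial.target_x, recording.y[idx] - trial.target_y
    )
    inside = dist <= analysis.acceptance_radius_deg
    dwell_samples = max(1, int(round(analysis.dwell_ms / 1000.0 * recording.sample_rate)))
    run = 0
    for j, ok in enumerate(inside):
        run = run + 1 if ok else 0
        if run >= dwell_samples:
            return float(recording.t[idx[j - run + 1]])
    return None


def prosaccade_trial(
    recording: GazeRecording,
    trial: Trial,
    events: Sequence[SaccadeEvent],
    analysis: AnalysisConfig | None = None,
) -> ProSaccadeTrialMetrics:
    """Score one pro-saccade trial.

    The responding saccade is the first event after target onset with
    amplitude >= 1 deg whose displacement points toward the target
    (positive dot product with the fixation→target vector). first_gain is
    the along-axis component of its displacement over the target
    eccentricity; first_gain_error is the 2-D distance from its landing
    point to the target.
    """
    analysis = analysis or AnalysisConfig()
    t_on = trial.target_onset
    t_end = t_on + trial.target_duration
    ecc = math.hypot(trial.target_x, trial.target_y)
    axis = (trial.target_x / ecc, trial.target_y / ecc)

    first = None
    for e in events:
        if e.onset_t <= t_on or e.onset_t > t_end:
            continue
        if e.amplitude < analysis.min_saccade_amp_deg:
            continue
        if e.direction[0] * axis[0] + e.direction[1] * axis[1] > 0:
            first = e
            break
    nan = float("nan")
    if first is None:
        return ProSaccadeTrialMetrics(
            trial.trial_id, trial.eccentricity_class, nan, nan, nan, nan, nan, nan, 0,
            status="non_responsive",
        )
    latency = first.onset_t - t_on
    arrival = _first_arrival(recording, trial, analysis, t_end)
    if arrival is None:
        time_to_target = nan
        n_sacc = 0
        status = "non_responsive"
    else:
        time_to_target = arrival - t_on
        n_sacc = sum(
            1
            for e in events
            if t_on < e.onset_t <= arrival + 1e-9
            and e.amplitude >= 0.5
        )
        n_sacc = max(n_sacc, 1)
        status = "ok"
    if status == "ok" and latency < analysis.anticipatory_ms / 1000.0:
        status = "anticipatory"

    along = first.amplitude * (
        first.direction[0] * axis[0] + first.direction[1] * axis[1]
    )
    # landing point = saccade displacement applied to the pre-saccade position
    i_pre = np.searchsorted(recording.t, first.onset_t, side="right") - 1
    land_x = recording.x[i_pre] + first.amplitude * first.direction[0]
    land_y = recording.y[i_pre] + first.amplitude * first.direction[1]
    gain_error = math.hypot(land_x - trial.target_x, land_y - trial.target_y)
    return ProSaccadeTrialMetrics(
        trial_id=trial.trial_id,
        eccentricity_class=trial.eccentricity_class,
        latency=latency,
        time_to_target=time_to_target,
        mean_velocity=first.mean_velocity,
        peak_velocity=first.peak_velocity,
        first_gain=along / ecc,
        first_gain_error=gain_error,
        n_saccades_to_target=n_sacc,
        status=status,
    )


def aggregate_prosaccade(
    trials: Sequence[ProSaccadeTrialMetrics],
) -> dict[str, float]:
    """Across-trial means per eccentricity class (14 canonical parameters).

    Non-responsive trials are excluded everywhere; anticipatory trials are
    excluded from the latency/velocity means but still contribute their
    n_saccades and gain. Empty classes yield NaN, never zero.
    """
    out: dict[str, float] = {}
    for ecc in ("short", "large"):
        cls = [t for t in trials if t.eccentricity_class == ecc and t.status != "non_responsive"]
        timed = [t for t in cls if t.status == "ok"]

        def mean(vals):
            vals = [v for v in vals if not math.isnan(v)]
            return float(np.mean(vals)) if vals else float("nan")

        out[f"pro_{ecc}_latency"] = mean([t.latency for t in timed])
        out[f"pro_{ecc}_time_to_target"] = mean([t.time_to_target for t in timed])
        out[f"pro_{ecc}_mean_velocity"] = mean([t.mean_velocity for t in timed])
        out[f"pro_{ecc}_peak_velocity"] = mean([t.peak_velocity for t in timed])
        out[f"pro_{ecc}_first_gain"] = mean([t.first_gain for t in cls])
        out[f"pro_{ecc}_first_gain_error"] = mean([t.first_gain_error for t in cls])
        out[f"pro_{ecc}_n_saccades"] = mean(
            [float(t.n_saccades_to_target) for t in cls if t.n_saccades_to_target >= 1]
        )
    return out


_SECTOR_OF = {"right": 0, "left": 1, "up": 2, "down": 3}


def _dwell_sector(recording: GazeRecording, t0: float, t1: float, dead: float) -> Optional[str]:
    """Arrow answer: half-plane sector with the longest dwell time.

    Sector of a sample is the direction of its dominant coordinate
    (|x| vs |y|), ignoring samples within the central dead zone. Ties or no
    qualifying samples → None (unrecognized).
    """
    m = (recording.t >= t0) & (recording.t <= t1) & recording.valid
    x, y = recording.x[m], recording.y[m]
    r = np.hypot(x, y)
    keep = r > dead
    x, y = x[keep], y[keep]
    if x.size == 0:
        return None
    horiz = np.abs(x) >= np.abs(y)
    counts = {
        "right": int(np.sum(horiz & (x > 0))),
        "left": int(np.sum(horiz & (x < 0))),
        "up": int(np.sum(~horiz & (y > 0))),
        "down": int(np.sum(~horiz & (y < 0))),
    }
    best = max(counts.values())
    winners = [k for k, v in counts.items() if v == best]
    return winners[0] if len(winners) == 1 and best > 0 else None


def antisaccade_trial(
    recording: GazeRecording,
    trial: Trial,
    events: Sequence[SaccadeEvent],
    analysis: AnalysisConfig | None = None,
) -> AntiSaccadeTrialMetrics:
    """Score one anti-saccade trial.

    The first saccade (>= 1 deg) after target onset is *correct* when its
    horizontal component points away from the target side. An error trial
    is *corrected* when a later saccade carries gaze across the vertical
    midline to the correct side before the arrow disappears. The arrow
    answer is the sector of longest dwell during the response screen.
    """
    analysis = analysis or AnalysisConfig()
    t_on = trial.target_onset
    arrow_off = (trial.arrow_onset or t_on) + (trial.arrow_duration or 0.0)
    resp_end = arrow_off + (trial.response_window or 0.0)
    target_side = 1.0 if trial.target_x > 0 else -1.0

    cands = [
        e
        for e in events
        if t_on < e.onset_t <= arrow_off
        and e.amplitude >= analysis.min_saccade_amp_deg
        and abs(e.direction[0]) > abs(e.direction[1])
    ]
    if not cands:
        return AntiSaccadeTrialMetrics(
            trial.trial_id, "error", None, False, float("nan"), status="no_saccade"
        )
    first = cands[0]
    is_error = first.direction[0] * target_side > 0
    corrected: Optional[bool] = None
    if is_error:
        corrected = False
        for e in cands[1:]:
            if e.onset_t >= arrow_off:
                break
            i = np.searchsorted(recording.t, e.offset_t, side="right") - 1
            if recording.valid[i] and recording.x[i] * target_side < 0:
                corrected = True
                break
    answer = _dwell_sector(recording, arrow_off, resp_end, analysis.response_dead_zone_deg)
    return AntiSaccadeTrialMetrics(
        trial_id=trial.trial_id,
        first_direction="error" if is_error else "correct",
        corrected=corrected,
        recognized_arrow=(answer == trial.arrow_direction),
        latency=first.onset_t - t_on,
    )


def aggregate_antisaccade(
    trials: Sequence[AntiSaccadeTrialMetrics],
) -> dict[str, float]:
    """The five canonical anti-saccade parameters.

    error rate = error trials / valid trials; corrected rate = corrected /
    errors (NaN when no errors); recognition rate over valid trials; mean
    latency separately over correct and error trials.
    """
    valid = [t for t in trials if t.status == "ok"]
    nan = float("nan")
    if not valid:
        return {name: nan for name in ANTISACCADE_PARAMETERS}
    errors = [t for t in valid if t.first_direction == "error"]
    correct = [t for t in valid if t.first_direction == "correct"]

    def mean_lat(group):
        vals = [t.latency for t in group if not math.isnan(t.latency)]
        return float(np.mean(vals)) if vals else nan

    return {
        "anti_error_rate": len(errors) / len(valid),
        "anti_corrected_rate": (
            sum(bool(t.corrected) for t in errors) / len(errors) if errors else nan
        ),
        "anti_recognition_rate": sum(t.recognized_arrow for t in valid) / len(valid),
        "anti_correct_latency": mean_lat(correct),
        "anti_incorrect_latency": mean_lat(errors),
    }


def extract_subject_parameters(
    recordings: dict[Task, GazeRecording],
    schedules: dict[Task, TrialSchedule],
    config: DetectionConfig | None = None,
    analysis: AnalysisConfig | None = None,
) -> tuple[dict[str, float], list[dict]]:
    """Run the full per-subject pipeline over the three task recordings.

    Returns the canonical 24-parameter map (NaN where a task is absent or
    unusable) and a QC list of per-trial status records.
    """
    config = config or DetectionConfig()
    analysis = analysis or AnalysisConfig()
    params: dict[str, float] = {name: float("nan") for name in CANONICAL_PARAMETERS}
    qc: list[dict] = []

    if Task.FIXATION in recordings:
        rec, _, events = preprocess_recording(recordings[Task.FIXATION], config)
        fm = fixation_metrics(rec, schedules[Task.FIXATION], events, config, analysis)
        params.update(
            fix_bcea68=fm.bcea68,
            fix_bcea95=fm.bcea95,
            fix_sd_h=fm.sd_h,
            fix_sd_v=fm.sd_v,
            fix_intrusion_rate=fm.intrusion_rate,
        )
        qc.append(
            {
                "task": "fixation",
                "trial_id": -1,
                "status": f"{fm.n_trials_used} trials used",
                "reason": "",
            }
        )

    if Task.PROSACCADE in recordings:
        rec, _, events = preprocess_recording(recordings[Task.PROSACCADE], config)
        trials = [
            prosaccade_trial(rec, tr, events, analysis)
            for tr in schedules[Task.PROSACCADE].trials
        ]
        params.update(aggregate_prosaccade(trials))
        qc.extend(
            {
                "task": "prosaccade",
                "trial_id": t.trial_id,
                "status": t.status,
                "reason": "" if t.status == "ok" else t.status,
            }
            for t in trials
        )

    if Task.ANTISACCADE in recordings:
        rec, _, events = preprocess_recording(recordings[Task.ANTISACCADE], config)
        trials = [
            antisaccade_trial(rec, tr, events, analysis)
            for tr in schedules[Task.ANTISACCADE].trials
        ]
        params.update(aggregate_antisaccade(trials))
        qc.extend(
            {
                "task": "antisaccade",
                "trial_id": t.trial_id,
                "status": t.status,
                "reason": "" if t.status == "ok" else t.status,
            }
            for t in trials
        )
    return params, qc
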