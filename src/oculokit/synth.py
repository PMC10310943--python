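"""Ground-truthed synthetic gaze: schedules, recordings, and cohorts.

The generator emulates 60 Hz tablet gaze recordings for the three tasks.
Saccades follow the main-sequence law ``Vp = Vmax * (1 - exp(-A / C))``
with raised-cosine velocity profiles; fixation carries Gaussian tracker
noise plus slow drift; saccadic intrusions are square-wave jerks (two
opposite, equal-amplitude saccades 200 ms apart); blinks are runs of
invalid samples. Every injected event is written to a truth log, and
cohorts carry a per-subject truth table of realized generating values so
pipeline estimates can be scored against ground truth.

Two-group (PD vs HC) defaults encode the qualitative patient effects this
package is built to measure: an elevated intrusion rate, hypometric
multi-step pro-saccades (lower first gain, more saccades to target),
shorter latencies, faster short-eccentricity saccades, and a higher
anti-saccade error rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Optional

import numpy as np
import pandas as pd

from .types import (
    CANONICAL_PARAMETERS,
    GazeRecording,
    Task,
    Trial,
    TrialSchedule,
)

__all__ = [
    "SubjectProfile",
    "ProfileVariation",
    "CohortConfig",
    "HC_PROFILE",
    "PD_PROFILE",
    "main_sequence_peak_velocity",
    "make_schedule",
    "synth_gaze",
    "synth_cohort",
]

FIXATION_TARGETS = [(0.0, 0.0), (-10.0, 0.0), (10.0, 0.0), (0.0, 14.0), (0.0, -14.0)]
PROSACCADE_TARGETS = [
    (5.0, 0.0, "short"),
    (-5.0, 0.0, "short"),
    (0.0, 6.0, "short"),
    (0.0, -6.0, "short"),
    (10.0, 0.0, "large"),
    (-10.0, 0.0, "large"),
    (0.0, 12.0, "large"),
    (0.0, -12.0, "large"),
]
ARROW_DIRECTIONS = ("left", "right", "up", "down")


@dataclass(frozen=True)
class SubjectProfile:
    """Generating parameters for one subject's oculomotor behaviour.

    Rates are per second (except ``blink_rate``, per minute), times in
    seconds, amplitudes/SDs in degrees, velocities in deg/s.
    ``intrusion_rate`` is the injection rate of square-wave-jerk *pairs*;
    each pair contributes two intrusion saccades.
    """

    latency_mean: float = 0.22
    latency_sd: float = 0.04
    antisaccade_latency_shift: float = 0.06
    main_sequence_vmax: float = 500.0
    main_sequence_c: float = 5.0
    primary_gain_mean: float = 0.95
    primary_gain_sd: float = 0.05
    multistep_prob: float = 0.06
    multistep_gain_factor: float = 0.6
    corrective_saccade_prob: float = 0.9
    corrective_delay_mean: float = 0.20
    landing_scatter_sd: float = 0.30
    intrusion_rate: float = 0.10
    intrusion_amp_mean: float = 1.6
    intrusion_amp_sd: float = 0.3
    fixation_noise_sd: float = 0.25
    drift_sd: float = 0.10
    blink_rate: float = 2.0
    antisaccade_error_prob: float = 0.22
    correction_prob: float = 0.65
    recognition_prob: float = 0.85

    def __post_init__(self) -> None:
        for name in (
            "multistep_prob",
            "corrective_saccade_prob",
            "antisaccade_error_prob",
            "correction_prob",
            "recognition_prob",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        for name in (
            "latency_sd",
            "intrusion_rate",
            "intrusion_amp_mean",
            "fixation_noise_sd",
            "drift_sd",
            "blink_rate",
            "landing_scatter_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.primary_gain_mean <= 0 or self.multistep_gain_factor <= 0:
            raise ValueError("gains must be > 0")


HC_PROFILE = SubjectProfile()
# Patient defaults: effect directions follow the published PD pattern —
# more intrusions, hypometric multi-step saccades, shorter latency, faster
# short saccades (lower C steepens the small-amplitude main sequence),
# noisier fixation, more anti-saccade errors.
PD_PROFILE = SubjectProfile(
    latency_mean=0.195,
    main_sequence_vmax=460.0,
    main_sequence_c=2.8,
    primary_gain_mean=0.91,
    multistep_prob=0.18,
    intrusion_rate=0.1887,
    fixation_noise_sd=0.30,
    landing_scatter_sd=0.38,
    antisaccade_error_prob=0.30,
    correction_prob=0.60,
    recognition_prob=0.78,
)


@dataclass(frozen=True)
class ProfileVariation:
    """Between-subject SDs applied to profile fields when drawing a cohort."""

    latency_mean: float = 0.030
    primary_gain_mean: float = 0.055
    multistep_prob: float = 0.06
    intrusion_rate: float = 0.055
    fixation_noise_sd: float = 0.04
    main_sequence_vmax: float = 40.0
    landing_scatter_sd: float = 0.06
    antisaccade_error_prob: float = 0.10
    recognition_prob: float = 0.08


@dataclass(frozen=True)
class CohortConfig:
    """A two-group synthetic study.

    UPDRS-III motor scores exist for PD subjects only, drawn around a
    latent severity that is linearly coupled to latency (+), first gain
    (−), landing scatter (+), peak velocity (−) and multi-step probability
    (+), with independent between-subject noise on top.
    """

    n_per_group: int = 20
    seed: int = 0
    hc: SubjectProfile = HC_PROFILE
    pd: SubjectProfile = PD_PROFILE
    variation: ProfileVariation = field(default_factory=ProfileVariation)
    sample_rate: float = 60.0
    n_antisaccade_trials: int = 12
    pd_age_mean: float = 63.76
    pd_age_sd: float = 8.23
    hc_age_mean: float = 56.64
    hc_age_sd: float = 8.56
    updrs_mean: float = 27.56
    updrs_sd: float = 13.8
    updrs_coupling: bool = True

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")


def main_sequence_peak_velocity(amplitude: float, vmax: float, c: float) -> float:
    """Main-sequence law: peak velocity saturates with amplitude."""
    return vmax * (1.0 - math.exp(-amplitude / c))


def make_schedule(
    task: Task | str,
    seed: int,
    n_antisaccade_trials: int = 12,
    sample_rate: float = 60.0,
) -> TrialSchedule:
    """Build one task schedule with seeded randomization.

    fixation: 5 trials x 7 s at the five canonical positions (shuffled).
    prosaccade: 8 locations (4 directions x 2 eccentricity classes) x 3
    repeats = 24 trials; random 1.0–3.5 s central fixation, 1.5 s target.
    antisaccade: ±10 deg targets shown 100 ms, 1200 ms blank, 400 ms arrow
    (uniform over 4 directions), 5 s response screen.
    """
    task = Task(task)
    rng = np.random.default_rng(seed)
    trials: list[Trial] = []
    t = 0.0
    if task == Task.FIXATION:
        targets = list(FIXATION_TARGETS)
        rng.shuffle(targets)
        for i, (tx, ty) in enumerate(targets):
            trials.append(
                Trial(
                    trial_id=i,
                    target_x=tx,
                    target_y=ty,
                    fixation_onset=t,
                    target_onset=t,
                    target_duration=7.0,
                )
            )
            t += 7.0
    elif task == Task.PROSACCADE:
        locs = [loc for loc in PROSACCADE_TARGETS for _ in range(3)]
        rng.shuffle(locs)
        for i, (tx, ty, ecc) in enumerate(locs):
            fix = rng.uniform(1.0, 3.5)
            trials.append(
                Trial(
                    trial_id=i,
                    target_x=tx,
                    target_y=ty,
                    fixation_onset=t,
                    target_onset=t + fix,
                    target_duration=1.5,
                    eccentricity_class=ecc,
                )
            )
            t += fix + 1.5
    else:
        sides = [10.0, -10.0] * (n_antisaccade_trials // 2 + 1)
        sides = sides[:n_antisaccade_trials]
        rng.shuffle(sides)
        for i, side in enumerate(sides):
            fix = rng.uniform(1.0, 3.5)
            target_onset = t + fix
            trials.append(
                Trial(
                    trial_id=i,
                    target_x=side,
                    target_y=0.0,
                    fixation_onset=t,
                    target_onset=target_onset,
                    target_duration=0.1,
                    arrow_direction=str(rng.choice(ARROW_DIRECTIONS)),
                    arrow_onset=target_onset + 0.1 + 1.2,
                    arrow_duration=0.4,
                    response_window=5.0,
                )
            )
            t = target_onset + 0.1 + 1.2 + 0.4 + 5.0
    return TrialSchedule(task=task, trials=trials, sample_rate=sample_rate)


@dataclass
class _Saccade:
    onset: float
    duration: float
    p0: tuple[float, float]
    p1: tuple[float, float]
    kind: str
    trial_id: int
    peak_velocity: float


def _plan_saccade(
    onset: float,
    p0: tuple[float, float],
    p1: tuple[float, float],
    profile: SubjectProfile,
    kind: str,
    trial_id: int,
) -> _Saccade:
    amp = math.hypot(p1[0] - p0[0], p1[1] - p0[1])
    vp = main_sequence_peak_velocity(amp, profile.main_sequence_vmax, profile.main_sequence_c)
    dur = max(0.015, 2.0 * amp / vp) if vp > 0 else 0.015
    return _Saccade(onset, dur, p0, p1, kind, trial_id, vp)


def _draw_latency(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Truncated-normal latency with an 80 ms physiological floor."""
    for _ in range(64):
        lat = rng.normal(mean, sd)
        if lat >= 0.08:
            return float(lat)
    return 0.08


def synth_gaze(
    schedule: TrialSchedule,
    profile: SubjectProfile,
    seed: int,
    subject_id: str = "synth",
    sample_rate: Optional[float] = None,
) -> tuple[GazeRecording, dict]:
    """Simulate one task recording; returns (recording, truth log).

    The truth log contains every injected saccade (onset, duration,
    amplitude, main-sequence peak velocity, kind), blink intervals, and
    per-trial truth records matching the analysis-layer definitions
    (latency, realized first gain along the target axis, landing error,
    saccades needed to come within 2 deg of the target, anti-saccade
    direction/correction/recognition outcomes).
    """
    rate = sample_rate or schedule.sample_rate
    if rate < 30:
        raise ValueError("sample_rate must be >= 30 Hz")
    rng = np.random.default_rng(seed)
    dt = 1.0 / rate
    task = schedule.task
    total = schedule.trials[-1].end + 0.5

    saccades: list[_Saccade] = []
    trial_truth: list[dict] = []
    cur = (0.0, 0.0)
    fixation_analysis: list[tuple[float, float]] = []  # intrusion-eligible spans

    for trial in schedule.trials:
        tid = trial.trial_id
        target = (trial.target_x, trial.target_y)
        if task == Task.FIXATION:
            t0 = trial.target_onset
            dist = math.hypot(target[0] - cur[0], target[1] - cur[1])
            acq_end = t0
            if dist > 0.3:
                lat = _draw_latency(rng, profile.latency_mean, profile.latency_sd)
                land = (
                    target[0] + rng.normal(0, profile.landing_scatter_sd * 0.5),
                    target[1] + rng.normal(0, profile.landing_scatter_sd * 0.5),
                )
                sac = _plan_saccade(t0 + lat, cur, land, profile, "acquisition", tid)
                saccades.append(sac)
                cur = land
                acq_end = sac.onset + sac.duration
            # mirror of the analysis layer's window: acquisition end + margin
            fixation_analysis.append((acq_end + 0.075, t0 + trial.target_duration))
        elif task == Task.PROSACCADE:
            cur = _return_to_center(saccades, rng, profile, trial, cur)
            lat = _draw_latency(rng, profile.latency_mean, profile.latency_sd)
            multistep = rng.random() < profile.multistep_prob
            gain = rng.normal(profile.primary_gain_mean, profile.primary_gain_sd)
            if multistep:
                gain *= profile.multistep_gain_factor
            gain = max(0.3, gain)
            land = (
                cur[0] + gain * (target[0] - cur[0]) + rng.normal(0, profile.landing_scatter_sd),
                cur[1] + gain * (target[1] - cur[1]) + rng.normal(0, profile.landing_scatter_sd),
            )
            primary = _plan_saccade(trial.target_onset + lat, cur, land, profile, "primary", tid)
            saccades.append(primary)
            ecc = math.hypot(*target)
            axis = (target[0] / ecc, target[1] / ecc)
            realized_gain = (
                (land[0] - cur[0]) * axis[0] + (land[1] - cur[1]) * axis[1]
            ) / ecc
            gain_error = math.hypot(land[0] - target[0], land[1] - target[1])
            cur = land
            n_sacc = 1
            arrival = (
                primary.onset + primary.duration
                if math.hypot(cur[0] - target[0], cur[1] - target[1]) <= 2.0
                else None
            )
            t_next = primary.onset + primary.duration
            # corrective steps close most of the remaining error
            while (
                arrival is None
                and n_sacc <= 3
                and rng.random() < profile.corrective_saccade_prob
            ):
                t_next += max(0.12, rng.normal(profile.corrective_delay_mean, 0.04))
                if t_next > trial.end - 0.08:
                    break
                land = (
                    cur[0] + 0.85 * (target[0] - cur[0]) + rng.normal(0, 0.15),
                    cur[1] + 0.85 * (target[1] - cur[1]) + rng.normal(0, 0.15),
                )
                corr = _plan_saccade(t_next, cur, land, profile, "corrective", tid)
                saccades.append(corr)
                cur = land
                n_sacc += 1
                t_next = corr.onset + corr.duration
                if math.hypot(cur[0] - target[0], cur[1] - target[1]) <= 2.0:
                    arrival = t_next
            trial_truth.append(
                {
                    "trial_id": tid,
                    "eccentricity_class": trial.eccentricity_class,
                    "latency": lat,
                    "first_gain": realized_gain,
                    "first_gain_error": gain_error,
                    "peak_velocity": primary.peak_velocity,
                    "mean_velocity": (
                        math.hypot(
                            primary.p1[0] - primary.p0[0], primary.p1[1] - primary.p0[1]
                        )
                        / primary.duration
                    ),
                    "n_saccades": n_sacc if arrival is not None else np.nan,
                    "time_to_target": (arrival - trial.target_onset) if arrival else np.nan,
                }
            )
        else:  # anti-saccade
            cur = _return_to_center(saccades, rng, profile, trial, cur)
            side = 1.0 if trial.target_x > 0 else -1.0
            is_error = rng.random() < profile.antisaccade_error_prob
            lat = _draw_latency(
                rng,
                profile.latency_mean
                + (0.0 if is_error else profile.antisaccade_latency_shift),
                profile.latency_sd,
            )
            gain = max(0.3, rng.normal(profile.primary_gain_mean, profile.primary_gain_sd))
            direction = side if is_error else -side
            land = (
                direction * 10.0 * gain + rng.normal(0, profile.landing_scatter_sd),
                rng.normal(0, profile.landing_scatter_sd),
            )
            sac = _plan_saccade(trial.target_onset + lat, cur, land, profile, "anti", tid)
            saccades.append(sac)
            cur = land
            corrected = None
            if is_error:
                corrected = rng.random() < profile.correction_prob
                if corrected:
                    t_corr = sac.onset + sac.duration + max(
                        0.15, rng.normal(0.30, 0.06)
                    )
                    land = (
                        -side * 10.0 * gain + rng.normal(0, profile.landing_scatter_sd),
                        rng.normal(0, profile.landing_scatter_sd),
                    )
                    corr = _plan_saccade(t_corr, cur, land, profile, "anti_correction", tid)
                    saccades.append(corr)
                    cur = land
            on_correct_side = cur[0] * side < 0
            recognized = bool(on_correct_side and rng.random() < profile.recognition_prob)
            arrow_off = trial.arrow_onset + trial.arrow_duration
            if recognized:
                answer = trial.arrow_direction
            else:
                others = [d for d in ARROW_DIRECTIONS if d != trial.arrow_direction]
                answer = str(rng.choice(others))
            ans_pos = {
                "left": (-8.0, 0.0),
                "right": (8.0, 0.0),
                "up": (0.0, 8.0),
                "down": (0.0, -8.0),
            }[answer]
            t_ans = arrow_off + 0.4 + rng.uniform(0.0, 0.3)
            ans = _plan_saccade(t_ans, cur, ans_pos, profile, "answer", tid)
            saccades.append(ans)
            cur = ans_pos
            trial_truth.append(
                {
                    "trial_id": tid,
                    "latency": lat,
                    "is_error": is_error,
                    "corrected": corrected,
                    "recognized": recognized,
                }
            )

    saccades.sort(key=lambda s: s.onset)

    # blinks: Poisson over the recording, kept clear of injected saccades
    blink_ivs: list[tuple[float, float]] = []
    n_blinks = rng.poisson(profile.blink_rate * total / 60.0)
    for _ in range(n_blinks):
        for _attempt in range(20):
            b0 = rng.uniform(0.3, total - 0.5)
            b1 = b0 + rng.uniform(0.15, 0.30)
            clear = all(
                b1 < s.onset - 0.1 or b0 > s.onset + s.duration + 0.1 for s in saccades
            )
            if clear and all(b1 < c0 - 0.1 or b0 > c1 + 0.1 for c0, c1 in blink_ivs):
                blink_ivs.append((b0, b1))
                break
    blink_ivs.sort()

    # square-wave-jerk intrusions on fixation trials
    intrusion_saccades = 0
    analyzed_time = 0.0
    if task == Task.FIXATION and profile.intrusion_rate > 0:
        for w0, w1 in fixation_analysis:
            span = max(0.0, (w1 - 0.45) - (w0 + 0.05))
            analyzed_time += _window_time(w0, w1, blink_ivs)
            n_pairs = rng.poisson(profile.intrusion_rate * span)
            times = np.sort(rng.uniform(w0 + 0.05, w0 + 0.05 + span, size=n_pairs))
            last_end = -1.0
            for t_j in times:
                if t_j < last_end + 0.35:
                    continue
                if any(b0 - 0.15 < t_j < b1 + 0.40 for b0, b1 in blink_ivs):
                    continue
                amp = max(0.8, rng.normal(profile.intrusion_amp_mean, profile.intrusion_amp_sd))
                ang = rng.choice([0.0, math.pi])  # SWJs are predominantly horizontal
                dx, dy = amp * math.cos(ang), amp * math.sin(ang)
                base = _trial_position(saccades, t_j)
                out = _plan_saccade(t_j, base, (base[0] + dx, base[1] + dy), profile, "intrusion", -1)
                back = _plan_saccade(
                    t_j + 0.2, out.p1, base, profile, "intrusion", -1
                )
                saccades.append(out)
                saccades.append(back)
                intrusion_saccades += 2
                last_end = back.onset + back.duration
        saccades.sort(key=lambda s: s.onset)
    elif task == Task.FIXATION:
        for w0, w1 in fixation_analysis:
            analyzed_time += _window_time(w0, w1, blink_ivs)

    # render to the sample grid
    n = int(round(total * rate))
    t = np.arange(n) * dt
    x = np.empty(n)
    y = np.empty(n)
    pos = (0.0, 0.0)
    ti = 0.0
    idx = 0
    for s in saccades:
        i_on = np.searchsorted(t, s.onset)
        x[idx:i_on] = pos[0]
        y[idx:i_on] = pos[1]
        i_off = np.searchsorted(t, s.onset + s.duration)
        u = (t[i_on:i_off] - s.onset) / s.duration
        frac = u - np.sin(2 * math.pi * u) / (2 * math.pi)
        x[i_on:i_off] = s.p0[0] + frac * (s.p1[0] - s.p0[0])
        y[i_on:i_off] = s.p0[1] + frac * (s.p1[1] - s.p0[1])
        pos = s.p1
        idx = i_off
    x[idx:] = pos[0]
    y[idx:] = pos[1]

    if profile.fixation_noise_sd > 0:
        x += rng.normal(0, profile.fixation_noise_sd, n)
        y += rng.normal(0, profile.fixation_noise_sd, n)
    if profile.drift_sd > 0:
        x += _slow_drift(rng, n, profile.drift_sd)
        y += _slow_drift(rng, n, profile.drift_sd)
    np.clip(x, -59.9, 59.9, out=x)
    np.clip(y, -59.9, 59.9, out=y)

    valid = np.ones(n, dtype=bool)
    for b0, b1 in blink_ivs:
        valid &= ~((t >= b0) & (t <= b1))

    trial_id = np.zeros(n, dtype=int)
    for trial in schedule.trials:
        trial_id[t >= trial.fixation_onset] = trial.trial_id

    rec = GazeRecording(
        subject_id=subject_id,
        task=task,
        t=t,
        x=x,
        y=y,
        valid=valid,
        trial_id=trial_id,
        sample_rate=rate,
    )
    truth = {
        "saccades": [
            {
                "onset": s.onset,
                "duration": s.duration,
                "amplitude": math.hypot(s.p1[0] - s.p0[0], s.p1[1] - s.p0[1]),
                "peak_velocity": s.peak_velocity,
                "kind": s.kind,
                "trial_id": s.trial_id,
            }
            for s in saccades
        ],
        "blinks": blink_ivs,
        "trials": trial_truth,
        "intrusion_saccades": intrusion_saccades,
        "analyzed_fixation_time": analyzed_time,
    }
    return rec, truth


def _slow_drift(rng: np.random.Generator, n: int, sd: float) -> np.ndarray:
    """Low-frequency drift with the requested RMS (smoothed random walk)."""
    from scipy.ndimage import gaussian_filter1d

    w = gaussian_filter1d(rng.normal(0, 1, n), sigma=45, mode="reflect")
    rms = float(np.sqrt(np.mean(w**2)))
    return w * (sd / rms) if rms > 0 else w


def _window_time(w0: float, w1: float, blinks: list[tuple[float, float]]) -> float:
    """Window length minus blink overlap (with the 50 ms pads the
    artifact-removal step adds around each blink)."""
    loss = 0.0
    for b0, b1 in blinks:
        ov = min(w1, b1 + 0.05) - max(w0, b0 - 0.05)
        if ov > 0:
            loss += ov
    return max(0.0, (w1 - w0) - loss)


def _trial_position(saccades: list[_Saccade], when: float) -> tuple[float, float]:
    """Noise-free eye position at `when` implied by the saccades so far."""
    pos = (0.0, 0.0)
    end = -math.inf
    for s in saccades:
        s_end = s.onset + s.duration
        if s_end <= when and s_end > end:
            pos, end = s.p1, s_end
    return pos


def _return_to_center(
    saccades: list[_Saccade],
    rng: np.random.Generator,
    profile: SubjectProfile,
    trial: Trial,
    cur: tuple[float, float],
) -> tuple[float, float]:
    """Re-fixate the central point during the pre-target fixation period."""
    if math.hypot(*cur) <= 0.5:
        return cur
    fix_dur = trial.target_onset - trial.fixation_onset
    lat = min(_draw_latency(rng, profile.latency_mean, profile.latency_sd), fix_dur - 0.4)
    land = (rng.normal(0, 0.2), rng.normal(0, 0.2))
    sac = _plan_saccade(trial.fixation_onset + max(0.08, lat), cur, land, profile, "refixation", trial.trial_id)
    saccades.append(sac)
    return land


def _draw_subject_profile(
    base: SubjectProfile,
    variation: ProfileVariation,
    rng: np.random.Generator,
    severity_z: float = 0.0,
    coupling: bool = True,
) -> SubjectProfile:
    """Between-subject draw around a group profile, with severity coupling."""
    dev = {
        f.name: rng.normal(0.0, getattr(variation, f.name))
        for f in fields(ProfileVariation)
    }
    adj = dict(
        latency_mean=base.latency_mean + dev["latency_mean"],
        primary_gain_mean=base.primary_gain_mean + dev["primary_gain_mean"],
        multistep_prob=base.multistep_prob + dev["multistep_prob"],
        intrusion_rate=base.intrusion_rate + dev["intrusion_rate"],
        fixation_noise_sd=base.fixation_noise_sd + dev["fixation_noise_sd"],
        main_sequence_vmax=base.main_sequence_vmax + dev["main_sequence_vmax"],
        landing_scatter_sd=base.landing_scatter_sd + dev["landing_scatter_sd"],
        antisaccade_error_prob=base.antisaccade_error_prob + dev["antisaccade_error_prob"],
        recognition_prob=base.recognition_prob + dev["recognition_prob"],
    )
    if coupling and severity_z != 0.0:
        adj["latency_mean"] += 0.018 * severity_z
        adj["primary_gain_mean"] -= 0.030 * severity_z
        adj["landing_scatter_sd"] += 0.05 * severity_z
        adj["main_sequence_vmax"] -= 30.0 * severity_z
        adj["multistep_prob"] += 0.03 * severity_z
    adj["latency_mean"] = float(np.clip(adj["latency_mean"], 0.10, 0.45))
    adj["primary_gain_mean"] = float(np.clip(adj["primary_gain_mean"], 0.5, 1.2))
    adj["multistep_prob"] = float(np.clip(adj["multistep_prob"], 0.0, 0.6))
    adj["intrusion_rate"] = float(np.clip(adj["intrusion_rate"], 0.01, 1.0))
    adj["fixation_noise_sd"] = float(np.clip(adj["fixation_noise_sd"], 0.08, 0.8))
    adj["main_sequence_vmax"] = float(np.clip(adj["main_sequence_vmax"], 250.0, 800.0))
    adj["landing_scatter_sd"] = float(np.clip(adj["landing_scatter_sd"], 0.05, 1.0))
    adj["antisaccade_error_prob"] = float(np.clip(adj["antisaccade_error_prob"], 0.0, 0.9))
    adj["recognition_prob"] = float(np.clip(adj["recognition_prob"], 0.1, 1.0))
    return replace(base, **adj)


def _truth_parameters(truths: dict[Task, dict], count_mode: str = "saccade") -> dict[str, float]:
    """Realized ground-truth values on the canonical parameter grid."""
    params = {name: float("nan") for name in CANONICAL_PARAMETERS}
    if Task.FIXATION in truths:
        tr = truths[Task.FIXATION]
        if tr["analyzed_fixation_time"] > 0:
            count = tr["intrusion_saccades"]
            if count_mode == "pair":
                count /= 2.0
            params["fix_intrusion_rate"] = count / tr["analyzed_fixation_time"]
    if Task.PROSACCADE in truths:
        rows = pd.DataFrame(truths[Task.PROSACCADE]["trials"])
        for ecc in ("short", "large"):
            sub = rows[rows["eccentricity_class"] == ecc]
            if sub.empty:
                continue
            params[f"pro_{ecc}_latency"] = float(sub["latency"].mean())
            params[f"pro_{ecc}_first_gain"] = float(sub["first_gain"].mean())
            params[f"pro_{ecc}_first_gain_error"] = float(sub["first_gain_error"].mean())
            params[f"pro_{ecc}_peak_velocity"] = float(sub["peak_velocity"].mean())
            params[f"pro_{ecc}_mean_velocity"] = float(sub["mean_velocity"].mean())
            params[f"pro_{ecc}_n_saccades"] = float(sub["n_saccades"].mean())
            params[f"pro_{ecc}_time_to_target"] = float(sub["time_to_target"].mean())
    if Task.ANTISACCADE in truths:
        rows = pd.DataFrame(truths[Task.ANTISACCADE]["trials"])
        if not rows.empty:
            errors = rows[rows["is_error"]]
            correct = rows[~rows["is_error"]]
            params["anti_error_rate"] = float(rows["is_error"].mean())
            params["anti_corrected_rate"] = (
                float(errors["corrected"].mean()) if len(errors) else float("nan")
            )
            params["anti_recognition_rate"] = float(rows["recognized"].mean())
            params["anti_correct_latency"] = (
                float(correct["latency"].mean()) if len(correct) else float("nan")
            )
            params["anti_incorrect_latency"] = (
                float(errors["latency"].mean()) if len(errors) else float("nan")
            )
    return params


def synth_cohort(config: CohortConfig) -> tuple[dict, pd.DataFrame]:
    """Simulate a two-group cohort across all three tasks.

    Returns ``(subjects, truth_table)`` where ``subjects`` maps subject id
    to ``{"group", "age", "sex", "updrs3", "profile", "recordings",
    "schedules", "truth"}`` and ``truth_table`` is a DataFrame of realized
    generating values on the canonical parameter grid (NaN for parameters
    whose ground truth is not defined by the generator, e.g. BCEA).
    """
    root = np.random.SeedSequence(config.seed)
    rows = []
    subjects: dict[str, dict] = {}
    seeds = root.spawn(2 * config.n_per_group)
    i = 0
    for group, base, age_mu, age_sd in (
        ("HC", config.hc, config.hc_age_mean, config.hc_age_sd),
        ("PD", config.pd, config.pd_age_mean, config.pd_age_sd),
    ):
        for k in range(config.n_per_group):
            ss = seeds[i]
            i += 1
            rng = np.random.default_rng(ss)
            sid = f"{group}{k:03d}"
            age = float(np.clip(rng.normal(age_mu, age_sd), 45, 80))
            sex = "F" if rng.random() < (0.40 if group == "PD" else 0.50) else "M"
            if group == "PD":
                updrs = float(np.clip(rng.normal(config.updrs_mean, config.updrs_sd), 3, 108))
                sev_z = (updrs - config.updrs_mean) / config.updrs_sd
            else:
                updrs, sev_z = float("nan"), 0.0
            profile = _draw_subject_profile(
                base, config.variation, rng, sev_z, config.updrs_coupling
            )
            recordings, schedules, truths = {}, {}, {}
            task_seeds = ss.spawn(6)
            for j, task in enumerate((Task.FIXATION, Task.PROSACCADE, Task.ANTISACCADE)):
                sched_seed, gaze_seed = (
                    int(s.generate_state(1)[0] % (2**31))
                    for s in task_seeds[2 * j : 2 * j + 2]
                )
                sched = make_schedule(
                    task,
                    sched_seed,
                    n_antisaccade_trials=config.n_antisaccade_trials,
                    sample_rate=config.sample_rate,
                )
                rec, truth = synth_gaze(sched, profile, gaze_seed, subject_id=sid)
                recordings[task], schedules[task], truths[task] = rec, sched, truth
            subjects[sid] = {
                "group": group,
                "age": age,
                "sex": sex,
                "updrs3": updrs,
                "profile": profile,
                "recordings": recordings,
                "schedules": schedules,
                "truth": truths,
            }
            row = {
                "subject_id": sid,
                "group": group,
                "age": age,
                "sex": sex,
                "updrs3": updrs,
            }
            row.update(_truth_parameters(truths))
            rows.append(row)
    truth_table = pd.DataFrame(rows)
    return subjects, truth_table
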