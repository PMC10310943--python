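"""Shared builders and session-scoped cohort fixtures.

The trace builders here are deliberately independent of the package's own
simulator: detection tests inject motion with a raised-cosine profile built
inline, so the detector and the test signal share no code.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import oculokit as ok
from oculokit.types import GazeRecording, Task

RATE = 60.0
DT = 1.0 / RATE


def make_recording(
    x,
    y,
    task=Task.FIXATION,
    valid=None,
    trial_id=None,
    subject="s",
    sample_rate=RATE,
    t=None,
):
    x = np.asarray(x, dtype=float)
    n = x.size
    if t is None:
        t = np.arange(n) / sample_rate
    if valid is None:
        valid = np.ones(n, dtype=bool)
    if trial_id is None:
        trial_id = np.zeros(n, dtype=int)
    return GazeRecording(subject, task, t, x, np.asarray(y, dtype=float), valid, trial_id, sample_rate)


def raised_cosine_step(t, onset, amplitude, duration):
    """Position profile of a saccade: smooth step of `amplitude` deg.

    x(u) = A*(u - sin(2*pi*u)/(2*pi)) for u in [0, 1]; peak velocity 2A/D.
    """
    u = np.clip((np.asarray(t) - onset) / duration, 0.0, 1.0)
    return amplitude * (u - np.sin(2.0 * np.pi * u) / (2.0 * np.pi))


def saccade_trace(
    amplitude,
    onset,
    duration=None,
    total_s=4.0,
    noise_sd=0.0,
    seed=0,
    angle=0.0,
    task=Task.PROSACCADE,
):
    """One saccade of known amplitude/onset embedded in Gaussian noise."""
    if duration is None:
        vp = 500.0 * (1.0 - np.exp(-amplitude / 5.0))
        duration = max(0.015, 2.0 * amplitude / vp)
    rng = np.random.default_rng(seed)
    n = int(round(total_s * RATE))
    t = np.arange(n) * DT
    step = raised_cosine_step(t, onset, amplitude, duration)
    x = step * np.cos(angle) + rng.normal(0.0, noise_sd, n)
    y = step * np.sin(angle) + rng.normal(0.0, noise_sd, n)
    return make_recording(x, y, task=task), onset, onset + duration


@pytest.fixture(scope="session")
def cohort50():
    """50 subjects per group with ground truth and extracted parameters.

    Shared by the recovery acceptance test, the classifier band test, and
    the statistics smoke tests; built once per session (~10 s).
    """
    from oculokit.cli import RunConfig, _extract_cohort

    subjects, truth = ok.synth_cohort(ok.CohortConfig(n_per_group=50, seed=7))
    rows, qc = _extract_cohort(subjects, RunConfig())
    est = pd.DataFrame(
        [
            {
                "subject_id": r.subject_id,
                "group": r.group,
                "age": r.age,
                "sex": r.sex,
                "updrs3": np.nan if r.updrs3 is None else r.updrs3,
                **r.parameters,
            }
            for r in rows
        ]
    )
    return {"subjects": subjects, "truth": truth, "estimates": est, "qc": qc}


@pytest.fixture(scope="session")
def small_cohort():
    """Small raw cohort (4/group) for structural simulator tests."""
    subjects, truth = ok.synth_cohort(ok.CohortConfig(n_per_group=4, seed=3))
    return subjects, truth
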