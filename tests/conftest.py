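"""Shared fixtures: one synthetic reference trial and its pipeline results.

Expensive artifacts (trial synthesis, preprocessing, the three pipeline
runs) are session-scoped so the whole suite pays for them once.
"""
from __future__ import annotations

import pytest

from liftsim import (BoxSpec, TaskConfig, build_model, preprocess_trial,
                     run_pipeline, synthesize_trial)
from liftsim.metrics import detect_grip_events, phases_from_events

ANTHRO = {"body_mass": 75.16, "stature": 1.74}


@pytest.fixture(scope="session")
def anthro():
    return dict(ANTHRO)


@pytest.fixture(scope="session")
def box():
    return BoxSpec()


@pytest.fixture(scope="session")
def task():
    # one lift+lower cycle, 0.3 s grip ramps, no marker noise
    return TaskConfig(n_repetitions=1, grip_ramp_duration=0.3, marker_noise_sd=0.0)


@pytest.fixture(scope="session")
def model(anthro):
    return build_model(anthro)


@pytest.fixture(scope="session")
def trial(task, box, anthro):
    return synthesize_trial(task, box, anthro, seed=1)


@pytest.fixture(scope="session")
def proc(trial):
    return preprocess_trial(trial)


@pytest.fixture(scope="session")
def phases(proc, box):
    events = detect_grip_events(proc.markers, box)
    return phases_from_events(events, proc.markers, box)


@pytest.fixture(scope="session")
def results(proc, model, phases):
    """Pipeline results for all three hand-load modeling approaches."""
    return {app: run_pipeline(proc, model, app, phases=phases)
            for app in ("APP1", "APP2", "APP3")}
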