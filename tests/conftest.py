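import numpy as np
import pytest

from microstim.datamodel import SessionRecording, TrialRecord
from microstim.synth import SyntheticConfig, generate_experiment


def make_trial(
    index,
    pulse_count,
    choice="left",
    outcome=None,
    rewarded=None,
    first_lick_time=1.5,
    shutter_close_frame=10,
    shutter_open_frame=12,
):
    """Build a consistent TrialRecord with minimal boilerplate."""
    bins = np.zeros(9, dtype=bool)
    bins[:pulse_count] = True
    if rewarded is None:
        rewarded = (
            "either" if pulse_count == 5 else ("right" if pulse_count in (7, 9) else "left")
        )
    if outcome is None:
        if choice == "none":
            outcome = "ignore"
        elif rewarded == "either":
            outcome = "correct"
        else:
            outcome = "correct" if choice == rewarded else "incorrect"
    return TrialRecord(
        trial_index=index,
        pulse_count=pulse_count,
        pulse_bins=bins,
        rewarded_side=rewarded,
        choice=choice,
        outcome=outcome,
        first_lick_time=first_lick_time,
        shutter_close_frame=shutter_close_frame,
        shutter_open_frame=shutter_open_frame,
    )


def make_session(
    n_neurons=3,
    n_trials=4,
    pre=6,
    closed=2,
    post=4,
    pulse_counts=None,
    choices=None,
    dff=None,
    frame_rate=7.0,
    first_lick_time=1.5,
):
    """Session with a regular trial grid; dff defaults to zeros."""
    fpt = pre + closed + post
    n_frames = n_trials * fpt
    if dff is None:
        dff = np.zeros((n_neurons, n_frames))
    if pulse_counts is None:
        pulse_counts = [9] * n_trials
    if choices is None:
        choices = ["left"] * n_trials
    trials = [
        make_trial(
            t,
            pulse_counts[t],
            choice=choices[t],
            first_lick_time=first_lick_time,
            shutter_close_frame=t * fpt + pre,
            shutter_open_frame=t * fpt + pre + closed,
        )
        for t in range(n_trials)
    ]
    s = SessionRecording(
        session_day=1,
        dff=dff,
        frame_rate=frame_rate,
        trials=trials,
        neuron_ids=[f"n{k:04d}" for k in range(n_neurons)],
        task_stage="full",
    )
    s.validate()
    return s


@pytest.fixture(scope="session")
def tiny_config():
    return SyntheticConfig(
        n_expressing=10,
        n_non_expressing=20,
        n_ambiguous=2,
        n_sessions=3,
        trials_per_session=30,
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_experiment(tiny_config):
    return generate_experiment(tiny_config, seed=7)
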