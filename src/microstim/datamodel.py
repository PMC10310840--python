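"""Shared data model for trial-structured microstimulation imaging experiments.

The objects here mirror how chronic two-photon experiments are organised in
practice: an :class:`Experiment` holds one :class:`SessionRecording` per
training day, each with a dense ΔF/F matrix (neurons x frames), a list of
:class:`TrialRecord` behavioral trials, and per-neuron metadata
(:class:`NeuronMeta`) that is stable across days via string neuron ids.

Conventions
-----------
* Frame indices are 0-based and windows are half-open; the frame at
  ``shutter_open_frame`` is the first post-reopen frame.
* Times are in seconds; ``first_lick_time`` is measured from shutter closure
  (~stimulus-epoch onset).
* Training days (``session_day``) are 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

PULSE_COUNTS = (0, 1, 3, 5, 7, 9)
N_PULSE_BINS = 9

TASK_STAGES = ("detect_0v9", "disc_1v9", "disc_13v79", "full")

#: pulse counts available in each task stage (left side low, right side high)
STAGE_COUNTS = {
    "detect_0v9": (0, 9),
    "disc_1v9": (1, 9),
    "disc_13v79": (1, 3, 7, 9),
    "full": (1, 3, 5, 7, 9),
}

OPSIN_CLASSES = ("expressing", "non_expressing", "ambiguous")


class InvalidInputError(ValueError):
    """Raised when an input violates a documented precondition."""


def classify_opsin(
    redness: float,
    red_pixel_fraction: float,
    hi_thresholds: Tuple[float, float] = (0.5, 0.25),
    lo_thresholds: Tuple[float, float] = (0.2, 0.1),
) -> str:
    """Classify a neuron's opsin expression from red-channel statistics.

    A neuron is ``expressing`` when both its mean demixed redness and its
    fraction of supra-noise red pixels reach the upper thresholds,
    ``non_expressing`` when both fall at or below the lower thresholds, and
    ``ambiguous`` otherwise.  Ambiguous neurons are excluded from downstream
    analyses.

    Parameters
    ----------
    redness : float
        Mean demixed red pixel intensity (a.u., >= 0).
    red_pixel_fraction : float
        Fraction of pixels exceeding the red noise threshold, in [0, 1].
    hi_thresholds, lo_thresholds : (float, float)
        (redness, fraction) threshold pairs; ``lo <= hi`` elementwise.
    """
    if redness < 0:
        raise InvalidInputError(f"redness must be >= 0, got {redness}")
    if not 0.0 <= red_pixel_fraction <= 1.0:
        raise InvalidInputError(
            f"red_pixel_fraction must be in [0, 1], got {red_pixel_fraction}"
        )
    if lo_thresholds[0] > hi_thresholds[0] or lo_thresholds[1] > hi_thresholds[1]:
        raise InvalidInputError("lo_thresholds must be elementwise <= hi_thresholds")
    if redness >= hi_thresholds[0] and red_pixel_fraction >= hi_thresholds[1]:
        return "expressing"
    if redness <= lo_thresholds[0] and red_pixel_fraction <= lo_thresholds[1]:
        return "non_expressing"
    return "ambiguous"


def demix_red(
    red_pixels: np.ndarray, green_pixels: np.ndarray, bleed_coefficient: float
) -> np.ndarray:
    """Linearly demix green bleed-through from a red pixel vector.

    Returns ``max(red - bleed_coefficient * green, 0)`` elementwise.
    """
    red = np.asarray(red_pixels, dtype=float)
    green = np.asarray(green_pixels, dtype=float)
    if red.shape != green.shape:
        raise InvalidInputError(
            f"red and green pixel vectors differ in shape: {red.shape} vs {green.shape}"
        )
    if bleed_coefficient < 0:
        raise InvalidInputError("bleed_coefficient must be >= 0")
    return np.maximum(red - bleed_coefficient * green, 0.0)


@dataclass
class TrialRecord:
    """One behavioral trial.

    ``pulse_bins`` is the 9-bin (5 ms, 20 Hz) occupancy pattern of the LED
    pulses; ``sum(pulse_bins) == pulse_count`` for counts <= 9.  5-pulse
    trials are rewarded on a randomly drawn side and carry
    ``rewarded_side == 'either'``.
    """

    trial_index: int
    pulse_count: int
    pulse_bins: np.ndarray
    rewarded_side: str  # left | right | either
    choice: str  # left | right | none
    outcome: str  # correct | incorrect | ignore
    first_lick_time: Optional[float]  # s from shutter closure; None if no lick
    shutter_close_frame: int
    shutter_open_frame: int

    def __post_init__(self) -> None:
        self.pulse_bins = np.asarray(self.pulse_bins, dtype=bool)

    def validate(self) -> None:
        if self.pulse_count not in range(0, N_PULSE_BINS + 1):
            raise InvalidInputError(f"pulse_count out of range: {self.pulse_count}")
        if self.pulse_bins.shape != (N_PULSE_BINS,):
            raise InvalidInputError("pulse_bins must have 9 entries")
        if int(self.pulse_bins.sum()) != self.pulse_count:
            raise InvalidInputError(
                f"pulse_bins sum {int(self.pulse_bins.sum())} != pulse_count "
                f"{self.pulse_count}"
            )
        if self.rewarded_side not in ("left", "right", "either"):
            raise InvalidInputError(f"bad rewarded_side: {self.rewarded_side}")
        if self.pulse_count == 5 and self.rewarded_side != "either":
            raise InvalidInputError("5-pulse trials must have rewarded_side 'either'")
        if self.choice not in ("left", "right", "none"):
            raise InvalidInputError(f"bad choice: {self.choice}")
        if self.outcome not in ("correct", "incorrect", "ignore"):
            raise InvalidInputError(f"bad outcome: {self.outcome}")
        if not self.shutter_close_frame < self.shutter_open_frame:
            raise InvalidInputError("shutter_close_frame must precede shutter_open_frame")


@dataclass
class NeuronMeta:
    """Per-neuron metadata; ``neuron_id`` is stable across sessions."""

    neuron_id: str
    plane: int
    xy: Tuple[float, float]  # micrometers within plane
    redness: float
    red_pixel_fraction: float
    opsin_class: str

    def validate(self) -> None:
        if self.opsin_class not in OPSIN_CLASSES:
            raise InvalidInputError(f"bad opsin_class: {self.opsin_class}")


@dataclass
class SessionRecording:
    """One session's ΔF/F matrix plus its trial list and neuron ordering."""

    session_day: int  # 1-based training day
    dff: np.ndarray  # neurons x frames
    frame_rate: float  # Hz
    trials: List[TrialRecord]
    neuron_ids: List[str]
    task_stage: str = "full"

    @property
    def n_neurons(self) -> int:
        return self.dff.shape[0]

    @property
    def n_frames(self) -> int:
        return self.dff.shape[1]

    def validate(self) -> None:
        if self.task_stage not in TASK_STAGES:
            raise InvalidInputError(f"bad task_stage: {self.task_stage}")
        if len(self.neuron_ids) != self.n_neurons:
            raise InvalidInputError("neuron_ids length must match dff rows")
        if len(set(self.neuron_ids)) != len(self.neuron_ids):
            raise InvalidInputError("neuron_ids must be unique")
        for tr in self.trials:
            tr.validate()
            if not (0 <= tr.shutter_close_frame < self.n_frames):
                raise InvalidInputError("trial shutter_close_frame out of bounds")
            if not (0 <= tr.shutter_open_frame < self.n_frames):
                raise InvalidInputError("trial shutter_open_frame out of bounds")

    def row_index(self) -> Dict[str, int]:
        return {nid: i for i, nid in enumerate(self.neuron_ids)}


@dataclass
class Experiment:
    """A subject's full training series: sessions ordered by training day.

    ``neurons`` maps neuron_id -> :class:`NeuronMeta`.  A neuron may be
    absent from a given session (chronic tracking loses cells); alignment is
    implicit through each session's ``neuron_ids``.
    """

    subject_id: str
    sessions: List[SessionRecording]
    neurons: Dict[str, NeuronMeta] = field(default_factory=dict)

    def validate(self) -> None:
        days = [s.session_day for s in self.sessions]
        if any(b <= a for a, b in zip(days, days[1:])):
            raise InvalidInputError("session_days must be strictly increasing")
        for s in self.sessions:
            s.validate()
        for meta in self.neurons.values():
            meta.validate()

    def session_days(self) -> List[int]:
        return [s.session_day for s in self.sessions]

    def neuron_ids_of_class(self, opsin_class: str) -> List[str]:
        """Ids of neurons in an opsin class, in insertion order.

        Ambiguous neurons never appear in analysis selections unless
        explicitly requested by ``opsin_class='ambiguous'``.
        """
        if opsin_class not in OPSIN_CLASSES:
            raise InvalidInputError(f"bad opsin_class: {opsin_class}")
        return [nid for nid, m in self.neurons.items() if m.opsin_class == opsin_class]

    def alignment_map(self) -> Dict[str, Dict[int, int]]:
        """neuron_id -> {session_day -> row index}; absent days omitted."""
        out: Dict[str, Dict[int, int]] = {nid: {} for nid in self.neurons}
        for s in self.sessions:
            for i, nid in enumerate(s.neuron_ids):
                out.setdefault(nid, {})[s.session_day] = i
        return out


def evoked_window_end_time(trial: TrialRecord, frame_rate: float, n_frames: int = 2) -> float:
    """End of the evoked window in seconds from shutter closure.

    Used to enforce the restriction that evoked activity precedes the first
    lick: a trial is dropped from choice analyses when its first lick falls
    before this time.
    """
    return (trial.shutter_open_frame + n_frames - trial.shutter_close_frame) / frame_rate
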