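"""Choice-conditioned comparison of evoked activity.

If an animal solves the pulse-count task by thresholding evoked activity,
then for a fixed pulse count trials where it licked right ("more
stimulation") should carry more evoked ΔF/F than trials where it licked
left.  These analyses compare left- vs right-choice evoked responses per
neuron and at the population level (strongly responsive neurons, response
probability > 0.25), with the evoked window required to precede the first
lick.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import ttest_ind, ttest_rel

from .datamodel import Experiment, SessionRecording, evoked_window_end_time
from .responsiveness import ResponseTensor, compute_response_tensor, response_probability

STRONG_RESPONSE_PROB = 0.25


def _usable_trial_mask(session: SessionRecording, tensor: ResponseTensor) -> np.ndarray:
    """Directional-choice trials whose evoked window precedes the first lick."""
    mask = np.zeros(tensor.trial_indices.size, dtype=bool)
    for row, t in enumerate(tensor.trial_indices):
        tr = session.trials[t]
        if tr.choice not in ("left", "right"):
            continue
        if tr.first_lick_time is not None:
            end = evoked_window_end_time(tr, session.frame_rate)
            if tr.first_lick_time < end:
                continue
        mask[row] = True
    return mask


def split_by_choice(
    session: SessionRecording,
    tensor: ResponseTensor,
    pulse_count: int,
    enforce_pre_lick: bool = True,
) -> Tuple[np.ndarray, np.ndarray]:
    """Left/right evoked sample sets (trials x neurons) for one pulse count.

    Trials without a directional choice, and trials whose first lick
    precedes the end of the evoked window, are dropped.
    """
    usable = (
        _usable_trial_mask(session, tensor)
        if enforce_pre_lick
        else np.array([session.trials[t].choice in ("left", "right") for t in tensor.trial_indices])
    )
    cmask = tensor.pulse_counts == pulse_count
    choices = np.array([session.trials[t].choice for t in tensor.trial_indices], dtype=object)
    left = tensor.evoked[usable & cmask & (choices == "left")]
    right = tensor.evoked[usable & cmask & (choices == "right")]
    return left, right


def neuron_choice_test(left_samples: np.ndarray, right_samples: np.ndarray) -> Tuple[float, float]:
    """Welch two-sided t-test of right vs left evoked samples for one neuron.

    Returns ``(t, p)``; ``(nan, nan)`` with fewer than 2 samples per side;
    ``(0, 1)`` when both sides are a single exact tie of constant values.
    """
    l = np.asarray(left_samples, dtype=float)
    r = np.asarray(right_samples, dtype=float)
    if l.size < 2 or r.size < 2:
        return float("nan"), float("nan")
    if np.ptp(l) == 0 and np.ptp(r) == 0:
        return (0.0, 1.0) if l[0] == r[0] else (float("inf"), 0.0)
    t, p = ttest_ind(r, l, equal_var=False)
    return float(t), float(p)


def choice_test_table(
    session: SessionRecording,
    tensor: ResponseTensor,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-neuron choice-predictiveness across pulse counts.

    One row per (neuron, pulse count) with the Welch test, plus a
    ``predictive_category`` per neuron: ``all_counts`` (significant at every
    testable count), ``some_counts`` or ``no_counts``.
    """
    counts = sorted(set(tensor.pulse_counts.tolist()))
    rows = []
    sig: Dict[str, List[Optional[bool]]] = {nid: [] for nid in tensor.neuron_ids}
    for count in counts:
        left, right = split_by_choice(session, tensor, count)
        for j, nid in enumerate(tensor.neuron_ids):
            t, p = neuron_choice_test(left[:, j] if left.size else left.reshape(0),
                                      right[:, j] if right.size else right.reshape(0))
            rows.append(
                {
                    "session_day": session.session_day,
                    "neuron_id": nid,
                    "pulse_count": count,
                    "n_left": int(left.shape[0]),
                    "n_right": int(right.shape[0]),
                    "t": t,
                    "p": p,
                }
            )
            sig[nid].append(None if np.isnan(p) else bool(p < alpha))
    df = pd.DataFrame(rows)
    cat = {}
    for nid, flags in sig.items():
        tested = [f for f in flags if f is not None]
        if not tested:
            cat[nid] = "untested"
        elif all(tested):
            cat[nid] = "all_counts"
        elif any(tested):
            cat[nid] = "some_counts"
        else:
            cat[nid] = "no_counts"
    df["predictive_category"] = df["neuron_id"].map(cat)
    return df


@dataclass
class PopulationChoiceCurve:
    """Per-subject peak-normalized mean evoked ΔF/F per (pulse count, choice)."""

    subject_id: str
    opsin_class: str
    pulse_counts: List[int]
    left: np.ndarray  # normalized means, NaN where undefined
    right: np.ndarray
    n_neurons: int


def subject_choice_curve(
    experiment: Experiment,
    opsin_class: str,
    session_days: Optional[Sequence[int]] = None,
    strong_prob: float = STRONG_RESPONSE_PROB,
    baseline_mode: str = "matched",
    tensors: Optional[Dict[int, ResponseTensor]] = None,
) -> Optional[PopulationChoiceCurve]:
    """Peak-normalized choice curve for one subject and opsin class.

    Pools final-stage sessions (or ``session_days``).  For each session the
    strongly responsive gate (response probability > ``strong_prob`` over
    all trials) selects neurons of the class; per (count, choice) the mean
    evoked ΔF/F over those neurons and trials is averaged across sessions,
    then normalized by the subject's maximum of the across-choice mean
    curve.  Returns None when no session qualifies.
    """
    class_ids = set(experiment.neuron_ids_of_class(opsin_class))
    sessions = [
        s
        for s in experiment.sessions
        if (session_days is None and s.task_stage == "full")
        or (session_days is not None and s.session_day in session_days)
    ]
    if not sessions:
        return None
    per_session: List[Dict[Tuple[int, str], float]] = []
    counts_seen = set()
    for s in sessions:
        tensor = (
            tensors[s.session_day]
            if tensors is not None and s.session_day in tensors
            else compute_response_tensor(s, baseline_mode=baseline_mode)
        )
        prob = response_probability(tensor)
        cols = np.array(
            [j for j, nid in enumerate(tensor.neuron_ids) if nid in class_ids and prob[j] > strong_prob],
            dtype=int,
        )
        if cols.size == 0:
            continue
        entry: Dict[Tuple[int, str], float] = {}
        for count in sorted(set(tensor.pulse_counts.tolist())):
            left, right = split_by_choice(s, tensor, count)
            if left.shape[0] > 0:
                entry[(count, "left")] = float(left[:, cols].mean())
            if right.shape[0] > 0:
                entry[(count, "right")] = float(right[:, cols].mean())
            counts_seen.add(count)
        per_session.append(entry)
    if not per_session or not counts_seen:
        return None
    counts = sorted(counts_seen)
    left = np.full(len(counts), np.nan)
    right = np.full(len(counts), np.nan)
    for i, c in enumerate(counts):
        lv = [e[(c, "left")] for e in per_session if (c, "left") in e]
        rv = [e[(c, "right")] for e in per_session if (c, "right") in e]
        if lv:
            left[i] = np.mean(lv)
        if rv:
            right[i] = np.mean(rv)
    # normalize by the subject's max of the across-choice mean curve
    with np.errstate(invalid="ignore"):
        combined = np.nanmean(np.stack([left, right]), axis=0)
    peak = np.nanmax(combined)
    if not np.isfinite(peak) or peak == 0:
        return None
    return PopulationChoiceCurve(
        subject_id=experiment.subject_id,
        opsin_class=opsin_class,
        pulse_counts=counts,
        left=left / peak,
        right=right / peak,
        n_neurons=-1,
    )


@dataclass
class PopulationChoiceResult:
    curves: List[PopulationChoiceCurve]
    mean_right_minus_left: Dict[str, float]  # per subject
    t_statistic: float
    p_value: float
    n_subjects: int
    descriptive_only: bool


def population_choice_curve(
    experiments: Sequence[Experiment],
    opsin_class: str,
    session_days: Optional[Sequence[int]] = None,
    strong_prob: float = STRONG_RESPONSE_PROB,
    baseline_mode: str = "matched",
) -> PopulationChoiceResult:
    """Across-subject paired test of right- vs left-choice evoked activity.

    Each subject contributes its peak-normalized curve; the paired
    two-sided t-test compares the per-subject mean (across pulse counts) of
    the right curve against the left curve.  With fewer than 2 usable
    subjects the result is descriptive only.
    """
    curves = []
    diffs: Dict[str, float] = {}
    rights, lefts = [], []
    for exp in experiments:
        c = subject_choice_curve(
            exp, opsin_class, session_days=session_days, strong_prob=strong_prob,
            baseline_mode=baseline_mode,
        )
        if c is None:
            continue
        both = np.isfinite(c.left) & np.isfinite(c.right)
        if not np.any(both):
            continue
        curves.append(c)
        r = float(np.mean(c.right[both]))
        l = float(np.mean(c.left[both]))
        rights.append(r)
        lefts.append(l)
        diffs[c.subject_id] = r - l
    n = len(rights)
    if n < 2:
        return PopulationChoiceResult(curves, diffs, float("nan"), float("nan"), n, True)
    t, p = ttest_rel(rights, lefts)
    return PopulationChoiceResult(curves, diffs, float(t), float(p), n, False)
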