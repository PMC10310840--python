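"""Behavioral performance metrics and task-schedule utilities.

The task is a two-lickport pulse-count discrimination: high pulse counts
(7, 9) are rewarded on the right, low counts (0, 1, 3) on the left, and
5-pulse trials are rewarded on a randomly drawn side.  Performance is
tracked with a sliding 61-trial window over which percent correct and
d-prime are computed; the learning criterion is a peak windowed d' >= 1.5
sustained across sessions.

d' convention: ``d' = z(hit rate) - z(false-alarm rate)`` where a hit is a
right response on a high trial and a false alarm a right response on a low
trial.  Rates are clipped to ``[1/(2n), 1 - 1/(2n)]`` per trial class (n =
trials of that class in the window) before the normal quantile, so d' is
always finite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.proportion import proportion_confint

from .datamodel import InvalidInputError, N_PULSE_BINS, TrialRecord

HIGH_COUNTS = (7, 9)
LOW_COUNTS = (0, 1, 3)

DEFAULT_WINDOW = 61
DEFAULT_CRITERION_DPRIME = 1.5
DEFAULT_HORIZON_SESSIONS = 8


def permute_pulses(pulse_count: int, rng) -> np.ndarray:
    """Draw a uniformly random 9-bin pulse pattern with ``pulse_count`` bins set.

    Every one of the C(9, k) patterns is equally likely, mirroring the random
    placement of 5-ms pulses among the nine 20-Hz time bins.

    Parameters
    ----------
    pulse_count : int
        Number of occupied bins, 0..9.
    rng : numpy.random.Generator or int
        Random generator or seed.
    """
    if not 0 <= pulse_count <= N_PULSE_BINS:
        raise InvalidInputError(f"pulse_count must be in [0, 9], got {pulse_count}")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    bins = np.zeros(N_PULSE_BINS, dtype=bool)
    occupied = rng.choice(N_PULSE_BINS, size=pulse_count, replace=False)
    bins[occupied] = True
    return bins


def clipped_rate(k: int, n: int) -> float:
    """Response rate k/n clipped to [1/(2n), 1 - 1/(2n)] (n >= 1)."""
    if n < 1:
        raise InvalidInputError("rate undefined for empty trial class")
    lo = 1.0 / (2.0 * n)
    return float(min(max(k / n, lo), 1.0 - lo))


def dprime(n_hit: int, n_high: int, n_fa: int, n_low: int) -> float:
    """d' from hit/false-alarm counts with the 1/(2n) clipping rule.

    ``d' = z(hit rate) - z(false-alarm rate)``; each rate is clipped within
    its own class size before the normal quantile, bounding |d'| by
    ``2 z(1 - 1/(2n))``.
    """
    hr = clipped_rate(n_hit, n_high)
    fa = clipped_rate(n_fa, n_low)
    return float(norm.ppf(hr) - norm.ppf(fa))


def _included_for_metrics(trials: Sequence[TrialRecord]) -> List[TrialRecord]:
    """Trials entering rolling metrics: directional choice, defined correct side.

    Ignore/no-response trials and 5-pulse trials (no defined correct side)
    are excluded from both percent-correct and d'.
    """
    return [
        t
        for t in trials
        if t.choice in ("left", "right") and t.pulse_count != 5
    ]


@dataclass
class RollingMetrics:
    """Per-center rolling percent-correct and d' series over included trials."""

    centers: np.ndarray  # indices into the included-trial sequence
    trial_indices: np.ndarray  # original trial_index of each center trial
    percent_correct: np.ndarray  # in [0, 100]
    dprime: np.ndarray  # NaN where a window lacks one trial class
    window: int

    @property
    def peak_dprime(self) -> float:
        """Max windowed d' (NaN if no window had both classes)."""
        if self.dprime.size == 0 or np.all(np.isnan(self.dprime)):
            return float("nan")
        return float(np.nanmax(self.dprime))


def rolling_metrics(trials: Sequence[TrialRecord], window: int = DEFAULT_WINDOW) -> RollingMetrics:
    """Centered sliding-window percent-correct and d' over a trial sequence.

    Ignore and 5-pulse trials are removed first; the window then slides over
    the remaining time-ordered trials.  Centers without a full window are
    omitted; if fewer than ``window`` trials remain in total, the single
    full-sequence window is used (centered).  A window containing only one
    trial class yields d' = NaN at that center (percent correct is still
    defined).
    """
    if window % 2 != 1:
        raise InvalidInputError("window must be odd")
    inc = _included_for_metrics(trials)
    n = len(inc)
    if n == 0:
        return RollingMetrics(
            centers=np.array([], dtype=int),
            trial_indices=np.array([], dtype=int),
            percent_correct=np.array([]),
            dprime=np.array([]),
            window=window,
        )
    is_high = np.array([t.pulse_count in HIGH_COUNTS for t in inc])
    went_right = np.array([t.choice == "right" for t in inc])
    correct = np.array([t.outcome == "correct" for t in inc])

    if n < window:
        centers = np.array([n // 2], dtype=int)
        spans = [(0, n)]
    else:
        half = window // 2
        centers = np.arange(half, n - half, dtype=int)
        spans = [(c - half, c + half + 1) for c in centers]

    pc = np.empty(len(centers))
    dp = np.empty(len(centers))
    for j, (a, b) in enumerate(spans):
        hi = is_high[a:b]
        rt = went_right[a:b]
        pc[j] = 100.0 * correct[a:b].mean()
        n_high = int(hi.sum())
        n_low = int((~hi).sum())
        if n_high == 0 or n_low == 0:
            dp[j] = np.nan
        else:
            dp[j] = dprime(int(rt[hi].sum()), n_high, int(rt[~hi].sum()), n_low)
    return RollingMetrics(
        centers=centers,
        trial_indices=np.array([inc[c].trial_index for c in centers], dtype=int),
        percent_correct=pc,
        dprime=dp,
        window=window,
    )


def session_peak_dprime(trials: Sequence[TrialRecord], window: int = DEFAULT_WINDOW) -> float:
    """Peak windowed d' of one session (the per-session learning statistic)."""
    return rolling_metrics(trials, window=window).peak_dprime


def classify_learner(
    session_peaks: Sequence[float],
    criterion_dprime: float = DEFAULT_CRITERION_DPRIME,
    horizon_sessions: int = DEFAULT_HORIZON_SESSIONS,
    consecutive: bool = True,
) -> bool:
    """Learner classification from per-session peak d' values.

    A subject is a learner iff, within the first ``horizon_sessions``
    sessions, at least two (by default consecutive) sessions reach
    ``criterion_dprime`` AND the horizon session itself still meets the
    criterion (performance has not regressed).  With fewer sessions than the
    horizon, the last available session stands in for the horizon session.

    ``consecutive=False`` relaxes the first clause to any two sessions.
    """
    peaks = np.asarray([p for p in session_peaks], dtype=float)
    if peaks.size == 0:
        raise InvalidInputError("need at least one session")
    horizon = min(horizon_sessions, peaks.size)
    within = peaks[:horizon]
    meets = np.nan_to_num(within, nan=-np.inf) >= criterion_dprime
    if consecutive:
        two = bool(np.any(meets[:-1] & meets[1:])) if meets.size >= 2 else False
    else:
        two = int(meets.sum()) >= 2
    sustained = bool(meets[horizon - 1])
    return two and sustained


def psychometric(trials: Sequence[TrialRecord]) -> pd.DataFrame:
    """P(lick right) per pulse count with Wilson binomial intervals.

    Only trials with a directional choice are used; counts with zero such
    trials are omitted.
    """
    rows = []
    chosen = [t for t in trials if t.choice in ("left", "right")]
    for count in sorted({t.pulse_count for t in chosen}):
        sub = [t for t in chosen if t.pulse_count == count]
        k = sum(t.choice == "right" for t in sub)
        n = len(sub)
        lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
        rows.append(
            {
                "pulse_count": count,
                "n_trials": n,
                "p_right": k / n,
                "ci_low": float(lo),
                "ci_high": float(hi),
            }
        )
    return pd.DataFrame(rows, columns=["pulse_count", "n_trials", "p_right", "ci_low", "ci_high"])


def fit_choice_slope(trials: Sequence[TrialRecord]) -> Tuple[float, float]:
    """Fit a logistic of right-choice on signed stimulus strength.

    Stimulus strength is ``(pulse_count - 4.5) / 4.5`` in [-1, 1].  Returns
    (slope, standard error); used for parameter-recovery checks against the
    generator's choice model.
    """
    import statsmodels.api as sm

    chosen = [t for t in trials if t.choice in ("left", "right")]
    if len(chosen) < 10:
        raise InvalidInputError("too few trials for a logistic fit")
    x = np.array([(t.pulse_count - 4.5) / 4.5 for t in chosen])
    y = np.array([t.choice == "right" for t in chosen], dtype=float)
    X = sm.add_constant(x)
    res = sm.Logit(y, X).fit(disp=0)
    return float(res.params[1]), float(res.bse[1])


@dataclass
class BehaviorSummary:
    """Per-session behavioral summary for one subject."""

    session_day: int
    n_trials: int
    n_included: int
    percent_correct: float
    peak_dprime: float
    task_stage: str


def summarize_behavior(experiment, window: int = DEFAULT_WINDOW) -> pd.DataFrame:
    """Behavior summary table (one row per session) for an experiment."""
    rows = []
    for s in experiment.sessions:
        rm = rolling_metrics(s.trials, window=window)
        inc = _included_for_metrics(s.trials)
        correct = [t.outcome == "correct" for t in inc]
        rows.append(
            {
                "subject_id": experiment.subject_id,
                "session_day": s.session_day,
                "n_trials": len(s.trials),
                "n_included": len(inc),
                "percent_correct": 100.0 * np.mean(correct) if inc else np.nan,
                "peak_dprime": rm.peak_dprime,
                "task_stage": s.task_stage,
            }
        )
    return pd.DataFrame(rows)
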