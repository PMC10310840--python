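"""Within-session and cross-session representational stability.

Within a session, each 9-pulse trial yields a population response vector
(evoked ΔF/F per included neuron); the Pearson correlation between all
trial pairs gives an inter-trial correlation matrix whose mean strict
upper triangle summarises within-day stability.  Across sessions, the
per-day mean evoked vector gives a day-pair correlation matrix from which
"days until R² < 0.5" — the first day lag at which the squared
correlation can no longer account for half the variance — measures drift.
R² here is the square of the Pearson correlation between the two vectors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .datamodel import Experiment, InvalidInputError, SessionRecording
from .responsiveness import ResponseTensor, compute_response_tensor, compare_groups, GroupComparison

MIN_CROSS_DAY_OVERLAP = 10


def trial_vectors(
    session: SessionRecording,
    tensor: ResponseTensor,
    pulse_count: int = 9,
    inclusion: str = "ever_responsive",
    neuron_ids: Optional[Sequence[str]] = None,
) -> Tuple[np.ndarray, List[str]]:
    """Trials x neurons evoked matrix for one pulse count.

    ``inclusion`` is ``'all'`` or ``'ever_responsive'`` (responsive on >= 1
    trial of the session, any pulse count).  ``neuron_ids`` restricts to a
    subset (e.g. one opsin class) before the inclusion rule.  Fewer than 2
    qualifying trials -> empty matrix (stability undefined).
    """
    if inclusion not in ("all", "ever_responsive"):
        raise InvalidInputError(f"unknown inclusion rule {inclusion!r}")
    cols = (
        np.arange(len(tensor.neuron_ids))
        if neuron_ids is None
        else tensor.columns_for(neuron_ids)
    )
    if inclusion == "ever_responsive":
        ever = tensor.responsive.any(axis=0)
        cols = cols[ever[cols]]
    ids = [tensor.neuron_ids[j] for j in cols]
    tmask = tensor.pulse_counts == pulse_count
    if tmask.sum() < 2:
        return np.zeros((0, cols.size)), ids
    return tensor.evoked[np.ix_(tmask, cols)], ids


def within_day_stability(trial_matrix: np.ndarray) -> Tuple[np.ndarray, float]:
    """Inter-trial Pearson matrix and its mean strict upper triangle.

    Zero-variance trial vectors produce NaN rows/columns which are excluded
    from the mean.  Requires >= 2 trials and >= 3 neurons.
    """
    m = np.asarray(trial_matrix, dtype=float)
    if m.shape[0] < 2 or m.shape[1] < 3:
        return np.zeros((0, 0)), float("nan")
    sd = m.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(m)
    corr[sd == 0, :] = np.nan
    corr[:, sd == 0] = np.nan
    iu = np.triu_indices(m.shape[0], k=1)
    vals = corr[iu]
    if np.all(np.isnan(vals)):
        return corr, float("nan")
    return corr, float(np.nanmean(vals))


def day_vectors(
    experiment: Experiment,
    tensors: Dict[int, ResponseTensor],
    pulse_count: int = 9,
    inclusion: str = "ever_responsive",
    neuron_ids: Optional[Sequence[str]] = None,
) -> Tuple[np.ndarray, List[int], List[str]]:
    """Days x neurons matrix of per-day mean evoked ΔF/F.

    Inclusion ``'ever_responsive'`` keeps neurons responsive on >= 1 trial
    of >= 1 session.  A neuron absent on a day gets NaN there; days with no
    qualifying trials are excluded with a warning.  Returns
    ``(matrix, session_days, neuron_id_order)``.
    """
    if inclusion not in ("all", "ever_responsive"):
        raise InvalidInputError(f"unknown inclusion rule {inclusion!r}")
    universe = list(experiment.neurons.keys()) if neuron_ids is None else list(neuron_ids)
    if inclusion == "ever_responsive":
        ever = set()
        for t in tensors.values():
            resp = t.responsive.any(axis=0)
            ever.update(nid for nid, r in zip(t.neuron_ids, resp) if r)
        universe = [nid for nid in universe if nid in ever]
    days: List[int] = []
    rows: List[np.ndarray] = []
    for s in experiment.sessions:
        if s.session_day not in tensors:
            continue
        tensor = tensors[s.session_day]
        tmask = tensor.pulse_counts == pulse_count
        if tmask.sum() == 0:
            warnings.warn(f"day {s.session_day} has no {pulse_count}-pulse trials; excluded")
            continue
        idx = {nid: j for j, nid in enumerate(tensor.neuron_ids)}
        row = np.full(len(universe), np.nan)
        mean_ev = tensor.evoked[tmask].mean(axis=0)
        for k, nid in enumerate(universe):
            j = idx.get(nid)
            if j is not None:
                row[k] = mean_ev[j]
        rows.append(row)
        days.append(s.session_day)
    if len(rows) < 2:
        return np.zeros((0, len(universe))), days, universe
    return np.stack(rows), days, universe


def cross_day_matrix(
    day_matrix: np.ndarray, min_overlap: int = MIN_CROSS_DAY_OVERLAP
) -> np.ndarray:
    """Pairwise-complete Pearson matrix across day vectors.

    A day pair uses only neurons observed on both days; pairs with fewer
    than ``min_overlap`` shared neurons are NaN.  A neuron absent on a day
    therefore contributes to no pair involving that day.
    """
    d = day_matrix.shape[0]
    out = np.full((d, d), np.nan)
    for i in range(d):
        out[i, i] = 1.0
        for j in range(i + 1, d):
            both = np.isfinite(day_matrix[i]) & np.isfinite(day_matrix[j])
            if both.sum() < min_overlap:
                continue
            a, b = day_matrix[i, both], day_matrix[j, both]
            if a.std() == 0 or b.std() == 0:
                continue
            r = float(np.corrcoef(a, b)[0, 1])
            out[i, j] = out[j, i] = r
    return out


def days_until_r2_below(
    cross_matrix: np.ndarray,
    start_index: int,
    threshold: float = 0.5,
    day_labels: Optional[Sequence[int]] = None,
    count: str = "sessions",
) -> Optional[int]:
    """Smallest lag at which R² = r² drops below ``threshold``; None if censored.

    Scans forward in recorded-day order from ``start_index``.  ``count``
    selects the lag unit: recorded ``'sessions'`` (default) or
    ``'calendar'`` days via ``day_labels``.  NaN entries (insufficient
    overlap) are skipped.  The start day must have at least one subsequent
    day.
    """
    d = cross_matrix.shape[0]
    if not 0 <= start_index < d - 1:
        raise InvalidInputError("start day needs at least one subsequent day")
    if count not in ("sessions", "calendar"):
        raise InvalidInputError(f"unknown count convention {count!r}")
    if count == "calendar" and day_labels is None:
        raise InvalidInputError("calendar counting requires day_labels")
    for j in range(start_index + 1, d):
        r = cross_matrix[start_index, j]
        if np.isnan(r):
            continue
        if r * r < threshold:
            if count == "sessions":
                return j - start_index
            return int(day_labels[j] - day_labels[start_index])
    return None


@dataclass
class StabilityResult:
    """Stability summary for one subject and opsin class."""

    subject_id: str
    opsin_class: str
    within_day: pd.DataFrame  # session_day, mean_upper_triangle_r, n_trials, n_neurons
    cross_day: np.ndarray
    session_days: List[int]
    days_until: List[Optional[int]]  # per start day (None = censored)


def compute_stability(
    experiment: Experiment,
    opsin_class: str,
    pulse_count: int = 9,
    baseline_mode: str = "matched",
    tensors: Optional[Dict[int, ResponseTensor]] = None,
    min_overlap: int = MIN_CROSS_DAY_OVERLAP,
) -> StabilityResult:
    """Full stability pipeline for one subject and opsin class."""
    if tensors is None:
        tensors = {
            s.session_day: compute_response_tensor(s, baseline_mode=baseline_mode)
            for s in experiment.sessions
        }
    ids = experiment.neuron_ids_of_class(opsin_class)
    rows = []
    for s in experiment.sessions:
        tensor = tensors[s.session_day]
        m, used = trial_vectors(s, tensor, pulse_count=pulse_count, neuron_ids=ids)
        _, scalar = within_day_stability(m)
        rows.append(
            {
                "session_day": s.session_day,
                "mean_upper_triangle_r": scalar,
                "n_trials": int(m.shape[0]),
                "n_neurons": len(used),
            }
        )
    day_mat, days, _ = day_vectors(experiment, tensors, pulse_count=pulse_count, neuron_ids=ids)
    cross = cross_day_matrix(day_mat, min_overlap=min_overlap) if day_mat.size else np.zeros((0, 0))
    until: List[Optional[int]] = []
    for i in range(max(cross.shape[0] - 1, 0)):
        until.append(days_until_r2_below(cross, i, day_labels=days))
    return StabilityResult(
        subject_id=experiment.subject_id,
        opsin_class=opsin_class,
        within_day=pd.DataFrame(rows),
        cross_day=cross,
        session_days=days,
        days_until=until,
    )


@dataclass
class GroupStabilityComparison:
    comparison: Optional[GroupComparison]
    per_subject: pd.DataFrame
    no_common_support: bool
    excluded_subjects: List[str]


def group_stability_comparison(
    results: Sequence[Tuple[str, StabilityResult]],
    metric: str,
    day_window: Tuple[int, int],
) -> GroupStabilityComparison:
    """Learner vs non-learner comparison of a stability metric.

    ``results`` pairs a group label with each subject's
    :class:`StabilityResult`.  ``metric`` is ``'within_day_mean'`` (mean
    upper-triangle r per session, averaged over ``day_window``) or
    ``'days_until'`` (mean days-until-R²<0.5 over the start days in
    ``day_window`` at which ALL subjects are uncensored).  Subjects censored
    on every candidate start day are excluded with a flag; if no start day
    has full support the result is flagged ``no_common_support``.
    """
    if metric not in ("within_day_mean", "days_until"):
        raise InvalidInputError(f"unknown metric {metric!r}")
    rows = []
    excluded: List[str] = []
    if metric == "within_day_mean":
        for label, res in results:
            df = res.within_day
            sel = df[(df["session_day"] >= day_window[0]) & (df["session_day"] <= day_window[1])]
            vals = sel["mean_upper_triangle_r"].dropna()
            if vals.empty:
                excluded.append(res.subject_id)
                continue
            rows.append({"subject": res.subject_id, "group": label, "day": 0, "value": float(vals.mean())})
    else:
        # start days (1-based training days) with a defined value for every subject
        candidate_days = [
            d for d in range(day_window[0], day_window[1] + 1)
        ]
        support: List[int] = []
        for d in candidate_days:
            ok = True
            for _, res in results:
                if d not in res.session_days:
                    ok = False
                    break
                i = res.session_days.index(d)
                if i >= len(res.days_until) or res.days_until[i] is None:
                    ok = False
                    break
            if ok:
                support.append(d)
        if not support:
            return GroupStabilityComparison(None, pd.DataFrame(), True, [])
        for label, res in results:
            vals = [res.days_until[res.session_days.index(d)] for d in support]
            rows.append({"subject": res.subject_id, "group": label, "day": 0, "value": float(np.mean(vals))})
    per_subject = pd.DataFrame(rows)
    if per_subject.empty or per_subject["group"].nunique() != 2:
        return GroupStabilityComparison(None, per_subject, True, excluded)
    comp = compare_groups(per_subject)
    return GroupStabilityComparison(comp, per_subject, False, excluded)
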