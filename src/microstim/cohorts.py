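"""Cohort-level evaluation: learner vs non-learner and choice-coupling designs.

These functions run the full per-subject pipeline (response tensors,
stability, decoding, choice curves) over a labelled cohort and return the
group-level statistics that the study designs compare: within-day mean
trial-pair correlation over the common early days, days-until-R²<0.5 over
the common start days, late-window decoding, and the paired right-vs-left
choice contrast — each computed separately for the opsin-expressing and
non-expressing populations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .choice import population_choice_curve
from .decoding import decoding_group_comparison, decoding_table
from .responsiveness import compute_response_tensor
from .stability import compute_stability, group_stability_comparison
from .synth import CohortMember

OPSIN_CLASSES = ("expressing", "non_expressing")


@dataclass
class ClassCohortStats:
    """Learner-minus-non-learner contrasts for one opsin class."""

    within_day_diff: float
    within_day_p: float
    days_until_diff: float  # NaN when no common support
    days_until_p: float
    days_until_supported: bool
    decoding_late_diff: float
    decoding_late_p: float


def evaluate_learning_cohort(
    cohort: Sequence[CohortMember],
    within_day_window: Tuple[int, int] = (1, 8),
    days_until_window: Tuple[int, int] = (1, 3),
    late_window: Tuple[int, int] = (6, 8),
    baseline_mode: str = "matched",
) -> Dict[str, ClassCohortStats]:
    """Group contrasts of stability and decoding for a labelled cohort.

    Windows follow the common-day conventions of the study design:
    within-day stability over training days 1-8, days-until-R²<0.5 over
    start days 1-3 (restricted to start days where every subject is
    uncensored), and decoding over the late common window (days 6-8).
    """
    stabs: Dict[str, List] = {cls: [] for cls in OPSIN_CLASSES}
    summaries = []
    labels: Dict[str, str] = {}
    for member in cohort:
        exp = member.experiment
        labels[exp.subject_id] = member.label
        tensors = {
            s.session_day: compute_response_tensor(s, baseline_mode=baseline_mode)
            for s in exp.sessions
        }
        for cls in OPSIN_CLASSES:
            stabs[cls].append((member.label, compute_stability(exp, cls, tensors=tensors)))
        _, summary = decoding_table(exp, tensors=tensors)
        summaries.append(summary)
    summary = pd.concat(summaries, ignore_index=True)

    out: Dict[str, ClassCohortStats] = {}
    for cls in OPSIN_CLASSES:
        wd = group_stability_comparison(stabs[cls], "within_day_mean", within_day_window)
        du = group_stability_comparison(stabs[cls], "days_until", days_until_window)
        dec = decoding_group_comparison(summary, labels, cls, late_window=late_window)
        late = dec.across_group_late

        def diff(comp) -> float:
            if comp is None or comp.insufficient_n:
                return float("nan")
            return comp.group_means["learner"] - comp.group_means["non_learner"]

        out[cls] = ClassCohortStats(
            within_day_diff=diff(wd.comparison) if wd.comparison else float("nan"),
            within_day_p=wd.comparison.p_value if wd.comparison else float("nan"),
            days_until_diff=diff(du.comparison) if not du.no_common_support else float("nan"),
            days_until_p=du.comparison.p_value if not du.no_common_support else float("nan"),
            days_until_supported=not du.no_common_support,
            decoding_late_diff=diff(late),
            decoding_late_p=late.p_value if late is not None else float("nan"),
        )
    return out


@dataclass
class ChoiceCohortStats:
    """Paired right-vs-left choice contrast for one opsin class."""

    mean_right_minus_left: float
    p_value: float
    n_subjects: int


def evaluate_choice_cohort(
    experiments: Sequence, baseline_mode: str = "matched"
) -> Dict[str, ChoiceCohortStats]:
    """Population choice curves and paired tests per opsin class."""
    out = {}
    for cls in OPSIN_CLASSES:
        res = population_choice_curve(experiments, cls, baseline_mode=baseline_mode)
        diffs = list(res.mean_right_minus_left.values())
        out[cls] = ChoiceCohortStats(
            mean_right_minus_left=float(np.mean(diffs)) if diffs else float("nan"),
            p_value=res.p_value,
            n_subjects=res.n_subjects,
        )
    return out
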