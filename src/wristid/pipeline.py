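"""End-to-end convenience: synthetic subjects through processing to ratios.

These helpers chain the stages the way an analysis session would:
generate (or load) trials, preprocess them, identify (B_r, K_r) per task
with the canonical-correlation route and optionally the grid search, and
collect per-subject ratios for group statistics or recovery scoring.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cca import CCAResult, identify_task
from .gridsearch import GridResult, grid_search_bk
from .signal import ProcessedTrial, process_trial
from .synth import Cohort, SyntheticSubject

__all__ = ["process_subject", "identify_subject", "recover_cohort"]


def process_subject(subject: SyntheticSubject, task: str) -> list[ProcessedTrial]:
    """Preprocess all of a synthetic subject's trials for one task."""
    return [process_trial(t, subject.rest) for t in subject.trials[task]]


def identify_subject(
    subject: SyntheticSubject,
    task: str,
    include_acceleration: bool = True,
    grid: bool = False,
    **kwargs,
):
    """CCA identification (and optionally grid search) for one task.

    Returns a ``CCAResult`` or, with ``grid=True``, a tuple
    ``(CCAResult, GridResult)``.
    """
    processed = process_subject(subject, task)
    cca = identify_task(processed, include_acceleration=include_acceleration, **kwargs)
    if not grid:
        return cca
    gs = grid_search_bk(processed, M=subject.truth.M)
    return cca, gs


def recover_cohort(
    cohort: Cohort,
    include_acceleration: bool = True,
    tasks=("step", "pursuit"),
) -> pd.DataFrame:
    """Recover every subject/task ratio and score it against ground truth.

    Returns a tidy frame with one row per subject and task: the true and
    estimated B/K ratio, their relative error, the canonical correlation
    and the first-pair eigenvalue proportion.
    """
    rows = []
    for subject in cohort.subjects:
        for task in tasks:
            if task not in subject.trials:
                continue
            res: CCAResult = identify_subject(
                subject, task, include_acceleration=include_acceleration
            )
            true = subject.truth.ratio(task)
            rows.append(
                {
                    "subject_id": subject.truth.subject_id,
                    "group": subject.truth.group,
                    "task": task,
                    "ratio_true": true,
                    "ratio": res.ratio,
                    "rel_error": abs(res.ratio - true) / true,
                    "cc": res.cc,
                    "eigen_proportion_first": res.eigen_proportion_first,
                    "mr_over_kr": res.mr_over_kr if res.mr_over_kr is not None else np.nan,
                }
            )
    return pd.DataFrame(rows)
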