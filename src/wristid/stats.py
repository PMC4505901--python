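"""Group summaries and nonparametric comparisons of B_r/K_r ratios.

The per-subject ratio is the unit of analysis.  Between-group differences
per task are tested with the Mann-Whitney U test (exact distribution when
the pooled sample is small and tie-free, otherwise the normal
approximation with mid-ranks, tie correction and continuity correction)
and with Student's two-sample t-test.  Within a group, the step and
pursuit ratio distributions are compared by their range overlap: healthy
motor control yields disjoint task distributions, cerebellar ataxia
collapses them onto each other.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as st

__all__ = [
    "Summary",
    "TaskOverlap",
    "GroupComparison",
    "summarize",
    "mann_whitney_u",
    "t_test",
    "compare_tasks",
    "compare_groups",
]


@dataclass
class Summary:
    mean: float
    sd: float
    min: float
    max: float
    n: int


@dataclass
class TaskOverlap:
    overlap: bool
    width: float   # length of the range intersection; <= 0 means disjoint


@dataclass
class GroupComparison:
    summaries: dict                      # (group, task) -> Summary
    between_groups: dict                 # task -> {"U", "p_mw", "t", "p_t"}
    task_overlap: dict                   # group -> TaskOverlap
    groups: tuple = ()
    tasks: tuple = ()
    extra: dict = field(default_factory=dict)


def summarize(values) -> Summary:
    """Sample mean, SD (n-1 denominator; 0 for a single value), extremes."""
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise ValueError("cannot summarize an empty sample")
    sd = float(np.std(v, ddof=1)) if v.size > 1 else 0.0
    return Summary(
        mean=float(np.mean(v)), sd=sd, min=float(np.min(v)), max=float(np.max(v)),
        n=int(v.size),
    )


def mann_whitney_u(x, y, exact_max_n: int = 40):
    """Two-sided Mann-Whitney U test, (U, p).

    Uses the exact U distribution when the pooled sample has no ties and
    n1 + n2 <= ``exact_max_n``; otherwise the normal approximation with
    mid-ranks, tie correction and continuity correction.  U is reported
    for the first sample.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (not has_ties and pooled.size <= exact_max_n) else "asymptotic"
    res = st.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def t_test(x, y, paired: bool = False):
    """Student's two-sample t-test (equal variances), or paired; (t, p)."""
    if paired:
        res = st.ttest_rel(x, y)
    else:
        res = st.ttest_ind(x, y, equal_var=True)
    return float(res.statistic), float(res.pvalue)


def compare_tasks(step_ratios, pursuit_ratios) -> TaskOverlap:
    """Range overlap of the two tasks' ratio distributions within a group."""
    s = np.asarray(list(step_ratios), dtype=float)
    p = np.asarray(list(pursuit_ratios), dtype=float)
    if s.size == 0 or p.size == 0:
        raise ValueError("both task samples must be nonempty")
    width = float(min(s.max(), p.max()) - max(s.min(), p.min()))
    return TaskOverlap(overlap=width > 0, width=width)


def compare_groups(cohort: pd.DataFrame) -> GroupComparison:
    """Full group/task comparison from a tidy cohort table.

    ``cohort`` needs columns ``group``, ``task``, ``ratio`` (one row per
    subject and task).  Produces per-(group, task) summaries, per-task
    between-group Mann-Whitney and t-tests, and per-group step/pursuit
    range overlap.
    """
    required = {"group", "task", "ratio"}
    if not required.issubset(cohort.columns):
        raise ValueError(f"cohort table must have columns {sorted(required)}")
    groups = tuple(pd.unique(cohort["group"]))
    tasks = tuple(pd.unique(cohort["task"]))

    summaries = {
        (g, t): summarize(sub["ratio"])
        for (g, t), sub in cohort.groupby(["group", "task"], sort=False)
    }

    between = {}
    if len(groups) == 2:
        g1, g2 = groups
        for t in tasks:
            a = cohort.query("group == @g1 and task == @t")["ratio"]
            b = cohort.query("group == @g2 and task == @t")["ratio"]
            U, p_mw = mann_whitney_u(a, b)
            tt, p_t = t_test(a, b)
            between[t] = {"U": U, "p_mw": p_mw, "t": tt, "p_t": p_t}

    overlap = {}
    if len(tasks) == 2:
        t1, t2 = tasks
        for g in groups:
            overlap[g] = compare_tasks(
                cohort.query("group == @g and task == @t1")["ratio"],
                cohort.query("group == @g and task == @t2")["ratio"],
            )

    return GroupComparison(
        summaries=summaries,
        between_groups=between,
        task_overlap=overlap,
        groups=groups,
        tasks=tasks,
    )
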