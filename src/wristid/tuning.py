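"""Directional tuning of muscle activity and agonist analyses.

Muscle activity in an 8-direction step-tracking task is summarized by a
cosine tuning curve m(d) = b0 + b1 cos(d - pd) fitted around movement
onset; pd is the preferred direction.  For each movement direction the
agonist muscle(s) are the ones whose preferred direction lies within
67.5 degrees (falling back to the single nearest muscle when none does,
and keeping at most the two nearest so every direction has one or two
agonists).  The agonist tension time course is then correlated with the
displacement along the target direction and with the tangential speed;
position-dominant motor commands show higher displacement than velocity
correlations.

All direction arithmetic is circular, in cursor-space degrees
(extension/right = 0, radial/up = 90).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import MuscleSpec, default_muscles
from .signal import ProcessedTrial, detect_movement_onset, tangential_speed

__all__ = [
    "DIRECTION_ANGLES",
    "TuningFit",
    "AgonistCorrelation",
    "preferred_direction",
    "assign_agonists",
    "agonist_kinematics_correlation",
    "tuning_from_step_trials",
    "agonist_correlations_by_direction",
]

# canonical 8 target directions, cursor convention of the step-tracking task
DIRECTION_ANGLES = {
    "RT": 0.0, "UR": 45.0, "UP": 90.0, "UL": 135.0,
    "LF": 180.0, "DL": 225.0, "DN": 270.0, "DR": 315.0,
}


@dataclass
class TuningFit:
    pd: float                  # degrees in [0, 360)
    modulation_depth: float    # b1 >= 0
    baseline: float            # b0
    r2: float
    reliable: bool             # False when b1 is indistinguishable from 0


@dataclass
class AgonistCorrelation:
    direction: str
    agonists: tuple
    r_displacement: float
    r_velocity: float
    defined: bool = True


def circular_distance(a: float, b: float) -> float:
    """Absolute angular distance in degrees, in [0, 180]."""
    d = abs((a - b) % 360.0)
    return min(d, 360.0 - d)


def preferred_direction(directions_deg, activity, se_factor: float = 2.0) -> TuningFit:
    """Cosine fit m(d) = b0 + b1 cos(d - pd) over sampled directions.

    Linearized as b0 + A cos d + B sin d; pd = atan2(B, A) wrapped to
    [0, 360).  The fit is flagged unreliable when the modulation depth b1
    does not exceed ``se_factor`` times its standard error (estimated from
    the residuals), e.g. for activity uniform across directions.
    """
    d = np.deg2rad(np.asarray(directions_deg, dtype=float))
    m = np.asarray(activity, dtype=float)
    if d.shape != m.shape or d.size < 4:
        raise ValueError("need matched direction/activity samples (>= 4 directions)")
    X = np.column_stack([np.ones_like(d), np.cos(d), np.sin(d)])
    coef, *_ = np.linalg.lstsq(X, m, rcond=None)
    b0, A, B = coef
    depth = float(np.hypot(A, B))
    pd = float(np.rad2deg(np.arctan2(B, A)) % 360.0)

    fit = X @ coef
    ss_res = float(np.sum((m - fit) ** 2))
    ss_tot = float(np.sum((m - m.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0

    dof = max(d.size - 3, 1)
    sigma2 = ss_res / dof
    cov = sigma2 * np.linalg.inv(X.T @ X)
    # delta-method SE of b1 = hypot(A, B); direction of the gradient at the fit
    if depth > 0:
        g = np.array([0.0, A / depth, B / depth])
        se = float(np.sqrt(g @ cov @ g))
    else:
        se = float(np.sqrt(max(cov[1, 1], cov[2, 2])))
    reliable = depth > se_factor * se
    return TuningFit(pd=pd, modulation_depth=depth, baseline=float(b0), r2=r2,
                     reliable=reliable)


def assign_agonists(
    direction_deg: float,
    specs: list[MuscleSpec] | None = None,
    window_deg: float = 67.5,
    max_agonists: int = 2,
) -> tuple:
    """Muscle names acting as agonists for a movement direction.

    Muscles whose preferred direction lies within ``window_deg`` of the
    movement direction, nearest first, capped at ``max_agonists``; when the
    window is empty the single nearest muscle is returned.
    """
    if specs is None:
        specs = default_muscles()
    if not specs:
        raise ValueError("empty muscle table")
    dist = [(circular_distance(direction_deg, s.preferred_direction), s.name) for s in specs]
    dist.sort()
    within = [name for d, name in dist if d < window_deg]
    if not within:
        return (dist[0][1],)
    return tuple(within[:max_agonists])


def _pearson(x, y) -> float:
    if np.std(x) == 0 or np.std(y) == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def agonist_kinematics_correlation(
    trial: ProcessedTrial,
    agonists,
    specs: list[MuscleSpec] | None = None,
    onset_s: float | None = None,
) -> AgonistCorrelation:
    """Correlate agonist tension with displacement and with speed.

    For a step trial, displacement is the wrist excursion projected on the
    target direction and speed is the tangential speed, both from movement
    onset to the end of the trial.  Per-muscle Pearson correlations are
    averaged when there are two agonists.
    """
    if trial.task != "step":
        raise ValueError("agonist/kinematics correlation is defined for step trials")
    if specs is None:
        specs = default_muscles()
    names = [s.name for s in specs]
    direction = DIRECTION_ANGLES[trial.direction]
    u = np.array([np.cos(np.deg2rad(direction)), np.sin(np.deg2rad(direction))])

    speed = tangential_speed(trial.vel_x, trial.vel_y)
    if onset_s is None:
        onset_s = detect_movement_onset(speed, trial.fs_out)
    i0 = int(round(onset_s * trial.fs_out))
    sl = slice(i0, None)

    disp = trial.theta()[sl] @ u
    spd = speed[sl]
    rs_d, rs_v = [], []
    for name in agonists:
        t = trial.tension[sl, names.index(name)]
        rs_d.append(_pearson(t, disp))
        rs_v.append(_pearson(t, spd))
    r_d = float(np.mean(rs_d))
    r_v = float(np.mean(rs_v))
    defined = np.isfinite(r_d) and np.isfinite(r_v)
    return AgonistCorrelation(
        direction=trial.direction,
        agonists=tuple(agonists),
        r_displacement=r_d,
        r_velocity=r_v,
        defined=defined,
    )


def tuning_from_step_trials(
    trials: list[ProcessedTrial],
    specs: list[MuscleSpec] | None = None,
    window_s: float = 0.025,
) -> dict:
    """Preferred-direction fits for each muscle from 8-direction step data.

    Mean tension within +/- ``window_s`` of movement onset is averaged
    over repetitions per direction, then cosine-fitted.  Returns
    {muscle name: TuningFit}.
    """
    if specs is None:
        specs = default_muscles()
    names = [s.name for s in specs]
    by_dir: dict[str, list] = {}
    for t in trials:
        if t.task != "step":
            continue
        onset = detect_movement_onset(tangential_speed(t.vel_x, t.vel_y), t.fs_out)
        i0 = int(round((onset - window_s) * t.fs_out))
        i1 = int(round((onset + window_s) * t.fs_out)) + 1
        i0 = max(i0, 0)
        by_dir.setdefault(t.direction, []).append(t.tension[i0:i1].mean(axis=0))
    if len(by_dir) < 4:
        raise ValueError(f"need >= 4 directions for tuning, got {sorted(by_dir)}")
    dirs = sorted(by_dir, key=lambda k: DIRECTION_ANGLES[k])
    angles = np.array([DIRECTION_ANGLES[d] for d in dirs])
    mean_act = np.array([np.mean(by_dir[d], axis=0) for d in dirs])  # (ndir, 4)
    return {
        name: preferred_direction(angles, mean_act[:, i])
        for i, name in enumerate(names)
    }


def agonist_correlations_by_direction(
    trials: list[ProcessedTrial],
    specs: list[MuscleSpec] | None = None,
) -> list[AgonistCorrelation]:
    """Per-direction agonist correlations averaged over repetitions.

    Agonists are assigned from the muscle table's preferred directions;
    pass specs with data-derived preferred directions (see
    ``tuning_from_step_trials``) when analyzing synthetic or novel
    recordings.
    """
    if specs is None:
        specs = default_muscles()
    by_dir: dict[str, list[AgonistCorrelation]] = {}
    for t in trials:
        if t.task != "step":
            continue
        agonists = assign_agonists(DIRECTION_ANGLES[t.direction], specs)
        res = agonist_kinematics_correlation(t, agonists, specs)
        if res.defined:
            by_dir.setdefault(t.direction, []).append(res)
    out = []
    for d in sorted(by_dir, key=lambda k: DIRECTION_ANGLES[k]):
        rs = by_dir[d]
        out.append(
            AgonistCorrelation(
                direction=d,
                agonists=rs[0].agonists,
                r_displacement=float(np.mean([r.r_displacement for r in rs])),
                r_velocity=float(np.mean([r.r_velocity for r in rs])),
            )
        )
    return out
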