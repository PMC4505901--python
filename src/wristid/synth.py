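"""Model-consistent synthetic subjects and trials.

No recordings were deposited with the study design this package analyzes,
so every identification and statistics stage is exercised on synthetic
data built to be exactly consistent with the joint model: trial
kinematics are generated first, the implied joint torque
tau = M theta'' + B* theta' + K* theta is computed from a subject's
ground-truth parameters, and the torque is decomposed into four
nonnegative muscle tensions along the muscles' pulling directions, plus a
co-contraction level that cancels in the torque and measurement noise
that does not.

Tasks emulate the two study conditions:

- step: 18-degree point-to-point movements to 8 targets (minimum-jerk
  profile, 0.4 s movement, variable 1-2 s pre-hold), 3 repetitions each;
- pursuit: constant-speed (6.2 deg/s) traversal of a smooth closed
  figure-eight path spanning +/-10 x +/-8 degrees through (-10, 8).

Noise is multiplicative log-normal on the tension envelopes (EMG envelope
noise scales with the signal) and additive white noise on the recorded
angles.  Tensions are smoothed with the same 3 Hz zero-phase envelope
filter the processing stage applies to EMG, which keeps the generated
tensions and the filtered kinematics related by the same (B*, K*).

Trials are generated directly at the 100 Hz working rate by default; an
optional raw-EMG mode synthesizes a 2 kHz noise carrier modulated by the
tension envelope for end-to-end demonstrations of the EMG processing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize

from .model import MuscleSpec, default_muscles, hand_inertia, kinematic_torque
from .signal import (
    CalibrationRecording,
    TrialRecording,
    lowpass_zero_phase,
)
from .tuning import DIRECTION_ANGLES

__all__ = [
    "SyntheticConfig",
    "GroupRatioModel",
    "STUDY_RATIO_MODELS",
    "Cohort",
    "make_step_kinematics",
    "make_pursuit_kinematics",
    "tensions_from_torque",
    "cocontraction_pattern",
    "make_trial",
    "generate_subject",
    "generate_cohort",
]

HAND_DENSITY_KG_M3 = 1000.0  # hand idealized as a water-density sphere


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the generator; defaults mirror the tasks."""

    fs: float = 100.0
    step_amplitude_deg: float = 18.0
    step_duration_s: float = 0.4
    hold_pre_range_s: tuple = (1.0, 2.0)
    hold_post_s: float = 1.0
    pursuit_speed_deg_s: float = 6.2
    pursuit_span_deg: tuple = (10.0, 8.0)
    reps_step: int = 3
    reps_pursuit: int = 5
    co_contraction: float = 0.1        # normalized tension units
    snr_db: float | None = 20.0        # envelope SNR; None = noise free
    angle_noise_deg: float = 0.1       # additive white noise on recorded angles
    envelope_filter: bool = True       # smooth tensions like an EMG envelope
    envelope_cutoff_hz: float = 3.0
    hand_radius_m: float = 0.049       # mean; per-subject draws around it
    hand_radius_sd_m: float = 0.002


@dataclass(frozen=True)
class GroupRatioModel:
    """Truncated-normal B*/K* distributions per task for one group."""

    step_mean: float
    step_sd: float
    pursuit_mean: float
    pursuit_sd: float
    min_ratio: float = 0.02


# group-level moments reported for the 10 controls and 19 patients
STUDY_RATIO_MODELS = {
    "control": GroupRatioModel(0.17, 0.06, 1.30, 0.27),
    "patient": GroupRatioModel(0.24, 0.10, 0.54, 0.28),
}


@dataclass
class Kinematics:
    """Noise-free kinematics of one trial (deg / rad duals kept explicit)."""

    time: np.ndarray
    theta: np.ndarray  # (n, 2) rad
    vel: np.ndarray    # (n, 2) rad/s
    acc: np.ndarray    # (n, 2) rad/s^2
    fs: float
    hold_samples: int = 0  # initial central-hold length (step task)

    @property
    def angle_deg(self) -> np.ndarray:
        return np.rad2deg(self.theta)


def _minimum_jerk(n: int) -> tuple:
    """Normalized position/velocity/acceleration profiles on [0, 1]."""
    u = np.linspace(0.0, 1.0, n)
    s = 10 * u**3 - 15 * u**4 + 6 * u**5
    v = 30 * u**2 - 60 * u**3 + 30 * u**4
    a = 60 * u - 180 * u**2 + 120 * u**3
    return s, v, a


def make_step_kinematics(
    direction,
    config: SyntheticConfig = SyntheticConfig(),
    amplitude_deg: float | None = None,
    hold_pre_s: float | None = None,
    rng: np.random.Generator | None = None,
    intermittency: float = 0.0,
) -> Kinematics:
    """Minimum-jerk step to one of the 8 targets, with hold periods.

    ``direction`` is a canonical label (``"UP"`` ...) or an angle in
    degrees.  The velocity profile is bell-shaped with exact zeros at the
    endpoints and peak speed 1.875 x amplitude / duration.

    ``intermittency`` > 0 superimposes two delayed corrective
    submovements of that relative amplitude (ataxia-like step-wise
    movement, for qualitative demonstrations only; requires ``rng``).
    """
    if isinstance(direction, str):
        direction_deg = DIRECTION_ANGLES[direction]
    else:
        direction_deg = float(direction)
    amp = np.deg2rad(config.step_amplitude_deg if amplitude_deg is None else amplitude_deg)
    if hold_pre_s is None:
        lo, hi = config.hold_pre_range_s
        hold_pre_s = float(rng.uniform(lo, hi)) if rng is not None else (lo + hi) / 2
    fs, T = config.fs, config.step_duration_s

    n_pre = int(round(hold_pre_s * fs))
    n_mov = int(round(T * fs)) + 1
    n_post = int(round(config.hold_post_s * fs))
    s, v, a = _minimum_jerk(n_mov)
    u = np.array([np.cos(np.deg2rad(direction_deg)), np.sin(np.deg2rad(direction_deg))])

    prof_s = np.concatenate([np.zeros(n_pre), s, np.ones(n_post)])
    prof_v = np.concatenate([np.zeros(n_pre), v / T, np.zeros(n_post)])
    prof_a = np.concatenate([np.zeros(n_pre), a / T**2, np.zeros(n_post)])
    n = len(prof_s)
    if intermittency > 0:
        if rng is None:
            raise ValueError("intermittency requires an rng")
        # step-wise corrective submovements: undershoot the main movement,
        # then catch up with two delayed pulses that sum back to the target
        prof_s, prof_v, prof_a = (1.0 - intermittency) * prof_s, \
            (1.0 - intermittency) * prof_v, (1.0 - intermittency) * prof_a
        for frac in (0.6, 0.4):
            delay = n_pre + n_mov + int(rng.uniform(0.1, 0.4) * fs)
            k = min(n_mov, n - delay)
            if k <= 1:
                continue
            ss, vv, aa = _minimum_jerk(n_mov)
            amp_i = intermittency * frac
            prof_s[delay:delay + k] += amp_i * ss[:k]
            prof_s[delay + k:] += amp_i * ss[k - 1]
            prof_v[delay:delay + k] += amp_i * vv[:k] / T
            prof_a[delay:delay + k] += amp_i * aa[:k] / T**2
    return Kinematics(
        time=np.arange(n) / fs,
        theta=amp * prof_s[:, None] * u,
        vel=amp * prof_v[:, None] * u,
        acc=amp * prof_a[:, None] * u,
        fs=fs,
        hold_samples=n_pre,
    )


def _pursuit_path(u: np.ndarray, span: tuple) -> np.ndarray:
    """Closed figure-eight Lissajous spanning +/- span_x by +/- span_y.

    x = span_x sin(2u), y = span_y sin(u).  The tangent never vanishes
    (no cusps), so a constant-speed traversal exists; note that no smooth
    constant-speed path spanning the full box can pass through a box
    corner, so the traversal starts at the path point nearest the
    upper-left hold target instead (u = 3 pi / 4, i.e. (-span_x,
    0.71 span_y)).
    """
    sx, sy = span
    return np.column_stack([sx * np.sin(2 * u), sy * np.sin(u)])


def make_pursuit_kinematics(
    config: SyntheticConfig = SyntheticConfig(),
    n_dense: int = 20001,
) -> Kinematics:
    """Arc-length-constant traversal of the closed pursuit path.

    The target moves at ``pursuit_speed_deg_s`` along the figure-eight;
    the trial covers exactly one lap (duration = path length / speed,
    about 1 min at the study speed), starting from the upper-left point.
    """
    u0 = 3 * np.pi / 4
    u = np.linspace(u0, u0 + 2 * np.pi, n_dense)
    pts = _pursuit_path(u, config.pursuit_span_deg)
    seg = np.hypot(*np.diff(pts, axis=0).T)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    length = arc[-1]
    duration = length / config.pursuit_speed_deg_s
    n = int(np.floor(duration * config.fs)) + 1
    t = np.arange(n) / config.fs
    u_t = np.interp(t * config.pursuit_speed_deg_s, arc, u)
    angle = _pursuit_path(u_t, config.pursuit_span_deg)

    theta = np.deg2rad(angle)
    vel = np.gradient(theta, 1.0 / config.fs, axis=0)
    acc = np.gradient(vel, 1.0 / config.fs, axis=0)
    return Kinematics(time=t, theta=theta, vel=vel, acc=acc, fs=config.fs)


def _action_matrix(specs: list[MuscleSpec], gains) -> np.ndarray:
    """(2, 4) tension-to-torque matrix from pulling directions and gains."""
    A = np.zeros((2, len(specs)))
    for i, (spec, g) in enumerate(zip(specs, gains)):
        if spec.action_direction is None:
            raise ValueError(f"{spec.name} has no action_direction for synthesis")
        psi = np.deg2rad(spec.action_direction)
        A[:, i] = g * np.array([np.cos(psi), np.sin(psi)])
    return A


def _validate_action_signs(A: np.ndarray, specs: list[MuscleSpec]) -> None:
    for i, spec in enumerate(specs):
        for ax, val in (("x", A[0, i]), ("y", A[1, i])):
            s = spec.sign(ax)
            if s != 0 and val * s < 0:
                raise ValueError(
                    f"action direction of {spec.name} violates its sign "
                    f"constraint on axis {ax} (a={val:g}, required sign {s:+d})"
                )


def cocontraction_pattern(A: np.ndarray) -> np.ndarray:
    """Strictly positive tension pattern producing zero net torque.

    Solves min ||A n|| with n >= 1 elementwise; feasible whenever the
    pulling directions positively span the plane.  Normalized to mean 1.
    """
    res = optimize.lsq_linear(A, np.zeros(2), bounds=(1.0, np.inf))
    n = res.x
    if np.linalg.norm(A @ n) > 1e-8 * np.linalg.norm(A):
        raise ValueError("pulling directions do not admit torque-free co-contraction")
    return n / n.mean()


def tensions_from_torque(
    tau: np.ndarray,
    A: np.ndarray,
    specs: list[MuscleSpec] | None = None,
    co_contraction: float = 0.0,
    snr_db: float | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Decompose a 2-axis torque series into 4 nonnegative tensions.

    At each sample the torque vector lies in the cone of two adjacent
    pulling directions; those two muscles take the (unique, nonnegative)
    share solving the exact 2x2 system, the others rest at zero, so
    A @ T(t) = tau(t) holds to machine precision before noise.  The
    co-contraction pattern adds activity in the null space of ``A``
    (antagonist shares cancel pairwise in the torque).  With ``snr_db``
    set, tensions are multiplied by unit-median log-normal noise of sigma
    = 10^(-snr/20).
    """
    tau = np.atleast_2d(np.asarray(tau, dtype=float))
    if tau.shape[1] != 2:
        raise ValueError(f"tau must be (n, 2), got {tau.shape}")
    if specs is not None:
        _validate_action_signs(A, specs)
    phi = np.arctan2(A[1], A[0])
    order = np.argsort(phi)
    phi_sorted = phi[order]
    gaps = np.diff(np.concatenate([phi_sorted, [phi_sorted[0] + 2 * np.pi]]))
    if np.any(gaps >= np.pi):
        raise ValueError("pulling directions must positively span the plane")

    n_m = A.shape[1]
    T = np.zeros((tau.shape[0], n_m))
    alpha = np.arctan2(tau[:, 1], tau[:, 0])
    rel = (alpha - phi_sorted[0]) % (2 * np.pi)
    edges = np.concatenate([(phi_sorted - phi_sorted[0]) % (2 * np.pi), [2 * np.pi]])
    # rel can round to exactly 2*pi when tau sits on the first boundary;
    # that boundary belongs equally to the last sector
    sector = np.clip(np.searchsorted(edges, rel, side="right") - 1, 0, n_m - 1)
    magnitude = np.hypot(tau[:, 0], tau[:, 1])
    active = magnitude > 0
    for s in range(n_m):
        i, j = order[s], order[(s + 1) % n_m]
        mask = active & (sector == s)
        if not np.any(mask):
            continue
        pair_inv = np.linalg.inv(A[:, [i, j]])
        shares = tau[mask] @ pair_inv.T
        T[mask, i] = shares[:, 0]
        T[mask, j] = shares[:, 1]
    if T.min() < -1e-9 * max(1.0, np.abs(T).max()):
        raise ValueError("negative tension share; inconsistent pulling directions")
    np.clip(T, 0.0, None, out=T)

    if co_contraction > 0:
        T = T + co_contraction * cocontraction_pattern(A)
    if snr_db is not None:
        if rng is None:
            raise ValueError("snr_db requires an rng for reproducibility")
        sigma = 10.0 ** (-snr_db / 20.0)
        T = T * rng.lognormal(mean=0.0, sigma=sigma, size=T.shape)
    return T


@dataclass
class SubjectTruth:
    subject_id: str
    group: str
    M: float
    hand_mass_kg: float
    hand_radius_m: float
    A: np.ndarray                 # (2, 4) tension-to-torque matrix
    bk: dict = field(default_factory=dict)   # task -> (B*, K*)

    def ratio(self, task: str) -> float:
        b, k = self.bk[task]
        return b / k


@dataclass
class SyntheticSubject:
    truth: SubjectTruth
    trials: dict                  # task -> list[TrialRecording]
    rest: CalibrationRecording    # tension-scale rest recording (baseline)


@dataclass
class Cohort:
    subjects: list
    config: SyntheticConfig
    seed: int

    def truth_table(self) -> pd.DataFrame:
        rows = [
            {
                "subject_id": s.truth.subject_id,
                "group": s.truth.group,
                "task": task,
                "B_true": s.truth.bk[task][0],
                "K_true": s.truth.bk[task][1],
                "ratio_true": s.truth.ratio(task),
                "M": s.truth.M,
            }
            for s in self.subjects
            for task in s.truth.bk
        ]
        return pd.DataFrame(rows)


def make_trial(
    kin: Kinematics,
    truth: SubjectTruth,
    task: str,
    config: SyntheticConfig,
    rng: np.random.Generator,
    direction: str | None = None,
    specs: list[MuscleSpec] | None = None,
) -> TrialRecording:
    """Torque-consistent trial from kinematics and subject ground truth."""
    B, K = truth.bk[task]
    tau = kinematic_torque(kin.theta, kin.vel, kin.acc, truth.M, B, K)
    T = tensions_from_torque(
        tau, truth.A, specs=specs, co_contraction=config.co_contraction,
        snr_db=None,
    )
    if config.envelope_filter:
        T = np.clip(
            lowpass_zero_phase(T, kin.fs, config.envelope_cutoff_hz), 0.0, None
        )
    if config.snr_db is not None:
        sigma = 10.0 ** (-config.snr_db / 20.0)
        T = T * rng.lognormal(mean=0.0, sigma=sigma, size=T.shape)
    angle = kin.angle_deg + rng.normal(0.0, config.angle_noise_deg, kin.theta.shape)
    return TrialRecording(
        time=kin.time,
        angle_x_deg=angle[:, 0],
        angle_y_deg=angle[:, 1],
        emg=T,
        fs=kin.fs,
        task=task,
        direction=direction,
        target_path=kin.angle_deg if task == "pursuit" else None,
        emg_kind="tension",
        meta={"hold_samples": kin.hold_samples, "subject_id": truth.subject_id},
    )


def _make_rest(truth: SubjectTruth, config: SyntheticConfig,
               rng: np.random.Generator) -> CalibrationRecording:
    n = int(round(2.0 * config.fs))
    rest = np.tile(config.co_contraction * cocontraction_pattern(truth.A), (n, 1))
    if config.snr_db is not None:
        sigma = 10.0 ** (-config.snr_db / 20.0)
        rest = rest * rng.lognormal(mean=0.0, sigma=sigma, size=rest.shape)
    return CalibrationRecording(
        emg=rest, central_rest=rest, fs=config.fs, emg_kind="tension"
    )


def _draw_truth(
    subject_id: str,
    group: str,
    model: GroupRatioModel,
    config: SyntheticConfig,
    rng: np.random.Generator,
    specs: list[MuscleSpec],
) -> SubjectTruth:
    # M scales as r^5 (mass itself grows as r^3), so the radius spread is
    # kept tight; bounds map to the reported inertia range 0.0012-0.0023
    r = rng.normal(config.hand_radius_m, config.hand_radius_sd_m)
    r = float(np.clip(r, 0.0456, 0.0521))
    mass = 4.0 / 3.0 * np.pi * r**3 * HAND_DENSITY_KG_M3
    M = hand_inertia(mass, r)

    gains = rng.uniform(0.15, 0.30, size=len(specs))
    A = _action_matrix(specs, gains)

    bk = {}
    for task, (mu, sd) in (
        ("step", (model.step_mean, model.step_sd)),
        ("pursuit", (model.pursuit_mean, model.pursuit_sd)),
    ):
        ratio = rng.normal(mu, sd)
        while ratio < model.min_ratio:
            ratio = rng.normal(mu, sd)
        K = rng.uniform(0.15, 0.30)
        bk[task] = (ratio * K, K)
    return SubjectTruth(
        subject_id=subject_id, group=group, M=M,
        hand_mass_kg=float(mass), hand_radius_m=r, A=A, bk=bk,
    )


def generate_subject(
    subject_id: str,
    group: str,
    rng: np.random.Generator,
    config: SyntheticConfig = SyntheticConfig(),
    model: GroupRatioModel | None = None,
    specs: list[MuscleSpec] | None = None,
    tasks=("step", "pursuit"),
) -> SyntheticSubject:
    """One virtual subject: ground truth plus a full trial set."""
    if specs is None:
        specs = default_muscles()
    if model is None:
        model = STUDY_RATIO_MODELS.get(group, STUDY_RATIO_MODELS["control"])
    truth = _draw_truth(subject_id, group, model, config, rng, specs)

    trials: dict[str, list] = {}
    if "step" in tasks:
        trials["step"] = [
            make_trial(
                make_step_kinematics(d, config, rng=rng),
                truth, "step", config, rng, direction=d, specs=specs,
            )
            for _rep in range(config.reps_step)
            for d in DIRECTION_ANGLES
        ]
    if "pursuit" in tasks:
        kin = make_pursuit_kinematics(config)
        trials["pursuit"] = [
            make_trial(kin, truth, "pursuit", config, rng, specs=specs)
            for _rep in range(config.reps_pursuit)
        ]
    rest = _make_rest(truth, config, rng)
    return SyntheticSubject(truth=truth, trials=trials, rest=rest)


def generate_cohort(
    n_controls: int = 10,
    n_patients: int = 19,
    seed: int = 0,
    config: SyntheticConfig = SyntheticConfig(),
    models: dict | None = None,
    specs: list[MuscleSpec] | None = None,
    tasks=("step", "pursuit"),
) -> Cohort:
    """Virtual cohort emulating the study design (10 controls, 19 patients).

    Per-subject ground-truth ratios are drawn from the group/task
    distributions (defaults: the reported group moments).  Fully
    reproducible from ``seed``; n = 0 groups are valid and empty.
    """
    if models is None:
        models = STUDY_RATIO_MODELS
    rng = np.random.default_rng(seed)
    subjects = []
    for group, count, prefix in (("control", n_controls, "C"), ("patient", n_patients, "P")):
        if count < 0:
            raise ValueError(f"negative subject count for {group}")
        for i in range(count):
            subjects.append(
                generate_subject(
                    f"{prefix}{i + 1}", group, rng, config,
                    model=models[group], specs=specs, tasks=tasks,
                )
            )
    return Cohort(subjects=subjects, config=config, seed=seed)
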