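"""EMG and kinematics preprocessing.

Raw surface EMG is rectified and smoothed with a zero-phase second-order
Butterworth low-pass (3.0 Hz cutoff) to obtain a tension envelope.  The
envelope is scaled so that the level produced by 0.78 Nm of isometric
wrist torque equals 1, and the resting level at the central position is
subtracted, giving the dimensionless muscle tension T_i(t).  Wrist angles
are converted to radians, smoothed with the same zero-phase filter and
differentiated to angular velocity and acceleration.

All filtering is zero-phase (forward-backward), so EMG and kinematics keep
their relative timing, which the torque-correlation analysis relies on.
After filtering, channels are decimated to a 100 Hz working rate: the
3 Hz-band signals are vastly oversampled at the 2 kHz acquisition rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

__all__ = [
    "TrialRecording",
    "CalibrationRecording",
    "ProcessedTrial",
    "NoMovementError",
    "REFERENCE_TORQUE_NM",
    "WORKING_RATE_HZ",
    "rectify_and_envelope",
    "normalize_tension",
    "differentiate_kinematics",
    "detect_movement_onset",
    "tangential_speed",
    "process_trial",
]

REFERENCE_TORQUE_NM = 0.78  # isometric torque whose tension envelope defines 1.0
WORKING_RATE_HZ = 100.0


class NoMovementError(RuntimeError):
    """Raised when a trial contains no detectable movement."""


@dataclass
class TrialRecording:
    """Raw synchronized wrist angles and 4-channel EMG for one trial.

    ``emg`` holds raw volts when ``emg_kind == "raw"``, a rectified
    envelope (volt scale) for ``"envelope"``, or already-normalized
    tensions (0.78 Nm scale, baseline not yet subtracted) for
    ``"tension"``; synthetic trials use the latter.
    """

    time: np.ndarray          # s, uniform
    angle_x_deg: np.ndarray
    angle_y_deg: np.ndarray
    emg: np.ndarray           # (n, 4) in ECR, ECU, FCU, FCR order
    fs: float
    task: str                 # "step" | "pursuit"
    direction: str | None = None   # step only, one of UP/UR/RT/DR/DN/DL/LF/UL
    target_path: np.ndarray | None = None  # (n, 2) deg, pursuit only
    emg_kind: str = "raw"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        n = len(self.time)
        if not (
            len(self.angle_x_deg) == len(self.angle_y_deg) == n
            and self.emg.shape == (n, 4)
        ):
            raise ValueError("trial channels disagree in length")
        if self.task not in ("step", "pursuit"):
            raise ValueError(f"unknown task {self.task!r}")
        if (self.task == "step") != (self.direction is not None):
            raise ValueError("direction must be present iff task is 'step'")
        _check_uniform_time(self.time, self.fs)


@dataclass
class CalibrationRecording:
    """Isometric calibration: EMG at a known torque plus relaxed rest EMG."""

    emg: np.ndarray           # (n, 4) during isometric torque production
    central_rest: np.ndarray  # (m, 4) relaxed at the central position
    fs: float
    torque_level: float = REFERENCE_TORQUE_NM  # Nm
    emg_kind: str = "raw"

    def __post_init__(self):
        if not self.torque_level > 0:
            raise ValueError(f"torque_level must be positive, got {self.torque_level}")


@dataclass
class ProcessedTrial:
    """Normalized tensions and kinematics on a common (decimated) time base."""

    tension: np.ndarray   # (n, 4), dimensionless, baseline-referenced
    theta_x: np.ndarray   # rad
    theta_y: np.ndarray
    vel_x: np.ndarray     # rad/s
    vel_y: np.ndarray
    acc_x: np.ndarray     # rad/s^2
    acc_y: np.ndarray
    fs_out: float
    task: str
    direction: str | None = None
    target_path: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return len(self.theta_x)

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs_out

    def theta(self) -> np.ndarray:
        return np.column_stack([self.theta_x, self.theta_y])

    def vel(self) -> np.ndarray:
        return np.column_stack([self.vel_x, self.vel_y])

    def acc(self) -> np.ndarray:
        return np.column_stack([self.acc_x, self.acc_y])


def _check_uniform_time(time: np.ndarray, fs: float, rtol: float = 1e-6) -> None:
    dt = np.diff(time)
    if len(dt) and (np.any(dt <= 0) or np.ptp(dt) > rtol / fs):
        raise ValueError("time must be strictly increasing with constant step 1/fs")
    if len(dt) and abs(dt[0] - 1.0 / fs) > rtol / fs:
        raise ValueError(f"time step {dt[0]:g} inconsistent with fs={fs:g}")


def _lowpass_sos(fs: float, cutoff: float, order: int):
    if cutoff >= fs / 2:
        raise ValueError(f"cutoff {cutoff} Hz must be below Nyquist ({fs / 2} Hz)")
    return sps.butter(order, cutoff, btype="low", fs=fs, output="sos")


def lowpass_zero_phase(x, fs: float, cutoff: float = 3.0, order: int = 2) -> np.ndarray:
    """Zero-phase Butterworth low-pass (applied forward and backward)."""
    sos = _lowpass_sos(fs, cutoff, order)
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=float), axis=0)


def rectify_and_envelope(
    raw, fs: float, cutoff: float = 3.0, order: int = 2
) -> np.ndarray:
    """Full-wave rectify and low-pass raw EMG into a tension envelope.

    Small negative excursions from filter ringing are clipped to zero.
    Positively homogeneous: envelope(c x) = c envelope(x) for c > 0.
    """
    raw = np.asarray(raw, dtype=float)
    if not np.all(np.isfinite(raw)):
        raise ValueError("raw EMG contains non-finite values")
    if fs <= 2 * cutoff:
        raise ValueError(f"fs={fs} too low for cutoff {cutoff} Hz")
    env = lowpass_zero_phase(np.abs(raw), fs, cutoff, order)
    return np.clip(env, 0.0, None)


def calibration_gain(
    calib_envelope_level: float,
    torque_level: float = REFERENCE_TORQUE_NM,
    noise_floor: float = 0.0,
) -> float:
    """Envelope amplitude corresponding to the 0.78 Nm reference torque.

    The calibration contraction at ``torque_level`` Nm produced an envelope
    of amplitude ``calib_envelope_level``; linear scaling maps it to the
    reference.
    """
    if calib_envelope_level <= noise_floor:
        raise ValueError(
            f"calibration envelope level {calib_envelope_level:g} is at or below "
            f"the noise floor {noise_floor:g}; calibration unusable"
        )
    return calib_envelope_level * REFERENCE_TORQUE_NM / torque_level


def normalize_tension(
    envelope,
    calib_envelope_level: float,
    torque_level: float = REFERENCE_TORQUE_NM,
    baseline: float | None = None,
    central_hold: slice | None = None,
    noise_floor: float = 0.0,
) -> np.ndarray:
    """Scale an envelope to the 0.78 Nm reference and subtract the rest level.

    ``baseline`` is the resting normalized tension at the central position;
    if not given it is taken as the mean normalized envelope over
    ``central_hold``.  Output may be negative after baseline subtraction.
    """
    envelope = np.asarray(envelope, dtype=float)
    gain = calibration_gain(calib_envelope_level, torque_level, noise_floor)
    tension = envelope / gain
    if baseline is None:
        if central_hold is None:
            baseline = 0.0
        else:
            baseline = float(np.mean(tension[central_hold]))
    return tension - baseline


def differentiate_kinematics(
    angle_deg,
    fs: float,
    smooth_cutoff: float | None = 3.0,
    order: int = 2,
):
    """Angle (deg) -> (theta rad, vel rad/s, acc rad/s^2).

    The angle is low-pass filtered (zero phase) before central-difference
    differentiation so that the acceleration is not noise dominated; pass
    ``smooth_cutoff=None`` to skip smoothing.  Endpoints use one-sided
    differences (numpy.gradient), so all outputs keep the input length.
    """
    angle_deg = np.asarray(angle_deg, dtype=float)
    if angle_deg.shape[0] < 5:
        raise ValueError("need at least 5 samples to differentiate")
    theta = np.deg2rad(angle_deg)
    if smooth_cutoff is not None:
        theta = lowpass_zero_phase(theta, fs, smooth_cutoff, order)
    vel = np.gradient(theta, 1.0 / fs, axis=0)
    acc = np.gradient(vel, 1.0 / fs, axis=0)
    return theta, vel, acc


def tangential_speed(vel_x, vel_y) -> np.ndarray:
    return np.hypot(np.asarray(vel_x, dtype=float), np.asarray(vel_y, dtype=float))


def detect_movement_onset(
    speed,
    fs: float,
    threshold_frac: float = 0.05,
    sustain_s: float = 0.05,
) -> float:
    """First time tangential speed exceeds 5% of its peak for >= 50 ms.

    Returns the onset time in seconds relative to the start of the series.
    """
    speed = np.asarray(speed, dtype=float)
    peak = np.max(speed) if speed.size else 0.0
    if peak <= 0:
        raise NoMovementError("no movement: tangential speed is identically zero")
    above = speed > threshold_frac * peak
    need = max(1, int(round(sustain_s * fs)))
    # first index where `above` holds for `need` consecutive samples
    run = 0
    for i, flag in enumerate(above):
        run = run + 1 if flag else 0
        if run >= need:
            return (i - need + 1) / fs
    raise NoMovementError(
        f"no sustained crossing of {threshold_frac:.0%} of peak speed"
    )


def _decimate_factor(fs: float, fs_out: float) -> int:
    factor = fs / fs_out
    if abs(factor - round(factor)) > 1e-9 or factor < 1:
        raise ValueError(f"fs {fs} is not an integer multiple of fs_out {fs_out}")
    return int(round(factor))


def process_trial(
    trial: TrialRecording,
    calib: CalibrationRecording | None = None,
    cutoff: float = 3.0,
    order: int = 2,
    fs_out: float = WORKING_RATE_HZ,
) -> ProcessedTrial:
    """Full preprocessing of one trial into model inputs.

    EMG handling depends on ``trial.emg_kind``:

    - ``"raw"``: rectify + envelope, then normalize against the calibration
      contraction and subtract the rest baseline (both from ``calib``).
    - ``"envelope"``: normalize and baseline-subtract only.
    - ``"tension"``: already on the reference scale; only the rest baseline
      (mean of ``calib.central_rest``) is subtracted.

    Kinematics are smoothed with the same zero-phase filter and
    differentiated.  Everything is decimated to ``fs_out`` (the signals are
    band-limited to ``cutoff`` beforehand, so plain subsampling is exact
    enough and keeps channel alignment trivial).
    """
    kind = trial.emg_kind
    if kind == "raw":
        env = rectify_and_envelope(trial.emg, trial.fs, cutoff, order)
    elif kind in ("envelope", "tension"):
        env = np.asarray(trial.emg, dtype=float)
    else:
        raise ValueError(f"unknown emg_kind {kind!r}")

    if kind == "tension":
        if calib is not None:
            baseline = np.mean(np.asarray(calib.central_rest, dtype=float), axis=0)
        else:
            baseline = np.zeros(env.shape[1])
        tension = env - baseline
    else:
        if calib is None:
            raise ValueError(f"emg_kind {kind!r} requires a calibration recording")
        if calib.emg_kind == "raw":
            calib_env = rectify_and_envelope(calib.emg, calib.fs, cutoff, order)
            rest_env = rectify_and_envelope(calib.central_rest, calib.fs, cutoff, order)
        else:
            calib_env = np.asarray(calib.emg, dtype=float)
            rest_env = np.asarray(calib.central_rest, dtype=float)
        levels = np.mean(calib_env, axis=0)
        tension = np.column_stack(
            [
                normalize_tension(
                    env[:, i],
                    levels[i],
                    calib.torque_level,
                    baseline=float(
                        np.mean(rest_env[:, i])
                        / calibration_gain(levels[i], calib.torque_level)
                    ),
                )
                for i in range(env.shape[1])
            ]
        )

    angles = np.column_stack([trial.angle_x_deg, trial.angle_y_deg])
    theta, vel, acc = differentiate_kinematics(angles, trial.fs, cutoff, order)

    step = _decimate_factor(trial.fs, fs_out)
    sl = slice(None, None, step)
    target = trial.target_path[sl] if trial.target_path is not None else None
    meta = dict(trial.meta)
    if "hold_samples" in meta:
        meta["hold_samples"] = int(meta["hold_samples"]) // step
    return ProcessedTrial(
        tension=np.ascontiguousarray(tension[sl]),
        theta_x=theta[sl, 0],
        theta_y=theta[sl, 1],
        vel_x=vel[sl, 0],
        vel_y=vel[sl, 1],
        acc_x=acc[sl, 0],
        acc_y=acc[sl, 1],
        fs_out=fs_out,
        task=trial.task,
        direction=trial.direction,
        target_path=target,
        meta=meta,
    )
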