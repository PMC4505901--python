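"""Linear viscoelastic model of the wrist joint.

The wrist is modeled as a second-order linear plant shared by its two
degrees of freedom (flexion/extension on x, radial/ulnar deviation on y):

    tau(t) = sum_i a_i T_i(t) = M theta''(t) + B theta'(t) + K theta(t)

where ``T_i`` are the normalized tensions of the four prime movers (ECR,
ECU, FCU, FCR), ``a_i`` convert tension into joint torque (Nm per unit
tension, sign-constrained by each muscle's pulling direction), and M
(kg m^2), B (Nm s/rad), K (Nm/rad) are inertia, viscosity and elasticity.
M, B, K are scalars shared by both axes; the a_i are axis-specific.

Only ratios of (M, B, K) are identifiable from tensions and kinematics
alone, hence the fitted values are denoted M_r, B_r, K_r elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import yaml

__all__ = [
    "MuscleSpec",
    "WristParams",
    "MUSCLE_NAMES",
    "default_muscles",
    "load_muscles",
    "hand_inertia",
    "kinematic_torque",
    "muscle_torque",
    "damping_ratio",
]

MUSCLE_NAMES = ("ECR", "ECU", "FCU", "FCR")


@dataclass(frozen=True)
class MuscleSpec:
    """Identity, directional tuning and sign constraints of one muscle.

    Angles are in cursor-space degrees (extension = 0, radial = 90).
    ``preferred_direction`` is the movement direction of maximal activity;
    ``action_direction`` is the direction of mechanical pull, which the
    sign constraints (``sign_x``, ``sign_y``; +1, -1 or 0 = free) encode
    per torque axis.
    """

    name: str
    preferred_direction: float
    sign_x: int
    sign_y: int
    action_direction: float | None = None

    def sign(self, axis: str) -> int:
        if axis == "x":
            return self.sign_x
        if axis == "y":
            return self.sign_y
        raise ValueError(f"axis must be 'x' or 'y', got {axis!r}")


def load_muscles(path) -> list[MuscleSpec]:
    """Load a muscle table from a YAML file (see the packaged default)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    specs = [MuscleSpec(**entry) for entry in doc["muscles"]]
    _validate_muscles(specs)
    return specs


def default_muscles() -> list[MuscleSpec]:
    """The packaged four-muscle table (ECR, ECU, FCU, FCR)."""
    ref = resources.files("wristid.data").joinpath("muscles.yaml")
    with resources.as_file(ref) as path:
        return load_muscles(path)


def _validate_muscles(specs: list[MuscleSpec]) -> None:
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate muscle names in spec: {names}")
    if len(specs) >= 3:
        pds = np.sort(np.array([s.preferred_direction % 360.0 for s in specs]))
        gaps = np.diff(np.concatenate([pds, [pds[0] + 360.0]]))
        if np.max(gaps) >= 180.0:
            raise ValueError(
                "preferred directions must spread around the circle "
                f"(largest gap {np.max(gaps):.0f} deg >= 180), got {pds.tolist()}"
            )


def hand_inertia(mass: float, radius: float) -> float:
    """Moment of inertia of the hand about the wrist, M = 7 m r^2 / 5.

    The hand is idealized as a homogeneous sphere of mass ``mass`` (kg) and
    radius ``radius`` (m) rotating about an axis on its surface
    (solid-sphere moment 2mr^2/5 plus the parallel-axis term mr^2).
    """
    if not (mass > 0 and radius > 0):
        raise ValueError(f"mass and radius must be positive, got {mass}, {radius}")
    return 7.0 * mass * radius**2 / 5.0


def kinematic_torque(theta, vel, acc, M: float, B: float, K: float) -> np.ndarray:
    """Joint torque from kinematics: tau = M theta'' + B theta' + K theta.

    ``theta`` (rad), ``vel`` (rad/s), ``acc`` (rad/s^2) may be 1-D (one
    axis) or (n, 2) arrays; the torque has the same shape (Nm).
    """
    theta, vel, acc = (np.asarray(a, dtype=float) for a in (theta, vel, acc))
    if not (theta.shape == vel.shape == acc.shape):
        raise ValueError(
            f"kinematic channels disagree in shape: {theta.shape}, {vel.shape}, {acc.shape}"
        )
    if not all(np.all(np.isfinite(a)) for a in (theta, vel, acc)):
        raise ValueError("kinematic channels contain non-finite values")
    return M * acc + B * vel + K * theta


def muscle_torque(
    tension,
    a,
    specs: list[MuscleSpec] | None = None,
    axis: str = "x",
) -> np.ndarray:
    """Joint torque from muscle tensions: tau = sum_i a_i T_i.

    Parameters
    ----------
    tension : (n, 4) array of normalized tensions, muscle order per ``specs``.
    a : (4,) tension-to-torque weights for one axis (Nm per unit tension).
    specs : if given, the sign of each a_i is checked against the muscle's
        constraint on ``axis``; a violation raises ``ValueError``.
    """
    tension = np.atleast_2d(np.asarray(tension, dtype=float))
    a = np.asarray(a, dtype=float)
    if tension.shape[1] != a.shape[0]:
        raise ValueError(
            f"{tension.shape[1]} tension channels but {a.shape[0]} weights"
        )
    if specs is not None:
        for weight, spec in zip(a, specs):
            s = spec.sign(axis)
            if s != 0 and weight * s < 0:
                raise ValueError(
                    f"weight a={weight:g} for {spec.name} violates its "
                    f"sign constraint ({s:+d}) on axis {axis}"
                )
    return tension @ a


def damping_ratio(M: float, B: float, K: float) -> float:
    """Damping ratio zeta = B / (2 sqrt(K M)).

    zeta < 1: underdamped; zeta > 1: overdamped.  Invariant under joint
    rescaling of (M, B, K), so it is well defined for the ratio-only
    parameters identified here.
    """
    if M <= 0 or K <= 0:
        raise ValueError(f"M and K must be positive, got M={M}, K={K}")
    if B < 0:
        raise ValueError(f"B must be nonnegative, got {B}")
    return B / (2.0 * np.sqrt(K * M))
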