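"""Uncentered canonical correlation identification of the joint model.

The muscle tensions (4 channels per axis) and the kinematic channels
(acceleration, velocity, position) are treated as the two variable sets of
a canonical correlation analysis computed WITHOUT mean subtraction: the
cross-product matrices X'X, X'Y, Y'Y are formed from the raw data, which
keeps the physical zero of each channel meaningful (the analogue of the
SAS CANCORR ``NOINT`` option).  The first canonical weight vectors give,
up to a common scale, the muscle-to-torque weights a_i and the kinematic
weights (M_r, B_r, K_r); only ratios of the latter are identifiable, and
B_r/K_r is the quantity of interest.

By default the two wrist axes are stacked into one problem: the kinematic
weights are shared across axes (scalar M, B, K) while each axis keeps its
own four muscle weights.  A per-axis mode is also available since the two
conventions cannot be distinguished from the published analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .model import MuscleSpec, default_muscles
from .signal import ProcessedTrial

__all__ = ["CCAResult", "build_design_matrices", "cca_uncentered", "identify_task"]


@dataclass
class CCAResult:
    """First-pair canonical solution, normalized so that K_r = 1."""

    weights_kin: tuple            # (M_r, B_r, K_r) or (B_r, K_r)
    weights_muscle: dict          # axis -> (4,) array of a_i
    cc: float                     # first canonical correlation
    all_cc: np.ndarray            # all canonical correlations, descending
    eigen_proportion_first: float
    ratio: float                  # B_r / K_r
    included_acceleration: bool
    mr_over_kr: float | None = None
    n_samples: int = 0
    axis_mode: str = "both"
    sign_violations: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "weights_kin": [float(w) for w in self.weights_kin],
            "weights_muscle": {k: [float(v) for v in w] for k, w in self.weights_muscle.items()},
            "cc": float(self.cc),
            "all_cc": [float(c) for c in self.all_cc],
            "eigen_proportion_first": float(self.eigen_proportion_first),
            "ratio": float(self.ratio),
            "mr_over_kr": None if self.mr_over_kr is None else float(self.mr_over_kr),
            "included_acceleration": self.included_acceleration,
            "n_samples": int(self.n_samples),
            "axis_mode": self.axis_mode,
            "sign_violations": self.sign_violations,
        }


def _trial_moving(trial: ProcessedTrial, min_excursion_deg: float) -> bool:
    peak = max(
        np.max(np.abs(trial.theta_x)), np.max(np.abs(trial.theta_y))
    )
    return np.rad2deg(peak) > min_excursion_deg


def build_design_matrices(
    trials: list[ProcessedTrial],
    include_acceleration: bool = True,
    axis: str = "both",
    min_excursion_deg: float = 1.0,
):
    """Stack trials into the tension design X and kinematic design Y.

    ``axis="both"`` stacks axis-x rows on top of axis-y rows: Y is
    (2n, 3) (or (2n, 2) without acceleration) with columns (acc, vel,
    theta), and X is (2n, 8) block-structured so each axis has its own
    four muscle columns while the kinematic weights are shared.  With
    ``axis="x"``/``"y"`` both matrices cover a single axis (X is (n, 4)).

    Trials with peak excursion below ``min_excursion_deg`` are dropped.
    """
    kept = [t for t in trials if _trial_moving(t, min_excursion_deg)]
    if not kept:
        raise ValueError("no trials with movement to identify from")

    T = np.vstack([t.tension for t in kept])
    theta = np.vstack([t.theta() for t in kept])
    vel = np.vstack([t.vel() for t in kept])
    acc = np.vstack([t.acc() for t in kept])

    def kin_cols(ax: int) -> np.ndarray:
        cols = [acc[:, ax], vel[:, ax], theta[:, ax]]
        if not include_acceleration:
            cols = cols[1:]
        return np.column_stack(cols)

    if axis in ("x", "y"):
        ax = 0 if axis == "x" else 1
        return T.copy(), kin_cols(ax)
    if axis != "both":
        raise ValueError(f"axis must be 'both', 'x' or 'y', got {axis!r}")

    n = T.shape[0]
    X = np.zeros((2 * n, 8))
    X[:n, :4] = T
    X[n:, 4:] = T
    Y = np.vstack([kin_cols(0), kin_cols(1)])
    return X, Y


def _inv_sqrt(S: np.ndarray, label: str) -> np.ndarray:
    evals, evecs = linalg.eigh(S)
    eps = 1e-12 * max(evals[-1], 1.0)
    if evals[0] < eps:
        warnings.warn(
            f"{label} cross-product matrix is rank deficient; "
            f"ridge-regularizing with epsilon={eps:.3e}",
            RuntimeWarning,
            stacklevel=3,
        )
        evals = evals + eps
    return (evecs / np.sqrt(evals)) @ evecs.T


def cca_uncentered(X, Y):
    """All canonical pairs of X and Y without mean subtraction.

    Returns ``(cc, Wx, Wy)``: canonical correlations in descending order
    and the weight matrices (one column per pair).  Solved by whitening
    X'X and Y'Y (symmetric inverse square roots) and taking the SVD of the
    whitened cross-product.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape[0] != Y.shape[0]:
        raise ValueError(f"row mismatch: X has {X.shape[0]}, Y has {Y.shape[0]}")
    if not np.any(np.abs(X).sum(axis=0) > 0) or not np.any(np.abs(Y).sum(axis=0) > 0):
        raise ValueError("X and Y must each have at least one nonzero column")
    Sxx = X.T @ X
    Syy = Y.T @ Y
    Sxy = X.T @ Y
    Rx = _inv_sqrt(Sxx, "tension (X)")
    Ry = _inv_sqrt(Syy, "kinematic (Y)")
    U, s, Vt = linalg.svd(Rx @ Sxy @ Ry, full_matrices=False)
    cc = np.clip(s, 0.0, 1.0)
    Wx = Rx @ U
    Wy = Ry @ Vt.T
    return cc, Wx, Wy


def _eigen_proportion_first(cc: np.ndarray) -> float:
    """Share of the first pair in the canonical eigenvalue sum.

    Uses the canonical-analysis eigenvalues lambda_i = cc_i^2 / (1 -
    cc_i^2) (the convention of standard CANCORR output), evaluated in the
    form 1 / (1 + sum_{i>1} lambda_i / lambda_1), which stays finite when
    the first correlation is exactly 1 on noise-free data.
    """
    if cc.size == 0 or cc[0] == 0:
        return 0.0
    c1 = float(cc[0])
    rest = cc[1:]
    with np.errstate(divide="ignore"):
        rel = (rest**2 * (1.0 - c1**2)) / (c1**2 * np.clip(1.0 - rest**2, 1e-300, None))
    return float(1.0 / (1.0 + rel.sum()))


def identify_task(
    trials: list[ProcessedTrial],
    include_acceleration: bool = True,
    axis: str = "both",
    specs: list[MuscleSpec] | None = None,
    min_excursion_deg: float = 1.0,
) -> CCAResult:
    """Identify (M_r, B_r, K_r) and a_i for one subject and task.

    All trials are concatenated into one design.  The first canonical pair
    is sign-normalized so K_r > 0 and scaled so K_r = 1; ``ratio`` is
    B_r/K_r.  No sign constraint is imposed on the muscle weights during
    the CCA; fitted a_i whose signs violate the muscle table are reported
    in ``sign_violations``.
    """
    if specs is None:
        specs = default_muscles()
    X, Y = build_design_matrices(trials, include_acceleration, axis, min_excursion_deg)
    cc, Wx, Wy = cca_uncentered(X, Y)

    wx = Wx[:, 0].copy()
    wy = Wy[:, 0].copy()
    k_r = wy[-1]
    if k_r == 0:
        raise ValueError("degenerate solution: K_r = 0 in the first canonical pair")
    # one common rescaling of both variates leaves the correlation unchanged
    wx /= k_r
    wy /= k_r

    if include_acceleration:
        m_r, b_r, _ = wy
        weights_kin = (m_r, b_r, 1.0)
        mr_over_kr = float(m_r)
    else:
        b_r, _ = wy
        weights_kin = (b_r, 1.0)
        mr_over_kr = None

    if axis == "both":
        weights_muscle = {"x": wx[:4], "y": wx[4:]}
    else:
        weights_muscle = {axis: wx}

    violations = []
    for ax, weights in weights_muscle.items():
        for w, spec in zip(weights, specs):
            s = spec.sign(ax)
            if s != 0 and w * s < 0:
                violations.append((spec.name, ax, float(w)))

    prop = _eigen_proportion_first(cc)
    return CCAResult(
        weights_kin=weights_kin,
        weights_muscle=weights_muscle,
        cc=float(cc[0]),
        all_cc=cc,
        eigen_proportion_first=prop,
        ratio=float(b_r),
        included_acceleration=include_acceleration,
        mr_over_kr=mr_over_kr,
        n_samples=X.shape[0],
        axis_mode=axis,
        sign_violations=violations,
    )
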