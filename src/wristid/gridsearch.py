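"""Grid-search identification of (B_r, K_r) with sign-constrained fits.

The alternative to the canonical-correlation route: for every (B, K) pair
on a physiological grid (0..10 Nm s/rad and 0..10 Nm/rad, step 0.2), the
kinematic torque M theta'' + B theta' + K theta is formed per axis and the
four muscle weights a_i are fitted by least squares under the sign
constraints of the muscle table.  The mean over the two axes of the
correlation R between fitted muscle torque and kinematic torque gives a
surface whose ridge runs along B/K = const (the acceleration term being
negligible, a common rescaling of B and K is absorbed by the a_i); the
reported quantity is the ridge ratio.

The constrained solver enumerates all 2^4 active sets (each weight either
free with its admissible sign or clamped to zero) and keeps the feasible
solution with the smallest residual — exact, deterministic, and cheap for
four muscles.  Because the kinematic torque is linear in (B, K, M), every
active set's solution is linear in (B, K, M) as well, so the whole R
surface is evaluated from a handful of precomputed cross-products rather
than per-cell regressions.

The coarse 0.2 grid cannot represent ratios below 0.2/10; a refinement
pass re-evaluates R along log-spaced ratios around the coarse optimum and
resolves the ridge ratio to a few percent.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .model import MuscleSpec, default_muscles
from .signal import ProcessedTrial

__all__ = [
    "GridResult",
    "fit_muscle_weights_constrained",
    "grid_search_bk",
    "compare_ratio_methods",
]

_FEAS_TOL = 1e-12


@dataclass
class GridResult:
    grid_b: np.ndarray
    grid_k: np.ndarray
    r_surface: np.ndarray       # (len(grid_b), len(grid_k)), mean R over axes
    best_b: float
    best_k: float
    best_ratio: float           # refined if refine=True
    best_r: float               # R at the best (refined) point
    a_best: dict                # axis -> (4,) weights at the best point
    M: float
    refined: bool = False
    refine_ratios: np.ndarray | None = None
    refine_r: np.ndarray | None = None

    def to_dict(self) -> dict:
        return {
            "best_b": float(self.best_b),
            "best_k": float(self.best_k),
            "best_ratio": float(self.best_ratio),
            "best_r": float(self.best_r),
            "a_best": {k: [float(v) for v in w] for k, w in self.a_best.items()},
            "M": float(self.M),
            "refined": self.refined,
        }


def _signs_for_axis(specs: list[MuscleSpec], axis: str) -> np.ndarray:
    return np.array([s.sign(axis) for s in specs], dtype=float)


def _subsets(n: int):
    idx = range(n)
    for k in range(n, -1, -1):
        for S in itertools.combinations(idx, k):
            yield np.array(S, dtype=int)


def _constrained_lstsq(G, c, tautau, signs):
    """Exact sign-constrained least squares via active-set enumeration.

    Minimizes ||tau - T a||^2 given G = T'T, c = T'tau and tau'tau, with
    sign(a_i) in {signs[i], 0} (signs[i] = 0 leaves a_i free).  Returns
    (a, objective, residual) where objective = a.c = ||T a||^2 for the
    least-squares solution on its active set.
    """
    n = len(c)
    best = (np.zeros(n), 0.0, float(tautau))
    for S in _subsets(n):
        if len(S) == 0:
            continue
        GS = G[np.ix_(S, S)]
        try:
            aS = np.linalg.solve(GS, c[S])
        except np.linalg.LinAlgError:
            aS = np.linalg.lstsq(GS, c[S], rcond=None)[0]
        sS = signs[S]
        if np.any((sS != 0) & (aS * sS < -_FEAS_TOL * max(1.0, np.abs(aS).max()))):
            continue
        obj = float(aS @ c[S])
        resid = float(tautau - obj)
        if resid < best[2] - 1e-15 * max(1.0, tautau):
            a = np.zeros(n)
            a[S] = aS
            best = (a, obj, resid)
    return best


def fit_muscle_weights_constrained(
    tension,
    tau,
    specs: list[MuscleSpec] | None = None,
    axis: str = "x",
    signs=None,
):
    """Fit a_i minimizing ||tau - sum a_i T_i||^2 under sign constraints.

    ``signs`` (array of +1/-1/0 per muscle) overrides ``specs``/``axis``.
    Returns ``(a, R)`` with R the uncentered correlation between the
    fitted muscle torque and ``tau`` (the convention of the canonical
    analysis).
    """
    T = np.atleast_2d(np.asarray(tension, dtype=float))
    tau = np.asarray(tau, dtype=float)
    if T.shape[0] != tau.shape[0]:
        raise ValueError(f"length mismatch: {T.shape[0]} tension rows, {len(tau)} torques")
    if not np.any(np.abs(T) > 0):
        raise ValueError("all-zero tensions: correlation undefined")
    if signs is None:
        if specs is None:
            specs = default_muscles()
        signs = _signs_for_axis(specs, axis)
    signs = np.asarray(signs, dtype=float)
    G = T.T @ T
    c = T.T @ tau
    tautau = float(tau @ tau)
    a, obj, _ = _constrained_lstsq(G, c, tautau, signs)
    R = float(np.sqrt(obj / tautau)) if tautau > 0 and obj > 0 else 0.0
    return a, R


class _AxisCrossProducts:
    """Cross-products that make the (B, K) surface a closed-form quadratic."""

    def __init__(self, T, theta, vel, acc, signs):
        self.G = T.T @ T
        self.c_v = T.T @ vel
        self.c_t = T.T @ theta
        self.c_a = T.T @ acc
        self.vv = float(vel @ vel)
        self.tt = float(theta @ theta)
        self.aa = float(acc @ acc)
        self.vt = float(vel @ theta)
        self.va = float(vel @ acc)
        self.ta = float(theta @ acc)
        self.signs = signs
        self._prep_subsets()

    def _prep_subsets(self):
        self.sub = []
        for S in _subsets(4):
            if len(S) == 0:
                continue
            GS = self.G[np.ix_(S, S)]
            try:
                W = np.linalg.inv(GS)
            except np.linalg.LinAlgError:
                W = np.linalg.pinv(GS)
            P = W @ self.c_v[S]
            Q = W @ self.c_t[S]
            R0 = W @ self.c_a[S]
            self.sub.append((S, P, Q, R0))

    def tautau(self, B, K, M):
        return (
            B**2 * self.vv + K**2 * self.tt + M**2 * self.aa
            + 2 * B * K * self.vt + 2 * B * M * self.va + 2 * K * M * self.ta
        )

    def best_objective(self, B, K, M):
        """Max over feasible active sets of ||T a||^2 on a (B, K) mesh."""
        best = np.zeros(np.broadcast(B, K).shape)
        which = np.full(best.shape, -1, dtype=int)
        for si, (S, P, Q, R0) in enumerate(self.sub):
            cv, ct, ca = self.c_v[S], self.c_t[S], self.c_a[S]
            a = (
                B[..., None] * P + K[..., None] * Q + M * R0
            )  # (..., k) solution surfaces
            sS = self.signs[S]
            con = sS != 0
            feas = np.all(a[..., con] * sS[con] >= -1e-9, axis=-1)
            obj = (
                B**2 * (P @ cv) + K**2 * (Q @ ct) + M**2 * (R0 @ ca)
                + B * K * (P @ ct + Q @ cv)
                + B * M * (P @ ca + R0 @ cv)
                + K * M * (Q @ ca + R0 @ ct)
            )
            upd = feas & (obj > best)
            best = np.where(upd, obj, best)
            which = np.where(upd, si, which)
        return best, which

    def weights_at(self, B, K, M):
        a, _, _ = _constrained_lstsq(
            self.G,
            B * self.c_v + K * self.c_t + M * self.c_a,
            self.tautau(B, K, M),
            self.signs,
        )
        return a


def _concat_axis(trials, axis_idx):
    T = np.vstack([t.tension for t in trials])
    theta = np.concatenate([t.theta()[:, axis_idx] for t in trials])
    vel = np.concatenate([t.vel()[:, axis_idx] for t in trials])
    acc = np.concatenate([t.acc()[:, axis_idx] for t in trials])
    return T, theta, vel, acc


def grid_search_bk(
    trials: list[ProcessedTrial],
    M: float,
    grid_b=None,
    grid_k=None,
    refine: bool = True,
    specs: list[MuscleSpec] | None = None,
) -> GridResult:
    """Exhaustive (B, K) search with per-cell sign-constrained fits.

    ``M`` is the subject's hand inertia (kg m^2) from anthropometry.  Each
    cell's score is the mean over the x and y axes of the uncentered
    correlation R between the fitted muscle torque and the kinematic
    torque.  The cell B = K = 0 is skipped (torque reduces to the
    near-zero inertial term).  With ``refine=True`` a log-spaced pass
    along the ratio direction around the coarse optimum resolves ratios
    finer than the 0.2 grid step.
    """
    if specs is None:
        specs = default_muscles()
    if grid_b is None:
        grid_b = np.arange(0.0, 10.0 + 1e-9, 0.2)
    if grid_k is None:
        grid_k = np.arange(0.0, 10.0 + 1e-9, 0.2)
    grid_b = np.asarray(grid_b, dtype=float)
    grid_k = np.asarray(grid_k, dtype=float)
    if grid_b.size == 0 or grid_k.size == 0:
        raise ValueError("empty grid")
    if not trials:
        raise ValueError("no trials")

    axes = []
    for ax_idx, ax in enumerate("xy"):
        T, theta, vel, acc = _concat_axis(trials, ax_idx)
        axes.append(_AxisCrossProducts(T, theta, vel, acc, _signs_for_axis(specs, ax)))

    B = grid_b[:, None]
    K = grid_k[None, :]
    r_surface = np.zeros((grid_b.size, grid_k.size))
    for cp in axes:
        obj, _ = cp.best_objective(B, K, M)
        tt = cp.tautau(B, K, M)
        with np.errstate(invalid="ignore", divide="ignore"):
            r_ax = np.sqrt(np.clip(obj, 0.0, None) / tt)
        r_surface += np.nan_to_num(r_ax, nan=0.0) / len(axes)
    r_surface[(grid_b[:, None] == 0) & (grid_k[None, :] == 0)] = np.nan

    flat = np.nan_to_num(r_surface, nan=-np.inf)
    ib, ik = np.unravel_index(np.argmax(flat), flat.shape)
    best_b, best_k = float(grid_b[ib]), float(grid_k[ik])
    best_r = float(r_surface[ib, ik])
    best_ratio = best_b / best_k if best_k > 0 else np.inf

    refined = False
    refine_ratios = refine_r = None
    if refine:
        if np.isfinite(best_ratio) and best_ratio > 0:
            center = best_ratio
        elif best_ratio == 0:
            center = 0.05  # ridge at or below the grid resolution
        else:
            center = grid_b[-1] / max(grid_k[1] if grid_k.size > 1 else 1.0, 1e-6)
        refine_ratios = center * np.logspace(-2, 2, 161, base=2.0)
        k0 = best_k if best_k > 0 else max(grid_k[grid_k > 0].min(initial=0.2), 0.2)
        rr = np.zeros_like(refine_ratios)
        for cp in axes:
            obj, _ = cp.best_objective(refine_ratios * k0, np.full_like(refine_ratios, k0), M)
            tt = cp.tautau(refine_ratios * k0, np.full_like(refine_ratios, k0), M)
            rr += np.sqrt(np.clip(obj, 0.0, None) / tt) / len(axes)
        j = int(np.argmax(rr))
        if rr[j] >= best_r - 1e-12:
            best_ratio = float(refine_ratios[j])
            best_r = float(rr[j])
            best_b, best_k = best_ratio * k0, k0
        refined = True
        refine_r = rr

    a_best = {
        ax: axes[i].weights_at(best_b, best_k, M) for i, ax in enumerate("xy")
    }
    return GridResult(
        grid_b=grid_b,
        grid_k=grid_k,
        r_surface=r_surface,
        best_b=best_b,
        best_k=best_k,
        best_ratio=float(best_ratio),
        best_r=best_r,
        a_best=a_best,
        M=M,
        refined=refined,
        refine_ratios=refine_ratios,
        refine_r=refine_r,
    )


def compare_ratio_methods(cca_results, grid_results) -> dict:
    """Pair per-subject ratios from the canonical and grid-search routes.

    Returns the paired ratios, their Pearson correlation across subjects
    (flagged undefined for fewer than two pairs or zero variance), and the
    least-squares line through the pairs.
    """
    cca_ratios = np.array([r.ratio for r in np.atleast_1d(cca_results)])
    grid_ratios = np.array([g.best_ratio for g in np.atleast_1d(grid_results)])
    if cca_ratios.shape != grid_ratios.shape:
        raise ValueError("paired results required")
    out = {
        "pairs": np.column_stack([cca_ratios, grid_ratios]),
        "n": len(cca_ratios),
        "correlation": np.nan,
        "correlation_defined": False,
        "slope": np.nan,
        "intercept": np.nan,
    }
    if len(cca_ratios) >= 2 and np.std(cca_ratios) > 0 and np.std(grid_ratios) > 0:
        out["correlation"] = float(np.corrcoef(cca_ratios, grid_ratios)[0, 1])
        out["correlation_defined"] = True
        slope, intercept = np.polyfit(cca_ratios, grid_ratios, 1)
        out["slope"], out["intercept"] = float(slope), float(intercept)
    return out
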