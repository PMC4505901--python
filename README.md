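# wristid

Quantifying the *composition* of motor commands for wrist movements — how
much of the muscle drive encodes position and how much encodes velocity —
from surface EMG of the four wrist prime movers and the recorded
movement kinematics.

## Problem and model

During visually guided wrist tasks (2 degrees of freedom: flexion/extension
and radial/ulnar deviation), the joint torque produced by the four prime
movers (ECR, ECU, FCU, FCR) can be written two ways:

```
tau(t) = sum_i a_i T_i(t) = M theta''(t) + B theta'(t) + K theta(t)
```

The left route builds *muscle torque* from the normalized muscle tensions
`T_i` (rectified, 3 Hz low-passed EMG envelopes scaled so that 0.78 Nm of
isometric torque maps to 1, with the resting level at the central position
subtracted); the `a_i` are sign-constrained by each muscle's pulling
direction.  The right route builds *kinematic torque* from the wrist
angle, velocity and acceleration with scalar inertia M (kg m²), viscosity
B (Nm s/rad) and elasticity K (Nm/rad) shared by the two axes.

Because the torque itself is not measured, only *ratios* of (M, B, K) are
identifiable.  The package estimates them two ways:

- **Uncentered canonical correlation** between the tension set and the
  kinematic set (no mean subtraction, so the physical zero of every
  channel is preserved); the first canonical pair yields `(M_r, B_r, K_r)`
  up to scale and the muscle weights per axis.
- **Grid search**: for every (B, K) on a physiological grid
  (0–10, step 0.2, with a log-spaced ratio refinement around the ridge),
  fit the `a_i` by exact sign-constrained least squares (active-set
  enumeration) and score the correlation R between the two torque
  estimates; the R surface is constant along rays B/K = const and its
  ridge identifies the ratio.

The headline statistic is the **B_r/K_r ratio**: below 1, the command is
position-dominant; above 1, velocity is weighted comparably or more.  The
related damping ratio is `zeta = B / (2 sqrt(K M))` (underdamped < 1 <
overdamped).  The inertia is computed from hand anthropometry as
`M = 7 m r^2 / 5` (sphere rotating about an axis on its surface).
In healthy subjects the ratio switches with the task — low for rapid
8-direction step tracking, high for constant-speed (6.2°/s) pursuit of a
smooth closed path — and this task-dependent switch collapses in
cerebellar ataxia, making the ratio pair a quantitative motor-function
marker.  A packaged reference table carries the published per-subject
ratios of 10 controls and 19 patients for the group statistics
(Mann-Whitney U, Student's t, range-overlap).

Because no recordings were deposited, the package ships a first-class
synthetic-data generator that inverts the model: task kinematics (minimum-
jerk steps, arc-length-constant figure-eight pursuit) → torque → exact
nonnegative tension decomposition along muscle pulling directions, plus
co-contraction (torque-free by construction) and EMG-like multiplicative
envelope noise.  Parameter recovery on virtual cohorts is the principal
validation surface.

## Worked example

```
$ python examples/01_identify_subject.py
ground truth: step B*/K* = 0.092, pursuit B*/K* = 1.215, hand inertia M = 0.00176 kg m^2
step     B_r/K_r = 0.091  CC = 0.988  zeta = 0.56 (underdamped)  M_r/K_r = 0.0067  first-pair eigenvalue share = 1.000
pursuit  B_r/K_r = 1.225  CC = 0.979  zeta = 8.54 (overdamped)  M_r/K_r = 0.0051  first-pair eigenvalue share = 0.987
```

A virtual control subject is generated with known parameters; the
identification recovers the position-dominant step command (ratio 0.091
vs true 0.092) and the velocity-weighted pursuit command (1.225 vs
1.215), with canonical correlations near 0.98 and a negligible inertial
weight M_r/K_r — the acceleration term can be dropped without changing
the ratio.  The other examples cover the grid-search ridge (`02`),
directional tuning and agonist/displacement correlations (`03`), the
reference-cohort group comparison (`04`), and cohort-level parameter
recovery (`05`).

A thin CLI mirrors the pipeline for file-based use:

```
wristid simulate --seed 7 --subjects 3 --out sim/
wristid identify-cca sim/C1 --task pursuit
wristid compare-groups
wristid report sim/
```

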