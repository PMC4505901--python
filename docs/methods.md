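# Methods

## Joint model and what is identifiable

The wrist is modeled as a linear second-order plant,
`tau = M theta'' + B theta' + K theta`, with scalar (M, B, K) shared by
the flexion/extension (x) and radial/ulnar (y) axes, driven by the four
prime movers through `tau = sum_i a_i T_i` with axis-specific weights
`a_i` (Nm per unit tension).  The torque itself is never measured, so the
kinematic weights are identifiable only up to a common positive scale;
all results are reported as ratios (B_r/K_r, M_r/K_r) or as the
scale-invariant damping ratio `zeta = B/(2 sqrt(KM))`.  Internally the
first canonical pair is normalized so K_r = 1.

Hand inertia is computed from anthropometry as `M = 7 m r^2 / 5`,
idealizing the hand as a homogeneous sphere (density 1.0 g/ml) rotating
about an axis on its surface.  A 4.9 cm radius gives M ≈ 0.0017 kg m²,
matching the reported subject average (0.0017 ± 0.00036 kg m²).

## Signal path

- EMG → tension: full-wave rectification, then a second-order Butterworth
  low-pass at 3.0 Hz applied forward-backward (zero phase).  The filter
  family is a package choice; zero phase is essential because the
  identification compares tension and kinematic time courses sample by
  sample.  Ringing excursions below zero are clipped before
  normalization.
- Normalization: the envelope amplitude produced by 0.78 Nm of isometric
  torque defines one tension unit (linear rescaling when the calibration
  was recorded at another torque); the resting tension at the central
  position is then subtracted.  Baseline-subtracted tensions MAY be
  negative: the "always positive" reading of uncentered analysis
  conflicts with baseline subtraction, and we resolve it by keeping the
  subtraction and passing negative values through unchanged.
- Kinematics: degrees at the I/O boundary, radians/SI internally.  Angles
  are smoothed with the same zero-phase 3 Hz filter before
  central-difference differentiation (numpy.gradient; endpoints one-sided)
  so the acceleration is not noise-dominated.
- Working rate: all channels are decimated to 100 Hz after filtering.
  The 3 Hz-band signals are oversampled ~7x even there, and the
  cross-product computations that drive both identification routes become
  20x cheaper than at the 2 kHz acquisition rate, with no measurable
  change in the fitted ratios.

## Uncentered canonical correlation

Cross-products X'X, X'Y, Y'Y are formed without mean subtraction and the
canonical system is solved by symmetric whitening and SVD.  Rank-deficient
blocks (e.g. a muscle silent for a whole task) are ridge-regularized with
an epsilon tied to the largest eigenvalue, with a warning.  The two axes
are stacked by default: kinematic weights shared, eight muscle columns
(four per axis); a per-axis mode exists because the published analysis
does not specify how the axes were combined, and on clean synthetic data
the two agree to a few percent.  Sign constraints are *not* imposed
inside the CCA (mirroring an unconstrained CANCORR run); violations of
the muscle table by the fitted weights are reported post hoc.  Trials
with peak excursion under 1° carry no identification signal and are
dropped from the design.

The first-pair eigenvalue proportion uses the canonical eigenvalues
`lambda_i = cc_i^2 / (1 - cc_i^2)` (the convention of standard CANCORR
output, and the one under which the reported real-data proportions
0.98/0.95 were printed), evaluated as `1/(1 + sum lambda_i/lambda_1)` so
it remains finite when the first correlation is exactly 1.  The plain
`cc^2`-proportion alternative gives visibly different numbers (~0.87 for
noise-free pursuit, where the figure-eight's harmonic structure supports
a genuine second pair), so the convention matters and is fixed here.

## Grid search

For each (B, K) in [0, 10]² at 0.2 steps, the kinematic torque is formed
per axis (with the subject's anthropometric M) and the muscle weights are
fitted by sign-constrained least squares; the cell score is the mean over
axes of the uncentered correlation R between fitted muscle torque and
kinematic torque.  The constrained solver enumerates all 2⁴ active sets
and keeps the feasible minimum — exact and deterministic, verified in the
tests against an independent NNLS construction.  Because the torque is
linear in (B, K, M), each active set's solution is linear in them too,
and the whole surface reduces to closed-form quadratics in precomputed
cross-products (hundreds of cells per millisecond).

With the acceleration term negligible, R is constant along rays
B/K = const, so the 0.2-step grid cannot resolve ratios below 0.2/10 nor
distinguish points on a ray; a refinement pass re-scores log-spaced
ratios (x/÷ 4, 161 points) around the coarse argmax and reports the ridge
ratio.  The B = K = 0 cell is skipped (near-zero torque).  Printed
best-fit parameter sets of the order K ≈ 0.09 are below the coarse grid
by construction; the refinement pass is this package's resolution of that
tension, and the coarse surface is still exported for contour rendering.

## Directional tuning and agonists

Mean tension in ±25 ms around movement onset (onset = tangential speed
first exceeding 5% of its trial peak for ≥ 50 ms), per direction and
muscle, is fitted with `b0 + b1 cos(d - pd)`; the fit is flagged
unreliable when b1 is within two standard errors of zero.  Agonists for a
direction are the muscles whose preferred direction lies within 67.5°,
nearest first; the window is a package choice (the source analysis never
states its rule) with two safeguards: a nearest-muscle fallback when the
window is empty (e.g. rightward movements with the default table, where
ECR sits 68° away), and a cap at the two nearest (the default table puts
three muscles inside the window for up-left movements at 135°).  Agonist
tension is correlated (Pearson) with displacement along the target
direction and with tangential speed from onset to trial end; the
correlation window is likewise a package choice.

The packaged muscle table distinguishes *preferred* directions (activity
tuning: 68°, 125°, 189°, 265° for ECR, ECU, FCU, FCR) from *action*
directions (mechanical pull: 30°, 315°, 225°, 135°).  The two differ
markedly for ECU and FCR in real recordings; the sign constraints encode
the action directions.  Synthetic data are generated from the action
directions, so analyses of synthetic cohorts should assign agonists from
tuning fits estimated on the data (as the examples do) rather than from
the real-data preferred directions.

## Group statistics

Per-subject ratios are summarized as mean/SD (n−1)/extremes; a single
value reports SD 0 by convention.  Mann-Whitney U uses the exact U
distribution when the pooled sample is ≤ 40 without ties, otherwise
mid-ranks with tie and continuity corrections under the normal
approximation — the combination that reproduces the published pursuit
bound (p = 4.87e-5 < 4.9e-5) on the packaged table.  On the same table
the step columns give p ≈ 0.073 by every standard variant (exact
tie-conditional permutation included), slightly below the published
"p > 0.08"; the discrepancy is a rounding artifact of the two-decimal
printed ratios and the package reports the computed value.  t-tests are
Student's equal-variance by default (matching the cited implementation),
with a paired option.  Task separation within a group is reported as the
range-intersection width of the step and pursuit ratio distributions.

## Synthetic data

The generator defines the study conditions and inverts the model exactly:

- **Step**: minimum-jerk 18° point-to-point movements in 8 directions,
  0.4 s movement time (a brisk "as fast as accurate" wrist step), 1–2 s
  variable pre-hold, 1 s post-hold, 3 repetitions per direction.
- **Pursuit**: constant 6.2°/s traversal of a closed figure-eight
  Lissajous spanning ±10° × ±8° (the published path shape is not
  recoverable from text, so any smooth closed path is a configuration
  choice, recorded in metadata).  No smooth constant-speed path spanning
  the full box can pass through a box corner, so the traversal starts at
  the path point nearest the upper-left hold target.  One lap ≈ 14 s;
  5 repetitions.
- **Tensions**: the trial torque is decomposed per sample onto the two
  adjacent pulling directions of its cone (exact, nonnegative; verified
  against per-sample NNLS), plus a strictly positive co-contraction
  pattern from the null space of the action matrix (cancels in the
  torque; default level 0.1 tension units), smoothed by the same 3 Hz
  zero-phase envelope filter the processing stage applies — this keeps
  the generated tensions and the filtered kinematics related by the same
  (B*, K*).  Noise: multiplicative log-normal on tensions with
  sigma = 10^(−SNR/20) (default 20 dB; envelope noise scales with the
  signal) and additive white noise on recorded angles (0.1° SD).
- **Subjects**: per-task B*/K* drawn from truncated normals at the
  reported group moments (controls 0.17 ± 0.06 step, 1.30 ± 0.27 pursuit;
  patients 0.24 ± 0.10, 0.54 ± 0.28); K* uniform in 0.15–0.30 Nm/rad so
  that M/K* sits in the realistic 0.005–0.012 band; hand radius ≈ 4.9 cm
  with a tight spread (M scales as r⁵) truncated to the reported inertia
  range; per-muscle gains uniform in 0.15–0.30 Nm per tension unit.

A cohort drawn at these moments reproduces the headline group contrast in
essentially every seed for pursuit (Mann-Whitney p < 0.01), but *not* for
step: the step columns carry only a ~0.8 SD effect at n = 10 vs 19
(power ≈ 0.6), so a borderline, non-significant step comparison is a
property of the particular draw, not of the distributions.

What the generator does *not* emulate: motor-unit-level EMG statistics,
motion artifacts, activation-dependent changes of B and K within a trial,
trajectory irregularity of ataxic subjects (an optional intermittency
mode exists for demonstrations but is excluded from recovery scoring),
and electrode cross-talk.  Passing recovery tests therefore demonstrate
that the estimators invert the stated model at realistic noise, not that
they are robust to every pathology of real recordings.

## Numerical notes and known limitations

- Active-set feasibility uses a 1e−9 tolerance on weight signs; the
  degenerate all-zero tension design is rejected rather than fitted.
- The tension decomposition treats torque vectors on a cone boundary as
  belonging to either adjacent sector (both give the same exact
  solution); an angle that rounds to exactly 2π past the first pulling
  direction is mapped into the last sector.
- Recovery at the study conditions: median |relative error| of B*/K*
  ≈ 0.7% at 20 dB SNR (100 virtual subjects), and the ratio moves by
  ≈ 1.4% (median) when the acceleration term is dropped.  For the
  briskest synthetic steps at the high end of M/K the with/without-
  acceleration difference can reach ~10%: the inertial term is not
  uniformly negligible for rapid movements, only in the aggregate and
  for pursuit.
- Identified ratios are unbiased only insofar as the EMG-to-tension map
  is linear; co-contraction above the modeled constant level or
  activation-dependent impedance would bias B_r/K_r in ways the linear
  model cannot see.
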