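import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wristid import (
    DIRECTION_ANGLES,
    MuscleSpec,
    agonist_correlations_by_direction,
    assign_agonists,
    agonist_kinematics_correlation,
    default_muscles,
    generate_cohort,
    preferred_direction,
    tuning_from_step_trials,
)
from wristid.pipeline import process_subject
from wristid.signal import ProcessedTrial
from wristid.synth import GroupRatioModel

ANGLES8 = np.arange(0.0, 360.0, 45.0)


def _cosine_activity(pd, depth=1.0, base=2.0, angles=ANGLES8):
    return base + depth * np.cos(np.deg2rad(angles - pd))


class TestPreferredDirection:
    @pytest.mark.parametrize("pd_true", [68.0, 125.0, 189.0, 265.0])
    def test_noise_free_recovery(self, pd_true):
        fit = preferred_direction(ANGLES8, _cosine_activity(pd_true))
        assert abs(fit.pd - pd_true) < 0.5
        assert fit.reliable and fit.r2 > 0.999

    def test_uniform_activity_flagged(self):
        rng = np.random.default_rng(0)
        fit = preferred_direction(ANGLES8, 1.0 + 1e-6 * rng.normal(size=8))
        assert not fit.reliable

    def test_wraparound_pd(self):
        fit = preferred_direction(ANGLES8, _cosine_activity(355.0))
        assert 354.5 < fit.pd < 355.5  # not -5

    @given(delta=st.floats(0.0, 360.0))
    @settings(max_examples=30, deadline=None)
    def test_rotation_equivariance(self, delta):
        base = preferred_direction(ANGLES8, _cosine_activity(68.0))
        rot = preferred_direction(ANGLES8 + delta, _cosine_activity(68.0))
        # rotating the direction labels rotates the fitted pd
        diff = (rot.pd - base.pd - delta) % 360.0
        assert min(diff, 360.0 - diff) < 1e-6


class TestAssignAgonists:
    def test_up_has_two_agonists(self, specs):
        assert set(assign_agonists(90.0, specs)) == {"ECR", "ECU"}

    def test_right_falls_back_to_nearest(self, specs):
        # ECR at 68 deg misses the 67.5 deg window by 0.5 deg; nearest wins
        assert assign_agonists(0.0, specs) == ("ECR",)

    def test_direction_on_pd_included(self, specs):
        assert "FCU" in assign_agonists(189.0, specs)

    def test_all_eight_directions_yield_one_or_two(self, specs):
        for d in DIRECTION_ANGLES.values():
            agonists = assign_agonists(d, specs)
            assert 1 <= len(agonists) <= 2

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            assign_agonists(0.0, specs=[])


def _step_trial(tension_col, direction="RT", n=300, fs=100.0):
    """Minimal step trial moving along +x with a prescribed ECR tension."""
    t = np.arange(n) / fs
    theta_x = np.clip((t - 1.0) / 0.5, 0.0, 1.0) * 0.3
    vel_x = np.gradient(theta_x, 1 / fs)
    tension = np.zeros((n, 4))
    tension[:, 0] = tension_col
    z = np.zeros(n)
    return ProcessedTrial(
        tension=tension, theta_x=theta_x, theta_y=z, vel_x=vel_x, vel_y=z,
        acc_x=np.gradient(vel_x, 1 / fs), acc_y=z, fs_out=fs, task="step",
        direction=direction,
    )


class TestAgonistCorrelation:
    def test_tension_tracking_displacement(self):
        trial = _step_trial(np.clip((np.arange(300) / 100 - 1.0) / 0.5, 0, 1))
        res = agonist_kinematics_correlation(trial, ("ECR",))
        assert res.r_displacement == pytest.approx(1.0, abs=1e-9)
        assert res.r_velocity < 1.0

    def test_tension_tracking_velocity(self):
        n, fs = 300, 100.0
        t = np.arange(n) / fs
        theta = np.clip((t - 1.0) / 0.5, 0.0, 1.0) * 0.3
        speed = np.abs(np.gradient(theta, 1 / fs))
        trial = _step_trial(speed)
        res = agonist_kinematics_correlation(trial, ("ECR",))
        assert res.r_velocity == pytest.approx(1.0, abs=1e-9)
        assert res.r_displacement < 1.0

    def test_affine_tension_rescaling_invariance(self):
        col = np.clip((np.arange(300) / 100 - 1.0) / 0.5, 0, 1)
        r1 = agonist_kinematics_correlation(_step_trial(col), ("ECR",))
        r2 = agonist_kinematics_correlation(_step_trial(3.0 * col + 0.7), ("ECR",))
        assert r1.r_displacement == pytest.approx(r2.r_displacement, abs=1e-12)
        assert r1.r_velocity == pytest.approx(r2.r_velocity, abs=1e-12)

    def test_constant_tension_flagged(self):
        res = agonist_kinematics_correlation(_step_trial(np.ones(300)), ("ECR",))
        assert not res.defined


class TestCohortPattern:
    def test_position_dominant_group_pattern(self):
        """Step-tracking with a low B/K ratio: agonist activity follows
        displacement more closely than velocity in nearly every direction."""
        models = {
            "control": GroupRatioModel(0.17, 0.0, 1.30, 0.0),
            "patient": GroupRatioModel(0.24, 0.0, 0.54, 0.0),
        }
        cohort = generate_cohort(3, 0, seed=13, models=models, tasks=("step",))
        wins = {}
        for subj in cohort.subjects:
            pts = process_subject(subj, "step")
            fits = tuning_from_step_trials(pts)
            specs = [
                MuscleSpec(name=s.name, preferred_direction=fits[s.name].pd,
                           sign_x=s.sign_x, sign_y=s.sign_y,
                           action_direction=s.action_direction)
                for s in default_muscles()
            ]
            for row in agonist_correlations_by_direction(pts, specs):
                wins.setdefault(row.direction, []).append(
                    row.r_displacement > row.r_velocity
                )
        assert len(wins) == 8
        n_dirs_position_dominant = sum(
            np.mean(v) > 0.5 for v in wins.values()
        )
        assert n_dirs_position_dominant >= 7

    def test_synthetic_tuning_matches_pulling_directions(self, quiet_config):
        """On noise-free synthetic steps each muscle's fitted preferred
        direction lies near its mechanical pulling direction."""
        from wristid.synth import generate_subject

        rng = np.random.default_rng(3)
        subj = generate_subject("S", "control", rng, quiet_config, tasks=("step",))
        fits = tuning_from_step_trials(process_subject(subj, "step"))
        for s in default_muscles():
            diff = abs((fits[s.name].pd - s.action_direction + 180) % 360 - 180)
            assert diff < 45.0
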