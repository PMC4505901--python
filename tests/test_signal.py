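import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import cumulative_trapezoid

from wristid import (
    NoMovementError,
    SyntheticConfig,
    detect_movement_onset,
    differentiate_kinematics,
    generate_subject,
    normalize_tension,
    process_trial,
    rectify_and_envelope,
)
from wristid.signal import tangential_speed


class TestEnvelope:
    def test_constant_input_passes_at_unity_gain(self):
        env = rectify_and_envelope(np.full(4000, 0.7), fs=2000)
        assert np.allclose(env, 0.7, atol=1e-6)

    def test_zero_signal_zero_envelope(self):
        assert np.all(rectify_and_envelope(np.zeros(1000), fs=2000) == 0)

    def test_sine_envelope_near_rectified_mean(self):
        # |A sin| has mean 2A/pi; a 3 Hz low-pass of the 150 Hz rectified
        # sine should sit there with little ripple
        A, fs = 1.7, 2000.0
        t = np.arange(int(4 * fs)) / fs
        env = rectify_and_envelope(A * np.sin(2 * np.pi * 150 * t), fs)
        core = env[int(fs):-int(fs)]  # away from edges
        expect = 2 * A / np.pi
        assert abs(core.mean() - expect) / expect < 0.05
        assert np.ptp(core) < 0.10 * core.mean()
        # independent oracle: moving average of the rectified signal
        oracle = np.convolve(np.abs(A * np.sin(2 * np.pi * 150 * t)),
                             np.ones(int(fs)) / fs, mode="valid").mean()
        assert abs(core.mean() - oracle) / oracle < 0.05

    def test_nonnegative_and_length_preserving(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=3000)
        env = rectify_and_envelope(x, fs=2000)
        assert env.shape == x.shape and np.all(env >= 0)

    def test_rejects_bad_cutoff_and_nonfinite(self):
        with pytest.raises(ValueError):
            rectify_and_envelope(np.ones(100), fs=5.0, cutoff=3.0)
        with pytest.raises(ValueError):
            rectify_and_envelope(np.array([1.0, np.nan]), fs=2000)

    @given(c=st.floats(0.01, 50.0))
    @settings(max_examples=20, deadline=None)
    def test_positively_homogeneous(self, c):
        rng = np.random.default_rng(5)
        x = rng.normal(size=1200)
        e1 = rectify_and_envelope(x, fs=2000)
        ec = rectify_and_envelope(c * x, fs=2000)
        np.testing.assert_allclose(ec, c * e1, rtol=1e-9, atol=1e-12)


class TestNormalizeTension:
    def test_calibration_amplitude_maps_to_one(self):
        env = np.full(100, 2.4)
        assert np.allclose(normalize_tension(env, calib_envelope_level=2.4), 1.0)

    def test_baseline_level_maps_to_zero(self):
        env = np.full(100, 0.6)
        out = normalize_tension(env, 2.4, central_hold=slice(0, 50))
        assert np.allclose(out, 0.0)

    def test_linearity(self):
        env = np.full(100, 4.8)  # 2x the calibration amplitude
        out = normalize_tension(env, 2.4, baseline=0.5)
        assert np.allclose(out, 1.5)

    def test_torque_level_rescaling(self):
        # a contraction at half the reference torque is half a tension unit
        env = np.full(10, 1.0)
        out = normalize_tension(env, 1.0, torque_level=0.39)
        assert np.allclose(out, 0.5)

    def test_rejects_calibration_at_noise_floor(self):
        with pytest.raises(ValueError, match="noise floor"):
            normalize_tension(np.ones(10), 0.01, noise_floor=0.05)

    @given(gain=st.floats(0.1, 1000.0))
    @settings(max_examples=20, deadline=None)
    def test_amplifier_gain_invariance(self, gain):
        env = np.linspace(0.1, 2.0, 50)
        a = normalize_tension(env, 1.3, baseline=0.2)
        b = normalize_tension(gain * env, gain * 1.3, baseline=0.2)
        np.testing.assert_allclose(a, b, rtol=1e-9)


class TestDifferentiate:
    def test_constant_angle(self):
        theta, vel, acc = differentiate_kinematics(np.full(500, 10.0), fs=100)
        assert np.allclose(theta, np.deg2rad(10.0), atol=1e-6)
        assert np.allclose(vel, 0.0, atol=1e-8)
        assert np.allclose(acc, 0.0, atol=1e-6)

    def test_ramp_velocity(self):
        fs, w_deg = 100.0, 12.0
        t = np.arange(1000) / fs
        theta, vel, acc = differentiate_kinematics(w_deg * t, fs, smooth_cutoff=None)
        interior = slice(2, -2)
        assert np.allclose(vel[interior], np.deg2rad(w_deg), rtol=1e-9)
        assert np.allclose(acc[interior], 0.0, atol=1e-9)

    def test_sine_derivative_against_analytic(self):
        fs, f = 2000.0, 0.5
        t = np.arange(int(6 * fs)) / fs
        theta, vel, _ = differentiate_kinematics(
            np.rad2deg(np.sin(2 * np.pi * f * t)), fs
        )
        analytic = 2 * np.pi * f * np.cos(2 * np.pi * f * t)
        core = slice(int(fs), -int(fs))
        assert np.max(np.abs(vel[core] - analytic[core])) < 0.01 * 2 * np.pi * f

    def test_differentiate_then_integrate_recovers_angle(self):
        fs = 100.0
        t = np.arange(int(8 * fs)) / fs
        angle = 10 * np.sin(2 * np.pi * 0.8 * t) + 4 * np.cos(2 * np.pi * 0.3 * t)
        theta, vel, _ = differentiate_kinematics(angle, fs, smooth_cutoff=None)
        rebuilt = theta[0] + cumulative_trapezoid(vel, dx=1 / fs, initial=0.0)
        rms = np.sqrt(np.mean((rebuilt - theta) ** 2))
        assert rms < 1e-3 * np.sqrt(np.mean(theta**2))

    def test_rejects_short_input(self):
        with pytest.raises(ValueError):
            differentiate_kinematics(np.zeros(4), fs=100)


class TestOnset:
    def test_clean_step_onset(self):
        fs = 100.0
        speed = np.concatenate([np.zeros(100), np.ones(100)])
        assert 0.95 <= detect_movement_onset(speed, fs) <= 1.05

    def test_all_zero_raises(self):
        with pytest.raises(NoMovementError):
            detect_movement_onset(np.zeros(100), fs=100)

    def test_noisy_synthetic_step_within_30ms(self, specs):
        cfg = SyntheticConfig()
        rng = np.random.default_rng(12)
        subj = generate_subject("S", "control", rng, cfg, tasks=("step",))
        # regenerate one trial with a known 0.8 s hold for ground truth
        from wristid.synth import make_step_kinematics, make_trial

        kin = make_step_kinematics("UP", cfg, hold_pre_s=0.8)
        trial = make_trial(kin, subj.truth, "step", cfg, rng, direction="UP")
        pt = process_trial(trial, subj.rest)
        onset = detect_movement_onset(
            tangential_speed(pt.vel_x, pt.vel_y), pt.fs_out
        )
        assert abs(onset - 0.8) <= 0.03


class TestProcessTrial:
    def test_tension_baseline_near_zero_in_central_hold(self, control_subject):
        pt = process_trial(control_subject.trials["step"][0], control_subject.rest)
        hold = slice(0, pt.meta["hold_samples"])
        assert np.all(np.abs(pt.tension[hold].mean(axis=0)) < 0.05)

    def test_kinematics_finite_and_aligned(self, control_subject):
        pt = process_trial(control_subject.trials["pursuit"][0], control_subject.rest)
        for ch in (pt.theta_x, pt.theta_y, pt.vel_x, pt.vel_y, pt.acc_x, pt.acc_y):
            assert np.all(np.isfinite(ch)) and len(ch) == pt.n_samples

    def test_raw_emg_route_matches_tension_route(self, specs):
        # a raw carrier modulated by a known envelope should normalize back
        # to the envelope's tension scale
        fs = 2000.0
        t = np.arange(int(3 * fs)) / fs
        target = 0.8 + 0.5 * np.sin(2 * np.pi * 1.0 * t)  # tension scale
        rng = np.random.default_rng(0)
        gain_v = 0.002  # volts per unit tension
        carrier = rng.choice([-1.0, 1.0], size=t.size)  # unit-magnitude carrier
        emg = np.tile((gain_v * target * carrier)[:, None], (1, 4))
        from wristid.signal import CalibrationRecording, TrialRecording

        calib = CalibrationRecording(
            emg=np.full((2000, 4), gain_v),
            central_rest=np.zeros((2000, 4)),
            fs=fs,
            emg_kind="envelope",
        )
        trial = TrialRecording(
            time=t, angle_x_deg=np.zeros_like(t), angle_y_deg=np.zeros_like(t),
            emg=emg, fs=fs, task="pursuit", target_path=np.zeros((t.size, 2)),
            emg_kind="raw",
        )
        pt = process_trial(trial, calib)
        core = slice(50, -50)
        np.testing.assert_allclose(
            pt.tension[core, 0], target[:: int(fs / 100)][core], rtol=0.05, atol=0.03
        )
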