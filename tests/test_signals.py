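"""Preprocessing chain: frames, gravity, filtering, integration, selection."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from motiontutor.errors import (
    CannotSegmentError,
    ConfigurationError,
    InvalidInputError,
    InvalidKindError,
)
from motiontutor.signals import (
    G0,
    Kind,
    OneDSignal,
    QuaternionSample,
    RotationMatrix,
    estimate_period,
    iir_alpha,
    iir_lowpass,
    integrate,
    quat_to_rotation,
    remove_gravity,
    select_signals,
    to_inertial,
)
from motiontutor.virtual_learner import simulate

from conftest import clean_config


def sig(values, kind=Kind.ACCEL, rate=100.0):
    return OneDSignal(index=0, values=np.asarray(values, float), kind=kind, sample_rate=rate)


class TestRotations:
    def test_identity_quaternion(self):
        A = quat_to_rotation(QuaternionSample(0, 0, 0, 1))
        assert np.allclose(A.matrix, np.eye(3))

    def test_quarter_turn_about_z_maps_x_to_y(self):
        s, c = np.sin(np.pi / 4), np.cos(np.pi / 4)
        A = quat_to_rotation((0, 0, s, c))
        assert np.allclose(A.matrix @ [1, 0, 0], [0, 1, 0], atol=1e-12)

    @given(st.integers(0, 10_000))
    def test_random_quaternion_gives_orthonormal_rotation(self, seed):
        q = np.random.default_rng(seed).normal(size=4)
        A = quat_to_rotation(q).matrix
        assert np.allclose(A.T @ A, np.eye(3), atol=1e-9)
        assert np.isclose(np.linalg.det(A), 1.0, atol=1e-9)

    def test_zero_quaternion_rejected(self):
        with pytest.raises(InvalidInputError):
            quat_to_rotation((0.0, 0.0, 0.0, 0.0))

    def test_to_inertial_is_inverse_rotation(self):
        s, c = np.sin(np.pi / 4), np.cos(np.pi / 4)
        A = quat_to_rotation((0, 0, s, c))
        # Aᵀ·(1,0,0) — hand-multiplied
        assert np.allclose(to_inertial([1, 0, 0], A), [0, -1, 0], atol=1e-12)
        a = np.array([0.3, -1.2, 2.4])
        assert np.allclose(A.matrix @ to_inertial(a, A), a, atol=1e-12)

    def test_non_orthonormal_matrix_rejected(self):
        with pytest.raises(InvalidInputError):
            RotationMatrix(np.eye(3) * 1.01)


class TestGravity:
    @pytest.mark.parametrize(
        "a_iner, expected",
        [((0, 0, G0), (0, 0, 0)), ((1, 0, G0), (1, 0, 0)), ((0.5, -2.0, 0.0), (0.5, -2.0, -G0))],
    )
    def test_constant_gravity_subtracted_from_z(self, a_iner, expected):
        assert np.allclose(remove_gravity(a_iner), expected)

    def test_stream_round_trip_recovers_motion_acceleration(self):
        """Sensor-frame synthesis followed by frame restoration reproduces
        the generating trajectory acceleration (noise off, wobble on)."""
        from motiontutor.signals import stream_to_inertial
        from motiontutor.virtual_learner import make_trajectory, synth_stream
        import dataclasses

        cfg = dataclasses.replace(clean_config(), wobble_deg=5.0)
        t, pos, _, _ = make_trajectory(cfg)
        stream = synth_stream(t, pos, cfg)
        recovered = stream_to_inertial(stream)
        dt = 1.0 / cfg.sample_rate
        truth = np.gradient(np.gradient(pos, dt, axis=0), dt, axis=0)
        assert np.abs(recovered - truth).max() < 1e-6


class TestIIRFilter:
    def test_alpha_for_5hz_at_100hz(self):
        assert iir_alpha(5.0, 100.0) == pytest.approx(0.2391, abs=5e-5)

    def test_dc_gain_is_one(self):
        out = iir_lowpass(sig(np.full(500, 3.7)), fc=5.0)
        assert np.allclose(out.values, 3.7)

    def test_linearity(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=300), rng.normal(size=300)
        fx = iir_lowpass(sig(x), 5.0).values
        fy = iir_lowpass(sig(y), 5.0).values
        fxy = iir_lowpass(sig(x + 2 * y), 5.0).values
        assert np.allclose(fxy, fx + 2 * fy, atol=1e-12)

    def test_white_noise_attenuation_close_to_10db(self):
        rng = np.random.default_rng(42)
        x = rng.normal(size=200_000)
        y = iir_lowpass(sig(x), fc=5.0).values[1000:]
        atten_db = -20 * np.log10(np.std(y) / np.std(x[1000:]))
        assert 8.0 < atten_db < 12.0

    def test_cutoff_out_of_range_rejected(self):
        with pytest.raises(InvalidInputError):
            iir_lowpass(sig(np.ones(10)), fc=60.0)


class TestIntegration:
    def test_zero_in_zero_out(self):
        out = integrate(sig(np.zeros(100)))
        assert np.allclose(out.values, 0.0)
        assert out.kind is Kind.VELOCITY

    def test_constant_accel_integrates_to_expected_velocity(self):
        out = integrate(sig(np.ones(100)))  # 1 m/s² for 1 s at 100 Hz
        assert out.values[-1] == pytest.approx(1.0, abs=0.01)

    def test_position_cannot_be_integrated(self):
        with pytest.raises(InvalidKindError):
            integrate(sig(np.ones(10), kind=Kind.POSITION))

    def test_detrended_integral_of_sinusoid_stays_periodic(self):
        w = 200
        x = np.sin(2 * np.pi * np.arange(10 * w) / w)
        out = integrate(sig(x), detrend_per_period=True, period_w=w).values
        per_period_means = out.reshape(10, w).mean(axis=1)
        # bounded drift: late periods have the same mean as early ones
        assert np.ptp(per_period_means[2:]) < 1e-3


class TestSelectSignals:
    def test_single_index_yields_single_signal(self):
        stream, _ = simulate(clean_config())
        S = select_signals([stream], [0], period_w=200)
        assert S.K == (0,)
        assert S[0].kind is Kind.ACCEL

    def test_position_indices_yield_position_signals(self):
        stream, _ = simulate(clean_config())
        S = select_signals([stream], [6, 8], period_w=200)
        assert S[6].kind is Kind.POSITION and S[8].kind is Kind.POSITION
        assert S[6].axis == "x" and S[8].axis == "z"

    def test_empty_selection_rejected(self):
        stream, _ = simulate(clean_config())
        with pytest.raises(ConfigurationError):
            select_signals([stream], [])

    def test_unknown_index_rejected(self):
        stream, _ = simulate(clean_config())
        with pytest.raises(ConfigurationError):
            select_signals([stream], [99])

    def test_recovered_positions_track_the_generating_trajectory(self):
        """Simulator → preprocessor inverse consistency (noise off,
        detrend on): per-period demeaned positions agree within the Euler
        integration tolerance."""
        cfg = clean_config()
        stream, truth = simulate(cfg)
        w = cfg.w
        S = select_signals([stream], (6, 8), fc=45.0, period_w=w)

        def demean(v):
            v = np.array(v, float)
            for s0 in range(0, v.size, w):
                v[s0 : s0 + w] -= v[s0 : s0 + w].mean()
            return v

        for i, ax in ((6, 0), (8, 2)):
            rec = demean(S[i].values)[2 * w :]
            tru = demean(truth["pos"][:, ax])[2 * w :]
            err = rec - tru
            assert np.sqrt((err**2).mean()) < 0.015  # m
            assert np.abs(err).max() < 0.06  # m


class TestPeriodEstimation:
    def test_pure_sine_period_recovered(self):
        x = np.sin(2 * np.pi * np.arange(1200) / 200)
        assert abs(estimate_period(x, 100.0) - 200) <= 1

    def test_white_noise_has_no_period(self):
        x = np.random.default_rng(3).normal(size=1000)
        with pytest.raises(CannotSegmentError):
            estimate_period(x, 100.0)
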