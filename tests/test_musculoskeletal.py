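"""Kinematics, muscle activation and overdamped joint dynamics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from legsearch import (LegGeometry, LegState, MusclePool, compute_alpha,
                       joint_step, joint_torque, muscle_step)
from legsearch.errors import ConfigurationError, LegsearchError


def pool(role="levator", speed="fast", rest=40.0, gain=8e-3, passive=5e-5,
         tau=40.0, **kw):
    return MusclePool(role=role, speed=speed, rest_angle_deg=rest,
                      max_force=gain, passive_stiffness=passive,
                      tau_act_ms=tau, **kw)


class TestComputeAlpha:
    def test_stretched_leg_alpha_equals_beta(self, geom):
        # gamma = 180 means femur and tibia are collinear
        for beta in (-40.0, 0.0, 17.3, 60.0):
            assert compute_alpha(beta, 180.0, geom) == pytest.approx(beta)

    def test_right_angle_equal_segments(self, equal_geom):
        # femur horizontal, tibia straight down -> tarsus at (L, -L)
        assert compute_alpha(0.0, 90.0, equal_geom) == pytest.approx(-45.0)

    def test_degenerate_tibia(self):
        geom = LegGeometry(13.0, 1e-9)
        assert compute_alpha(12.0, 77.0, geom) == pytest.approx(12.0, abs=1e-6)

    def test_rejects_nonphysical_gamma(self, geom):
        with pytest.raises(LegsearchError):
            compute_alpha(0.0, 181.0, geom)
        with pytest.raises(LegsearchError):
            compute_alpha(0.0, 0.0, geom)

    @given(beta=st.floats(-80, 80), gamma=st.floats(1.0, 180.0))
    @settings(max_examples=200, deadline=None)
    def test_alpha_bounded_by_flexion_cone(self, beta, gamma):
        # tibia flexes downward, so alpha lies in [beta - (180 - gamma), beta]
        a = compute_alpha(beta, gamma, LegGeometry(13.0, 12.0))
        assert beta - (180.0 - gamma) - 1e-6 <= a <= beta + 1e-6

    def test_vectorized_matches_scalar(self, geom):
        betas = np.linspace(-40, 40, 7)
        gammas = np.linspace(60, 180, 7)
        vec = compute_alpha(betas, gammas, geom)
        for b, g, a in zip(betas, gammas, vec):
            assert a == pytest.approx(compute_alpha(float(b), float(g), geom))


class TestMuscleStep:
    def test_decay_to_zero(self):
        p = pool(gain=8e-3)
        p = MusclePool(**{**p.__dict__, "activation": 0.9})
        for _ in range(1000):
            p = muscle_step(p, 0.0, 1.0)
        assert p.activation < 1e-4

    def test_saturation_at_full_drive(self):
        p = pool()
        for _ in range(1000):
            p = muscle_step(p, 1.0, 1.0)
        assert p.activation == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("fraction", [0.0, 0.25, 0.5, 1.0])
    def test_recruitment_caps_steady_state(self, fraction):
        p = pool(active_fraction=fraction)
        for _ in range(2000):
            p = muscle_step(p, 1.0, 1.0)
        assert p.activation == pytest.approx(fraction, abs=1e-5)
        assert p.activation <= fraction + 1e-9

    def test_rejects_out_of_range_drive(self):
        with pytest.raises(ConfigurationError):
            muscle_step(pool(), 1.5, 0.5)


class TestJointTorque:
    def test_symmetric_pair_balances_at_midpoint(self):
        lev = pool(rest=30.0)
        dep = pool(role="depressor", rest=-10.0)
        lev = MusclePool(**{**lev.__dict__, "activation": 0.5})
        dep = MusclePool(**{**dep.__dict__, "activation": 0.5})
        assert joint_torque(lev, dep, 10.0) == pytest.approx(0.0, abs=1e-12)

    def test_passive_restoring_torque(self):
        # silent muscles still pull back toward the passive equilibrium
        lev = pool(rest=30.0)
        dep = pool(role="depressor", rest=-10.0)
        assert joint_torque(lev, dep, 25.0) < 0.0
        assert joint_torque(lev, dep, -5.0) > 0.0
        assert joint_torque(lev, dep, 10.0) == pytest.approx(0.0, abs=1e-12)

    def test_depressor_drives_beta_down(self):
        lev = pool(rest=30.0)
        dep = pool(role="depressor", rest=-10.0)
        dep = MusclePool(**{**dep.__dict__, "activation": 1.0})
        assert joint_torque(lev, dep, 10.0) < 0.0

    def test_mixed_joints_rejected(self):
        with pytest.raises(ConfigurationError):
            joint_torque(pool(role="levator"), pool(role="flexor", rest=70.0), 10.0)


class TestJointStep:
    def test_zero_torque_keeps_angles(self, geom):
        s = LegState.from_angles(10.0, 150.0, geom)
        s2 = joint_step(s, 0.0, 0.0, 0.5, geom)
        assert s2.beta == s.beta and s2.gamma == s.gamma

    def test_gamma_stops_at_stretch_limit(self, geom):
        s = LegState.from_angles(10.0, 170.0, geom)
        for _ in range(2000):
            s = joint_step(s, 0.0, 0.05, 1.0, geom)
        assert s.gamma == 180.0
        assert s.gamma_rate == 0.0
        assert s.alpha == pytest.approx(s.beta)

    def test_sinusoidal_torque_gives_phase_lagged_angle(self, geom):
        # pure integrator: theta(t) = theta0 + (A/w)(1 - cos wt), a sinusoid
        # lagging the torque by a quarter period
        amp, period = 0.01, 500.0
        w = 2 * math.pi / period
        dt = 0.5
        s = LegState.from_angles(0.0, 150.0, geom)
        ts, thetas = [], []
        for i in range(4000):
            torque = amp * math.sin(w * i * dt)
            s = joint_step(s, torque, 0.0, dt, geom)
            ts.append((i + 1) * dt)
            thetas.append(s.beta)
        expected = [amp / w * (1 - math.cos(w * t)) for t in ts]
        assert np.allclose(thetas, expected, atol=amp / w * 0.02)

    def test_alpha_always_consistent(self, geom):
        s = LegState.from_angles(5.0, 120.0, geom)
        for _ in range(100):
            s = joint_step(s, 0.01, -0.02, 1.0, geom)
            assert s.alpha == pytest.approx(
                compute_alpha(s.beta, s.gamma, geom))


class TestMusclePoolInvariants:
    def test_extensor_pools_are_single_units(self):
        with pytest.raises(ConfigurationError):
            pool(role="extensor", rest=176.0, n_units=5)

    def test_unknown_role_rejected(self):
        with pytest.raises(ConfigurationError):
            pool(role="abductor")

    def test_fast_levator_pool_has_several_units(self, config):
        assert config.musculoskeletal.levator_fast.n_units > 1
        assert config.musculoskeletal.extensor_fast.n_units == 1
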