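"""Assistive controllers: closed-form checks and torque bookkeeping."""

import numpy as np
import pytest

import exoassist as xa
from exoassist import dynamics as dy
from exoassist.body_model import ExoskeletonSpec
from exoassist.controllers import (ControllerConfig, assistive_torque,
                                   damped_pendulum_torque, pendulum_torque,
                                   physiological_torque,
                                   rotational_actuator_torque,
                                   stance_pendulum_torque,
                                   swing_pendulum_torque)
from tests.conftest import (make_axial_foot_model, make_swing_pendulum_trial,
                            zero_grf)


class TestControllerConfig:
    @pytest.mark.parametrize("kwargs", [
        dict(K=-1.0), dict(a_stance=1.5), dict(a_swing=-0.1),
        dict(b_stance=-2.0), dict(mode="XX"),
    ])
    def test_invalid_configs_rejected(self, kwargs):
        base = dict(mode="DPM")
        with pytest.raises(ValueError):
            ControllerConfig(**{**base, **kwargs})

    def test_recommended_parameters(self):
        assert xa.recommended_config("RA").K == 4.0
        spm = xa.recommended_config("SPM")
        assert (spm.a_stance, spm.a_swing) == (0.23, 0.78)
        dn = xa.recommended_config("DPM", "normal")
        assert (dn.a_stance, dn.b_stance, dn.a_swing, dn.b_swing) == \
            (0.33, 12.6, 0.78, 0.34)
        df = xa.recommended_config("DPM", "fast")
        assert (df.b_stance, df.b_swing) == (18.4, 0.1)


class TestRotationalActuator:
    def test_linear_formula(self):
        trial = make_swing_pendulum_trial(lambda ph: np.full_like(ph, 0.5))
        u = rotational_actuator_torque(ControllerConfig("RA", K=4.0), trial)
        assert np.allclose(u.u_exo, -2.0, atol=1e-12)
        assert np.allclose(u.tau_device, 2.0, atol=1e-12)

    def test_zero_at_reference_angle(self):
        trial = make_swing_pendulum_trial(lambda ph: np.zeros_like(ph))
        u = rotational_actuator_torque(ControllerConfig("RA", K=4.0), trial)
        assert np.allclose(u.u_exo, 0.0)

    def test_zero_stiffness_equals_no_assistance(self, trial_normal, model):
        u = rotational_actuator_torque(ControllerConfig("RA", K=0.0),
                                       trial_normal)
        na = assistive_torque(ControllerConfig("NA"), trial_normal, model)
        assert np.array_equal(u.u_exo, na.u_exo)


class TestPendulumFormulas:
    def test_swing_formula_direct_arithmetic(self):
        # I th'' + m g l sin(th): 2*1.5 + 4*9.81*0.25*sin(0.3)
        u = swing_pendulum_torque(2.0, 1.5, 4.0, 9.81, 0.25, 0.3)
        assert u == pytest.approx(2 * 1.5 + 4 * 9.81 * 0.25 * np.sin(0.3))

    def test_stance_formula_direct_arithmetic(self):
        """I_s th_a'' - T_a + m g l sin(th_a) with the worked numbers:
        1*2 - 30 + 10 = -18 N*m."""
        theta_a = 0.5
        mgl = 10.0 / np.sin(theta_a)  # choose m g l so the gravity term is 10
        u = stance_pendulum_torque(1.0, 2.0, 30.0, mgl / 9.81, 9.81,
                                   1.0, theta_a)
        assert u == pytest.approx(-18.0, abs=1e-12)

    def test_damping_adds_b_theta_dot(self):
        u0 = swing_pendulum_torque(2.0, 1.5, 4.0, 9.81, 0.25, 0.3)
        u1 = swing_pendulum_torque(2.0, 1.5, 4.0, 9.81, 0.25, 0.3,
                                   b=0.34, theta_k_d=1.0)
        assert u1 - u0 == pytest.approx(0.34)


@pytest.fixture(scope="module")
def pendulum_setup():
    """Knee-pendulum swing trial on the axial-foot model with zero ground
    reactions; the pendulum equation is exact up to discretization."""
    model = make_axial_foot_model()
    trial = make_swing_pendulum_trial(np.full(101, 0.4))
    kin = dy.compute_kinematics(trial, model)
    net = dy.inverse_dynamics(trial, model, zero_grf(trial, model), kin)
    return trial, model, net


class TestPendulumControllers:
    def test_constant_angle_swing_torque(self, pendulum_setup):
        """theta_k constant: u_s = m_c1 g l_c1 sin(theta0) and the emitted
        torque is a_swing times that."""
        trial, model, net = pendulum_setup
        cfg = ControllerConfig("SPM", a_swing=0.78)
        out = pendulum_torque(cfg, trial, model, net)
        pc = xa.pendulum_constants(model)
        u_expected = pc.m_c1 * model.gravity * pc.l_c1 * np.sin(0.4)
        sw = ~out.stance
        assert np.allclose(out.u_unscaled[sw], u_expected, atol=1e-9)
        assert np.allclose(out.u_exo[sw], 0.78 * u_expected, atol=1e-9)

    def test_zero_angle_zero_torque(self):
        model = make_axial_foot_model()
        trial = make_swing_pendulum_trial(np.zeros(101))
        net = dy.inverse_dynamics(trial, model, zero_grf(trial, model))
        out = pendulum_torque(ControllerConfig("SPM", a_swing=1.0),
                              trial, model, net)
        assert np.allclose(out.u_unscaled[~out.stance], 0.0, atol=1e-10)

    def test_dpm_reduces_to_spm_without_damping(self, pendulum_setup):
        trial, model, net = pendulum_setup
        spm = pendulum_torque(
            ControllerConfig("SPM", a_stance=0.3, a_swing=0.7),
            trial, model, net)
        dpm = damped_pendulum_torque(
            ControllerConfig("DPM", a_stance=0.3, a_swing=0.7),
            trial, model, net)
        assert np.allclose(spm.u_exo, dpm.u_exo, atol=1e-12)

    def test_dpm_minus_spm_is_a_b_theta_dot(self, trial_normal, model,
                                            ctx_normal):
        net = ctx_normal.net_torques
        a_st, a_sw, b_st, b_sw = 0.33, 0.78, 12.6, 0.34
        spm = pendulum_torque(
            ControllerConfig("SPM", a_stance=a_st, a_swing=a_sw),
            trial_normal, model, net)
        dpm = damped_pendulum_torque(
            ControllerConfig("DPM", a_stance=a_st, a_swing=a_sw,
                             b_stance=b_st, b_swing=b_sw),
            trial_normal, model, net)
        leg = net.kinematics.legs["right"]
        expected = np.where(spm.stance,
                            a_st * b_st * leg.theta_a_d1,
                            a_sw * b_sw * leg.theta_k_d1)
        assert np.allclose(dpm.u_exo - spm.u_exo, expected, atol=1e-10)

    def test_full_assistance_zeroes_swing_physiological_torque(self):
        """A trial built from the knee-pendulum dynamics with a = 1 leaves
        the user no knee torque to produce during swing."""
        model = make_axial_foot_model(ExoskeletonSpec.zero())
        trial = make_swing_pendulum_trial(np.full(101, 0.4))
        net = dy.inverse_dynamics(trial, model, zero_grf(trial, model))
        out = pendulum_torque(ControllerConfig("SPM", a_swing=1.0),
                              trial, model, net)
        tau_physio = physiological_torque(net, out, model)
        assert np.max(np.abs(tau_physio[~out.stance])) < 1e-8

    def test_swing_physio_torque_non_increasing_in_a(self):
        model = make_axial_foot_model(ExoskeletonSpec.zero())
        trial = make_swing_pendulum_trial(np.full(101, 0.4))
        net = dy.inverse_dynamics(trial, model, zero_grf(trial, model))
        prev = np.inf
        for a in (0.0, 0.25, 0.5, 0.75, 1.0):
            out = pendulum_torque(ControllerConfig("SPM", a_swing=a),
                                  trial, model, net)
            peak = np.max(np.abs(physiological_torque(net, out, model)
                                 [~out.stance]))
            assert peak <= prev + 1e-12
            prev = peak


class TestPhysiologicalTorque:
    def test_na_mode_without_damping_keeps_net_torque(self, trial_normal):
        model = xa.build_model(xa.Anthropometry(66.0, 1.75),
                               ExoskeletonSpec.zero())
        ctx_net = dy.inverse_dynamics(trial_normal, model,
                                      zero_grf(trial_normal, model))
        na = assistive_torque(ControllerConfig("NA"), trial_normal, model)
        tau = physiological_torque(ctx_net, na, model)
        assert np.array_equal(tau, ctx_net.knee)

    def test_device_matching_net_torque_leaves_zero(self, ctx_normal,
                                                    trial_normal, model):
        net = ctx_normal.net_torques
        na = assistive_torque(ControllerConfig("NA"), trial_normal, model)
        na.u_exo = -net.knee.copy()  # device supplies the net torque exactly
        tau = physiological_torque(net, na, model,
                                   charge_damping_to_device=False)
        assert np.allclose(tau, 0.0, atol=1e-12)

    def test_stance_swing_discontinuity_is_reported(self, ctx_normal,
                                                    trial_normal, model):
        out = pendulum_torque(xa.recommended_config("SPM"), trial_normal,
                              model, ctx_normal.net_torques)
        jump = out.stance_swing_discontinuity()
        assert np.isfinite(jump) and jump >= 0.0
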