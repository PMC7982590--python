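"""Inverse dynamics against independent oracles.

The Newton-Euler recursion is checked against symbolically derived
Lagrangian torques (sympy) on toy chains with analytically supplied
kinematics, and its finite-difference path against the closed-form knee
pendulum at increasing frame rates.
"""

import numpy as np
import pytest
import sympy as sp

import exoassist as xa
from exoassist import dynamics as dy
from tests.conftest import (make_axial_foot_model, make_chain_model,
                            make_standing_trial, make_swing_pendulum_trial,
                            zero_grf)

G = 9.81


def _analytic_body_kinematics(model, q1_expr, q2_expr, tsym, time):
    """Build BodyKinematics for one leg from symbolic absolute segment
    angles q1 (thigh) and q2 (shank); hip fixed, foot rigid with the shank
    (ankle neutral), all derivatives taken symbolically."""
    segs = model.segments
    l1 = segs["thigh"].length
    c1 = segs["thigh"].com_offset
    c2 = segs["shank"].com_offset
    l2 = segs["shank"].length
    hip = sp.Matrix([0.0, 1.0])

    def unit(q):
        return sp.Matrix([sp.sin(q), -sp.cos(q)])

    knee = hip + l1 * unit(q1_expr)
    ankle = knee + l2 * unit(q2_expr)
    pts = {
        "hip": hip,
        "knee": knee,
        "ankle": ankle,
        "com_thigh": hip + c1 * unit(q1_expr),
        "com_shank": knee + c2 * unit(q2_expr),
        "com_foot": ankle,
        "com_thigh_shell": hip,
        "com_shank_shell": knee,
    }
    n = time.size

    def ev(expr):
        f = sp.lambdify(tsym, expr, "numpy")
        out = np.asarray(f(time), dtype=float)
        return np.broadcast_to(out, time.shape).copy()

    points, vel, acc = {}, {}, {}
    for name, p in pts.items():
        points[name] = np.stack([ev(p[0]), ev(p[1])], axis=-1)
        dp = p.diff(tsym)
        ddp = dp.diff(tsym)
        vel[name] = np.stack([ev(dp[0]), ev(dp[1])], axis=-1)
        acc[name] = np.stack([ev(ddp[0]), ev(ddp[1])], axis=-1)

    omega = {"thigh": ev(q1_expr.diff(tsym)), "shank": ev(q2_expr.diff(tsym))}
    omega["foot"] = omega["shank"].copy()
    alpha = {"thigh": ev(q1_expr.diff(tsym, 2)),
             "shank": ev(q2_expr.diff(tsym, 2))}
    alpha["foot"] = alpha["shank"].copy()

    zeros2 = np.zeros((n, model.n_foot_nodes, 2))
    leg = dy.LegKinematics(
        side="right", phi_thigh=ev(q1_expr), phi_shank=ev(q2_expr),
        gamma=ev(q2_expr), omega=omega, alpha=alpha, points=points,
        vel=vel, acc=acc, foot_nodes=zeros2, foot_nodes_vel=zeros2.copy(),
        strap_points=np.zeros((n, 0, 2)),
        theta_k=ev(q1_expr - q2_expr), theta_k_d1=ev((q1_expr - q2_expr).diff(tsym)),
        theta_k_d2=ev((q1_expr - q2_expr).diff(tsym, 2)),
        theta_a=-ev(q2_expr), theta_a_d1=-ev(q2_expr.diff(tsym)),
        theta_a_d2=-ev(q2_expr.diff(tsym, 2)),
        stance=np.zeros(n, dtype=bool), channels={},
    )
    left = dy.LegKinematics(**{**leg.__dict__})
    return dy.BodyKinematics(
        trial=None, model=model, legs={"right": leg, "left": left},
        hat_com=points["hip"].copy(), com=points["hip"].copy(),
        com_acc=np.zeros((n, 2)), dL=np.zeros(n))


def _lagrangian_torques(model, q1_expr, q2_expr, tsym, time):
    """Generalized joint torques from the Lagrangian of the 2-link chain
    (independent oracle; foot massless). Returns (tau_hip, tau_knee)."""
    segs = model.segments
    l1, c1 = segs["thigh"].length, segs["thigh"].com_offset
    c2 = segs["shank"].com_offset
    m1, I1 = segs["thigh"].mass, segs["thigh"].inertia_com
    m2, I2 = segs["shank"].mass, segs["shank"].inertia_com

    q1 = sp.Function("q1")(tsym)
    q2 = sp.Function("q2")(tsym)
    x1 = c1 * sp.sin(q1)
    y1 = -c1 * sp.cos(q1)
    x2 = l1 * sp.sin(q1) + c2 * sp.sin(q2)
    y2 = -l1 * sp.cos(q1) - c2 * sp.cos(q2)
    T = (sp.Rational(1, 2) * m1 * (x1.diff(tsym)**2 + y1.diff(tsym)**2)
         + sp.Rational(1, 2) * I1 * q1.diff(tsym)**2
         + sp.Rational(1, 2) * m2 * (x2.diff(tsym)**2 + y2.diff(tsym)**2)
         + sp.Rational(1, 2) * I2 * q2.diff(tsym)**2)
    V = m1 * G * y1 + m2 * G * y2
    L = T - V

    # Euler-Lagrange: Q_i = d/dt dL/dqi' - dL/dqi, then substitute the
    # prescribed trajectory (highest derivatives first)
    subs = {}
    for q, expr in ((q1, q1_expr), (q2, q2_expr)):
        subs[q.diff(tsym, 2)] = expr.diff(tsym, 2)
        subs[q.diff(tsym)] = expr.diff(tsym)
        subs[q] = expr
    Q = []
    for q in (q1, q2):
        Qi = (L.diff(q.diff(tsym))).diff(tsym) - L.diff(q)
        Q.append(Qi.subs(subs, simultaneous=True))
    # absolute-angle coordinates: Q1 = tau_hip - tau_knee, Q2 = tau_knee
    f_hip = sp.lambdify(tsym, Q[0] + Q[1], "numpy")
    f_knee = sp.lambdify(tsym, Q[1], "numpy")
    return (np.broadcast_to(f_hip(time), time.shape).astype(float),
            np.broadcast_to(f_knee(time), time.shape).astype(float))


@pytest.fixture(scope="module")
def toy_time():
    return np.linspace(0.0, 1.2, 121)


class TestLagrangianOracle:
    def test_single_segment_chain(self, toy_time):
        """Shank pendulum about a fixed knee (massless thigh) matches the
        symbolic Lagrangian torque to 1e-8 N*m over a full cycle."""
        model = make_chain_model(0.0, 0.45, 0.2, 0.0,
                                 m_shank=3.2, l_shank=0.42, c_shank=0.18,
                                 I_shank=0.05)
        t = sp.symbols("t")
        q1 = sp.Integer(0) * t
        q2 = 0.7 * sp.sin(2 * sp.pi * t / 1.2) + 0.2
        kin = _analytic_body_kinematics(model, q1, q2, t, toy_time)
        tau_hip, tau_knee = _lagrangian_torques(model, q1, q2, t, toy_time)

        # the trial only supplies the time grid here
        trial = make_standing_trial(n=toy_time.size, cycle=1.2)
        grf = zero_grf(trial, model)
        net = dy.inverse_dynamics(trial, model, grf, kinematics=kin)
        assert np.max(np.abs(net.knee - tau_knee)) < 1e-8

    def test_double_segment_chain(self, toy_time):
        """Thigh+shank double pendulum about a fixed hip: both joint torques
        match the symbolic Lagrangian to 1e-8 N*m."""
        model = make_chain_model(7.0, 0.43, 0.19, 0.12,
                                 m_shank=3.2, l_shank=0.42, c_shank=0.18,
                                 I_shank=0.05)
        t = sp.symbols("t")
        q1 = 0.5 * sp.sin(2 * sp.pi * t / 1.2)
        q2 = 0.8 * sp.sin(2 * sp.pi * t / 1.2 + 0.9) - 0.1
        kin = _analytic_body_kinematics(model, q1, q2, t, toy_time)
        tau_hip, tau_knee = _lagrangian_torques(model, q1, q2, t, toy_time)

        trial = make_standing_trial(n=toy_time.size, cycle=1.2)
        grf = zero_grf(trial, model)
        net = dy.inverse_dynamics(trial, model, grf, kinematics=kin)
        assert np.max(np.abs(net.knee - tau_knee)) < 1e-8
        assert np.max(np.abs(net.hip - tau_hip)) < 1e-8


class TestFiniteDifferencePath:
    def _pendulum_error(self, n):
        model = make_axial_foot_model()
        trial = make_swing_pendulum_trial(
            lambda ph: 0.5 + 0.3 * np.sin(2 * np.pi * ph), n=n)
        kin = dy.compute_kinematics(trial, model)
        net = dy.inverse_dynamics(trial, model, zero_grf(trial, model), kin)
        pc = xa.pendulum_constants(model)
        leg = kin.legs["right"]
        u_s = (pc.I_c1 * leg.theta_k_d2
               + pc.m_c1 * model.gravity * pc.l_c1 * np.sin(leg.theta_k))
        # the net knee torque in the extension-positive convention is the
        # negated flexion-coordinate pendulum torque
        return np.max(np.abs(net.knee - (-u_s)))

    def test_swing_pendulum_closed_form(self):
        assert self._pendulum_error(6401) < 2.5e-7

    def test_halving_dt_shrinks_error_fourfold(self):
        e1, e2 = self._pendulum_error(401), self._pendulum_error(801)
        assert 3.0 < e1 / e2 < 5.5

    def test_gravitational_torques_linear_in_mass(self):
        """Static posture, zero reactions: doubling all segment masses
        exactly doubles the (purely gravitational) joint torques."""
        kw = dict(m_thigh=7.0, l_thigh=0.43, c_thigh=0.19, I_thigh=0.12,
                  m_shank=3.2, l_shank=0.42, c_shank=0.18, I_shank=0.05,
                  m_foot=1.0, foot_com=(0.05, -0.03))
        m1 = make_chain_model(**kw)
        kw2 = dict(kw, m_thigh=14.0, m_shank=6.4, m_foot=2.0)
        m2 = make_chain_model(**kw2)
        trial = make_standing_trial(n=21, knee_angle=0.3)
        net1 = dy.inverse_dynamics(trial, m1, zero_grf(trial, m1))
        net2 = dy.inverse_dynamics(trial, m2, zero_grf(trial, m2))
        for a, b in ((net1.knee, net2.knee), (net1.hip, net2.hip),
                     (net1.ankle, net2.ankle)):
            assert np.allclose(2 * a, b, atol=1e-10)


def test_grid_mismatch_rejected(trial_normal, model):
    other = xa.generate_gait(trial_normal.speed_preset, 51, 0)
    grf = zero_grf(other, model)
    with pytest.raises(ValueError, match="time grid"):
        dy.inverse_dynamics(trial_normal, model, grf)


def test_whole_body_force_residual_small(ctx_normal, model):
    """With predicted ground reactions, the whole-body Newton residual is
    far below body weight at every frame."""
    assert ctx_normal.net_torques.residual.max() < 1e-3 * model.body_weight
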