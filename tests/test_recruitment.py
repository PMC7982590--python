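"""Static-optimization recruitment: QP oracle checks, GRF prediction,
strap-force distribution."""

import numpy as np
import pytest

import exoassist as xa
from exoassist import config
from exoassist import dynamics as dy
from exoassist import recruitment as rc
from exoassist.body_model import (Anthropometry, ExoskeletonSpec, StrapNode,
                                  build_model)
from tests.conftest import make_standing_trial, make_swing_pendulum_trial

BIG_RESERVE = np.array([1e8])  # effectively disable the reserve in toys


def grid_search_oracle(arms, f_max, demand, step=1e-3):
    """Brute-force minimizer of sum a_i^2 under one torque equality: grid
    the first n-1 activations, solve the last from the equality. The
    largest-torque muscle is solved last so the grid quantization is not
    amplified through the equality."""
    arms = np.asarray(arms, float)
    f_max = np.asarray(f_max, float)
    tau = arms * f_max
    order = np.argsort(np.abs(tau))
    tau = tau[order]
    inverse = np.argsort(order)
    n = tau.size
    grid = np.arange(0.0, 1.0 + step / 2, step)
    if n == 2:
        a0 = grid
        a1 = (demand - tau[0] * a0) / tau[1]
        ok = (a1 >= -1e-12) & (a1 <= 1 + 1e-12)
        cost = np.where(ok, a0**2 + a1**2, np.inf)
        k = int(np.argmin(cost))
        return np.array([a0[k], np.clip(a1[k], 0, 1)])[inverse]
    a0, a1 = np.meshgrid(grid, grid, indexing="ij")
    a2 = (demand - tau[0] * a0 - tau[1] * a1) / tau[2]
    ok = (a2 >= -1e-12) & (a2 <= 1 + 1e-12)
    cost = np.where(ok, a0**2 + a1**2 + a2**2, np.inf)
    k = np.unravel_index(np.argmin(cost), cost.shape)
    return np.array([a0[k], a1[k], np.clip(a2[k], 0, 1)])[inverse]


class TestRecruitFrame:
    def test_single_muscle_hand_solution(self):
        a, res, _ = rc.recruit_joint_frame([[0.05]], [2000.0], [50.0],
                                           reserve_weights=BIG_RESERVE)
        assert a[0] == pytest.approx(0.5, abs=1e-6)
        assert a[0] * 2000.0 == pytest.approx(1000.0, rel=1e-6)

    def test_two_identical_muscles_split_equally(self):
        a, _, _ = rc.recruit_joint_frame([[0.05, 0.05]], [2000.0, 2000.0],
                                         [50.0], reserve_weights=BIG_RESERVE)
        assert np.allclose(a, [0.25, 0.25], atol=1e-8)

    def test_zero_demand_zero_activations(self):
        a, reserves, res = rc.recruit_joint_frame(
            [[0.05, -0.03]], [2000.0, 1500.0], [0.0])
        assert np.allclose(a, 0.0, atol=1e-12)
        assert res.objective == pytest.approx(0.0, abs=1e-15)

    def test_matches_grid_search_oracle(self):
        """Randomized 2-3 muscle problems agree with the brute-force
        activation-grid oracle within 2e-3 per activation."""
        rng = np.random.default_rng(7)
        for trial_i in range(60):
            n = 2 if trial_i % 2 == 0 else 3
            arms = rng.uniform(0.02, 0.06, n)
            f_max = rng.uniform(500.0, 3000.0, n)
            tau = arms * f_max
            # keep the optimum strictly interior (no saturated activation):
            # the unconstrained minimizer has a_i = D tau_i / sum(tau^2)
            cap = float(np.sum(tau**2) / tau.max())
            demand = rng.uniform(0.1, 0.9) * cap
            a, _, _ = rc.recruit_joint_frame([arms], f_max, [demand],
                                             reserve_weights=BIG_RESERVE)
            a_star = grid_search_oracle(arms, f_max, demand)
            assert np.max(np.abs(a - a_star)) < 2e-3

    def test_max_activation_monotone_in_demand(self):
        arms = [[0.05, 0.04, -0.03]]
        f_max = [2000.0, 1500.0, 1000.0]
        prev = -1.0
        for demand in np.linspace(0.0, 120.0, 13):
            a, _, _ = rc.recruit_joint_frame(arms, f_max, [demand])
            peak = a.max()
            assert peak >= prev - 1e-9
            prev = peak

    def test_infeasible_equalities_raise_named_error(self):
        qp = rc.QuadraticProgram(
            weights=[1.0], A_eq=[[1.0], [1.0]], b_eq=[0.0, 1.0],
            lb=np.array([-10.0]), ub=np.array([10.0]),
            row_names=("row A", "row B"))
        with pytest.raises(rc.RecruitmentError, match="row"):
            rc.solve_qp(qp)


class TestPredictGrf:
    def test_static_standing_supports_total_weight(self, model):
        trial = make_standing_trial()
        grf = rc.predict_grf(trial, model)
        total_v = grf.total_force()[:, 1]
        expected = model.total_mass * model.gravity
        assert np.allclose(total_v, expected, rtol=1e-3)

    def test_swing_leg_carries_zero_force(self, ctx_normal, trial_normal):
        swing = ~trial_normal.in_stance()
        right = ctx_normal.grf.force["right"]
        assert np.all(right[swing] == 0.0)

    def test_midstance_newton_residual(self, ctx_normal, model):
        """Direct F = ma check at mid-stance frames."""
        ph = np.mod(ctx_normal.trial.phase, 1.0)
        mid = (ph > 0.2) & (ph < 0.4)
        assert ctx_normal.grf.residual[mid].max() < 1e-3 * model.body_weight

    def test_normal_forces_nonnegative_and_cone_respected(self, ctx_normal,
                                                          model):
        for side in ("right", "left"):
            n = ctx_normal.grf.node_normal[side]
            t = ctx_normal.grf.node_tangential[side]
            assert np.all(n >= -1e-9)
            assert np.all(np.abs(t) <= model.ground_friction * n + 1e-6)


def _static_strap_geometry(model, nodes):
    """World node positions for a straight-down leg, knee at the origin."""
    l_t = model.segments["thigh_free"].length
    pts = []
    for nd in nodes:
        if nd.host_segment == "shank":
            base = np.array([0.0, 0.0])
        else:
            base = np.array([0.0, l_t])
        pts.append(base + np.array([0.0, -nd.axial_position])
                   + nd.normal_sign * nd.cuff_radius * np.array([1.0, 0.0]))
    return np.array(pts)


def _massless_shells(model):
    z = np.zeros(2)
    return {"thigh": (0.0, z, np.array([0.0, 0.3])),
            "shank": (0.0, z, np.array([0.0, -0.3]))}


def _two_ring_model():
    nodes = []
    for seg, posts in (("shank", (0.10, 0.20)), ("thigh", (0.10, 0.25))):
        for pos in posts:
            for sign in (1, -1):
                nodes.append(StrapNode(host_segment=seg, axial_position=pos,
                                       normal_sign=sign, cuff_radius=0.05))
    return build_model(Anthropometry(66.0, 1.75),
                       ExoskeletonSpec(strap_nodes=tuple(nodes)))


class TestStrapEquilibrium:
    def test_zero_torque_massless_shells_zero_forces(self):
        model = _two_ring_model()
        pts = _static_strap_geometry(model, model.strap_nodes)
        normal, tang, _ = rc.solve_strap_frame(
            model, 0.0, pts, np.zeros(2), _massless_shells(model), 0.0, 0.0)
        assert np.allclose(normal, 0.0, atol=1e-9)
        assert np.allclose(tang, 0.0, atol=1e-9)

    def test_commanded_torque_balanced_by_shank_nodes(self):
        """10 N*m on the shank shell is carried by the node forces:
        the moment of the shank-node forces about the knee equals the
        commanded torque to 1e-6 N*m."""
        model = _two_ring_model()
        pts = _static_strap_geometry(model, model.strap_nodes)
        normal, tang, _ = rc.solve_strap_frame(
            model, 10.0, pts, np.zeros(2), _massless_shells(model), 0.0, 0.0)
        moment = 0.0
        for k, nd in enumerate(model.strap_nodes):
            if nd.host_segment != "shank":
                continue
            f = (nd.normal_sign * np.array([1.0, 0.0]) * normal[k]
                 + np.array([0.0, -1.0]) * tang[k])
            r = pts[k]
            moment += r[0] * f[1] - r[1] * f[0]
        assert moment == pytest.approx(-10.0, abs=1e-6)

    def test_coulomb_cone_hard_constraint(self):
        model = _two_ring_model()
        pts = _static_strap_geometry(model, model.strap_nodes)
        normal, tang, _ = rc.solve_strap_frame(
            model, 25.0, pts, np.zeros(2), _massless_shells(model), 0.0, 0.0)
        mu = model.exo.friction_coefficient
        assert np.all(np.abs(tang) <= mu * normal + 1e-6)

    def test_node_outside_window_transmits_nothing(self):
        nodes = list(_two_ring_model().exo.strap_nodes)
        # displace the first shank node beyond its radius limit
        from dataclasses import replace
        nodes[0] = replace(nodes[0], radial_offset=1.0)
        model = build_model(Anthropometry(66.0, 1.75),
                           ExoskeletonSpec(strap_nodes=tuple(nodes)))
        pts = _static_strap_geometry(model, model.strap_nodes)
        normal, tang, _ = rc.solve_strap_frame(
            model, 10.0, pts, np.zeros(2), _massless_shells(model), 0.0, 0.0)
        assert normal[0] == 0.0 and tang[0] == 0.0

    def test_untransmittable_assistance_raises(self):
        from dataclasses import replace
        nodes = tuple(replace(n, radial_offset=1.0)
                      for n in _two_ring_model().exo.strap_nodes)
        model = build_model(Anthropometry(66.0, 1.75),
                           ExoskeletonSpec(strap_nodes=nodes))
        pts = _static_strap_geometry(model, model.strap_nodes)
        with pytest.raises(rc.RecruitmentError, match="cannot be transmitted"):
            rc.solve_strap_frame(model, 10.0, pts, np.zeros(2),
                                 _massless_shells(model), 0.0, 0.0)


class TestSolveRecruitment:
    def test_solution_invariants(self, reports, model):
        sol = reports[("SPM", "normal")].solution
        assert np.all((sol.activations >= -1e-9) & (sol.activations <= 1 + 1e-9))
        assert np.all(sol.strap_normal >= -1e-9)
        mu = model.exo.friction_coefficient
        assert np.all(np.abs(sol.strap_tangential)
                      <= mu * sol.strap_normal + 1e-6)

    def test_torque_balance_residuals_small(self, reports):
        for key in (("NA", "normal"), ("DPM", "normal")):
            assert reports[key].solution.residual.max() < 1e-6 * 100.0

    def test_knee_reserve_barely_used(self, reports):
        """The heavily penalized knee reserve stays negligible: the ten
        muscles carry the knee demand."""
        sol = reports[("NA", "normal")].solution
        assert np.abs(sol.reserves[:, 1]).max() < 1.0
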