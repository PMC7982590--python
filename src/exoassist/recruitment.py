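"""Static-optimization recruitment of muscles, reserves, foot-contact and
strap-contact actuators.

Every force source is an "artificial muscle": a decision variable is an
activation (force / strength), the objective is a weighted sum of squared
activations, and equality constraints express mechanical balance. Muscles
carry weight 1; foot and strap contact actuators are load paths, not
effort, and carry a small weight; the knee reserve actuator is heavily
penalized so it only reports what the muscles cannot deliver, while the
hip/ankle reserves stand in for the (out-of-scope) hip and ankle
musculature at ordinary weight.

The per-frame problem separates into three strictly convex quadratic
programs solved by a shared engine:

1. ground-reaction prediction — foot-node actuators vs whole-body
   Newton-Euler (forces exactly, sagittal moment with a heavily penalized
   slack);
2. muscle recruitment — hip/knee/ankle torque balance of the instrumented
   leg, the knee demand being the user's physiological share;
3. strap-force distribution — free-body force/torque balance of the two
   exoskeleton shells transmitting the commanded device torque through the
   conditional contact nodes under a Coulomb friction cone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import (Bounds, LinearConstraint, NonlinearConstraint,
                            minimize)

from . import config
from .body_model import LinkedSegmentModel, moment_arm
from .dynamics import (BodyKinematics, FootLoads, NetTorques, compute_kinematics,
                       cross2)
from .synthetic_gait import GaitTrial

__all__ = [
    "QuadraticProgram",
    "QPResult",
    "RecruitmentError",
    "RecruitmentProblem",
    "RecruitmentSolution",
    "solve_qp",
    "recruit_joint_frame",
    "predict_grf",
    "strap_equilibrium_constraints",
    "solve_strap_frame",
    "build_recruitment_problem",
    "solve_recruitment",
    "write_solution_csv",
]


class RecruitmentError(RuntimeError):
    """Raised when a recruitment problem is infeasible."""


@dataclass
class QuadraticProgram:
    """min 0.5 * sum_i weights_i x_i^2  s.t.  A_eq x = b_eq, A_ub x <= b_ub,
    lb <= x <= ub. Strictly convex for positive weights."""

    weights: np.ndarray
    A_eq: np.ndarray
    b_eq: np.ndarray
    lb: np.ndarray
    ub: np.ndarray
    A_ub: np.ndarray | None = None
    b_ub: np.ndarray | None = None
    row_names: tuple = ()

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.weights <= 0):
            raise ValueError("objective weights must be positive")
        self.A_eq = np.atleast_2d(np.asarray(self.A_eq, dtype=float))
        self.b_eq = np.atleast_1d(np.asarray(self.b_eq, dtype=float))


@dataclass
class QPResult:
    x: np.ndarray
    objective: float
    eq_residual: np.ndarray
    success: bool
    message: str


def _violated_row(qp: QuadraticProgram, x: np.ndarray) -> str:
    res = np.abs(qp.A_eq @ x - qp.b_eq)
    i = int(np.argmax(res))
    name = qp.row_names[i] if i < len(qp.row_names) else f"equality row {i}"
    return f"{name} (|residual| = {res[i]:.3g})"


def _equality_only_minimizer(qp: QuadraticProgram) -> np.ndarray | None:
    """Closed-form minimizer subject to the equality rows only:
    x = W^-1 A^T lam with (A W^-1 A^T) lam = b."""
    Winv_At = qp.A_eq.T / qp.weights[:, None]
    G = qp.A_eq @ Winv_At
    try:
        lam = np.linalg.solve(G, qp.b_eq)
    except np.linalg.LinAlgError:
        lam, *_ = np.linalg.lstsq(G, qp.b_eq, rcond=None)
    x = Winv_At @ lam
    scale = 1.0 + np.abs(qp.b_eq)
    if np.any(np.abs(qp.A_eq @ x - qp.b_eq) > 1e-9 * scale):
        return None
    return x


def _inequality_rows(qp: QuadraticProgram):
    """All inequality constraints as G x <= h rows (cones plus finite bounds)."""
    n = qp.weights.size
    G_rows, h_rows = [], []
    if qp.A_ub is not None and len(qp.A_ub):
        G_rows.append(np.atleast_2d(qp.A_ub))
        h_rows.append(np.atleast_1d(qp.b_ub))
    finite_ub = np.isfinite(qp.ub)
    if np.any(finite_ub):
        E = np.eye(n)[finite_ub]
        G_rows.append(E)
        h_rows.append(qp.ub[finite_ub])
    finite_lb = np.isfinite(qp.lb)
    if np.any(finite_lb):
        E = -np.eye(n)[finite_lb]
        G_rows.append(E)
        h_rows.append(-qp.lb[finite_lb])
    if not G_rows:
        return np.zeros((0, n)), np.zeros(0)
    return np.vstack(G_rows), np.concatenate(h_rows)


def _active_set_qp(qp: QuadraticProgram, tol: float = 1e-10):
    """Primal active-set solve of the strictly convex diagonal-Hessian QP.

    Repeatedly solves the equality-constrained KKT system with the current
    working set of tight inequalities, adding the most violated inequality
    and dropping members with the wrong multiplier sign. Returns None if the
    iteration cap is hit (caller falls back to SLSQP).
    """
    G, h = _inequality_rows(qp)
    m_eq = qp.b_eq.size
    active: list[int] = []
    Winv = 1.0 / qp.weights
    for _ in range(200):
        A_ext = np.vstack([qp.A_eq, G[active]]) if active else qp.A_eq
        b_ext = np.concatenate([qp.b_eq, h[active]]) if active else qp.b_eq
        Winv_At = A_ext.T * Winv[:, None]
        K = A_ext @ Winv_At
        try:
            lam = np.linalg.solve(K, b_ext)
        except np.linalg.LinAlgError:
            lam, *_ = np.linalg.lstsq(K, b_ext, rcond=None)
        x = Winv_At @ lam
        # multipliers of active inequalities must satisfy lam <= 0
        if active:
            mu = lam[m_eq:]
            worst = int(np.argmax(mu))
            if mu[worst] > tol:
                active.pop(worst)
                continue
        if len(G):
            viol = G @ x - h
            worst = int(np.argmax(viol))
            if viol[worst] > tol * (1.0 + abs(h[worst])):
                if worst in active:
                    return None  # degenerate; let SLSQP handle it
                active.append(worst)
                continue
        return x
    return None


def solve_qp(qp: QuadraticProgram, x0: np.ndarray | None = None) -> QPResult:
    """Solve the strictly convex QP.

    A closed-form equality-only KKT step plus a primal active-set loop
    handles almost every frame exactly; SLSQP (then trust-constr) covers the
    rest. Raises :class:`RecruitmentError` naming the most violated
    constraint if no feasible point is found.
    """
    n = qp.weights.size
    w = qp.weights

    x_as = _active_set_qp(qp)
    if x_as is not None:
        eq_res = qp.A_eq @ x_as - qp.b_eq
        scale = 1.0 + np.abs(qp.b_eq)
        if np.all(np.abs(eq_res) <= 1e-8 * scale):
            x_as = np.clip(x_as, qp.lb, qp.ub)
            return QPResult(x=x_as,
                            objective=0.5 * float(np.dot(w, x_as * x_as)),
                            eq_residual=qp.A_eq @ x_as - qp.b_eq,
                            success=True, message="active-set KKT")

    if x0 is None:
        x_kkt = _equality_only_minimizer(qp)
        x0 = np.clip(x_kkt if x_kkt is not None else np.zeros(n),
                     qp.lb, qp.ub)

    def fun(x):
        return 0.5 * float(np.dot(w, x * x))

    def jac(x):
        return w * x

    cons = [{"type": "eq",
             "fun": lambda x: qp.A_eq @ x - qp.b_eq,
             "jac": lambda x: qp.A_eq}]
    if qp.A_ub is not None and len(qp.A_ub):
        A_ub = np.atleast_2d(qp.A_ub)
        b_ub = np.atleast_1d(qp.b_ub)
        cons.append({"type": "ineq",
                     "fun": lambda x: b_ub - A_ub @ x,
                     "jac": lambda x: -A_ub})

    def _feasible(x):
        eq = np.abs(qp.A_eq @ x - qp.b_eq) <= 1e-6 * (1.0 + np.abs(qp.b_eq))
        ok = np.all(eq) and np.all(x >= qp.lb - 1e-8) and np.all(x <= qp.ub + 1e-8)
        if ok and qp.A_ub is not None and len(qp.A_ub):
            A_ub = np.atleast_2d(qp.A_ub)
            b_ub = np.atleast_1d(qp.b_ub)
            ok = np.all(A_ub @ x <= b_ub + 1e-8 * (1.0 + np.abs(b_ub)))
        return bool(ok)

    res = minimize(fun, x0, jac=jac, method="SLSQP",
                   bounds=list(zip(qp.lb, qp.ub)), constraints=cons,
                   options={"maxiter": 300, "ftol": config.SOLVER_FTOL})
    x = res.x
    eq_res = qp.A_eq @ x - qp.b_eq
    scale = 1.0 + np.abs(qp.b_eq)
    if not _feasible(x):
        lc = [LinearConstraint(qp.A_eq, qp.b_eq, qp.b_eq)]
        if qp.A_ub is not None and len(qp.A_ub):
            lc.append(LinearConstraint(np.atleast_2d(qp.A_ub),
                                       -np.inf, np.atleast_1d(qp.b_ub)))
        try:
            res2 = minimize(fun, x0, jac=jac, method="trust-constr",
                            bounds=Bounds(qp.lb, qp.ub), constraints=lc,
                            options={"gtol": 1e-12, "xtol": 1e-14,
                                     "maxiter": 2000, "verbose": 0})
        except (ValueError, np.linalg.LinAlgError):
            res2 = None
        if res2 is not None:
            x2 = res2.x
            eq2 = qp.A_eq @ x2 - qp.b_eq
            if np.max(np.abs(eq2) / scale) < np.max(np.abs(eq_res) / scale):
                x, eq_res, res = x2, eq2, res2
        if not _feasible(x):
            raise RecruitmentError(
                "recruitment infeasible: violated constraint "
                + _violated_row(qp, x))
    return QPResult(x=x, objective=fun(x), eq_residual=eq_res,
                    success=True, message=str(res.message))


# ---------------------------------------------------------------------------
# Muscle recruitment (per frame)
# ---------------------------------------------------------------------------

def recruit_joint_frame(
    arms: np.ndarray,
    f_max: np.ndarray,
    demands: np.ndarray,
    reserve_weights: np.ndarray | None = None,
    muscle_weights: np.ndarray | None = None,
    x0: np.ndarray | None = None,
):
    """Recruit muscles plus one reserve per joint for a single frame.

    Parameters
    ----------
    arms : (n_joints, n_muscles) signed moment arms in metres.
    f_max : (n_muscles,) muscle strengths, N.
    demands : (n_joints,) net torque demands, N*m.
    reserve_weights, muscle_weights : optional objective weights.

    Returns
    -------
    activations : (n_muscles,) in [0, 1]
    reserves : (n_joints,) reserve torques, N*m
    result : QPResult
    """
    arms = np.atleast_2d(np.asarray(arms, dtype=float))
    f_max = np.asarray(f_max, dtype=float)
    demands = np.atleast_1d(np.asarray(demands, dtype=float))
    nj, nm = arms.shape
    if muscle_weights is None:
        muscle_weights = np.full(nm, config.W_MUSCLE)
    if reserve_weights is None:
        reserve_weights = np.full(nj, config.W_OTHER_RESERVE)
    A_eq = np.hstack([arms * f_max[None, :],
                      config.RESERVE_TORQUE_SCALE * np.eye(nj)])
    qp = QuadraticProgram(
        weights=np.r_[muscle_weights, reserve_weights],
        A_eq=A_eq, b_eq=demands,
        lb=np.r_[np.zeros(nm), np.full(nj, -np.inf)],
        ub=np.r_[np.ones(nm), np.full(nj, np.inf)],
        row_names=tuple(f"torque balance joint {j}" for j in range(nj)),
    )
    res = solve_qp(qp, x0=x0)
    a = res.x[:nm]
    reserves = res.x[nm:] * config.RESERVE_TORQUE_SCALE
    return a, reserves, res


# ---------------------------------------------------------------------------
# Ground-reaction prediction
# ---------------------------------------------------------------------------

def predict_grf(trial: GaitTrial, model: LinkedSegmentModel,
                kinematics: BodyKinematics | None = None) -> FootLoads:
    """Predict ground reactions with foot-contact actuators.

    At each frame the active contact nodes (stance-window legs whose nodes
    lie within a height gate of the lowest foot point and move slower than
    the speed gate) receive a vertical actuator plus an antagonistic
    antero-posterior pair bounded by a Coulomb cone. The weakly penalized
    node activations reproduce the whole-body Newton equation exactly and
    the sagittal angular-momentum balance up to a heavily penalized slack.
    Frames with no active node (swing) carry zero force.
    """
    kin = kinematics if kinematics is not None else compute_kinematics(trial, model)
    n = trial.n_frames
    n_nodes = model.n_foot_nodes
    M = model.total_mass
    gvec = np.array([0.0, -model.gravity])
    mu = model.ground_friction

    # In the sagittal plane the medio-laterally stacked nodes of one
    # antero-posterior column are co-located, so the quadratic objective
    # splits a column's load equally among them; solving per column and
    # dividing by the stack size is exact and much cheaper. Likewise the
    # antagonistic tangential pair of a column collapses to one signed
    # variable (at the optimum at most one member of a pair is active).
    per_col = n_nodes // config.FOOT_NODE_COLUMNS
    S = config.FOOT_NODE_STRENGTH * per_col  # column strength
    cols = {j: slice(j * per_col, (j + 1) * per_col)
            for j in range(config.FOOT_NODE_COLUMNS)}

    node_normal = {s: np.zeros((n, n_nodes)) for s in ("right", "left")}
    node_tang = {s: np.zeros((n, n_nodes)) for s in ("right", "left")}
    residual = np.zeros(n)

    demand = M * kin.com_acc - M * gvec  # required total GRF

    for i in range(n):
        active: list[tuple[str, int]] = []
        ys = []
        for side, leg in kin.legs.items():
            if leg.stance[i]:
                ys.append(leg.foot_nodes[i, :, 1].min())
        if ys:
            y_ref = min(ys)
            for side, leg in kin.legs.items():
                if not leg.stance[i]:
                    continue
                for j, sl in cols.items():
                    k0 = sl.start  # representative node of the column
                    h = leg.foot_nodes[i, k0, 1] - y_ref
                    speed = float(np.linalg.norm(leg.foot_nodes_vel[i, k0]))
                    if h < config.GRF_HEIGHT_GATE and speed < config.GRF_SPEED_GATE:
                        active.append((side, j))
        if not active:
            residual[i] = float(np.linalg.norm(demand[i]))
            continue

        na = len(active)
        nv = 2 * na + 1  # per column: normal, signed AP; plus moment slack
        A_eq = np.zeros((3, nv))
        pos = np.array([kin.legs[s].foot_nodes[i, cols[j].start]
                        for s, j in active])
        r = pos - kin.com[i]
        # vertical force row, AP force row, moment-about-COM row
        A_eq[0, 0:2 * na:2] = S
        A_eq[1, 1:2 * na:2] = S
        A_eq[2, 0:2 * na:2] = S * r[:, 0]          # x * Fy
        A_eq[2, 1:2 * na:2] = -S * r[:, 1]         # -y * Fx
        A_eq[2, -1] = 1.0                          # moment slack, N*m
        b_eq = np.array([demand[i, 1], demand[i, 0], kin.dL[i]])

        # Coulomb cone per column: +/- t <= mu * n
        A_ub = np.zeros((2 * na, nv))
        for k in range(na):
            A_ub[2 * k, 2 * k] = -mu
            A_ub[2 * k, 2 * k + 1] = 1.0
            A_ub[2 * k + 1, 2 * k] = -mu
            A_ub[2 * k + 1, 2 * k + 1] = -1.0
        lb = np.r_[np.tile([0.0, -10.0], na), [-np.inf]]
        ub = np.r_[np.full(2 * na, 10.0), [np.inf]]
        qp = QuadraticProgram(
            weights=np.r_[np.full(2 * na, config.W_SUPPORT),
                          [config.W_MOMENT_SLACK]],
            A_eq=A_eq, b_eq=b_eq, lb=lb, ub=ub,
            A_ub=A_ub, b_ub=np.zeros(2 * na),
            row_names=("whole-body vertical force", "whole-body AP force",
                       "whole-body sagittal moment"),
        )
        res = solve_qp(qp)
        for k, (side, j) in enumerate(active):
            node_normal[side][i, cols[j]] = S * res.x[2 * k] / per_col
            node_tang[side][i, cols[j]] = S * res.x[2 * k + 1] / per_col
        residual[i] = float(np.linalg.norm(res.eq_residual[:2]))

    # project solver-tolerance dust back onto the friction cone
    for side in node_tang:
        lim = mu * node_normal[side]
        node_tang[side] = np.clip(node_tang[side], -lim, lim)

    force = {}
    moment = {}
    for side, leg in kin.legs.items():
        fx = node_tang[side]
        fy = node_normal[side]
        force[side] = np.stack([fx.sum(axis=1), fy.sum(axis=1)], axis=-1)
        rel = leg.foot_nodes - leg.points["ankle"][:, None, :]
        moment[side] = (rel[..., 0] * fy - rel[..., 1] * fx).sum(axis=1)

    return FootLoads(time=trial.time, node_normal=node_normal,
                     node_tangential=node_tang, force=force,
                     moment_ankle=moment, residual=residual)


# ---------------------------------------------------------------------------
# Strap interaction forces
# ---------------------------------------------------------------------------

def strap_equilibrium_constraints(
    model: LinkedSegmentModel,
    u_device: float,
    strap_points: np.ndarray,
    knee_point: np.ndarray,
    shell_states: dict,
    phi_thigh: float,
    phi_shank: float,
):
    """Equality block for the exoskeleton free bodies at one frame.

    Variables are, per active in-plane node, the activations of (normal,
    tangential+, tangential-) artificial muscles (force = activation *
    strength). The pin force at the device hinge is eliminated, leaving the
    combined force balance of both shells (2 rows) and one moment-about-knee
    balance per shell (2 rows). ``u_device`` is the device torque on the
    shank shell in the knee-extension-positive convention;
    ``shell_states[seg] = (mass, g_minus_a)`` supplies shell gravity/inertia.

    Returns ``(A_eq, b_eq, active, row_names)`` where ``active`` is the list
    of indices into ``model.strap_nodes`` that can currently transmit force.

    Raises :class:`RecruitmentError` if a non-zero device torque must be
    transmitted with no active node on some shell.
    """
    active = [k for k, nd in enumerate(model.strap_nodes)
              if nd.in_plane and nd.active()]
    by_seg = {"thigh": [], "shank": []}
    for k in active:
        by_seg[model.strap_nodes[k].host_segment].append(k)
    if u_device != 0.0 and (not by_seg["thigh"] or not by_seg["shank"]):
        raise RecruitmentError(
            "assistance cannot be transmitted: no active strap node on the "
            + ("thigh" if not by_seg["thigh"] else "shank") + " shell")

    na = len(active)
    A_eq = np.zeros((4, 3 * na))
    b_eq = np.zeros(4)

    def _axes(seg):
        phi = phi_thigh if seg == "thigh" else phi_shank
        u = np.array([np.sin(phi), -np.cos(phi)])     # axial, distal-ward
        nhat = np.array([np.cos(phi), np.sin(phi)])   # anterior perpendicular
        return u, nhat

    for col, k in enumerate(active):
        nd = model.strap_nodes[k]
        u, nhat = _axes(nd.host_segment)
        # force on the shell: outward normal reaction, +/- axial friction
        f_n = nd.normal_sign * nhat * nd.strength
        f_tp = u * nd.strength
        f_tm = -u * nd.strength
        r = strap_points[k] - knee_point
        mrow = 2 if nd.host_segment == "shank" else 3
        for off, f in ((0, f_n), (1, f_tp), (2, f_tm)):
            A_eq[0, 3 * col + off] = f[0]
            A_eq[1, 3 * col + off] = f[1]
            A_eq[mrow, 3 * col + off] = cross2(r, f)

    # gravity/inertia of the shells and the device hinge torque
    for seg, mrow in (("shank", 2), ("thigh", 3)):
        mass, g_minus_a, com = shell_states[seg]
        w = mass * g_minus_a
        b_eq[0] -= w[0]
        b_eq[1] -= w[1]
        b_eq[mrow] -= cross2(com - knee_point, w)
    b_eq[2] -= u_device
    b_eq[3] += u_device

    names = ("device force balance x", "device force balance y",
             "shank shell moment about knee", "thigh shell moment about knee")
    return A_eq, b_eq, active, names


def solve_strap_frame(
    model: LinkedSegmentModel,
    u_device: float,
    strap_points: np.ndarray,
    knee_point: np.ndarray,
    shell_states: dict,
    phi_thigh: float,
    phi_shank: float,
):
    """Distribute the device loads over the strap nodes at one frame.

    Returns ``(normal, tangential, result)`` as length-16 arrays (N); the
    Coulomb cone |tangential| <= mu * normal is a hard constraint.
    """
    A_eq, b_eq, active, names = strap_equilibrium_constraints(
        model, u_device, strap_points, knee_point, shell_states,
        phi_thigh, phi_shank)
    na = len(active)
    n_nodes = len(model.strap_nodes)
    if na == 0:
        if np.any(np.abs(b_eq) > 1e-9):
            raise RecruitmentError(
                "assistance cannot be transmitted: no active strap nodes")
        zero = np.zeros(n_nodes)
        return zero, zero.copy(), None
    mu = model.exo.friction_coefficient
    A_ub = np.zeros((na, 3 * na))
    for k in range(na):
        A_ub[k, 3 * k] = -mu
        A_ub[k, 3 * k + 1] = 1.0
        A_ub[k, 3 * k + 2] = 1.0
    qp = QuadraticProgram(
        weights=np.full(3 * na, config.W_SUPPORT),
        A_eq=A_eq, b_eq=b_eq,
        lb=np.zeros(3 * na), ub=np.full(3 * na, 1.0),
        A_ub=A_ub, b_ub=np.zeros(na),
        row_names=names,
    )
    res = solve_qp(qp)
    normal = np.zeros(n_nodes)
    tang = np.zeros(n_nodes)
    for col, k in enumerate(active):
        s = model.strap_nodes[k].strength
        normal[k] = s * res.x[3 * col]
        tang[k] = s * (res.x[3 * col + 1] - res.x[3 * col + 2])
    tang = np.clip(tang, -mu * normal, mu * normal)
    return normal, tang, res


# ---------------------------------------------------------------------------
# Full per-trial recruitment
# ---------------------------------------------------------------------------

@dataclass
class RecruitmentProblem:
    """Everything needed to recruit muscles and straps over a trial."""

    trial: GaitTrial
    model: LinkedSegmentModel
    net_torques: NetTorques
    tau_physio: np.ndarray       # knee demand carried by the user, N*m
    tau_device: np.ndarray       # device knee torque (assist + damping), N*m
    grf: FootLoads


@dataclass
class RecruitmentSolution:
    """Per-frame activations, forces and residuals of the recruitment."""

    time: np.ndarray
    muscle_names: tuple
    activations: np.ndarray      # (n, n_muscles) in [0, 1]
    forces: np.ndarray           # (n, n_muscles), N
    reserves: np.ndarray         # (n, 3) hip/knee/ankle reserve torque, N*m
    objective: np.ndarray        # (n,)
    strap_normal: np.ndarray     # (n, 16), N, >= 0
    strap_tangential: np.ndarray  # (n, 16), N, signed
    grf_total: np.ndarray        # (n, 2), N
    residual: np.ndarray         # (n,) largest torque-balance residual, N*m


def build_recruitment_problem(
    trial: GaitTrial,
    model: LinkedSegmentModel,
    net_torques: NetTorques,
    tau_physio: np.ndarray,
    tau_device: np.ndarray,
    grf: FootLoads,
) -> RecruitmentProblem:
    return RecruitmentProblem(trial, model, net_torques,
                              np.asarray(tau_physio, dtype=float),
                              np.asarray(tau_device, dtype=float), grf)


def solve_recruitment(problem: RecruitmentProblem) -> RecruitmentSolution:
    """Recruit muscles, reserves and strap actuators at every frame."""
    trial, model = problem.trial, problem.model
    kin = problem.net_torques.kinematics
    leg = kin.legs["right"]
    n = trial.n_frames
    muscles = model.muscles
    nm = len(muscles)
    f_max = np.array([m.f_max for m in muscles])

    hip_angle = leg.channels["hip_flexion"]
    knee_angle = leg.theta_k
    ankle_angle = leg.channels["ankle_dorsiflexion"]

    arms = np.zeros((n, 3, nm))
    for j, m in enumerate(muscles):
        arms[:, 0, j] = moment_arm(m, "hip", hip_angle)
        arms[:, 1, j] = moment_arm(m, "knee", knee_angle)
        arms[:, 2, j] = moment_arm(m, "ankle", ankle_angle)

    demands = np.stack([problem.net_torques.right.hip,
                        problem.tau_physio,
                        problem.net_torques.right.ankle], axis=-1)
    reserve_w = np.array([config.W_OTHER_RESERVE, config.W_KNEE_RESERVE,
                          config.W_OTHER_RESERVE])

    activations = np.zeros((n, nm))
    reserves = np.zeros((n, 3))
    objective = np.zeros(n)
    residual = np.zeros(n)
    x_prev = None
    for i in range(n):
        a, r, res = recruit_joint_frame(arms[i], f_max, demands[i],
                                        reserve_weights=reserve_w, x0=x_prev)
        activations[i] = a
        reserves[i] = r
        objective[i] = res.objective
        residual[i] = float(np.max(np.abs(res.eq_residual)))
        x_prev = res.x

    forces = activations * f_max[None, :]

    n_nodes = len(model.strap_nodes)
    strap_normal = np.zeros((n, n_nodes))
    strap_tang = np.zeros((n, n_nodes))
    gvec = np.array([0.0, -model.gravity])
    m_ts = model.exo.thigh_attach_mass
    m_ss = model.exo.shank_attach_mass
    for i in range(n):
        shell_states = {
            "thigh": (m_ts, gvec - leg.acc["com_thigh_shell"][i],
                      leg.points["com_thigh_shell"][i]),
            "shank": (m_ss, gvec - leg.acc["com_shank_shell"][i],
                      leg.points["com_shank_shell"][i]),
        }
        normal, tang, _ = solve_strap_frame(
            model, float(problem.tau_device[i]), leg.strap_points[i],
            leg.points["knee"][i], shell_states,
            float(leg.phi_thigh[i]), float(leg.phi_shank[i]))
        strap_normal[i] = normal
        strap_tang[i] = tang

    # objective includes the strap terms' contribution implicitly per frame;
    # report the muscle-side objective (the strap side is a load path)
    return RecruitmentSolution(
        time=trial.time,
        muscle_names=tuple(m.name for m in muscles),
        activations=activations, forces=forces, reserves=reserves,
        objective=objective, strap_normal=strap_normal,
        strap_tangential=strap_tang, grf_total=problem.grf.total_force(),
        residual=residual,
    )


def write_solution_csv(sol: RecruitmentSolution, path) -> None:
    cols = {"time_s": sol.time}
    for j, name in enumerate(sol.muscle_names):
        cols[f"act_{name}"] = sol.activations[:, j]
    cols["grf_total_N"] = np.linalg.norm(sol.grf_total, axis=-1)
    for k in range(sol.strap_normal.shape[1]):
        cols[f"strap{k}_normal_N"] = sol.strap_normal[:, k]
        cols[f"strap{k}_tangential_N"] = sol.strap_tangential[:, k]
    pd.DataFrame(cols).to_csv(path, index=False)
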