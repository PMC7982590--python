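"""Planar chain kinematics and inverse dynamics.

The body is a sagittal linked-segment chain: the hip translates at the
trial's mean speed at constant height, the HAT rides vertically above it,
and each leg hangs as thigh -> shank -> foot driven by the trial's joint
angles (the left leg runs the same channels shifted by half a cycle).
Velocities and accelerations come from periodic central differencing of the
point trajectories, so the whole pipeline is consistent with
:func:`exoassist.synthetic_gait.differentiate`.

Inverse dynamics is a distal-up Newton-Euler recursion per leg
(foot -> shank -> thigh) with the HAT closing the chain; the reported net
joint torques are the totals the muscle+device system must produce, in the
knee-extension / hip-flexion / ankle-dorsiflexion positive convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import config
from .body_model import LinkedSegmentModel
from .synthetic_gait import GaitTrial, differentiate, phase_shift

__all__ = [
    "LegKinematics",
    "BodyKinematics",
    "FootLoads",
    "LegTorques",
    "NetTorques",
    "compute_kinematics",
    "inverse_dynamics",
    "device_damping_torque",
    "write_torque_csv",
]


def _unit(phi: np.ndarray) -> np.ndarray:
    """Direction of a segment whose proximal joint is up: -y rotated CCW by phi."""
    return np.stack([np.sin(phi), -np.cos(phi)], axis=-1)


def _perp(phi: np.ndarray) -> np.ndarray:
    """Anterior perpendicular of :func:`_unit` (forward when phi = 0)."""
    return np.stack([np.cos(phi), np.sin(phi)], axis=-1)


def cross2(r: np.ndarray, f: np.ndarray) -> np.ndarray:
    """z-component of the planar cross product r x f."""
    return r[..., 0] * f[..., 1] - r[..., 1] * f[..., 0]


@dataclass
class LegKinematics:
    """Per-frame kinematics of one leg.

    ``points``/``vel``/``acc`` map point names (knee, ankle, com_thigh,
    com_shank, com_foot, com_thigh_shell, com_shank_shell) to (n, 2) world
    arrays. Segment absolute angles are CCW-positive about +z with x forward
    and y up; ``theta_a`` is the stance shank inclination from vertical
    (forward lean positive), the inverted-pendulum coordinate.
    """

    side: str
    phi_thigh: np.ndarray
    phi_shank: np.ndarray
    gamma: np.ndarray              # foot axis angle from horizontal
    omega: dict
    alpha: dict
    points: dict
    vel: dict
    acc: dict
    foot_nodes: np.ndarray         # (n, nodes, 2) world positions
    foot_nodes_vel: np.ndarray
    strap_points: np.ndarray       # (n, n_straps, 2)
    theta_k: np.ndarray            # knee flexion angle
    theta_k_d1: np.ndarray
    theta_k_d2: np.ndarray
    theta_a: np.ndarray            # shank inclination (stance pendulum angle)
    theta_a_d1: np.ndarray
    theta_a_d2: np.ndarray
    stance: np.ndarray             # boolean mask
    channels: dict


@dataclass
class BodyKinematics:
    """Kinematics of the whole model plus global quantities."""

    trial: GaitTrial
    model: LinkedSegmentModel
    legs: dict                    # side -> LegKinematics
    hat_com: np.ndarray           # (n, 2)
    com: np.ndarray               # whole-body COM (n, 2)
    com_acc: np.ndarray
    dL: np.ndarray                # rate of angular momentum about the COM (n,)

    @property
    def time(self) -> np.ndarray:
        return self.trial.time


def _point_derivatives(pos: np.ndarray, time: np.ndarray,
                       v_mean: float) -> tuple[np.ndarray, np.ndarray]:
    """Velocity/acceleration of a world trajectory whose only non-periodic
    part is the uniform forward hip advance ``v_mean * t``."""
    rel = pos.copy()
    rel[:, 0] -= v_mean * time
    vel = np.empty_like(pos)
    acc = np.empty_like(pos)
    for j in range(pos.shape[1]):
        vel[:, j], acc[:, j] = differentiate(rel[:, j], time)
    vel[:, 0] += v_mean
    return vel, acc


def _leg_kinematics(trial: GaitTrial, model: LinkedSegmentModel,
                    side: str) -> LegKinematics:
    chans = trial.channels()
    lo, hi = trial.events
    if side == "left":
        chans = {k: phase_shift(v, 0.5) for k, v in chans.items()}
        lo, hi = (lo + 0.5) % 1.0, (hi + 0.5) % 1.0
    hip_flex = chans["hip_flexion"]
    knee_flex = chans["knee_flexion"]
    ankle_dorsi = chans["ankle_dorsiflexion"]

    time = trial.time
    v = trial.speed_preset.mean_speed
    segs = model.segments
    thigh = segs["thigh"] if side == "right" else segs["thigh_free"]
    shank = segs["shank"] if side == "right" else segs["shank_free"]
    foot = segs["foot"]

    phi_th = hip_flex
    phi_sh = phi_th - knee_flex
    gamma = phi_sh + ankle_dorsi

    hip = np.stack([v * time, np.full_like(time, model.hip_height())], axis=-1)
    u_th, u_sh = _unit(phi_th), _unit(phi_sh)
    knee = hip + thigh.length * u_th
    ankle = knee + shank.length * u_sh
    cg, sg = np.cos(gamma), np.sin(gamma)

    def foot_point(local_xy):
        lx, ly = local_xy
        return ankle + np.stack([lx * cg - ly * sg, lx * sg + ly * cg], axis=-1)

    points = {
        "hip": hip,
        "knee": knee,
        "ankle": ankle,
        "com_thigh": hip + thigh.com_offset * u_th,
        "com_shank": knee + shank.com_offset * u_sh,
        "com_foot": foot_point(model.foot_com_local),
        "com_thigh_shell": hip + model.exo.thigh_attach_frac
        * segs["thigh_free"].length * u_th,
        "com_shank_shell": knee + model.exo.shank_attach_frac
        * segs["shank_free"].length * u_sh,
    }

    local_nodes = model.foot_node_local()
    foot_nodes = np.stack([foot_point(p) for p in local_nodes], axis=1)

    strap_pts = []
    for node in model.strap_nodes:
        if node.host_segment == "thigh":
            base, u, n_hat = hip, u_th, _perp(phi_th)
        else:
            base, u, n_hat = knee, u_sh, _perp(phi_sh)
        strap_pts.append(base + node.axial_position * u
                         + node.normal_sign * node.cuff_radius * n_hat)
    strap_points = np.stack(strap_pts, axis=1) if strap_pts else \
        np.zeros((time.size, 0, 2))

    vel, acc = {}, {}
    for name, pos in points.items():
        vel[name], acc[name] = _point_derivatives(pos, time, v)
    nodes_vel = np.empty_like(foot_nodes)
    for j in range(foot_nodes.shape[1]):
        nodes_vel[:, j], _ = _point_derivatives(foot_nodes[:, j], time, v)

    omega, alpha = {}, {}
    for name, phi in (("thigh", phi_th), ("shank", phi_sh), ("foot", gamma)):
        omega[name], alpha[name] = differentiate(phi, time)

    tk_d1, tk_d2 = differentiate(knee_flex, time)
    theta_a = -phi_sh
    ta_d1, ta_d2 = differentiate(theta_a, time)

    ph = np.mod(trial.phase, 1.0)
    if lo < hi:
        stance = (ph >= lo) & (ph < hi)
    else:  # wrapped interval
        stance = (ph >= lo) | (ph < hi)

    return LegKinematics(
        side=side, phi_thigh=phi_th, phi_shank=phi_sh, gamma=gamma,
        omega=omega, alpha=alpha, points=points, vel=vel, acc=acc,
        foot_nodes=foot_nodes, foot_nodes_vel=nodes_vel,
        strap_points=strap_points,
        theta_k=knee_flex, theta_k_d1=tk_d1, theta_k_d2=tk_d2,
        theta_a=theta_a, theta_a_d1=ta_d1, theta_a_d2=ta_d2,
        stance=stance, channels=chans,
    )


def _leg_mass_items(model: LinkedSegmentModel, leg: LegKinematics):
    """(mass, inertia, com point name, angular-rate segment key) per segment."""
    right = leg.side == "right"
    segs = model.segments
    thigh = segs["thigh"] if right else segs["thigh_free"]
    shank = segs["shank"] if right else segs["shank_free"]
    return [
        (thigh.mass, thigh.inertia_com, "com_thigh", "thigh"),
        (shank.mass, shank.inertia_com, "com_shank", "shank"),
        (segs["foot"].mass, segs["foot"].inertia_com, "com_foot", "foot"),
    ]


def compute_kinematics(trial: GaitTrial, model: LinkedSegmentModel) -> BodyKinematics:
    """Kinematics of both legs, the HAT, the whole-body COM and the rate of
    angular momentum about it."""
    legs = {side: _leg_kinematics(trial, model, side)
            for side in ("right", "left")}
    time = trial.time
    v = trial.speed_preset.mean_speed
    hat = model.segments["hat"]
    hip = legs["right"].points["hip"]
    hat_com = hip + np.stack(
        [np.zeros_like(time), np.full_like(time, hat.com_offset)], axis=-1)
    hat_vel, hat_acc = _point_derivatives(hat_com, time, v)

    items = [(hat.mass, hat.inertia_com, hat_com, hat_vel, hat_acc,
              np.zeros_like(time))]
    for leg in legs.values():
        for m, inertia, pname, akey in _leg_mass_items(model, leg):
            items.append((m, inertia, leg.points[pname], leg.vel[pname],
                          leg.acc[pname], leg.omega[akey]))

    M = sum(m for m, *_ in items)
    com = sum(m * p for m, _, p, *_ in items) / M
    com_vel, com_acc = _point_derivatives(com, time, v)

    L = np.zeros_like(time)
    for m, inertia, p, vel, _, om in items:
        L += inertia * om + m * cross2(p - com, vel - com_vel)
    dL, _ = differentiate(L, time)

    return BodyKinematics(trial=trial, model=model, legs=legs,
                          hat_com=hat_com, com=com, com_acc=com_acc, dL=dL)


@dataclass
class FootLoads:
    """Predicted ground reactions for both feet on the trial's time grid.

    ``node_normal``/``node_tangential`` are (n, nodes) per-node vertical and
    antero-posterior forces; ``force`` the per-foot resultant (n, 2) and
    ``moment_ankle`` the per-foot sagittal moment of the node forces about
    the ankle. ``residual`` is the whole-body force-balance residual (N).
    """

    time: np.ndarray
    node_normal: dict      # side -> (n, nodes)
    node_tangential: dict  # side -> (n, nodes)
    force: dict            # side -> (n, 2)
    moment_ankle: dict     # side -> (n,)
    residual: np.ndarray   # (n,)

    def total_force(self) -> np.ndarray:
        return self.force["right"] + self.force["left"]


@dataclass
class LegTorques:
    """Net internal joint torques of one leg (muscle + device totals) and the
    intersegmental joint forces on the distal segment, world frame."""

    hip: np.ndarray     # N*m, flexion positive
    knee: np.ndarray    # N*m, extension positive
    ankle: np.ndarray   # N*m, dorsiflexion positive
    f_hip: np.ndarray   # (n, 2) force on thigh at the hip
    f_knee: np.ndarray  # (n, 2) force on shank at the knee
    f_ankle: np.ndarray  # (n, 2) force on foot at the ankle


@dataclass
class NetTorques:
    """Inverse-dynamics output for both legs plus the whole-body residual."""

    time: np.ndarray
    right: LegTorques
    left: LegTorques
    residual: np.ndarray     # (n,) whole-body force residual magnitude, N
    kinematics: BodyKinematics

    # the instrumented (right) leg is the default surface
    @property
    def hip(self) -> np.ndarray:
        return self.right.hip

    @property
    def knee(self) -> np.ndarray:
        return self.right.knee

    @property
    def ankle(self) -> np.ndarray:
        return self.right.ankle


def _leg_inverse_dynamics(model: LinkedSegmentModel, leg: LegKinematics,
                          grf_force: np.ndarray, grf_moment: np.ndarray,
                          gvec: np.ndarray) -> LegTorques:
    segs = model.segments
    right = leg.side == "right"
    thigh = segs["thigh"] if right else segs["thigh_free"]
    shank = segs["shank"] if right else segs["shank_free"]
    foot = segs["foot"]
    p, a = leg.points, leg.acc
    al = leg.alpha

    f_ankle = foot.mass * (a["com_foot"] - gvec) - grf_force
    r_af = p["ankle"] - p["com_foot"]
    tau_ankle = (foot.inertia_com * al["foot"]
                 - grf_moment - cross2(r_af, grf_force)
                 - cross2(r_af, f_ankle))

    f_knee = shank.mass * (a["com_shank"] - gvec) + f_ankle
    tau_knee = (shank.inertia_com * al["shank"] + tau_ankle
                - cross2(p["knee"] - p["com_shank"], f_knee)
                + cross2(p["ankle"] - p["com_shank"], f_ankle))

    f_hip = thigh.mass * (a["com_thigh"] - gvec) + f_knee
    tau_hip = (thigh.inertia_com * al["thigh"] + tau_knee
               - cross2(p["hip"] - p["com_thigh"], f_hip)
               + cross2(p["knee"] - p["com_thigh"], f_knee))

    return LegTorques(hip=tau_hip, knee=tau_knee, ankle=tau_ankle,
                      f_hip=f_hip, f_knee=f_knee, f_ankle=f_ankle)


def inverse_dynamics(trial: GaitTrial, model: LinkedSegmentModel,
                     grf: FootLoads,
                     kinematics: BodyKinematics | None = None) -> NetTorques:
    """Net joint torques from kinematics and (predicted) ground reactions.

    Gravitational, inertial and reaction contributions are all included; the
    returned knee torque is the *total* internal torque, i.e. the sum of the
    user's physiological share, the device's assistive torque and the
    device's passive damping torque. Splitting that total is the
    controllers' job (:func:`exoassist.controllers.physiological_torque`).

    Raises ``ValueError`` on a time-grid mismatch between trial and loads.
    """
    if grf.time.shape != trial.time.shape or np.any(
            np.abs(grf.time - trial.time) > 1e-12):
        raise ValueError("foot loads and trial do not share the time grid")
    kin = kinematics if kinematics is not None else compute_kinematics(trial, model)
    gvec = np.array([0.0, -model.gravity])

    torques = {}
    for side, leg in kin.legs.items():
        torques[side] = _leg_inverse_dynamics(
            model, leg, grf.force[side], grf.moment_ankle[side], gvec)

    # whole-body force residual: sum of external forces minus sum m*a
    resid = grf.total_force().copy()
    hat = model.segments["hat"]
    hat_acc = np.zeros_like(kin.hat_com)
    resid += hat.mass * (gvec - hat_acc)
    for leg in kin.legs.values():
        for m, _, pname, _ in _leg_mass_items(model, leg):
            resid += m * (gvec - leg.acc[pname])
    residual = np.linalg.norm(resid, axis=-1)

    return NetTorques(time=trial.time, right=torques["right"],
                      left=torques["left"], residual=residual, kinematics=kin)


def device_damping_torque(model: LinkedSegmentModel,
                          theta_k_d1: np.ndarray) -> np.ndarray:
    """Passive hinge damping torque in the knee-extension-positive
    convention: the device resists knee angular velocity, so a flexing knee
    (theta_k_dot > 0) sees a positive (extension-direction) damping torque
    ``c * theta_k_dot`` charged to the device."""
    return model.exo.joint_damping * theta_k_d1


def write_torque_csv(net: NetTorques, path, side: str = "right") -> None:
    leg = getattr(net, side)
    pd.DataFrame({
        "time_s": net.time,
        "hip_Nm": leg.hip,
        "knee_Nm": leg.knee,
        "ankle_Nm": leg.ankle,
        "residual_N": net.residual,
    }).to_csv(path, index=False)
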