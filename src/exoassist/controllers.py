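"""Assistive-torque controllers for the knee exoskeleton.

Four modes: NA (no assistance, the device is dead weight), RA (rotational
actuator, a pseudo-stiffness pulling the knee toward full extension), SPM
(simple pendulum model) and DPM (damped pendulum model). The pendulum modes
model the shank-foot-lower-exoskeleton as a pendulum about the knee during
swing and the shank-exoskeleton as an inverted pendulum about the ankle
during stance, and supply a fraction ``a`` of the pendulum-model torque.

Sign bookkeeping: the controller equations are written in the pendulum
coordinates (knee flexion angle during swing, shank inclination during
stance), so the raw controller torque ``u`` is flexion-positive. The device
torque in the package-wide knee-extension-positive convention is ``-u``;
that single mapping is applied when forming the user's physiological share
``tau_physio = tau_net - tau_device``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import config
from .body_model import LinkedSegmentModel, pendulum_constants
from .dynamics import NetTorques, device_damping_torque
from .synthetic_gait import GaitTrial

__all__ = [
    "MODES",
    "ControllerConfig",
    "AssistiveTorqueSeries",
    "recommended_config",
    "rotational_actuator_torque",
    "pendulum_torque",
    "damped_pendulum_torque",
    "assistive_torque",
    "physiological_torque",
    "write_assist_csv",
]

MODES = ("NA", "RA", "SPM", "DPM")


@dataclass(frozen=True)
class ControllerConfig:
    """Assistance mode and its parameters.

    ``K`` is the rotational-actuator pseudo-stiffness (N*m/rad) about
    ``theta_ref`` (0 = fully extended knee); ``a_*`` are the per-phase
    assistance levels of the pendulum modes; ``b_*`` the per-phase viscous
    damping constants of the damped pendulum (N*m*s/rad).
    """

    mode: str
    K: float = 4.0
    theta_ref: float = 0.0
    a_stance: float = 0.0
    a_swing: float = 0.0
    b_stance: float = 0.0
    b_swing: float = 0.0
    blend: bool = False   # optional cosine blending at phase switches

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.K < 0:
            raise ValueError("K must be >= 0")
        for name in ("a_stance", "a_swing"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("b_stance", "b_swing"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def recommended_config(mode: str, speed: str = "normal") -> ControllerConfig:
    """Reference parameter set per mode (RA: K = 4 N*m/rad; SPM: a =
    0.23 stance / 0.78 swing; DPM: a = 0.33/0.78 with speed-specific b)."""
    mode = mode.upper()
    if mode == "NA":
        return ControllerConfig("NA")
    if mode == "RA":
        return ControllerConfig("RA", K=config.REFERENCE_CONTROLLER["RA"]["K"])
    if mode == "SPM":
        p = config.REFERENCE_CONTROLLER["SPM"]
        return ControllerConfig("SPM", a_stance=p["a_stance"],
                                a_swing=p["a_swing"])
    if mode == "DPM":
        p = config.REFERENCE_CONTROLLER["DPM"][speed]
        return ControllerConfig("DPM", a_stance=p["a_stance"],
                                a_swing=p["a_swing"],
                                b_stance=p["b_stance"], b_swing=p["b_swing"])
    raise ValueError(f"unknown mode {mode!r}")


@dataclass
class AssistiveTorqueSeries:
    """Per-frame controller output.

    ``u_exo`` is the raw controller torque in the pendulum (flexion-positive)
    coordinate; ``tau_device`` is the same torque mapped to the
    knee-extension-positive convention (``-u_exo``), which is what enters the
    torque bookkeeping and the strap transmission. ``stance`` is the phase
    label per frame.
    """

    time: np.ndarray
    mode: str
    u_exo: np.ndarray
    stance: np.ndarray           # boolean phase label
    u_unscaled: np.ndarray       # pendulum-model torque before the a-scaling

    @property
    def tau_device(self) -> np.ndarray:
        return -self.u_exo

    def phase_labels(self) -> np.ndarray:
        return np.where(self.stance, "stance", "swing")

    def stance_swing_discontinuity(self) -> float:
        """|u_exo| jump at the stance->swing switch (no smoothing applied)."""
        edges = np.nonzero(np.diff(self.stance.astype(int)))[0]
        if edges.size == 0:
            return 0.0
        return float(max(abs(self.u_exo[e + 1] - self.u_exo[e]) for e in edges))


def _stance_mask(trial: GaitTrial) -> np.ndarray:
    return trial.in_stance()


def rotational_actuator_torque(config_: ControllerConfig,
                               trial: GaitTrial) -> AssistiveTorqueSeries:
    """u_r = -K (theta - theta_ref), theta the knee flexion angle.

    Applied during both phases (no phase gating): the actuator always pulls
    the knee toward the reference extension angle.
    """
    if config_.mode != "RA":
        raise ValueError("rotational_actuator_torque requires mode RA")
    u = -config_.K * (trial.knee_flexion - config_.theta_ref)
    return AssistiveTorqueSeries(time=trial.time, mode="RA", u_exo=u,
                                 stance=_stance_mask(trial), u_unscaled=u)


def swing_pendulum_torque(I_c1, theta_k_dd, m_c1, g, l_c1, theta_k,
                          b=0.0, theta_k_d=0.0):
    """Torque driving the shank-foot-device pendulum about the knee:
    u = I_c1 th'' + m_c1 g l_c1 sin(th) (+ b th' for the damped variant)."""
    return I_c1 * theta_k_dd + m_c1 * g * l_c1 * np.sin(theta_k) + b * theta_k_d


def stance_pendulum_torque(I_s, theta_a_dd, T_a, m_c2, g, l_s, theta_a,
                           b=0.0, theta_a_d=0.0):
    """Torque driving the stance inverted pendulum about the ankle:
    u = I_s th_a'' - T_a + m_c2 g l_s sin(th_a) (+ b th_a' when damped)."""
    return (I_s * theta_a_dd - T_a + m_c2 * g * l_s * np.sin(theta_a)
            + b * theta_a_d)


def _pendulum_u(trial: GaitTrial, model: LinkedSegmentModel,
                net: NetTorques, b_stance: float, b_swing: float):
    """Raw pendulum-model torque u(t) per frame (before the a-scaling).

    Swing (pendulum about the knee):   u = I_c1 th_k'' + m_c1 g l_c1 sin th_k
    Stance (inverted pendulum about the ankle):
                                       u = I_s th_a'' - T_a + m_c2 g l_s sin th_a
    with the damping term +b * th' of the damped variant added per phase.
    ``T_a`` is the same-leg ankle torque from inverse dynamics at the
    current frame.
    """
    pc = pendulum_constants(model)
    leg = net.kinematics.legs["right"]
    g = model.gravity
    stance = _stance_mask(trial)

    u_swing = swing_pendulum_torque(pc.I_c1, leg.theta_k_d2, pc.m_c1, g,
                                    pc.l_c1, leg.theta_k,
                                    b_swing, leg.theta_k_d1)
    T_a = net.right.ankle
    if T_a is None:
        raise ValueError("stance pendulum torque requires ankle torques")
    u_stance = stance_pendulum_torque(pc.I_s, leg.theta_a_d2, T_a, pc.m_c2,
                                      g, pc.l_s, leg.theta_a,
                                      b_stance, leg.theta_a_d1)
    u = np.where(stance, u_stance, u_swing)
    return u, stance


def pendulum_torque(config_: ControllerConfig, trial: GaitTrial,
                    model: LinkedSegmentModel,
                    net_torques: NetTorques) -> AssistiveTorqueSeries:
    """Simple-pendulum assistance: u_es = a_phase * u_s."""
    if config_.mode != "SPM":
        raise ValueError("pendulum_torque requires mode SPM")
    u_s, stance = _pendulum_u(trial, model, net_torques, 0.0, 0.0)
    a = np.where(stance, config_.a_stance, config_.a_swing)
    return AssistiveTorqueSeries(time=trial.time, mode="SPM", u_exo=a * u_s,
                                 stance=stance, u_unscaled=u_s)


def damped_pendulum_torque(config_: ControllerConfig, trial: GaitTrial,
                           model: LinkedSegmentModel,
                           net_torques: NetTorques) -> AssistiveTorqueSeries:
    """Damped-pendulum assistance: u_ed = a_phase * u_d, where u_d adds the
    +b*theta_dot damping term to the simple-pendulum torque (swing uses the
    knee angular velocity, stance the shank-inclination rate)."""
    if config_.mode != "DPM":
        raise ValueError("damped_pendulum_torque requires mode DPM")
    u_d, stance = _pendulum_u(trial, model, net_torques,
                              config_.b_stance, config_.b_swing)
    a = np.where(stance, config_.a_stance, config_.a_swing)
    return AssistiveTorqueSeries(time=trial.time, mode="DPM", u_exo=a * u_d,
                                 stance=stance, u_unscaled=u_d)


def assistive_torque(config_: ControllerConfig, trial: GaitTrial,
                     model: LinkedSegmentModel,
                     net_torques: NetTorques | None = None) -> AssistiveTorqueSeries:
    """Dispatch on the assistance mode (NA yields identically zero torque)."""
    if config_.mode == "NA":
        zero = np.zeros_like(trial.time)
        return AssistiveTorqueSeries(time=trial.time, mode="NA", u_exo=zero,
                                     stance=_stance_mask(trial),
                                     u_unscaled=zero.copy())
    if config_.mode == "RA":
        return rotational_actuator_torque(config_, trial)
    if net_torques is None:
        raise ValueError(f"{config_.mode} requires net torques (stance T_a)")
    if config_.mode == "SPM":
        return pendulum_torque(config_, trial, model, net_torques)
    return damped_pendulum_torque(config_, trial, model, net_torques)


def physiological_torque(net_torques: NetTorques,
                         assist: AssistiveTorqueSeries,
                         model: LinkedSegmentModel | None = None,
                         charge_damping_to_device: bool = True) -> np.ndarray:
    """The user's required knee torque: tau_physio = tau_net - tau_device.

    ``tau_device`` is the controller torque mapped to knee-extension-positive
    plus, when ``charge_damping_to_device`` (the default), the passive hinge
    damping torque; in NA mode only the damping remains. This is the knee
    demand handed to muscle recruitment.
    """
    tau_device = assist.tau_device.copy()
    if charge_damping_to_device and model is not None:
        leg = net_torques.kinematics.legs["right"]
        tau_device = tau_device + device_damping_torque(model, leg.theta_k_d1)
    return net_torques.knee - tau_device


def total_device_torque(assist: AssistiveTorqueSeries,
                        net_torques: NetTorques,
                        model: LinkedSegmentModel,
                        charge_damping_to_device: bool = True) -> np.ndarray:
    """Device knee torque transmitted through the straps (extension-positive):
    controller torque plus passive hinge damping."""
    leg = net_torques.kinematics.legs["right"]
    tau = assist.tau_device.copy()
    if charge_damping_to_device:
        tau = tau + device_damping_torque(model, leg.theta_k_d1)
    return tau


def write_assist_csv(assist: AssistiveTorqueSeries, net_torques: NetTorques,
                     tau_physio: np.ndarray, path) -> None:
    pd.DataFrame({
        "time_s": assist.time,
        "phase": assist.phase_labels(),
        "u_exo_Nm": assist.u_exo,
        "tau_net_Nm": net_torques.knee,
        "tau_physio_Nm": tau_physio,
    }).to_csv(path, index=False)
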