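"""Outcome metrics, controller sensitivity search, and the end-to-end
pipeline.

The pipeline runs: synthetic gait -> model build -> ground-reaction
prediction -> inverse dynamics -> assistive controller -> muscle/strap
recruitment -> knee contact loads -> outcome report. Everything is
deterministic for a fixed trial, model and controller; the sensitivity
search reuses the controller-independent stages (kinematics, ground
reactions, net torques) across grid points.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import config
from .body_model import LinkedSegmentModel, default_model
from .controllers import (AssistiveTorqueSeries, ControllerConfig,
                          assistive_torque, physiological_torque,
                          recommended_config, total_device_torque,
                          write_assist_csv)
from .dynamics import (FootLoads, NetTorques, compute_kinematics,
                       inverse_dynamics, write_torque_csv)
from .knee_loads import KneeLoadSeries, compute_knee_loads, write_contact_csv
from .recruitment import (RecruitmentSolution, build_recruitment_problem,
                          solve_recruitment, write_solution_csv)
from .synthetic_gait import GaitTrial, SpeedPreset, generate_gait

__all__ = [
    "OutcomeReport",
    "SensitivityResult",
    "PipelineError",
    "PipelineContext",
    "prepare_context",
    "muscle_impulse",
    "interaction_maxima",
    "sensitivity_search",
    "run_pipeline",
]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {original}")
        self.stage = stage
        self.original = original


def _stage(name: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except Exception as exc:  # propagate with the stage name
        raise PipelineError(name, exc) from exc


@dataclass
class PipelineContext:
    """Controller-independent artifacts of a trial, reusable across modes."""

    trial: GaitTrial
    model: LinkedSegmentModel
    grf: FootLoads
    net_torques: NetTorques


def prepare_context(trial: GaitTrial,
                    model: LinkedSegmentModel | None = None) -> PipelineContext:
    from .recruitment import predict_grf  # local to avoid cycle at import time
    if model is None:
        model = _stage("build_model", default_model)
    kin = _stage("kinematics", compute_kinematics, trial, model)
    grf = _stage("predict_grf", predict_grf, trial, model, kin)
    net = _stage("inverse_dynamics", inverse_dynamics, trial, model, grf, kin)
    return PipelineContext(trial=trial, model=model, grf=grf, net_torques=net)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def muscle_impulse(force: np.ndarray, time: np.ndarray) -> float:
    """Time integral of a (tensile-only) muscle force over one cycle, N*s.

    Trapezoidal rule on the trial's time grid; negative forces are rejected
    because muscle forces are tensile-only.
    """
    force = np.asarray(force, dtype=float)
    if np.any(force < 0):
        raise ValueError("muscle forces must be >= 0 (tensile-only)")
    return float(np.trapezoid(force, np.asarray(time, dtype=float)))


def interaction_maxima(solution: RecruitmentSolution,
                       body_weight: float) -> tuple[np.ndarray, np.ndarray]:
    """Frame-wise maxima over the strap nodes of the normal and of the
    |tangential| interaction force, as % body weight."""
    max_n = solution.strap_normal.max(axis=1)
    max_t = np.abs(solution.strap_tangential).max(axis=1)
    return 100.0 * max_n / body_weight, 100.0 * max_t / body_weight


def _phase_mask(trial: GaitTrial, scope: str) -> np.ndarray:
    ph = np.mod(trial.phase, 1.0)
    stance = trial.in_stance()
    if scope == "cycle":
        return np.ones_like(ph, dtype=bool)
    if scope == "stance":
        return stance
    if scope == "swing":
        return ~stance
    raise ValueError("scope must be one of {'stance', 'swing', 'cycle'}")


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

@dataclass
class OutcomeReport:
    """All outcome surfaces of one run.

    Impulses are per-muscle over one cycle (N*s), grouped into knee flexors
    (SAR, BFL, ST, SM, GRA, GAS) and extensors (VL, VM, VI, RF); torque
    series are knee-extension-positive; strap maxima are frame-wise maxima
    over the sixteen nodes.
    """

    mode: str
    speed: str
    controller: ControllerConfig
    trial: GaitTrial
    model: LinkedSegmentModel
    impulses: dict                     # muscle -> N*s
    tau_net: np.ndarray
    tau_physio: np.ndarray
    u_exo: np.ndarray
    assist: AssistiveTorqueSeries
    knee_loads: KneeLoadSeries
    solution: RecruitmentSolution
    max_strap_normal_pct_bw: np.ndarray
    max_strap_tangential_pct_bw: np.ndarray
    manifest: dict

    @property
    def flexor_impulse(self) -> float:
        return sum(self.impulses[m] for m in config.KNEE_FLEXORS)

    @property
    def extensor_impulse(self) -> float:
        return sum(self.impulses[m] for m in config.KNEE_EXTENSORS)

    @property
    def total_impulse(self) -> float:
        return self.flexor_impulse + self.extensor_impulse


def _manifest(trial, model, controller, seed) -> dict:
    import scipy

    from . import __version__
    cfg = {
        "mode": controller.mode,
        "controller": {k: getattr(controller, k)
                       for k in ("K", "theta_ref", "a_stance", "a_swing",
                                 "b_stance", "b_swing")},
        "speed": trial.speed_preset.name,
        "mean_speed": trial.speed_preset.mean_speed,
        "cycle_duration": trial.speed_preset.cycle_duration,
        "stance_fraction": trial.speed_preset.stance_fraction,
        "n_frames": trial.n_frames,
        "body_mass": model.anthro.body_mass,
        "height": model.anthro.height,
        "exo": {
            "thigh_attach_mass": model.exo.thigh_attach_mass,
            "shank_attach_mass": model.exo.shank_attach_mass,
            "rotor_inertia_at_knee": model.exo.rotor_inertia_at_knee,
            "joint_damping": model.exo.joint_damping,
        },
        "seed": seed,
    }
    digest = hashlib.sha256(
        json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]
    return {**cfg, "config_hash": digest,
            "versions": {"exoassist": __version__,
                         "numpy": np.__version__, "scipy": scipy.__version__}}


def run_pipeline(
    trial: GaitTrial | SpeedPreset | str,
    model: LinkedSegmentModel | None = None,
    controller: ControllerConfig | None = None,
    n_frames: int = 101,
    seed: int = 0,
    out_dir=None,
    charge_damping_to_device: bool = True,
    context: PipelineContext | None = None,
) -> OutcomeReport:
    """Execute the full pipeline for one trial and one assistance mode.

    ``trial`` may be a ready GaitTrial, a SpeedPreset, or a preset name
    ("normal"/"fast"). In NA mode the device stays on the leg as dead
    weight; its passive damping is charged to the device by default.
    Writes the CSV contract (impulses, assist, contact, interaction,
    torques, solution) plus a run manifest when ``out_dir`` is given.
    """
    if controller is None:
        controller = ControllerConfig("NA")
    if isinstance(trial, str):
        trial = SpeedPreset.from_name(trial)
    if isinstance(trial, SpeedPreset):
        trial = _stage("generate_gait", generate_gait, trial, n_frames, seed)
    if model is None:
        model = _stage("build_model", default_model)

    if context is None:
        context = prepare_context(trial, model)
    grf, net = context.grf, context.net_torques

    assist = _stage("controller", assistive_torque, controller, trial, model, net)
    tau_physio = _stage("physiological_torque", physiological_torque,
                        net, assist, model, charge_damping_to_device)
    tau_device = total_device_torque(assist, net, model,
                                     charge_damping_to_device)

    problem = build_recruitment_problem(trial, model, net, tau_physio,
                                        tau_device, grf)
    solution = _stage("recruitment", solve_recruitment, problem)
    loads = _stage("knee_loads", compute_knee_loads, trial, solution, net, model)

    impulses = {name: muscle_impulse(solution.forces[:, j], trial.time)
                for j, name in enumerate(solution.muscle_names)}
    max_n, max_t = interaction_maxima(solution, model.body_weight)

    report = OutcomeReport(
        mode=controller.mode, speed=trial.speed_preset.name,
        controller=controller, trial=trial, model=model, impulses=impulses,
        tau_net=net.knee, tau_physio=tau_physio, u_exo=assist.u_exo,
        assist=assist, knee_loads=loads, solution=solution,
        max_strap_normal_pct_bw=max_n, max_strap_tangential_pct_bw=max_t,
        manifest=_manifest(trial, model, controller, seed),
    )
    if out_dir is not None:
        _write_outputs(report, net, Path(out_dir))
    return report


def _write_outputs(report: OutcomeReport, net: NetTorques, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    groups = {m: "flexor" for m in config.KNEE_FLEXORS}
    groups.update({m: "extensor" for m in config.KNEE_EXTENSORS})
    pd.DataFrame({
        "muscle": list(report.impulses),
        "group": [groups.get(m, "other") for m in report.impulses],
        "impulse_Ns": list(report.impulses.values()),
    }).to_csv(out / "impulses.csv", index=False)
    write_assist_csv(report.assist, net, report.tau_physio, out / "assist.csv")
    write_contact_csv(report.knee_loads, out / "contact.csv")
    bw = report.model.body_weight
    pd.DataFrame({
        "time_s": report.trial.time,
        "max_normal_N": report.max_strap_normal_pct_bw * bw / 100.0,
        "max_tangential_N": report.max_strap_tangential_pct_bw * bw / 100.0,
        "max_normal_pctBW": report.max_strap_normal_pct_bw,
        "max_tangential_pctBW": report.max_strap_tangential_pct_bw,
    }).to_csv(out / "interaction.csv", index=False)
    write_torque_csv(net, out / "torques.csv")
    write_solution_csv(report.solution, out / "solution.csv")
    with open(out / "manifest.json", "w") as fh:
        json.dump(report.manifest, fh, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# Sensitivity search
# ---------------------------------------------------------------------------

@dataclass
class SensitivityResult:
    """Exhaustive grid search over controller parameters.

    ``objective`` is the summed flexor+extensor muscle impulse (N*s),
    restricted to the requested phase scope; ties break toward the smaller
    parameter values (grid order).
    """

    mode: str
    scope: str
    grid: list                  # list of parameter dicts
    objective: np.ndarray       # (n_points,)
    argmin: dict

    @property
    def optimum_value(self) -> float:
        return float(self.objective.min())

    def is_interior(self, param: str, values) -> bool:
        """True if the optimum of ``param`` is strictly inside its grid."""
        values = sorted(set(values))
        return self.argmin[param] not in (values[0], values[-1])


def _grid_points(grid_spec: dict) -> list[dict]:
    keys = list(grid_spec)
    pts: list[dict] = [{}]
    for key in keys:
        vals = list(grid_spec[key])
        if not vals:
            raise ValueError(f"empty grid for parameter {key!r}")
        pts = [dict(p, **{key: v}) for p in pts for v in vals]
    if not pts or not keys:
        raise ValueError("grid specification must name at least one parameter")
    return pts


def _windowed_impulse(forces: np.ndarray, trial: GaitTrial,
                      mask: np.ndarray) -> float:
    time = trial.time
    total = 0.0
    for j in range(forces.shape[1]):
        total += float(np.trapezoid(forces[:, j] * mask, time))
    return total


def sensitivity_search(
    mode: str,
    trial: GaitTrial,
    model: LinkedSegmentModel | None = None,
    grid_spec: dict | None = None,
    scope: str = "cycle",
    base_config: ControllerConfig | None = None,
    objective_fn=None,
    context: PipelineContext | None = None,
) -> SensitivityResult:
    """Exhaustive search for controller parameters minimizing muscle impulse.

    ``grid_spec`` maps ControllerConfig field names (``K``, ``a_stance``,
    ``a_swing``, ``b_stance``, ``b_swing``) to candidate values; the search
    covers the cartesian product. ``objective_fn(point) -> float``, when
    given, replaces the pipeline evaluation (used to validate the search
    itself). The controller-independent stages are computed once and shared.
    """
    mode = mode.upper()
    if grid_spec is None:
        grid_spec = {"K": config.K_GRID} if mode == "RA" else \
            {"a_stance": config.A_GRID} if mode == "SPM" else \
            {"a_stance": config.A_GRID, "b_stance": config.B_GRID}
    points = _grid_points(grid_spec)
    if base_config is None:
        base_config = recommended_config(mode, trial.speed_preset.name
                                         if trial.speed_preset.name in
                                         config.SPEED_PRESETS else "normal")

    if objective_fn is None:
        if model is None:
            model = default_model()
        if context is None:
            context = prepare_context(trial, model)
        mask = _phase_mask(trial, scope)

        def objective_fn(point):
            cfg = replace(base_config, **point)
            forces = _muscle_forces_only(context, cfg)
            return _windowed_impulse(forces, trial, mask)

    values = np.array([objective_fn(p) for p in points])
    best = int(np.argmin(values))  # argmin takes the first (smallest) tie
    return SensitivityResult(mode=mode, scope=scope, grid=points,
                             objective=values, argmin=points[best])


def _muscle_forces_only(context: PipelineContext,
                        controller: ControllerConfig) -> np.ndarray:
    """Muscle force series for one controller, skipping the strap stage
    (the sweep objective only needs impulses)."""
    from .body_model import moment_arm
    trial, model, net = context.trial, context.model, context.net_torques
    assist = assistive_torque(controller, trial, model, net)
    tau_physio = physiological_torque(net, assist, model)

    from .recruitment import recruit_joint_frame
    leg = net.kinematics.legs["right"]
    muscles = model.muscles
    f_max = np.array([m.f_max for m in muscles])
    n = trial.n_frames
    nm = len(muscles)
    arms = np.zeros((n, 3, nm))
    for j, m in enumerate(muscles):
        arms[:, 0, j] = moment_arm(m, "hip", leg.channels["hip_flexion"])
        arms[:, 1, j] = moment_arm(m, "knee", leg.theta_k)
        arms[:, 2, j] = moment_arm(m, "ankle", leg.channels["ankle_dorsiflexion"])
    demands = np.stack([net.right.hip, tau_physio, net.right.ankle], axis=-1)
    reserve_w = np.array([config.W_OTHER_RESERVE, config.W_KNEE_RESERVE,
                          config.W_OTHER_RESERVE])
    forces = np.zeros((n, nm))
    x_prev = None
    for i in range(n):
        a, _, res = recruit_joint_frame(arms[i], f_max, demands[i],
                                        reserve_weights=reserve_w, x0=x_prev)
        forces[i] = a * f_max
        x_prev = res.x
    return forces
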