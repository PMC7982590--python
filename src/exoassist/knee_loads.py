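"""Tibiofemoral compartment contact forces.

The total knee compression is the axial (along-shank) intersegmental
reaction at the knee plus the axial components of all knee-crossing muscle
forces. The total is decomposed into medial and lateral compartment loads
by a frontal-plane moment balance about the joint centre driven by the
exogenous knee abduction moment ``M_kad``:

    M_kad + F_kcl * r_l - F_kcm * r_m = 0,      F_kcl + F_kcm = F_kc

with ``r_l``/``r_m`` the lateral/medial condyle moment arms. A compartment
whose unclamped solution would be tensile is clamped to zero (lift-off) and
the whole load assigned to the other, preserving the force balance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import config
from .body_model import LinkedSegmentModel
from .dynamics import NetTorques
from .recruitment import RecruitmentSolution
from .synthetic_gait import GaitTrial

__all__ = [
    "KneeLoadSeries",
    "condyle_moment_arms",
    "split_compartments",
    "total_knee_compression",
    "compute_knee_loads",
    "write_contact_csv",
]


@dataclass
class KneeLoadSeries:
    """Per-frame total, medial and lateral tibiofemoral compression."""

    time: np.ndarray
    F_kc: np.ndarray          # N, total compression
    F_kcm: np.ndarray         # N, medial compartment
    F_kcl: np.ndarray         # N, lateral compartment
    M_kad: np.ndarray         # N*m, abduction moment passthrough
    r_m: float                # m
    r_l: float                # m
    liftoff: np.ndarray       # bool, unclamped solution was tensile
    tension_flag: np.ndarray  # bool, intersegmental axial reaction was tensile
    body_weight: float        # N

    @property
    def F_kc_pct_bw(self) -> np.ndarray:
        return 100.0 * self.F_kc / self.body_weight


def condyle_moment_arms(knee_width: float, ratio_l: float,
                        ratio_m: float) -> tuple[float, float]:
    """Condyle moment arms from the knee width and reported condylar-width
    ratios: r = ratio * knee_width."""
    if not knee_width > 0:
        raise ValueError("knee_width must be > 0")
    for name, r in (("ratio_l", ratio_l), ("ratio_m", ratio_m)):
        if not 0.0 < r < 0.5:
            raise ValueError(f"{name} must be in (0, 0.5)")
    return ratio_l * knee_width, ratio_m * knee_width


def split_compartments(F_kc, M_kad, r_l: float, r_m: float):
    """Solve the 2x2 frontal-plane system for (F_kcl, F_kcm).

    Vectorized over frames. Lift-off: a negative compartment is clamped to 0
    and the total assigned to the other; the returned boolean array flags
    those frames. The compartment sum always equals ``F_kc``.
    """
    if r_l + r_m <= 0:
        raise ValueError("r_l + r_m must be > 0")
    F_kc = np.asarray(F_kc, dtype=float)
    M_kad = np.asarray(M_kad, dtype=float)
    # moment balance: M_kad + F_kcl r_l - F_kcm r_m = 0; force: sum = F_kc
    F_kcm = (M_kad + F_kc * r_l) / (r_l + r_m)
    F_kcl = F_kc - F_kcm
    liftoff = (F_kcm < 0) | (F_kcl < 0)
    # clamp the tensile compartment to zero, hand the full load to the other
    F_kcm = np.where(F_kcm < 0, 0.0, F_kcm)
    F_kcm = np.where(F_kcl < 0, F_kc, F_kcm)
    F_kcl = F_kc - F_kcm
    return F_kcl, F_kcm, liftoff


def total_knee_compression(solution: RecruitmentSolution,
                           net_torques: NetTorques,
                           model: LinkedSegmentModel):
    """Per-frame total knee compression of the instrumented leg.

    ``|axial intersegmental reaction| + sum_i force_i * axial_fraction_i``
    over the knee-crossing muscles; a tensile intersegmental reaction is
    clamped to zero and flagged.
    """
    leg = net_torques.kinematics.legs["right"]
    axial_unit = (leg.points["ankle"] - leg.points["knee"])
    axial_unit = axial_unit / np.linalg.norm(axial_unit, axis=-1, keepdims=True)
    # force on the shank from the thigh, projected on the distal shank axis:
    # positive = the femur pushes the tibia along the shank (compression)
    axial = np.einsum("ij,ij->i", net_torques.right.f_knee, axial_unit)
    tension = axial < 0
    axial = np.clip(axial, 0.0, None)

    muscle_axial = np.zeros_like(axial)
    for j, m in enumerate(model.muscles):
        if m.crosses("knee"):
            muscle_axial += solution.forces[:, j] * m.axial_fraction
    return axial + muscle_axial, tension


def compute_knee_loads(trial: GaitTrial, solution: RecruitmentSolution,
                       net_torques: NetTorques,
                       model: LinkedSegmentModel) -> KneeLoadSeries:
    """Total compression and its medial/lateral split for a solved trial."""
    F_kc, tension = total_knee_compression(solution, net_torques, model)
    r_l, r_m = condyle_moment_arms(model.knee_width,
                                   model.condyle_ratio_lateral,
                                   model.condyle_ratio_medial)
    F_kcl, F_kcm, liftoff = split_compartments(
        F_kc, trial.knee_abduction_moment, r_l, r_m)
    return KneeLoadSeries(
        time=trial.time, F_kc=F_kc, F_kcm=F_kcm, F_kcl=F_kcl,
        M_kad=trial.knee_abduction_moment, r_m=r_m, r_l=r_l,
        liftoff=liftoff, tension_flag=tension,
        body_weight=model.body_weight,
    )


def write_contact_csv(loads: KneeLoadSeries, path) -> None:
    pd.DataFrame({
        "time_s": loads.time,
        "Fkc_N": loads.F_kc,
        "Fkc_pctBW": loads.F_kc_pct_bw,
        "Fkcm_N": loads.F_kcm,
        "Fkcl_N": loads.F_kcl,
        "liftoff_flag": loads.liftoff.astype(int),
    }).to_csv(path, index=False)
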