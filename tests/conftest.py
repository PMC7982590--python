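"""Shared fixtures: trials, models and pre-solved pipeline contexts.

The expensive controller-independent stages (ground-reaction prediction,
inverse dynamics) are session-scoped so every test reuses them.
"""

from __future__ import annotations

import numpy as np
import pytest

import exoassist as xa
from exoassist import dynamics as dy
from exoassist.body_model import (Anthropometry, ExoskeletonSpec,
                                  LinkedSegmentModel, Segment)
from exoassist.synthetic_gait import GaitTrial, SpeedPreset


@pytest.fixture(scope="session")
def model():
    return xa.default_model()


@pytest.fixture(scope="session")
def trial_normal():
    return xa.generate_gait(SpeedPreset.from_name("normal"), 101, 0)


@pytest.fixture(scope="session")
def trial_fast():
    return xa.generate_gait(SpeedPreset.from_name("fast"), 101, 0)


@pytest.fixture(scope="session")
def ctx_normal(trial_normal, model):
    return xa.prepare_context(trial_normal, model)


@pytest.fixture(scope="session")
def ctx_fast(trial_fast, model):
    return xa.prepare_context(trial_fast, model)


@pytest.fixture(scope="session")
def reports(trial_normal, trial_fast, model, ctx_normal, ctx_fast):
    """OutcomeReport per (mode, speed) with the reference controller
    parameters."""
    out = {}
    for speed, trial, ctx in (("normal", trial_normal, ctx_normal),
                              ("fast", trial_fast, ctx_fast)):
        for mode in ("NA", "RA", "SPM", "DPM"):
            cfg = xa.recommended_config(mode, speed)
            out[(mode, speed)] = xa.run_pipeline(
                trial, model=model, controller=cfg, context=ctx)
    return out


# ---------------------------------------------------------------------------
# Constructors for degenerate scenarios
# ---------------------------------------------------------------------------

def make_standing_trial(n=21, knee_angle=0.0, stance_fraction=0.99,
                        cycle=1.0):
    """Quasi-static double-support posture: constant angles, negligible
    forward speed, both legs inside their stance windows at every frame."""
    preset = SpeedPreset("standing", 1e-9, cycle, stance_fraction)
    time = np.linspace(0.0, cycle, n)
    const = np.full(n, knee_angle)
    zeros = np.zeros(n)
    return GaitTrial(time=time, hip_flexion=zeros, knee_flexion=const,
                     ankle_dorsiflexion=zeros, knee_abduction_moment=zeros,
                     events=(0.0, stance_fraction), speed_preset=preset)


def make_swing_pendulum_trial(theta_k, n=101, cycle=1.0):
    """A trial whose right leg swings as a knee pendulum: thigh vertical and
    fixed, ankle neutral, knee flexion following ``theta_k`` (callable of
    phase or array). The stance window is collapsed to the first frame."""
    phase = np.linspace(0.0, 1.0, n)
    theta = theta_k(phase) if callable(theta_k) else np.asarray(theta_k)
    zeros = np.zeros(n)
    preset = SpeedPreset("pendulum", 1e-9, cycle, 1e-6)
    return GaitTrial(time=phase * cycle, hip_flexion=zeros,
                     knee_flexion=theta, ankle_dorsiflexion=zeros,
                     knee_abduction_moment=zeros, events=(0.0, 1e-6),
                     speed_preset=preset)


def make_axial_foot_model(exo=None):
    """Default model with the foot COM moved onto the shank axis, so the
    shank-foot composite COM lies along the knee-pendulum coordinate and the
    knee-pendulum equation is exact."""
    base = xa.build_model(Anthropometry(66.0, 1.75),
                          exo if exo is not None else ExoskeletonSpec())
    return LinkedSegmentModel(**{**base.__dict__, "foot_com_local": (0.0, -0.02)})


def make_chain_model(m_thigh, l_thigh, c_thigh, I_thigh,
                     m_shank, l_shank, c_shank, I_shank,
                     m_foot=0.0, foot_com=(0.0, 0.0)):
    """A bare planar chain with explicit segment parameters (toy chains for
    dynamics oracles). The HAT is massless; no exoskeleton."""
    segs = {
        "hat": Segment("hat", 0.0, 0.5, 0.25, 0.0),
        "thigh": Segment("thigh", m_thigh, l_thigh, c_thigh, I_thigh),
        "shank": Segment("shank", m_shank, l_shank, c_shank, I_shank),
        "foot": Segment("foot", m_foot, 0.2, 0.1, 0.0),
        "thigh_free": Segment("thigh", m_thigh, l_thigh, c_thigh, I_thigh),
        "shank_free": Segment("shank", m_shank, l_shank, c_shank, I_shank),
    }
    return LinkedSegmentModel(
        anthro=Anthropometry(66.0, 1.75), exo=ExoskeletonSpec.zero(),
        segments=segs, muscles=(), strap_nodes=(),
        ankle_height=0.0, heel_frac=0.25, foot_com_local=foot_com,
    )


def zero_grf(trial, model):
    n = trial.n_frames
    z = {s: np.zeros((n, model.n_foot_nodes)) for s in ("right", "left")}
    return dy.FootLoads(
        time=trial.time, node_normal=z,
        node_tangential={k: v.copy() for k, v in z.items()},
        force={s: np.zeros((n, 2)) for s in ("right", "left")},
        moment_ankle={s: np.zeros(n) for s in ("right", "left")},
        residual=np.zeros(n),
    )
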