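"""Package-wide constants and documented default parameter tables.

Everything here is configuration: anthropometric scaling fractions, the
truncated-Fourier joint-angle templates of the synthetic gait generator,
default muscle properties, exoskeleton hardware defaults, and the weights
of the static-optimization objective. All values can be overridden through
the model/controller configuration objects; the defaults are chosen to be
physiologically plausible for a 66 kg / 1.75 m adult.
"""

from __future__ import annotations

GRAVITY = 9.81  # m/s^2

# ---------------------------------------------------------------------------
# Anthropometric segment scaling (cadaver-based fraction tables).
# mass fractions of body mass; lengths as fraction of stature; COM measured
# from the proximal joint as a fraction of segment length; radius of gyration
# about the segment COM as a fraction of segment length.
# The HAT segment lumps head, arms and trunk and closes the chain at the hip.
# ---------------------------------------------------------------------------
SEGMENT_TABLE = {
    # segment: (mass_frac, length_frac, com_frac, rog_frac)
    "hat":   (0.678, 0.470, 0.450, 0.450),
    "thigh": (0.100, 0.245, 0.433, 0.323),
    "shank": (0.0465, 0.246, 0.433, 0.302),
    "foot":  (0.0145, 0.152, 0.500, 0.475),
}
ANKLE_HEIGHT_FRAC = 0.039   # height of ankle joint above the sole, frac of stature
FOOT_HEEL_FRAC = 0.25       # fraction of foot length behind the ankle

# ---------------------------------------------------------------------------
# Synthetic gait: truncated Fourier templates per joint, radians.
# theta(phi) = a0 + sum_k ak[k-1] cos(2 pi k phi) + bk[k-1] sin(2 pi k phi),
# phi = fraction of the gait cycle, 0 = initial contact of the right foot.
# Coefficients were fit once to a periodic spline through normative sagittal
# gait way-points (knee flexion ~60 deg peak near 70% cycle, hip flexion
# +30/-10 deg, ankle dorsiflexion +10/-20 deg) and are frozen here.
# ---------------------------------------------------------------------------
FOURIER_TEMPLATES = {
    "hip_flexion": {
        "a0": 0.228931,
        "ak": [0.351524, -0.059499, 0.000851, 0.004385, -0.003417, 0.000954],
        "bk": [-0.117912, -0.039349, 0.016773, -0.004768, 0.000113, 0.001006],
    },
    "knee_flexion": {
        "a0": 0.382726,
        "ak": [-0.010289, -0.219969, 0.015067, -0.017097, -0.004990, -0.004660],
        "bk": [-0.355757, 0.157815, 0.089055, -0.004728, -0.004993, 0.000542],
    },
    "ankle_dorsiflexion": {
        "a0": -0.014813,
        "ak": [-0.005312, 0.060832, -0.063328, 0.022840, -0.002288, 0.000926],
        "bk": [0.074642, -0.178459, -0.006076, 0.016473, -0.011729, 0.004971],
    },
}

# Speed presets: (mean speed m/s, cycle duration s, stance fraction,
# amplitude scale applied to the deviation of each template from its mean).
SPEED_PRESETS = {
    "normal": (1.22, 1.10, 0.60, 1.00),
    "fast":   (1.49, 1.00, 0.60, 1.10),
}

# Frontal-plane knee abduction moment template (exogenous): a smooth,
# positive (adduction-loading) double hump spanning stance, zero in swing.
MKAD_PEAK_NM = 20.0   # peak magnitude, N*m
MKAD_DIP = 0.7        # mid-stance dip shaping constant (see synthetic_gait)

# ---------------------------------------------------------------------------
# Default muscle table: the ten knee-crossing muscles.
# Moment arms are low-order polynomials in the joint angle (ascending
# coefficients, metres); knee extension / hip flexion / ankle dorsiflexion
# positive, so extensor arms are positive and flexor arms negative.
# axial_fraction is the fraction of muscle force compressing the knee along
# the shank axis.
# ---------------------------------------------------------------------------
MUSCLE_TABLE = {
    # name: (F_max N, knee arm poly, hip arm poly, ankle arm poly, axial frac)
    "SAR": (200.0,  [-0.013, -0.004], [0.035], None, 0.55),
    "BFL": (800.0,  [-0.028, -0.006], [-0.055], None, 0.92),
    "ST":  (600.0,  [-0.032, -0.008], [-0.050], None, 0.92),
    "SM":  (1000.0, [-0.030, -0.007], [-0.050], None, 0.94),
    "GRA": (100.0,  [-0.016, -0.004], [0.008], None, 0.55),
    "GAS": (1500.0, [-0.020, -0.005], None, [-0.042], 0.90),
    "VL":  (3000.0, [0.041, -0.006], None, None, 0.97),
    "VM":  (2500.0, [0.040, -0.006], None, None, 0.97),
    "VI":  (2000.0, [0.042, -0.006], None, None, 0.98),
    "RF":  (1200.0, [0.044, -0.007], [0.040], None, 0.96),
}
KNEE_FLEXORS = ("SAR", "BFL", "ST", "SM", "GRA", "GAS")
KNEE_EXTENSORS = ("VL", "VM", "VI", "RF")

# ---------------------------------------------------------------------------
# Exoskeleton hardware defaults (configurable; the device carries a thigh
# shell and a shank shell joined by an actuated hinge at the knee).
# ---------------------------------------------------------------------------
EXO_THIGH_MASS = 1.2          # kg
EXO_SHANK_MASS = 0.8          # kg
EXO_ROTOR_INERTIA = 0.005     # kg m^2, reflected at the knee
EXO_JOINT_DAMPING = 0.1       # N m s / rad, passive hinge damping
EXO_FRICTION_MU = 0.5         # strap/skin Coulomb friction coefficient
EXO_STRAP_STRENGTH = 2000.0   # N, artificial-muscle strength per strap node
# strap ring axial positions, fraction of segment length from the proximal
# joint (hip for the thigh shell, knee for the shank shell)
THIGH_RING_FRACS = (0.60, 0.85)
SHANK_RING_FRACS = (0.15, 0.40)
THIGH_RADIUS = 0.060          # m, modelled leg radius at the thigh cuff
SHANK_RADIUS = 0.045          # m, at the shank cuff
STRAP_LOWER_LIMIT = -0.01     # m, normal-direction contact window
STRAP_UPPER_LIMIT = 0.01      # m
STRAP_RADIUS_LIMIT = 0.03     # m, tangential-plane contact window

# ---------------------------------------------------------------------------
# Ground contact
# ---------------------------------------------------------------------------
N_FOOT_NODES = 25             # contact nodes under each foot (5 x 5 grid)
FOOT_NODE_COLUMNS = 5         # distinct antero-posterior columns (planar)
GROUND_FRICTION_MU = 0.8
FOOT_NODE_STRENGTH = 1000.0   # N, artificial-actuator strength per node
GRF_HEIGHT_GATE = 0.04        # m, node active if within this height of the
                              # lowest foot point of the frame
GRF_SPEED_GATE = 3.0          # m/s, node active if slower than this

# ---------------------------------------------------------------------------
# Static-optimization objective weights (per activation^2 term).
# Muscles carry weight 1; foot and strap artificial actuators are load paths,
# not effort, and are weakly penalized; the knee reserve is heavily penalized
# so that it only reports model insufficiency; hip/ankle reserves stand in
# for the out-of-scope hip/ankle musculature and carry ordinary weight.
# ---------------------------------------------------------------------------
W_MUSCLE = 1.0
W_SUPPORT = 1.0e-3
W_KNEE_RESERVE = 1.0e3
W_OTHER_RESERVE = 1.0
RESERVE_TORQUE_SCALE = 100.0  # N*m mapped to activation 1
W_MOMENT_SLACK = 1.0e3        # whole-body moment slack in the GRF problem

EQ_RESIDUAL_RTOL = 1e-6       # relative equality residual accepted
SOLVER_FTOL = 1e-14

# ---------------------------------------------------------------------------
# Knee contact geometry
# ---------------------------------------------------------------------------
KNEE_WIDTH = 0.10             # m
CONDYLE_RATIO_LATERAL = 0.25  # condyle moment arm / knee width
CONDYLE_RATIO_MEDIAL = 0.25

# Reporting windows, fraction of the gait cycle
LATE_STANCE_WINDOW = (0.40, 0.60)
LATE_SWING_WINDOW = (0.85, 1.00)

# Reference controller parameters reported for this class of device
# (pseudo-stiffness K in N*m/rad; assistance level a per phase; damping b in
# N*m*s/rad per phase, speed-specific).
REFERENCE_CONTROLLER = {
    "RA": {"K": 4.0},
    "SPM": {"a_stance": 0.23, "a_swing": 0.78},
    "DPM": {
        "normal": {"a_stance": 0.33, "b_stance": 12.6,
                   "a_swing": 0.78, "b_swing": 0.34},
        "fast": {"a_stance": 0.33, "b_stance": 18.4,
                 "a_swing": 0.78, "b_swing": 0.10},
    },
}

# Default sensitivity grids
K_GRID = tuple(float(k) for k in range(0, 11))
A_GRID = tuple(round(0.05 * i, 2) for i in range(0, 21))
B_GRID = (0.0, 0.1, 0.34, 1.0, 5.0, 12.6, 18.4, 25.0)
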