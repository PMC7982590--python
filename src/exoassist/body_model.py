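"""Planar human + knee-exoskeleton linked-segment model.

The human is reduced to a sagittal chain of HAT (head-arms-trunk), thigh,
shank and foot per leg, scaled to body mass and stature by cadaver-based
fraction tables. The exoskeleton contributes a thigh shell and a shank shell
(masses merged into the host segments for the rigid-body dynamics, kept
separate for the strap free-body balance), a reflected rotor inertia and a
passive hinge damping at the knee, and sixteen strap contact nodes modelled
as conditional contact elements.

Only the ten knee-crossing muscles are carried: flexors SAR, BFL, ST, SM,
GRA, GAS and extensors VL, VM, VI, RF. Moment arms are low-order polynomials
in the joint angle with knee extension / hip flexion / ankle dorsiflexion
positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np
import yaml

from . import config

__all__ = [
    "Anthropometry",
    "ExoskeletonSpec",
    "StrapNode",
    "Muscle",
    "Segment",
    "LinkedSegmentModel",
    "PendulumConstants",
    "build_model",
    "default_model",
    "moment_arm",
    "pendulum_constants",
    "default_muscles",
    "default_strap_nodes",
    "load_model_config",
]

MUSCLE_NAMES = tuple(config.MUSCLE_TABLE)
JOINTS = ("hip", "knee", "ankle")


@dataclass(frozen=True)
class Anthropometry:
    """Whole-body size plus the segment scaling fraction table."""

    body_mass: float  # kg
    height: float     # m
    segment_table: dict = field(
        default_factory=lambda: dict(config.SEGMENT_TABLE)
    )

    def __post_init__(self) -> None:
        if not self.body_mass > 0:
            raise ValueError("Anthropometry.body_mass must be > 0")
        if not self.height > 0:
            raise ValueError("Anthropometry.height must be > 0")
        total = self.segment_table["hat"][0] + 2 * sum(
            self.segment_table[s][0] for s in ("thigh", "shank", "foot")
        )
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"segment mass fractions must sum to 1 (got {total!r})"
            )
        for seg, fracs in self.segment_table.items():
            for name, f in zip(("mass", "length", "com", "rog"), fracs):
                if not 0.0 < f < 1.0:
                    raise ValueError(
                        f"segment_table[{seg}] {name} fraction must be in (0,1)"
                    )


@dataclass(frozen=True)
class StrapNode:
    """One conditional contact element between a strap and the leg.

    The node sits on the host segment's axis at ``axial_position`` metres
    from the proximal joint, offset radially by the cuff radius along
    ``normal_axis`` (a unit vector in the segment's cross-sectional plane;
    in the sagittal model only the +/- anterior axis carries load and
    medial/lateral nodes are flagged ``in_plane=False``). It transmits
    compression between strap and leg only while the counterpart lies inside
    the window: normal gap within [lower_limit, upper_limit] and tangential
    offset within radius_limit.
    """

    host_segment: str        # "thigh" | "shank"
    axial_position: float    # m from the proximal joint
    lower_limit: float = config.STRAP_LOWER_LIMIT
    upper_limit: float = config.STRAP_UPPER_LIMIT
    radius_limit: float = config.STRAP_RADIUS_LIMIT
    strength: float = config.EXO_STRAP_STRENGTH
    normal_sign: int = 1     # +1 anterior surface, -1 posterior
    cuff_radius: float = 0.05
    in_plane: bool = True
    normal_gap: float = 0.0      # current normal-direction separation, m
    radial_offset: float = 0.0   # current tangential-plane separation, m
    axial_is_fraction: bool = False  # axial_position given as a fraction of
                                     # segment length (resolved in build_model)

    def __post_init__(self) -> None:
        if self.host_segment not in ("thigh", "shank"):
            raise ValueError("StrapNode.host_segment must be thigh or shank")
        if not self.lower_limit < self.upper_limit:
            raise ValueError("StrapNode requires lower_limit < upper_limit")
        if not self.radius_limit > 0:
            raise ValueError("StrapNode.radius_limit must be > 0")
        if not self.strength > 0:
            raise ValueError("StrapNode.strength must be > 0")

    def active(self) -> bool:
        """Cylindrical window test: can this node transmit force now?"""
        return (
            self.lower_limit <= self.normal_gap <= self.upper_limit
            and abs(self.radial_offset) <= self.radius_limit
        )


def default_strap_nodes() -> list[StrapNode]:
    """Sixteen nodes: 2 rings x 4 nodes on the thigh shell and on the shank
    shell; per ring one anterior and one posterior in-plane node plus one
    medial and one lateral out-of-plane node."""
    nodes: list[StrapNode] = []
    for seg, fracs, radius in (
        ("thigh", config.THIGH_RING_FRACS, config.THIGH_RADIUS),
        ("shank", config.SHANK_RING_FRACS, config.SHANK_RADIUS),
    ):
        for frac in fracs:
            for sign, in_plane in ((1, True), (-1, True), (1, False), (-1, False)):
                nodes.append(
                    StrapNode(
                        host_segment=seg,
                        axial_position=frac,
                        axial_is_fraction=True,  # resolved in build_model
                        normal_sign=sign,
                        cuff_radius=radius,
                        in_plane=in_plane,
                    )
                )
    return nodes


@dataclass(frozen=True)
class ExoskeletonSpec:
    """Exoskeleton hardware: shell masses, rotor inertia, hinge damping,
    strap nodes and strap friction."""

    thigh_attach_mass: float = config.EXO_THIGH_MASS
    shank_attach_mass: float = config.EXO_SHANK_MASS
    rotor_inertia_at_knee: float = config.EXO_ROTOR_INERTIA
    joint_damping: float = config.EXO_JOINT_DAMPING
    friction_coefficient: float = config.EXO_FRICTION_MU
    strap_nodes: tuple = field(default_factory=lambda: tuple(default_strap_nodes()))
    thigh_attach_frac: float = 0.75  # shell COM, fraction of thigh length from hip
    shank_attach_frac: float = 0.275  # shell COM, fraction of shank length from knee

    def __post_init__(self) -> None:
        if self.thigh_attach_mass < 0 or self.shank_attach_mass < 0:
            raise ValueError("exoskeleton masses must be >= 0")
        if self.rotor_inertia_at_knee < 0:
            raise ValueError("rotor_inertia_at_knee must be >= 0")
        if self.joint_damping < 0:
            raise ValueError("joint_damping must be >= 0")
        if not self.friction_coefficient > 0:
            raise ValueError("friction_coefficient must be > 0")

    @classmethod
    def zero(cls) -> "ExoskeletonSpec":
        """A massless, inertia-free, undamped device (straps retained)."""
        return cls(0.0, 0.0, 0.0, 0.0)


@dataclass(frozen=True)
class Muscle:
    """One knee-crossing muscle with polynomial moment arms.

    ``knee_ma``/``hip_ma``/``ankle_ma`` hold ascending polynomial
    coefficients in the respective joint angle (radians -> metres); ``None``
    marks a joint the muscle does not cross. Extensor knee arms are positive,
    flexor arms negative (and analogously at hip and ankle).
    ``axial_fraction`` is the fraction of muscle force compressing the knee
    along the shank axis.
    """

    name: str
    f_max: float
    knee_ma: tuple
    hip_ma: tuple | None = None
    ankle_ma: tuple | None = None
    axial_fraction: float = 0.95

    def __post_init__(self) -> None:
        if not self.f_max > 0:
            raise ValueError(f"Muscle {self.name}: f_max must be > 0")
        if not 0.0 <= self.axial_fraction <= 1.0:
            raise ValueError(f"Muscle {self.name}: axial_fraction in [0,1]")

    def crosses(self, joint: str) -> bool:
        return self._poly(joint) is not None

    def _poly(self, joint: str):
        if joint not in JOINTS:
            raise ValueError(f"unknown joint {joint!r}")
        return {"knee": self.knee_ma, "hip": self.hip_ma, "ankle": self.ankle_ma}[joint]


def default_muscles() -> list[Muscle]:
    out = []
    for name, (fmax, knee, hip, ankle, axial) in config.MUSCLE_TABLE.items():
        out.append(
            Muscle(
                name=name,
                f_max=fmax,
                knee_ma=tuple(knee),
                hip_ma=tuple(hip) if hip is not None else None,
                ankle_ma=tuple(ankle) if ankle is not None else None,
                axial_fraction=axial,
            )
        )
    return out


def moment_arm(muscle: Muscle, joint: str, angle: float):
    """Signed moment arm (m) of ``muscle`` about ``joint`` at ``angle`` (rad).

    Returns 0.0 for a joint the muscle does not cross; use
    ``muscle.crosses(joint)`` to distinguish a genuine zero arm from
    "not crossed".
    """
    poly = muscle._poly(joint)
    if poly is None:
        return np.zeros_like(np.asarray(angle, dtype=float)) + 0.0
    angle = np.asarray(angle, dtype=float)
    out = np.zeros_like(angle)
    for k, c in enumerate(poly):
        out = out + c * angle**k
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class Segment:
    """A rigid planar segment: mass, length, COM offset from the proximal
    joint along the segment axis, and moment of inertia about the COM."""

    name: str
    mass: float
    length: float
    com_offset: float       # m from the proximal joint along the axis
    inertia_com: float      # kg m^2

    def __post_init__(self) -> None:
        if self.mass < 0 or self.length <= 0:
            raise ValueError(f"Segment {self.name}: bad mass/length")
        if self.inertia_com < 0:
            raise ValueError(f"Segment {self.name}: inertia must be >= 0")


class PendulumConstants(NamedTuple):
    """Composite constants of the swing pendulum (about the knee, ankle
    neutral) and of the stance inverted pendulum (about the ankle)."""

    I_c1: float   # kg m^2, shank+foot+lower-exo about the knee
    m_c1: float   # kg, combined shank+foot+lower-exo mass
    l_c1: float   # m, knee -> composite COM
    I_s: float    # kg m^2, shank+lower-exo about the ankle
    m_c2: float   # kg, total model mass minus one foot
    l_s: float    # m, ankle -> shank(+lower-exo) COM


@dataclass(frozen=True)
class LinkedSegmentModel:
    """Scaled planar human-exoskeleton model.

    Shell masses are merged into the host segments (``thigh``/``shank``
    entries already include them); the unmerged shell parameters remain
    available through ``exo`` for the strap free-body balance. Foot geometry:
    the foot axis runs heel->toe passing ``ankle_height`` below the ankle,
    with the heel ``heel_frac * length`` behind it.
    """

    anthro: Anthropometry
    exo: ExoskeletonSpec
    segments: dict
    muscles: tuple
    strap_nodes: tuple         # axial_position resolved to metres
    ankle_height: float        # m
    heel_frac: float
    foot_com_local: tuple      # (x, y) m in the foot frame, origin at ankle
    knee_width: float = config.KNEE_WIDTH
    condyle_ratio_lateral: float = config.CONDYLE_RATIO_LATERAL
    condyle_ratio_medial: float = config.CONDYLE_RATIO_MEDIAL
    n_foot_nodes: int = config.N_FOOT_NODES
    ground_friction: float = config.GROUND_FRICTION_MU
    gravity: float = config.GRAVITY

    @property
    def total_mass(self) -> float:
        """Human + exoskeleton mass (device on the right leg only)."""
        return (
            self.segments["hat"].mass
            + self.segments["thigh"].mass + self.segments["shank"].mass
            + self.segments["thigh_free"].mass + self.segments["shank_free"].mass
            + 2 * self.segments["foot"].mass
        )

    @property
    def body_weight(self) -> float:
        """Human body weight (N) used for %BW normalization."""
        return self.anthro.body_mass * self.gravity

    def hip_height(self) -> float:
        """Standing hip height above the ground (leg straight)."""
        return (
            self.segments["thigh"].length
            + self.segments["shank"].length
            + self.ankle_height
        )

    def foot_node_local(self) -> np.ndarray:
        """(n_nodes, 2) node positions in the foot frame (origin ankle)."""
        lf = self.segments["foot"].length
        xs = np.linspace(-self.heel_frac * lf, (1 - self.heel_frac) * lf,
                         config.FOOT_NODE_COLUMNS)
        per_col = self.n_foot_nodes // config.FOOT_NODE_COLUMNS
        pts = [(x, -self.ankle_height) for x in xs for _ in range(per_col)]
        return np.array(pts)


def _scaled_segment(name: str, anthro: Anthropometry) -> Segment:
    mfrac, lfrac, cfrac, rfrac = anthro.segment_table[name]
    m = mfrac * anthro.body_mass
    length = lfrac * anthro.height
    return Segment(
        name=name,
        mass=m,
        length=length,
        com_offset=cfrac * length,
        inertia_com=m * (rfrac * length) ** 2,
    )


def _merge_point_mass(seg: Segment, m_add: float, pos: float) -> Segment:
    """Merge a point mass at axial position ``pos`` into a segment."""
    if m_add == 0.0:
        return seg
    m = seg.mass + m_add
    com = (seg.mass * seg.com_offset + m_add * pos) / m
    inertia = (
        seg.inertia_com
        + seg.mass * (seg.com_offset - com) ** 2
        + m_add * (pos - com) ** 2
    )
    return replace(seg, mass=m, com_offset=com, inertia_com=inertia)


def build_model(
    anthro: Anthropometry,
    exo: ExoskeletonSpec,
    muscles: list[Muscle] | None = None,
) -> LinkedSegmentModel:
    """Scale segments from body mass/stature and merge the exoskeleton.

    The device rides the right leg: the right thigh/shank segments carry the
    shell masses and the reflected rotor inertia, the left leg stays
    human-only (exposed as ``thigh_free``/``shank_free``).
    """
    if muscles is None:
        muscles = default_muscles()
    hat = _scaled_segment("hat", anthro)
    thigh = _scaled_segment("thigh", anthro)
    shank = _scaled_segment("shank", anthro)
    foot = _scaled_segment("foot", anthro)

    thigh_exo = _merge_point_mass(
        thigh, exo.thigh_attach_mass, exo.thigh_attach_frac * thigh.length
    )
    shank_exo = _merge_point_mass(
        shank, exo.shank_attach_mass, exo.shank_attach_frac * shank.length
    )
    shank_exo = replace(
        shank_exo, inertia_com=shank_exo.inertia_com + exo.rotor_inertia_at_knee
    )

    ankle_h = config.ANKLE_HEIGHT_FRAC * anthro.height
    heel_frac = config.FOOT_HEEL_FRAC
    # foot COM halfway along the heel->toe axis, at sole height
    lf = foot.length
    foot_com_local = ((0.5 - heel_frac) * lf, -ankle_h)

    nodes = []
    for node in exo.strap_nodes:
        seg = thigh if node.host_segment == "thigh" else shank
        if node.axial_is_fraction:
            node = replace(
                node,
                axial_position=node.axial_position * seg.length,
                axial_is_fraction=False,
            )
        nodes.append(node)

    return LinkedSegmentModel(
        anthro=anthro,
        exo=exo,
        segments={
            "hat": hat,
            "thigh": thigh_exo,
            "shank": shank_exo,
            "foot": foot,
            "thigh_free": thigh,
            "shank_free": shank,
        },
        muscles=tuple(muscles),
        strap_nodes=tuple(nodes),
        ankle_height=ankle_h,
        heel_frac=heel_frac,
        foot_com_local=foot_com_local,
    )


def default_model() -> LinkedSegmentModel:
    """The reference subject: 66 kg, 1.75 m, default exoskeleton."""
    return build_model(Anthropometry(66.0, 1.75), ExoskeletonSpec())


def pendulum_constants(model: LinkedSegmentModel) -> PendulumConstants:
    """Composite pendulum constants by parallel-axis composition.

    Swing: shank(+shell+rotor) and foot rigidly composed about the knee with
    the ankle in the neutral position. Stance: shank(+shell) about the
    ankle; ``m_c2`` is the whole model mass minus one foot.
    """
    shank = model.segments["shank"]
    foot = model.segments["foot"]
    ls = shank.length

    # ankle-neutral configuration, knee at origin, shank axis pointing down
    com_shank = np.array([0.0, -shank.com_offset])
    ankle = np.array([0.0, -ls])
    fx, fy = model.foot_com_local
    com_foot = ankle + np.array([fx, fy])

    m_c1 = shank.mass + foot.mass
    com_c1 = (shank.mass * com_shank + foot.mass * com_foot) / m_c1
    l_c1 = float(np.linalg.norm(com_c1))
    I_c1 = float(
        shank.inertia_com + shank.mass * np.dot(com_shank, com_shank)
        + foot.inertia_com + foot.mass * np.dot(com_foot, com_foot)
    )

    d_ankle = ls - shank.com_offset
    I_s = float(shank.inertia_com + shank.mass * d_ankle**2)
    l_s = float(abs(d_ankle))
    m_c2 = model.total_mass - foot.mass
    return PendulumConstants(I_c1, m_c1, l_c1, I_s, m_c2, l_s)


# ---------------------------------------------------------------------------
# YAML configuration loading
# ---------------------------------------------------------------------------

def load_model_config(path) -> LinkedSegmentModel:
    """Build a model from a single YAML document mirroring the domain types.

    Recognized top-level keys: ``anthropometry`` (body_mass, height),
    ``exoskeleton`` (any ExoskeletonSpec field except strap_nodes),
    ``strap_nodes`` (list of StrapNode field mappings, replacing the default
    sixteen), ``muscles`` (mapping name -> {f_max, knee_ma, hip_ma,
    ankle_ma, axial_fraction}). Validation errors name the offending field.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}

    anth = doc.get("anthropometry", {})
    try:
        anthro = Anthropometry(
            body_mass=float(anth.get("body_mass", 66.0)),
            height=float(anth.get("height", 1.75)),
        )
    except (TypeError, ValueError) as exc:
        raise ValueError(f"anthropometry: {exc}") from exc

    exo_doc = dict(doc.get("exoskeleton", {}))
    nodes_doc = doc.get("strap_nodes")
    kwargs = {}
    for key in ("thigh_attach_mass", "shank_attach_mass", "rotor_inertia_at_knee",
                "joint_damping", "friction_coefficient", "thigh_attach_frac",
                "shank_attach_frac"):
        if key in exo_doc:
            kwargs[key] = float(exo_doc[key])
    if nodes_doc is not None:
        try:
            kwargs["strap_nodes"] = tuple(StrapNode(**nd) for nd in nodes_doc)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"strap_nodes: {exc}") from exc
    try:
        exo = ExoskeletonSpec(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"exoskeleton: {exc}") from exc

    muscles = None
    if "muscles" in doc:
        muscles = []
        for name, md in doc["muscles"].items():
            try:
                muscles.append(
                    Muscle(
                        name=name,
                        f_max=float(md["f_max"]),
                        knee_ma=tuple(md["knee_ma"]),
                        hip_ma=tuple(md["hip_ma"]) if md.get("hip_ma") else None,
                        ankle_ma=tuple(md["ankle_ma"]) if md.get("ankle_ma") else None,
                        axial_fraction=float(md.get("axial_fraction", 0.95)),
                    )
                )
            except (KeyError, TypeError, ValueError) as exc:
                raise ValueError(f"muscles[{name}]: {exc}") from exc

    return build_model(anthro, exo, muscles)
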