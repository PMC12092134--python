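"""Musculoskeletal data model for planar (sagittal) biped simulations.

The world is the sagittal plane: 2-vectors are (x, z) with z up, and all
rotations are counter-clockwise positive.  A model is a tree of rigid
segments connected by hinge joints.  Each segment carries a local frame
with its origin at the proximal joint (the root segment's origin is the
floating base) and its +x axis running toward the distal end, so segment
geometry, muscle path points and contact points are expressed as fixed
2-vectors in that frame.

Units are SI throughout except muscle architecture, which follows the
conventions of the comparative literature: fibre and tendon lengths in mm,
PCSA in mm^2, maximum shortening velocity in fibre lengths per second and
maximum isometric stress in N mm^-2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import yaml

__all__ = [
    "Shape",
    "Segment",
    "Joint",
    "PathPoint",
    "WrapCylinder",
    "Actuator",
    "ContactPoint",
    "BoneSection",
    "Model",
    "SchemaError",
    "LinkageError",
    "segment_properties",
    "validate_model",
    "load_model",
    "save_model",
    "forward_kinematics",
]


class SchemaError(ValueError):
    """A model description violates the documented schema."""


class LinkageError(SchemaError):
    """The joint/segment graph is not a valid tree."""


# ---------------------------------------------------------------------------
# primitive geometry
# ---------------------------------------------------------------------------

@dataclass
class Shape:
    """Solid primitive used for segment mass/inertia.

    ``length`` runs along the segment's local +x axis.  ``cylinder`` takes a
    ``radius``; ``cuboid`` takes an in-plane ``width`` and out-of-plane
    ``depth``.
    """

    kind: str
    length: float
    radius: float = 0.0
    width: float = 0.0
    depth: float = 0.0

    def volume(self) -> float:
        if self.kind == "cylinder":
            return math.pi * self.radius**2 * self.length
        if self.kind == "cuboid":
            return self.length * self.width * self.depth
        raise SchemaError(f"unknown shape kind {self.kind!r}")


def segment_properties(shape: Shape, density: float) -> tuple[float, float, float]:
    """Mass, out-of-plane moment of inertia about the CoM and CoM offset of a
    uniform solid primitive.

    Returns ``(mass kg, moi kg m^2, com_offset m)`` where the CoM offset is
    measured along the segment axis from the proximal origin.
    """
    if density <= 0:
        raise SchemaError(f"density must be positive, got {density}")
    if shape.length <= 0:
        raise SchemaError(f"shape length must be positive, got {shape.length}")
    if shape.kind == "cylinder":
        if shape.radius <= 0:
            raise SchemaError(f"cylinder radius must be positive, got {shape.radius}")
        mass = density * shape.volume()
        moi = mass * (shape.length**2 / 12.0 + shape.radius**2 / 4.0)
    elif shape.kind == "cuboid":
        if shape.width <= 0 or shape.depth <= 0:
            raise SchemaError("cuboid width and depth must be positive")
        mass = density * shape.volume()
        moi = mass * (shape.length**2 + shape.width**2) / 12.0
    else:
        raise SchemaError(f"unknown shape kind {shape.kind!r}")
    return mass, moi, shape.length / 2.0


@dataclass
class Segment:
    """A rigid body segment.

    ``mass``, ``moi`` and ``com_offset`` are derived from ``shape`` and
    ``density`` when omitted; an explicit ``mass`` override rescales the
    derived inertia proportionally (shape then only sets proportions).
    """

    name: str
    shape: Shape
    density: float = 1000.0
    mass: Optional[float] = None
    com_offset: Optional[float] = None
    moi: Optional[float] = None

    def __post_init__(self) -> None:
        if isinstance(self.shape, dict):
            self.shape = Shape(**self.shape)
        m, i, c = segment_properties(self.shape, self.density)
        if self.mass is None:
            self.mass = m
        elif self.moi is None:
            # keep the primitive's radius of gyration under a mass override
            i = i * (self.mass / m)
        if self.com_offset is None:
            self.com_offset = c
        if self.moi is None:
            self.moi = i
        if self.mass <= 0:
            raise SchemaError(f"segment {self.name!r}: mass must be positive")

    @property
    def com_local(self) -> np.ndarray:
        return np.array([self.com_offset, 0.0])


@dataclass
class Joint:
    """A hinge permitting flexion-extension only, with soft angle limits.

    ``anchor`` locates the hinge in the parent frame; the child frame origin
    sits on the hinge.  ``reference_angle_deg`` is the CCW rotation of the
    child frame relative to the parent frame at anatomical neutral (joint
    angle zero); the geometric rotation at joint angle q is
    ``reference + sign * q``.  ``sign`` is +1 when extension is positive CCW
    in the parent frame and -1 otherwise, letting builders match printed
    anatomical conventions (e.g. knee flexion negative).
    """

    name: str
    parent: str
    child: str
    anchor: tuple[float, float] = (0.0, 0.0)
    angle_lo: float = -180.0
    angle_hi: float = 180.0
    soft_limit_stiffness: float = 1000.0
    soft_limit_damping: float = 10.0
    sign: int = 1
    reference_angle_deg: float = 0.0
    #: +1 when anatomical extension increases the joint angle, -1 when it
    #: decreases it (e.g. hip flexion positive -> extension_sign = -1)
    extension_sign: int = 1

    def __post_init__(self) -> None:
        if self.parent == self.child:
            raise SchemaError(f"joint {self.name!r}: parent == child")
        if not self.angle_lo < self.angle_hi:
            raise SchemaError(
                f"joint {self.name!r}: angle_lo ({self.angle_lo}) must be < "
                f"angle_hi ({self.angle_hi})"
            )
        if self.soft_limit_stiffness < 0 or self.soft_limit_damping < 0:
            raise SchemaError(f"joint {self.name!r}: negative soft-limit parameter")
        if self.sign not in (1, -1):
            raise SchemaError(f"joint {self.name!r}: sign must be +1 or -1")


@dataclass
class PathPoint:
    segment: str
    pos: tuple[float, float]


@dataclass
class WrapCylinder:
    """A frictionless circular wrapping surface for one actuator.

    The cable wraps between path points ``after_point`` and
    ``after_point + 1`` whenever the straight line between them would cut
    the circle; ``side`` (+1 CCW / -1 CW) is the direction the cable runs
    around the circle.
    """

    segment: str
    center: tuple[float, float]
    radius: float
    side: int = 1
    after_point: int = 0


@dataclass
class Actuator:
    """One aggregated muscle-tendon unit (pooled action of a functional group).

    Bilateral pairs are collapsed into a single planar actuator whose PCSA is
    the two-limb total.
    """

    name: str
    path: list[PathPoint]
    fl_mm: float
    pcsa_mm2: float
    tl_mm: float = 0.0
    vmax_ls: float = 8.4
    sigma_max: float = 0.3  # N mm^-2; conventional vertebrate maximum stress
    se_strain: float = 0.04  # tendon strain at maximum isometric force
    fl_width: float = 0.5  # force-length half-width as a fraction of L_opt
    actions: list[tuple[str, str]] = field(default_factory=list)
    region: str = "proximal"
    wrap: Optional[WrapCylinder] = None
    tendon_gene_bounds: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        self.path = [PathPoint(**p) if isinstance(p, dict) else p for p in self.path]
        if isinstance(self.wrap, dict):
            self.wrap = WrapCylinder(**self.wrap)
        self.actions = [tuple(a) for a in self.actions]
        if self.fl_mm <= 0:
            raise SchemaError(f"actuator {self.name!r}: fibre length must be positive")
        if self.tl_mm < 0:
            raise SchemaError(f"actuator {self.name!r}: tendon length must be >= 0")
        if self.pcsa_mm2 < 0:
            raise SchemaError(f"actuator {self.name!r}: PCSA must be >= 0")
        if self.vmax_ls <= 0:
            raise SchemaError(f"actuator {self.name!r}: vmax must be positive")
        for _, kind in self.actions:
            if kind not in ("extensor", "flexor"):
                raise SchemaError(
                    f"actuator {self.name!r}: action kind must be extensor|flexor"
                )

    @property
    def action_joints(self) -> list[str]:
        seen: list[str] = []
        for j, _ in self.actions:
            if j not in seen:
                seen.append(j)
        return seen

    @property
    def uniarticular(self) -> bool:
        return len(self.action_joints) == 1

    @property
    def f_max(self) -> float:
        """Maximum isometric force in N (sigma_max N mm^-2 x PCSA mm^2)."""
        return self.sigma_max * self.pcsa_mm2


@dataclass
class ContactPoint:
    """Unilateral spring-damper ground contact (no adhesion)."""

    segment: str
    local_pos: tuple[float, float]
    stiffness: float = 1.0e5
    damping: float = 1.0e3
    friction_mu: float = 1.0
    v_ref: float = 0.01  # slip-speed scale of the smoothed Coulomb law, m/s

    def __post_init__(self) -> None:
        if self.stiffness <= 0:
            raise SchemaError("contact stiffness must be positive")


@dataclass
class BoneSection:
    """Midshaft cross-section monitored for peak compressive stress."""

    name: str
    segment: str
    local_pos: tuple[float, float]
    area: float
    second_moment: float
    c: float
    failure_stress: float = 300.0e6  # Pa

    def __post_init__(self) -> None:
        if self.area <= 0 or self.second_moment <= 0 or self.c <= 0:
            raise SchemaError(f"bone section {self.name!r}: A, I, c must be positive")


@dataclass
class Model:
    """A complete planar musculoskeletal model."""

    taxon: str
    body_mass: float
    segments: list[Segment] = field(default_factory=list)
    joints: list[Joint] = field(default_factory=list)
    actuators: list[Actuator] = field(default_factory=list)
    contacts: list[ContactPoint] = field(default_factory=list)
    bone_sections: list[BoneSection] = field(default_factory=list)
    starting_pose: dict[str, float] = field(default_factory=dict)
    gravity: float = 9.81
    base_fixed: bool = False
    base_orientation_deg: float = 0.0

    def __post_init__(self) -> None:
        self.segments = [Segment(**s) if isinstance(s, dict) else s for s in self.segments]
        self.joints = [Joint(**j) if isinstance(j, dict) else j for j in self.joints]
        self.actuators = [Actuator(**a) if isinstance(a, dict) else a for a in self.actuators]
        self.contacts = [
            ContactPoint(**c) if isinstance(c, dict) else c for c in self.contacts
        ]
        self.bone_sections = [
            BoneSection(**b) if isinstance(b, dict) else b for b in self.bone_sections
        ]

    # -- lookups ----------------------------------------------------------
    def segment(self, name: str) -> Segment:
        for s in self.segments:
            if s.name == name:
                return s
        raise KeyError(name)

    def joint(self, name: str) -> Joint:
        for j in self.joints:
            if j.name == name:
                return j
        raise KeyError(name)

    def actuator(self, name: str) -> Actuator:
        for a in self.actuators:
            if a.name == name:
                return a
        raise KeyError(name)

    @property
    def root(self) -> str:
        children = {j.child for j in self.joints}
        roots = [s.name for s in self.segments if s.name not in children]
        if len(roots) != 1:
            raise LinkageError(f"model must have exactly one root segment, found {roots}")
        return roots[0]

    @property
    def total_segment_mass(self) -> float:
        return sum(s.mass for s in self.segments)

    def validate(self) -> None:
        report = validate_model(self)
        if report:
            raise SchemaError("invalid model:\n  " + "\n  ".join(report))

    # -- (de)serialisation ------------------------------------------------
    def to_dict(self) -> dict:
        return _plain(asdict(self))

    @classmethod
    def from_dict(cls, d: dict) -> "Model":
        required = ("taxon", "body_mass")
        for key in required:
            if key not in d:
                raise SchemaError(f"missing required field {key!r}")
        return cls(**d)


def _plain(obj):
    """Recursively turn tuples into lists (YAML-stable representation)."""
    if isinstance(obj, (list, tuple)):
        return [_plain(x) for x in obj]
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def validate_model(m: Model) -> list[str]:
    """List every invariant violation; an empty report means simulatable."""
    report: list[str] = []
    seg_names = [s.name for s in m.segments]
    if len(set(seg_names)) != len(seg_names):
        report.append("duplicate segment names")
    if not m.segments:
        report.append("model has no segments")
        return report

    known = set(seg_names)
    for j in m.joints:
        for end in (j.parent, j.child):
            if end not in known:
                report.append(f"joint {j.name!r} references unknown segment {end!r}")

    # tree structure: every segment except one root has exactly one parent joint
    parents: dict[str, str] = {}
    for j in m.joints:
        if j.child in parents:
            report.append(f"segment {j.child!r} has more than one parent joint")
        parents[j.child] = j.parent
    roots = [s for s in seg_names if s not in parents]
    if len(roots) != 1:
        report.append(f"expected exactly one root segment, found {roots}")
    else:
        # connectivity / loop check
        for name in seg_names:
            seen = set()
            cur = name
            while cur in parents:
                if cur in seen:
                    report.append(f"linkage loop through segment {cur!r}")
                    break
                seen.add(cur)
                cur = parents[cur]

    if m.body_mass > 0:
        rel = abs(m.total_segment_mass - m.body_mass) / m.body_mass
        if rel > 0.01:
            report.append(
                f"segment masses sum to {m.total_segment_mass:.4f} kg, which is "
                f"{100 * rel:.1f}% off body mass {m.body_mass} kg (limit 1%)"
            )
    else:
        report.append("body_mass must be positive")

    joint_names = {j.name for j in m.joints}
    for j in m.joints:
        q = m.starting_pose.get(j.name)
        if q is not None and not (j.angle_lo <= q <= j.angle_hi):
            report.append(
                f"starting pose {j.name}={q} deg outside [{j.angle_lo}, {j.angle_hi}]"
            )
    for name in m.starting_pose:
        if name not in joint_names:
            report.append(f"starting pose references unknown joint {name!r}")

    for a in m.actuators:
        if not a.actions:
            report.append(f"actuator {a.name!r} has no actions")
        for jn, _ in a.actions:
            if jn not in joint_names:
                report.append(f"actuator {a.name!r} acts on unknown joint {jn!r}")
        if len(a.path) < 2:
            report.append(f"actuator {a.name!r} path needs at least two points")
        for p in a.path:
            if p.segment not in known:
                report.append(f"actuator {a.name!r} path on unknown segment {p.segment!r}")
        if a.wrap is not None and a.wrap.segment not in known:
            report.append(f"actuator {a.name!r} wrap on unknown segment")

    for c in m.contacts:
        if c.segment not in known:
            report.append(f"contact on unknown segment {c.segment!r}")
    for b in m.bone_sections:
        if b.segment not in known:
            report.append(f"bone section {b.name!r} on unknown segment {b.segment!r}")
    return report


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def load_model(path) -> Model:
    """Read a model from a YAML configuration file and validate it."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise SchemaError(f"{path}: expected a mapping at top level")
    model = Model.from_dict(data)
    report = validate_model(model)
    linkage = [r for r in report if "unknown segment" in r or "root" in r or "loop" in r]
    if linkage:
        raise LinkageError("; ".join(linkage))
    if report:
        raise SchemaError("; ".join(report))
    return model


def save_model(model: Model, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(model.to_dict(), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# planar forward kinematics
# ---------------------------------------------------------------------------

def forward_kinematics(
    model: Model,
    pose_deg: Optional[dict[str, float]] = None,
    base: Sequence[float] = (0.0, 0.0),
    base_angle_deg: Optional[float] = None,
) -> dict[str, tuple[np.ndarray, float]]:
    """World origin and orientation (rad) of every segment frame at a pose.

    ``pose_deg`` maps joint name to the anatomical joint angle in degrees
    (missing joints default to the model starting pose, then to zero).
    """
    if pose_deg is None:
        pose_deg = {}
    if base_angle_deg is None:
        base_angle_deg = model.base_orientation_deg
    pose = dict(model.starting_pose)
    pose.update(pose_deg)

    out: dict[str, tuple[np.ndarray, float]] = {}
    root = model.root
    out[root] = (np.asarray(base, dtype=float), math.radians(base_angle_deg))
    joints_by_parent: dict[str, list[Joint]] = {}
    for j in model.joints:
        joints_by_parent.setdefault(j.parent, []).append(j)

    stack = [root]
    while stack:
        parent = stack.pop()
        origin_p, ang_p = out[parent]
        for j in joints_by_parent.get(parent, ()):
            q = math.radians(pose.get(j.name, 0.0))
            rot = math.radians(j.reference_angle_deg) + j.sign * q
            ca, sa = math.cos(ang_p), math.sin(ang_p)
            anchor = np.array(
                [
                    origin_p[0] + ca * j.anchor[0] - sa * j.anchor[1],
                    origin_p[1] + sa * j.anchor[0] + ca * j.anchor[1],
                ]
            )
            out[j.child] = (anchor, ang_p + rot)
            stack.append(j.child)
    return out


def world_point(fk: dict, segment: str, local) -> np.ndarray:
    """Map a point fixed in a segment frame to world coordinates."""
    origin, ang = fk[segment]
    ca, sa = math.cos(ang), math.sin(ang)
    return np.array(
        [
            origin[0] + ca * local[0] - sa * local[1],
            origin[1] + sa * local[0] + ca * local[1],
        ]
    )
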