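"""Reference fixtures and synthetic data with known ground truth.

Builds the two reference planar biped models (a 68.33 kg human with 9
aggregated actuators and a 1.38 kg guineafowl with 11, including a TMTP
joint) from the shipped actuator architecture table, all the named model
variants (measured / schematic / regression PCSAs plus the fibre-length
and tendon sensitivity variants), a small toy jumper for optimization
experiments, and analytic force/CoM traces whose jump metrics are known
in closed form.

Segment proportions, joint limits, muscle path geometry and contact
parameters are documented package defaults: the architecture table pins
fibre lengths and PCSAs, while the skeleton around them is a
parameterized primitive-geometry stand-in for scan-derived morphology.
Angle conventions: hip positive = flexion (0 = fully extended), knee
flexion negative (0 = straight), ankle positive = dorsiflexion; printed
human starting postures are expressed directly in these conventions.
"""

from __future__ import annotations

import importlib.resources
import itertools
import math
from dataclasses import replace
from typing import Optional

import numpy as np
import pandas as pd

from .model import (
    Actuator,
    BoneSection,
    ContactPoint,
    Joint,
    Model,
    PathPoint,
    Segment,
    Shape,
    WrapCylinder,
)
from .muscles import apply_fibre_tuning, compute_tendon_length, path_length_m
from .metrics import JumpMetrics

__all__ = [
    "POSTURES_HUMAN",
    "POSTURES_GUINEAFOWL",
    "VARIANTS",
    "actuator_table",
    "make_reference_human",
    "make_reference_guineafowl",
    "make_toy_jumper",
    "synth_trace",
]

#: printed mean starting joint angles (deg) of the human jumping trials
POSTURES_HUMAN = {
    "full_extension": {"hip": 10.0, "knee": 0.0, "ankle": -5.0},
    "shallow_crouch": {"hip": 67.0, "knee": -58.0, "ankle": 6.0},
    "deep_crouch": {"hip": 114.0, "knee": -95.0, "ankle": 11.0},
}

#: documented estimates (hip started horizontal-ish, flat toes); the
#: habitual crouch is the main condition, the deeper crouch a sensitivity
POSTURES_GUINEAFOWL = {
    "crouched": {"hip": 75.0, "knee": -80.0, "ankle": 40.0, "tmtp": -35.0},
    "deeper_crouch": {"hip": 95.0, "knee": -100.0, "ankle": 55.0, "tmtp": -30.0},
}

VARIANTS = [
    "model1",
    "model2",
    "model3",
    "deeper_crouch",
    "optimized_tendons",
    "fl_half",
    "fl_x2",
    "fl_x2_tendons",
]

_PCSA_COLUMN = {"model1": "m1", "model2": "m2", "model3": "m3"}


def actuator_table(taxon: Optional[str] = None) -> pd.DataFrame:
    """The shipped per-limb actuator architecture table (FL mm, PCSA mm^2)."""
    ref = importlib.resources.files("jumpsim").joinpath("data/actuator_tables.tsv")
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t", comment="#")
    if taxon is not None:
        df = df[df["taxon"] == taxon].reset_index(drop=True)
        if df.empty:
            raise ValueError(f"unknown taxon {taxon!r}")
    return df


def _parse_actions(s: str) -> list[tuple[str, str]]:
    return [tuple(part.split(":")) for part in s.split(";")]


# ---------------------------------------------------------------------------
# skeleton builders
# ---------------------------------------------------------------------------

def _choose_wrap_sides(model: Model) -> None:
    """Pick each wrap cylinder's side to match the actuator's role.

    The wrap cylinders of these models sit on joint hinges, so the side
    determines the sign of the moment arm there: an extensor must
    lengthen when the joint flexes and vice versa.  The side satisfying
    that sign condition over the joint range wins; a tie (wrap never
    engaged) falls back to the shorter route.
    """
    for a in model.actuators:
        if a.wrap is None:
            continue
        # the joint whose hinge carries this wrap (child frame holds it)
        wrap_joint = next(
            (j for j in model.joints if j.child == a.wrap.segment), None
        )
        role = dict(a.actions).get(wrap_joint.name) if wrap_joint is not None else None
        scores = {}
        totals = {}
        for side in (1, -1):
            a.wrap.side = side
            score = 0
            tot = 0.0
            if wrap_joint is not None and role is not None:
                jr = np.linspace(wrap_joint.angle_lo, wrap_joint.angle_hi, 9)
                pose = dict(model.starting_pose)
                for qd in jr:
                    pose[wrap_joint.name] = float(qd)
                    L0 = path_length_m(model, a, pose)
                    pose[wrap_joint.name] = float(qd) + 0.5
                    L1 = path_length_m(model, a, pose)
                    dldq = (L1 - L0) * wrap_joint.extension_sign
                    # extensor: shortens along extension; flexor: lengthens
                    want = -1.0 if role == "extensor" else 1.0
                    if dldq * want > 1e-12:
                        score += 1
                    tot += L0
            scores[side] = score
            totals[side] = tot
        if scores[1] != scores[-1]:
            a.wrap.side = 1 if scores[1] > scores[-1] else -1
        else:
            a.wrap.side = 1 if totals[1] <= totals[-1] else -1


def _finish_model(model: Model, reference_pose: Optional[dict] = None) -> Model:
    """Choose wrap sides and fill tendon lengths from the reference pose."""
    _choose_wrap_sides(model)
    for a in model.actuators:
        a.tl_mm = compute_tendon_length(model, a, reference_pose)
    model.validate()
    return model


def _apply_variant(model: Model, variant: str, deeper_pose: Optional[dict] = None) -> Model:
    if variant in _PCSA_COLUMN or variant == "deeper_crouch":
        if variant == "deeper_crouch":
            if deeper_pose is None:
                raise ValueError("no deeper-crouch pose defined for this model")
            model.starting_pose = dict(deeper_pose)
        return model
    acts = list(model.actuators)
    if variant in ("fl_x2", "fl_x2_tendons"):
        acts = [apply_fibre_tuning(a, 2.0) for a in acts]
    elif variant == "fl_half":
        acts = [
            apply_fibre_tuning(a, 0.5) if a.region == "distal" else a for a in acts
        ]
    elif variant not in ("optimized_tendons",):
        raise ValueError(f"unknown variant {variant!r}")
    if variant in ("optimized_tendons", "fl_x2_tendons"):
        acts = [
            replace(a, tendon_gene_bounds=(0.9, 1.1))
            if a.uniarticular and any(k == "extensor" for _, k in a.actions)
            else a
            for a in acts
        ]
    model.actuators = acts
    return model


def _table_actuators(taxon: str, variant: str, paths: dict, wraps: dict, vmax: float):
    col = _PCSA_COLUMN.get(variant, "m1")
    rows = actuator_table(taxon)
    acts = []
    for _, r in rows.iterrows():
        name = r["actuator"]
        acts.append(
            Actuator(
                name=name,
                path=[PathPoint(seg, tuple(pos)) for seg, pos in paths[name]],
                wrap=wraps.get(name),
                fl_mm=float(r["fl_mm"]),
                pcsa_mm2=float(r[col]),
                vmax_ls=vmax,
                actions=_parse_actions(r["actions"]),
                region=r["region"],
            )
        )
    return acts



def _flat_foot_base(pose: dict) -> float:
    """Base (trunk) orientation that keeps the distal foot segment flat.

    With the reference-angle chain used by these builders the foot's world
    angle is base - 90 + sum(joint angles), so a flat foot requires the
    trunk to pitch forward by the angle sum (the natural trunk lean of a
    crouched posture).
    """
    return 90.0 - sum(pose.values())


def make_reference_human(variant: str = "model1", posture: str = "full_extension") -> Model:
    """The 68.33 kg planar human: 4 segments, 3 hinge joints, 9 actuators.

    ``variant`` picks the PCSA column (model1/2/3) or a sensitivity
    variant; ``posture`` one of the printed starting postures.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    if posture not in POSTURES_HUMAN:
        raise ValueError(f"unknown posture {posture!r}")
    M = 68.33
    segments = [
        Segment("hat", Shape("cylinder", length=0.85, radius=0.15), density=850.0, mass=0.678 * M),
        Segment("thigh", Shape("cylinder", length=0.42, radius=0.07), density=1000.0, mass=0.200 * M),
        Segment("shank", Shape("cylinder", length=0.43, radius=0.05), density=1000.0, mass=0.093 * M),
        Segment("foot", Shape("cuboid", length=0.26, width=0.06, depth=0.09), density=1000.0, mass=0.029 * M),
    ]
    joints = [
        Joint("hip", "hat", "thigh", anchor=(0.0, 0.0), angle_lo=-25.0, angle_hi=130.0,
              soft_limit_stiffness=600.0, soft_limit_damping=40.0, reference_angle_deg=-180.0,
              extension_sign=-1),
        Joint("knee", "thigh", "shank", anchor=(0.42, 0.0), angle_lo=-140.0, angle_hi=5.0,
              soft_limit_stiffness=600.0, soft_limit_damping=40.0, reference_angle_deg=0.0,
              extension_sign=1),
        Joint("ankle", "shank", "foot", anchor=(0.43, 0.0), angle_lo=-50.0, angle_hi=30.0,
              soft_limit_stiffness=400.0, soft_limit_damping=25.0, reference_angle_deg=90.0,
              extension_sign=-1),
    ]
    paths = {
        "hip ext": [("hat", (0.12, 0.06)), ("thigh", (0.12, -0.03))],
        "hip ext knee flx": [("hat", (0.10, 0.05)), ("shank", (0.04, -0.03))],
        "hip flx": [("hat", (0.08, -0.05)), ("thigh", (0.08, 0.03))],
        "hip flx knee ext": [("hat", (0.06, -0.05)), ("thigh", (0.38, 0.05)), ("shank", (0.05, 0.045))],
        "knee ext": [("thigh", (0.10, 0.04)), ("thigh", (0.38, 0.05)), ("shank", (0.05, 0.045))],
        "knee flx": [("thigh", (0.12, -0.03)), ("shank", (0.05, -0.04))],
        "knee flx ankle ext": [("thigh", (0.36, -0.03)), ("foot", (-0.04, 0.01))],
        "ankle ext": [("shank", (0.10, -0.03)), ("foot", (-0.04, 0.01))],
        "ankle flx": [("shank", (0.15, 0.035)), ("foot", (0.06, 0.02))],
    }
    wraps = {
        "hip ext": WrapCylinder("thigh", (0.0, 0.0), 0.05, after_point=0),
        "hip ext knee flx": WrapCylinder("thigh", (0.0, 0.0), 0.05, after_point=0),
        "hip flx": WrapCylinder("thigh", (0.0, 0.0), 0.04, after_point=0),
        "hip flx knee ext": WrapCylinder("shank", (0.0, 0.0), 0.045, after_point=1),
        "knee ext": WrapCylinder("shank", (0.0, 0.0), 0.045, after_point=1),
        "knee flx": WrapCylinder("shank", (0.0, 0.0), 0.04, after_point=0),
        "knee flx ankle ext": WrapCylinder("foot", (0.0, 0.0), 0.045, after_point=0),
        "ankle ext": WrapCylinder("foot", (0.0, 0.0), 0.045, after_point=0),
        "ankle flx": WrapCylinder("foot", (0.0, 0.0), 0.035, after_point=0),
    }
    actuators = _table_actuators("human", variant, paths, wraps, vmax=8.4)
    contacts = [
        ContactPoint("foot", (-0.05, -0.07), stiffness=1.2e5, damping=1.2e3),
        ContactPoint("foot", (0.19, -0.07), stiffness=1.2e5, damping=1.2e3),
    ]
    sections = [
        BoneSection("femur", "thigh", (0.21, 0.0), area=5.0e-4, second_moment=2.0e-8, c=0.0126),
        BoneSection("tibia", "shank", (0.215, 0.0), area=4.0e-4, second_moment=1.5e-8, c=0.011),
    ]
    model = Model(
        taxon="human",
        body_mass=M,
        segments=segments,
        joints=joints,
        actuators=actuators,
        contacts=contacts,
        bone_sections=sections,
        starting_pose=dict(POSTURES_HUMAN[posture]),
        base_orientation_deg=_flat_foot_base(POSTURES_HUMAN[posture]),
    )
    model = _finish_model(model)
    return _apply_variant(model, variant)


def make_reference_guineafowl(variant: str = "model1") -> Model:
    """The 1.38 kg planar guineafowl: 5 segments, 4 joints (incl. TMTP),
    11 actuators, Vmax 14 L/s."""
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    M = 1.38
    segments = [
        Segment("body", Shape("cylinder", length=0.15, radius=0.05), density=850.0, mass=1.100),
        Segment("thigh", Shape("cylinder", length=0.07, radius=0.015), density=1000.0, mass=0.130),
        Segment("shank", Shape("cylinder", length=0.12, radius=0.010), density=1000.0, mass=0.100),
        Segment("tmt", Shape("cylinder", length=0.07, radius=0.006), density=1000.0, mass=0.035),
        Segment("toes", Shape("cuboid", length=0.05, width=0.01, depth=0.02), density=1000.0, mass=0.015),
    ]
    joints = [
        Joint("hip", "body", "thigh", anchor=(0.0, 0.0), angle_lo=-10.0, angle_hi=110.0,
              soft_limit_stiffness=15.0, soft_limit_damping=0.6, reference_angle_deg=-180.0,
              extension_sign=-1),
        Joint("knee", "thigh", "shank", anchor=(0.07, 0.0), angle_lo=-130.0, angle_hi=5.0,
              soft_limit_stiffness=15.0, soft_limit_damping=0.6, reference_angle_deg=0.0,
              extension_sign=1),
        Joint("ankle", "shank", "tmt", anchor=(0.12, 0.0), angle_lo=-10.0, angle_hi=90.0,
              soft_limit_stiffness=12.0, soft_limit_damping=0.5, reference_angle_deg=0.0,
              extension_sign=-1),
        Joint("tmtp", "tmt", "toes", anchor=(0.07, 0.0), angle_lo=-70.0, angle_hi=30.0,
              soft_limit_stiffness=8.0, soft_limit_damping=0.3, reference_angle_deg=90.0,
              extension_sign=-1),
    ]
    paths = {
        "hip ext": [("body", (0.03, 0.02)), ("thigh", (0.03, -0.008))],
        "hip ext knee ext": [("body", (0.035, 0.015)), ("thigh", (0.065, 0.012)), ("shank", (0.015, 0.01))],
        "hip ext knee flx": [("body", (0.03, 0.02)), ("shank", (0.012, -0.01))],
        "hip flx": [("body", (0.025, -0.012)), ("thigh", (0.025, 0.008))],
        "hip flx knee ext": [("body", (0.02, -0.012)), ("thigh", (0.065, 0.012)), ("shank", (0.015, 0.01))],
        "knee ext": [("thigh", (0.02, 0.01)), ("thigh", (0.065, 0.012)), ("shank", (0.015, 0.01))],
        "knee flx ankle ext": [("thigh", (0.06, -0.008)), ("tmt", (0.012, -0.012))],
        "ankle ext": [("shank", (0.03, -0.008)), ("tmt", (0.012, -0.012))],
        "ankle flx": [("shank", (0.04, 0.008)), ("tmt", (0.015, 0.01))],
        "pes dfx": [("tmt", (0.03, 0.008)), ("toes", (0.02, 0.008))],
        "pes pfx": [("tmt", (0.03, -0.008)), ("toes", (0.02, -0.006))],
    }
    wraps = {
        "hip ext": WrapCylinder("thigh", (0.0, 0.0), 0.012, after_point=0),
        "hip ext knee ext": WrapCylinder("shank", (0.0, 0.0), 0.012, after_point=1),
        "hip ext knee flx": WrapCylinder("thigh", (0.0, 0.0), 0.012, after_point=0),
        "hip flx": WrapCylinder("thigh", (0.0, 0.0), 0.010, after_point=0),
        "hip flx knee ext": WrapCylinder("shank", (0.0, 0.0), 0.012, after_point=1),
        "knee ext": WrapCylinder("shank", (0.0, 0.0), 0.012, after_point=1),
        "knee flx ankle ext": WrapCylinder("tmt", (0.0, 0.0), 0.012, after_point=0),
        "ankle ext": WrapCylinder("tmt", (0.0, 0.0), 0.012, after_point=0),
        "ankle flx": WrapCylinder("tmt", (0.0, 0.0), 0.009, after_point=0),
        "pes dfx": WrapCylinder("toes", (0.0, 0.0), 0.007, after_point=0),
        "pes pfx": WrapCylinder("toes", (0.0, 0.0), 0.007, after_point=0),
    }
    actuators = _table_actuators("guineafowl", variant, paths, wraps, vmax=14.0)
    contacts = [
        ContactPoint("toes", (0.005, -0.012), stiffness=8.0e3, damping=60.0, v_ref=0.005),
        ContactPoint("toes", (0.045, -0.012), stiffness=8.0e3, damping=60.0, v_ref=0.005),
        ContactPoint("tmt", (0.068, -0.004), stiffness=8.0e3, damping=60.0, v_ref=0.005),
    ]
    sections = [
        BoneSection("femur", "thigh", (0.035, 0.0), area=2.2e-5, second_moment=6.0e-11, c=0.0031),
        BoneSection("tibiotarsus", "shank", (0.06, 0.0), area=1.8e-5, second_moment=4.0e-11, c=0.0028),
        BoneSection("tarsometatarsus", "tmt", (0.035, 0.0), area=1.5e-5, second_moment=3.0e-11, c=0.0026),
    ]
    model = Model(
        taxon="guineafowl",
        body_mass=M,
        segments=segments,
        joints=joints,
        actuators=actuators,
        contacts=contacts,
        bone_sections=sections,
        starting_pose=dict(POSTURES_GUINEAFOWL["crouched"]),
        base_orientation_deg=_flat_foot_base(POSTURES_GUINEAFOWL["crouched"]),
    )
    model = _finish_model(model)
    model = _apply_variant(model, variant, deeper_pose=POSTURES_GUINEAFOWL["deeper_crouch"])
    model.base_orientation_deg = _flat_foot_base(model.starting_pose)
    return model


def make_toy_jumper(posture: str = "deep_crouch", tendon_genes: bool = False) -> Model:
    """A small human-like 4-segment jumper for optimization experiments.

    Three uniarticular extensor actuators (hip, knee, ankle) are enough to
    jump; the deep-crouch pose sits near the flexion limits (no room to
    countermove), the full-extension pose near the extension limits (a
    jump requires a transient flexion first).  No bone sections: nothing
    is discarded, keeping toy fitness landscapes smooth.
    """
    poses = {
        "deep_crouch": {"hip": 119.0, "knee": -129.0, "ankle": 44.0},
        "full_extension": {"hip": 1.0, "knee": 0.0, "ankle": 3.0},
    }
    if posture not in poses:
        raise ValueError(f"unknown posture {posture!r}")
    segments = [
        Segment("trunk", Shape("cylinder", length=0.30, radius=0.09), density=1000.0, mass=6.0),
        Segment("thigh", Shape("cylinder", length=0.25, radius=0.035), density=1000.0, mass=2.0),
        Segment("shank", Shape("cylinder", length=0.25, radius=0.025), density=1000.0, mass=1.5),
        Segment("foot", Shape("cuboid", length=0.16, width=0.03, depth=0.05), density=1000.0, mass=0.5),
    ]
    joints = [
        Joint("hip", "trunk", "thigh", anchor=(0.0, 0.0), angle_lo=0.0, angle_hi=120.0,
              soft_limit_stiffness=1500.0, soft_limit_damping=40.0, reference_angle_deg=-180.0,
              extension_sign=-1),
        Joint("knee", "thigh", "shank", anchor=(0.25, 0.0), angle_lo=-130.0, angle_hi=3.0,
              soft_limit_stiffness=1500.0, soft_limit_damping=40.0, reference_angle_deg=0.0,
              extension_sign=1),
        Joint("ankle", "shank", "foot", anchor=(0.25, 0.0), angle_lo=0.0, angle_hi=60.0,
              soft_limit_stiffness=1500.0, soft_limit_damping=40.0, reference_angle_deg=90.0,
              extension_sign=-1),
    ]
    mk = lambda name, pts, wrap, fl, pcsa, actions: Actuator(
        name=name,
        path=[PathPoint(s, p) for s, p in pts],
        wrap=wrap,
        fl_mm=fl,
        pcsa_mm2=pcsa,
        vmax_ls=8.4,
        se_strain=0.12,  # compliant toy tendons keep the toy integrable at coarse dt
        fl_width=0.85,  # wide curves let toy fibres work across the whole crouch
        actions=actions,
        region="proximal",
    )
    actuators = [
        mk(
            "hip ext",
            [("trunk", (0.09, 0.05)), ("thigh", (0.10, -0.02))],
            WrapCylinder("thigh", (0.0, 0.0), 0.05, after_point=0),
            200.0,
            4000.0,
            [("hip", "extensor")],
        ),
        mk(
            "knee ext",
            [("thigh", (0.08, 0.03)), ("thigh", (0.22, 0.035)), ("shank", (0.04, 0.03))],
            WrapCylinder("shank", (0.0, 0.0), 0.04, after_point=1),
            160.0,
            3200.0,
            [("knee", "extensor")],
        ),
        mk(
            "ankle ext",
            [("shank", (0.06, -0.02)), ("foot", (-0.03, 0.01))],
            WrapCylinder("foot", (0.0, 0.0), 0.04, after_point=0),
            90.0,
            2200.0,
            [("ankle", "extensor")],
        ),
        # antagonists give the optimizer authority over the countermovement
        mk(
            "hip flx",
            [("trunk", (0.07, -0.04)), ("thigh", (0.08, 0.02))],
            WrapCylinder("thigh", (0.0, 0.0), 0.04, after_point=0),
            160.0,
            2000.0,
            [("hip", "flexor")],
        ),
        mk(
            "knee flx",
            [("thigh", (0.10, -0.025)), ("shank", (0.04, -0.025))],
            WrapCylinder("shank", (0.0, 0.0), 0.035, after_point=0),
            140.0,
            1600.0,
            [("knee", "flexor")],
        ),
        mk(
            "ankle flx",
            [("shank", (0.05, 0.02)), ("foot", (0.04, 0.015))],
            WrapCylinder("foot", (0.0, 0.0), 0.03, after_point=0),
            80.0,
            1100.0,
            [("ankle", "flexor")],
        ),
    ]
    contacts = [
        ContactPoint("foot", (-0.14, -0.05), stiffness=2.0e4, damping=150.0),
        ContactPoint("foot", (0.16, -0.05), stiffness=2.0e4, damping=150.0),
    ]
    # midshaft stress constraints prune whip-kick optimizer exploits the
    # same way the full models discard skeletal failures
    sections = [
        BoneSection("femur", "thigh", (0.125, 0.0), area=1.0e-3,
                    second_moment=9.0e-8, c=0.014),
        BoneSection("tibia", "shank", (0.125, 0.0), area=8.0e-4,
                    second_moment=6.0e-8, c=0.013),
    ]
    model = Model(
        taxon="toy",
        body_mass=10.0,
        segments=segments,
        joints=joints,
        actuators=actuators,
        contacts=contacts,
        bone_sections=sections,
        starting_pose=poses[posture],
        base_orientation_deg=_flat_foot_base(poses[posture]),
    )
    # tendons referenced at a mid-range pose: fibres then pass through
    # optimum mid-extension whichever posture the jump starts from
    model = _finish_model(
        model, reference_pose={"hip": 55.0, "knee": -60.0, "ankle": 5.0}
    )
    if tendon_genes:
        model.actuators = [
            replace(a, tendon_gene_bounds=(0.9, 1.1)) for a in model.actuators
        ]
    return model


# ---------------------------------------------------------------------------
# analytic force/CoM traces
# ---------------------------------------------------------------------------

def synth_trace(
    strategy: str,
    body_mass: float,
    v_takeoff: float,
    quiet: float = 0.5,
    unweight_duration: float = 0.3,
    push_duration: float = 0.3,
    release_duration: float = 0.04,
    unweight_fraction: float = 0.3,
    com_start: float = 1.0,
    dt: float = 5e-5,
    noise_sd: float = 0.0,
    seed: int = 0,
    g: float = 9.81,
    takeoff_epsilon: float = 0.5,
) -> tuple[pd.DataFrame, JumpMetrics]:
    """Piecewise-sinusoidal jump trace with closed-form ground truth.

    The vertical force profile is quiet standing at body weight, an
    optional unweighting dip (CMJ only, amplitude ``unweight_fraction`` of
    BW), a push-off hump scaled to hit the target take-off velocity, a
    smooth force release to zero, and a ballistic flight past the apex.
    The CoM trace is the exact double integral of the noise-free profile;
    Gaussian noise with the given seed is added to the force only.  The
    returned metrics are computed analytically from the construction, so
    they serve as an independent oracle for the metrics module.  Because
    take-off is operationally the first instant the force reaches the
    small ``takeoff_epsilon`` rather than exact zero, the take-off-state
    ground truths are evaluated at the analytic epsilon-crossing (the
    apex is crossing-invariant); the default 20 kHz sampling keeps the
    sub-sample residual well below the 1e-3 recovery target.

    A target ``v_takeoff <= 0`` builds a grounded bump with no flight
    phase (exercising the no-takeoff error path downstream).
    """
    if strategy not in ("CMJ", "SJ"):
        raise ValueError("strategy must be CMJ or SJ")
    if body_mass <= 0:
        raise ValueError("body mass must be positive")
    m = body_mass
    bw = m * g
    tau_u = unweight_duration if strategy == "CMJ" else 0.0
    tau_p = push_duration
    tau_r = release_duration
    B = unweight_fraction * bw if strategy == "CMJ" else 0.0
    if B >= bw:
        raise ValueError("unweighting amplitude must stay below body weight")

    grounded = v_takeoff <= 0.0
    v_u = -2.0 * B * tau_u / (math.pi * m)  # velocity after unweighting
    if grounded:
        A_p = 0.2 * bw
        tau_r = 0.0
    else:
        A_p = math.pi * m * (v_takeoff + g * tau_r / 2.0 - v_u) / (2.0 * tau_p)
        if A_p <= 0.05 * bw:
            raise ValueError(
                "target take-off velocity too low for a detectable push phase"
            )

    # closed-form phase boundary states
    z_u = com_start - (B / m) * (tau_u / math.pi) * tau_u  # end of unweighting
    v_p = v_u + 2.0 * A_p * tau_p / (math.pi * m)
    z_p = z_u + v_u * tau_p + (A_p / m) * (tau_p / math.pi) * tau_p
    v_to = v_p - g * tau_r / 2.0
    z_to = (
        z_p
        + v_p * tau_r
        + (g / 2.0) * ((tau_r / math.pi) ** 2 * 2.0 - tau_r**2 / 2.0)
    )
    flight = 0.0 if grounded else 2.0 * v_to / g + 0.1

    t_u0 = quiet
    t_p0 = quiet + tau_u
    t_r0 = t_p0 + tau_p
    t_to = t_r0 + tau_r
    t_end = t_to + flight + (0.3 if grounded else 0.0)

    n = int(round(t_end / dt)) + 1
    t = np.arange(n) * dt
    fz = np.full(n, bw)
    z = np.full(n, com_start)

    if strategy == "CMJ":
        s = (t >= t_u0) & (t < t_p0)
        tt = t[s] - t_u0
        fz[s] = bw - B * np.sin(math.pi * tt / tau_u)
        z[s] = com_start - (B / m) * (tau_u / math.pi) * (
            tt - (tau_u / math.pi) * np.sin(math.pi * tt / tau_u)
        )
    s = (t >= t_p0) & (t < t_r0)
    tt = t[s] - t_p0
    fz[s] = bw + A_p * np.sin(math.pi * tt / tau_p)
    z[s] = (
        z_u
        + v_u * tt
        + (A_p / m) * (tau_p / math.pi) * (tt - (tau_p / math.pi) * np.sin(math.pi * tt / tau_p))
    )
    if not grounded:
        s = (t >= t_r0) & (t < t_to)
        tt = t[s] - t_r0
        fz[s] = bw * (1.0 + np.cos(math.pi * tt / tau_r)) / 2.0
        z[s] = (
            z_p
            + v_p * tt
            + (g / 2.0)
            * ((tau_r / math.pi) ** 2 * (1.0 - np.cos(math.pi * tt / tau_r)) - tt**2 / 2.0)
        )
        s = t >= t_to
        tt = t[s] - t_to
        fz[s] = 0.0
        z[s] = z_to + v_to * tt - 0.5 * g * tt**2
    else:
        s = t >= t_r0
        fz[s] = bw
        z[s] = z_p + v_p * (t[s] - t_r0)  # grounded bump: residual drift only

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        fz = fz + rng.normal(0.0, noise_sd, n)

    df = pd.DataFrame({"time": t, "fz": fz, "com_z": z})

    # analytic ground truth
    thr = 0.05 * bw
    if strategy == "CMJ":
        t_start = t_u0 + (tau_u / math.pi) * math.asin(min(1.0, thr / B))
    else:
        t_start = t_p0 + (tau_p / math.pi) * math.asin(min(1.0, thr / A_p))
    # take-off state at the analytic epsilon-crossing of the release
    if not grounded:
        x_eps = math.acos(max(-1.0, 2.0 * takeoff_epsilon / bw - 1.0))
        t_eps = (tau_r / math.pi) * x_eps
        v_eps = v_p + (g / 2.0) * ((tau_r / math.pi) * math.sin(math.pi * t_eps / tau_r) - t_eps)
        z_eps = (
            z_p
            + v_p * t_eps
            + (g / 2.0)
            * ((tau_r / math.pi) ** 2 * (1.0 - math.cos(math.pi * t_eps / tau_r)) - t_eps**2 / 2.0)
        )
        t_to_eps = t_r0 + t_eps
    else:
        v_eps, z_eps, t_to_eps = 0.0, z_p, t_r0
    if strategy == "CMJ" and not grounded:
        c = 1.0 + v_u * math.pi * m / (A_p * tau_p)
        t_low = t_p0 + (tau_p / math.pi) * math.acos(min(1.0, max(-1.0, c)))
        z_low = (
            z_u
            + v_u * (t_low - t_p0)
            + (A_p / m)
            * (tau_p / math.pi)
            * ((t_low - t_p0) - (tau_p / math.pi) * math.sin(math.pi * (t_low - t_p0) / tau_p))
        )
        v_low = 0.0
    else:
        t_low = t_start
        tt = t_start - t_p0
        z_low = z_u + v_u * tt + (A_p / m) * (tau_p / math.pi) * (
            tt - (tau_p / math.pi) * math.sin(math.pi * tt / tau_p)
        )
        v_low = v_u + (A_p / m) * (tau_p / math.pi) * (1.0 - math.cos(math.pi * tt / tau_p))
    truth = JumpMetrics(
        max_com_height=z_to + v_to**2 / (2.0 * g) if not grounded else com_start,
        concentric_distance=z_eps - z_low if not grounded else 0.0,
        takeoff_velocity=v_eps if not grounded else 0.0,
        contact_time=t_to_eps - t_start if not grounded else 0.0,
        rnvi=v_eps - v_low if not grounded else 0.0,
        strategy=strategy,
    )
    return df, truth
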