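"""Muscle architecture reconstruction.

Three routes to per-actuator force capacity are implemented, mirroring the
levels of certainty available when modelling living versus fossil taxa:

1. measured muscle masses converted to PCSA (mass / density / fibre length);
2. schematic partitioning of a whole-limb muscle mass budget across joints
   and actions;
3. regression prediction of mass or PCSA from bone/attachment areas.

Fibre lengths follow the range-of-motion (RoM) convention: the fibre is
assumed to work across the actuator's full path-length excursion over the
admissible joint range, so FL equals that excursion.  Tendon slack length
is whatever is left of the reference-pose path once the fibre is laid in.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np

from .model import Actuator, Model, forward_kinematics, world_point
from ._pathgeom import wrap_segment_length

__all__ = [
    "DomainError",
    "AllocationError",
    "PartitionScheme",
    "RegressionSpec",
    "ReconConfig",
    "MUSCLE_DENSITY",
    "pcsa_from_mass",
    "mass_from_pcsa",
    "path_length_m",
    "fibre_length_rom",
    "tendon_length_from_reference",
    "compute_tendon_length",
    "apply_fibre_tuning",
    "partition_masses_schematic",
    "predict_regression",
    "load_regression_specs",
    "joint_extensor_totals",
    "round_half_away",
    "ZeroExcursionWarning",
]

log = logging.getLogger(__name__)

#: default vertebrate skeletal muscle density, kg m^-3
MUSCLE_DENSITY = 1056.0


class DomainError(ValueError):
    """An input is outside the physically meaningful domain."""


class AllocationError(ValueError):
    """A partition pool has no actuator to receive its mass."""


class ZeroExcursionWarning(UserWarning):
    pass


# ---------------------------------------------------------------------------
# mass <-> PCSA
# ---------------------------------------------------------------------------

def pcsa_from_mass(mass_kg: float, fl_mm: float, density: float = MUSCLE_DENSITY) -> float:
    """PCSA (mm^2) = muscle volume / fibre length.

    Volume is mass / density; the inverse relation
    ``mass = pcsa * fl * density`` holds exactly.
    """
    if mass_kg <= 0 or fl_mm <= 0 or density <= 0:
        raise DomainError(
            f"mass, fibre length and density must be positive "
            f"(got {mass_kg}, {fl_mm}, {density})"
        )
    volume_mm3 = mass_kg / density * 1e9
    return volume_mm3 / fl_mm


def mass_from_pcsa(pcsa_mm2: float, fl_mm: float, density: float = MUSCLE_DENSITY) -> float:
    """Inverse of :func:`pcsa_from_mass` (kg)."""
    if pcsa_mm2 < 0 or fl_mm <= 0 or density <= 0:
        raise DomainError("pcsa must be >= 0 and fl, density positive")
    return pcsa_mm2 * fl_mm * density * 1e-9


# ---------------------------------------------------------------------------
# path lengths, RoM fibre lengths, tendons
# ---------------------------------------------------------------------------

def path_length_m(model: Model, actuator: Actuator, pose_deg: Optional[dict] = None) -> float:
    """Total actuator path length (m) at a pose, including any wrap."""
    fk = forward_kinematics(model, pose_deg)
    pts = [world_point(fk, p.segment, p.pos) for p in actuator.path]
    total = 0.0
    for i in range(len(pts) - 1):
        p1, p2 = pts[i], pts[i + 1]
        w = actuator.wrap
        if w is not None and w.after_point == i:
            c = world_point(fk, w.segment, w.center)
            length, _, _, _, _, _ = wrap_segment_length(
                p1[0], p1[1], p2[0], p2[1], c[0], c[1], w.radius, w.side
            )
            total += length
        else:
            total += float(np.hypot(p2[0] - p1[0], p2[1] - p1[1]))
    return total


def fibre_length_rom(
    model: Model,
    actuator: Actuator,
    resolution_deg: float = 1.0,
    joints: Optional[Sequence[str]] = None,
    fl_floor_mm: float = 1.0,
) -> float:
    """Fibre length (mm) as the path-length excursion over the joint range.

    The admissible range of every joint the actuator acts on is scanned on a
    regular grid (default 1 degree per joint; all combinations for
    multi-joint actuators); FL is the difference between the longest and
    shortest path.  An actuator whose path never changes raises a
    zero-excursion warning and receives the configured floor length.
    """
    if resolution_deg <= 0:
        raise DomainError("resolution must be positive")
    names = list(joints) if joints is not None else actuator.action_joints
    if not names:
        warnings.warn(
            f"actuator {actuator.name!r} crosses no joint; FL floored",
            ZeroExcursionWarning,
        )
        return fl_floor_mm
    grids = []
    for name in names:
        j = model.joint(name)
        n = max(2, int(round((j.angle_hi - j.angle_lo) / resolution_deg)) + 1)
        grids.append(np.linspace(j.angle_lo, j.angle_hi, n))
    lo = math.inf
    hi = -math.inf
    for combo in itertools.product(*grids):
        pose = dict(zip(names, combo))
        L = path_length_m(model, actuator, pose)
        lo = min(lo, L)
        hi = max(hi, L)
    fl = (hi - lo) * 1000.0
    if fl < fl_floor_mm:
        warnings.warn(
            f"actuator {actuator.name!r}: path excursion {fl:.3g} mm below floor",
            ZeroExcursionWarning,
        )
        return fl_floor_mm
    return fl


def tendon_length_from_reference(reference_length_mm: float, fl_mm: float) -> float:
    """Tendon slack length: reference-pose path length minus fibre length.

    Clamped at zero (a fibre longer than the whole path leaves no tendon).
    """
    if reference_length_mm <= 0:
        raise DomainError("reference path length must be positive")
    tl = reference_length_mm - fl_mm
    if tl < 0:
        log.info(
            "tendon length clamped to 0 (reference %.2f mm < FL %.2f mm)",
            reference_length_mm,
            fl_mm,
        )
        return 0.0
    return tl


def compute_tendon_length(
    model: Model, actuator: Actuator, reference_pose: Optional[dict] = None
) -> float:
    """Tendon length (mm) from the actuator path at a reference pose."""
    ref_mm = path_length_m(model, actuator, reference_pose) * 1000.0
    return tendon_length_from_reference(ref_mm, actuator.fl_mm)


def apply_fibre_tuning(actuator: Actuator, factor: float) -> Actuator:
    """Rescale fibre length by ``factor`` at constant muscle volume.

    PCSA divides by the factor (volume = PCSA x FL is conserved) and the
    tendon absorbs the length change: TL' = max(0, TL + FL - FL').
    """
    if factor <= 0:
        raise DomainError("tuning factor must be positive")
    fl = actuator.fl_mm * factor
    pcsa = actuator.pcsa_mm2 / factor
    tl = max(0.0, actuator.tl_mm + actuator.fl_mm - fl)
    return replace(actuator, fl_mm=fl, pcsa_mm2=pcsa, tl_mm=tl)


# ---------------------------------------------------------------------------
# schematic partitioning (whole-limb mass budget)
# ---------------------------------------------------------------------------

@dataclass
class PartitionScheme:
    """Schematic limb-muscle budget for striding bipeds.

    35% of body mass is limb muscle (both limbs), split 40/30/20/10 across
    hip, knee, ankle and TMTP, then 65:35 between extensors (including
    plantarflexors) and flexors at each joint, and finally equally among the
    actuators of each (joint, action) pool.
    """

    total_limb_fraction: float = 0.35
    joint_fractions: dict[str, float] = field(
        default_factory=lambda: {"hip": 0.40, "knee": 0.30, "ankle": 0.20, "tmtp": 0.10}
    )
    extensor_fraction: float = 0.65
    flexor_fraction: float = 0.35
    biarticular_policy: str = "sum-of-joint-shares"
    missing_joint_policy: str = "drop"

    def __post_init__(self) -> None:
        if not math.isclose(self.extensor_fraction + self.flexor_fraction, 1.0):
            raise DomainError("extensor_fraction + flexor_fraction must equal 1")
        if self.biarticular_policy not in ("sum-of-joint-shares", "equal-within-action"):
            raise DomainError(f"unknown biarticular policy {self.biarticular_policy!r}")
        if self.missing_joint_policy not in ("drop", "renormalize"):
            raise DomainError(f"unknown missing-joint policy {self.missing_joint_policy!r}")


def _actions_of(actuators) -> dict[str, list[tuple[str, str]]]:
    if isinstance(actuators, Mapping):
        return {k: list(v) for k, v in actuators.items()}
    return {a.name: list(a.actions) for a in actuators}


def partition_masses_schematic(
    body_mass: float, scheme: PartitionScheme, actuators
) -> dict[str, float]:
    """Allocate the schematic limb muscle budget to actuators (kg per limb).

    ``actuators`` is either a mapping name -> [(joint, action), ...] or a
    sequence of :class:`~jumpsim.model.Actuator`.  Under the default
    sum-of-joint-shares policy a biarticular actuator receives its equal
    share from every pool it belongs to and the per-limb budget is conserved
    exactly; under equal-within-action each actuator's pooled take is
    down-weighted by its number of pools.
    """
    if body_mass <= 0:
        raise DomainError("body mass must be positive")
    actions = _actions_of(actuators)
    per_limb = body_mass * scheme.total_limb_fraction / 2.0

    joints_present = {j for acts in actions.values() for j, _ in acts}
    fractions = {
        j: f for j, f in scheme.joint_fractions.items() if j in joints_present
    }
    missing = set(scheme.joint_fractions) - joints_present
    if missing and scheme.missing_joint_policy == "renormalize":
        total = sum(fractions.values())
        if total <= 0:
            raise AllocationError("no joint fraction left after dropping missing joints")
        fractions = {j: f / total for j, f in fractions.items()}

    kind_fraction = {
        "extensor": scheme.extensor_fraction,
        "flexor": scheme.flexor_fraction,
    }
    # pool membership
    pools: dict[tuple[str, str], list[str]] = {}
    for name, acts in actions.items():
        for joint, kind in acts:
            pools.setdefault((joint, kind), []).append(name)

    masses = {name: 0.0 for name in actions}
    for joint, jf in fractions.items():
        for kind, kf in kind_fraction.items():
            members = pools.get((joint, kind), [])
            pool_mass = per_limb * jf * kf
            if pool_mass == 0:
                continue
            if not members:
                raise AllocationError(
                    f"pool ({joint}, {kind}) holds {pool_mass:.4f} kg but has no actuator"
                )
            for name in members:
                share = pool_mass / len(members)
                if scheme.biarticular_policy == "equal-within-action":
                    share /= max(1, len(actions[name]))
                masses[name] += share
    return masses


# ---------------------------------------------------------------------------
# regression prediction (fossil-style scaling equations)
# ---------------------------------------------------------------------------

@dataclass
class RegressionSpec:
    """One predictive scaling equation: response against a bone area (mm^2).

    With ``log10=True`` (the usual allometric form) the response is
    ``10 ** (intercept + slope * log10(area))``; otherwise it is linear.
    The coefficients are user-supplied data.
    """

    intercept: Optional[float]
    slope: Optional[float]
    response: str = "mass"  # "mass" (kg) | "pcsa" (mm^2)
    log10: bool = True


def load_regression_specs(path) -> dict[str, RegressionSpec]:
    """Read per-actuator scaling coefficients from a delimited text file.

    Expected columns: actuator, intercept, slope, and optionally response
    (mass|pcsa) and log10 (true/false).  Lines starting with '#' are
    comments.
    """
    import pandas as pd

    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    for col in ("actuator", "intercept", "slope"):
        if col not in df.columns:
            raise DomainError(f"regression file missing column {col!r}")
    out = {}
    for _, r in df.iterrows():
        log = r.get("log10", True)
        if isinstance(log, str):
            log = log.strip().lower() in ("1", "true", "yes")
        out[r["actuator"]] = RegressionSpec(
            intercept=float(r["intercept"]),
            slope=float(r["slope"]),
            response=str(r.get("response", "mass")),
            log10=bool(log),
        )
    return out


def predict_regression(area_mm2: float, spec: RegressionSpec) -> float:
    if spec.intercept is None or spec.slope is None:
        raise DomainError("regression spec is missing coefficients")
    if area_mm2 <= 0:
        raise DomainError(f"predictor area must be positive, got {area_mm2}")
    if spec.log10:
        return 10.0 ** (spec.intercept + spec.slope * math.log10(area_mm2))
    return spec.intercept + spec.slope * area_mm2


@dataclass
class ReconConfig:
    muscle_density: float = MUSCLE_DENSITY
    tuning_factor: float = 1.0
    reference_pose: Optional[dict[str, float]] = None

    def __post_init__(self) -> None:
        if self.muscle_density <= 0 or self.tuning_factor <= 0:
            raise DomainError("density and tuning factor must be positive")


# ---------------------------------------------------------------------------
# extensor aggregation tables
# ---------------------------------------------------------------------------

def round_half_away(x: float) -> int:
    """Round to the nearest integer with halves going away from zero."""
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


def joint_extensor_totals(actuators: Sequence[Actuator]) -> dict:
    """Summed extensor PCSA per joint, in total, and as integer percents.

    A biarticular extensor contributes its full PCSA to every joint it
    extends, but is counted exactly once in the grand extensor total.
    Percentages are extensor/total PCSA and joint/extensor-total shares,
    rounded half away from zero as in the comparative tables.
    """
    pcsa_tot = sum(a.pcsa_mm2 for a in actuators)
    joint_totals: dict[str, float] = {}
    ext_tot = 0.0
    for a in actuators:
        ext_joints = [j for j, kind in a.actions if kind == "extensor"]
        if ext_joints:
            ext_tot += a.pcsa_mm2
        for j in ext_joints:
            joint_totals[j] = joint_totals.get(j, 0.0) + a.pcsa_mm2
    out = {
        "pcsa_tot": pcsa_tot,
        "ext_tot": ext_tot,
        "joint_totals": joint_totals,
        "ext_pct": round_half_away(100.0 * ext_tot / pcsa_tot) if pcsa_tot else 0,
        "joint_pct": {
            j: round_half_away(100.0 * v / ext_tot) if ext_tot else 0
            for j, v in joint_totals.items()
        },
    }
    return out
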