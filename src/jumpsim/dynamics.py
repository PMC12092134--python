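"""Planar forward-dynamics engine.

The model tree is integrated in generalized coordinates
``q = [x, z, phi, theta_1 .. theta_nj]`` — floating-base position and
orientation plus one anatomical hinge angle (radians) per joint.  Mass
matrix and bias forces are assembled from point Jacobians each step (for a
point P on segment i, ``dP/dtheta_j = s_j * perp(P - hinge_j)`` whenever
joint j lies between the root and segment i), and the equations of motion
``M(q) qdd + h(q, qd) = Q`` are solved by a small Cholesky factorisation.

Muscles are Hill-type: an active contractile element (CE) with quadratic
force-length and hyperbolic force-velocity curves, a linear parallel
elastic element (PE) and a linear series elastic element (SE, the tendon).
The CE length is a state variable advanced by inverting the force-velocity
relation so that CE+PE force equilibrates the SE force each step
(activation acts instantaneously).  Muscle tension enters the skeleton as
the generalized force ``-T dL/dq`` where L is the path length.

Ground contacts are unilateral spring-dampers with a smoothed Coulomb
friction bound; joint limits engage a spring-damper torque only outside
the admissible range.  Midshaft bone stress is recovered by a backward
Newton-Euler pass and combines axial and bending terms
(``|F|/A + |M| c / I``); exceeding the failure stress aborts the
simulation with a flag so optimizers can discard the solution.

The inner loop is compiled with numba; a fixed-step semi-implicit
(symplectic) Euler integrator is the default, with classical RK4
available for high-accuracy checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from numba import njit

from .model import (
    Actuator,
    BoneSection,
    ContactPoint,
    Joint,
    Model,
    forward_kinematics,
    world_point,
)
from .muscles import path_length_m
from ._pathgeom import wrap_segment_length

__all__ = [
    "HillParams",
    "Trajectory",
    "SimulationError",
    "hill_force",
    "force_length",
    "force_velocity",
    "joint_limit_torque",
    "contact_force",
    "bone_stress",
    "simulate",
    "constant_activation",
]

DEFAULT_DT = 1e-4  # s; stiff contacts demand small fixed steps
DEFAULT_OUTPUT_DT = 1e-3


class SimulationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Hill-type muscle curves (reference scalar implementations)
# ---------------------------------------------------------------------------

@dataclass
class HillParams:
    """Parameters of one Hill-type muscle-tendon unit.

    ``f_max`` is sigma_max x PCSA.  ``fv_shape`` is the Hill hyperbola's
    a/F0 ratio; ``fl_width`` the half-width of the quadratic force-length
    curve as a fraction of optimal CE length; ``se_strain_at_fmax`` the
    tendon strain at maximum isometric force; ``pe_stiffness`` the parallel
    element stiffness in N per unit CE strain beyond ``pe_engage_strain``.
    """

    f_max: float
    l_opt_mm: float
    vmax_ls: float
    tl_mm: float = 0.0
    fv_shape: float = 0.25
    fl_width: float = 0.5
    se_strain_at_fmax: float = 0.04
    #: CE strain beyond L_opt where the parallel element engages
    pe_engage_strain: float = 0.2
    #: N per unit CE strain beyond engagement; default 2 f_max reaches
    #: ~0.5 f_max of passive force at 45% stretch, a conventional shape
    pe_stiffness: Optional[float] = None

    def __post_init__(self) -> None:
        if self.pe_stiffness is None:
            self.pe_stiffness = 2.0 * self.f_max

    @classmethod
    def from_actuator(cls, a: Actuator, **kw) -> "HillParams":
        return cls(
            f_max=a.f_max, l_opt_mm=a.fl_mm, vmax_ls=a.vmax_ls, tl_mm=a.tl_mm, **kw
        )


def force_length(l_ce_mm: float, l_opt_mm: float, width: float = 0.5) -> float:
    """Quadratic active force-length factor, 1 at L_opt, 0 at +/-width*L_opt."""
    x = (l_ce_mm - l_opt_mm) / (width * l_opt_mm)
    return max(0.0, 1.0 - x * x)


def force_velocity(v_ls: float, vmax_ls: float, shape: float = 0.25) -> float:
    """Hill hyperbola; v positive shortening, clamped to 0 beyond vmax.

    Lengthening (v < 0) sits on a plateau at 1 (no eccentric enhancement).
    """
    if v_ls <= 0.0:
        return 1.0
    if v_ls >= vmax_ls:
        return 0.0
    return (1.0 - v_ls / vmax_ls) / (1.0 + v_ls / (shape * vmax_ls))


def hill_force(p: HillParams, activation: float, l_ce_mm: float, v_ce_ls: float) -> float:
    """CE + PE force (N) of the muscle at a given state.

    ``activation`` in [0, 1]; ``v_ce_ls`` positive shortening in fibre
    lengths per second.  The series element is not part of this call: in a
    simulation the SE force equals this value by construction of the CE
    velocity (series equilibrium).
    """
    if not 0.0 <= activation <= 1.0:
        raise ValueError(f"activation must lie in [0, 1], got {activation}")
    f_act = (
        activation
        * p.f_max
        * force_length(l_ce_mm, p.l_opt_mm, p.fl_width)
        * force_velocity(v_ce_ls, p.vmax_ls, p.fv_shape)
    )
    strain = l_ce_mm / p.l_opt_mm - 1.0
    f_pe = p.pe_stiffness * max(0.0, strain - p.pe_engage_strain)
    return f_act + f_pe


def joint_limit_torque(angle_deg: float, rate_rad_s: float, joint: Joint) -> float:
    """Soft-limit torque (N m) in the anatomical joint coordinate.

    Zero inside [angle_lo, angle_hi]; outside, a spring pulls back toward
    the range and the damper opposes motion while in violation.
    """
    if angle_deg > joint.angle_hi:
        viol = math.radians(angle_deg - joint.angle_hi)
        return -joint.soft_limit_stiffness * viol - joint.soft_limit_damping * rate_rad_s
    if angle_deg < joint.angle_lo:
        viol = math.radians(joint.angle_lo - angle_deg)
        return joint.soft_limit_stiffness * viol - joint.soft_limit_damping * rate_rad_s
    return 0.0


def contact_force(
    height_m: float, v_z: float, v_x: float, cp: ContactPoint
) -> tuple[float, float]:
    """Unilateral spring-damper normal force and smoothed Coulomb friction.

    Returns ``(Fz, Fx)``; Fz is clamped at zero so damping can never pull
    the foot down (no adhesion), and Fx is bounded by mu * Fz.
    """
    pen = -height_m
    if pen <= 0.0:
        return 0.0, 0.0
    fz = cp.stiffness * pen - cp.damping * v_z
    if fz <= 0.0:
        return 0.0, 0.0
    fx = -cp.friction_mu * fz * math.tanh(v_x / cp.v_ref)
    return fz, fx


def bone_stress(axial_n: float, moment_nm: float, section: BoneSection) -> float:
    """Peak compressive midshaft stress (Pa): |F|/A + |M| c / I."""
    return abs(axial_n) / section.area + abs(moment_nm) * section.c / section.second_moment


# ---------------------------------------------------------------------------
# model compilation to flat arrays
# ---------------------------------------------------------------------------

def _compile_model(model: Model, gravity: float):
    seg_names = [s.name for s in model.segments]
    root = model.root
    # topological order, root first
    order = [root]
    children: dict[str, list[Joint]] = {}
    for j in model.joints:
        children.setdefault(j.parent, []).append(j)
    jt_order: list[Joint] = []
    i = 0
    while i < len(order):
        for j in children.get(order[i], ()):
            jt_order.append(j)
            order.append(j.child)
        i += 1
    if len(order) != len(model.segments):
        raise SimulationError("segment tree is disconnected")
    seg_idx = {n: k for k, n in enumerate(order)}
    jnt_idx = {j.name: k for k, j in enumerate(jt_order)}
    nseg, nj = len(order), len(jt_order)

    parent = np.full(nseg, -1, dtype=np.int64)
    jof = np.full(nseg, -1, dtype=np.int64)  # joint whose child is this segment
    for k, j in enumerate(jt_order):
        parent[seg_idx[j.child]] = seg_idx[j.parent]
        jof[seg_idx[j.child]] = k

    anc = np.zeros((nseg, max(nj, 1)), dtype=np.int8)
    for si in range(nseg):
        cur = si
        while parent[cur] >= 0:
            anc[si, jof[cur]] = 1
            cur = parent[cur]

    segs = [model.segment(n) for n in order]
    seg_mass = np.array([s.mass for s in segs])
    seg_inertia = np.array([s.moi for s in segs])
    seg_com = np.array([[s.com_offset, 0.0] for s in segs])

    jnt_parent = np.array([seg_idx[j.parent] for j in jt_order], dtype=np.int64)
    jnt_child = np.array([seg_idx[j.child] for j in jt_order], dtype=np.int64)
    jnt_anchor = np.array([list(j.anchor) for j in jt_order]) if nj else np.zeros((0, 2))
    jnt_sign = np.array([float(j.sign) for j in jt_order])
    jnt_ref = np.array([math.radians(j.reference_angle_deg) for j in jt_order])
    jnt_lo = np.array([math.radians(j.angle_lo) for j in jt_order])
    jnt_hi = np.array([math.radians(j.angle_hi) for j in jt_order])
    jnt_k = np.array([j.soft_limit_stiffness for j in jt_order])
    jnt_c = np.array([j.soft_limit_damping for j in jt_order])

    nc = len(model.contacts)
    con_seg = np.array([seg_idx[c.segment] for c in model.contacts], dtype=np.int64)
    con_local = (
        np.array([list(c.local_pos) for c in model.contacts]) if nc else np.zeros((0, 2))
    )
    con_k = np.array([c.stiffness for c in model.contacts])
    con_c = np.array([c.damping for c in model.contacts])
    con_mu = np.array([c.friction_mu for c in model.contacts])
    con_vref = np.array([c.v_ref for c in model.contacts])

    nm = len(model.actuators)
    pt_start = np.zeros(nm + 1, dtype=np.int64)
    pt_seg_l: list[int] = []
    pt_loc_l: list[list[float]] = []
    wrap_seg = np.full(max(nm, 1), -1, dtype=np.int64)
    wrap_center = np.zeros((max(nm, 1), 2))
    wrap_radius = np.zeros(max(nm, 1))
    wrap_side = np.ones(max(nm, 1))
    wrap_after = np.zeros(max(nm, 1), dtype=np.int64)
    for mi, a in enumerate(model.actuators):
        for p in a.path:
            pt_seg_l.append(seg_idx[p.segment])
            pt_loc_l.append(list(p.pos))
        pt_start[mi + 1] = len(pt_seg_l)
        if a.wrap is not None:
            wrap_seg[mi] = seg_idx[a.wrap.segment]
            wrap_center[mi] = a.wrap.center
            wrap_radius[mi] = a.wrap.radius
            wrap_side[mi] = float(a.wrap.side)
            wrap_after[mi] = a.wrap.after_point
    pt_seg = np.array(pt_seg_l, dtype=np.int64) if pt_seg_l else np.zeros(0, dtype=np.int64)
    pt_loc = np.array(pt_loc_l) if pt_loc_l else np.zeros((0, 2))

    hills = [
        HillParams.from_actuator(a, se_strain_at_fmax=a.se_strain, fl_width=a.fl_width)
        for a in model.actuators
    ]
    mus_fmax = np.array([h.f_max for h in hills]) if nm else np.zeros(0)
    mus_lopt = np.array([h.l_opt_mm * 1e-3 for h in hills]) if nm else np.zeros(0)
    mus_vmax = mus_lopt * np.array([h.vmax_ls for h in hills]) if nm else np.zeros(0)
    # tendon slack floored so the series element stays well-posed, and its
    # stiffness floored on a fraction of L_opt so a near-zero slack length
    # cannot produce an arbitrarily stiff (unintegrable) spring
    mus_tl = (
        np.array([max(h.tl_mm, 0.02 * h.l_opt_mm, 1.0) * 1e-3 for h in hills])
        if nm
        else np.zeros(0)
    )
    mus_sek = (
        np.array(
            [
                h.f_max
                / (h.se_strain_at_fmax * max(tl, 0.05 * h.l_opt_mm * 1e-3))
                for h, tl in zip(hills, mus_tl)
            ]
        )
        if nm
        else np.zeros(0)
    )
    mus_ah = np.array([h.fv_shape for h in hills]) if nm else np.zeros(0)
    mus_flw = np.array([h.fl_width for h in hills]) if nm else np.zeros(0)
    mus_pek = (
        np.array([h.pe_stiffness / lo for h, lo in zip(hills, mus_lopt)])
        if nm
        else np.zeros(0)
    )  # N per metre of CE stretch beyond engagement
    mus_peng = (
        np.array([lo * (1.0 + h.pe_engage_strain) for h, lo in zip(hills, mus_lopt)])
        if nm
        else np.zeros(0)
    )

    ns = len(model.bone_sections)
    bs_seg = np.array([seg_idx[b.segment] for b in model.bone_sections], dtype=np.int64)
    bs_local = (
        np.array([list(b.local_pos) for b in model.bone_sections])
        if ns
        else np.zeros((0, 2))
    )
    bs_area = np.array([b.area for b in model.bone_sections])
    bs_imom = np.array([b.second_moment for b in model.bone_sections])
    bs_cdist = np.array([b.c for b in model.bone_sections])
    bs_fail = np.array([b.failure_stress for b in model.bone_sections])

    mdl = (
        parent,
        anc,
        jnt_parent,
        jnt_child,
        jnt_anchor,
        jnt_sign,
        jnt_ref,
        jnt_lo,
        jnt_hi,
        jnt_k,
        jnt_c,
        seg_mass,
        seg_inertia,
        seg_com,
        con_seg,
        con_local,
        con_k,
        con_c,
        con_mu,
        con_vref,
        pt_start,
        pt_seg,
        pt_loc,
        wrap_seg,
        wrap_center,
        wrap_radius,
        wrap_side,
        wrap_after,
        mus_fmax,
        mus_lopt,
        mus_vmax,
        mus_tl,
        mus_sek,
        mus_ah,
        mus_flw,
        mus_pek,
        mus_peng,
        bs_seg,
        bs_local,
        bs_area,
        bs_imom,
        bs_cdist,
        bs_fail,
        np.int64(1 if model.base_fixed else 0),
        float(gravity),
    )
    meta = {
        "order": order,
        "seg_idx": seg_idx,
        "jnt_order": [j.name for j in jt_order],
        "jnt_idx": jnt_idx,
    }
    return mdl, meta


# ---------------------------------------------------------------------------
# compiled core
# ---------------------------------------------------------------------------

@njit(cache=False)
def _chol_solve(M, b, x, n):
    # in-place Cholesky of M (destroyed), solve M x = b
    for k in range(n):
        s = M[k, k]
        for t in range(k):
            s -= M[k, t] * M[k, t]
        if s < 1e-12:
            s = 1e-12
        M[k, k] = math.sqrt(s)
        for i in range(k + 1, n):
            s2 = M[i, k]
            for t in range(k):
                s2 -= M[i, t] * M[k, t]
            M[i, k] = s2 / M[k, k]
    for i in range(n):
        s = b[i]
        for t in range(i):
            s -= M[i, t] * x[t]
        x[i] = s / M[i, i]
    for i in range(n - 1, -1, -1):
        s = x[i]
        for t in range(i + 1, n):
            s -= M[t, i] * x[t]
        x[i] = s / M[i, i]


@njit(cache=False)
def _eval(
    mdl,
    q,
    v,
    lce,
    t,
    dt,
    act_times,
    act_levels,
    qdd,
    lcedot,
    diag,
    mdiag,
    sdiag,
    scr,
):
    (
        parent,
        anc,
        jnt_parent,
        jnt_child,
        jnt_anchor,
        jnt_sign,
        jnt_ref,
        jnt_lo,
        jnt_hi,
        jnt_k,
        jnt_c,
        seg_mass,
        seg_inertia,
        seg_com,
        con_seg,
        con_local,
        con_k,
        con_c,
        con_mu,
        con_vref,
        pt_start,
        pt_seg,
        pt_loc,
        wrap_seg,
        wrap_center,
        wrap_radius,
        wrap_side,
        wrap_after,
        mus_fmax,
        mus_lopt,
        mus_vmax,
        mus_tl,
        mus_sek,
        mus_ah,
        mus_flw,
        mus_pek,
        mus_peng,
        bs_seg,
        bs_local,
        bs_area,
        bs_imom,
        bs_cdist,
        bs_fail,
        base_fixed,
        gravity,
    ) = mdl
    (
        origin,
        ang,
        wrate,
        ovel,
        obias,
        jpos,
        compos,
        comvel,
        combias,
        Jv,
        wrow,
        Mmat,
        Qvec,
        hvec,
        appF,
        appM,
        Rf,
        Rm,
        Jp,
        dl,
        ptbuf,
        ptjac,
        Mwork,
    ) = scr

    nseg = seg_mass.shape[0]
    nj = jnt_sign.shape[0]
    nq = 3 + nj
    nm = mus_fmax.shape[0]
    nc = con_seg.shape[0]
    ns = bs_seg.shape[0]

    # ---- kinematics (root-first order == array order) ----
    origin[0, 0] = q[0]
    origin[0, 1] = q[1]
    ang[0] = q[2]
    wrate[0] = v[2]
    ovel[0, 0] = v[0]
    ovel[0, 1] = v[1]
    obias[0, 0] = 0.0
    obias[0, 1] = 0.0
    for jj in range(nj):
        p = jnt_parent[jj]
        c = jnt_child[jj]
        ca = math.cos(ang[p])
        sa = math.sin(ang[p])
        ax = ca * jnt_anchor[jj, 0] - sa * jnt_anchor[jj, 1]
        az = sa * jnt_anchor[jj, 0] + ca * jnt_anchor[jj, 1]
        jpos[jj, 0] = origin[p, 0] + ax
        jpos[jj, 1] = origin[p, 1] + az
        origin[c, 0] = jpos[jj, 0]
        origin[c, 1] = jpos[jj, 1]
        ang[c] = ang[p] + jnt_ref[jj] + jnt_sign[jj] * q[3 + jj]
        wrate[c] = wrate[p] + jnt_sign[jj] * v[3 + jj]
        wp = wrate[p]
        ovel[c, 0] = ovel[p, 0] - wp * az
        ovel[c, 1] = ovel[p, 1] + wp * ax
        obias[c, 0] = obias[p, 0] - wp * wp * ax
        obias[c, 1] = obias[p, 1] - wp * wp * az

    # ---- CoM points, Jacobians, mass matrix, bias, gravity ----
    for i in range(nq):
        Qvec[i] = 0.0
        hvec[i] = 0.0
        for k in range(nq):
            Mmat[i, k] = 0.0
    for s in range(nseg):
        appF[s, 0] = 0.0
        appF[s, 1] = 0.0
        appM[s] = 0.0
    comx = 0.0
    comz = 0.0
    comvx = 0.0
    comvz = 0.0
    ke = 0.0
    pe = 0.0
    mtot = 0.0
    for s in range(nseg):
        ca = math.cos(ang[s])
        sa = math.sin(ang[s])
        lx = seg_com[s, 0]
        lz = seg_com[s, 1]
        rx = ca * lx - sa * lz
        rz = sa * lx + ca * lz
        px = origin[s, 0] + rx
        pz = origin[s, 1] + rz
        compos[s, 0] = px
        compos[s, 1] = pz
        w = wrate[s]
        vx = ovel[s, 0] - w * rz
        vz = ovel[s, 1] + w * rx
        comvel[s, 0] = vx
        comvel[s, 1] = vz
        combias[s, 0] = obias[s, 0] - w * w * rx
        combias[s, 1] = obias[s, 1] - w * w * rz
        # Jacobian of the CoM point
        for k in range(nq):
            Jv[s, 0, k] = 0.0
            Jv[s, 1, k] = 0.0
            wrow[s, k] = 0.0
        Jv[s, 0, 0] = 1.0
        Jv[s, 1, 1] = 1.0
        Jv[s, 0, 2] = -(pz - q[1])
        Jv[s, 1, 2] = px - q[0]
        wrow[s, 2] = 1.0
        for jj in range(nj):
            if anc[s, jj] == 1:
                sg = jnt_sign[jj]
                Jv[s, 0, 3 + jj] = -sg * (pz - jpos[jj, 1])
                Jv[s, 1, 3 + jj] = sg * (px - jpos[jj, 0])
                wrow[s, 3 + jj] = sg
        m = seg_mass[s]
        I = seg_inertia[s]
        mtot += m
        comx += m * px
        comz += m * pz
        comvx += m * vx
        comvz += m * vz
        ke += 0.5 * (m * (vx * vx + vz * vz) + I * w * w)
        pe += m * gravity * pz
        for i in range(nq):
            ji0 = Jv[s, 0, i]
            ji1 = Jv[s, 1, i]
            wi = wrow[s, i]
            for k in range(i, nq):
                Mmat[i, k] += m * (ji0 * Jv[s, 0, k] + ji1 * Jv[s, 1, k]) + I * wi * wrow[s, k]
            hvec[i] += m * (ji0 * combias[s, 0] + ji1 * combias[s, 1])
            Qvec[i] += -m * gravity * ji1
    for i in range(nq):
        for k in range(i):
            Mmat[i, k] = Mmat[k, i]
    comx /= mtot
    comz /= mtot
    comvx /= mtot
    comvz /= mtot

    # ---- contacts ----
    grf = 0.0
    grfx = 0.0
    for ci in range(nc):
        s = con_seg[ci]
        ca = math.cos(ang[s])
        sa = math.sin(ang[s])
        lx = con_local[ci, 0]
        lz = con_local[ci, 1]
        rx = ca * lx - sa * lz
        rz = sa * lx + ca * lz
        px = origin[s, 0] + rx
        pz = origin[s, 1] + rz
        w = wrate[s]
        vx = ovel[s, 0] - w * rz
        vz = ovel[s, 1] + w * rx
        pen = -pz
        if pen > 0.0:
            fz = con_k[ci] * pen - con_c[ci] * vz
            if fz > 0.0:
                fx = -con_mu[ci] * fz * math.tanh(vx / con_vref[ci])
                grf += fz
                grfx += fx
                # generalized force via the point Jacobian
                Qvec[0] += fx
                Qvec[1] += fz
                Qvec[2] += -(pz - q[1]) * fx + (px - q[0]) * fz
                for jj in range(nj):
                    if anc[s, jj] == 1:
                        sg = jnt_sign[jj]
                        Qvec[3 + jj] += sg * (
                            -(pz - jpos[jj, 1]) * fx + (px - jpos[jj, 0]) * fz
                        )
                appF[s, 0] += fx
                appF[s, 1] += fz
                appM[s] += (px - compos[s, 0]) * fz - (pz - compos[s, 1]) * fx

    # ---- joint soft limits ----
    for jj in range(nj):
        th = q[3 + jj]
        rate = v[3 + jj]
        tau = 0.0
        # damping capped at the explicit-integration stability bound for
        # this coordinate's inertia (light distal segments otherwise blow up)
        cj = jnt_c[jj]
        cmax = 0.5 * Mmat[3 + jj, 3 + jj] / dt
        if cj > cmax:
            cj = cmax
        if th > jnt_hi[jj]:
            tau = -jnt_k[jj] * (th - jnt_hi[jj]) - cj * rate
        elif th < jnt_lo[jj]:
            tau = jnt_k[jj] * (jnt_lo[jj] - th) - cj * rate
        if tau != 0.0:
            Qvec[3 + jj] += tau
            gt = jnt_sign[jj] * tau
            appM[jnt_child[jj]] += gt
            appM[jnt_parent[jj]] -= gt

    # ---- muscles ----
    for mi in range(nm):
        a0 = pt_start[mi]
        a1 = pt_start[mi + 1]
        npt = a1 - a0
        for k in range(npt):
            s = pt_seg[a0 + k]
            ca = math.cos(ang[s])
            sa = math.sin(ang[s])
            ptbuf[k, 0] = origin[s, 0] + ca * pt_loc[a0 + k, 0] - sa * pt_loc[a0 + k, 1]
            ptbuf[k, 1] = origin[s, 1] + sa * pt_loc[a0 + k, 0] + ca * pt_loc[a0 + k, 1]
        for i in range(nq):
            dl[i] = 0.0
        L = 0.0
        for k in range(npt - 1):
            p1x = ptbuf[k, 0]
            p1z = ptbuf[k, 1]
            p2x = ptbuf[k + 1, 0]
            p2z = ptbuf[k + 1, 1]
            s1 = pt_seg[a0 + k]
            s2 = pt_seg[a0 + k + 1]
            ws = wrap_seg[mi]
            wrapped = False
            t1x = t1z = t2x = t2z = 0.0
            wcx = wcz = 0.0
            if ws >= 0 and wrap_after[mi] == k:
                ca = math.cos(ang[ws])
                sa = math.sin(ang[ws])
                wcx = origin[ws, 0] + ca * wrap_center[mi, 0] - sa * wrap_center[mi, 1]
                wcz = origin[ws, 1] + sa * wrap_center[mi, 0] + ca * wrap_center[mi, 1]
                seglen, wrapped, t1x, t1z, t2x, t2z = wrap_segment_length(
                    p1x, p1z, p2x, p2z, wcx, wcz, wrap_radius[mi], wrap_side[mi]
                )
            else:
                seglen = math.hypot(p2x - p1x, p2z - p1z)
            L += seglen
            if wrapped:
                # straight parts to/from the tangent points; arc length has
                # no first-order q-dependence (envelope of the tangency)
                n1 = math.hypot(t1x - p1x, t1z - p1z)
                n2 = math.hypot(p2x - t2x, p2z - t2z)
                if n1 > 1e-12:
                    u1x = (t1x - p1x) / n1
                    u1z = (t1z - p1z) / n1
                    _accum_dl(dl, u1x, u1z, ws, t1x, t1z, s1, p1x, p1z, q, jpos, anc, jnt_sign, nj)
                else:
                    u1x = u1z = 0.0
                if n2 > 1e-12:
                    u2x = (p2x - t2x) / n2
                    u2z = (p2z - t2z) / n2
                    _accum_dl(dl, u2x, u2z, s2, p2x, p2z, ws, t2x, t2z, q, jpos, anc, jnt_sign, nj)
                else:
                    u2x = u2z = 0.0
                ptjac[k, 0] = u1x
                ptjac[k, 1] = u1z
                ptjac[k, 2] = u2x
                ptjac[k, 3] = u2z
                ptjac[k, 4] = wcx
                ptjac[k, 5] = wcz
                ptjac[k, 6] = 1.0
            else:
                n = math.hypot(p2x - p1x, p2z - p1z)
                if n > 1e-12:
                    ux = (p2x - p1x) / n
                    uz = (p2z - p1z) / n
                else:
                    ux = uz = 0.0
                _accum_dl(dl, ux, uz, s2, p2x, p2z, s1, p1x, p1z, q, jpos, anc, jnt_sign, nj)
                ptjac[k, 0] = ux
                ptjac[k, 1] = uz
                ptjac[k, 6] = 0.0

        vmt = 0.0
        for i in range(nq):
            vmt += dl[i] * v[i]

        # series-elastic equilibrium -> CE velocity, tension
        lmt = L
        lc = lce[mi]
        lse = lmt - lc
        fse = mus_sek[mi] * (lse - mus_tl[mi])
        if fse < 0.0:
            fse = 0.0
        fpe = mus_pek[mi] * (lc - mus_peng[mi])
        if fpe < 0.0:
            fpe = 0.0
        # activation level at time t
        nph = act_times.shape[1]
        act = act_levels[mi, nph - 1]
        for k in range(nph):
            if t < act_times[mi, k]:
                act = act_levels[mi, k]
                break
        x = (lc - mus_lopt[mi]) / (mus_flw[mi] * mus_lopt[mi])
        fl = 1.0 - x * x
        if fl < 0.0:
            fl = 0.0
        fiso = act * mus_fmax[mi] * fl
        need = fse - fpe
        vmax = mus_vmax[mi]
        if need <= 0.0:
            vce = vmax
        elif fiso <= 1e-9:
            vce = -2.0 * vmax  # unloaded CE yields; stretch at capped rate
        else:
            phi = need / fiso
            if phi >= 1.0:
                exc = phi - 1.0
                if exc > 1.0:
                    exc = 1.0
                vce = -2.0 * vmax * exc
            else:
                ah = mus_ah[mi]
                vce = vmax * (1.0 - phi) / (1.0 + phi / ah)
        lcedot[mi] = -vce
        T = fse
        for i in range(nq):
            Qvec[i] -= T * dl[i]
        mdiag[mi, 0] = T
        mdiag[mi, 1] = fse - fpe  # equilibrium CE force
        mdiag[mi, 2] = fpe
        mdiag[mi, 3] = vce
        mdiag[mi, 4] = lmt
        mdiag[mi, 5] = act

        # applied-force bookkeeping for the Newton-Euler pass
        if ns > 0 and T > 0.0:
            for k in range(npt - 1):
                s1 = pt_seg[a0 + k]
                s2 = pt_seg[a0 + k + 1]
                p1x = ptbuf[k, 0]
                p1z = ptbuf[k, 1]
                p2x = ptbuf[k + 1, 0]
                p2z = ptbuf[k + 1, 1]
                if ptjac[k, 6] > 0.5:
                    ws = wrap_seg[mi]
                    u1x = ptjac[k, 0]
                    u1z = ptjac[k, 1]
                    u2x = ptjac[k, 2]
                    u2z = ptjac[k, 3]
                    wcx = ptjac[k, 4]
                    wcz = ptjac[k, 5]
                    appF[s1, 0] += T * u1x
                    appF[s1, 1] += T * u1z
                    appM[s1] += (p1x - compos[s1, 0]) * T * u1z - (p1z - compos[s1, 1]) * T * u1x
                    appF[s2, 0] -= T * u2x
                    appF[s2, 1] -= T * u2z
                    appM[s2] += -((p2x - compos[s2, 0]) * T * u2z - (p2z - compos[s2, 1]) * T * u2x)
                    fxw = T * (u2x - u1x)
                    fzw = T * (u2z - u1z)
                    appF[ws, 0] += fxw
                    appF[ws, 1] += fzw
                    appM[ws] += (wcx - compos[ws, 0]) * fzw - (wcz - compos[ws, 1]) * fxw
                else:
                    ux = ptjac[k, 0]
                    uz = ptjac[k, 1]
                    appF[s1, 0] += T * ux
                    appF[s1, 1] += T * uz
                    appM[s1] += (p1x - compos[s1, 0]) * T * uz - (p1z - compos[s1, 1]) * T * ux
                    appF[s2, 0] -= T * ux
                    appF[s2, 1] -= T * uz
                    appM[s2] += -((p2x - compos[s2, 0]) * T * uz - (p2z - compos[s2, 1]) * T * ux)

    # ---- solve equations of motion ----
    for i in range(nq):
        for k in range(nq):
            Mwork[i, k] = Mmat[i, k]
        Mwork[i, i] += 1e-9
        hvec[i] = Qvec[i] - hvec[i]
    if base_fixed == 1:
        for i in range(3):
            for k in range(nq):
                Mwork[i, k] = 0.0
                Mwork[k, i] = 0.0
            Mwork[i, i] = 1.0
            hvec[i] = 0.0
    _chol_solve(Mwork, hvec, qdd, nq)

    # ---- bone stress via backward Newton-Euler ----
    maxratio = 0.0
    if ns > 0:
        for s in range(nseg - 1, -1, -1):
            ax = combias[s, 0]
            az = combias[s, 1]
            wd = 0.0
            for i in range(nq):
                ax += Jv[s, 0, i] * qdd[i]
                az += Jv[s, 1, i] * qdd[i]
                wd += wrow[s, i] * qdd[i]
            m = seg_mass[s]
            rfx = m * ax - appF[s, 0] + Rf[s, 0]
            rfz = m * az + m * gravity - appF[s, 1] + Rf[s, 1]
            jj = -1
            for k in range(jnt_sign.shape[0]):
                if jnt_child[k] == s:
                    jj = k
                    break
            rm = (
                seg_inertia[s] * wd
                - appM[s]
                + Rm[s]
            )
            if jj >= 0:
                rm -= (jpos[jj, 0] - compos[s, 0]) * rfz - (jpos[jj, 1] - compos[s, 1]) * rfx
                Rf[s, 0] = rfx
                Rf[s, 1] = rfz
                Rm[s] = rm
                p = parent[s]
                Rf[p, 0] += rfx
                Rf[p, 1] += rfz
                Rm[p] += rm + (jpos[jj, 0] - compos[p, 0]) * rfz - (jpos[jj, 1] - compos[p, 1]) * rfx
            else:
                Rf[s, 0] = rfx
                Rf[s, 1] = rfz
                Rm[s] = rm
        for bi in range(ns):
            s = bs_seg[bi]
            jj = -1
            for k in range(jnt_sign.shape[0]):
                if jnt_child[k] == s:
                    jj = k
                    break
            if jj < 0:
                sdiag[bi] = 0.0
                continue
            ca = math.cos(ang[s])
            sa = math.sin(ang[s])
            bx = origin[s, 0] + ca * bs_local[bi, 0] - sa * bs_local[bi, 1]
            bz = origin[s, 1] + sa * bs_local[bi, 0] + ca * bs_local[bi, 1]
            fx = Rf[s, 0]
            fz = Rf[s, 1]
            mm = Rm[s] + (jpos[jj, 0] - bx) * fz - (jpos[jj, 1] - bz) * fx
            axial = abs(fx * ca + fz * sa)
            sigma = axial / bs_area[bi] + abs(mm) * bs_cdist[bi] / bs_imom[bi]
            sdiag[bi] = sigma
            r = sigma / bs_fail[bi]
            if r > maxratio:
                maxratio = r
        for s in range(nseg):
            Rf[s, 0] = 0.0
            Rf[s, 1] = 0.0
            Rm[s] = 0.0

    diag[0] = grf
    diag[1] = grfx
    diag[2] = comx
    diag[3] = comz
    diag[4] = comvx
    diag[5] = comvz
    diag[6] = ke
    diag[7] = pe
    diag[8] = maxratio


@njit(cache=False)
def _accum_dl(dl, ux, uz, s_to, px_to, pz_to, s_from, px_from, pz_from, q, jpos, anc, jnt_sign, nj):
    # dL/dq += u . (J(point_to) - J(point_from)); u is the unit vector from
    # point_from to point_to.  Base translation moves both points identically
    # so only the rotational coordinates contribute.
    dl[2] +=ux * (-(pz_to - q[1]) + (pz_from - q[1])) + uz * ((px_to - q[0]) - (px_from - q[0]))
    for jj in range(nj):
        a_to = anc[s_to, jj]
        a_from = anc[s_from, jj]
        if a_to == 1 or a_from == 1:
            sg = jnt_sign[jj]
            val = 0.0
            if a_to == 1:
                val += ux * (-sg * (pz_to - jpos[jj, 1])) + uz * (sg * (px_to - jpos[jj, 0]))
            if a_from == 1:
                val -= ux * (-sg * (pz_from - jpos[jj, 1])) + uz * (sg * (px_from - jpos[jj, 0]))
            dl[3 + jj] += val


@njit(cache=False)
def _run_core(
    mdl,
    q,
    v,
    lce,
    act_times,
    act_levels,
    duration,
    dt,
    stride,
    integrator,
    early_stop,
    out_t,
    out_q,
    out_v,
    out_diag,
    out_mdiag,
    out_works,
    out_sdiag,
    out_act,
    out_lce,
):
    nj = mdl[5].shape[0]
    nseg = mdl[11].shape[0]
    nq = 3 + nj
    nm = mdl[28].shape[0]
    ns = mdl[37].shape[0]
    npts_max = 2
    for mi in range(nm):
        n = mdl[20][mi + 1] - mdl[20][mi]
        if n > npts_max:
            npts_max = n

    scr = (
        np.zeros((nseg, 2)),  # origin
        np.zeros(nseg),  # ang
        np.zeros(nseg),  # wrate
        np.zeros((nseg, 2)),  # ovel
        np.zeros((nseg, 2)),  # obias
        np.zeros((max(nj, 1), 2)),  # jpos
        np.zeros((nseg, 2)),  # compos
        np.zeros((nseg, 2)),  # comvel
        np.zeros((nseg, 2)),  # combias
        np.zeros((nseg, 2, nq)),  # Jv
        np.zeros((nseg, nq)),  # wrow
        np.zeros((nq, nq)),  # Mmat
        np.zeros(nq),  # Qvec
        np.zeros(nq),  # hvec
        np.zeros((nseg, 2)),  # appF
        np.zeros(nseg),  # appM
        np.zeros((nseg, 2)),  # Rf
        np.zeros(nseg),  # Rm
        np.zeros((2, nq)),  # Jp (unused scratch)
        np.zeros(nq),  # dl
        np.zeros((npts_max, 2)),  # ptbuf
        np.zeros((npts_max, 7)),  # ptjac bookkeeping
        np.zeros((nq, nq)),  # Mwork
    )
    qdd = np.zeros(nq)
    lcedot = np.zeros(max(nm, 1))
    diag = np.zeros(16)
    mdiag = np.zeros((max(nm, 1), 6))
    sdiag = np.zeros(max(ns, 1))
    works = np.zeros((max(nm, 1), 4))  # cumulative CE, SE, PE, MTU
    lmt_prev = np.zeros(max(nm, 1))
    lce_prev = lce.copy()
    fprev = np.zeros((max(nm, 1), 3))

    # RK4 scratch
    k1q = np.zeros(nq)
    k1v = np.zeros(nq)
    k1l = np.zeros(max(nm, 1))
    k2v = np.zeros(nq)
    k2l = np.zeros(max(nm, 1))
    k3v = np.zeros(nq)
    k3l = np.zeros(max(nm, 1))
    k4v = np.zeros(nq)
    k4l = np.zeros(max(nm, 1))
    qt = np.zeros(nq)
    vt = np.zeros(nq)
    lt = np.zeros(max(nm, 1))

    nsteps = int(round(duration / dt))
    nrec = 0
    status = 0
    fail_time = -1.0
    max_com_z = -1e30
    dl_scr = scr[19]

    for step in range(nsteps + 1):
        t = step * dt
        _eval(mdl, q, v, lce, t, dt, act_times, act_levels, qdd, lcedot, diag, mdiag, sdiag, scr)

        # cumulative work ledger: forces from the start of each interval
        # against the actual state changes across it, so CE + PE + SE work
        # sums to the muscle-tendon work identically (T = F_ce + F_pe)
        if step > 0:
            for mi in range(nm):
                dlmt = mdiag[mi, 4] - lmt_prev[mi]
                dlce = lce[mi] - lce_prev[mi]
                T = fprev[mi, 0]
                fce = fprev[mi, 1]
                fpe = fprev[mi, 2]
                works[mi, 0] += -fce * dlce
                works[mi, 1] += -T * (dlmt - dlce)
                works[mi, 2] += -fpe * dlce
                works[mi, 3] += -T * dlmt
        for mi in range(nm):
            lmt_prev[mi] = mdiag[mi, 4]
            lce_prev[mi] = lce[mi]
            fprev[mi, 0] = mdiag[mi, 0]
            fprev[mi, 1] = mdiag[mi, 1]
            fprev[mi, 2] = mdiag[mi, 2]

        if diag[3] > max_com_z:
            max_com_z = diag[3]

        bad = False
        for i in range(nq):
            if not math.isfinite(q[i]) or abs(q[i]) > 50.0 or abs(v[i]) > 500.0:
                bad = True
        if bad:
            status = 1
            fail_time = t
        elif diag[8] > 1.0:
            status = 2
            fail_time = t

        record = (step % stride == 0) or status != 0 or step == nsteps
        if record and nrec < out_t.shape[0]:
            out_t[nrec] = t
            for i in range(nq):
                out_q[nrec, i] = q[i]
                out_v[nrec, i] = v[i]
            for i in range(9):
                out_diag[nrec, i] = diag[i]
            for mi in range(nm):
                for k in range(6):
                    out_mdiag[nrec, mi, k] = mdiag[mi, k]
                for k in range(4):
                    out_works[nrec, mi, k] = works[mi, k]
                out_lce[nrec, mi] = lce[mi]
                out_act[nrec, mi] = mdiag[mi, 5]
            for bi in range(ns):
                out_sdiag[nrec, bi] = sdiag[bi]
            nrec += 1

        if status != 0 or step == nsteps:
            break
        # airborne, past the apex, and actually higher than the start:
        # nothing after this can raise the maximum CoM height
        if step == 0:
            com_z0 = diag[3]
        if (
            early_stop == 1
            and t > 0.05
            and diag[0] <= 0.0
            and diag[5] < -1e-3
            and diag[3] > com_z0 + 0.02
        ):
            break

        if integrator == 0:
            # semi-implicit Euler
            for i in range(nq):
                v[i] += qdd[i] * dt
                q[i] += v[i] * dt
            for mi in range(nm):
                lce[mi] += lcedot[mi] * dt
                if lce[mi] < 1e-5:
                    lce[mi] = 1e-5
        else:
            # classical RK4; stage 1 already evaluated
            for i in range(nq):
                k1q[i] = v[i]
                k1v[i] = qdd[i]
            for mi in range(nm):
                k1l[mi] = lcedot[mi]
            for i in range(nq):
                qt[i] = q[i] + 0.5 * dt * k1q[i]
                vt[i] = v[i] + 0.5 * dt * k1v[i]
            for mi in range(nm):
                lt[mi] = lce[mi] + 0.5 * dt * k1l[mi]
            _eval(mdl, qt, vt, lt, t + 0.5 * dt, dt, act_times, act_levels, qdd, lcedot, diag, mdiag, sdiag, scr)
            for i in range(nq):
                k2v[i] = qdd[i]
            for mi in range(nm):
                k2l[mi] = lcedot[mi]
            q2 = vt.copy()
            for i in range(nq):
                qt[i] = q[i] + 0.5 * dt * q2[i]
                vt[i] = v[i] + 0.5 * dt * k2v[i]
            for mi in range(nm):
                lt[mi] = lce[mi] + 0.5 * dt * k2l[mi]
            _eval(mdl, qt, vt, lt, t + 0.5 * dt, dt, act_times, act_levels, qdd, lcedot, diag, mdiag, sdiag, scr)
            for i in range(nq):
                k3v[i] = qdd[i]
            q3 = vt.copy()
            for mi in range(nm):
                k3l[mi] = lcedot[mi]
            for i in range(nq):
                qt[i] = q[i] + dt * q3[i]
                vt[i] = v[i] + dt * k3v[i]
            for mi in range(nm):
                lt[mi] = lce[mi] + dt * k3l[mi]
            _eval(mdl, qt, vt, lt, t + dt, dt, act_times, act_levels, qdd, lcedot, diag, mdiag, sdiag, scr)
            for i in range(nq):
                k4v[i] = qdd[i]
            q4 = vt.copy()
            for mi in range(nm):
                k4l[mi] = lcedot[mi]
            for i in range(nq):
                q[i] += dt / 6.0 * (k1q[i] + 2.0 * q2[i] + 2.0 * q3[i] + q4[i])
                v[i] += dt / 6.0 * (k1v[i] + 2.0 * k2v[i] + 2.0 * k3v[i] + k4v[i])
            for mi in range(nm):
                lce[mi] += dt / 6.0 * (k1l[mi] + 2.0 * k2l[mi] + 2.0 * k3l[mi] + k4l[mi])
                if lce[mi] < 1e-5:
                    lce[mi] = 1e-5

    return nrec, status, fail_time, max_com_z


# ---------------------------------------------------------------------------
# trajectory container and public entry point
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Uniformly sampled simulation output."""

    time: np.ndarray
    q: np.ndarray
    qd: np.ndarray
    com: np.ndarray
    com_vel: np.ndarray
    grf: np.ndarray
    grf_x: np.ndarray
    ke: np.ndarray
    pe: np.ndarray
    muscle_force: np.ndarray
    muscle_ce_force: np.ndarray
    muscle_pe_force: np.ndarray
    muscle_vce: np.ndarray
    muscle_lce: np.ndarray
    muscle_act: np.ndarray
    work_ce: np.ndarray
    work_se: np.ndarray
    work_pe: np.ndarray
    work_mtu: np.ndarray
    bone_stress: np.ndarray
    joint_names: list[str]
    muscle_names: list[str]
    section_names: list[str]
    stress_exceeded: bool = False
    blown_up: bool = False
    fail_time: float = -1.0
    max_com_height: float = float("nan")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0]) if len(self.time) > 1 else 0.0

    def joint_angles_deg(self) -> np.ndarray:
        return np.degrees(self.q[:, 3:])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "time": self.time,
                "fz": self.grf,
                "fx": self.grf_x,
                "com_x": self.com[:, 0],
                "com_z": self.com[:, 1],
                "com_vx": self.com_vel[:, 0],
                "com_vz": self.com_vel[:, 1],
                "ke": self.ke,
                "pe": self.pe,
            }
        )
        ang = self.joint_angles_deg()
        for k, name in enumerate(self.joint_names):
            df[f"angle_{name}"] = ang[:, k]
        for k, name in enumerate(self.muscle_names):
            df[f"force_{name}"] = self.muscle_force[:, k]
        for k, name in enumerate(self.section_names):
            df[f"stress_{name}"] = self.bone_stress[:, k]
        return df

    def write_tsv(self, path, downsample: int = 1) -> None:
        self.to_frame().iloc[::downsample].to_csv(path, sep="\t", index=False)


def constant_activation(model: Model, level=0.0, duration: float = 1e9):
    """Activation schedule arrays holding each actuator at a constant level.

    ``level`` may be a scalar or a mapping actuator-name -> level.
    """
    nm = len(model.actuators)
    times = np.full((max(nm, 1), 1), duration)
    if isinstance(level, dict):
        levels = np.array([[float(level.get(a.name, 0.0))] for a in model.actuators])
        if nm == 0:
            levels = np.zeros((1, 1))
    else:
        levels = np.full((max(nm, 1), 1), float(level))
    return times, levels


def _initial_state(model: Model, mdl, meta, settle: bool):
    nj = len(meta["jnt_order"])
    nq = 3 + nj
    q = np.zeros(nq)
    q[2] = math.radians(model.base_orientation_deg)
    for k, name in enumerate(meta["jnt_order"]):
        q[3 + k] = math.radians(model.starting_pose.get(name, 0.0))
    # drop the model so the lowest contact just loads the springs with
    # the body weight (static preload avoids touchdown transients)
    if model.contacts and not model.base_fixed:
        fk = forward_kinematics(model, {}, base=(0.0, 0.0))
        zmin = math.inf
        ktot = 0.0
        for c in model.contacts:
            p = world_point(fk, c.segment, c.local_pos)
            zmin = min(zmin, p[1])
            ktot += c.stiffness
        pen = model.total_segment_mass * model.gravity / ktot if settle else 0.0
        q[1] = -zmin - pen
    lce = np.zeros(max(len(model.actuators), 1))
    for mi, a in enumerate(model.actuators):
        lmt = path_length_m(model, a, None)
        # offset by the base shift: path lengths are pose-dependent only
        tl = mdl[31][mi]
        lce[mi] = max(1e-4, lmt - tl)
    return q, lce


def simulate(
    model: Model,
    controller=None,
    duration: float = 1.0,
    dt: float = DEFAULT_DT,
    output_dt: Optional[float] = None,
    integrator: str = "semi_implicit",
    gravity: Optional[float] = None,
    initial_q: Optional[np.ndarray] = None,
    initial_qd: Optional[np.ndarray] = None,
    settle_contacts: bool = True,
    early_stop: bool = False,
) -> Trajectory:
    """Integrate the model forward under an activation schedule.

    ``controller`` is ``None`` (all muscles off), a scalar/mapping constant
    level, or a pair ``(times, levels)`` of (n_muscles, n_phases) arrays
    where ``times`` holds cumulative phase end times.  Integration stops
    early with a flag when the state blows up or a bone section exceeds its
    failure stress; with ``early_stop=True`` it also stops once the model
    is airborne and past its apex (useful inside optimizers).
    """
    if duration <= 0 or dt <= 0:
        raise ValueError("duration and dt must be positive")
    g = model.gravity if gravity is None else gravity
    mdl, meta = _compile_model(model, g)

    if controller is None or isinstance(controller, (int, float, dict)):
        act_times, act_levels = constant_activation(model, controller or 0.0)
    else:
        act_times, act_levels = controller
        act_times = np.ascontiguousarray(act_times, dtype=float)
        act_levels = np.ascontiguousarray(act_levels, dtype=float)

    q0, lce0 = _initial_state(model, mdl, meta, settle_contacts)
    if initial_q is not None:
        q0 = np.asarray(initial_q, dtype=float).copy()
    v0 = (
        np.asarray(initial_qd, dtype=float).copy()
        if initial_qd is not None
        else np.zeros_like(q0)
    )

    if output_dt is None:
        output_dt = max(dt, DEFAULT_OUTPUT_DT)
    stride = max(1, int(round(output_dt / dt)))
    nsteps = int(round(duration / dt))
    nrec_max = nsteps // stride + 3
    nj = len(meta["jnt_order"])
    nm = len(model.actuators)
    ns = len(model.bone_sections)
    nq = 3 + nj

    out_t = np.zeros(nrec_max)
    out_q = np.zeros((nrec_max, nq))
    out_v = np.zeros((nrec_max, nq))
    out_diag = np.zeros((nrec_max, 9))
    out_mdiag = np.zeros((nrec_max, max(nm, 1), 6))
    out_works = np.zeros((nrec_max, max(nm, 1), 4))
    out_sdiag = np.zeros((nrec_max, max(ns, 1)))
    out_act = np.zeros((nrec_max, max(nm, 1)))
    out_lce = np.zeros((nrec_max, max(nm, 1)))

    nrec, status, fail_time, max_com_z = _run_core(
        mdl,
        q0,
        v0,
        lce0,
        act_times,
        act_levels,
        float(duration),
        float(dt),
        stride,
        0 if integrator == "semi_implicit" else 1,
        1 if early_stop else 0,
        out_t,
        out_q,
        out_v,
        out_diag,
        out_mdiag,
        out_works,
        out_sdiag,
        out_act,
        out_lce,
    )
    sl = slice(0, nrec)
    traj = Trajectory(
        time=out_t[sl].copy(),
        q=out_q[sl].copy(),
        qd=out_v[sl].copy(),
        com=out_diag[sl, 2:4].copy(),
        com_vel=out_diag[sl, 4:6].copy(),
        grf=out_diag[sl, 0].copy(),
        grf_x=out_diag[sl, 1].copy(),
        ke=out_diag[sl, 6].copy(),
        pe=out_diag[sl, 7].copy(),
        muscle_force=out_mdiag[sl, :nm, 0].copy() if nm else np.zeros((nrec, 0)),
        muscle_ce_force=out_mdiag[sl, :nm, 1].copy() if nm else np.zeros((nrec, 0)),
        muscle_pe_force=out_mdiag[sl, :nm, 2].copy() if nm else np.zeros((nrec, 0)),
        muscle_vce=out_mdiag[sl, :nm, 3].copy() if nm else np.zeros((nrec, 0)),
        muscle_lce=out_lce[sl, :nm].copy() if nm else np.zeros((nrec, 0)),
        muscle_act=out_act[sl, :nm].copy() if nm else np.zeros((nrec, 0)),
        work_ce=out_works[sl, :nm, 0].copy() if nm else np.zeros((nrec, 0)),
        work_se=out_works[sl, :nm, 1].copy() if nm else np.zeros((nrec, 0)),
        work_pe=out_works[sl, :nm, 2].copy() if nm else np.zeros((nrec, 0)),
        work_mtu=out_works[sl, :nm, 3].copy() if nm else np.zeros((nrec, 0)),
        bone_stress=out_sdiag[sl, :ns].copy() if ns else np.zeros((nrec, 0)),
        joint_names=meta["jnt_order"],
        muscle_names=[a.name for a in model.actuators],
        section_names=[b.name for b in model.bone_sections],
        stress_exceeded=(status == 2),
        blown_up=(status == 1),
        fail_time=fail_time,
        max_com_height=max_com_z,
    )
    return traj
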