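"""Planar cable geometry shared by the reconstruction code and the engine.

A muscle path is a polyline of via points with at most one circular
wrapping surface between a designated pair of consecutive points.  The
wrap is a frictionless pulley: the cable takes the tangent-arc-tangent
route around its side of the circle and lifts off (continuously, with the
arc shrinking to zero at exact tangency) when it passes the circle on the
free side.
"""

import math

from numba import njit

__all__ = ["wrap_segment_length"]

#: wraps beyond this sweep are treated as lifted off the free side; hinge
#: pulleys in these models legitimately reach ~2.7 rad at deep flexion,
#: while a cable pushed onto its wrong side would wrap >4 rad
_MAX_SWEEP = math.pi


@njit(cache=False)
def wrap_segment_length(p1x, p1z, p2x, p2z, cx, cz, r, side):
    """Length of the cable from P1 to P2 around a circle (C, r).

    ``side`` is +1 when the cable runs counter-clockwise around the circle
    and -1 for clockwise.  Returns ``(length, wrapped, t1x, t1z, t2x, t2z)``
    where T1/T2 are the tangent (lift-off) points; they equal the endpoints
    when the cable is straight.
    """
    straight = math.hypot(p2x - p1x, p2z - p1z)
    d1x = p1x - cx
    d1z = p1z - cz
    d2x = p2x - cx
    d2z = p2z - cz
    dist1 = math.sqrt(d1x * d1x + d1z * d1z)
    dist2 = math.sqrt(d2x * d2x + d2z * d2z)
    # endpoints inside the circle are degenerate; fall back to straight
    if dist1 <= r * 1.0000001 or dist2 <= r * 1.0000001:
        return straight, False, p1x, p1z, p2x, p2z

    g1 = math.acos(r / dist1)
    g2 = math.acos(r / dist2)
    phi1 = math.atan2(d1z, d1x)
    phi2 = math.atan2(d2z, d2x)
    # tangent departure/arrival angles for travel around the given side
    a1 = phi1 + side * g1
    a2 = phi2 - side * g2
    twopi = 2.0 * math.pi
    sweep = (side * (a2 - a1)) % twopi
    if sweep >= _MAX_SWEEP:
        return straight, False, p1x, p1z, p2x, p2z
    tl1 = math.sqrt(dist1 * dist1 - r * r)
    tl2 = math.sqrt(dist2 * dist2 - r * r)
    length = tl1 + tl2 + r * sweep
    t1x = cx + r * math.cos(a1)
    t1z = cz + r * math.sin(a1)
    t2x = cx + r * math.cos(a2)
    t2z = cz + r * math.sin(a2)
    return length, True, t1x, t1z, t2x, t2z
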