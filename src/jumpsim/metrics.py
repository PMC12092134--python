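"""Jump-performance analysis of force/CoM traces.

Works identically on simulated trajectories and force-plate-style
experimental traces: a uniformly sampled table with columns ``time`` (s),
``fz`` (total vertical ground reaction force, N) and ``com_z`` (vertical
centre-of-mass position, m).

Phases are found from force and positional criteria: the jump starts at
the first departure of the vertical force from body weight by 5% (downward
for a countermovement, upward for a squat jump), take-off is the first
instant the force reaches zero, the eccentric-concentric transition of a
countermovement is the lowest CoM position before take-off, and the jump
ends at the CoM apex.

The discrete performance parameters are the ones conventionally reported
for maximal vertical jumps: jump height (CoM apex), concentric
displacement distance, take-off velocity, contact time and the relative
net vertical impulse (RNVI) — the net-of-body-weight vertical impulse over
the concentric phase divided by body mass, which by impulse-momentum
equals the CoM velocity change and hence approximates take-off velocity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "JumpPhases",
    "JumpMetrics",
    "NoJumpError",
    "NoTakeoffError",
    "detect_phases",
    "compute_metrics",
    "ballistic_height",
    "classify_strategy",
    "analyze_trace",
    "read_trace",
]

#: force threshold for take-off detection (floating-point GRF is never
#: exactly zero), N
TAKEOFF_EPSILON = 0.5
#: jump-start departure from body weight, fraction of BW
START_THRESHOLD = 0.05
#: CoM descent distinguishing a countermovement from numerical jitter, m
CMJ_DEPTH_THRESHOLD = 0.005


class NoJumpError(RuntimeError):
    """The force trace never departs from body weight."""


class NoTakeoffError(RuntimeError):
    """The vertical force never reaches zero (subject stays grounded)."""


@dataclass
class JumpPhases:
    t_start: float
    t_low: float
    t_takeoff: float
    t_apex: float
    strategy: str  # provisional, from the sign of the first force departure
    i_start: int = 0
    i_low: int = 0
    i_takeoff: int = 0
    i_apex: int = 0


@dataclass
class JumpMetrics:
    max_com_height: float
    concentric_distance: float
    takeoff_velocity: float
    contact_time: float
    rnvi: float
    strategy: str


def _columns(trace: pd.DataFrame):
    t = np.asarray(trace["time"], dtype=float)
    fz = np.asarray(trace["fz"], dtype=float)
    com = np.asarray(trace["com_z"], dtype=float)
    if len(t) < 3:
        raise ValueError("trace too short")
    return t, fz, com


def detect_phases(
    trace: pd.DataFrame,
    body_weight: float,
    start_threshold: float = START_THRESHOLD,
    takeoff_epsilon: float = TAKEOFF_EPSILON,
) -> JumpPhases:
    """Locate the jump phases in a quiet-standing-then-jump trace.

    ``body_weight`` is in N.  The provisional strategy label reflects the
    sign of the first force departure (below BW: countermovement
    unweighting; above BW: squat-jump push); the positional criterion in
    :func:`classify_strategy` gives the definitive label.
    """
    t, fz, com = _columns(trace)
    dev = fz - body_weight
    crossing = np.abs(dev) > start_threshold * body_weight
    if not crossing.any():
        raise NoJumpError("force never departs from body weight by the threshold")
    i_start = int(np.argmax(crossing))
    strategy = "CMJ" if dev[i_start] < 0 else "SJ"

    off = fz[i_start:] <= takeoff_epsilon
    if not off.any():
        raise NoTakeoffError("vertical force never reaches zero")
    i_takeoff = i_start + int(np.argmax(off))
    # A vigorous simulated countermovement can unload the feet completely
    # mid-dip; the take-off that matters is the start of the zero-force
    # interval leading to the CoM apex (identical on traces whose force
    # first reaches zero at the true take-off).  Ground contact is judged
    # on a 5 ms moving average so single noisy flight samples cannot pose
    # as contact, then the crossing is refined on the raw signal.
    i_peak = int(np.argmax(com))
    if i_peak > i_start and com[i_peak] > com[i_start]:
        win = max(1, int(round(0.005 / max(t[1] - t[0], 1e-9))))
        kernel = np.ones(win) / win
        smooth = np.convolve(fz, kernel, mode="same")
        before = np.nonzero(smooth[i_start:i_peak] > takeoff_epsilon)[0]
        if len(before):
            last_ground = i_start + int(before[-1])
            # smoothing smears the lift-off by up to a window, so refine the
            # crossing on the raw signal around it
            lo = max(i_start, last_ground - win)
            after = np.nonzero(fz[lo : i_peak + 1] <= takeoff_epsilon)[0]
            if len(after):
                i_takeoff = lo + int(after[0])

    if strategy == "CMJ":
        i_low = i_start + int(np.argmin(com[i_start : i_takeoff + 1]))
    else:
        i_low = i_start
    i_apex = i_takeoff + int(np.argmax(com[i_takeoff:]))
    return JumpPhases(
        t_start=float(t[i_start]),
        t_low=float(t[i_low]),
        t_takeoff=float(t[i_takeoff]),
        t_apex=float(t[i_apex]),
        strategy=strategy,
        i_start=i_start,
        i_low=i_low,
        i_takeoff=i_takeoff,
        i_apex=i_apex,
    )


def compute_metrics(
    trace: pd.DataFrame,
    phases: JumpPhases,
    body_mass: float,
    g: float = 9.81,
) -> JumpMetrics:
    """Discrete performance parameters for a detected jump.

    Take-off velocity is the central finite difference of the CoM height at
    the take-off sample.  RNVI is net of body weight over the concentric
    window only: ``integral(fz) / m - g * (t_takeoff - t_low)``, so it
    equals the CoM velocity change by impulse-momentum.
    """
    for f in ("i_low", "i_takeoff", "i_apex"):
        if getattr(phases, f) is None:
            raise ValueError(f"phases missing field {f}")
    t, fz, com = _columns(trace)
    i0, i1 = phases.i_low, phases.i_takeoff
    rnvi = float(np.trapezoid(fz[i0 : i1 + 1], t[i0 : i1 + 1])) / body_mass - g * (
        t[i1] - t[i0]
    )
    ia = phases.i_takeoff
    lo = max(1, ia - 1)
    hi = min(len(t) - 1, ia + 1)
    v_to = float((com[hi] - com[lo]) / (t[hi] - t[lo]))
    return JumpMetrics(
        max_com_height=float(com[phases.i_apex]),
        concentric_distance=float(com[i1] - com[i0]),
        takeoff_velocity=v_to,
        contact_time=float(t[i1] - t[phases.i_start]),
        rnvi=rnvi,
        strategy=phases.strategy,
    )


def ballistic_height(com_takeoff: float, v_takeoff: float, g: float = 9.81) -> float:
    """Predicted CoM apex from the take-off state: z + v^2 / (2 g)."""
    if g <= 0:
        raise ValueError("g must be positive")
    return com_takeoff + v_takeoff**2 / (2.0 * g)


def classify_strategy(
    phases: JumpPhases,
    trace: pd.DataFrame,
    depth_threshold: float = CMJ_DEPTH_THRESHOLD,
) -> str:
    """CMJ if the CoM drops below its starting height by at least the
    threshold before take-off (transient use of a more flexed posture);
    otherwise SJ.  A descent exactly at the threshold counts as CMJ."""
    _, _, com = _columns(trace)
    start = com[phases.i_start]
    low = com[phases.i_start : phases.i_takeoff + 1].min()
    return "CMJ" if start - low >= depth_threshold else "SJ"


def analyze_trace(
    trace: pd.DataFrame,
    body_mass: float,
    g: float = 9.81,
    start_threshold: float = START_THRESHOLD,
    takeoff_epsilon: float = TAKEOFF_EPSILON,
    depth_threshold: float = CMJ_DEPTH_THRESHOLD,
) -> tuple[JumpPhases, JumpMetrics]:
    """Phase detection + metrics with the definitive strategy label."""
    phases = detect_phases(
        trace, body_mass * g, start_threshold=start_threshold, takeoff_epsilon=takeoff_epsilon
    )
    strategy = classify_strategy(phases, trace, depth_threshold=depth_threshold)
    phases.strategy = strategy
    t, _, com = _columns(trace)
    if strategy == "SJ":
        phases.i_low = phases.i_start
    else:
        phases.i_low = phases.i_start + int(
            np.argmin(com[phases.i_start : phases.i_takeoff + 1])
        )
    phases.t_low = float(t[phases.i_low])
    metrics = compute_metrics(trace, phases, body_mass, g=g)
    return phases, metrics


def read_trace(path) -> pd.DataFrame:
    """Read a tab-separated trace with at least time, fz, com_z columns."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = {"time", "fz", "com_z"} - set(df.columns)
    if missing:
        raise ValueError(f"trace file missing columns: {sorted(missing)}")
    return df
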