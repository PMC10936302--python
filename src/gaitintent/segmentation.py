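"""Gait-phase segmentation from foot contacts or leg kinematics.

Walking is divided into four phases in fixed cyclic order::

    LDS -> LSS -> RDS -> RSS -> LDS -> ...

where LDS/RDS are the double-support phases named for the leading (front)
leg and LSS/RSS the single-support phases named for the stance leg. Each
frame additionally carries a within-phase timestep index ``k`` (k = 1 on the
first frame of a phase, incrementing once per sample interval ``dt``).

Two inference paths are provided. When per-leg foot-contact flags are
available they are used directly. Otherwise stance and swing are inferred
from the *virtual leg vector* ``2*(knee - hip) + (heel - knee)``, whose
angle with the vertical rises monotonically through swing and falls through
stance; trend reversals of that angle mark heel strike and toe-off.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from gaitintent.exceptions import (
    DegenerateGeometryError,
    InsufficientDataError,
    UnresolvedPhaseError,
)

__all__ = [
    "GaitPhase",
    "PhaseTimestep",
    "LegState",
    "virtual_leg_vector",
    "vertical_angle",
    "sagittal_vertical_angle",
    "detect_stance_swing",
    "assign_phase",
    "track_timestep",
    "segment_stream",
]


class GaitPhase(enum.Enum):
    """The four gait phases, in cyclic successor order."""

    LDS = "LDS"
    LSS = "LSS"
    RDS = "RDS"
    RSS = "RSS"

    @property
    def successor(self) -> "GaitPhase":
        order = [GaitPhase.LDS, GaitPhase.LSS, GaitPhase.RDS, GaitPhase.RSS]
        return order[(order.index(self) + 1) % 4]

    @property
    def is_double_support(self) -> bool:
        return self in (GaitPhase.LDS, GaitPhase.RDS)


#: Fixed cyclic order used throughout the package.
PHASE_ORDER = (GaitPhase.LDS, GaitPhase.LSS, GaitPhase.RDS, GaitPhase.RSS)


@dataclass(frozen=True)
class PhaseTimestep:
    """A gait phase together with the 1-based timestep index within it."""

    phase: GaitPhase
    k: int

    def __post_init__(self):
        if self.k < 1:
            raise ValueError(f"timestep index must be >= 1, got {self.k}")


@dataclass
class LegState:
    """Per-leg stance/swing state at one frame.

    ``entered_stance_at`` is the time (s) of the most recent swing->stance
    transition, used to decide the leading leg in double support.
    """

    stance: bool
    angle: float = float("nan")
    trend: int = 0  # +1 increasing (swing), -1 decreasing (stance), 0 flat
    entered_stance_at: Optional[float] = None


def virtual_leg_vector(hip, knee, heel) -> np.ndarray:
    """Virtual extended leg vector ``2*(knee - hip) + (heel - knee)``.

    Points may be 2-D (sagittal plane, vertical last) or 3-D. Raises
    :class:`DegenerateGeometryError` if the result is the zero vector.
    """
    hip = np.asarray(hip, dtype=float)
    knee = np.asarray(knee, dtype=float)
    heel = np.asarray(heel, dtype=float)
    if not (np.all(np.isfinite(hip)) and np.all(np.isfinite(knee)) and np.all(np.isfinite(heel))):
        raise ValueError("leg landmark positions must be finite")
    v = 2.0 * (knee - hip) + (heel - knee)
    if np.allclose(v, 0.0):
        raise DegenerateGeometryError("virtual leg vector is zero (coincident landmarks)")
    return v


def vertical_angle(v) -> float:
    """Unsigned angle (degrees, in [0, 180]) between ``v`` and straight down.

    The vertical axis is the last coordinate, positive up; the reference
    direction is downward since a standing leg points down from the hip.
    """
    v = np.asarray(v, dtype=float)
    norm = np.linalg.norm(v)
    if norm == 0.0 or not np.all(np.isfinite(v)):
        raise DegenerateGeometryError("cannot take the vertical angle of a zero vector")
    down = np.zeros_like(v)
    down[-1] = -1.0
    cosang = np.clip(np.dot(v, down) / norm, -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def sagittal_vertical_angle(v, forward_axis: int = 0) -> float:
    """Signed sagittal-plane angle with the downward vertical (degrees).

    Positive when the vector points forward of vertical, negative behind.
    Unlike :func:`vertical_angle` this is monotone through a full leg swing,
    which is what the stance/swing trend detector needs.
    """
    v = np.asarray(v, dtype=float)
    if np.allclose(v, 0.0):
        raise DegenerateGeometryError("cannot take the vertical angle of a zero vector")
    return float(np.degrees(np.arctan2(v[forward_axis], -v[-1])))


def _causal_moving_average(x: np.ndarray, window: int) -> np.ndarray:
    c = np.cumsum(np.insert(x, 0, 0.0))
    out = np.empty_like(x, dtype=float)
    for i in range(len(x)):
        lo = max(0, i - window + 1)
        out[i] = (c[i + 1] - c[lo]) / (i + 1 - lo)
    return out


def _stance_flags_from_angles(
    angles: np.ndarray,
    window: int = 5,
    persistence: int = 3,
    backdate: bool = False,
) -> np.ndarray:
    """Boolean stance flags from a signed virtual-leg-angle series.

    Swing while the smoothed angle is increasing, stance while decreasing.
    A trend reversal must persist ``persistence`` frames before the state
    switches (debounce). With ``backdate=True`` each confirmed transition is
    moved back by the confirmation lag plus the smoothing group delay so
    that offline segmentations line up with the true extrema.
    """
    angles = np.asarray(angles, dtype=float)
    n = len(angles)
    if n < window:
        raise InsufficientDataError(
            f"angle series of length {n} is shorter than the smoothing window {window}"
        )
    sm = _causal_moving_average(angles, window)
    diff = np.diff(sm, prepend=sm[0])

    # initial state from the first nonzero trend; a flat series holds stance
    state = True  # stance
    for d in diff[1:]:
        if d > 0:
            state = False
            break
        if d < 0:
            state = True
            break

    lag = (persistence - 1) + (window - 1) // 2
    stance = np.empty(n, dtype=bool)
    count = 0
    last_switch = 0
    for i in range(n):
        d = diff[i]
        opposing = (d > 0 and state) or (d < 0 and not state)
        count = count + 1 if opposing else 0
        if count >= persistence:
            state = not state
            count = 0
            if backdate:
                j = max(last_switch + 1, i - lag)
                stance[j:i] = state
                last_switch = j
            else:
                last_switch = i
        stance[i] = state
    return stance


def detect_stance_swing(
    angle_series: Sequence[float],
    times: Optional[Sequence[float]] = None,
    window: int = 5,
    persistence: int = 3,
    backdate: bool = False,
) -> list[LegState]:
    """Per-frame :class:`LegState` from one leg's vertical-angle series."""
    angles = np.asarray(angle_series, dtype=float)
    stance = _stance_flags_from_angles(angles, window, persistence, backdate)
    sm = _causal_moving_average(angles, window)
    diff = np.diff(sm, prepend=sm[0])
    if times is None:
        times = np.arange(len(angles), dtype=float)
    else:
        times = np.asarray(times, dtype=float)
    states: list[LegState] = []
    entered: Optional[float] = None
    for i in range(len(angles)):
        if stance[i] and (i == 0 or not stance[i - 1]):
            entered = float(times[i])
        states.append(
            LegState(
                stance=bool(stance[i]),
                angle=float(angles[i]),
                trend=int(np.sign(diff[i])),
                entered_stance_at=entered,
            )
        )
    return states


def assign_phase(
    left: LegState,
    right: LegState,
    previous_phase: Optional[GaitPhase] = None,
) -> GaitPhase:
    """Combine per-leg stance states into one of the four gait phases.

    One leg in stance gives that leg's single support. Both legs in stance
    give the double support of the *leading* leg, operationalized as the leg
    that most recently entered stance (a heel strike initiates double
    support). Both legs in swing holds the previous phase; flight is outside
    the model.
    """
    if left.stance and not right.stance:
        return GaitPhase.LSS
    if right.stance and not left.stance:
        return GaitPhase.RSS
    if left.stance and right.stance:
        lt, rt = left.entered_stance_at, right.entered_stance_at
        if lt is not None and rt is not None and lt != rt:
            return GaitPhase.LDS if lt > rt else GaitPhase.RDS
        if previous_phase is not None:
            if previous_phase.is_double_support:
                return previous_phase
            # entering double support from single support: the striking leg
            # (the one that was in swing) leads
            return GaitPhase.LDS if previous_phase == GaitPhase.RSS else GaitPhase.RDS
        raise UnresolvedPhaseError(
            "cannot name the leading leg in double support at stream start"
        )
    # both in swing
    if previous_phase is None:
        raise UnresolvedPhaseError("both legs in swing with no previous phase")
    return previous_phase


def track_timestep(
    current_phase: GaitPhase,
    previous: Optional[PhaseTimestep],
    dt: float,
    elapsed: Optional[float] = None,
) -> PhaseTimestep:
    """Advance the within-phase timestep index.

    With ``elapsed`` (seconds since the phase began) given, the frame is
    binned to the nearest ``dt`` grid cell: ``k = max(1, round(elapsed/dt))``.
    Otherwise k increments by one while the phase holds and resets to 1 on a
    phase change.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if elapsed is not None:
        return PhaseTimestep(current_phase, max(1, int(round(elapsed / dt))))
    if previous is None or previous.phase != current_phase:
        return PhaseTimestep(current_phase, 1)
    return PhaseTimestep(current_phase, previous.k + 1)


_POSITION_COLS = [
    f"{seg}_{leg}_{ax}" for leg in ("l", "r") for seg in ("hip", "knee", "heel") for ax in ("x", "z")
]


def _phases_from_stance(
    stance_l: np.ndarray, stance_r: np.ndarray, times: np.ndarray
) -> list[GaitPhase]:
    n = len(stance_l)
    phases: list[Optional[GaitPhase]] = [None] * n
    entered_l: Optional[float] = None
    entered_r: Optional[float] = None
    prev: Optional[GaitPhase] = None
    first_resolved: Optional[int] = None
    for i in range(n):
        if stance_l[i] and (i == 0 or not stance_l[i - 1]):
            entered_l = None if i == 0 else float(times[i])
        if stance_r[i] and (i == 0 or not stance_r[i - 1]):
            entered_r = None if i == 0 else float(times[i])
        left = LegState(stance=bool(stance_l[i]), entered_stance_at=entered_l)
        right = LegState(stance=bool(stance_r[i]), entered_stance_at=entered_r)
        try:
            prev = assign_phase(left, right, prev)
            if first_resolved is None:
                first_resolved = i
        except UnresolvedPhaseError:
            prev = None
        phases[i] = prev
    if first_resolved is None:
        raise UnresolvedPhaseError(
            "gait phase could not be resolved anywhere in the stream"
        )
    # backfill the ambiguous opening frames: an initial double support is
    # led by the leg that remains in stance after the first toe-off, which
    # is exactly the phase first resolved (LSS follows LDS, RSS follows RDS)
    head = phases[first_resolved]
    for i in range(first_resolved):
        fill = head
        if stance_l[i] and stance_r[i] and head in (GaitPhase.LSS, GaitPhase.RSS):
            fill = GaitPhase.LDS if head == GaitPhase.LSS else GaitPhase.RDS
        phases[i] = fill
    return phases  # type: ignore[return-value]


def segment_stream(
    frames: pd.DataFrame,
    dt: Optional[float] = None,
    contact_columns: tuple[str, str] = ("contact_left", "contact_right"),
    window: int = 5,
    persistence: int = 3,
) -> list[PhaseTimestep]:
    """Segment a stream of frames into per-frame (phase, k) assignments.

    Contact flags take precedence when present; otherwise per-leg
    hip/knee/heel sagittal positions are required and stance/swing is
    inferred from the virtual-leg angle trend (with transition backdating to
    compensate the smoothing and debounce latency).
    """
    if dt is None:
        if "time" in frames.columns and len(frames) > 1:
            dt = float(np.median(np.diff(frames["time"].to_numpy())))
        else:
            dt = 0.01
    times = (
        frames["time"].to_numpy(dtype=float)
        if "time" in frames.columns
        else np.arange(len(frames)) * dt
    )
    if len(frames) == 0:
        return []

    cl, cr = contact_columns
    if cl in frames.columns and cr in frames.columns:
        stance_l = frames[cl].to_numpy() > 0.5
        stance_r = frames[cr].to_numpy() > 0.5
    elif all(c in frames.columns for c in _POSITION_COLS):
        stance = {}
        for leg in ("l", "r"):
            pts = {
                seg: frames[[f"{seg}_{leg}_x", f"{seg}_{leg}_z"]].to_numpy(dtype=float)
                for seg in ("hip", "knee", "heel")
            }
            v = 2.0 * (pts["knee"] - pts["hip"]) + (pts["heel"] - pts["knee"])
            ang = np.degrees(np.arctan2(v[:, 0], -v[:, 1]))
            stance[leg] = _stance_flags_from_angles(
                ang, window=window, persistence=persistence, backdate=True
            )
        stance_l, stance_r = stance["l"], stance["r"]
    else:
        raise ValueError(
            "stream has neither foot-contact columns nor per-leg position columns"
        )

    phases = _phases_from_stance(np.asarray(stance_l), np.asarray(stance_r), times)
    out: list[PhaseTimestep] = []
    prev: Optional[PhaseTimestep] = None
    for ph in phases:
        prev = track_timestep(ph, prev, dt)
        out.append(prev)
    return out
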