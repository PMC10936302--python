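"""Synthetic treadmill-walking generator.

Produces labeled multichannel joint-angle streams with the statistical
structure the intent algorithm assumes: at constant speed the measurement
at each (gait phase, timestep) cell is an i.i.d. Gaussian draw around a
periodic template, while speed changes shift both the trajectory amplitude
and the gait-cycle duration, so the classifier has signal in the distance
channel and in the timing channel.

The default template carries four channels — left/right thigh and shank
elevation angles (degrees, sagittal orientation relative to vertical,
positive forward), a standard planar representation of leg kinematics.
Per-channel trajectories are low-order Fourier series over normalized cycle
phase; the speed dependence is an amplitude gain ``1 + g (v - v_ref)`` and
a power-law cycle duration ``T(v) = T_ref (v_ref / v)^e`` calibrated so the
cycle lasts 1.03 s at the 1.4 m/s reference speed.

The standard protocol mirrors a treadmill experiment: ramp from standstill
to a 1.4 m/s baseline, then nine speed-up and nine slow-down trials (three
each of 0.1, 0.2, 0.3 m/s, in that fixed order), every trial consisting of
a 15 s baseline dwell, a constant-acceleration ramp, a 15 s plateau at the
new speed and a ramp back.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from gaitintent.exceptions import InvalidProtocolError
from gaitintent.segmentation import PHASE_ORDER, GaitPhase

__all__ = [
    "GaitTemplate",
    "TreadmillProfile",
    "Trial",
    "LabeledStream",
    "default_template",
    "build_standard_protocol",
    "constant_speed_profile",
    "simulate",
    "derive_segment_positions",
]

#: stance phases per leg under the LDS -> LSS -> RDS -> RSS convention
LEFT_STANCE = (GaitPhase.LDS, GaitPhase.LSS, GaitPhase.RDS)
RIGHT_STANCE = (GaitPhase.RDS, GaitPhase.RSS, GaitPhase.LDS)


@dataclass
class GaitTemplate:
    """Periodic trajectory template plus noise and speed-dependence.

    ``fourier`` has shape (channels, 1 + 2 H): per channel the constant
    term, then H cosine and H sine coefficients over normalized cycle phase
    (degrees). ``phase_fractions`` are the (LDS, LSS, RDS, RSS) shares of
    the cycle.
    """

    fourier: np.ndarray
    noise_covariance: np.ndarray
    phase_fractions: tuple[float, float, float, float] = (0.12, 0.38, 0.12, 0.38)
    amplitude_speed_gain: float = 0.4  # per (m/s)
    cycle_duration_at_reference: float = 1.03  # s
    reference_speed: float = 1.4  # m/s
    cycle_speed_exponent: float = 0.5
    channel_names: tuple[str, ...] = ("thigh_l", "shank_l", "thigh_r", "shank_r")

    def __post_init__(self):
        self.fourier = np.atleast_2d(np.asarray(self.fourier, dtype=float))
        self.noise_covariance = np.asarray(self.noise_covariance, dtype=float)
        m = self.fourier.shape[0]
        if self.noise_covariance.shape != (m, m):
            raise ValueError("noise covariance must be channels x channels")
        if not np.allclose(self.noise_covariance, self.noise_covariance.T):
            raise ValueError("noise covariance must be symmetric")
        if np.min(np.linalg.eigvalsh(self.noise_covariance)) <= 0:
            raise ValueError("noise covariance must be positive definite")
        fr = np.asarray(self.phase_fractions, dtype=float)
        if fr.shape != (4,) or np.any(fr <= 0) or abs(fr.sum() - 1.0) > 1e-12:
            raise ValueError("phase fractions must be four positives summing to 1")
        if self.cycle_duration_at_reference <= 0:
            raise ValueError("cycle duration must be positive")

    @property
    def channel_count(self) -> int:
        return self.fourier.shape[0]

    @property
    def harmonics(self) -> int:
        return (self.fourier.shape[1] - 1) // 2

    def evaluate(self, s) -> np.ndarray:
        """Template trajectory at normalized cycle phase(s) ``s`` in [0, 1)."""
        s = np.atleast_1d(np.asarray(s, dtype=float))
        h = np.arange(1, self.harmonics + 1)
        arg = 2.0 * np.pi * np.outer(s, h)
        design = np.hstack([np.ones((len(s), 1)), np.cos(arg), np.sin(arg)])
        return design @ self.fourier.T

    def cycle_duration(self, speed) -> np.ndarray:
        """Instantaneous cycle duration ``T(v)`` (s) at walking speed(s)."""
        v = np.asarray(speed, dtype=float)
        with np.errstate(divide="ignore"):
            return self.cycle_duration_at_reference * np.power(
                self.reference_speed / v, self.cycle_speed_exponent
            )


def _fit_fourier(values: np.ndarray, s: np.ndarray, harmonics: int) -> np.ndarray:
    h = np.arange(1, harmonics + 1)
    arg = 2.0 * np.pi * np.outer(s, h)
    design = np.hstack([np.ones((len(s), 1)), np.cos(arg), np.sin(arg)])
    coef, *_ = np.linalg.lstsq(design, values, rcond=None)
    return coef


def default_template(
    noise_std: float = 1.0,
    amplitude_speed_gain: float = 0.4,
    phase_fractions: tuple[float, float, float, float] = (0.12, 0.38, 0.12, 0.38),
    harmonics: int = 8,
) -> GaitTemplate:
    """Four-channel default template (left/right thigh & shank elevation).

    Each segment angle follows a time-warped cosine: it peaks at that leg's
    heel strike, falls monotonically through stance (fraction
    LDS + LSS + RDS of the cycle for the left leg) and rises monotonically
    through swing, which is exactly the monotone virtual-leg-angle behavior
    the stance/swing detector relies on. Amplitudes of 25 deg (thigh) and
    35 deg (shank) span typical sagittal excursions; the right leg is the
    left delayed by half a cycle. Noise defaults to independent 1 deg
    standard deviation per channel.
    """
    fr = np.asarray(phase_fractions, dtype=float)
    stance_fraction = fr[0] + fr[1] + fr[2]  # left leg stance share

    s = (np.arange(4096) + 0.5) / 4096

    def warped_cosine(amplitude: float, offset: float, shift: float) -> np.ndarray:
        ss = np.mod(s - shift, 1.0)
        u = np.where(
            ss < stance_fraction,
            ss / stance_fraction,
            1.0 + (ss - stance_fraction) / (1.0 - stance_fraction),
        )
        return offset + amplitude * np.cos(np.pi * u)

    channels = np.column_stack(
        [
            warped_cosine(25.0, 2.0, 0.0),   # left thigh
            warped_cosine(35.0, -3.0, 0.0),  # left shank
            warped_cosine(25.0, 2.0, 0.5),   # right thigh
            warped_cosine(35.0, -3.0, 0.5),  # right shank
        ]
    )
    coef = _fit_fourier(channels, s, harmonics).T
    return GaitTemplate(
        fourier=coef,
        noise_covariance=noise_std**2 * np.eye(4),
        phase_fractions=tuple(fr),
        amplitude_speed_gain=amplitude_speed_gain,
    )


@dataclass(frozen=True)
class Trial:
    """One speed-change trial of the treadmill protocol."""

    kind: str  # "SU" or "SD"
    magnitude: float  # m/s, positive
    onset: float  # s, instant the speed first leaves baseline
    ramp_end: float
    plateau_end: float
    return_time: float  # s, instant the speed is back at baseline

    @property
    def target_speed_offset(self) -> float:
        return self.magnitude if self.kind == "SU" else -self.magnitude


@dataclass
class TreadmillProfile:
    """Piecewise-linear treadmill speed trajectory."""

    breakpoints: list[tuple[float, float]]
    baseline_speed: float = 1.4
    acceleration: float = 0.5
    trials: list[Trial] = field(default_factory=list)

    def __post_init__(self):
        ts = np.asarray([t for t, _ in self.breakpoints], dtype=float)
        vs = np.asarray([v for _, v in self.breakpoints], dtype=float)
        if len(ts) < 2 or np.any(np.diff(ts) <= 0):
            raise InvalidProtocolError("breakpoint times must be strictly increasing")
        if np.any(vs < 0):
            raise InvalidProtocolError("speeds must be nonnegative")
        self._ts, self._vs = ts, vs

    @property
    def duration(self) -> float:
        return float(self._ts[-1])

    def speed_at(self, t) -> np.ndarray:
        """Speed (m/s) at time(s) ``t`` by linear interpolation."""
        return np.interp(t, self._ts, self._vs)


def constant_speed_profile(speed: float, duration: float) -> TreadmillProfile:
    """A trivial profile: constant walking speed for ``duration`` seconds."""
    if speed < 0 or duration <= 0:
        raise ValueError("speed must be >= 0 and duration positive")
    return TreadmillProfile(
        [(0.0, speed), (float(duration), speed)], baseline_speed=speed
    )


def build_standard_protocol(
    baseline_speed: float = 1.4,
    deltas: Sequence[float] = (0.1, 0.2, 0.3),
    dwell: float = 15.0,
    acceleration: float = 0.5,
    repeats: int = 3,
) -> TreadmillProfile:
    """The treadmill testing protocol: speed-up then slow-down trials.

    Ramps from standstill to ``baseline_speed``; then for each direction
    (speed-up first), each magnitude in ascending order repeated ``repeats``
    times: a ``dwell`` at baseline, a constant-acceleration ramp to
    baseline +/- delta, a ``dwell`` plateau, and a ramp back. A final dwell
    at baseline closes the profile. With the defaults this yields nine SU
    and nine SD trials (three each of 0.1/0.2/0.3 m/s) in fixed order.
    """
    if baseline_speed <= 0:
        raise ValueError("baseline speed must be positive")
    if dwell <= 0 or acceleration <= 0:
        raise ValueError("dwell and acceleration must be positive")
    if any(d <= 0 for d in deltas):
        raise ValueError("speed-change magnitudes must be positive")
    if any(baseline_speed - d < 0 for d in deltas):
        raise ValueError("a slow-down trial would require negative speed")

    t = baseline_speed / acceleration
    bps: list[tuple[float, float]] = [(0.0, 0.0), (t, baseline_speed)]
    trials: list[Trial] = []
    for kind, sign in (("SU", 1.0), ("SD", -1.0)):
        for delta in sorted(deltas):
            for _ in range(repeats):
                onset = t + dwell
                ramp = delta / acceleration
                target = baseline_speed + sign * delta
                ramp_end = onset + ramp
                plateau_end = ramp_end + dwell
                return_time = plateau_end + ramp
                bps += [
                    (onset, baseline_speed),
                    (ramp_end, target),
                    (plateau_end, target),
                    (return_time, baseline_speed),
                ]
                trials.append(
                    Trial(kind, float(delta), onset, ramp_end, plateau_end, return_time)
                )
                t = return_time
    bps.append((t + dwell, baseline_speed))
    return TreadmillProfile(
        bps, baseline_speed=baseline_speed, acceleration=acceleration, trials=trials
    )


@dataclass
class LabeledStream:
    """A simulated sensor stream with ground-truth phase and speed labels."""

    frames: pd.DataFrame
    dt: float
    n_channels: int

    @property
    def channel_columns(self) -> list[str]:
        return [f"ch_{i + 1}" for i in range(self.n_channels)]

    def measurements(self) -> np.ndarray:
        return self.frames[self.channel_columns].to_numpy(dtype=float)

    def to_csv(self, path) -> None:
        self.frames.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "LabeledStream":
        frames = pd.read_csv(path)
        channels = [c for c in frames.columns if c.startswith("ch_")]
        dt = (
            float(np.median(np.diff(frames["time"].to_numpy())))
            if len(frames) > 1
            else 0.01
        )
        return cls(frames, dt, len(channels))


def simulate(
    template: GaitTemplate,
    profile: TreadmillProfile,
    duration: Optional[float] = None,
    seed: int = 0,
    dt: float = 0.01,
) -> LabeledStream:
    """Simulate a labeled walking stream under a treadmill speed profile.

    The cycle phase advances by ``dt / T(v)`` per frame; the gait phase
    label follows the template's phase fractions in the fixed cyclic order;
    the measurement is the template trajectory scaled by
    ``1 + g (v - v_ref)`` plus correlated Gaussian noise. Frames at zero
    speed carry a standing flag and do not advance the cycle. The stream is
    reproducible given the seed.
    """
    if duration is None:
        duration = profile.duration
    if duration <= 0:
        raise ValueError("duration must be positive")
    n = int(round(duration / dt))
    times = np.arange(n) * dt
    v = profile.speed_at(times)
    standing = v <= 0.0

    T = template.cycle_duration(np.where(standing, np.nan, v))
    ds = np.where(standing, 0.0, dt / T)
    s = np.concatenate([[0.0], np.cumsum(ds[:-1])])
    frac = np.mod(s, 1.0)

    bounds = np.cumsum(np.asarray(template.phase_fractions)[:3])
    phase_idx = np.searchsorted(bounds, frac, side="right")
    phase_labels = np.array([p.value for p in PHASE_ORDER], dtype=object)[phase_idx]
    phase_labels[standing] = "STAND"

    rng = np.random.default_rng(seed)
    gain = 1.0 + template.amplitude_speed_gain * (v - template.reference_speed)
    clean = template.evaluate(frac) * gain[:, None]
    chol = np.linalg.cholesky(template.noise_covariance)
    noise = rng.standard_normal((n, template.channel_count)) @ chol.T
    x = clean + noise

    left_stance = np.isin(phase_labels, [p.value for p in LEFT_STANCE]) | standing
    right_stance = np.isin(phase_labels, [p.value for p in RIGHT_STANCE]) | standing

    frames = pd.DataFrame({"time": times})
    for j in range(template.channel_count):
        frames[f"ch_{j + 1}"] = x[:, j]
    frames["phase"] = phase_labels
    frames["speed"] = v
    frames["standing"] = standing.astype(int)
    frames["contact_left"] = left_stance.astype(int)
    frames["contact_right"] = right_stance.astype(int)
    return LabeledStream(frames, dt, template.channel_count)


def derive_segment_positions(
    stream: LabeledStream,
    thigh_length: float = 0.45,
    shank_length: float = 0.45,
    channel_pairs: tuple[tuple[int, int], tuple[int, int]] = ((0, 1), (2, 3)),
) -> LabeledStream:
    """Append per-leg hip/knee/heel sagittal positions to a stream.

    Planar two-link kinematics per leg: the channels indexed by
    ``channel_pairs`` are (thigh, shank) elevation angles relative to
    vertical. The hip translates horizontally at the treadmill speed; the
    vertical axis is the last ('z') coordinate. Zero angles give a straight
    vertical leg.
    """
    frames = stream.frames.copy()
    chans = stream.channel_columns
    needed = max(i for pair in channel_pairs for i in pair)
    if needed >= stream.n_channels:
        raise ValueError(
            f"channel pair index {needed} exceeds the stream's {stream.n_channels} channels"
        )
    hip_z = thigh_length + shank_length + 0.05
    if "speed" in frames.columns:
        hip_x = np.concatenate(
            [[0.0], np.cumsum(frames["speed"].to_numpy()[:-1] * stream.dt)]
        )
    else:
        hip_x = np.zeros(len(frames))
    for leg, (i_thigh, i_shank) in zip(("l", "r"), channel_pairs):
        th = np.radians(frames[chans[i_thigh]].to_numpy(dtype=float))
        sh = np.radians(frames[chans[i_shank]].to_numpy(dtype=float))
        knee_x = hip_x + thigh_length * np.sin(th)
        knee_z = hip_z - thigh_length * np.cos(th)
        heel_x = knee_x + shank_length * np.sin(sh)
        heel_z = knee_z - shank_length * np.cos(sh)
        frames[f"hip_{leg}_x"] = hip_x
        frames[f"hip_{leg}_z"] = hip_z
        frames[f"knee_{leg}_x"] = knee_x
        frames[f"knee_{leg}_z"] = knee_z
        frames[f"heel_{leg}_x"] = heel_x
        frames[f"heel_{leg}_z"] = heel_z
    return LabeledStream(frames, stream.dt, stream.n_channels)
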