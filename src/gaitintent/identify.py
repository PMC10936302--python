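"""Real-time walking-speed intent classification.

Each incoming frame is scored against the fitted gait model by squared
Mahalanobis distance, smoothed with a causal first-order Butterworth
low-pass filter, and compared with a chi-squared-calibrated threshold
(default 13.5, the 0.99 CDF level for four channels). Two timing checks
complement the distance test:

* Question A — the current phase has lasted more timesteps than the model
  holds for it, by more than one (configurable) training standard
  deviation: the gait is running long.
* Question B — the phase that just completed ended more timesteps short of
  the model than one training standard deviation: the gait is running
  short. The flag is held for the duration of the newly entered phase.

Either condition, or the filtered distance exceeding the threshold, flags a
change of intended speed. Its type comes from Question C: whether the most
recently completed gait cycle was faster or slower than the training mean
(faster -> SU, slower -> SD). Without a flag, or without a resolved cycle
direction, the frame is labeled NC.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.signal
import yaml

from gaitintent.model import GaitModelResults, PhaseTimingStats
from gaitintent.segmentation import GaitPhase, PhaseTimestep, segment_stream

__all__ = [
    "IntentLabel",
    "Direction",
    "ClassifierConfig",
    "ClassifierState",
    "FirstOrderLowpass",
    "question_a",
    "question_b",
    "question_c",
    "IntentIdentifier",
    "run_stream",
]


class IntentLabel(enum.Enum):
    SU = "SU"  # speed up
    SD = "SD"  # slow down
    NC = "NC"  # no change


class Direction(enum.Enum):
    FASTER = "faster"
    SLOWER = "slower"
    UNCHANGED = "unchanged"
    NONE = "none"  # no completed cycle yet


@dataclass
class ClassifierConfig:
    """Tunable parameters of the real-time classifier.

    ``squared_md_threshold`` defaults to 13.5, the squared-distance level
    whose chi-squared CDF with four channels is 0.99. ``filter_cutoff`` is
    the Butterworth low-pass cut-off in Hz. ``ridge`` of None defers to the
    fitted model's value.
    """

    squared_md_threshold: float = 13.5
    filter_cutoff: float = 1.2
    dt: float = 0.01
    timing_std_multiplier: float = 1.0
    ridge: Optional[float] = None
    reference_phase: GaitPhase = GaitPhase.LDS

    def __post_init__(self):
        if self.squared_md_threshold <= 0:
            raise ValueError("threshold must be positive")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not 0 < self.filter_cutoff < 0.5 / self.dt:
            raise ValueError("filter cutoff must lie in (0, Nyquist)")
        if self.timing_std_multiplier <= 0:
            raise ValueError("timing std multiplier must be positive")

    @classmethod
    def from_yaml(cls, path) -> "ClassifierConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "reference_phase" in raw:
            raw["reference_phase"] = GaitPhase(raw["reference_phase"])
        return cls(**raw)


class FirstOrderLowpass:
    """Causal first-order Butterworth low-pass filter, stepped per sample.

    The state initializes to the first input value, so a constant input
    passes through unchanged from the first sample (DC gain 1) and startup
    transients cannot spuriously cross the novelty threshold.
    """

    def __init__(self, cutoff: float, dt: float):
        if not 0 < cutoff < 0.5 / dt:
            raise ValueError("cutoff must lie strictly between 0 and Nyquist")
        b, a = scipy.signal.butter(1, cutoff * 2.0 * dt, btype="low")
        self.b0, self.b1 = float(b[0]), float(b[1])
        self.a1 = float(a[1])
        self._x1: Optional[float] = None
        self._y1: Optional[float] = None

    @property
    def initialized(self) -> bool:
        return self._y1 is not None

    @property
    def value(self) -> float:
        if self._y1 is None:
            raise ValueError("filter has not seen any input")
        return self._y1

    def step(self, x: float) -> float:
        if self._y1 is None:
            self._x1 = self._y1 = float(x)
            return float(x)
        y = self.b0 * x + self.b1 * self._x1 - self.a1 * self._y1
        self._x1, self._y1 = float(x), float(y)
        return float(y)


def _timing_std(model: GaitModelResults, phase: GaitPhase) -> float:
    """Training phase-length std, floored at one timestep.

    Phase lengths are quantized to the sample grid, so a measured std below
    one timestep reflects grid aliasing rather than gait variability; a
    sub-frame std would make the timing questions fire on the inevitable
    +/- 1-frame wobble of clean, steady walking.
    """
    return max(model.timing.phase_steps_std.get(phase, 0.0), 1.0)


def question_a(current: PhaseTimestep, model: GaitModelResults, multiplier: float = 1.0) -> bool:
    """Has the current phase outlasted the model by more than ``multiplier``
    training standard deviations of its length?"""
    max_k = model.max_k(current.phase)
    return (current.k - max_k) > multiplier * _timing_std(model, current.phase)


def question_b(
    previous_phase: GaitPhase,
    previous_final_k: int,
    model: GaitModelResults,
    multiplier: float = 1.0,
) -> bool:
    """Did the phase that just completed end short of the model by more than
    ``multiplier`` training standard deviations?"""
    max_k = model.max_k(previous_phase)
    return (max_k - previous_final_k) > multiplier * _timing_std(model, previous_phase)


def question_c(completed_cycle_duration: float, timing: PhaseTimingStats) -> Direction:
    """Was the most recently completed gait cycle faster or slower than the
    training mean? An exact tie resolves to UNCHANGED."""
    if completed_cycle_duration < timing.cycle_mean:
        return Direction.FASTER
    if completed_cycle_duration > timing.cycle_mean:
        return Direction.SLOWER
    return Direction.UNCHANGED


@dataclass
class ClassifierState:
    """Mutable per-stream classifier state."""

    pt: Optional[PhaseTimestep] = None
    filter: Optional[FirstOrderLowpass] = None
    b_flag: bool = False
    direction: Direction = Direction.NONE
    last_cycle_duration: Optional[float] = None
    ref_start_index: Optional[int] = None
    frame_index: int = -1


class IntentIdentifier:
    """Streaming SU/SD/NC classifier bound to a fitted gait model."""

    def __init__(self, results: GaitModelResults, config: Optional[ClassifierConfig] = None):
        self.results = results
        self.config = config or ClassifierConfig(dt=results.dt)
        if self.config.ridge is not None and self.config.ridge != results.ridge:
            # scoring ridge is a property of the results object; rebind
            results.ridge = self.config.ridge
            results._cho_cache.clear()
        self.state = ClassifierState()

    def reset(self) -> None:
        self.state = ClassifierState()

    def classify_step(self, x, phase_timestep: PhaseTimestep, standing: bool = False):
        """Process one frame; returns ``(label, diagnostics)``.

        Diagnostics expose the raw and filtered squared distances, which
        trigger (distance / Question A / Question B) fired, and the current
        cycle-speed direction.
        """
        st = self.state
        cfg = self.config
        st.frame_index += 1
        i = st.frame_index

        diag = {
            "phase": phase_timestep.phase.value if not standing else "STAND",
            "k": phase_timestep.k,
            "raw_d2": np.nan,
            "filtered_d2": np.nan,
            "trigger_md": False,
            "trigger_a": False,
            "trigger_b": False,
            "direction": st.direction.value,
            "note": "",
        }
        if standing:
            diag["note"] = "standing"
            return IntentLabel.NC, diag

        if st.pt is not None and phase_timestep.phase != st.pt.phase:
            # the previous phase just completed
            st.b_flag = question_b(
                st.pt.phase, st.pt.k, self.results, cfg.timing_std_multiplier
            )
            if phase_timestep.phase == cfg.reference_phase:
                if st.ref_start_index is not None:
                    st.last_cycle_duration = (i - st.ref_start_index) * cfg.dt
                    st.direction = question_c(st.last_cycle_duration, self.results.timing)
                    diag["direction"] = st.direction.value
                st.ref_start_index = i
        elif st.pt is None and phase_timestep.phase == cfg.reference_phase:
            st.ref_start_index = i
        st.pt = phase_timestep

        phase, k = phase_timestep.phase, phase_timestep.k
        max_k = self.results.max_k(phase)
        if k <= max_k:
            cell = self.results.cell(phase, k)
            if cell is None:
                raise RuntimeError(
                    f"model range for phase {phase.value} covers k={k} but the "
                    "cell is missing (non-contiguous model)"
                )
            d2 = self.results.squared_mahalanobis(np.asarray(x, dtype=float), phase, k)
            if st.filter is None:
                st.filter = FirstOrderLowpass(cfg.filter_cutoff, cfg.dt)
            filtered = st.filter.step(d2)
            diag["raw_d2"] = d2
            diag["filtered_d2"] = filtered
        else:
            # gait has outlasted the model: no distribution to score against;
            # the filter holds its last value and timing flags carry the load
            if st.filter is not None and st.filter.initialized:
                diag["filtered_d2"] = st.filter.value

        trig_md = (
            st.filter is not None
            and st.filter.initialized
            and st.filter.value > cfg.squared_md_threshold
        )
        trig_a = question_a(phase_timestep, self.results, cfg.timing_std_multiplier)
        diag["trigger_md"] = trig_md
        diag["trigger_a"] = trig_a
        diag["trigger_b"] = st.b_flag

        if trig_md or trig_a or st.b_flag:
            if st.direction == Direction.FASTER:
                return IntentLabel.SU, diag
            if st.direction == Direction.SLOWER:
                return IntentLabel.SD, diag
            diag["note"] = "type-unresolvable"
        return IntentLabel.NC, diag

    def run(
        self,
        frames: pd.DataFrame,
        phase_timesteps: Optional[Sequence[PhaseTimestep]] = None,
        channels: Optional[Sequence[str]] = None,
    ) -> pd.DataFrame:
        """Classify every frame of a stream; returns a diagnostics table.

        Columns: time, phase, k, raw_d2, filtered_d2, trigger flags,
        direction and label. One label per frame; deterministic given the
        inputs. An empty stream yields an empty table.
        """
        self.reset()
        cols = [
            "time", "phase", "k", "raw_d2", "filtered_d2",
            "trigger_md", "trigger_a", "trigger_b", "direction", "note", "label",
        ]
        if len(frames) == 0:
            return pd.DataFrame(columns=cols)
        if channels is None:
            channels = [c for c in frames.columns if c.startswith("ch_")]
        if phase_timesteps is None:
            phase_timesteps = segment_stream(frames, dt=self.config.dt)
        x = frames[list(channels)].to_numpy(dtype=float)
        times = (
            frames["time"].to_numpy(dtype=float)
            if "time" in frames.columns
            else np.arange(len(frames)) * self.config.dt
        )
        standing = (
            frames["standing"].to_numpy() > 0.5
            if "standing" in frames.columns
            else np.zeros(len(frames), dtype=bool)
        )
        records = []
        for i, pt in enumerate(phase_timesteps):
            label, diag = self.classify_step(x[i], pt, standing=bool(standing[i]))
            diag["time"] = times[i]
            diag["label"] = label.value
            records.append(diag)
        return pd.DataFrame.from_records(records, columns=cols)


def run_stream(
    frames: pd.DataFrame,
    model: GaitModelResults,
    config: Optional[ClassifierConfig] = None,
    phase_timesteps: Optional[Sequence[PhaseTimestep]] = None,
) -> pd.DataFrame:
    """Functional wrapper: classify a whole stream against a fitted model."""
    return IntentIdentifier(model, config).run(frames, phase_timesteps)
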