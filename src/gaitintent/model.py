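"""Cyclostationary Gaussian gait model.

Constant-speed walking is modeled as a cyclostationary random process: the
sensor vector at timestep ``k`` of gait phase ``phi`` is multivariate
Gaussian with cell-specific mean ``mu[phi,k]`` and covariance
``Sigma[phi,k]``, independent across timesteps. Each cell is trained with
single-pass recursive updates that reproduce the batch maximum-likelihood
(divide-by-n) estimates exactly, so the model converges with minutes of
data. Scoring a new frame uses the squared Mahalanobis distance

    d2 = (x - mu)' (Sigma + ridge*I)^{-1} (x - mu)

which for in-distribution Gaussian frames follows a chi-squared law with
``m`` (channel count) degrees of freedom; chi-squared calibration turns a
CDF level (e.g. 0.99) into a novelty threshold on d2.

The public surface follows the model/results split common in statistical
packages: :class:`CyclostationaryGaitModel` holds the training data and
configuration, ``fit()`` returns a :class:`GaitModelResults` carrying the
cells, phase/cycle timing statistics, ``summary()`` and persistence.
"""

from __future__ import annotations

import datetime
import json
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.stats

from gaitintent.exceptions import IllConditionedModelError, ModelFormatError
from gaitintent.segmentation import (
    PHASE_ORDER,
    GaitPhase,
    PhaseTimestep,
    segment_stream,
)

__all__ = [
    "GaussianCell",
    "PhaseTimingStats",
    "CyclostationaryGaitModel",
    "GaitModelResults",
    "update_cell",
    "squared_mahalanobis",
    "chi2_cdf",
    "threshold_for_cdf",
]

MODEL_FORMAT_VERSION = "1"


@dataclass
class GaussianCell:
    """Running Gaussian estimate for one (phase, timestep) cell.

    ``mu`` is the sample mean and ``sigma`` the maximum-likelihood
    (divide-by-n) covariance of the ``n`` observations seen so far.
    """

    n: int
    mu: np.ndarray
    sigma: np.ndarray

    def copy(self) -> "GaussianCell":
        return GaussianCell(self.n, self.mu.copy(), self.sigma.copy())


def update_cell(cell: Optional[GaussianCell], x: Sequence[float]) -> GaussianCell:
    """Incorporate one observation into a cell (recursive MLE update).

    With ``cell=None`` a fresh cell is created (n=1, zero covariance).
    The recursion keeps ``mu`` equal to the sample mean and ``sigma`` equal
    to the divide-by-n covariance of all observations so far:

        mu_n    = mu_{n-1} + (x - mu_{n-1}) / n
        Sigma_n = (n-1)/n * Sigma_{n-1}
                  + (n-1)/n^2 * (x - mu_{n-1})(x - mu_{n-1})'
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("observation must be a 1-D vector")
    if not np.all(np.isfinite(x)):
        raise ValueError("observation must be finite")
    if cell is None:
        m = len(x)
        return GaussianCell(1, x.copy(), np.zeros((m, m)))
    if len(x) != len(cell.mu):
        raise ValueError(
            f"observation length {len(x)} does not match cell dimension {len(cell.mu)}"
        )
    n = cell.n + 1
    delta = x - cell.mu
    mu = cell.mu + delta / n
    sigma = (n - 1) / n * cell.sigma + (n - 1) / n**2 * np.outer(delta, delta)
    sigma = 0.5 * (sigma + sigma.T)  # keep exact symmetry
    return GaussianCell(n, mu, sigma)


def squared_mahalanobis(
    x: Sequence[float], cell: GaussianCell, ridge: float = 1e-6
) -> float:
    """Squared Mahalanobis distance of ``x`` from a cell's Gaussian.

    The covariance is regularized with ``ridge`` (degrees^2) on the
    diagonal and inverted implicitly through a Cholesky solve.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != cell.mu.shape:
        raise ValueError(
            f"vector length {x.shape} does not match cell dimension {cell.mu.shape}"
        )
    a = cell.sigma + ridge * np.eye(len(x))
    delta = x - cell.mu
    try:
        cho = scipy.linalg.cho_factor(a, lower=True)
        y = scipy.linalg.cho_solve(cho, delta)
    except scipy.linalg.LinAlgError as exc:
        raise IllConditionedModelError(
            f"regularized covariance is numerically singular: {exc}"
        ) from exc
    return float(max(delta @ y, 0.0))


def chi2_cdf(d2: float, dof: int) -> float:
    """Chi-squared CDF at ``d2`` with ``dof`` degrees of freedom."""
    if dof < 1:
        raise ValueError("degrees of freedom must be a positive integer")
    d2 = np.asarray(d2, dtype=float)
    if np.any(d2 < 0):
        raise ValueError("a squared distance cannot be negative")
    out = scipy.stats.chi2.cdf(d2, dof)
    return float(out) if np.isscalar(d2) or d2.ndim == 0 else out


def threshold_for_cdf(p: float, dof: int) -> float:
    """Squared-distance threshold whose chi-squared CDF equals ``p``."""
    if dof < 1:
        raise ValueError("degrees of freedom must be a positive integer")
    if not 0.0 < p < 1.0:
        raise ValueError("the CDF level must lie strictly between 0 and 1")
    return float(scipy.stats.chi2.ppf(p, dof))


@dataclass
class PhaseTimingStats:
    """Phase-length and gait-cycle-duration statistics from training.

    Phase lengths are in timesteps (frames); cycle durations in seconds,
    measured between successive starts of the reference phase and computed
    as frame-count x dt so that identical cycles compare exactly equal.
    Standard deviations are population (divide-by-n) values; with a single
    occurrence the std is stored as 0 and the model flagged.
    """

    phase_steps_mean: dict[GaitPhase, float]
    phase_steps_std: dict[GaitPhase, float]
    phase_max_k: dict[GaitPhase, int]
    cycle_mean: float
    cycle_std: float
    n_cycles: int


class CyclostationaryGaitModel:
    """Model specification bound to a training stream.

    Parameters
    ----------
    measurements : (n_frames, m) array
        Sensor vectors (e.g. joint angles in degrees) at a fixed rate.
    phase_timesteps : sequence of PhaseTimestep
        Per-frame gait phase and within-phase timestep, aligned with
        ``measurements``.
    dt : float
        Sample interval in seconds.
    reference_phase : GaitPhase
        Phase whose start anchors gait-cycle boundaries for timing stats.
    ridge : float
        Diagonal regularization (degrees^2) applied when scoring.
    min_cell_count : int
        Cells trained on fewer observations are flagged in the results.
    """

    def __init__(
        self,
        measurements,
        phase_timesteps: Sequence[PhaseTimestep],
        dt: float = 0.01,
        reference_phase: GaitPhase = GaitPhase.LDS,
        ridge: float = 1e-6,
        min_cell_count: int = 3,
        standing: Optional[Sequence[bool]] = None,
    ):
        self.measurements = np.asarray(measurements, dtype=float)
        if self.measurements.ndim != 2:
            raise ValueError("measurements must be a 2-D (frames x channels) array")
        if len(phase_timesteps) != len(self.measurements):
            raise ValueError("measurements and phase_timesteps must be aligned")
        if dt <= 0:
            raise ValueError("dt must be positive")
        self.phase_timesteps = list(phase_timesteps)
        self.dt = float(dt)
        self.reference_phase = reference_phase
        self.ridge = float(ridge)
        self.min_cell_count = int(min_cell_count)
        self.standing = (
            np.zeros(len(self.measurements), dtype=bool)
            if standing is None
            else np.asarray(standing, dtype=bool)
        )

    @classmethod
    def from_dataframe(
        cls,
        frames: pd.DataFrame,
        channels: Optional[Sequence[str]] = None,
        phase_timesteps: Optional[Sequence[PhaseTimestep]] = None,
        **kwargs,
    ) -> "CyclostationaryGaitModel":
        """Build the model from a stream DataFrame.

        Channels default to the ``ch_*`` columns; phases are segmented from
        contact flags or positions when not supplied. Frames flagged as
        standing are excluded from training.
        """
        if channels is None:
            channels = [c for c in frames.columns if c.startswith("ch_")]
        if not channels:
            raise ValueError("no measurement channels found or given")
        if phase_timesteps is None:
            phase_timesteps = segment_stream(frames, dt=kwargs.get("dt"))
        standing = (
            frames["standing"].to_numpy() > 0.5
            if "standing" in frames.columns
            else None
        )
        if "time" in frames.columns and "dt" not in kwargs and len(frames) > 1:
            kwargs["dt"] = float(np.median(np.diff(frames["time"].to_numpy())))
        return cls(
            frames[list(channels)].to_numpy(dtype=float),
            phase_timesteps,
            standing=standing,
            **kwargs,
        )

    def fit(self) -> "GaitModelResults":
        """Train the per-cell Gaussians and timing statistics.

        Frames are folded in one at a time with :func:`update_cell`. The
        first (possibly partial) phase occurrence is excluded, since a
        stream may start mid-phase with an unknown offset; timing
        statistics use only occurrences whose boundaries both fall inside
        the stream.
        """
        pts = self.phase_timesteps
        n = len(pts)
        if n == 0:
            raise ValueError("cannot fit a model on an empty stream")
        walking = ~self.standing

        # identify phase runs over walking frames
        runs: list[tuple[GaitPhase, int, int]] = []  # (phase, start, stop) stop excl.
        start = None
        for i in range(n):
            if not walking[i]:
                if start is not None:
                    runs.append((pts[start].phase, start, i))
                    start = None
                continue
            if start is None:
                start = i
            elif pts[i].phase != pts[start].phase or pts[i].k <= pts[i - 1].k:
                runs.append((pts[start].phase, start, i))
                start = i
        if start is not None:
            runs.append((pts[start].phase, start, n))
        if not runs:
            raise ValueError("no walking frames to train on")

        cells: dict[tuple[GaitPhase, int], GaussianCell] = {}
        # drop the first run: a stream may begin mid-phase with unknown k offset
        train_runs = runs[1:] if len(runs) > 1 else runs
        for phase, lo, hi in train_runs:
            for i in range(lo, hi):
                key = (phase, pts[i].k)
                cells[key] = update_cell(cells.get(key), self.measurements[i])

        # complete occurrences: all but the first and last run
        complete = runs[1:-1] if len(runs) > 2 else []
        phase_lengths: dict[GaitPhase, list[int]] = {p: [] for p in PHASE_ORDER}
        for phase, lo, hi in complete:
            phase_lengths[phase].append(pts[hi - 1].k)

        warning_flags: list[str] = []
        steps_mean, steps_std, max_k = {}, {}, {}
        for p in PHASE_ORDER:
            lens = phase_lengths[p]
            ks = [k for (ph, k) in cells if ph == p]
            max_k[p] = max(ks) if ks else 0
            if len(lens) == 0:
                steps_mean[p] = float(max_k[p])
                steps_std[p] = 0.0
                warning_flags.append(f"no complete occurrence of phase {p.value}")
            else:
                steps_mean[p] = float(np.mean(lens))
                steps_std[p] = float(np.std(lens))
                if len(lens) < 2:
                    warning_flags.append(
                        f"only one complete occurrence of phase {p.value}; timing std set to 0"
                    )

        # cycle durations between successive reference-phase starts
        ref_starts = [lo for phase, lo, hi in complete + ([runs[-1]] if len(runs) > 1 else [])
                      if phase == self.reference_phase]
        durations = [
            (ref_starts[i + 1] - ref_starts[i]) * self.dt
            for i in range(len(ref_starts) - 1)
        ]
        if durations:
            cycle_mean = float(np.mean(durations))
            cycle_std = float(np.std(durations))
        else:
            cycle_mean = float(sum(steps_mean[p] for p in PHASE_ORDER)) * self.dt
            cycle_std = 0.0
            warning_flags.append("no complete gait cycle; cycle stats from phase means")

        timing = PhaseTimingStats(
            steps_mean, steps_std, max_k, cycle_mean, cycle_std, max(len(durations), 0)
        )
        low = sorted(
            f"{p.value}:{k}" for (p, k), c in cells.items() if c.n < self.min_cell_count
        )
        if low:
            warning_flags.append(f"{len(low)} cells below min count {self.min_cell_count}")

        metadata = {
            "n_frames": int(walking.sum()),
            "training_duration_s": float(walking.sum() * self.dt),
            "created": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        }
        return GaitModelResults(
            m=self.measurements.shape[1],
            dt=self.dt,
            cells=cells,
            timing=timing,
            reference_phase=self.reference_phase,
            ridge=self.ridge,
            min_cell_count=self.min_cell_count,
            warning_flags=warning_flags,
            metadata=metadata,
        )


@dataclass
class GaitModelResults:
    """A fitted cyclostationary gait model.

    Maps every observed (phase, timestep) to a :class:`GaussianCell` and
    carries the phase-length and cycle-duration statistics the real-time
    classifier needs. Obtained from :meth:`CyclostationaryGaitModel.fit` or
    :meth:`load`.
    """

    m: int
    dt: float
    cells: dict[tuple[GaitPhase, int], GaussianCell]
    timing: PhaseTimingStats
    reference_phase: GaitPhase = GaitPhase.LDS
    ridge: float = 1e-6
    min_cell_count: int = 3
    warning_flags: list[str] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self._cho_cache: dict[tuple[GaitPhase, int], object] = {}

    # -- queries ---------------------------------------------------------

    def max_k(self, phase: GaitPhase) -> int:
        return self.timing.phase_max_k.get(phase, 0)

    def cell(self, phase: GaitPhase, k: int) -> Optional[GaussianCell]:
        return self.cells.get((phase, k))

    def squared_mahalanobis(self, x, phase: GaitPhase, k: int) -> float:
        """Squared Mahalanobis distance of ``x`` from cell (phase, k)."""
        cell = self.cells.get((phase, k))
        if cell is None:
            raise KeyError(f"no cell for phase {phase.value}, timestep {k}")
        x = np.asarray(x, dtype=float)
        if x.shape != (self.m,):
            raise ValueError(f"expected a length-{self.m} vector")
        key = (phase, k)
        cho = self._cho_cache.get(key)
        if cho is None:
            a = cell.sigma + self.ridge * np.eye(self.m)
            try:
                cho = scipy.linalg.cho_factor(a, lower=True)
            except scipy.linalg.LinAlgError as exc:
                raise IllConditionedModelError(
                    f"cell ({phase.value}, k={k}) has a numerically singular "
                    f"regularized covariance"
                ) from exc
            self._cho_cache[key] = cho
        delta = x - cell.mu
        return float(max(delta @ scipy.linalg.cho_solve(cho, delta), 0.0))

    def check_contiguity(self) -> None:
        """Verify that each phase's timestep keys form 1..max_k."""
        for p in PHASE_ORDER:
            ks = sorted(k for (ph, k) in self.cells if ph == p)
            if ks and ks != list(range(1, ks[-1] + 1)):
                raise ModelFormatError(f"cells for phase {p.value} are not contiguous")

    # -- training continuation -------------------------------------------

    def update(self, measurements, phase_timesteps: Sequence[PhaseTimestep]) -> None:
        """Continue training with additional aligned frames (in place)."""
        measurements = np.asarray(measurements, dtype=float)
        for x, pt in zip(measurements, phase_timesteps):
            key = (pt.phase, pt.k)
            self.cells[key] = update_cell(self.cells.get(key), x)
            self.timing.phase_max_k[pt.phase] = max(
                self.timing.phase_max_k.get(pt.phase, 0), pt.k
            )
            self._cho_cache.pop(key, None)

    # -- reporting --------------------------------------------------------

    def summary(self) -> str:
        lines = [
            "Cyclostationary gait model",
            "==========================",
            f"channels (m):            {self.m}",
            f"sample interval dt:      {self.dt:.4g} s",
            f"ridge regularization:    {self.ridge:g} deg^2",
            f"training frames:         {self.metadata.get('n_frames', 'n/a')}",
            f"training duration:       {self.metadata.get('training_duration_s', float('nan')):.1f} s",
            f"gait cycles observed:    {self.timing.n_cycles}",
            f"cycle duration:          {self.timing.cycle_mean:.3f} +/- {self.timing.cycle_std:.3f} s",
            "",
            "phase   cells  steps_mean  steps_std",
        ]
        for p in PHASE_ORDER:
            lines.append(
                f"{p.value:5s}  {self.max_k(p):5d}  "
                f"{self.timing.phase_steps_mean.get(p, float('nan')):10.2f}  "
                f"{self.timing.phase_steps_std.get(p, float('nan')):9.2f}"
            )
        if self.warning_flags:
            lines += ["", "warnings:"] + [f"  - {w}" for w in self.warning_flags]
        return "\n".join(lines)

    # -- persistence -------------------------------------------------------

    def save(self, path) -> None:
        """Write the model to a human-readable JSON file."""
        payload = {
            "format_version": MODEL_FORMAT_VERSION,
            "m": self.m,
            "dt": self.dt,
            "ridge": self.ridge,
            "min_cell_count": self.min_cell_count,
            "reference_phase": self.reference_phase.value,
            "timing": {
                "phase_steps_mean": {p.value: v for p, v in self.timing.phase_steps_mean.items()},
                "phase_steps_std": {p.value: v for p, v in self.timing.phase_steps_std.items()},
                "phase_max_k": {p.value: v for p, v in self.timing.phase_max_k.items()},
                "cycle_mean": self.timing.cycle_mean,
                "cycle_std": self.timing.cycle_std,
                "n_cycles": self.timing.n_cycles,
            },
            "warning_flags": self.warning_flags,
            "metadata": self.metadata,
            "cells": [
                {
                    "phase": p.value,
                    "k": k,
                    "n": c.n,
                    "mu": c.mu.tolist(),
                    "sigma": c.sigma.tolist(),
                }
                for (p, k), c in sorted(
                    self.cells.items(), key=lambda it: (it[0][0].value, it[0][1])
                )
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "GaitModelResults":
        """Load a model written by :meth:`save` (lossless round-trip)."""
        with open(path) as fh:
            try:
                payload = json.load(fh)
            except json.JSONDecodeError as exc:
                raise ModelFormatError(f"model file is not valid JSON: {exc}") from exc
        if payload.get("format_version") != MODEL_FORMAT_VERSION:
            raise ModelFormatError(
                f"unsupported model format version {payload.get('format_version')!r}"
            )
        for req in ("m", "dt", "timing", "cells"):
            if req not in payload:
                raise ModelFormatError(f"model file is missing the {req!r} block")
        m = int(payload["m"])
        cells = {}
        for rec in payload["cells"]:
            mu = np.asarray(rec["mu"], dtype=float)
            sigma = np.asarray(rec["sigma"], dtype=float)
            if mu.shape != (m,) or sigma.shape != (m, m):
                raise ModelFormatError(
                    f"cell ({rec.get('phase')}, {rec.get('k')}) has inconsistent shapes"
                )
            cells[(GaitPhase(rec["phase"]), int(rec["k"]))] = GaussianCell(
                int(rec["n"]), mu, sigma
            )
        t = payload["timing"]
        timing = PhaseTimingStats(
            {GaitPhase(p): float(v) for p, v in t["phase_steps_mean"].items()},
            {GaitPhase(p): float(v) for p, v in t["phase_steps_std"].items()},
            {GaitPhase(p): int(v) for p, v in t["phase_max_k"].items()},
            float(t["cycle_mean"]),
            float(t["cycle_std"]),
            int(t["n_cycles"]),
        )
        return cls(
            m=m,
            dt=float(payload["dt"]),
            cells=cells,
            timing=timing,
            reference_phase=GaitPhase(payload.get("reference_phase", "LDS")),
            ridge=float(payload.get("ridge", 1e-6)),
            min_cell_count=int(payload.get("min_cell_count", 3)),
            warning_flags=list(payload.get("warning_flags", [])),
            metadata=dict(payload.get("metadata", {})),
        )
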