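"""Evaluation machinery for the intent classifier.

Per-timestep scoring against speed-derived ground truth (3x3 confusion
matrix, one-vs-rest class metrics, macro F1), per-trial detection delays,
the threshold trade-off sweep, the model-convergence curve with
5 x IQR-from-median outlier removal, and the mean-distance-vs-speed-offset
regression.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from gaitintent.exceptions import InsufficientDataError, InvalidProtocolError
from gaitintent.identify import ClassifierConfig, IntentIdentifier, IntentLabel
from gaitintent.model import CyclostationaryGaitModel, GaitModelResults
from gaitintent.segmentation import PhaseTimestep, segment_stream
from gaitintent.synthetic import GaitTemplate, LabeledStream, Trial, constant_speed_profile, simulate

__all__ = [
    "ConfusionMatrix3",
    "ClassMetrics",
    "DelayRecord",
    "EvaluationReport",
    "ground_truth",
    "ground_truth_labels",
    "confusion",
    "class_counts",
    "metrics",
    "time_delays",
    "threshold_sweep",
    "convergence_curve",
    "remove_outliers_iqr",
    "md_by_speed_offset",
    "md_speed_regression",
    "evaluate_protocol",
]

_CLASSES = ("U", "D", "N")
_LABEL_TO_CLASS = {"SU": "U", "SD": "D", "NC": "N"}


def ground_truth(speed: float, baseline: float = 1.4, tolerance: float = 0.0) -> IntentLabel:
    """Ground-truth intent from the treadmill speed.

    Faster than baseline (beyond ``tolerance``) is SU, slower is SD,
    otherwise NC. The default zero tolerance is the literal speed-sign
    rule; note that during a return ramp (e.g. decelerating from 1.7
    toward 1.4) this still labels SU even though the user is slowing.
    """
    if speed > baseline + tolerance:
        return IntentLabel.SU
    if speed < baseline - tolerance:
        return IntentLabel.SD
    return IntentLabel.NC


def ground_truth_labels(speeds, baseline: float = 1.4, tolerance: float = 0.0) -> np.ndarray:
    """Vectorized :func:`ground_truth`; returns an array of 'SU'/'SD'/'NC'."""
    v = np.asarray(speeds, dtype=float)
    out = np.full(v.shape, "NC", dtype=object)
    out[v > baseline + tolerance] = "SU"
    out[v < baseline - tolerance] = "SD"
    return out


@dataclass
class ConfusionMatrix3:
    """3x3 confusion counts; rows = ground truth (U, D, N), cols = estimate."""

    counts: np.ndarray = field(default_factory=lambda: np.zeros((3, 3), dtype=int))

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (3, 3) or np.any(self.counts < 0):
            raise ValueError("confusion counts must be a nonnegative 3x3 matrix")

    def __getitem__(self, cell: str) -> int:
        """Cell by two-letter name, e.g. ``cm['DU']`` = truth D, estimate U."""
        truth, pred = cell[0], cell[1]
        return int(self.counts[_CLASSES.index(truth), _CLASSES.index(pred)])

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(_CLASSES), columns=list(_CLASSES))


def _as_class_array(labels) -> np.ndarray:
    out = []
    for lab in labels:
        if isinstance(lab, IntentLabel):
            lab = lab.value
        out.append(_LABEL_TO_CLASS.get(lab, lab))
    arr = np.asarray(out, dtype=object)
    bad = set(arr) - set(_CLASSES)
    if bad:
        raise ValueError(f"unknown labels: {sorted(bad)}")
    return arr


def confusion(pred_labels, truth_labels) -> ConfusionMatrix3:
    """Tabulate per-frame (truth, prediction) counts."""
    pred = _as_class_array(pred_labels)
    truth = _as_class_array(truth_labels)
    if len(pred) != len(truth):
        raise ValueError("prediction and truth sequences differ in length")
    counts = np.zeros((3, 3), dtype=int)
    for i, t in enumerate(_CLASSES):
        ti = truth == t
        for j, p in enumerate(_CLASSES):
            counts[i, j] = int(np.sum(ti & (pred == p)))
    return ConfusionMatrix3(counts)


def class_counts(cm: ConfusionMatrix3, cls: str) -> tuple[int, int, int, int]:
    """One-vs-rest (TP, TN, FP, FN) for class ``cls`` in {'U','D','N'}."""
    i = _CLASSES.index(cls)
    c = cm.counts
    tp = int(c[i, i])
    fp = int(c[:, i].sum() - c[i, i])
    fn = int(c[i, :].sum() - c[i, i])
    tn = int(c.sum() - tp - fp - fn)
    return tp, tn, fp, fn


@dataclass
class ClassMetrics:
    """Per-class precision/recall/F1/accuracy plus macro F1.

    Undefined ratios (0/0) are reported as 0 and listed in
    ``undefined_flags``.
    """

    per_class: dict[str, dict[str, float]]
    macro_f1: float
    undefined_flags: list[str] = field(default_factory=list)


def metrics(cm: ConfusionMatrix3) -> ClassMetrics:
    """One-vs-rest metrics for each class and the macro-averaged F1."""
    per_class = {}
    flags = []
    f1s = []
    for cls in _CLASSES:
        tp, tn, fp, fn = class_counts(cm, cls)
        if tp + fp == 0:
            precision = 0.0
            flags.append(f"{cls}:precision")
        else:
            precision = tp / (tp + fp)
        if tp + fn == 0:
            recall = 0.0
            flags.append(f"{cls}:recall")
        else:
            recall = tp / (tp + fn)
        if precision + recall == 0:
            f1 = 0.0
        else:
            f1 = 2 * precision * recall / (precision + recall)
        total = tp + tn + fp + fn
        accuracy = (tp + tn) / total if total else 0.0
        per_class[cls] = {
            "TP": tp, "TN": tn, "FP": fp, "FN": fn,
            "precision": precision, "recall": recall,
            "f1": f1, "accuracy": accuracy,
        }
        f1s.append(f1)
    return ClassMetrics(per_class, float(np.mean(f1s)), flags)


@dataclass
class DelayRecord:
    """Detection delay for one speed-change trial (missing if never correct)."""

    kind: str
    magnitude: float
    onset: float
    first_correct: Optional[float]
    delay: Optional[float]


def time_delays(
    labels, times, trials: Sequence[Trial]
) -> list[DelayRecord]:
    """Per-trial delay from speed-change onset to first correct-type label.

    The evaluation window for a trial runs from its onset until the
    treadmill is back at baseline; a trial with no correct label inside the
    window yields a missing delay (excluded from averages with a count).
    """
    labels = np.asarray([l.value if isinstance(l, IntentLabel) else l for l in labels], dtype=object)
    times = np.asarray(times, dtype=float)
    for a, b in zip(trials, list(trials)[1:]):
        if b.onset < a.return_time:
            raise InvalidProtocolError("trial windows overlap")
    records = []
    for tr in trials:
        in_window = (times >= tr.onset) & (times < tr.return_time)
        hit = in_window & (labels == tr.kind)
        if np.any(hit):
            t_first = float(times[np.argmax(hit)])
            records.append(DelayRecord(tr.kind, tr.magnitude, tr.onset, t_first, t_first - tr.onset))
        else:
            records.append(DelayRecord(tr.kind, tr.magnitude, tr.onset, None, None))
    return records


@dataclass
class EvaluationReport:
    """Confusion matrix, class metrics and per-trial delays for one run."""

    confusion: ConfusionMatrix3
    metrics: ClassMetrics
    delays: list[DelayRecord]

    @property
    def mean_delay(self) -> float:
        d = [r.delay for r in self.delays if r.delay is not None]
        return float(np.mean(d)) if d else float("nan")

    @property
    def n_missed_trials(self) -> int:
        return sum(1 for r in self.delays if r.delay is None)


def evaluate_protocol(
    stream: LabeledStream,
    results: GaitModelResults,
    trials: Sequence[Trial],
    config: Optional[ClassifierConfig] = None,
    phase_timesteps: Optional[Sequence[PhaseTimestep]] = None,
    baseline: float = 1.4,
    diagnostics: Optional[pd.DataFrame] = None,
) -> EvaluationReport:
    """Classify a protocol stream and score it against speed ground truth."""
    if diagnostics is None:
        diagnostics = IntentIdentifier(results, config).run(
            stream.frames, phase_timesteps
        )
    truth = ground_truth_labels(stream.frames["speed"].to_numpy(), baseline)
    cm = confusion(diagnostics["label"].to_numpy(), truth)
    return EvaluationReport(
        cm, metrics(cm), time_delays(diagnostics["label"], diagnostics["time"], trials)
    )


def threshold_sweep(
    stream: LabeledStream,
    results: GaitModelResults,
    thresholds: Sequence[float],
    trials: Sequence[Trial],
    config: Optional[ClassifierConfig] = None,
    phase_timesteps: Optional[Sequence[PhaseTimestep]] = None,
    baseline: float = 1.4,
) -> pd.DataFrame:
    """Trade-off table across squared-distance thresholds.

    For each threshold the full classify-and-evaluate pipeline is rerun;
    reported are 1 - macro F1, the mean delay over identified trials, the
    number of unidentified trials, and the count of frames with any active
    trigger.
    """
    thresholds = list(thresholds)
    if any(t <= 0 for t in thresholds) or sorted(thresholds) != thresholds:
        raise ValueError("thresholds must be positive and sorted ascending")
    base = config or ClassifierConfig(dt=results.dt)
    if phase_timesteps is None:
        phase_timesteps = segment_stream(stream.frames, dt=base.dt)
    rows = []
    for thr in thresholds:
        cfg = ClassifierConfig(
            squared_md_threshold=thr,
            filter_cutoff=base.filter_cutoff,
            dt=base.dt,
            timing_std_multiplier=base.timing_std_multiplier,
            ridge=base.ridge,
            reference_phase=base.reference_phase,
        )
        diag = IntentIdentifier(results, cfg).run(stream.frames, phase_timesteps)
        report = evaluate_protocol(
            stream, results, trials, cfg, phase_timesteps,
            baseline=baseline, diagnostics=diag,
        )
        flagged = int(
            (diag["trigger_md"] | diag["trigger_a"] | diag["trigger_b"]).sum()
        )
        rows.append(
            {
                "threshold": thr,
                "one_minus_macro_f1": 1.0 - report.metrics.macro_f1,
                "mean_delay": report.mean_delay,
                "n_missed_trials": report.n_missed_trials,
                "flagged_frames": flagged,
            }
        )
    return pd.DataFrame(rows)


def remove_outliers_iqr(values, multiplier: float = 5.0) -> np.ndarray:
    """Drop values beyond ``multiplier`` interquartile ranges from the median.

    Quartiles use linear interpolation between order statistics, so the
    rule is reproducible bit-for-bit.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if len(v) == 0:
        return v
    med = np.median(v)
    q25, q75 = np.percentile(v, [25, 75])
    iqr = q75 - q25
    return v[np.abs(v - med) <= multiplier * iqr]


def convergence_curve(
    stream: LabeledStream,
    durations: Sequence[float],
    config: Optional[ClassifierConfig] = None,
    phase_timesteps: Optional[Sequence[PhaseTimestep]] = None,
    iqr_multiplier: float = 5.0,
) -> pd.DataFrame:
    """Mean filtered squared distance of the training set vs training size.

    For each duration, a model is fitted on that prefix of the training
    stream and the *full* training stream is scored with the same real-time
    pipeline as classification (including the low-pass filter); values
    beyond ``iqr_multiplier`` IQRs from the median are dropped before the
    mean. The curve converging toward the channel count is the sign that
    the cyclostationary model has converged.
    """
    cfg = config or ClassifierConfig(dt=stream.dt)
    if phase_timesteps is None:
        phase_timesteps = segment_stream(stream.frames, dt=cfg.dt)
    total = len(stream.frames) * stream.dt
    rows = []
    for dur in durations:
        if dur > total + 1e-9:
            raise InsufficientDataError(
                f"requested training duration {dur} s exceeds the stream ({total:.1f} s)"
            )
        n = int(round(dur / stream.dt))
        prefix = stream.frames.iloc[:n]
        model = CyclostationaryGaitModel.from_dataframe(
            prefix,
            phase_timesteps=phase_timesteps[:n],
            dt=stream.dt,
            reference_phase=cfg.reference_phase,
        )
        results = model.fit()
        if results.timing.n_cycles < 1:
            raise InsufficientDataError(
                f"training duration {dur} s holds less than one gait cycle"
            )
        diag = IntentIdentifier(results, cfg).run(stream.frames, phase_timesteps)
        vals = diag["filtered_d2"].to_numpy(dtype=float)
        kept = remove_outliers_iqr(vals, iqr_multiplier)
        rows.append(
            {
                "duration": dur,
                "mean_squared_md": float(np.mean(kept)),
                "outlier_fraction": 1.0 - len(kept) / max(np.isfinite(vals).sum(), 1),
            }
        )
    return pd.DataFrame(rows)


def md_by_speed_offset(
    results: GaitModelResults,
    template: GaitTemplate,
    offsets: Sequence[float],
    duration: float = 60.0,
    seed: int = 0,
    config: Optional[ClassifierConfig] = None,
    iqr_multiplier: float = 5.0,
) -> pd.DataFrame:
    """Mean filtered squared distance at constant speeds off the baseline.

    Simulates ``duration`` seconds of constant walking at baseline + offset
    for each offset, scores it with the real-time pipeline against the
    baseline model, removes outliers, and reports the mean — the offline
    probe behind the distance-vs-speed regression.
    """
    cfg = config or ClassifierConfig(dt=results.dt)
    rows = []
    for j, dv in enumerate(offsets):
        speed = template.reference_speed + dv
        stream = simulate(
            template, constant_speed_profile(speed, duration), seed=seed + j
        )
        diag = IntentIdentifier(results, cfg).run(stream.frames)
        vals = diag["filtered_d2"].to_numpy(dtype=float)
        kept = remove_outliers_iqr(vals, iqr_multiplier)
        rows.append({"speed_offset": float(dv), "mean_squared_md": float(np.mean(kept))})
    return pd.DataFrame(rows)


def _ols(x: np.ndarray, y: np.ndarray) -> dict[str, float]:
    slope, intercept = np.polyfit(x, y, 1)
    yhat = slope * x + intercept
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return {"slope": float(slope), "intercept": float(intercept), "r2": r2}


def md_speed_regression(table: pd.DataFrame) -> dict[str, Optional[dict[str, float]]]:
    """Separate linear fits of mean squared distance vs speed offset.

    One ordinary-least-squares line for nonpositive offsets and one for
    nonnegative offsets (the zero-offset point belongs to both). A side
    with fewer than two points is omitted with a flag.
    """
    dv = table["speed_offset"].to_numpy(dtype=float)
    md = table["mean_squared_md"].to_numpy(dtype=float)
    out: dict[str, Optional[dict[str, float]]] = {"negative": None, "positive": None, "flags": []}
    for name, mask in (("negative", dv <= 0), ("positive", dv >= 0)):
        if mask.sum() >= 2:
            out[name] = _ols(dv[mask], md[mask])
        else:
            out["flags"].append(f"{name} side has fewer than 2 points; fit omitted")
    return out
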